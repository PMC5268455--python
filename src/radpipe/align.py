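"""Site-anchored color-space alignment of pre-processed RAD reads.

Pre-processed reads begin with the full recognition-site color signature, so
every genuine placement is anchored at a restriction site: a downstream read
covers ``ref[p : p+76]`` on the top strand and an upstream read covers the
reverse complement of ``ref[p-70 : p+6]``, where ``p`` is the site start.
Alignment therefore reduces to retrieving candidate anchors and comparing
colors.

Candidates are retrieved by exact k-color seed lookup in the reference color
string (seeds are taken at several offsets after the signature, so a single
color error cannot hide a placement), which also retrieves *novel* sites that
are absent from the in-silico catalog (restriction-site gains).  Comparison
happens in color space — a single color sequencing error stays a single
mismatch instead of corrupting all downstream bases the way a decoded-base
comparison would.

Filtering follows the two-tier scheme of RAD discovery pipelines: reads are
kept only when the best placement is unique (strictly better than the second
best) and its color identity is at least 0.90; mapping quality is
``min(60, 4 * (best_matches - second_best_matches))``, 60 when there is no
second candidate, 0 on a tie.  Summaries report unique alignments above and
below MapQ 10; genotyping downstream uses MapQ > 17.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .colorspace import ColorRead, encode
from .digest import RESiteCatalog

__all__ = [
    "AlignmentRecord",
    "ColorIndex",
    "build_index",
    "align_read",
    "align_reads",
    "call_bases",
    "BaseEvidence",
    "SamplePileup",
    "pileup_sample",
    "alignment_summary",
    "write_sam",
]

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASES = "ACGT"


def _revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


@dataclass
class AlignmentRecord:
    """Placement of one read at a restriction-site anchor."""

    read_id: str
    contig: str
    site_pos: int               # 0-based recognition-site start on the reference
    orientation: str            # "down" (top strand) | "up" (bottom strand)
    identity: float
    mapq: int
    unique: bool
    mismatch_positions: tuple[int, ...] = ()
    n_colors: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity must lie in [0, 1]")


@dataclass
class Rejection:
    read_id: str
    reason: str                 # "identity" | "ambiguous" | "unaligned" | "short"


class ColorIndex:
    """Exact k-color seed index over the reference color string.

    The reference color string of a contig has ``R[i] = color(ref[i],
    ref[i+1])``; a downstream read's color ``j >= 1`` equals ``R[p + j - 1]``
    and an upstream read's color ``j >= 1`` equals ``R[p + 5 - j]`` (site
    start ``p``, six-base recognition site), so both orientations are
    retrievable from one index.
    """

    def __init__(self, reference: dict[str, str], catalog: RESiteCatalog,
                 k: int = 16, seed_offsets: Sequence[int] = (6, 26, 46),
                 read_length: int = 76):
        if not 8 <= k <= 24:
            raise ValueError("seed length k must be between 8 and 24")
        self.reference = reference
        self.catalog = catalog
        self.k = k
        self.seed_offsets = tuple(seed_offsets)
        self.read_length = read_length
        self.enzyme = catalog.enzyme
        self.motif_len = len(self.enzyme.recognition)
        self.color_strings: dict[str, str] = {}
        self.seeds: dict[str, list[tuple[str, int]]] = {}
        for contig, seq in reference.items():
            if len(seq) < 2:
                continue
            colors = encode(seq[0], seq[1:])
            self.color_strings[contig] = colors
            for i in range(0, len(colors) - k + 1):
                self.seeds.setdefault(colors[i:i + k], []).append((contig, i))
        self._expected_cache: dict[tuple[str, int, str, int], Optional[str]] = {}

    # -- candidate generation ------------------------------------------------

    def candidates(self, colors: str) -> set[tuple[str, int, str]]:
        """(contig, site_pos, orientation) candidates for a read's colors."""
        out: set[tuple[str, int, str]] = set()
        k = self.k
        for a in self.seed_offsets:
            if a + k > len(colors):
                break
            seed = colors[a:a + k]
            for contig, q in self.seeds.get(seed, ()):
                out.add((contig, q - a + 1, "down"))
            for contig, q in self.seeds.get(seed[::-1], ()):
                out.add((contig, q + a + k - self.motif_len, "up"))
        return out

    def site_candidates(self) -> list[tuple[str, int, str]]:
        """Every catalog site in both orientations (always candidate anchors)."""
        out = []
        for contig, positions in self.catalog.sites.items():
            for p in positions:
                out.append((contig, int(p), "down"))
                out.append((contig, int(p), "up"))
        return out

    # -- expected read content at a placement --------------------------------

    def expected_bases(self, contig: str, site_pos: int, orientation: str,
                       n: int) -> Optional[str]:
        """Reference-implied base sequence of an n-color read at an anchor."""
        seq = self.reference.get(contig)
        if seq is None:
            return None
        m, p = self.motif_len, site_pos
        if orientation == "down":
            if p < 0 or p + n > len(seq):
                return None
            return seq[p:p + n]
        b = p + m
        if b - n < 0 or b > len(seq):
            return None
        return _revcomp(seq[b - n:b])

    def expected_colors(self, contig: str, site_pos: int, orientation: str,
                        n: int) -> Optional[str]:
        key = (contig, site_pos, orientation, n)
        hit = self._expected_cache.get(key, "?")
        if hit != "?":
            return hit
        bases = self.expected_bases(contig, site_pos, orientation, n)
        val = None if bases is None else encode("T", bases)
        self._expected_cache[key] = val
        return val


def build_index(reference: dict[str, str], catalog: RESiteCatalog,
                k: int = 16, **kw) -> ColorIndex:
    """Build the color-space seed index for a reference + site catalog."""
    return ColorIndex(reference, catalog, k=k, **kw)


def align_read(
    read: ColorRead,
    index: ColorIndex,
    min_identity: float = 0.90,
    min_length: int = 30,
):
    """Align one pre-processed read; returns AlignmentRecord or Rejection."""
    colors = read.colors
    n = len(colors)
    if n < min_length:
        return Rejection(read.id, "short")
    scored: list[tuple[int, tuple[str, int, str], tuple[int, ...]]] = []
    for contig, p, orient in index.candidates(colors):
        exp = index.expected_colors(contig, p, orient, n)
        if exp is None:
            continue
        mism = tuple(j for j in range(n) if colors[j] != exp[j])
        scored.append((n - len(mism), (contig, p, orient), mism))
    if not scored:
        return Rejection(read.id, "unaligned")
    scored.sort(key=lambda t: -t[0])
    best_score, (contig, p, orient), mism = scored[0]
    second = scored[1][0] if len(scored) > 1 else None
    if second is not None and second == best_score:
        return Rejection(read.id, "ambiguous")
    identity = best_score / n
    if identity < min_identity:
        return Rejection(read.id, "identity")
    if second is None:
        mapq = 60
    else:
        mapq = min(60, 4 * (best_score - second))
    return AlignmentRecord(
        read_id=read.id, contig=contig, site_pos=p, orientation=orient,
        identity=identity, mapq=mapq, unique=True,
        mismatch_positions=mism, n_colors=n)


def align_reads(reads: Iterable[ColorRead], index: ColorIndex,
                min_identity: float = 0.90):
    """Align a batch; returns (records, rejections) keeping read pairing."""
    records, rejections = [], []
    for read in reads:
        res = align_read(read, index, min_identity)
        if isinstance(res, AlignmentRecord):
            records.append((res, read))
        else:
            rejections.append(res)
    return records, rejections


# ---------------------------------------------------------------------------
# base evidence from color mismatches

@dataclass
class BaseEvidence:
    """Per-reference-position evidence extracted from one aligned read.

    ``alt_observations`` holds (ref_pos, base) for consistent adjacent
    color-mismatch pairs (true substitutions); ``ref_positions`` are the
    reference positions observed as reference base; positions touched by
    unexplained mismatches yield no observation but still count as covered.
    """

    contig: str
    ref_positions: list[int]
    alt_observations: list[tuple[int, str]]
    covered: tuple[int, int]    # half-open reference interval covered


def _read_index_to_ref(record: AlignmentRecord, motif_len: int, i: int) -> int:
    if record.orientation == "down":
        return record.site_pos + i
    return record.site_pos + motif_len - 1 - i


def call_bases(record: AlignmentRecord, read: ColorRead,
               index: ColorIndex) -> BaseEvidence:
    """Interpret color mismatches of an accepted alignment.

    Two adjacent mismatching colors whose implied substitution is
    self-consistent become one alternate-base observation; an isolated
    mismatch is a sequencing error (no observation at the two bases it
    touches); all other read bases are reference observations.
    """
    n = len(read.colors)
    m = index.motif_len
    exp_bases = index.expected_bases(record.contig, record.site_pos,
                                     record.orientation, n)
    mism = set(record.mismatch_positions)
    excluded: set[int] = set()      # read base indices without observation
    alt: list[tuple[int, str]] = []  # (read base index, read-frame base)
    handled: set[int] = set()
    for i in sorted(mism):
        if i in handled:
            continue
        pair = (i + 1 in mism) and (i + 2 not in mism) and (i - 1 not in mism)
        if pair:
            handled.update((i, i + 1))
            left = exp_bases[i - 1] if i > 0 else read.primer
            right = exp_bases[i + 1]
            b_left = _BASES[_BASE_INDEX[left] ^ int(read.colors[i])]
            b_right = _BASES[_BASE_INDEX[right] ^ int(read.colors[i + 1])]
            if b_left == b_right and b_left != exp_bases[i]:
                alt.append((i, b_left))
            else:
                excluded.update((i - 1, i, i + 1))
        else:
            # isolated mismatch, or part of a longer run: sequencing error /
            # uninterpretable — drop the touched bases
            handled.add(i)
            excluded.update((i - 1, i))
    alt_idx = {i for i, _ in alt}
    ref_positions = []
    for i in range(n):
        if i in excluded or i in alt_idx:
            continue
        ref_positions.append(_read_index_to_ref(record, m, i))
    alt_obs = []
    for i, b in alt:
        rp = _read_index_to_ref(record, m, i)
        base = b if record.orientation == "down" else _COMP[b]
        alt_obs.append((rp, base))
    lo = _read_index_to_ref(record, m, 0)
    hi = _read_index_to_ref(record, m, n - 1)
    return BaseEvidence(contig=record.contig, ref_positions=ref_positions,
                        alt_observations=alt_obs,
                        covered=(min(lo, hi), max(lo, hi) + 1))


# ---------------------------------------------------------------------------
# per-sample pileup

class SamplePileup:
    """Aggregated base evidence for one sample.

    ``depth[contig][pos]`` counts covering reads, ``ref_obs`` counts
    reference-base observations, and ``alt`` maps (contig, pos) to a Counter
    of alternate-base observations.
    """

    def __init__(self, contig_lengths: dict[str, int]):
        self.depth = {c: np.zeros(ln, dtype=np.int32)
                      for c, ln in contig_lengths.items()}
        self.ref_obs = {c: np.zeros(ln, dtype=np.int32)
                        for c, ln in contig_lengths.items()}
        self.alt: dict[tuple[str, int], Counter] = {}

    def add(self, ev: BaseEvidence) -> None:
        lo, hi = ev.covered
        d = self.depth[ev.contig]
        lo = max(lo, 0)
        hi = min(hi, len(d))
        d[lo:hi] += 1
        r = self.ref_obs[ev.contig]
        for p in ev.ref_positions:
            if 0 <= p < len(r):
                r[p] += 1
        for p, b in ev.alt_observations:
            if 0 <= p < len(d):
                self.alt.setdefault((ev.contig, p), Counter())[b] += 1


def pileup_sample(records_with_reads, index: ColorIndex,
                  mapq_min: int = 17) -> SamplePileup:
    """Build a pileup from (AlignmentRecord, ColorRead) pairs above MapQ."""
    pile = SamplePileup(index.catalog.contig_lengths)
    for record, read in records_with_reads:
        if record.mapq <= mapq_min:
            continue
        pile.add(call_bases(record, read, index))
    return pile


# ---------------------------------------------------------------------------
# reporting / SAM export

def alignment_summary(records, rejections, mapq_report: int = 10) -> dict[str, int]:
    """Counts of unique MapQ>cut, unique MapQ<=cut, and rejected reads."""
    hi = sum(1 for r, _ in records if r.mapq > mapq_report)
    lo = len(records) - hi
    return {
        f"unique_mapq_gt{mapq_report}": hi,
        f"unique_mapq_le{mapq_report}": lo,
        "rejected": len(rejections),
        "total": len(records) + len(rejections),
    }


def write_sam(records_with_reads, index: ColorIndex, path,
              sample: str = "sample") -> None:
    """Minimal SAM export of accepted alignments (color mismatches in CM tag)."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": c, "LN": ln}
               for c, ln in index.catalog.contig_lengths.items()],
        "RG": [{"ID": sample, "SM": sample}],
    }
    order = {c: i for i, c in enumerate(index.catalog.contig_lengths)}
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for record, read in records_with_reads:
            a = pysam.AlignedSegment(fh.header)
            a.query_name = record.read_id
            n = record.n_colors
            bases = index.expected_bases(record.contig, record.site_pos,
                                         record.orientation, n)
            a.query_sequence = bases or "*"
            a.flag = 16 if record.orientation == "up" else 0
            a.reference_id = order[record.contig]
            if record.orientation == "down":
                a.reference_start = record.site_pos
            else:
                a.reference_start = record.site_pos + index.motif_len - n
            a.mapping_quality = record.mapq
            a.cigarstring = f"{n}M"
            a.set_tag("CM", ",".join(map(str, record.mismatch_positions)) or "-")
            a.set_tag("CS", read.primer + read.colors)
            fh.write(a)
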