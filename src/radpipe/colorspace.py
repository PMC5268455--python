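"""SOLiD two-base color-space encoding and restriction-site read pre-processing.

SOLiD instruments report each read as a known primer base followed by a string
of color calls (0–3), where each color encodes the *transition* between two
adjacent bases rather than a base itself.  The dibase code is::

    color 0 = {AA, CC, GG, TT}     color 1 = {AC, CA, GT, TG}
    color 2 = {AG, GA, CT, TC}     color 3 = {AT, TA, CG, GC}

The code is symmetric (encode(x,y) == encode(y,x)) and, for a fixed first
base, the four colors map bijectively onto the four second bases, so a color
string plus an anchor base decodes uniquely.

RAD reads produced after a sticky-end ligation are expected to begin with the
enzyme's overhang sequence (GATCC for BamHI, ``T12320`` in color space).  The
pre-processing filter inspects that start signature, tolerates at most one
color error there, and rewrites the start with the *full* recognition-site
signature (``T102320``), lengthening each retained 75-color read to 76 colors.
Reads with more than one color error in the start signature are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence, TextIO

__all__ = [
    "ColorRead",
    "PreprocessResult",
    "encode",
    "decode",
    "classify_start",
    "preprocess",
    "preprocess_batch",
    "start_signature",
    "full_site_signature",
    "read_csfasta",
    "write_csfasta",
    "read_quals",
    "write_quals",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}

# color(x, y) = index(x) XOR index(y) under the A=0, C=1, G=2, T=3 ordering.
# This reproduces the dibase table exactly: identical bases -> 0,
# A<->C and G<->T -> 1, A<->G and C<->T -> 2, A<->T and C<->G -> 3.
def _color(x: str, y: str) -> int:
    return _BASE_INDEX[x] ^ _BASE_INDEX[y]


class InvalidSequenceError(ValueError):
    """Raised on characters outside A/C/G/T (ambiguity codes are rejected)."""


@dataclass
class ColorRead:
    """A SOLiD-style color-space read.

    Attributes
    ----------
    id : read identifier
    primer : the known synthesis primer base (single A/C/G/T)
    colors : ordered color calls, a string over {0,1,2,3}
    quals : optional Phred-like integer quality per color
    """

    id: str
    primer: str
    colors: str
    quals: Optional[list[int]] = None

    def __post_init__(self) -> None:
        if len(self.primer) != 1 or self.primer not in _BASES:
            raise InvalidSequenceError(f"invalid primer base {self.primer!r}")
        if not self.colors:
            raise ValueError("color string must be non-empty")
        if any(c not in "0123" for c in self.colors):
            raise ValueError(f"invalid color symbol in {self.colors!r}")
        if self.quals is not None and len(self.quals) != len(self.colors):
            raise ValueError("quality list length must match color string length")

    def __len__(self) -> int:
        return len(self.colors)


@dataclass
class PreprocessResult:
    """Outcome of the start-signature filter for one read.

    ``status`` is ``exact`` (no start errors), ``repaired`` (one start error,
    start rewritten) or ``discarded`` (more than one start error).
    ``mismatches`` counts color mismatches over the start signature.
    """

    status: str
    mismatches: int
    read: Optional[ColorRead] = None

    def __post_init__(self) -> None:
        if self.status not in ("exact", "repaired", "discarded"):
            raise ValueError(f"invalid status {self.status!r}")
        if (self.status == "discarded") != (self.read is None):
            raise ValueError("discarded results carry no read; retained results must")


def encode(primer: str, seq: str) -> str:
    """Encode a base sequence into color space, anchored at ``primer``.

    Returns one color per base of ``seq``; the first color encodes the
    primer-to-first-base transition.  Ambiguity codes are rejected.
    """
    if len(primer) != 1 or primer not in _BASES:
        raise InvalidSequenceError(f"invalid primer base {primer!r}")
    if not seq:
        raise InvalidSequenceError("sequence must be non-empty")
    out = []
    prev = primer
    for b in seq:
        if b not in _BASE_INDEX:
            raise InvalidSequenceError(f"invalid base {b!r} (ambiguity codes rejected)")
        out.append(str(_color(prev, b)))
        prev = b
    return "".join(out)


def decode(primer: str, colors: str) -> str:
    """Decode a color string back to bases; inverse of :func:`encode`."""
    if len(primer) != 1 or primer not in _BASES:
        raise InvalidSequenceError(f"invalid primer base {primer!r}")
    out = []
    prev = _BASE_INDEX[primer]
    for c in colors:
        if c not in "0123":
            raise ValueError(f"invalid color symbol {c!r}")
        prev ^= int(c)
        out.append(_BASES[prev])
    return "".join(out)


def start_signature(enzyme=None, primer: str = "T") -> str:
    """Color signature a raw read is expected to start with.

    Derived from the enzyme's sticky-end sequence (default BamHI GATCC,
    giving ``12320`` with primer T).
    """
    sticky = "GATCC" if enzyme is None else enzyme.sticky_end
    return encode(primer, sticky)


def full_site_signature(enzyme=None, primer: str = "T") -> str:
    """Color signature of the full recognition site (``102320`` for BamHI)."""
    recognition = "GGATCC" if enzyme is None else enzyme.recognition
    return encode(primer, recognition)


def classify_start(read: ColorRead, signature: str) -> int:
    """Hamming distance between the read's leading colors and ``signature``."""
    if len(read.colors) < len(signature):
        raise ValueError(
            f"read {read.id!r} shorter ({len(read.colors)}) than signature "
            f"({len(signature)})"
        )
    return sum(a != b for a, b in zip(read.colors, signature))


def preprocess(
    read: ColorRead,
    enzyme=None,
    max_start_errors: int = 1,
    primer: str = "T",
) -> PreprocessResult:
    """Apply the restriction-site start filter to one read.

    Reads whose leading colors are within ``max_start_errors`` of the
    sticky-end signature have their start replaced by the full-site signature
    (one color longer); others are discarded.
    """
    sig = start_signature(enzyme, primer)
    full = full_site_signature(enzyme, primer)
    mism = classify_start(read, sig)
    if mism > max_start_errors:
        return PreprocessResult(status="discarded", mismatches=mism)
    new_colors = full + read.colors[len(sig):]
    quals = None
    if read.quals is not None:
        # the rewritten start is synthetic; give it the read's max quality
        pad = [max(read.quals)] * len(full)
        quals = pad + list(read.quals[len(sig):])
    out = ColorRead(id=read.id, primer=primer, colors=new_colors, quals=quals)
    status = "exact" if mism == 0 else "repaired"
    return PreprocessResult(status=status, mismatches=mism, read=out)


@dataclass
class PreprocessSummary:
    """Batch accounting for the start filter (counts and fractions)."""

    exact: int = 0
    repaired: int = 0
    discarded: int = 0
    results: list[PreprocessResult] = field(default_factory=list, repr=False)

    @property
    def total(self) -> int:
        return self.exact + self.repaired + self.discarded

    @property
    def retained(self) -> int:
        return self.exact + self.repaired

    def fractions(self) -> dict[str, float]:
        t = self.total or 1
        return {
            "exact": self.exact / t,
            "repaired": self.repaired / t,
            "discarded": self.discarded / t,
        }


def preprocess_batch(
    reads: Iterable[ColorRead],
    enzyme=None,
    max_start_errors: int = 1,
    primer: str = "T",
    keep_results: bool = True,
) -> PreprocessSummary:
    """Run :func:`preprocess` over a batch, tallying exact/repaired/discarded."""
    summary = PreprocessSummary()
    for read in reads:
        res = preprocess(read, enzyme, max_start_errors, primer)
        setattr(summary, res.status, getattr(summary, res.status) + 1)
        if keep_results:
            summary.results.append(res)
    return summary


# ---------------------------------------------------------------------------
# csfasta-style I/O: header line, then primer base immediately followed by the
# color digits ("T12320...").  Qualities travel in a parallel file of
# space-separated integers under the same headers.

def read_csfasta(handle: TextIO) -> Iterator[ColorRead]:
    """Iterate ColorReads from a csfasta-style stream (no qualities)."""
    rid = None
    for line in handle:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith(">"):
            rid = line[1:].split()[0]
        else:
            if rid is None:
                raise ValueError("sequence line before any header")
            yield ColorRead(id=rid, primer=line[0], colors=line[1:])
            rid = None


def write_csfasta(reads: Iterable[ColorRead], handle: TextIO) -> int:
    """Write reads in the csfasta-style dialect; returns the count written."""
    n = 0
    for r in reads:
        handle.write(f">{r.id}\n{r.primer}{r.colors}\n")
        n += 1
    return n


def read_quals(handle: TextIO) -> Iterator[tuple[str, list[int]]]:
    """Iterate (read id, qualities) pairs from a parallel quality file."""
    rid = None
    for line in handle:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith(">"):
            rid = line[1:].split()[0]
        else:
            if rid is None:
                raise ValueError("quality line before any header")
            yield rid, [int(x) for x in line.split()]
            rid = None


def write_quals(reads: Iterable[ColorRead], handle: TextIO) -> int:
    n = 0
    for r in reads:
        if r.quals is None:
            continue
        handle.write(f">{r.id}\n{' '.join(map(str, r.quals))}\n")
        n += 1
    return n
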