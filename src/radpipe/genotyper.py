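"""Bayesian diploid genotype calling and multi-sample VCF merging.

Per-sample calls follow the standard diploid observation model: a read base
``b`` drawn from genotype ``{a1, a2}`` has likelihood ``P(b | {a1,a2}) =
(P(b|a1) + P(b|a2)) / 2`` with ``P(b|a) = 1-e`` when ``b = a`` and ``e/3``
otherwise; the genotype likelihood is the product over reads.  The prior over
(hom-ref, het, hom-alt) is the conventional population-genetics split
``(1 - 3θ/2, θ, θ/2)`` with heterozygosity prior θ; the call is the genotype
with the greatest posterior probability, with ties reported as missing.

Multi-sample merging emits a biallelic VCF site whenever at least one sample
has a non-reference call at depth >= ``dp_min`` (default 10); samples below
the depth floor at an emitted site are recorded as missing.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "GenotyperParams",
    "SampleCall",
    "genotype_likelihoods",
    "likelihoods_from_counts",
    "call_genotype",
    "call_site",
    "merge_samples",
    "write_vcf",
]

GENOTYPES = ("hom_ref", "het", "hom_alt")
_GT_FIELD = {"hom_ref": "0/0", "het": "0/1", "hom_alt": "1/1", "missing": "./."}


@dataclass(frozen=True)
class GenotyperParams:
    """Error rate e, heterozygosity prior theta, and merge depth floor."""

    error_rate: float = 0.01
    theta: float = 0.001
    dp_min: int = 10

    def __post_init__(self) -> None:
        if not 0.0 < self.error_rate < 0.5:
            raise ValueError("error rate must lie in (0, 0.5)")
        if not 0.0 < self.theta < 0.1:
            raise ValueError("theta must lie in (0, 0.1)")
        if self.dp_min < 1:
            raise ValueError("dp_min must be >= 1")

    def priors(self) -> tuple[float, float, float]:
        return (1.0 - 1.5 * self.theta, self.theta, 0.5 * self.theta)


@dataclass
class SampleCall:
    """One sample's genotype at one site."""

    contig: str
    pos: int                    # 1-based
    ref: str
    alt: str
    genotype: str               # hom_ref | het | hom_alt | missing
    depth: int
    gq: int
    likelihoods: tuple[float, float, float]


def genotype_likelihoods(
    observations: Sequence[str], ref: str, alt: str, e: float = 0.01,
) -> tuple[float, float, float]:
    """Log10 likelihoods of (ref/ref, ref/alt, alt/alt) given observed bases.

    Observations outside A/C/G/T are skipped with a warning; an empty list
    after skipping is an error.
    """
    if not observations:
        raise ValueError("no observations")
    obs = []
    for b in observations:
        if b not in "ACGT":
            warnings.warn(f"skipping non-ACGT observation {b!r}")
            continue
        obs.append(b)
    if not obs:
        raise ValueError("no valid observations after skipping")

    def p_base_given_allele(b: str, a: str) -> float:
        return 1.0 - e if b == a else e / 3.0

    out = []
    for a1, a2 in ((ref, ref), (ref, alt), (alt, alt)):
        ll = 0.0
        for b in obs:
            p = 0.5 * p_base_given_allele(b, a1) + 0.5 * p_base_given_allele(b, a2)
            ll += math.log10(p)
        out.append(ll)
    return tuple(out)


def likelihoods_from_counts(
    n_ref: int, n_alt: int, e: float = 0.01,
) -> tuple[float, float, float]:
    """Count-based shortcut of :func:`genotype_likelihoods` (same model)."""
    if n_ref + n_alt == 0:
        raise ValueError("no observations")
    l_match = math.log10(1.0 - e)
    l_mis = math.log10(e / 3.0)
    l_het_ref = math.log10(0.5 * (1.0 - e) + 0.5 * e / 3.0)
    hom_ref = n_ref * l_match + n_alt * l_mis
    het = (n_ref + n_alt) * l_het_ref
    hom_alt = n_alt * l_match + n_ref * l_mis
    return (hom_ref, het, hom_alt)


def call_genotype(
    log10_likelihoods: Sequence[float], theta: float = 0.001,
) -> tuple[str, int, tuple[float, float, float]]:
    """Posterior-mode genotype, GQ, and normalized posterior triple.

    GQ is the Phred-scaled posterior gap between the best and second-best
    genotype (capped at 99).  Exact posterior ties and degenerate
    likelihoods give a missing call.
    """
    ll = np.asarray(log10_likelihoods, dtype=float)
    if len(ll) != 3 or not np.all(np.isfinite(ll)):
        return "missing", 0, (math.nan,) * 3
    priors = np.array([1.0 - 1.5 * theta, theta, 0.5 * theta])
    logpost = ll + np.log10(priors)
    post = 10.0 ** (logpost - logpost.max())
    total = post.sum()
    if total == 0:
        return "missing", 0, (math.nan,) * 3
    post /= total
    order = np.argsort(logpost)[::-1]
    if logpost[order[0]] == logpost[order[1]]:
        return "missing", 0, tuple(post)
    gq = min(99, int(round(10.0 * (logpost[order[0]] - logpost[order[1]]))))
    return GENOTYPES[order[0]], gq, tuple(post)


def call_site(
    n_ref: int, n_alt: int, params: GenotyperParams = GenotyperParams(),
) -> tuple[str, int, tuple[float, float, float]]:
    """Genotype call from ref/alt observation counts."""
    ll = likelihoods_from_counts(n_ref, n_alt, params.error_rate)
    gt, gq, post = call_genotype(ll, params.theta)
    return gt, gq, ll


# ---------------------------------------------------------------------------
# multi-sample merge

@dataclass
class VcfRecord:
    contig: str
    pos: int                    # 1-based
    ref: str
    alt: str
    calls: dict                 # sample -> (gt string, DP, GQ, PL triple)


def merge_samples(
    pileups: Mapping[str, "SamplePileup"],
    reference: Mapping[str, str],
    params: GenotyperParams = GenotyperParams(),
) -> list[VcfRecord]:
    """Merge per-sample pileups into biallelic multi-sample records.

    A site is emitted iff at least one sample makes a non-reference call
    with depth >= ``params.dp_min``.  Sites with substantial evidence for a
    second alternate allele are dropped with a warning (biallelic records
    only).  Samples below the depth floor are missing.
    """
    from collections import Counter

    positions: dict[tuple[str, int], Counter] = {}
    for pile in pileups.values():
        for (contig, pos), counts in pile.alt.items():
            positions.setdefault((contig, pos), Counter()).update(counts)

    records: list[VcfRecord] = []
    for (contig, pos) in sorted(positions):
        ref_base = reference[contig][pos]
        counts = positions[(contig, pos)]
        counts.pop(ref_base, None)
        if not counts:
            continue
        ranked = counts.most_common()
        alt = ranked[0][0]
        if len(ranked) > 1 and ranked[1][1] >= 2 and \
                ranked[1][1] >= 0.2 * ranked[0][1]:
            warnings.warn(
                f"dropping multi-allelic site {contig}:{pos + 1} "
                f"({ref_base}->{[b for b, _ in ranked]})")
            continue
        calls = {}
        any_variant = False
        for sample, pile in pileups.items():
            dp = int(pile.depth[contig][pos])
            n_ref = int(pile.ref_obs[contig][pos])
            n_alt = int(pile.alt.get((contig, pos), Counter()).get(alt, 0))
            if dp < params.dp_min or n_ref + n_alt == 0:
                calls[sample] = ("missing", dp, 0, None)
                continue
            gt, gq, ll = call_site(n_ref, n_alt, params)
            pl = _phred_scaled(ll)
            calls[sample] = (gt, dp, gq, pl)
            if gt in ("het", "hom_alt"):
                any_variant = True
        if any_variant:
            records.append(VcfRecord(contig=contig, pos=pos + 1, ref=ref_base,
                                     alt=alt, calls=calls))
    return records


def _phred_scaled(log10_likelihoods) -> tuple[int, int, int]:
    ll = np.asarray(log10_likelihoods, dtype=float)
    pl = -10.0 * (ll - ll.max())
    return tuple(int(round(x)) for x in pl)


def write_vcf(
    records: Iterable[VcfRecord],
    samples: Sequence[str],
    handle,
    contig_lengths: Optional[Mapping[str, int]] = None,
) -> int:
    """Write records as VCF v4.2 with GT:DP:GQ:PL fields; returns count."""
    handle.write("##fileformat=VCFv4.2\n")
    handle.write("##source=radpipe\n")
    if contig_lengths:
        for c, ln in contig_lengths.items():
            handle.write(f"##contig=<ID={c},length={ln}>\n")
    handle.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    handle.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
    handle.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
    handle.write('##FORMAT=<ID=PL,Number=G,Type=Integer,Description="Phred-scaled likelihoods">\n')
    handle.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" +
                 "\t".join(samples) + "\n")
    n = 0
    for rec in records:
        fields = [rec.contig, str(rec.pos), ".", rec.ref, rec.alt, ".", "PASS",
                  ".", "GT:DP:GQ:PL"]
        for s in samples:
            gt, dp, gq, pl = rec.calls.get(s, ("missing", 0, 0, None))
            if gt == "missing" or pl is None:
                fields.append(f"./.:{dp}:.:.")
            else:
                fields.append(f"{_GT_FIELD[gt]}:{dp}:{gq}:{','.join(map(str, pl))}")
        handle.write("\t".join(fields) + "\n")
        n += 1
    return n
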