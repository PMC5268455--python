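"""RAD-site recovery accounting, depth-bias diagnostics, SNP-density summaries.

A restriction site is *recovered* when the aligned reads anchored at it reach
a depth threshold (default 10 across samples); recovered sites are classified
as predicted (present in the in-silico digest of the reference) or
unpredicted (restriction-site gains in the panel), separately for nuclear and
organellar contigs.  Depth diagnostics cover the up/downstream asymmetry of
RAD loci and the correlation between locus depth and the log-length of the
restriction fragment it reads into (a shearing/capture bias).  SNP density is
tiled in non-overlapping 500 kb bins per contig.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .digest import RESiteCatalog

__all__ = [
    "site_depth_table",
    "classify_sites",
    "depth_asymmetry",
    "depth_fraglen_correlation",
    "snp_density",
    "CorrelationResult",
]


@dataclass
class CorrelationResult:
    """Pearson correlation with p-value and sample size (r is NaN when the
    input is degenerate, e.g. zero-variance depth)."""

    r: float
    p_value: float
    n: int

    @property
    def available(self) -> bool:
        return not math.isnan(self.r)


def site_depth_table(records_by_sample: Mapping[str, Iterable]) -> pd.DataFrame:
    """Aggregate alignment records into per-site, per-sample locus depths.

    Returns a tidy frame with columns contig, site_pos, sample, up, down
    (read counts per RAD locus orientation).
    """
    rows: dict[tuple[str, int, str], list[int]] = {}
    for sample, records in records_by_sample.items():
        for rec in records:
            rec = rec[0] if isinstance(rec, tuple) else rec
            key = (rec.contig, rec.site_pos, sample)
            if key not in rows:
                rows[key] = [0, 0]
            rows[key][0 if rec.orientation == "up" else 1] += 1
    out = pd.DataFrame(
        [(c, p, s, u, d) for (c, p, s), (u, d) in rows.items()],
        columns=["contig", "site_pos", "sample", "up", "down"])
    return out.sort_values(["contig", "site_pos", "sample"]).reset_index(drop=True)


def classify_sites(
    depth_table: pd.DataFrame,
    catalog: RESiteCatalog,
    min_alignments: int = 10,
) -> pd.DataFrame:
    """Recovered-site classification: {predicted, unpredicted} x {nuclear,
    organellar} counts plus the total and predicted/unpredicted percentages.

    A site is recovered when its total alignment count (both RAD loci, all
    samples) reaches ``min_alignments``.
    """
    totals = depth_table.groupby(["contig", "site_pos"])[["up", "down"]].sum()
    totals = totals[(totals["up"] + totals["down"]) >= min_alignments]
    counts = {("predicted", "nuclear"): 0, ("predicted", "organellar"): 0,
              ("unpredicted", "nuclear"): 0, ("unpredicted", "organellar"): 0}
    cat_positions = {c: set(int(x) for x in pos)
                     for c, pos in catalog.sites.items()}
    for contig, pos in totals.index:
        predicted = int(pos) in cat_positions.get(contig, set())
        klass = catalog.contig_class.get(contig, "nuclear")
        counts[("predicted" if predicted else "unpredicted", klass)] += 1
    total = sum(counts.values())
    rows = [{"type": t, "contig_class": k, "count": v}
            for (t, k), v in counts.items()]
    table = pd.DataFrame(rows)
    table.attrs["total"] = total
    n_pred = counts[("predicted", "nuclear")] + counts[("predicted", "organellar")]
    table.attrs["predicted_pct"] = 100.0 * n_pred / total if total else math.nan
    table.attrs["unpredicted_pct"] = (100.0 * (total - n_pred) / total
                                      if total else math.nan)
    return table


def depth_asymmetry(
    depth_table: pd.DataFrame,
    depth_min: int = 10,
    sample_fraction: float = 0.8,
) -> pd.DataFrame:
    """Flag sites deep on exactly one side in most samples.

    A site is flagged when more than ``sample_fraction`` of its samples
    exceed ``depth_min`` reads at exactly one of the two RAD loci.
    Returns per-site rows with the flag and the one-sided sample fraction.
    """
    n_samples = depth_table["sample"].nunique()
    out = []
    for (contig, pos), grp in depth_table.groupby(["contig", "site_pos"]):
        one_sided = ((grp["up"] > depth_min) ^ (grp["down"] > depth_min)).sum()
        frac = one_sided / n_samples
        out.append({"contig": contig, "site_pos": pos,
                    "one_sided_fraction": frac,
                    "flagged": frac > sample_fraction})
    return pd.DataFrame(out)


def depth_fraglen_correlation(
    loci: pd.DataFrame,
    boundary: int = 10_000,
) -> dict[str, CorrelationResult]:
    """Pearson r between RAD-locus depth and log10 restriction-fragment length.

    ``loci`` needs columns ``depth`` and ``frag_len`` (the fragment on the
    side the locus reads into).  Returns results overall and stratified at
    the ``boundary`` (default 10 kb) fragment length.
    """
    def corr(sub: pd.DataFrame) -> CorrelationResult:
        if len(sub) < 3 or sub["depth"].nunique() < 2 or \
                sub["frag_len"].nunique() < 2:
            return CorrelationResult(math.nan, math.nan, len(sub))
        r, p = stats.pearsonr(sub["depth"], np.log10(sub["frag_len"]))
        return CorrelationResult(float(r), float(p), len(sub))

    return {
        "overall": corr(loci),
        "short": corr(loci[loci["frag_len"] < boundary]),
        "long": corr(loci[loci["frag_len"] >= boundary]),
    }


def snp_density(
    positions: pd.DataFrame,
    contig_lengths: Mapping[str, int],
    window: int = 500_000,
) -> tuple[pd.DataFrame, pd.DataFrame, CorrelationResult]:
    """Per-window SNP counts, per-contig totals, and the size correlation.

    ``positions`` needs columns ``contig`` and ``pos`` (1-based, sorted
    within contig; unsorted input is an error).  Windows tile each contig
    without overlap; the final partial window is kept.  Returns (bins frame,
    per-contig totals frame, Pearson r between contig length and SNP count).
    """
    bin_rows = []
    totals = []
    for contig, ln in contig_lengths.items():
        sub = positions.loc[positions["contig"] == contig, "pos"].to_numpy()
        if len(sub) and np.any(np.diff(sub) < 0):
            raise ValueError(f"positions on {contig} are not sorted")
        n_bins = max(1, math.ceil(ln / window))
        counts = np.zeros(n_bins, dtype=int)
        if len(sub):
            idx = np.minimum((sub - 1) // window, n_bins - 1)
            np.add.at(counts, idx, 1)
        for b in range(n_bins):
            bin_rows.append({"contig": contig, "bin_start": b * window,
                             "bin_end": min((b + 1) * window, ln),
                             "n_snps": int(counts[b])})
        totals.append({"contig": contig, "length": ln,
                       "n_snps": int(counts.sum())})
    bins = pd.DataFrame(bin_rows)
    per_contig = pd.DataFrame(totals)
    if len(per_contig) >= 3 and per_contig["n_snps"].nunique() > 1 and \
            per_contig["length"].nunique() > 1:
        r, p = stats.pearsonr(per_contig["length"], per_contig["n_snps"])
        corr = CorrelationResult(float(r), float(p), len(per_contig))
    else:
        corr = CorrelationResult(math.nan, math.nan, len(per_contig))
    return bins, per_contig, corr
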