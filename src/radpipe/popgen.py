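"""Genotype-matrix filtering, LD-kNNi imputation, diversity and LD statistics.

The analysis contract follows the standard discovery-panel workflow:
missingness filters (samples with > 50% missing, then loci with > 20%
missing), LD-kNN genotype imputation for the remaining gaps, a MAF >= 0.05
filter, and then per-subpopulation summaries — observed and (unbiased)
expected heterozygosity, the inbreeding coefficient F_IS = 1 - Ho/He,
private-allele counts, minor-allele-frequency spectra, LD decay as the
median genotype-correlation r² in 10 kb distance bins, and genotype
concordance between call sets.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "DiversityStats",
    "LDResult",
    "filter_matrix",
    "impute_ldknni",
    "maf_filter",
    "allele_frequencies",
    "diversity",
    "ld_decay",
    "maf_spectrum",
    "concordance",
    "read_vcf_matrix",
    "write_matrix_tsv",
    "read_matrix_tsv",
]

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Samples × loci diploid dosage matrix (0/1/2, -1 = missing).

    ``loci`` carries contig, pos (0-based), ref, alt per locus; ``subpop``
    maps sample name to its subpopulation label (cultivated | wild).
    """

    genotypes: np.ndarray
    samples: list[str]
    loci: pd.DataFrame
    subpop: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.samples), len(self.loci)):
            raise ValueError("genotype matrix shape must be samples x loci")
        if not np.isin(self.genotypes, [-1, 0, 1, 2]).all():
            raise ValueError("genotypes must be 0/1/2 or -1 (missing)")
        for contig, grp in self.loci.groupby("contig"):
            if np.any(np.diff(grp["pos"].to_numpy()) < 0):
                raise ValueError(f"loci positions unsorted within {contig}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def missing_mask(self) -> np.ndarray:
        return self.genotypes == MISSING

    def subset(self, sample_idx=None, locus_idx=None) -> "GenotypeMatrix":
        g = self.genotypes
        samples = self.samples
        loci = self.loci
        if sample_idx is not None:
            g = g[sample_idx]
            samples = [self.samples[i] for i in np.atleast_1d(sample_idx)]
        if locus_idx is not None:
            g = g[:, locus_idx]
            loci = self.loci.iloc[np.atleast_1d(locus_idx)].reset_index(drop=True)
        sub = None if self.subpop is None else self.subpop.loc[samples]
        return GenotypeMatrix(g.copy(), list(samples), loci, sub)

    def for_subpop(self, label: str) -> "GenotypeMatrix":
        if self.subpop is None:
            raise ValueError("no subpopulation labels attached")
        idx = [i for i, s in enumerate(self.samples) if self.subpop[s] == label]
        return self.subset(sample_idx=idx)


# ---------------------------------------------------------------------------
# filters

def filter_matrix(
    gm: GenotypeMatrix,
    sample_miss: float = 0.5,
    snp_miss: float = 0.2,
) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Missingness filters: samples first (rate > ``sample_miss``), then loci
    (rate > ``snp_miss`` computed on the retained samples).

    Returns the filtered matrix and a removal report.
    """
    if gm.n_samples == 0 or gm.n_loci == 0:
        raise ValueError("empty genotype matrix")
    miss = gm.missing_mask()
    sample_rate = miss.mean(axis=1)
    keep_s = np.flatnonzero(sample_rate <= sample_miss)
    if len(keep_s) == 0:
        raise ValueError("all samples removed by missingness filter")
    gm2 = gm.subset(sample_idx=keep_s)
    locus_rate = gm2.missing_mask().mean(axis=0)
    keep_l = np.flatnonzero(locus_rate <= snp_miss)
    out = gm2.subset(locus_idx=keep_l)
    report = {
        "samples_removed": gm.n_samples - len(keep_s),
        "loci_removed": gm.n_loci - len(keep_l),
        "samples_kept": len(keep_s),
        "loci_kept": len(keep_l),
    }
    return out, report


def allele_frequencies(gm: GenotypeMatrix) -> np.ndarray:
    """Alt-allele frequency per locus over non-missing genotypes (NaN when
    a locus is entirely missing)."""
    g = gm.genotypes.astype(float)
    g[g == MISSING] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(g, axis=0) / 2.0


def maf_filter(gm: GenotypeMatrix, maf_min: float = 0.05) -> GenotypeMatrix:
    """Remove loci with minor allele frequency strictly below ``maf_min``
    (a locus at exactly the threshold is retained)."""
    p = allele_frequencies(gm)
    maf = np.minimum(p, 1.0 - p)
    keep = np.flatnonzero(~np.isnan(maf) & (maf >= maf_min))
    return gm.subset(locus_idx=keep)


# ---------------------------------------------------------------------------
# LD-kNN imputation

def _pairwise_r2_with(g: np.ndarray, j: int) -> np.ndarray:
    """r² of locus j against every locus, pairwise-complete over samples."""
    n, m = g.shape
    target = g[:, j].astype(float)
    target[target == MISSING] = np.nan
    others = g.astype(float)
    others[others == MISSING] = np.nan
    out = np.full(m, np.nan)
    valid_t = ~np.isnan(target)
    for l in range(m):
        mask = valid_t & ~np.isnan(others[:, l])
        if mask.sum() < 3:
            continue
        x, y = target[mask], others[mask, l]
        sx, sy = x.std(), y.std()
        if sx == 0 or sy == 0:
            continue
        r = np.corrcoef(x, y)[0, 1]
        out[l] = r * r
    return out


def impute_ldknni(
    gm: GenotypeMatrix,
    k: int = 5,
    l: int = 20,
    eps: float = 1e-9,
) -> GenotypeMatrix:
    """LD-kNN genotype imputation (works with unordered markers).

    For each missing entry: rank the other loci by r² with the target locus,
    measure inter-sample distance over the top-``l`` loci (mean absolute
    dosage difference over pairwise non-missing loci), take the ``k``
    nearest samples with an observed genotype at the target locus, and
    impute the genotype with the largest Σ 1/(d+eps) weight.  Observed
    entries are never altered.
    """
    g = gm.genotypes.copy()
    n, m = g.shape
    if n < k + 1 or m < l + 1:
        raise ValueError("matrix too small for the requested k / l")
    if np.any((g == MISSING).all(axis=0)):
        raise ValueError("a locus is entirely missing")
    missing = np.argwhere(g == MISSING)
    if len(missing) == 0:
        return GenotypeMatrix(g, list(gm.samples), gm.loci.copy(),
                              gm.subpop)
    by_locus: dict[int, list[int]] = {}
    for s, j in missing:
        by_locus.setdefault(int(j), []).append(int(s))
    gf = g.astype(float)
    gf[gf == MISSING] = np.nan
    for j, sample_rows in by_locus.items():
        r2 = _pairwise_r2_with(g, j)
        r2[j] = np.nan
        order = np.argsort(-np.nan_to_num(r2, nan=-1.0))
        proxies = order[:l]
        observed = np.flatnonzero(g[:, j] != MISSING)
        sub = gf[:, proxies]
        for s in sample_rows:
            diff = np.abs(sub[observed] - sub[s])
            counts = np.sum(~np.isnan(diff), axis=1)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                d = np.nanmean(diff, axis=1)
            d[counts == 0] = np.inf
            nearest = observed[np.argsort(d)[:k]]
            dd = d[np.argsort(d)[:k]]
            weights: dict[int, float] = {}
            for t, dist in zip(nearest, dd):
                geno = int(g[t, j])
                w = 1.0 / (dist + eps) if np.isfinite(dist) else 0.0
                weights[geno] = weights.get(geno, 0.0) + w
            best = max(sorted(weights), key=lambda x: weights[x])
            g[s, j] = best
    return GenotypeMatrix(g, list(gm.samples), gm.loci.copy(), gm.subpop)


# ---------------------------------------------------------------------------
# diversity statistics

@dataclass
class DiversityStats:
    """Multilocus diversity summary for one subpopulation."""

    label: str
    n_samples: int
    n_loci: int
    ho: float                   # observed heterozygosity (mean het fraction)
    he: float                   # expected heterozygosity (unbiased by default)
    fis: float                  # 1 - mean(Ho)/mean(He) (ratio of averages)
    private_alleles: int
    fis_per_locus: float = math.nan  # mean of per-locus 1 - Ho/He


def _subpop_stats(g: np.ndarray, unbiased: bool) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus (Ho, He) for one subpopulation's dosage block."""
    gf = g.astype(float)
    gf[gf == MISSING] = np.nan
    n_obs = np.sum(~np.isnan(gf), axis=0)
    het = np.where(np.isnan(gf), np.nan, (gf == 1).astype(float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ho = np.nanmean(het, axis=0)
        p = np.nanmean(gf, axis=0) / 2.0
    he = 2.0 * p * (1.0 - p)
    if unbiased:
        two_n = 2.0 * n_obs
        with np.errstate(divide="ignore", invalid="ignore"):
            he = np.where(two_n > 1, two_n / (two_n - 1.0) * he, np.nan)
    return ho, he


def diversity(
    gm: GenotypeMatrix,
    unbiased: bool = True,
) -> dict[str, DiversityStats]:
    """Ho, He, F_IS and private-allele counts per subpopulation.

    Per locus: Ho = heterozygote fraction; He = 2n/(2n-1) * (1 - Σp²)
    (sample-size-corrected; set ``unbiased=False`` for the naive estimator).
    The multilocus F_IS is 1 - mean(Ho)/mean(He) (ratio of averages); the
    per-locus-averaged variant is also reported.  A private allele is a
    locus where an allele present in this subpopulation is absent from the
    other.
    """
    if gm.subpop is None:
        raise ValueError("diversity requires subpopulation labels")
    labels = list(dict.fromkeys(gm.subpop.loc[gm.samples]))
    blocks = {}
    for lab in labels:
        idx = [i for i, s in enumerate(gm.samples) if gm.subpop[s] == lab]
        if len(idx) < 2:
            raise ValueError(f"subpopulation {lab!r} has fewer than 2 samples")
        blocks[lab] = gm.genotypes[idx]
    freqs = {lab: _block_allele_presence(b) for lab, b in blocks.items()}
    out = {}
    for lab in labels:
        ho, he = _subpop_stats(blocks[lab], unbiased)
        ok = ~np.isnan(ho) & ~np.isnan(he)
        mean_ho = float(np.mean(ho[ok]))
        mean_he = float(np.mean(he[ok]))
        poly = ok & (he > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            fis_loc = 1.0 - ho[poly] / he[poly]
        pa = 0
        for other in labels:
            if other == lab:
                continue
            ref_here, alt_here = freqs[lab]
            ref_there, alt_there = freqs[other]
            pa += int(np.sum((alt_here & ~alt_there) | (ref_here & ~ref_there)))
        out[lab] = DiversityStats(
            label=lab, n_samples=blocks[lab].shape[0], n_loci=int(ok.sum()),
            ho=mean_ho, he=mean_he,
            fis=1.0 - mean_ho / mean_he if mean_he > 0 else math.nan,
            private_alleles=pa,
            fis_per_locus=float(np.mean(fis_loc)) if poly.any() else math.nan,
        )
    return out


def _block_allele_presence(g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per locus: (ref allele present, alt allele present) in a block."""
    valid = g != MISSING
    has_alt = np.any(valid & (g > 0), axis=0)
    has_ref = np.any(valid & (g < 2), axis=0)
    return has_ref, has_alt


def maf_spectrum(
    gm: GenotypeMatrix,
    bin_width: float = 0.05,
) -> pd.DataFrame:
    """Per-subpopulation MAF histogram in bins of ``bin_width``.

    Returns a frame with columns subpop, bin_low, bin_high, count, plus a
    ``low_maf_count`` attribute per subpop (loci with MAF < 0.1).
    """
    if gm.subpop is None:
        raise ValueError("maf_spectrum requires subpopulation labels")
    edges = np.arange(0.0, 0.5 + bin_width, bin_width)
    rows = []
    low_counts = {}
    for lab in dict.fromkeys(gm.subpop.loc[gm.samples]):
        sub = gm.for_subpop(lab)
        p = allele_frequencies(sub)
        maf = np.minimum(p, 1.0 - p)
        maf = maf[~np.isnan(maf)]
        counts, _ = np.histogram(maf, bins=edges)
        # histogram's last bin is closed on the right, matching MAF <= 0.5
        for i in range(len(edges) - 1):
            rows.append({"subpop": lab, "bin_low": edges[i],
                         "bin_high": edges[i + 1], "count": int(counts[i])})
        low_counts[lab] = int(np.sum(maf < 0.1))
    out = pd.DataFrame(rows)
    out.attrs["low_maf_count"] = low_counts
    return out


# ---------------------------------------------------------------------------
# LD decay

@dataclass
class LDResult:
    """Pairwise r² records and the binned decay curve for one panel."""

    pairs: pd.DataFrame         # columns: contig, pos_a, pos_b, distance, r2
    curve: pd.DataFrame         # columns: bin_low, bin_high, median_r2, n_pairs
    crossing_distance: float    # first bin (midpoint) with median r² < 0.2


def ld_decay(
    gm: GenotypeMatrix,
    bin_size: int = 10_000,
    maf_min: float = 0.05,
    max_distance: int = 500_000,
    max_pairs_per_locus: Optional[int] = None,
    r2_threshold: float = 0.2,
) -> LDResult:
    """LD decay: r² = squared Pearson correlation of dosages, same-contig
    pairs within ``max_distance``, median per half-open ``bin_size`` bin.

    Pairs with a monomorphic member (after the ``maf_min`` filter) are
    skipped; empty bins report NaN.  ``crossing_distance`` is the midpoint of
    the first bin whose median r² falls below ``r2_threshold`` (NaN when the
    curve never crosses).
    """
    work = maf_filter(gm, maf_min) if maf_min > 0 else gm
    g = work.genotypes.astype(float)
    g[g == MISSING] = np.nan
    rows = []
    for contig, grp in work.loci.groupby("contig"):
        idx = grp.index.to_numpy()
        pos = grp["pos"].to_numpy()
        for a_i in range(len(idx)):
            hi = np.searchsorted(pos, pos[a_i] + max_distance, side="right")
            partners = range(a_i + 1, hi)
            if max_pairs_per_locus is not None:
                partners = list(partners)[:max_pairs_per_locus]
            for b_i in partners:
                x, y = g[:, idx[a_i]], g[:, idx[b_i]]
                mask = ~np.isnan(x) & ~np.isnan(y)
                if mask.sum() < 3:
                    continue
                xs, ys = x[mask], y[mask]
                if xs.std() == 0 or ys.std() == 0:
                    continue
                r = np.corrcoef(xs, ys)[0, 1]
                rows.append((contig, int(pos[a_i]), int(pos[b_i]),
                             int(pos[b_i] - pos[a_i]), r * r))
    pairs = pd.DataFrame(rows, columns=["contig", "pos_a", "pos_b",
                                        "distance", "r2"])
    edges = np.arange(0, max_distance + bin_size, bin_size)
    curve_rows = []
    crossing = math.nan
    for i in range(len(edges) - 1):
        sel = pairs[(pairs["distance"] >= edges[i]) &
                    (pairs["distance"] < edges[i + 1])]
        med = float(sel["r2"].median()) if len(sel) else math.nan
        curve_rows.append({"bin_low": int(edges[i]), "bin_high": int(edges[i + 1]),
                           "median_r2": med, "n_pairs": len(sel)})
        if math.isnan(crossing) and not math.isnan(med) and med < r2_threshold:
            crossing = float((edges[i] + edges[i + 1]) / 2.0)
    curve = pd.DataFrame(curve_rows)
    return LDResult(pairs=pairs, curve=curve, crossing_distance=crossing)


# ---------------------------------------------------------------------------
# concordance

def concordance(
    callset_a: GenotypeMatrix,
    callset_b: GenotypeMatrix,
) -> tuple[float, pd.DataFrame]:
    """Fitted-genotype rate between two call sets on shared samples/loci.

    Rate = matching genotype pairs / compared pairs; entries missing in
    either set are excluded from both numerator and denominator.  Returns
    the rate and per-locus mismatch counts.
    """
    shared_samples = [s for s in callset_a.samples if s in set(callset_b.samples)]
    key_a = callset_a.loci.apply(lambda r: (r["contig"], r["pos"]), axis=1)
    key_b = callset_b.loci.apply(lambda r: (r["contig"], r["pos"]), axis=1)
    shared_keys = [k for k in key_a if k in set(key_b)]
    if not shared_samples or not shared_keys:
        raise ValueError("no shared samples/loci between call sets")
    ia = {k: i for i, k in enumerate(key_a)}
    ib = {k: i for i, k in enumerate(key_b)}
    sa = {s: i for i, s in enumerate(callset_a.samples)}
    sb = {s: i for i, s in enumerate(callset_b.samples)}
    rows_a = [sa[s] for s in shared_samples]
    rows_b = [sb[s] for s in shared_samples]
    compared = matched = 0
    detail = []
    for k in shared_keys:
        ga = callset_a.genotypes[rows_a, ia[k]]
        gb = callset_b.genotypes[rows_b, ib[k]]
        ok = (ga != MISSING) & (gb != MISSING)
        n_cmp = int(ok.sum())
        n_match = int(np.sum(ga[ok] == gb[ok]))
        compared += n_cmp
        matched += n_match
        detail.append({"contig": k[0], "pos": k[1], "compared": n_cmp,
                       "mismatches": n_cmp - n_match})
    if compared == 0:
        raise ValueError("zero comparable genotype pairs")
    return matched / compared, pd.DataFrame(detail)


# ---------------------------------------------------------------------------
# I/O

def read_vcf_matrix(path, subpop: Optional[Mapping[str, str]] = None,
                    ) -> GenotypeMatrix:
    """Load a VCF (v4.x, biallelic records) into a GenotypeMatrix."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, dosages = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        gts = var.gt_types  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        d = np.where(gts == 0, 0, np.where(gts == 1, 1,
                     np.where(gts == 3, 2, MISSING)))
        rows.append({"contig": var.CHROM, "pos": var.POS - 1,
                     "ref": var.REF, "alt": var.ALT[0]})
        dosages.append(d)
    loci = pd.DataFrame(rows, columns=["contig", "pos", "ref", "alt"])
    g = (np.array(dosages, dtype=np.int8).T if dosages
         else np.zeros((len(samples), 0), dtype=np.int8))
    sp = None
    if subpop is not None:
        sp = pd.Series({s: subpop[s] for s in samples}, name="subpop")
    return GenotypeMatrix(g, samples, loci, sp)


def write_matrix_tsv(gm: GenotypeMatrix, handle) -> None:
    handle.write("contig\tpos\tref\talt\t" + "\t".join(gm.samples) + "\n")
    for j in range(gm.n_loci):
        row = gm.loci.iloc[j]
        vals = "\t".join(str(int(x)) for x in gm.genotypes[:, j])
        handle.write(f"{row['contig']}\t{row['pos']}\t{row['ref']}\t"
                     f"{row['alt']}\t{vals}\n")


def read_matrix_tsv(handle, subpop: Optional[Mapping[str, str]] = None,
                    ) -> GenotypeMatrix:
    df = pd.read_csv(handle, sep="\t")
    samples = [c for c in df.columns if c not in ("contig", "pos", "ref", "alt")]
    g = df[samples].to_numpy(dtype=np.int8).T
    loci = df[["contig", "pos", "ref", "alt"]].copy()
    sp = None
    if subpop is not None:
        sp = pd.Series({s: subpop[s] for s in samples}, name="subpop")
    return GenotypeMatrix(g, samples, loci, sp)
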