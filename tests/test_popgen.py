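"""Genotype-matrix filtering, imputation, diversity and LD statistics."""

import io
import math

import numpy as np
import pandas as pd
import pytest

from radpipe import popgen, radsim
from radpipe.popgen import MISSING, GenotypeMatrix


def make_gm(genotypes, subpop=None, positions=None, contig="c1"):
    g = np.asarray(genotypes, dtype=np.int8)
    n, m = g.shape
    samples = [f"s{i}" for i in range(n)]
    pos = positions if positions is not None else np.arange(m) * 1000
    loci = pd.DataFrame({"contig": [contig] * m, "pos": pos,
                         "ref": ["A"] * m, "alt": ["G"] * m})
    sp = None
    if subpop is not None:
        sp = pd.Series(dict(zip(samples, subpop)), name="subpop")
    return GenotypeMatrix(g, samples, loci, sp)


# --- filtering ---------------------------------------------------------------

def test_filter_removes_high_missing_sample():
    g = np.zeros((3, 10), dtype=np.int8)
    g[0, :6] = MISSING                   # 60% missing sample
    gm, report = popgen.filter_matrix(make_gm(g))
    assert report["samples_removed"] == 1
    assert gm.n_samples == 2 and gm.n_loci == 10


def test_filter_toy_matrix_hand_enumeration():
    """4 samples x 6 loci with planted missingness: sample 0 (4/6 missing)
    goes first; locus rates recomputed on the remaining 3 samples remove
    exactly the loci with > 0.2 missing."""
    M = MISSING
    g = np.array([
        [M, M, M, M, 0, 0],
        [0, M, 0, 0, 0, 0],
        [0, 0, 0, 0, 0, 0],
        [0, 0, M, 0, 0, 0],
    ], dtype=np.int8)
    gm, report = popgen.filter_matrix(make_gm(g), sample_miss=0.5,
                                      snp_miss=0.2)
    assert report["samples_removed"] == 1
    # on samples 1..3: loci 1 and 2 each 1/3 missing -> removed
    assert report["loci_removed"] == 2
    assert gm.n_loci == 4 and gm.missing_mask().sum() == 0


def test_filter_no_missing_is_identity():
    g = np.ones((4, 5), dtype=np.int8)
    gm, report = popgen.filter_matrix(make_gm(g))
    assert (gm.genotypes == g).all()
    assert report["samples_removed"] == report["loci_removed"] == 0


def test_filter_all_samples_removed_errors():
    g = np.full((2, 4), MISSING, dtype=np.int8)
    with pytest.raises(ValueError):
        popgen.filter_matrix(make_gm(g))


# --- MAF filter --------------------------------------------------------------

def test_maf_filter_single_het_in_45_removed():
    g = np.zeros((45, 1), dtype=np.int8)
    g[0, 0] = 1                           # MAF = 1/90 ~ 0.011
    assert popgen.maf_filter(make_gm(g)).n_loci == 0


def test_maf_filter_exactly_at_threshold_retained():
    g = np.zeros((10, 1), dtype=np.int8)
    g[0, 0] = 1                           # MAF = 1/20 = 0.05 exactly
    assert popgen.maf_filter(make_gm(g), 0.05).n_loci == 1


def test_maf_filter_monomorphic_removed():
    g = np.zeros((10, 2), dtype=np.int8)
    g[:, 1] = 2
    assert popgen.maf_filter(make_gm(g)).n_loci == 0


# --- LD-kNN imputation -------------------------------------------------------

def test_impute_no_missing_is_identity():
    rng = np.random.default_rng(0)
    g = rng.integers(0, 3, size=(10, 30)).astype(np.int8)
    gm = make_gm(g)
    out = popgen.impute_ldknni(gm, k=3, l=5)
    assert (out.genotypes == g).all()


def test_impute_duplicated_locus_is_perfect_proxy():
    """A missing entry at a locus whose exact duplicate is present is
    imputed with the duplicate's value."""
    rng = np.random.default_rng(1)
    base = rng.integers(0, 3, size=(30, 25)).astype(np.int8)
    g = np.concatenate([base, base[:, :1]], axis=1)   # locus 25 == locus 0
    g[5, 25] = MISSING
    out = popgen.impute_ldknni(make_gm(g), k=5, l=3)
    assert out.genotypes[5, 25] == base[5, 0]


def test_impute_never_alters_observed_and_completes():
    gm = radsim.simulate_genotype_matrix(
        radsim.PopulationModel(n_cultivated=20, n_wild=20), n_loci=120, seed=4)
    rng = np.random.default_rng(5)
    g = gm.genotypes.copy()
    mask = rng.random(g.shape) < 0.1
    g[mask] = MISSING
    masked = GenotypeMatrix(g, gm.samples, gm.loci, gm.subpop)
    out = popgen.impute_ldknni(masked, k=5, l=20)
    assert (out.genotypes != MISSING).all()
    observed = ~mask
    assert (out.genotypes[observed] == gm.genotypes[observed]).all()


def test_impute_beats_modal_baseline():
    gm = radsim.simulate_genotype_matrix(
        radsim.PopulationModel(n_cultivated=25, n_wild=25), n_loci=200, seed=9)
    rng = np.random.default_rng(10)
    g = gm.genotypes.copy()
    mask = rng.random(g.shape) < 0.1
    g[mask] = MISSING
    out = popgen.impute_ldknni(GenotypeMatrix(g, gm.samples, gm.loci,
                                              gm.subpop), k=5, l=20)
    acc = np.mean(out.genotypes[mask] == gm.genotypes[mask])
    # per-locus modal genotype baseline
    modal_acc = []
    for j in range(g.shape[1]):
        col = g[:, j]
        obs = col[col != MISSING]
        if not (mask[:, j]).any():
            continue
        vals, counts = np.unique(obs, return_counts=True)
        modal = vals[np.argmax(counts)]
        modal_acc += list(gm.genotypes[mask[:, j], j] == modal)
    assert acc > np.mean(modal_acc)


def test_impute_all_missing_locus_errors():
    g = np.zeros((10, 25), dtype=np.int8)
    g[:, 3] = MISSING
    with pytest.raises(ValueError):
        popgen.impute_ldknni(make_gm(g), k=3, l=5)


# --- diversity ---------------------------------------------------------------

def test_diversity_all_het_locus_formulas():
    """An all-heterozygote locus in 10 samples: Ho = 1, unbiased
    He = (20/19) * 0.5, so the locus F_IS is negative."""
    g = np.ones((10, 1), dtype=np.int8)
    gm = make_gm(g, subpop=["a"] * 5 + ["b"] * 5)
    d = popgen.diversity(gm)
    he = (10 / 9) * 0.5                   # per subpop: n=5 -> 2n/(2n-1)=10/9
    for lab in ("a", "b"):
        assert d[lab].ho == pytest.approx(1.0)
        assert d[lab].he == pytest.approx(he)
        assert d[lab].fis < 0


def test_diversity_unbiased_he_brute_force_oracle():
    rng = np.random.default_rng(3)
    g = rng.integers(0, 3, size=(12, 40)).astype(np.int8)
    gm = make_gm(g, subpop=["a"] * 12)
    d = popgen.diversity(gm)["a"]
    hes = []
    for j in range(40):
        col = g[:, j]
        p = col.sum() / (2 * len(col))
        hes.append((2 * len(col) / (2 * len(col) - 1)) * 2 * p * (1 - p))
    assert d.he == pytest.approx(float(np.mean(hes)), abs=1e-12)


def test_diversity_hwe_population_fis_near_zero():
    rng = np.random.default_rng(6)
    p = rng.uniform(0.1, 0.9, size=5000)
    g = (rng.random((40, 5000)) < p).astype(np.int8) + \
        (rng.random((40, 5000)) < p).astype(np.int8)
    gm = make_gm(g, subpop=["a"] * 40)
    d = popgen.diversity(gm)["a"]
    assert abs(d.fis) < 0.02


def test_private_alleles_definition():
    # locus 0: alt only in subpop b; locus 1: segregating in both
    g = np.array([[0, 1],
                  [0, 1],
                  [1, 0],
                  [1, 1]], dtype=np.int8)
    gm = make_gm(g, subpop=["a", "a", "b", "b"])
    d = popgen.diversity(gm)
    assert d["b"].private_alleles == 1
    assert d["a"].private_alleles == 0


def test_diversity_requires_two_samples_per_subpop():
    g = np.zeros((3, 4), dtype=np.int8)
    gm = make_gm(g, subpop=["a", "a", "b"])
    with pytest.raises(ValueError):
        popgen.diversity(gm)


# --- LD ----------------------------------------------------------------------

def test_ld_duplicated_locus_r2_is_one():
    rng = np.random.default_rng(7)
    col = rng.integers(0, 3, size=(50, 1)).astype(np.int8)
    g = np.concatenate([col, col], axis=1)
    gm = make_gm(g, positions=[0, 5000])
    res = popgen.ld_decay(gm, maf_min=0.0)
    assert len(res.pairs) == 1
    assert res.pairs.iloc[0]["r2"] == pytest.approx(1.0)


def test_ld_independent_loci_mean_r2_near_1_over_n():
    rng = np.random.default_rng(8)
    n = 100
    g = (rng.random((n, 60)) < 0.5).astype(np.int8) + \
        (rng.random((n, 60)) < 0.5).astype(np.int8)
    gm = make_gm(g, positions=np.arange(60) * 100)
    res = popgen.ld_decay(gm, maf_min=0.0, max_distance=10_000)
    mean_r2 = res.pairs["r2"].mean()
    assert abs(mean_r2 - 1.0 / n) < 3.0 / n


def test_ld_r2_matches_brute_force_pearson():
    rng = np.random.default_rng(9)
    g = rng.integers(0, 3, size=(30, 10)).astype(np.int8)
    gm = make_gm(g, positions=np.arange(10) * 500)
    res = popgen.ld_decay(gm, maf_min=0.0)
    for _, row in res.pairs.iterrows():
        ja = gm.loci.index[gm.loci["pos"] == row["pos_a"]][0]
        jb = gm.loci.index[gm.loci["pos"] == row["pos_b"]][0]
        x, y = g[:, ja].astype(float), g[:, jb].astype(float)
        num = np.mean(x * y) - x.mean() * y.mean()
        r = num / (x.std() * y.std())
        assert row["r2"] == pytest.approx(r * r, abs=1e-12)


def test_ld_monomorphic_pairs_skipped_and_bins_half_open():
    g = np.zeros((20, 2), dtype=np.int8)
    g[:10, 0] = 1
    gm = make_gm(g, positions=[0, 10_000])   # locus 1 monomorphic
    res = popgen.ld_decay(gm, maf_min=0.0)
    assert len(res.pairs) == 0
    assert math.isnan(res.crossing_distance)


def test_ld_decay_direction_cultivated_vs_wild():
    gm = radsim.simulate_genotype_matrix(radsim.PopulationModel(),
                                         n_loci=400, seed=5)
    crossing = {}
    for lab in ("cultivated", "wild"):
        res = popgen.ld_decay(gm.for_subpop(lab), max_distance=200_000)
        x = res.crossing_distance
        crossing[lab] = math.inf if math.isnan(x) else x
    assert crossing["cultivated"] < crossing["wild"]


# --- concordance -------------------------------------------------------------

def test_concordance_identical_sets():
    rng = np.random.default_rng(11)
    g = rng.integers(0, 3, size=(7, 20)).astype(np.int8)
    rate, detail = popgen.concordance(make_gm(g), make_gm(g.copy()))
    assert rate == 1.0
    assert detail["mismatches"].sum() == 0


def test_concordance_validation_scale_construction():
    """7 samples x 148 loci with 145 planted mismatches reproduce the
    published validation arithmetic: (1036 - 145) / 1036 ~ 0.86."""
    rng = np.random.default_rng(12)
    g = rng.integers(0, 3, size=(7, 148)).astype(np.int8)
    other = g.copy()
    flat = rng.choice(g.size, size=145, replace=False)
    for idx in flat:
        s, j = divmod(idx, 148)
        other[s, j] = (g[s, j] + 1) % 3
    rate, _ = popgen.concordance(make_gm(g), make_gm(other))
    assert rate == pytest.approx((1036 - 145) / 1036)
    assert round(rate, 2) == 0.86


def test_concordance_missing_excluded_both_sides():
    g = np.zeros((2, 3), dtype=np.int8)
    h = g.copy()
    g[0, 0] = MISSING
    h[1, 1] = MISSING
    rate, detail = popgen.concordance(make_gm(g), make_gm(h))
    assert rate == 1.0
    assert detail["compared"].sum() == 4


def test_concordance_all_missing_errors():
    g = np.zeros((2, 2), dtype=np.int8)
    h = np.full((2, 2), MISSING, dtype=np.int8)
    with pytest.raises(ValueError):
        popgen.concordance(make_gm(g), make_gm(h))


# --- MAF spectrum ------------------------------------------------------------

def test_maf_spectrum_conservation_and_top_bin():
    g = np.ones((10, 4), dtype=np.int8)       # all het: MAF 0.5
    gm = make_gm(g, subpop=["a"] * 5 + ["b"] * 5)
    spec = popgen.maf_spectrum(gm)
    for lab in ("a", "b"):
        sub = spec[spec["subpop"] == lab]
        assert sub["count"].sum() == 4
        assert sub.iloc[-1]["count"] == 4     # single top bin
    assert spec.attrs["low_maf_count"] == {"a": 0, "b": 0}


def test_maf_spectrum_wild_low_maf_abundance():
    gm = radsim.simulate_genotype_matrix(radsim.PopulationModel(),
                                         n_loci=800, seed=13)
    pc = popgen.allele_frequencies(gm.for_subpop("cultivated"))
    pw = popgen.allele_frequencies(gm.for_subpop("wild"))
    low = lambda p: int(np.sum((np.minimum(p, 1 - p) > 0) &
                               (np.minimum(p, 1 - p) < 0.1)))
    assert low(pw) > low(pc)


# --- I/O ---------------------------------------------------------------------

def test_matrix_tsv_roundtrip():
    rng = np.random.default_rng(14)
    g = rng.integers(-1, 3, size=(6, 9)).astype(np.int8)
    gm = make_gm(g, subpop=["a"] * 3 + ["b"] * 3)
    buf = io.StringIO()
    popgen.write_matrix_tsv(gm, buf)
    buf.seek(0)
    back = popgen.read_matrix_tsv(buf, subpop=dict(gm.subpop))
    assert (back.genotypes == g).all()
    assert back.samples == gm.samples
    assert (back.loci["pos"] == gm.loci["pos"]).all()
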