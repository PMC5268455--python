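"""Synthetic-data generator for the RAD-seq pipeline, with ground truth.

The generator emulates the study design the pipeline targets: a germplasm
panel of two diploid subpopulations — a "cultivated" group (51 samples by
default) and a "wild" group (44 samples) — genotyped by restriction-site
associated sequencing on a color-space instrument.  Three stages:

``simulate_reference``
    A multi-contig reference with recognition sites planted at a requested
    density (accidental motif occurrences are scrubbed so the site catalog is
    exactly the planted set).

``simulate_population``
    A founder-haplotype mosaic model.  A small set of shared ancestral
    haplotypes is expanded by a copy-and-mutate chain into a founder pool per
    subpopulation (more founders for the cultivated group); each individual
    haplotype is a recombinant mosaic of founders, and wild homologs are
    drawn with correlation ``f_wild`` (excess homozygosity).  Mutations give
    SNP loci inside RAD windows, plus gain/loss alleles at recognition sites
    (gains become "unpredicted" recovered sites, losses become null alleles).
    The chain topology gives founder haplotypes genuine long-range allele
    correlation, so the extent of linkage disequilibrium in the two groups is
    controlled by their founder counts: fewer founders (wild) means slower LD
    decay, more founders (cultivated) means faster decay.

``simulate_library``
    Restriction digestion + sticky-end ligation + random shearing + biotin
    capture, reduced to its observable consequence: 75-color reads starting
    at the cut on both strands of every surviving site, with independent
    per-color errors, per-sample depth variation, and an optional shear-bias
    linking depth to restriction-fragment length.

Every read, genotype and site presence/absence is recorded in ``SimTruth``.
All randomness flows from one integer seed through named substreams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .colorspace import ColorRead, encode
from .digest import BAMHI, RESiteCatalog, RestrictionEnzyme, catalog as digest_catalog

__all__ = [
    "PopulationModel",
    "LibraryModel",
    "PopulationSim",
    "LibrarySim",
    "simulate_reference",
    "simulate_population",
    "simulate_library",
    "simulate_genotype_matrix",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


# ---------------------------------------------------------------------------
# models

@dataclass(frozen=True)
class PopulationModel:
    """Parameters of the two-subpopulation germplasm panel.

    Both founder pools are serial copy-and-mutate pedigrees hanging off a
    few shared ancestral haplotypes.  The cultivated group draws from many
    founders with a skewed usage distribution (popular parents) and
    accumulated more effective recombination; it carries most private-allele
    loci.  The wild group descends from few founders (a bottleneck: strong
    founder LD, slow decay), uses them evenly, has a rare-skewed allele
    frequency spectrum and an inbreeding coefficient ``f_wild``.
    """

    n_cultivated: int = 51
    n_wild: int = 44
    founders_cultivated: int = 24
    founders_wild: int = 4
    n_ancestral: int = 4                    # shared proto-haplotypes
    mutation_rate: float = 0.007            # SNP loci per bp of RAD window
    recombination: float = 150.0            # effective crossovers per contig per gamete
    recombination_wild_factor: float = 0.25  # wild history accumulated fewer crossovers
    f_wild: float = 0.02                    # homolog correlation in the wild group
    re_loss_rate: float = 0.05              # fraction of catalog sites with a loss allele
    re_gain_rate: float = 0.05              # gained sites per catalog site
    private_fraction_cultivated: float = 0.20
    private_fraction_wild: float = 0.01
    rare_wild_fraction: float = 0.30        # shared loci rare (1-3 carriers) in wild
    alpha_cultivated: Optional[float] = 2.0  # Dirichlet founder-usage concentration
    alpha_wild: Optional[float] = None       # None = exactly even founder usage

    def __post_init__(self) -> None:
        for r in (self.mutation_rate, self.f_wild, self.re_loss_rate,
                  self.re_gain_rate, self.private_fraction_cultivated,
                  self.private_fraction_wild, self.rare_wild_fraction):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if min(self.n_cultivated, self.n_wild) <= 0:
            raise ValueError("sample counts must be positive")
        if min(self.founders_cultivated, self.founders_wild, self.n_ancestral) < 2:
            raise ValueError("founder counts must be at least 2")


@dataclass(frozen=True)
class LibraryModel:
    """Library-prep and sequencing parameters.

    ``mean_depth`` is the expected read depth per RAD locus per sample;
    ``depth_dispersion`` is the coefficient of variation of the per-sample
    depth factor.  ``shear_bias`` links depth to the log-length of the
    restriction fragment a locus reads into (the capture-efficiency bias of
    shearing-based protocols).
    """

    read_length: int = 75                   # colors per raw read
    shear_min: int = 150
    shear_max: int = 350
    mean_depth: float = 20.0
    depth_dispersion: float = 0.3
    color_error_rate: float = 0.01
    shear_bias: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.shear_min < self.shear_max):
            raise ValueError("shear size range must be positive and ordered")
        if not 0.0 <= self.color_error_rate < 1.0:
            raise ValueError("color error rate must lie in [0, 1)")


# ---------------------------------------------------------------------------
# reference

def simulate_reference(
    n_contigs: int = 1,
    lengths: Sequence[int] = (1_000_000,),
    site_density: float = 1 / 8000.0,
    seed: int = 0,
    enzyme: RestrictionEnzyme = BAMHI,
    organellar: Sequence[str] = (),
    min_separation: int = 400,
) -> tuple[dict[str, str], RESiteCatalog]:
    """Random reference with recognition sites planted at ``site_density``.

    Accidental motif occurrences are scrubbed (one base mutated) so the
    emitted catalog is exactly the planted positions; sites sit on a jittered
    grid with at least ``min_separation`` bp between them.  Contigs are named
    chr1..chrN unless listed in ``organellar`` (those are appended and
    flagged organellar).
    """
    if len(lengths) == 1 and n_contigs > 1:
        lengths = list(lengths) * n_contigs
    if len(lengths) != n_contigs + len(organellar):
        raise ValueError("need one length per contig (nuclear + organellar)")
    if any(ln <= 0 for ln in lengths):
        raise ValueError("contig lengths must be positive")
    if site_density > 0 and 1.0 / site_density < min_separation:
        raise ValueError("site density too high: sites would overlap")
    rng = np.random.default_rng([seed, 101])
    names = [f"chr{i + 1}" for i in range(n_contigs)] + list(organellar)
    motif = enzyme.recognition
    genome: dict[str, str] = {}
    for name, ln in zip(names, lengths):
        arr = _BASES[rng.integers(0, 4, size=ln)]
        seq = arr.tobytes().decode()
        seq = _scrub_motif(seq, motif, rng)
        if site_density > 0:
            step = 1.0 / site_density
            positions = []
            x = step * rng.uniform(0.2, 1.0)
            while x + len(motif) + 1 < ln:
                positions.append(int(x))
                x += step * rng.uniform(0.6, 1.4)
            chars = list(seq)
            for p in positions:
                chars[p:p + len(motif)] = motif
            seq = "".join(chars)
            # planting may have created overlapping accidental matches nearby
            seq = _scrub_motif(seq, motif, rng, keep=set(positions))
        genome[name] = seq
    return genome, digest_catalog(genome, enzyme, organellar_contigs=organellar)


def _scrub_motif(seq: str, motif: str, rng, keep: set[int] = frozenset()) -> str:
    """Mutate one base inside every non-kept motif occurrence until none remain."""
    from .digest import find_sites as _find

    chars = list(seq)
    enz = RestrictionEnzyme("tmp", motif, 1)
    while True:
        hits = [p for p in _find("".join(chars), enz) if p not in keep]
        if not hits:
            return "".join(chars)
        for p in hits:
            i = p + int(rng.integers(0, len(motif)))
            old = chars[i]
            chars[i] = "ACGT"[int(rng.integers(0, 4))]
            if chars[i] == old:
                chars[i] = _COMP[old]


# ---------------------------------------------------------------------------
# founder pool: copy-and-mutate chain with shared ancestral haplotypes

class _FounderPool:
    """Ancestry bookkeeping for one subpopulation's founder haplotypes.

    Nodes 0..n_ancestral-1 are the shared proto-haplotypes; founders form a
    serial copy-and-mutate pedigree rooted at a random proto.  A locus whose
    mutation originates at node v is carried by exactly the founders
    descending from v (a suffix of the pedigree), which gives the founder
    pool hierarchical allele sharing and hence long-range LD.
    """

    def __init__(self, rng, n_ancestral: int, n_founders: int,
                 proto_parents: list[int]):
        self.n_ancestral = n_ancestral
        self.n_founders = n_founders
        parents = list(proto_parents)
        # serial pedigree: each founder descends from the previous one, so
        # mutation carrier sets are nested suffixes — founder LD is strong
        # and the menu of subtree frequencies is fully graduated (1/k steps)
        for i in range(n_founders):
            if i == 0:
                parents.append(int(rng.integers(0, n_ancestral)))
            else:
                parents.append(n_ancestral + i - 1)
        anc: list[set[int]] = []
        for node, par in enumerate(parents):
            s = {node} if par < 0 else anc[par] | {node}
            anc.append(s)
        self.ancestors = anc  # per node, set of ancestor node ids (incl. self)
        self.founder_nodes = list(range(n_ancestral, n_ancestral + n_founders))

    def carriers(self, origin: int) -> np.ndarray:
        """Boolean vector over founders carrying a mutation from ``origin``."""
        return np.array([origin in self.ancestors[f] for f in self.founder_nodes])


def _make_proto_parents(rng, n_ancestral: int) -> list[int]:
    return [-1] + [int(rng.integers(0, j)) for j in range(1, n_ancestral)]


def _usage_weights(rng, n_founders: int, alpha: Optional[float]) -> np.ndarray:
    """Founder-usage weights: Dirichlet(alpha) or exactly even when alpha
    is None (no usage preference)."""
    if alpha is None:
        return np.full(n_founders, 1.0 / n_founders)
    return rng.dirichlet(np.full(n_founders, alpha))


#: target-frequency Beta shapes: the cultivated pool keeps intermediate
#: frequencies (high heterozygosity), the wild pool is skewed toward rare
#: alleles (drift in small isolated populations); private loci are spread
#: (cultivated) or rare (wild)
_FREQ_SHAPES = {"shared_cultivated": (1.5, 1.5), "shared_wild": (0.7, 1.1),
                "private_cultivated": (1.4, 1.8), "private_wild": (0.4, 2.5)}
_ORIGIN_SOFTMAX_SIGMA = 0.06


def _weighted_descendant_fraction(pool: _FounderPool, weights: np.ndarray,
                                  nodes: Sequence[int]) -> np.ndarray:
    """Usage-weighted fraction of founders descending from each node."""
    out = np.zeros(len(nodes))
    for i, v in enumerate(nodes):
        mask = pool.carriers(v)
        out[i] = float(np.sum(weights[mask]))
    return out


def _pick_origin(rng, nodes: Sequence[int], fracs: np.ndarray,
                 p_target: float) -> int:
    """Soft nearest-frequency origin choice (spreads loci across subtrees)."""
    d = (fracs - p_target) ** 2
    w = np.exp(-d / (2.0 * _ORIGIN_SOFTMAX_SIGMA ** 2))
    if w.sum() <= 0:
        return int(nodes[int(np.argmin(d))])
    return int(rng.choice(nodes, p=w / w.sum()))


def _founder_alleles(rng, pool_c: _FounderPool, pool_w: _FounderPool,
                     locus_class: np.ndarray, w_c: np.ndarray,
                     w_w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Assign each locus an origin node and derive founder allele matrices.

    ``locus_class``: 0 = shared (segregating in both pools), 1 =
    private-cultivated, 2 = private-wild.  Each locus draws a target allele
    frequency per pool from that pool's Beta shape and settles on the chain
    node whose usage-weighted descendant fraction is closest (softly), so
    carrier sets remain subtrees of the founder chain (preserving founder
    LD) while the marginal frequency spectra are shaped per subpopulation.
    Returns (A_cult, A_wild) founder × locus.
    """
    n = len(locus_class)
    a_c = np.zeros((pool_c.n_founders, n), dtype=np.int8)
    a_w = np.zeros((pool_w.n_founders, n), dtype=np.int8)
    n_anc = pool_c.n_ancestral
    # proto 0 is ancestral to everything: excluded so loci segregate
    proto_nodes = list(range(1, n_anc)) if n_anc > 1 else []
    nodes_c = proto_nodes + pool_c.founder_nodes
    nodes_w = proto_nodes + pool_w.founder_nodes
    frac_c = _weighted_descendant_fraction(pool_c, w_c, nodes_c)
    frac_w = _weighted_descendant_fraction(pool_w, w_w, nodes_w)
    for j, cls in enumerate(locus_class):
        if cls in (0, 1):
            shape = "shared_cultivated" if cls == 0 else "private_cultivated"
            origin = _pick_origin(rng, nodes_c, frac_c, rng.beta(*_FREQ_SHAPES[shape]))
            a_c[:, j] = pool_c.carriers(origin)
        if cls in (0, 2):
            shape = "shared_wild" if cls == 0 else "private_wild"
            origin = _pick_origin(rng, nodes_w, frac_w, rng.beta(*_FREQ_SHAPES[shape]))
            a_w[:, j] = pool_w.carriers(origin)
    return a_c, a_w


# ---------------------------------------------------------------------------
# individuals: recombinant founder mosaics

def _mosaic(rng, positions: np.ndarray, contig_len: int, n_events: float,
            weights: np.ndarray) -> np.ndarray:
    """Founder id per locus for one gamete haplotype on one contig."""
    k = int(rng.poisson(n_events))
    cuts = np.sort(rng.uniform(0, contig_len, size=k))
    seg = np.searchsorted(cuts, positions)
    founders = rng.choice(len(weights), size=k + 1, p=weights)
    return founders[seg]


def _sample_haplotypes(rng, positions_by_contig, contig_lengths, alleles,
                       n_samples, recombination, weights, f_homolog):
    """Draw diploid haplotype allele vectors for one subpopulation.

    Returns an array (n_samples, 2, n_loci).  With probability ``f_homolog``
    per mosaic segment the second homolog copies the first homolog's founder,
    producing genome-wide excess homozygosity of that magnitude.
    """
    n_loci = sum(len(p) for p in positions_by_contig.values())
    out = np.zeros((n_samples, 2, n_loci), dtype=np.int8)
    for s in range(n_samples):
        off = 0
        for contig, pos in positions_by_contig.items():
            ln = contig_lengths[contig]
            f1 = _mosaic(rng, pos, ln, recombination, weights)
            f2 = _mosaic(rng, pos, ln, recombination, weights)
            if f_homolog > 0 and len(pos):
                # per-segment IBD: copy homolog-1's founder on a fraction of
                # the second homolog's segments
                k = int(rng.poisson(recombination))
                cuts = np.sort(rng.uniform(0, ln, size=k))
                seg = np.searchsorted(cuts, pos)
                ibd_seg = rng.random(k + 1) < f_homolog
                copy = ibd_seg[seg]
                f2 = np.where(copy, f1, f2)
            idx = np.arange(off, off + len(pos))
            out[s, 0, idx] = alleles[f1, idx]
            out[s, 1, idx] = alleles[f2, idx]
            off += len(pos)
    return out



def _apply_rare_wild(rng, hap_wild: np.ndarray, a_c: np.ndarray,
                     locus_class: np.ndarray, fraction: float) -> None:
    """Make a fraction of shared loci rare in the wild group.

    Wild allele frequencies are quantized by the small founder pool, so the
    rare tail of the wild spectrum (young variants carried by one or two
    individuals) is drawn at the haplotype level instead: the selected loci
    keep their cultivated frequencies but are carried by only 1-3 wild
    haplotypes.  Only loci segregating in the cultivated pool are eligible,
    so these loci never become wild private alleles.
    """
    if fraction <= 0:
        return
    cult_poly = (a_c.sum(axis=0) > 0) & (a_c.sum(axis=0) < a_c.shape[0])
    eligible = np.flatnonzero((locus_class == 0) & cult_poly)
    pick = eligible[rng.random(len(eligible)) < fraction]
    n, _, _ = hap_wild.shape
    for j in pick:
        hap_wild[:, :, j] = 0
        k = 1 + int(rng.integers(0, 3))
        carriers = rng.choice(n * 2, size=k, replace=False)
        for c in carriers:
            hap_wild[c // 2, c % 2, j] = 1


# ---------------------------------------------------------------------------
# population simulation

@dataclass
class PopulationSim:
    """A simulated germplasm panel with full ground truth (SimTruth).

    ``snp_loci`` rows: contig, pos (0-based), ref, alt.  ``genotypes`` is the
    samples × SNP-loci alt-dosage matrix.  ``sites`` rows: contig, pos,
    predicted (in the reference catalog), loss/gain locus indices.
    ``site_presence`` is samples × 2 haplotypes × sites (1 = site present).
    """

    reference: dict[str, str]
    catalog: RESiteCatalog
    model: PopulationModel
    enzyme: RestrictionEnzyme
    samples: list[str]
    subpop: pd.Series
    snp_loci: pd.DataFrame
    genotypes: np.ndarray
    hap_alleles: np.ndarray
    sites: pd.DataFrame
    site_presence: np.ndarray

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def truth_dosage_frame(self) -> pd.DataFrame:
        idx = pd.MultiIndex.from_frame(self.snp_loci[["contig", "pos"]])
        return pd.DataFrame(self.genotypes.T, index=idx, columns=self.samples)

    def haplotype_edits(self, sample_i: int, hap: int):
        """(pos -> alt base) edits per contig for one haplotype.

        RE-site loss/gain alleles are ordinary loci of the truth table
        (kind re_loss / re_gain), so all edits come from ``snp_loci``.
        """
        edits: dict[str, dict[int, str]] = {c: {} for c in self.reference}
        loci = self.snp_loci
        carried = np.flatnonzero(self.hap_alleles[sample_i, hap])
        for j in carried:
            edits[loci.at[j, "contig"]][int(loci.at[j, "pos"])] = loci.at[j, "alt"]
        return edits

    def presence_dosage(self) -> np.ndarray:
        """Samples × sites count of haplotypes carrying each site (0/1/2)."""
        return self.site_presence.sum(axis=1)


def _rad_windows(cat: RESiteCatalog, read_length: int):
    """Per contig, the union of intervals read from each site (both loci)."""
    m = len(cat.enzyme.recognition)
    windows: dict[str, list[tuple[int, int]]] = {}
    for contig, positions in cat.sites.items():
        ln = cat.contig_lengths[contig]
        iv = []
        for p in positions:
            iv.append((max(0, p - (read_length - m)), p))
            iv.append((p + m, min(ln, p + read_length)))
        windows[contig] = iv
    return windows


def simulate_population(
    reference: dict[str, str],
    cat: RESiteCatalog,
    model: PopulationModel = PopulationModel(),
    seed: int = 0,
    read_length: int = 75,
) -> PopulationSim:
    """Simulate the diploid panel on a reference + site catalog.

    SNP loci are placed inside RAD windows (the intervals reads cover around
    each catalog site) at ``model.mutation_rate`` per bp; recognition-site
    loss and gain alleles segregate like ordinary loci on the founder chain.
    """
    rng = np.random.default_rng([seed, 202])
    enzyme = cat.enzyme
    motif = enzyme.recognition

    # --- founder pools (shared protos)
    proto_parents = _make_proto_parents(rng, model.n_ancestral)
    pool_c = _FounderPool(rng, model.n_ancestral, model.founders_cultivated, proto_parents)
    pool_w = _FounderPool(rng, model.n_ancestral, model.founders_wild, proto_parents)

    # --- site table: catalog sites + gained sites (one-substitution motifs)
    site_rows = [
        {"contig": c, "pos": int(p), "predicted": True}
        for c in sorted(cat.sites) for p in cat.sites[c]
    ]
    n_gain = rng.poisson(model.re_gain_rate * cat.n_sites)
    gain_candidates = []
    for contig, seq in reference.items():
        tail = motif[1:]
        start = seq.find(tail)
        while start != -1:
            p = start - 1
            if p >= 0 and seq[p] != motif[0] and _clear_of_sites(p, cat.sites[contig], 200):
                gain_candidates.append((contig, p))
            start = seq.find(tail, start + 1)
    if n_gain > len(gain_candidates):
        n_gain = len(gain_candidates)
    if n_gain:
        pick = rng.choice(len(gain_candidates), size=n_gain, replace=False)
        for i in sorted(pick):
            contig, p = gain_candidates[i]
            site_rows.append({"contig": contig, "pos": p, "predicted": False})
    sites = pd.DataFrame(site_rows).sort_values(["contig", "pos"]).reset_index(drop=True)

    # --- SNP locus placement inside RAD windows of catalog sites, avoiding
    # the motifs themselves; each locus remembers its generating site
    site_row_of = {(sites.at[k, "contig"], int(sites.at[k, "pos"])): k
                   for k in sites.index}
    forbidden: dict[str, set[int]] = {c: set() for c in reference}
    for contig, positions in cat.sites.items():
        for p in positions:
            forbidden[contig].update(range(p, p + len(motif)))
    loci_rows = []
    m = len(motif)
    for contig, positions in cat.sites.items():
        seq = reference[contig]
        ln = len(seq)
        last_pos = -10
        for p in positions:
            k = site_row_of[(contig, int(p))]
            # outermost covered base of each window is only ever a read's
            # terminal color, where a substitution is indistinguishable from
            # a sequencing error — no SNPs planted there
            windows = [(max(0, p - (read_length - m)), p),
                       (p + m, min(ln, p + read_length))]
            for a, b in windows:
                # at most 3 SNPs per read window: a fourth would push an
                # error-free read from a fully divergent haplotype below the
                # 90% color-identity cut, silently dropping that haplotype
                n_in_window = 0
                for pos in range(a, b):
                    if n_in_window >= 3:
                        break
                    if pos in forbidden[contig]:
                        continue
                    # keep >= 3 bp between loci: substitutions closer than
                    # that merge their color-mismatch pairs and cannot be
                    # separated by two-base decoding
                    if pos - last_pos < 3:
                        continue
                    if rng.random() < model.mutation_rate:
                        ref_b = seq[pos]
                        alt = rng.choice([x for x in "ACGT" if x != ref_b])
                        loci_rows.append((contig, pos, ref_b, str(alt), "snp", k))
                        last_pos = pos
                        n_in_window += 1
    loci_rows.sort(key=lambda r: (r[0], r[1]))
    snp_loci = pd.DataFrame(
        loci_rows, columns=["contig", "pos", "ref", "alt", "kind", "site_idx"])

    # --- allele origin classes
    n_snp = len(snp_loci)
    pc, pw = model.private_fraction_cultivated, model.private_fraction_wild
    locus_class = rng.choice(3, size=n_snp, p=[1 - pc - pw, pc, pw])
    w_c = _usage_weights(rng, model.founders_cultivated, model.alpha_cultivated)
    w_w = _usage_weights(rng, model.founders_wild, model.alpha_wild)
    a_c, a_w = _founder_alleles(rng, pool_c, pool_w, locus_class, w_c, w_w)

    # presence alleles for sites: predicted sites carry an optional loss
    # allele (allele=1 -> site absent); gained sites carry a gain allele
    # (allele=1 -> site present).  Both segregate as shared-class loci.
    n_sites = len(sites)
    predicted = sites["predicted"].to_numpy()
    has_loss = predicted & (rng.random(n_sites) < model.re_loss_rate)
    variable = has_loss | ~predicted
    sc, sw = _founder_alleles(rng, pool_c, pool_w,
                              np.zeros(int(variable.sum()), dtype=int),
                              w_c, w_w)

    # --- draw individuals (SNP loci and site-presence loci share mosaics by
    # drawing them as one concatenated locus set, preserving within-genome LD)
    positions_by_contig = {
        c: snp_loci.loc[snp_loci["contig"] == c, "pos"].to_numpy(dtype=float)
        for c in reference
    }
    site_pos_by_contig = {
        c: sites.loc[(sites["contig"] == c) & pd.Series(variable),
                     "pos"].to_numpy(dtype=float)
        for c in reference
    }
    combined_positions = {}
    order_maps = {}
    for c in reference:
        snp_p = positions_by_contig[c]
        sit_p = site_pos_by_contig[c]
        allp = np.concatenate([snp_p, sit_p])
        combined_positions[c] = allp
        order_maps[c] = (len(snp_p), len(sit_p))

    # column order of the combined allele matrix: per contig, SNP loci then
    # variable-site loci
    def _combined_alleles(a_snp, a_site):
        cols = []
        snp_off = {c: 0 for c in reference}
        var_idx = np.flatnonzero(variable)
        snp_cols_by_contig = {
            c: np.flatnonzero((snp_loci["contig"] == c).to_numpy()) for c in reference}
        var_cols_by_contig = {
            c: [k for k, j in enumerate(var_idx) if sites.at[j, "contig"] == c]
            for c in reference}
        for c in reference:
            if len(snp_cols_by_contig[c]):
                cols.append(a_snp[:, snp_cols_by_contig[c]])
            if len(var_cols_by_contig[c]):
                cols.append(a_site[:, var_cols_by_contig[c]])
        if not cols:
            return np.zeros((a_snp.shape[0], 0), dtype=np.int8)
        return np.concatenate(cols, axis=1)

    comb_c = _combined_alleles(a_c, sc)
    comb_w = _combined_alleles(a_w, sw)

    hap_c = _sample_haplotypes(rng, combined_positions, cat.contig_lengths,
                               comb_c, model.n_cultivated, model.recombination,
                               w_c, 0.0)
    hap_w = _sample_haplotypes(rng, combined_positions, cat.contig_lengths,
                               comb_w, model.n_wild,
                               model.recombination * model.recombination_wild_factor,
                               w_w, model.f_wild)
    hap_all = np.concatenate([hap_c, hap_w], axis=0)

    # --- unscramble combined columns back into SNP / site blocks
    n_total = hap_all.shape[0]
    snp_alleles = np.zeros((n_total, 2, n_snp), dtype=np.int8)
    var_alleles = np.zeros((n_total, 2, int(variable.sum())), dtype=np.int8)
    col = 0
    var_idx = np.flatnonzero(variable)
    for c in reference:
        snp_cols = np.flatnonzero((snp_loci["contig"] == c).to_numpy())
        var_cols = [k for k, j in enumerate(var_idx) if sites.at[j, "contig"] == c]
        if len(snp_cols):
            snp_alleles[:, :, snp_cols] = hap_all[:, :, col:col + len(snp_cols)]
            col += len(snp_cols)
        if len(var_cols):
            var_alleles[:, :, var_cols] = hap_all[:, :, col:col + len(var_cols)]
            col += len(var_cols)

    # site presence per haplotype: predicted sites present unless loss allele;
    # gained sites present iff gain allele
    site_presence = np.ones((n_total, 2, n_sites), dtype=np.int8)
    for k, j in enumerate(var_idx):
        if sites.at[j, "predicted"]:
            site_presence[:, :, j] = 1 - var_alleles[:, :, k]
        else:
            site_presence[:, :, j] = var_alleles[:, :, k]
    site_presence[:, :, np.flatnonzero(~predicted & ~variable)] = 0

    # rare-in-wild layer (haplotype-level, shared SNP loci only)
    _apply_rare_wild(rng, snp_alleles[model.n_cultivated:], a_c, locus_class,
                     model.rare_wild_fraction)

    # --- RE loss/gain alleles are genuine substitutions: add them to the
    # truth locus table (kind re_loss / re_gain) so called SNPs at those
    # positions have a truth entry
    extra_rows = []
    extra_alleles = []
    for j in sites.index:
        contig, pos = sites.at[j, "contig"], int(sites.at[j, "pos"])
        seq = reference[contig]
        if sites.at[j, "predicted"]:
            if not bool(has_loss[j]):
                continue
            i = pos + len(motif) // 2
            ref_b = seq[i]
            extra_rows.append((contig, i, ref_b, _COMP[ref_b], "re_loss", j))
            extra_alleles.append(1 - site_presence[:, :, j])
        else:
            extra_rows.append((contig, pos, seq[pos], motif[0], "re_gain", j))
            extra_alleles.append(site_presence[:, :, j])
    if extra_rows:
        extra = pd.DataFrame(extra_rows, columns=snp_loci.columns)
        snp_loci = pd.concat([snp_loci, extra], ignore_index=True)
        snp_alleles = np.concatenate(
            [snp_alleles, np.stack(extra_alleles, axis=2)], axis=2)
    order = snp_loci.sort_values(["contig", "pos"]).index.to_numpy()
    snp_loci = snp_loci.iloc[order].reset_index(drop=True)
    snp_alleles = snp_alleles[:, :, order]

    samples = [f"cult{i + 1:03d}" for i in range(model.n_cultivated)] + \
              [f"wild{i + 1:03d}" for i in range(model.n_wild)]
    subpop = pd.Series(
        ["cultivated"] * model.n_cultivated + ["wild"] * model.n_wild,
        index=samples, name="subpop")

    return PopulationSim(
        reference=reference, catalog=cat, model=model, enzyme=enzyme,
        samples=samples, subpop=subpop, snp_loci=snp_loci,
        genotypes=snp_alleles.sum(axis=1), hap_alleles=snp_alleles,
        sites=sites, site_presence=site_presence,
    )


def _clear_of_sites(pos: int, site_positions: np.ndarray, margin: int) -> bool:
    if len(site_positions) == 0:
        return True
    i = np.searchsorted(site_positions, pos)
    for j in (i - 1, i):
        if 0 <= j < len(site_positions) and abs(int(site_positions[j]) - pos) < margin:
            return False
    return True


# ---------------------------------------------------------------------------
# library simulation

@dataclass
class LibrarySim:
    """Simulated reads plus provenance (part of SimTruth)."""

    reads: dict[str, list[ColorRead]]           # sample -> reads
    provenance: pd.DataFrame                    # read_id, sample, hap, contig,
                                                # site_pos, orientation, truncated
    library: LibraryModel

    @property
    def n_reads(self) -> int:
        return sum(len(v) for v in self.reads.values())


def _shear_bias_factor(frag_len: int) -> float:
    # monotone in log10(length) between ~100 bp and ~10 kb
    x = (math.log10(max(frag_len, 1)) - 2.0) / 2.0
    return 0.25 + 0.75 * min(max(x, 0.0), 1.0)


def simulate_library(
    pop: PopulationSim,
    library: LibraryModel = LibraryModel(),
    seed: int = 0,
) -> LibrarySim:
    """Generate color-space reads from every surviving site of every haplotype.

    For each sample, haplotype and present site, upstream and downstream
    reads start at the cut with the sticky-end sequence, are color-encoded
    with primer T and independent per-color errors, and are truncated (and
    flagged) when the restriction fragment is shorter than the read.
    """
    rng = np.random.default_rng([seed, 303])
    enzyme = pop.enzyme
    m = len(enzyme.recognition)
    rl = library.read_length
    e = library.color_error_rate
    sigma = math.sqrt(math.log(1 + library.depth_dispersion ** 2))
    reads: dict[str, list[ColorRead]] = {}
    prov_rows = []
    sites = pop.sites
    site_contig = sites["contig"].to_numpy()
    site_pos = sites["pos"].to_numpy()

    # per-sample haplotype edit dictionaries (SNPs + site gain/loss edits)
    for si, sample in enumerate(pop.samples):
        sample_factor = float(np.exp(rng.normal(-0.5 * sigma ** 2, sigma)))
        out: list[ColorRead] = []
        edits = [pop.haplotype_edits(si, h) for h in (0, 1)]
        for h in (0, 1):
            pres = pop.site_presence[si, h]
            for k in np.flatnonzero(pres):
                contig = site_contig[k]
                p = int(site_pos[k])
                seq = pop.reference[contig]
                ln = len(seq)
                # fragment bounds on this haplotype: nearest present sites
                up_len, down_len = _hap_fragment_lengths(
                    site_pos, site_contig, pres, k, ln, enzyme.cut_offset, m)
                for orientation, frag_len in (("down", down_len), ("up", up_len)):
                    lam = sample_factor * library.mean_depth / 2.0
                    if library.shear_bias:
                        lam *= _shear_bias_factor(frag_len)
                    depth = rng.poisson(lam)
                    for _ in range(depth):
                        base_seq, truncated = _read_sequence(
                            seq, edits[h][contig], p, orientation, rl,
                            enzyme.cut_offset, m, frag_len)
                        if len(base_seq) < 2:
                            continue
                        colors = encode("T", base_seq)
                        if e > 0:
                            colors = _corrupt(colors, e, rng)
                        rid = f"{sample}_r{len(out)}"
                        out.append(ColorRead(id=rid, primer="T", colors=colors))
                        prov_rows.append((rid, sample, h, contig, p,
                                          orientation, truncated))
        reads[sample] = out
    prov = pd.DataFrame(prov_rows, columns=[
        "read_id", "sample", "hap", "contig", "site_pos", "orientation",
        "truncated"])
    return LibrarySim(reads=reads, provenance=prov, library=library)


def _hap_fragment_lengths(site_pos, site_contig, presence, k, contig_len,
                          cut_offset, motif_len):
    """(upstream, downstream) fragment lengths between present sites."""
    contig = site_contig[k]
    cut = int(site_pos[k]) + cut_offset
    prev_cut, next_cut = 0, contig_len
    mask = (site_contig == contig) & (presence == 1)
    cuts = np.sort(site_pos[mask].astype(int)) + cut_offset
    i = np.searchsorted(cuts, cut)
    if i > 0:
        prev_cut = int(cuts[i - 1])
    if i + 1 < len(cuts):
        next_cut = int(cuts[i + 1])
    return cut - prev_cut, next_cut - cut


def _read_sequence(ref_seq, edit_map, p, orientation, read_length, cut_offset,
                   motif_len, frag_len):
    """Base sequence of one read from the cut at site p, with edits applied."""
    ln = len(ref_seq)
    usable = min(read_length, frag_len)
    truncated = usable < read_length
    if orientation == "down":
        a = p + cut_offset
        b = min(ln, a + usable)
        chars = list(ref_seq[a:b])
        for pos, alt in edit_map.items():
            if a <= pos < b:
                chars[pos - a] = alt
        return "".join(chars), truncated or b - a < read_length
    else:
        b = p + motif_len - cut_offset
        a = max(0, b - usable)
        chars = list(ref_seq[a:b])
        for pos, alt in edit_map.items():
            if a <= pos < b:
                chars[pos - a] = alt
        return _revcomp("".join(chars)), truncated or b - a < read_length


def _corrupt(colors: str, rate: float, rng) -> str:
    arr = np.frombuffer(colors.encode(), dtype=np.uint8) - ord("0")
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    if len(hits) == 0:
        return colors
    arr = arr.copy()
    arr[hits] = (arr[hits] + rng.integers(1, 4, size=len(hits))) % 4
    return (arr + ord("0")).astype(np.uint8).tobytes().decode()


# ---------------------------------------------------------------------------
# matrix-only convenience path (for population-genetics experiments)

def simulate_genotype_matrix(
    model: PopulationModel = PopulationModel(),
    n_loci: int = 5000,
    contig_length: int = 1_000_000,
    n_contigs: int = 1,
    seed: int = 0,
):
    """Draw a genotype panel directly, skipping sequences and reads.

    Loci are placed uniformly on ``n_contigs`` contigs of ``contig_length``
    bp.  Returns a :class:`radpipe.popgen.GenotypeMatrix` whose entries are
    the true dosages (no missingness) — callers mask entries themselves when
    studying imputation.
    """
    from .popgen import GenotypeMatrix

    rng = np.random.default_rng([seed, 404])
    per = [n_loci // n_contigs] * n_contigs
    per[0] += n_loci - sum(per)
    rows = []
    positions_by_contig = {}
    for ci in range(n_contigs):
        name = f"chr{ci + 1}"
        pos = np.sort(rng.choice(contig_length, size=per[ci], replace=False))
        positions_by_contig[name] = pos.astype(float)
        rows += [(name, int(p), "A", "G") for p in pos]
    loci = pd.DataFrame(rows, columns=["contig", "pos", "ref", "alt"])

    proto_parents = _make_proto_parents(rng, model.n_ancestral)
    pool_c = _FounderPool(rng, model.n_ancestral, model.founders_cultivated, proto_parents)
    pool_w = _FounderPool(rng, model.n_ancestral, model.founders_wild, proto_parents)
    pc, pw = model.private_fraction_cultivated, model.private_fraction_wild
    locus_class = rng.choice(3, size=n_loci, p=[1 - pc - pw, pc, pw])
    w_c = _usage_weights(rng, model.founders_cultivated, model.alpha_cultivated)
    w_w = _usage_weights(rng, model.founders_wild, model.alpha_wild)
    a_c, a_w = _founder_alleles(rng, pool_c, pool_w, locus_class, w_c, w_w)
    lengths = {f"chr{ci + 1}": contig_length for ci in range(n_contigs)}
    hap_c = _sample_haplotypes(rng, positions_by_contig, lengths, a_c,
                               model.n_cultivated, model.recombination, w_c, 0.0)
    hap_w = _sample_haplotypes(rng, positions_by_contig, lengths, a_w,
                               model.n_wild,
                               model.recombination * model.recombination_wild_factor,
                               w_w, model.f_wild)
    _apply_rare_wild(rng, hap_w, a_c, locus_class, model.rare_wild_fraction)
    geno = np.concatenate([hap_c.sum(axis=1), hap_w.sum(axis=1)], axis=0)
    samples = [f"cult{i + 1:03d}" for i in range(model.n_cultivated)] + \
              [f"wild{i + 1:03d}" for i in range(model.n_wild)]
    subpop = pd.Series(["cultivated"] * model.n_cultivated +
                       ["wild"] * model.n_wild, index=samples, name="subpop")
    return GenotypeMatrix(genotypes=geno.astype(np.int8), samples=samples,
                          loci=loci, subpop=subpop)
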