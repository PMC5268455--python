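"""Published benchmark counts from a grapevine BamHI RAD-seq discovery assay.

These are the printed headline counts of a reference study on a germplasm
panel of 51 cultivated and 44 wild grapevine accessions, kept here as fixed
inputs so the pipeline's accounting arithmetic (retention percentages,
predicted-site share, resequenced genome fraction, survivor counts of the
locus filters) can be recomputed and checked against the published summary
figures.  Nothing here is measured by this package; the functions below do
the arithmetic the published summaries imply.
"""

from __future__ import annotations

__all__ = [
    "READ_ACCOUNTING",
    "SITE_CLASSIFICATION",
    "SNP_ACCOUNTING",
    "GENOME",
    "preprocess_retained_pct",
    "unique_mapq10_pct",
    "predicted_site_pct",
    "genome_resequenced_pct",
    "final_snp_count",
    "mean_snps_per_chromosome",
    "mean_snps_per_bin",
]

#: read counts per filtering step (sequencing, start filter, unique
#: alignment, MapQ > 10); the two alignment rows are exact read counts
READ_ACCOUNTING = {
    "sequenced": 566_000_000,
    "preprocessed": 485_000_000,
    "unique": 293_786_586,
    "unique_mapq_gt10": 177_212_079,
}

#: recovered restriction sites by {predicted, unpredicted} x {nuclear,
#: organellar}
SITE_CLASSIFICATION = {
    ("predicted", "nuclear"): 32_080,
    ("unpredicted", "nuclear"): 2_353,
    ("predicted", "organellar"): 163,
    ("unpredicted", "organellar"): 4,
}

#: SNP counts through the locus filters of the diversity analysis
SNP_ACCOUNTING = {
    "total": 37_748,
    "mtdna": 120,
    "cpdna": 34,
    "missing_filtered": 21_920,
    "maf_filtered": 1_333,
    "chromosomal_fraction": 0.93,   # share on the 19 assembled chromosomes
    "n_chromosomes": 19,
    "n_bins_500kb": 985,
}

#: reference genome size (bp) and the read length after start rewriting
GENOME = {"size_bp": 487_000_000, "read_length": 75}


def preprocess_retained_pct() -> float:
    """Percentage of raw reads surviving the start-signature filter."""
    r = READ_ACCOUNTING
    return 100.0 * r["preprocessed"] / r["sequenced"]


def unique_mapq10_pct() -> float:
    """Percentage of unique alignments above MapQ 10."""
    r = READ_ACCOUNTING
    return 100.0 * r["unique_mapq_gt10"] / r["unique"]


def predicted_site_pct() -> float:
    """Share of recovered restriction sites present in the reference digest."""
    total = sum(SITE_CLASSIFICATION.values())
    predicted = sum(v for k, v in SITE_CLASSIFICATION.items()
                    if k[0] == "predicted")
    return 100.0 * predicted / total


def genome_resequenced_pct() -> float:
    """Genome fraction covered by two read-length loci per recovered site."""
    total_sites = sum(SITE_CLASSIFICATION.values())
    covered = total_sites * 2 * GENOME["read_length"]
    return 100.0 * covered / GENOME["size_bp"]


def final_snp_count() -> int:
    """Nuclear loci surviving the missingness and MAF filters."""
    s = SNP_ACCOUNTING
    return (s["total"] - s["mtdna"] - s["cpdna"]
            - s["missing_filtered"] - s["maf_filtered"])


def mean_snps_per_chromosome() -> float:
    """Average SNPs per assembled chromosome."""
    s = SNP_ACCOUNTING
    return s["chromosomal_fraction"] * s["total"] / s["n_chromosomes"]


def mean_snps_per_bin() -> float:
    """Average SNPs per 500 kb window of the assembled chromosomes."""
    s = SNP_ACCOUNTING
    return s["chromosomal_fraction"] * s["total"] / s["n_bins_500kb"]
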