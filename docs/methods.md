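# Methods

This note documents the models and numerical choices behind `radpipe`: what
each stage assumes, which parameters matter, what the synthetic-data
generator does and does not emulate, and where the design was genuinely
open.

## Color-space model

The dibase code is implemented as XOR over the base ordering A=0, C=1, G=2,
T=3, which reproduces the standard table exactly (identical bases -> 0,
A<->C and G<->T -> 1, A<->G and C<->T -> 2, A<->T and C<->G -> 3). The code
is symmetric and, for a fixed first base, bijective in the second, so
encode/decode are mutual inverses for any anchor base.

Two consequences drive the pipeline design:

- a single color error corrupts every *decoded* base downstream, so reads
  are compared in color space and bases are only inferred after placement;
- a true substitution flips exactly two adjacent colors (one when it is the
  last position), and the two flipped colors must agree on the implied base.
  An isolated mismatch is treated as a sequencing error; adjacent mismatch
  pairs whose implied substitution is self-consistent become alternate-base
  observations; longer runs are uninterpretable and yield no observation.
  A substitution at a read's terminal base changes only one color and is
  therefore indistinguishable from an error — such positions are never
  called.

## Read pre-processing

Reads are expected to start with the enzyme's sticky end (GATCC for BamHI,
colors `12320` from primer T). Reads within Hamming distance
`max_start_errors` (default 1) of the signature are kept and their start is
rewritten with the full-site signature (`102320`), lengthening each read by
one color; others are discarded. Both signatures are derived from the enzyme
definition, so other enzymes work unchanged. Of the 4^5 = 1024 possible
five-color starts, exactly 16 (1 exact + 5x3 single errors) are retained.
Base qualities are carried but not used by the filter, which is purely
positional.

## Digestion

Coordinates are 0-based half-open everywhere internally; VCF output is
1-based. Recognition-site scanning is overlap-aware; windows containing N
never match (conservative motif calling). Fragments are cut at
`site + cut_offset` on the top strand; they concatenate back to the input
and every internal fragment begins with the sticky end. The catalog's mean
inter-site distance is computed over consecutive same-contig pairs only.

## Alignment

Every candidate placement is a (contig, site, orientation) anchor. The seed
index stores every k-color window (default k = 16) of each contig's color
string; seeds are taken at read offsets 6, 26 and 46 so one color error can
hide at most one seed. Upstream placements are retrieved by looking up the
reversed seed (the color string of a reverse complement is the reversed
color string). Identity is matching colors over compared colors at the best
placement; a read is kept only when the best placement is strictly better
than the second best (no random tie-breaking) and identity >= 0.90.
MapQ = min(60, 4·(best − second-best matches)), 60 with a single candidate.
Two thresholds are exposed because summaries and genotyping use different
cuts (reporting at MapQ > 10, calling at MapQ > 17); both default to the
conventional values for this pipeline family. Gapped alignment is out of
scope: RAD reads are anchored and short, and the downstream analysis is
SNP-only.

## Genotyping

The diploid observation model is P(b|{a1,a2}) = ½P(b|a1) + ½P(b|a2) with
P(b|a) = 1−e (match) or e/3 (mismatch); likelihoods multiply over reads and
are kept in log10. The prior (1 − 3θ/2, θ, θ/2) over (hom-ref, het,
hom-alt) uses θ = 0.001 by default — the conventional population
heterozygosity prior. GQ is the Phred-scaled posterior gap between the two
best genotypes (capped at 99); PL is the usual likelihood triple scaled to
the maximum. Exact posterior ties are missing. Merging emits a biallelic
record when >= 1 sample makes a non-reference call at depth >= 10; samples
below the floor are missing; sites with substantial evidence for a second
alternate allele (>= 2 observations and >= 20% of the leading alternate) are
dropped with a warning. Depth DP counts covering reads, so DP >= used
observations always.

## The synthetic-data generator

The generator is the package's study stand-in and its defaults are the
study conditions: 51 cultivated + 44 wild diploids, 75-color reads, one
recognition site per ~8 kb, shear fragments 150–350 bp, per-color error
0.01, per-sample depth dispersion (CV) 0.3.

**Population model.** Each subpopulation's founder haplotypes form a serial
copy-and-mutate pedigree rooted in a handful of shared ancestral haplotypes
(4 by default). A mutation originating at pedigree node v is carried by
exactly the founders descending from v, so carrier sets are nested subtrees:
founder haplotypes have genuine long-range allele correlation, and the menu
of subtree frequencies is graduated in 1/k steps. Individuals are
recombinant founder mosaics (crossovers Poisson per contig, founder chosen
per segment by the pool's usage weights); the `recombination` parameter is
an *effective, history-accumulated* crossover count per contig, not a
per-meiosis rate — with 150 crossovers on a 1 Mb contig the mosaic segment
scale is ~7 kb. Wild homologs copy each other's founder per segment with
probability `f_wild`, producing genome-wide excess homozygosity of that
magnitude.

The two groups differ in:

- founder count (24 cultivated vs 4 wild) and usage (Dirichlet α = 2 for
  cultivated — popular parents; exactly even for wild),
- effective recombination (wild x0.25 — less recombined history),
- allele-frequency targets: each locus draws a target frequency per pool
  from a class-specific Beta (intermediate for cultivated, rare-skewed for
  wild) and settles softly on the pedigree node whose usage-weighted
  descendant fraction is closest, so marginal spectra are shaped while
  carrier sets remain subtrees. Shared loci draw origins independently per
  pool; cross-pool frequency correlation is deliberately not modeled,
- private-allele locus fractions (0.20 cultivated vs 0.01 wild),
- a rare-in-wild layer: 30% of shared loci are re-assigned at the haplotype
  level to 1–3 wild carriers (young variants in small populations). These
  loci stay common in the cultivated pool, so they create the wild low-MAF
  abundance without inflating wild private-allele counts; they fall below
  the MAF filter used in LD analysis, so they do not perturb decay curves.

Under the defaults this yields (800-locus panels, 20 seeds): cultivated
Ho ≈ 0.37 > wild Ho ≈ 0.18, wild F_IS ≈ 0.02, private alleles ~280 vs ~27,
wild low-MAF excess, and median-r² curves crossing 0.2 near 5 kb
(cultivated) vs 15 kb (wild) — the qualitative contrasts of the study
system, treated as tuning goals rather than asserted equalities.

**Site gain/loss.** 5% of catalog sites carry a segregating loss allele
(the motif's center base flipped) and gains are planted at positions one
substitution away from the motif (the first base restored). Both segregate
like ordinary loci and are recorded in the truth table (kinds `re_loss`,
`re_gain`) because they are genuine substitutions the caller will see.
Losses produce null alleles: a haplotype without the site contributes no
reads, biasing flanking genotypes toward homozygosity — exactly the bias
the pipeline's accounting is meant to expose.

**SNP placement.** Truth SNPs are planted only inside RAD windows (the
intervals reads cover around each site), at 0.007 per bp, at least 3 bp
apart (closer substitutions merge their color-mismatch pairs and cannot be
separated by two-base decoding), at most 3 per 70 bp window (a fourth would
push an error-free read from a fully divergent haplotype below the fixed
90% identity cut and silently drop that haplotype), and never at a window's
outermost base (observable only as a terminal color).

**Library model.** Each surviving site on each haplotype yields upstream and
downstream reads starting at the cut; per-locus depth is Poisson with a
lognormal per-sample factor; reads are truncated and flagged when the
restriction fragment is shorter than the read. The optional shear bias
multiplies expected depth by a monotone function of log10 fragment length
(saturating between ~100 bp and ~10 kb), giving a positive depth vs
log-fragment-length correlation when enabled and none otherwise.

**What the generator does not emulate.** Instrument-specific error profiles
(the error model is one per-color rate; the study's 75%/11%/14% start-error
split is not a target), PCR duplicates, adapter dimers, base-quality
learning, coalescent demography, methylation sensitivity, and real
per-sample batch effects. Passing tests therefore demonstrate the
pipeline's correctness under a controlled, simplified data-generating
process — not performance on any particular real instrument run.

## Population-genetics choices

- r² is the squared Pearson correlation of 0/1/2 dosages (genotype r²), not
  haplotype-EM r².
- He uses the sample-size-corrected (unbiased) estimator 2n/(2n−1)·2p(1−p)
  by default; the naive estimator is available via `unbiased=False`.
- F_IS is 1 − mean(Ho)/mean(He) over loci (ratio of averages); the
  per-locus-averaged variant is also reported since conventions differ.
- Filtering order is fixed: sample missingness, locus missingness (on the
  retained samples), imputation, MAF — the order the downstream statistics
  assume.
- LD pairs are same-contig within 500 kb by default; bins are half-open
  [d, d + 10 kb); the crossing distance is the midpoint of the first bin
  whose median r² falls below 0.2 (NaN if it never does).
- LD-kNNi defaults: k = 5 neighbours, l = 20 proxy loci, ε = 1e-9 in the
  inverse-distance weights; inter-sample distance is the mean absolute
  dosage difference over pairwise-observed proxy loci. Observed entries are
  never altered; imputed output has no missing entries.
- SNP density uses non-overlapping 500 kb windows (the published bin
  arithmetic implies tiling), keeping the final partial window.
- Multi-allelic sites are excluded throughout (biallelic SNP analysis).

## Experiment sizes

The self-contained experiments (`radpipe.experiments`) are scaled-down
study analogues chosen to run in seconds to a couple of minutes on one CPU:
a 1 Mb reference (~125 sites at the study's observed ~8 kb spacing), 20
samples at depth 40 for the zero-error end-to-end run (deep coverage keeps
binomial allele-sampling noise out of the 100%-concordance check; the
genotyper error is floored at 1e-4 to match the error-free library), 40
wild samples x 5,000 loci on four contigs for inbreeding recovery, 95
samples x 600–800 loci for the diversity and LD contrasts, and 50 samples x
200 loci with 10% masking for the imputation comparison. At per-color error
0.005 and depth 20 the same end-to-end pipeline measures ~99.7% genotype
concordance.

## Known limitations

- The aligner is exhaustive only over seed-retrievable anchors; a read with
  errors in all three seed windows is unaligned (negligible below ~2%
  per-color error).
- Reference-biased dropout is real: haplotypes diverging by more than ~7
  colors in one read window fall below the 90% identity cut. The generator
  avoids planting such haplotypes; with real data this bias would add to
  the null-allele effect.
- The founder-pedigree population model controls marginal spectra, F_IS and
  LD scale with few parameters, but it is not a coalescent: allele-frequency
  trajectories, recombination hotspots and cross-pool frequency correlation
  at shared loci are not modeled.
- The genotyper assumes independent reads (no duplicate handling) and a
  single global error rate unless per-base qualities are supplied.
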