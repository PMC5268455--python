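# radpipe

A tested, reusable re-implementation of a RAD-seq SNP-discovery pipeline for
SOLiD color-space reads, together with a synthetic-data generator that
emulates the study design it targets: a germplasm panel of cultivated and
wild grapevine accessions sequenced by restriction-site associated DNA
(RAD) sequencing with the BamHI enzyme.

## Who this is for

Researchers who want to study — or sanity-check — reduced-representation
SNP discovery on a two-base color-space platform: how restriction-site
anchored reads are filtered and aligned, how restriction-site presence/absence
polymorphism creates "unpredicted" loci and null alleles, and how the
resulting genotype panel behaves in downstream diversity and linkage-
disequilibrium (LD) analyses contrasting a diverse domesticated group with a
bottlenecked wild relative.

## The method

**Color space.** SOLiD reads encode *transitions* between adjacent bases:
color 0 = {AA,CC,GG,TT}, 1 = {AC,CA,GT,TG}, 2 = {AG,GA,CT,TC},
3 = {AT,TA,CG,GC}, anchored by a known primer base. A RAD read ligated at a
BamHI cut starts with the sticky end GATCC, i.e. `T12320` in color space.
The pre-processing filter keeps reads whose first five colors are within
Hamming distance 1 of that signature and rewrites the start with the full
recognition-site signature `T102320` (75 colors -> 76).

**Site-anchored alignment.** Every genuine placement of a pre-processed
read is anchored at a recognition site: downstream reads cover
`ref[p : p+76]`, upstream reads the reverse complement of `ref[p-70 : p+6]`.
Candidates are retrieved by exact k-color seed lookup (which also finds
*gained* sites absent from the reference digest); a read is kept when its
best placement is unique and its color identity is >= 0.90, with
MapQ = min(60, 4·(best − second-best matches)).

**Genotype calling.** Per read base b and genotype {a1,a2}:
P(b|{a1,a2}) = ½P(b|a1) + ½P(b|a2) with P(b|a) = 1−e if b = a else e/3;
the prior over (hom-ref, het, hom-alt) is (1 − 3θ/2, θ, θ/2). The call is
the posterior mode; sites are emitted when at least one sample has a
non-reference call at depth >= 10 (biallelic records only).

**Population genetics.** Missingness filters (samples > 0.5, then loci
> 0.2), LD-kNN genotype imputation (rank loci by r² with the target, measure
sample distance over the top-l loci, impute by inverse-distance vote of the
k nearest), MAF >= 0.05 filter, then per-subpopulation observed/expected
heterozygosity (unbiased He = 2n/(2n−1)·2p(1−p)), F_IS = 1 − H̄o/H̄e,
private-allele counts, MAF spectra, genotype concordance between call sets,
and LD decay as the median genotype-correlation r² in 10 kb distance bins.

**Simulator.** `radpipe.radsim` generates the whole study: a reference with
planted recognition sites, a two-subpopulation diploid panel built from
founder-haplotype mosaics (serial copy-and-mutate founder pedigrees hanging
off shared ancestral haplotypes; 24 cultivated vs 4 wild founders, wild
homolog correlation `f_wild`, site gain/loss alleles, a rare-in-wild variant
layer), and color-space reads with per-color errors — all with complete
ground truth (genotypes, per-haplotype site presence, read provenance).

## Worked example

```python
import numpy as np, pandas as pd, warnings
from radpipe import radsim, align, colorspace, popgen
from radpipe.genotyper import GenotyperParams, merge_samples

genome, cat = radsim.simulate_reference(1, [500_000], 1/8000.0, seed=42)
print("sites:", cat.n_sites, " mean spacing: %.0f bp" % cat.mean_intersite_distance())

model = radsim.PopulationModel(n_cultivated=12, n_wild=12)
pop = radsim.simulate_population(genome, cat, model, seed=43)
lib = radsim.simulate_library(pop, radsim.LibraryModel(mean_depth=25), seed=44)

index = align.build_index(genome, cat)
pileups = {}
for sample, reads in lib.reads.items():
    summary = colorspace.preprocess_batch(reads)
    records, _ = align.align_reads(
        [r.read for r in summary.results if r.read is not None], index)
    pileups[sample] = align.pileup_sample(records, index, mapq_min=17)

records = merge_samples(pileups, genome, GenotyperParams(error_rate=0.01))
code = {"hom_ref": 0, "het": 1, "hom_alt": 2, "missing": -1}
g = np.array([[code[r.calls[s][0]] for r in records] for s in pop.samples],
             dtype=np.int8)
loci = pd.DataFrame({"contig": [r.contig for r in records],
                     "pos": [r.pos - 1 for r in records],
                     "ref": [r.ref for r in records],
                     "alt": [r.alt for r in records]})
gm = popgen.GenotypeMatrix(g, pop.samples, loci, pop.subpop)
gm, _ = popgen.filter_matrix(gm)
gm = popgen.maf_filter(popgen.impute_ldknni(gm), 0.05)
for label, st in popgen.diversity(gm).items():
    print(f"{label:11s} Ho={st.ho:.3f}  He={st.he:.3f}  "
          f"Fis={st.fis:+.3f}  PA={st.private_alleles}")
```

prints

```
sites: 64  mean spacing: 7775 bp
cultivated  Ho=0.384  He=0.351  Fis=-0.094  PA=22
wild        Ho=0.129  He=0.150  Fis=+0.142  PA=4
```

64 recognition sites were planted about 7.8 kb apart; 49 biallelic SNPs are
called from ~79k simulated reads. The cultivated panel is more heterozygous
and carries far more private alleles than the wild one — the qualitative
contrast the generator is parameterized for (exact values move with the
seed and panel size).

The same workflow is available from the shell:

```bash
radpipe simulate --seed 5 --outdir sim
radpipe preprocess sim/cult001.csfasta --out cult001.pre
radpipe align cult001.pre sim/reference.fa --sam cult001.sam
radpipe call cult001.sam ... sim/reference.fa --out calls.vcf
radpipe stats calls.vcf labels.tsv --ld
radpipe annotate calls.vcf genes.gff3 sim/reference.fa --out annotated.tsv
```

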