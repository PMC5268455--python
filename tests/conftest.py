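import warnings

import pytest

from radpipe import align, colorspace, radsim
from radpipe.genotyper import GenotyperParams, merge_samples


@pytest.fixture(scope="session")
def tiny_reference():
    """200 kb single-contig reference with ~25 planted BamHI sites."""
    return radsim.simulate_reference(1, [200_000], 1 / 8000.0, seed=7)


@pytest.fixture(scope="session")
def tiny_population(tiny_reference):
    genome, cat = tiny_reference
    model = radsim.PopulationModel(n_cultivated=6, n_wild=5)
    return radsim.simulate_population(genome, cat, model, seed=3)


@pytest.fixture(scope="session")
def tiny_library(tiny_population):
    """Error-free reads at depth 20 from the tiny panel."""
    lib_model = radsim.LibraryModel(mean_depth=20.0, color_error_rate=0.0)
    return radsim.simulate_library(tiny_population, lib_model, seed=1)


@pytest.fixture(scope="session")
def tiny_index(tiny_reference):
    genome, cat = tiny_reference
    return align.build_index(genome, cat)


@pytest.fixture(scope="session")
def tiny_pileups(tiny_library, tiny_index):
    """Per-sample pileups of the error-free tiny panel (MapQ > 17)."""
    pileups = {}
    records_by_sample = {}
    for sample, reads in tiny_library.reads.items():
        pre = [res.read for res in (colorspace.preprocess(r) for r in reads)
               if res.read is not None]
        records, _ = align.align_reads(pre, tiny_index)
        records_by_sample[sample] = records
        pileups[sample] = align.pileup_sample(records, tiny_index, mapq_min=17)
    return pileups, records_by_sample


@pytest.fixture(scope="session")
def tiny_vcf_records(tiny_pileups, tiny_reference):
    genome, _ = tiny_reference
    pileups, _ = tiny_pileups
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return merge_samples(pileups, genome, GenotyperParams(error_rate=1e-4))
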