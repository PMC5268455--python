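"""Site-anchored color-space alignment and base-evidence extraction."""

import numpy as np
import pytest

from radpipe import align, colorspace as cs, digest as dg


def make_read(index, contig, site_pos, orientation, rid="r",
              mutate=()):  # mutate: list of (color index, new color)
    bases = index.expected_bases(contig, site_pos, orientation, 76)
    colors = list(cs.encode("T", bases))
    for i, c in mutate:
        colors[i] = c
    return cs.ColorRead(rid, "T", "".join(colors))


@pytest.fixture(scope="module")
def small_index():
    genome, cat = __import__("radpipe.radsim", fromlist=["simulate_reference"]) \
        .simulate_reference(1, [60_000], 1 / 6000.0, seed=13)
    return align.build_index(genome, cat)


def test_every_catalog_site_is_a_candidate(small_index):
    """An error-free read from any catalog site retrieves that placement."""
    for contig, p, orient in small_index.site_candidates():
        read = make_read(small_index, contig, p, orient)
        cands = small_index.candidates(read.colors)
        assert (contig, p, orient) in cands


def test_error_free_read_aligns_perfectly(small_index):
    contig, p, orient = small_index.site_candidates()[0]
    rec = align.align_read(make_read(small_index, contig, p, orient),
                           small_index)
    assert isinstance(rec, align.AlignmentRecord)
    assert (rec.contig, rec.site_pos, rec.orientation) == (contig, p, orient)
    assert rec.identity == 1.0
    assert rec.unique
    assert rec.mapq == 60 or rec.mapq > 10   # 60 unless a second seed hit


def test_identity_threshold_boundary(small_index):
    """8 mismatches over 76 colors gives identity 0.8947 < 0.90: rejected;
    7 mismatches (0.9079) is kept."""
    contig, p, orient = small_index.site_candidates()[2]
    exp = small_index.expected_colors(contig, p, orient, 76)
    # plant substitutions late in the read, away from the seed offsets
    def flip(i):
        return (i, "0123"[("0123".index(exp[i]) + 1) % 4])
    rej = align.align_read(
        make_read(small_index, contig, p, orient,
                  mutate=[flip(i) for i in range(66, 74)]), small_index)
    assert isinstance(rej, align.Rejection) and rej.reason == "identity"
    assert 68 / 76 < 0.90 < 69 / 76
    rec = align.align_read(
        make_read(small_index, contig, p, orient,
                  mutate=[flip(i) for i in range(66, 73)]), small_index)
    assert isinstance(rec, align.AlignmentRecord)
    assert rec.identity == pytest.approx(69 / 76)


def test_duplicated_region_is_ambiguous():
    """Reads from a region duplicated elsewhere get two equal-score
    candidates and are dropped (no random tie-breaking)."""
    rng = np.random.default_rng(3)
    block = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 994)])
    unit = "GGATCC" + block
    seq = unit + unit + "".join(np.array(list("ACGT"))[rng.integers(0, 4, 2000)])
    genome = {"c1": seq}
    cat = dg.catalog(genome, dg.BAMHI)
    assert len(cat.sites["c1"]) == 2
    index = align.build_index(genome, cat)
    read = make_read(index, "c1", 0, "down")
    res = align.align_read(read, index)
    assert isinstance(res, align.Rejection) and res.reason == "ambiguous"


def test_short_read_rejected(small_index):
    res = align.align_read(cs.ColorRead("r", "T", "102320"), small_index)
    assert isinstance(res, align.Rejection) and res.reason == "short"


def test_mapq_formula(small_index):
    contig, p, orient = small_index.site_candidates()[4]
    exp = small_index.expected_colors(contig, p, orient, 76)
    read = make_read(small_index, contig, p, orient,
                     mutate=[(70, "0123"[("0123".index(exp[70]) + 1) % 4])])
    rec = align.align_read(read, small_index)
    assert isinstance(rec, align.AlignmentRecord)
    assert rec.mapq == 60 or rec.mapq == min(60, 4 * (75 - rec.mapq))


def test_retention_monotone_in_identity_threshold(small_index, tiny_library):
    reads = []
    for sample_reads in list(tiny_library.reads.values())[:2]:
        reads += [cs.preprocess(r).read for r in sample_reads[:300]]
    kept = []
    for thr in (0.85, 0.90, 0.95, 1.0):
        records, _ = align.align_reads(reads, small_index, min_identity=thr)
        kept.append(len(records))
    assert kept == sorted(kept, reverse=True)


# --- base evidence ---------------------------------------------------------

def _substituted_read(index, contig, p, orient, base_index, new_base):
    bases = index.expected_bases(contig, p, orient, 76)
    mutated = bases[:base_index] + new_base + bases[base_index + 1:]
    return cs.ColorRead("r", "T", cs.encode("T", mutated))


def test_every_substitution_recovered_exhaustively(small_index):
    """Every single-base substitution at read indices 6..74 yields exactly
    one alternate observation at the right reference position and base."""
    contig, p, orient = small_index.site_candidates()[1]
    bases = small_index.expected_bases(contig, p, orient, 76)
    m = small_index.motif_len
    for i in range(m, 75):
        for sub in "ACGT":
            if sub == bases[i]:
                continue
            read = _substituted_read(small_index, contig, p, orient, i, sub)
            rec = align.align_read(read, small_index)
            assert isinstance(rec, align.AlignmentRecord)
            ev = align.call_bases(rec, read, small_index)
            assert len(ev.alt_observations) == 1
            ref_pos, obs = ev.alt_observations[0]
            if orient == "down":
                assert ref_pos == p + i and obs == sub
            else:
                assert ref_pos == p + m - 1 - i
                assert obs == {"A": "T", "C": "G", "G": "C", "T": "A"}[sub]


def test_isolated_color_error_gives_no_observation(small_index):
    contig, p, orient = small_index.site_candidates()[3]
    exp = small_index.expected_colors(contig, p, orient, 76)
    read = make_read(small_index, contig, p, orient,
                     mutate=[(40, "0123"[("0123".index(exp[40]) + 1) % 4])])
    rec = align.align_read(read, small_index)
    ev = align.call_bases(rec, read, small_index)
    assert ev.alt_observations == []
    # the two touched bases are not observed as reference either
    touched = {align._read_index_to_ref(rec, small_index.motif_len, i)
               for i in (39, 40)}
    assert not (touched & set(ev.ref_positions))


def test_error_free_read_observes_reference_everywhere(small_index):
    contig, p, orient = small_index.site_candidates()[0]
    read = make_read(small_index, contig, p, orient)
    rec = align.align_read(read, small_index)
    ev = align.call_bases(rec, read, small_index)
    assert len(ev.ref_positions) == 76
    assert ev.alt_observations == []
    lo, hi = ev.covered
    assert hi - lo == 76


def test_alignment_summary_partition(small_index, tiny_library):
    reads = [cs.preprocess(r).read
             for r in list(tiny_library.reads.values())[0][:200]]
    records, rejections = align.align_reads(reads, small_index)
    s = align.alignment_summary(records, rejections)
    assert s["unique_mapq_gt10"] + s["unique_mapq_le10"] + s["rejected"] \
        == s["total"] == len(reads)


def test_sam_export_readable_by_pysam(small_index, tmp_path):
    import pysam

    contig, p, orient = small_index.site_candidates()[0]
    read = make_read(small_index, contig, p, orient, rid="sam1")
    rec = align.align_read(read, small_index)
    path = tmp_path / "out.sam"
    align.write_sam([(rec, read)], small_index, path)
    with pysam.AlignmentFile(str(path)) as fh:
        rows = list(fh)
    assert len(rows) == 1
    assert rows[0].query_name == "sam1"
    assert rows[0].get_tag("CS") == "T" + read.colors
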