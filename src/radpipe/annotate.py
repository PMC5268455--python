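"""SNP annotation: genomic feature class and coding effect from GFF3.

Each variant gets exactly one feature class — CDS, UTR, intron or intergenic
— with CDS taking precedence over UTR over intron when transcripts overlap.
For CDS variants the coding effect (synonymous / nonsynonymous) is derived
by strand-aware codon extraction and standard-genetic-code translation;
changes that create or destroy a stop codon count as nonsynonymous, and
variants whose codon cannot be recovered (partial models) are flagged and
excluded from effect counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional

import pandas as pd

__all__ = [
    "GeneModel",
    "load_gene_models",
    "classify_snp",
    "coding_effect",
    "annotate_sites",
]

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _revcomp(seq: str) -> str:
    return "".join(_COMP.get(b, "N") for b in reversed(seq))


@dataclass
class GeneModel:
    """One gene: strand, span, and ordered CDS/UTR intervals (0-based
    half-open; introns are the gaps between exonic features)."""

    gene_id: str
    contig: str
    strand: str
    start: int                  # 0-based
    end: int                    # half-open
    cds: list[tuple[int, int]] = field(default_factory=list)
    utr: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.cds.sort()
        self.utr.sort()

    def cds_length(self) -> int:
        return sum(b - a for a, b in self.cds)

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def feature_at(self, pos: int) -> Optional[str]:
        if not self.contains(pos):
            return None
        for a, b in self.cds:
            if a <= pos < b:
                return "CDS"
        for a, b in self.utr:
            if a <= pos < b:
                return "UTR"
        return "intron"


def load_gene_models(gff3_path) -> dict[str, list[GeneModel]]:
    """Parse GFF3 gene models (via gffutils, in-memory DB), keyed by contig.

    GFF3 coordinates are 1-based inclusive; they are converted to 0-based
    half-open internally.
    """
    import gffutils

    db = gffutils.create_db(str(gff3_path), ":memory:",
                            merge_strategy="create_unique", keep_order=True)
    models: dict[str, list[GeneModel]] = {}
    for gene in db.features_of_type("gene"):
        gm = GeneModel(gene_id=gene.id, contig=gene.seqid, strand=gene.strand,
                       start=gene.start - 1, end=gene.end)
        for f in db.children(gene, featuretype="CDS"):
            gm.cds.append((f.start - 1, f.end))
        for ft in ("five_prime_UTR", "three_prime_UTR", "UTR"):
            for f in db.children(gene, featuretype=ft):
                gm.utr.append((f.start - 1, f.end))
        gm.cds.sort()
        gm.utr.sort()
        models.setdefault(gm.contig, []).append(gm)
    for lst in models.values():
        lst.sort(key=lambda g: g.start)
    return models


_PRECEDENCE = {"CDS": 0, "UTR": 1, "intron": 2}


def classify_snp(
    contig: str, pos: int, models: Mapping[str, list[GeneModel]],
) -> tuple[str, Optional[GeneModel]]:
    """Feature class of a site (0-based position) and the winning gene model.

    CDS beats UTR beats intron when transcripts overlap; a site on a contig
    absent from the annotation is intergenic (with a warning).
    """
    if contig not in models:
        warnings.warn(f"contig {contig!r} absent from annotation; "
                      "classifying as intergenic")
        return "intergenic", None
    best: tuple[int, str, Optional[GeneModel]] = (3, "intergenic", None)
    for gm in models[contig]:
        if gm.start > pos:
            break
        feat = gm.feature_at(pos)
        if feat is not None and _PRECEDENCE[feat] < best[0]:
            best = (_PRECEDENCE[feat], feat, gm)
    return best[1], best[2]


def coding_effect(
    contig: str, pos: int, ref: str, alt: str,
    gene: GeneModel, reference: Mapping[str, str],
) -> str:
    """``synonymous`` or ``nonsynonymous`` for a CDS variant.

    Raises ValueError when the site is not inside the model's CDS or the
    codon cannot be recovered (partial terminal codon).
    """
    from Bio.Seq import Seq

    seq = reference[contig]
    offset = 0
    cds_index = None
    for a, b in gene.cds:
        if a <= pos < b:
            cds_index = offset + (pos - a)
            break
        offset += b - a
    if cds_index is None:
        raise ValueError("site is not inside this gene's CDS")
    cds_seq = "".join(seq[a:b] for a, b in gene.cds)
    if seq[pos] != ref:
        warnings.warn(f"reference base at {contig}:{pos + 1} is {seq[pos]!r}, "
                      f"not {ref!r}")
    alt_cds = cds_seq[:cds_index] + alt + cds_seq[cds_index + 1:]
    if gene.strand == "-":
        cds_seq = _revcomp(cds_seq)
        alt_cds = _revcomp(alt_cds)
        cds_index = len(cds_seq) - 1 - cds_index
    codon_i = cds_index // 3
    a, b = codon_i * 3, codon_i * 3 + 3
    if b > len(cds_seq):
        raise ValueError("partial codon: effect not determined")
    ref_codon, alt_codon = cds_seq[a:b], alt_cds[a:b]
    aa_ref = str(Seq(ref_codon).translate())
    aa_alt = str(Seq(alt_codon).translate())
    return "synonymous" if aa_ref == aa_alt else "nonsynonymous"


def annotate_sites(
    sites: pd.DataFrame,
    models: Mapping[str, list[GeneModel]],
    reference: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Classify every site; returns the input plus feature_class and effect.

    ``sites`` needs columns contig, pos (0-based), ref, alt.  ``effect`` is
    filled for CDS sites when a reference is given ("undetermined" for
    unrecoverable codons), empty otherwise.
    """
    out_class, out_effect = [], []
    for _, row in sites.iterrows():
        feat, gene = classify_snp(row["contig"], int(row["pos"]), models)
        effect = ""
        if feat == "CDS" and reference is not None and gene is not None:
            try:
                effect = coding_effect(row["contig"], int(row["pos"]),
                                       row["ref"], row["alt"], gene, reference)
            except ValueError:
                effect = "undetermined"
        out_class.append(feat)
        out_effect.append(effect)
    out = sites.copy()
    out["feature_class"] = out_class
    out["effect"] = out_effect
    return out
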