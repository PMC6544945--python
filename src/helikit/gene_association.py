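"""Genomic context of element insertions relative to gene annotation.

Each copy is classified as CDS, UTR5, UTR3, intron or intergenic by the
feature type with the largest overlap; ties are broken by the precedence
CDS > UTR5/UTR3 > intron (conservative toward exonic impact). When
transcripts disagree, the highest-precedence classification wins.
Intergenic copies carry a signed distance to the nearest gene boundary
(negative = upstream of the gene start in genome coordinates).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .core_io import GeneModel, HelitronCopy, Interval

CATEGORIES = ("CDS", "UTR5", "UTR3", "intron", "intergenic")
_PRECEDENCE = {"CDS": 0, "UTR5": 1, "UTR3": 1, "intron": 2}


@dataclass
class InsertionContext:
    category: str
    gene_id: str | None
    gene_strand: str | None
    distance: int | None  # 0 inside a gene; None when unknown


def _overlap(a: Interval, b: Interval) -> int:
    if a.contig_id != b.contig_id:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def classify_insertion(
    copy: HelitronCopy | Interval, gene_models: Sequence[GeneModel]
) -> InsertionContext:
    """Classify one copy against the annotation (strand-agnostic category)."""
    locus = copy.locus if isinstance(copy, HelitronCopy) else copy
    relevant = [g for g in gene_models if g.contig_id == locus.contig_id]
    if not any(g.contig_id == locus.contig_id for g in gene_models):
        return InsertionContext("intergenic", None, None, None)
    best: tuple | None = None  # (overlap, -precedence, category, gene)
    for g in relevant:
        for category, ivs in (
            ("CDS", g.cds),
            ("UTR5", g.utr5),
            ("UTR3", g.utr3),
            ("intron", g.introns),
        ):
            ov = sum(_overlap(locus, iv) for iv in ivs)
            if ov > 0:
                key = (ov, -_PRECEDENCE[category])
                if best is None or key > best[0]:
                    best = (key, category, g)
    if best is not None:
        _, category, g = best
        return InsertionContext(category, g.gene_id, g.strand, 0)
    # intergenic: signed distance to the nearest gene boundary
    nearest: tuple[int, GeneModel] | None = None
    for g in relevant:
        span = g.span
        if locus.end <= span.start:
            dist = locus.end - span.start  # negative: copy upstream of gene
        elif locus.start >= span.end:
            dist = locus.start - span.end  # positive: downstream
        else:
            dist = 0
        if nearest is None or abs(dist) < abs(nearest[0]):
            nearest = (dist, g)
    if nearest is None:
        return InsertionContext("intergenic", None, None, None)
    dist, g = nearest
    return InsertionContext("intergenic", g.gene_id, g.strand, dist)


def summarize_contexts(contexts: Sequence[InsertionContext]) -> dict:
    """Counts and fractions per category, plus copies-per-gene multiplicity."""
    if not contexts:
        raise ValueError("no labelled copies to summarise")
    counts = {c: 0 for c in CATEGORIES}
    per_gene: dict[str, int] = {}
    for ctx in contexts:
        counts[ctx.category] += 1
        if ctx.gene_id and ctx.category != "intergenic":
            per_gene[ctx.gene_id] = per_gene.get(ctx.gene_id, 0) + 1
    total = len(contexts)
    fractions = {c: counts[c] / total for c in CATEGORIES}
    return {"counts": counts, "fractions": fractions, "per_gene": per_gene, "total": total}


def write_context_table(contexts: Sequence[InsertionContext], loci: Sequence[Interval], path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tstart\tend\tstrand\tcategory\tgene\tgene_strand\tdistance\n")
        for ctx, iv in zip(contexts, loci):
            fh.write(
                f"{iv.contig_id}\t{iv.start + 1}\t{iv.end}\t{iv.strand}\t{ctx.category}\t"
                f"{ctx.gene_id or '.'}\t{ctx.gene_strand or '.'}\t"
                f"{'NA' if ctx.distance is None else ctx.distance}\n"
            )
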