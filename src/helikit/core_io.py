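"""Domain types shared across the pipeline, plus file readers and writers.

All genomic coordinates are held internally as 0-based half-open intervals;
anything written for human consumption (reports, GFF3) is converted to the
1-based inclusive convention used by NCBI and the GFF3 standard.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = frozenset("ACGTN")
FASTA_WRAP = 70


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeSeq:
    """One contig: identifier, uppercase sequence over {A,C,G,T,N}."""

    contig_id: str
    sequence: str

    def __post_init__(self):
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise ParseError(
                f"contig {self.contig_id!r}: characters outside A/C/G/T/N: {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Interval:
    """0-based half-open genomic interval with strand."""

    contig_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.contig_id == other.contig_id
            and self.start < other.end
            and other.start < self.end
        )

    def to_1based(self) -> str:
        """Human-facing locus string, 1-based inclusive."""
        return f"{self.contig_id}:{self.start + 1}-{self.end}({self.strand})"


@dataclass
class Hairpin:
    """A 3'-proximal inverted repeat able to fold into a stem-loop."""

    stem_len: int
    loop_len: int
    mismatches: int
    distance_to_3prime_terminus: int

    @property
    def palindrome_span(self) -> int:
        return 2 * self.stem_len + self.loop_len


@dataclass
class HelitronCopy:
    """One genomic occurrence of an element, with structural annotations.

    Hallmark flags are tri-state: True/False once tested, None when untested
    or un-validatable (N in the tested positions, missing flank).
    """

    locus: Interval
    sequence: str
    left_flank: str = ""
    right_flank: str = ""
    has_tc_start: bool | None = None
    three_prime_motif: str | None = None
    left_host_base: str = "N"
    right_host_base: str = "N"
    host_context_at: bool | None = None
    hairpin: Hairpin | None = None
    identity_to_consensus: float = 0.0
    consensus_coverage: float = 0.0
    assigned_label: str = ""

    def __post_init__(self):
        if not 0.0 <= self.identity_to_consensus <= 1.0:
            raise ValueError("identity_to_consensus outside [0, 1]")
        if not 0.0 <= self.consensus_coverage <= 1.0:
            raise ValueError("consensus_coverage outside [0, 1]")


@dataclass
class ConsensusElement:
    """Reconstructed exemplar consensus with its classification labels."""

    name: str
    sequence: str
    n_copies_used: int
    species: str = ""
    family_id: int = 0
    subfamily_letter: str = ""
    exemplar_letter: str = ""
    low_support: bool = False

    def __post_init__(self):
        if self.n_copies_used < 1:
            raise ValueError("n_copies_used must be >= 1")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class GeneModel:
    """One gene with per-transcript feature intervals (introns derived)."""

    gene_id: str
    contig_id: str
    strand: str
    exons: list[Interval] = field(default_factory=list)
    cds: list[Interval] = field(default_factory=list)
    utr5: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)
    introns: list[Interval] = field(default_factory=list)

    @property
    def span(self) -> Interval:
        parts = self.exons or self.cds
        return Interval(
            self.contig_id,
            min(p.start for p in parts),
            max(p.end for p in parts),
            self.strand,
        )


# ---------------------------------------------------------------------------
# sequence helpers
# ---------------------------------------------------------------------------

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path) -> list[GenomeSeq]:
    """Read a (optionally gzipped) FASTA file into GenomeSeq records.

    Lowercase input is uppercased; any character outside {A,C,G,T,N}
    (including U) is a parse error naming the offending line.
    """
    records: list[GenomeSeq] = []
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            seq = str(rec.seq).upper()
            if set(seq) - DNA_ALPHABET:
                raise ParseError(
                    f"{path}: record {rec.id!r}, line {_find_bad_line(path, rec.id)}: "
                    "sequence contains characters outside A/C/G/T/N"
                )
            records.append(GenomeSeq(rec.id, seq))
    return records


def _find_bad_line(path, record_id: str) -> int:
    """Locate the first offending sequence line of a record (error path only)."""
    in_record = False
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.startswith(">"):
                in_record = line[1:].split()[0] == record_id if line[1:].strip() else False
                continue
            if in_record and set(line.strip().upper()) - DNA_ALPHABET:
                return lineno
    return -1


def write_fasta(records: Iterable, path, wrap: int = FASTA_WRAP) -> None:
    """Write records (GenomeSeq/ConsensusElement/(id, seq) pairs) as FASTA."""
    seqrecords = []
    for rec in records:
        if isinstance(rec, GenomeSeq):
            rid, seq = rec.contig_id, rec.sequence
        elif isinstance(rec, ConsensusElement):
            rid, seq = rec.name, rec.sequence
        elif isinstance(rec, (tuple, list)):
            rid, seq = rec
        else:
            rid, seq = rec.id, str(rec.seq)
        seqrecords.append(SeqRecord(Seq(seq), id=rid, description=""))
    with open(path, "w") as handle:
        FastaWriter(handle, wrap=wrap).write_file(seqrecords)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def read_gff3(path) -> list[GeneModel]:
    """Read gene models from GFF3 (1-based inclusive -> 0-based half-open).

    Introns are derived as the gaps between consecutive exons of each
    transcript and deduplicated per gene. UTRs are taken from explicit
    five_prime_UTR/three_prime_UTR features when present, otherwise derived
    as exon minus CDS on the appropriate side. Unknown feature types are
    ignored; a child feature outside its parent's span triggers a warning
    but is kept.
    """
    genes: dict[str, GeneModel] = {}
    transcripts: dict[str, dict] = {}
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 tab-separated columns")
            contig, _, ftype, start1, end1, _, strand, _, attrs = cols
            try:
                start, end = int(start1) - 1, int(end1)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric coordinates") from exc
            attr = _parse_attrs(attrs)
            if ftype == "gene":
                gid = attr.get("ID", f"gene{lineno}")
                genes[gid] = GeneModel(gid, contig, strand)
                genes[gid]._span = (start, end)  # type: ignore[attr-defined]
            elif ftype in ("mRNA", "transcript"):
                tid = attr.get("ID", f"tx{lineno}")
                transcripts[tid] = {
                    "gene": attr.get("Parent", tid),
                    "contig": contig,
                    "strand": strand,
                    "exons": [],
                    "cds": [],
                    "utr5": [],
                    "utr3": [],
                    "span": (start, end),
                }
            elif ftype in ("exon", "CDS", "five_prime_UTR", "three_prime_UTR"):
                parent = attr.get("Parent")
                tx = transcripts.get(parent)
                if tx is None:
                    # exon attached directly to a gene record
                    if parent in genes:
                        tx = transcripts.setdefault(
                            parent + ".t",
                            {
                                "gene": parent,
                                "contig": contig,
                                "strand": strand,
                                "exons": [],
                                "cds": [],
                                "utr5": [],
                                "utr3": [],
                                "span": genes[parent]._span,  # type: ignore[attr-defined]
                            },
                        )
                    else:
                        continue
                pspan = tx["span"]
                if start < pspan[0] or end > pspan[1]:
                    warnings.warn(
                        f"{path}:{lineno}: {ftype} outside parent span; kept", stacklevel=2
                    )
                iv = Interval(contig, start, end, strand)
                key = {
                    "exon": "exons",
                    "CDS": "cds",
                    "five_prime_UTR": "utr5",
                    "three_prime_UTR": "utr3",
                }[ftype]
                tx[key].append(iv)
    return _assemble_gene_models(genes, transcripts)


def _parse_attrs(attrs: str) -> dict[str, str]:
    out = {}
    for item in attrs.split(";"):
        item = item.strip()
        if "=" in item:
            k, v = item.split("=", 1)
            out[k] = v
    return out


def _assemble_gene_models(genes, transcripts) -> list[GeneModel]:
    for tx in transcripts.values():
        gid = tx["gene"]
        gene = genes.setdefault(gid, GeneModel(gid, tx["contig"], tx["strand"]))
        exons = sorted(tx["exons"], key=lambda iv: iv.start)
        gene.exons.extend(iv for iv in exons if iv not in gene.exons)
        gene.cds.extend(iv for iv in tx["cds"] if iv not in gene.cds)
        # introns: gaps between consecutive exons of this transcript
        for a, b in zip(exons, exons[1:]):
            if b.start > a.end:
                intron = Interval(tx["contig"], a.end, b.start, tx["strand"])
                if intron not in gene.introns:
                    gene.introns.append(intron)
        utr5, utr3 = tx["utr5"], tx["utr3"]
        if not (utr5 or utr3) and tx["cds"] and exons:
            utr5, utr3 = _derive_utrs(exons, tx["cds"], tx["strand"])
        gene.utr5.extend(iv for iv in utr5 if iv not in gene.utr5)
        gene.utr3.extend(iv for iv in utr3 if iv not in gene.utr3)
    return [g for g in genes.values() if g.exons or g.cds]


def _derive_utrs(exons, cds, strand):
    """Exonic sequence outside the CDS extent, split by side of the CDS."""
    cds_start = min(iv.start for iv in cds)
    cds_end = max(iv.end for iv in cds)
    left, right = [], []
    for ex in exons:
        if ex.start < cds_start:
            left.append(Interval(ex.contig_id, ex.start, min(ex.end, cds_start), strand))
        if ex.end > cds_end:
            right.append(Interval(ex.contig_id, max(ex.start, cds_end), ex.end, strand))
    if strand == "+":
        return left, right
    return right, left


def write_gff3(gene_models: Sequence[GeneModel], path, extra_lines: Sequence[str] = ()) -> None:
    """Write gene models (one transcript per gene) back to GFF3, 1-based."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in gene_models:
            sp = g.span
            fh.write(
                f"{g.contig_id}\thelikit\tgene\t{sp.start + 1}\t{sp.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            tid = g.gene_id + ".t1"
            fh.write(
                f"{g.contig_id}\thelikit\tmRNA\t{sp.start + 1}\t{sp.end}\t.\t{g.strand}\t.\tID={tid};Parent={g.gene_id}\n"
            )
            for ftype, ivs in (
                ("exon", g.exons),
                ("CDS", g.cds),
                ("five_prime_UTR", g.utr5),
                ("three_prime_UTR", g.utr3),
            ):
                for iv in sorted(ivs, key=lambda v: v.start):
                    fh.write(
                        f"{iv.contig_id}\thelikit\t{ftype}\t{iv.start + 1}\t{iv.end}\t.\t{g.strand}\t.\tParent={tid}\n"
                    )
        for line in extra_lines:
            fh.write(line.rstrip("\n") + "\n")


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

REPORT_COLUMNS = [
    "name",
    "avg_divergence",
    "length_bp",
    "n_copies_for_consensus",
    "copies",
    "pct_genome",
]


def write_report(rows, path) -> None:
    """Write per-exemplar divergence/copy-number rows as TSV.

    Rows are DivergenceReport-like objects (see quantify). Divergence and
    genome fraction are printed to 3 decimals; a divergence of None prints
    as "ND" (fragmentation rule). Refuses to write an empty table.
    """
    rows = list(rows)
    if not rows:
        raise ValueError("write_report: no rows to write")
    with open(path, "w") as fh:
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for r in rows:
            div = "ND" if r.avg_divergence is None else f"{r.avg_divergence:.3f}"
            fh.write(
                f"{r.exemplar_name}\t{div}\t{r.consensus_len}\t"
                f"{r.n_copies_for_divergence}\t{r.n_copies} ({r.genome_fraction:.3f})\n"
            )


def write_bed(intervals: Sequence[Interval], path, names: Sequence[str] | None = None) -> None:
    """Write intervals as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names else f"feature{i + 1}"
            fh.write(f"{iv.contig_id}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------


def read_newick(path):
    """Read one tree from a Newick file (dendropy Tree)."""
    import dendropy

    return dendropy.Tree.get(path=str(path), schema="newick")


def write_newick(tree, path) -> None:
    """Write a dendropy Tree (or Newick string) to file."""
    if isinstance(tree, str):
        text = tree.strip()
        if not text.endswith(";"):
            text += ";"
        Path(path).write_text(text + "\n")
    else:
        tree.write(path=str(path), schema="newick", suppress_rooting=True)
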