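"""Stepwise sequence acquisition, autonomous-element reconstruction and
empty-site detection.

Non-autonomous Helitron exemplars within a subfamily often form a nested
series: a short core sequence plus successively captured host fragments
(filler DNA patched into double-strand breaks, leaving 2-13 bp junction
microhomologies that match the flanks of the source locus). This module
infers the core and the inserted regions from a consensus set, locates each
insert's genomic source locus and its end junctions, orders exemplars by
average divergence (older = more diverged), rebuilds the autonomous
Rep/helicase partner from degenerate copies, scans the protein for
replication-initiator and SF1 helicase motif blocks, and finds paralogous
or orthologous empty sites (the joined host flanks without the element).

The bundled motif reference blocks are synthetic stand-ins written for this
package (see data/rep_hel_motifs_synthetic.fasta): short blocks carrying
the canonical features (two-His initiator motif, two catalytic tyrosines,
eight SF1 motif blocks), not sequences taken from any published element.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .align import semiglobal_align
from .consensus import align_copies, build_consensus
from .core_io import ConsensusElement, GenomeSeq, HelitronCopy, Interval, revcomp
from .homology_search import KmerIndex, index_genome, search
from .quantify import DivergenceReport

MIN_CORE_BLOCK = 50
JUNCTION_RANGE = (2, 13)


class NoCoreError(ValueError):
    """No common block of sufficient length across the consensus set."""


class NoAutonomousPartner(ValueError):
    """No uninterrupted ORF of the required length could be reconstructed."""


# ---------------------------------------------------------------------------
# core inference
# ---------------------------------------------------------------------------


@dataclass
class CaptureRegion:
    """An inserted segment of a child consensus relative to the core."""

    child_exemplar: str
    parent: str  # parent exemplar or "core"
    insert_start: int  # on the child consensus, 0-based
    insert_end: int
    source_locus: Interval | None = None
    source_strand: str = "+"
    left_junction: str | None = None
    right_junction: str | None = None
    junction_in_range: bool = False

    @property
    def length(self) -> int:
        return self.insert_end - self.insert_start


def infer_core(
    members: Sequence[ConsensusElement | tuple[str, str]],
) -> tuple[str, dict[str, list[tuple[int, int]]]]:
    """Infer the shared core and per-member insertions from a consensus set.

    The set (optionally including a genomic copy shorter than all
    exemplars) is aligned with the shortest member as the alignment center;
    the core is the majority base over columns occupied in every member, and
    each member's insertions are the runs of non-core columns it occupies,
    reported in its own coordinates. Raises NoCoreError when no common
    block reaches 50 bp.
    """
    named = [
        (m.name, m.sequence) if isinstance(m, ConsensusElement) else tuple(m)
        for m in members
    ]
    if len(named) < 2:
        raise ValueError("need at least 2 sequences to infer a core")
    seqs = [s for _, s in named]
    center = min(range(len(seqs)), key=lambda i: len(seqs[i]))
    rows = align_copies(seqs, center_index=center)
    ncol = len(rows[0])
    core_cols = [all(r[c] != "-" for r in rows) for c in range(ncol)]
    longest = run = 0
    for flag in core_cols:
        run = run + 1 if flag else 0
        longest = max(longest, run)
    if longest < MIN_CORE_BLOCK:
        raise NoCoreError(f"no common block >= {MIN_CORE_BLOCK} bp")
    core_seq = "".join(
        _majority_base([r[c] for r in rows]) for c in range(ncol) if core_cols[c]
    )
    inserts: dict[str, list[tuple[int, int]]] = {}
    for (name, _), row in zip(named, rows):
        spans = []
        pos = 0  # position on the ungapped member sequence
        start = None
        for c in range(ncol):
            occupied = row[c] != "-"
            if occupied and not core_cols[c]:
                if start is None:
                    start = pos
            elif start is not None:
                spans.append((start, pos))
                start = None
            if occupied:
                pos += 1
        if start is not None:
            spans.append((start, pos))
        inserts[name] = spans
    return core_seq, inserts


def _majority_base(chars: list[str]) -> str:
    counts: dict[str, int] = {}
    for ch in chars:
        if ch not in "-N":
            counts[ch] = counts.get(ch, 0) + 1
    return min(counts, key=lambda b: (-counts[b], "ACGT".index(b)))


# ---------------------------------------------------------------------------
# source loci and filler-DNA junctions
# ---------------------------------------------------------------------------


def find_source_locus(
    insert_seq: str,
    element_seq: str,
    insert_start: int,
    genomes: Sequence[GenomeSeq],
    exclude: Sequence[Interval] = (),
    index: KmerIndex | None = None,
    min_identity: float = 0.8,
    child_exemplar: str = "child",
    parent: str = "core",
) -> CaptureRegion:
    """Locate the genomic source of an inserted region and its end junctions.

    The best genomic match of the insert outside known element copies is the
    source locus; the junctions are the maximal exact overlaps between the
    element sequence flanking the insert and the genomic sequence flanking
    the source. Junctions of 2-13 bp support the filler-DNA model; longer
    overlaps are reported but flagged out of range. A missing match leaves
    the source unknown.
    """
    if len(insert_seq) < 20:
        raise ValueError("insert too short to search (need >= 20 bp)")
    region = CaptureRegion(
        child_exemplar, parent, insert_start, insert_start + len(insert_seq)
    )
    idx = index if index is not None else index_genome(genomes)
    hits = search(insert_seq, idx, min_identity=min_identity, min_len=min(20, len(insert_seq)))
    hits = [
        h
        for h in hits
        if not any(h.target_span.overlaps(iv) for iv in exclude)
    ]
    if not hits:
        return region  # source unknown
    best = max(hits, key=lambda h: h.score)
    seqs = {g.contig_id: g.sequence for g in genomes}
    contig = seqs[best.target_span.contig_id]
    t0, t1 = best.target_span.start, best.target_span.end
    q0, q1 = best.query_span.start, best.query_span.end
    elem_left = element_seq[: insert_start + q0]
    elem_right = element_seq[insert_start + q1 :]
    if best.strand == "+":
        src_left, src_right = contig[:t0], contig[t1:]
    else:
        src_left, src_right = revcomp(contig[t1:]), revcomp(contig[:t0])
    left_j = _common_suffix(elem_left, src_left)
    right_j = _common_prefix(elem_right, src_right)
    region.source_locus = best.target_span
    region.source_strand = best.strand
    region.left_junction = left_j or None
    region.right_junction = right_j or None
    lo, hi = JUNCTION_RANGE
    region.junction_in_range = (
        lo <= len(left_j) <= hi and lo <= len(right_j) <= hi
    )
    return region


def _common_suffix(a: str, b: str) -> str:
    n = 0
    while n < min(len(a), len(b)) and a[-1 - n] == b[-1 - n]:
        n += 1
    return a[len(a) - n :] if n else ""


def _common_prefix(a: str, b: str) -> str:
    n = 0
    while n < min(len(a), len(b)) and a[n] == b[n]:
        n += 1
    return a[:n]


def order_exemplars_by_divergence(
    reports: Sequence[DivergenceReport],
) -> tuple[list[str], bool]:
    """Acquisition order (oldest -> youngest) by descending average divergence.

    Returns (ordered names, ambiguous flag); ambiguous is set when two
    exemplars tie. Exemplars with ND divergence are excluded; at least two
    determined values are required.
    """
    usable = [r for r in reports if r.avg_divergence is not None]
    if len(usable) < 2:
        raise ValueError("need >= 2 exemplars with determined divergence")
    usable.sort(key=lambda r: (-r.avg_divergence, r.exemplar_name))
    values = [r.avg_divergence for r in usable]
    ambiguous = any(a == b for a, b in zip(values, values[1:]))
    return [r.exemplar_name for r in usable], ambiguous


# ---------------------------------------------------------------------------
# autonomous partner reconstruction
# ---------------------------------------------------------------------------


@dataclass
class RepHelProtein:
    """Reconstructed Rep/helicase protein with motif annotations."""

    aa_sequence: str
    orf_start: int  # on the reconstructed DNA, 0-based
    orf_end: int
    strand: str
    rep_his_positions: list[int] = field(default_factory=list)
    rep_tyr_positions: list[int] = field(default_factory=list)
    helicase_motif_count: int = 0
    motif_hits: dict = field(default_factory=dict)


def reconstruct_autonomous(
    copy_set: Sequence[str], min_aa: int = 1000
) -> tuple[str, RepHelProtein]:
    """Rebuild the uninterrupted Rep/helicase ORF from degenerate copies.

    Copies are aligned and majority-voted; a frameshifting deletion present
    in a minority of rows is outvoted by the intact rows (columns are never
    invented, only chosen among observed ones). The longest ORF of at least
    min_aa amino acids on either strand is returned with its translation.
    Raises NoAutonomousPartner if no such ORF survives.
    """
    copies = [c for c in copy_set if c]
    if not copies:
        raise ValueError("empty copy set")
    if len(copies) == 1:
        dna = copies[0]
    else:
        rows = align_copies(list(copies))
        dna, _ = build_consensus(rows, min_copies=2)
    best = _longest_orf(dna)
    if best is None or best[3] < min_aa:
        raise NoAutonomousPartner(
            f"no ORF >= {min_aa} aa after reconstruction"
        )
    start, end, strand, _ = best
    frame_seq = dna if strand == "+" else revcomp(dna)
    aa = str(Seq(frame_seq[start:end]).translate())
    assert "*" not in aa.rstrip("*")
    aa = aa.rstrip("*")
    return dna, RepHelProtein(aa, start, end, strand)


def _longest_orf(dna: str):
    """(start, end, strand, aa_len) of the longest ATG..stop ORF, or None."""
    stops = {"TAA", "TAG", "TGA"}
    best = None
    for strand in "+-":
        seq = dna if strand == "+" else revcomp(dna)
        for frame in range(3):
            start = None
            for i in range(frame, len(seq) - 2, 3):
                codon = seq[i : i + 3]
                if codon in stops:
                    if start is not None:
                        aa_len = (i - start) // 3
                        if best is None or aa_len > best[3]:
                            best = (start, i + 3, strand, aa_len)
                        start = None
                elif codon == "ATG" and start is None:
                    start = i
    return best


# ---------------------------------------------------------------------------
# Rep/helicase motif scan
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MotifBlock:
    name: str
    sequence: str
    key_positions: tuple[int, ...]  # conserved residues within the block


def load_motif_blocks() -> list[MotifBlock]:
    """Bundled synthetic Rep/helicase reference motif blocks."""
    blocks = []
    text = (
        resources.files("helikit")
        .joinpath("data/rep_hel_motifs_synthetic.fasta")
        .read_text()
    )
    name, keys, chunks = None, (), []
    for line in text.splitlines():
        if line.startswith(">"):
            if name:
                blocks.append(MotifBlock(name, "".join(chunks), keys))
            fields = line[1:].split()
            name = fields[0]
            keys = ()
            for f in fields[1:]:
                if f.startswith("key=") and len(f) > 4:
                    keys = tuple(int(x) for x in f[4:].split(","))
            chunks = []
        elif line.strip():
            chunks.append(line.strip())
    if name:
        blocks.append(MotifBlock(name, "".join(chunks), keys))
    return blocks


def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner(mode="local")
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def scan_rep_hel_motifs(
    protein: RepHelProtein | str,
    min_block_identity: float = 0.5,
    blocks: Sequence[MotifBlock] | None = None,
) -> RepHelProtein | dict:
    """Annotate Rep (two-His, two-Tyr) and SF1 helicase motif blocks.

    Each bundled block is locally aligned to the protein; a block counts as
    found when its identity (exact matches / block length) reaches
    min_block_identity. Key residues of found Rep blocks are mapped to
    protein coordinates. Returns the annotated RepHelProtein (or a plain
    dict when given a bare string).
    """
    aa = protein.aa_sequence if isinstance(protein, RepHelProtein) else protein
    if len(aa) < 30:
        raise ValueError("protein too short to scan")
    blocks = list(blocks) if blocks is not None else load_motif_blocks()
    aligner = _protein_aligner()
    hits: dict[str, dict] = {}
    his_pos: list[int] = []
    tyr_pos: list[int] = []
    hel_count = 0
    for block in blocks:
        try:
            aln = aligner.align(block.sequence, aa)[0]
        except (IndexError, ValueError):
            continue
        counts = aln.counts()
        identity = counts.identities / len(block.sequence)
        if identity < min_block_identity:
            continue
        b_blocks, p_blocks = aln.aligned
        mapping = {}
        for (bs, be), (ps, _pe) in zip(b_blocks, p_blocks):
            for off in range(be - bs):
                mapping[bs + off] = ps + off
        key_map = [int(mapping[k]) for k in block.key_positions if k in mapping]
        hits[block.name] = {
            "identity": round(identity, 4),
            "protein_span": (int(p_blocks[0][0]), int(p_blocks[-1][1])),
            "key_positions": key_map,
        }
        if block.name == "rep_two_his":
            his_pos = key_map
        elif block.name == "rep_two_tyr":
            tyr_pos = key_map
        elif block.name.startswith("hel_"):
            hel_count += 1
    if isinstance(protein, RepHelProtein):
        protein.rep_his_positions = his_pos
        protein.rep_tyr_positions = tyr_pos
        protein.helicase_motif_count = hel_count
        protein.motif_hits = hits
        return protein
    return {
        "rep_his_positions": his_pos,
        "rep_tyr_positions": tyr_pos,
        "helicase_motif_count": hel_count,
        "motif_hits": hits,
    }


# ---------------------------------------------------------------------------
# empty sites
# ---------------------------------------------------------------------------


def find_empty_sites(
    copy: HelitronCopy,
    genomes_by_name: Mapping[str, Sequence[GenomeSeq]],
    home_genome: str,
    flank: int = 50,
    min_identity: float = 0.9,
    max_junction_gap: int = 2,
    indexes: Mapping[str, KmerIndex] | None = None,
) -> list[tuple[Interval, str, str]]:
    """Loci where the copy's joined host flanks occur without the element.

    The query is left flank + right flank concatenated; a locus qualifies
    when it matches at >= min_identity with at most max_junction_gap extra
    bases at the junction, excluding the copy's own locus. Sites in the
    copy's own genome are paralogous, sites in another genome orthologous.
    """
    if len(copy.left_flank) < flank or len(copy.right_flank) < flank:
        raise ValueError("copy lacks sufficient flanks for empty-site search")
    query = copy.left_flank[-flank:] + copy.right_flank[:flank]
    results = []
    for name, genomes in genomes_by_name.items():
        idx = indexes[name] if indexes else index_genome(genomes)
        hits = search(query, idx, min_identity=min_identity, min_len=int(1.5 * flank))
        seqs = {g.contig_id: g.sequence for g in genomes}
        own = Interval(
            copy.locus.contig_id,
            max(0, copy.locus.start - flank),
            copy.locus.end + flank,
            copy.locus.strand,
        )
        for h in hits:
            if name == home_genome and h.target_span.overlaps(own):
                continue
            target = seqs[h.target_span.contig_id][
                h.target_span.start : h.target_span.end
            ]
            if h.strand == "-":
                target = revcomp(target)
            if _junction_gap(query, target, flank) > max_junction_gap:
                continue
            label = "paralogous" if name == home_genome else "orthologous"
            results.append((h.target_span, name, label))
    return results


def _junction_gap(query: str, target: str, junction_pos: int) -> int:
    """Extra target bases inserted at the query's flank junction."""
    res = semiglobal_align(query, target)
    qpos = res.span_a[0]
    gap_run = 0
    max_gap_at_junction = 0
    for a, _b in zip(res.aligned_a, res.aligned_b):
        if a == "-":
            gap_run += 1
        else:
            if qpos == junction_pos:
                max_gap_at_junction = gap_run
            gap_run = 0
            qpos += 1
    return max_gap_at_junction
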