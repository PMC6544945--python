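"""Synthetic genomes with planted Helitron copies and ground truth.

The generator emulates the genomic situations the analysis assumes: random
background at a stated GC content, element copies radiating from a master
sequence under a Kimura two-parameter substitution process (star phylogeny,
one mutation round per copy), precise A|T host integration context, 3'
truncations, stepwise capture series with filler-DNA junction
microhomologies, source loci, element-absent (empty) sites, and simple gene
models. Every planted feature is recorded in a truth ledger so parameter
recovery can be scored exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .core_io import (
    GeneModel,
    GenomeSeq,
    Interval,
    revcomp,
    write_fasta,
    write_gff3,
)

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}

THREE_PRIME = "CTGT"  # one realisation of the CTRY terminal motif
HAIRPIN_STEM = 8
HAIRPIN_LOOP = 4
HAIRPIN_GAP = 10  # bp between hairpin end and element 3' end


# ---------------------------------------------------------------------------
# configuration and truth ledger
# ---------------------------------------------------------------------------


@dataclass
class CaptureSpec:
    """One stepwise-acquisition event: a fragment inserted into a parent."""

    parent_label: str
    child_label: str
    insert_len: int
    insert_offset: int  # bp from the parent's 5' end
    junction_len: int = 6

    def __post_init__(self):
        if not 2 <= self.junction_len <= 13:
            raise ValueError("junction_len must be within [2, 13]")
        if self.insert_len <= 0:
            raise ValueError("insert_len must be positive")


@dataclass
class SimConfig:
    seed: int = 0
    n_contigs: int = 2
    contig_len: int = 200_000
    gc_content: float = 0.40
    copies_per_element: int = 50
    divergence_d: float = 0.05
    ts_tv_kappa: float = 2.0
    truncation_prob: float = 0.0
    truncation_range: tuple[int, int] = (50, 150)
    element_len: int = 300
    n_genes: int = 0
    exons_per_gene: int = 3
    empty_site_pairs: int = 0

    def __post_init__(self):
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content outside [0, 1]")
        if self.divergence_d < 0:
            raise ValueError("divergence_d must be >= 0")
        if self.ts_tv_kappa <= 0:
            raise ValueError("ts_tv_kappa must be > 0")


@dataclass
class MasterElement:
    """A master (source) element plus the positions exempt from mutation."""

    label: str
    sequence: str
    protected: frozenset[int] = frozenset()


@dataclass
class PlantedCopy:
    label: str
    locus: Interval
    sequence: str  # element-strand sequence as planted
    divergence_d: float
    truncated: bool


@dataclass
class PlantedCapture:
    spec: CaptureSpec
    insert_seq: str
    source_locus: Interval | None


@dataclass
class SimTruth:
    copies: list[PlantedCopy] = field(default_factory=list)
    captures: list[PlantedCapture] = field(default_factory=list)
    empty_sites: list[tuple[Interval, Interval]] = field(default_factory=list)
    gene_models: list[GeneModel] = field(default_factory=list)
    masters: dict[str, MasterElement] = field(default_factory=dict)

    def copies_of(self, label: str) -> list[PlantedCopy]:
        return [c for c in self.copies if c.label == label]


# ---------------------------------------------------------------------------
# K2P substitution process
# ---------------------------------------------------------------------------


def expected_pq(d: float, kappa: float) -> tuple[float, float]:
    """Expected transition (P) and transversion (Q) proportions at distance d.

    Rates are normalised so d is the expected substitutions per site, with
    transition:transversion rate ratio kappa (each of the two transversion
    targets at rate beta, the transition target at rate alpha = kappa*beta).
    """
    beta_t = d / (kappa + 2.0)
    alpha_t = kappa * beta_t
    p = 0.25 + 0.25 * math.exp(-4.0 * beta_t) - 0.5 * math.exp(-2.0 * (alpha_t + beta_t))
    q = 0.5 - 0.5 * math.exp(-4.0 * beta_t)
    return p, q


def _compensated_distance(d: float, kappa: float, free_fraction: float) -> float:
    """Rate on the free sites such that the whole-sequence expected K2P
    estimate equals d.

    With a fraction of sites held invariant (hallmark protection), the
    sequence-wide substitution proportions are a mixture, and the K2P
    inverse is nonlinear in them, so a simple rate rescaling leaves a bias
    at larger d; solve for the free-site distance by bisection instead.
    """
    if d == 0 or free_fraction >= 1.0:
        return d

    def estimate(d_eff: float) -> float:
        p, q = expected_pq(d_eff, kappa)
        pm, qm = free_fraction * p, free_fraction * q
        return -0.5 * math.log((1 - 2 * pm - qm) * math.sqrt(1 - 2 * qm))

    lo, hi = d, d / free_fraction * 1.5
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if estimate(mid) < d:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def mutate_copy(
    master: str,
    d: float,
    kappa: float,
    rng: np.random.Generator | int,
    protected: frozenset[int] | None = None,
) -> str:
    """One realisation of the K2P process applied to a master sequence.

    Per-site independent substitutions whose expected K2P estimate over the
    WHOLE sequence equals d. Positions in `protected` (default: first 2 bp
    and last 4 bp, so the terminal hallmarks survive) are exempt; the rate
    on the free sites is scaled up to compensate, so a downstream estimator
    that sees all sites remains unbiased for d.
    """
    if d < 0:
        raise ValueError("d must be >= 0")
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    if d == 0:
        return master
    if protected is None:
        protected = frozenset(range(2)) | frozenset(range(len(master) - 4, len(master)))
    n_free = len(master) - len(protected & frozenset(range(len(master))))
    if n_free <= 0:
        return master
    d_eff = _compensated_distance(d, kappa, n_free / len(master))
    p, q = expected_pq(d_eff, kappa)
    if 1.0 - 2.0 * p - q <= 1e-12 or 1.0 - 2.0 * q <= 1e-12:
        raise ValueError("d too large: K2P distance saturates; use a smaller d")
    u = rng.random(len(master))
    which_tv = rng.integers(0, 2, len(master))
    out = list(master)
    for i, base in enumerate(master):
        if i in protected or base not in "ACGT":
            continue
        if u[i] < p:
            out[i] = TRANSITION[base]
        elif u[i] < p + q:
            out[i] = TRANSVERSIONS[base][which_tv[i]]
    return "".join(out)


# ---------------------------------------------------------------------------
# background and master construction
# ---------------------------------------------------------------------------


def make_background(config: SimConfig, rng: np.random.Generator | None = None) -> list[GenomeSeq]:
    """I.i.d. background contigs at the configured GC content."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    gc = config.gc_content
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    genomes = []
    for i in range(config.n_contigs):
        draws = rng.choice(4, size=config.contig_len, p=probs)
        seq = BASES[draws].tobytes().decode()
        genomes.append(GenomeSeq(f"contig{i + 1}", seq))
    return genomes


def make_master_element(
    rng: np.random.Generator,
    label: str = "Hel1",
    length: int = 300,
    gc: float = 0.40,
) -> MasterElement:
    """A structurally complete master element.

    Layout: TC + internal sequence + 20 bp palindromic hairpin (stem 8,
    loop 4) + 10 bp spacer ending in the 4 bp CTRY terminus. The terminal
    motifs and the hairpin positions are marked protected so hallmark
    checks on mutated copies stay deterministic.
    """
    span = 2 * HAIRPIN_STEM + HAIRPIN_LOOP
    tail_len = span + HAIRPIN_GAP
    internal_len = length - 2 - tail_len
    if internal_len < 10:
        raise ValueError("element length too short for the hallmark layout")
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])

    def rand(n):
        return BASES[rng.choice(4, size=n, p=probs)].tobytes().decode()

    stem = rand(HAIRPIN_STEM)
    loop = rand(HAIRPIN_LOOP)
    hairpin = stem + loop + revcomp(stem)
    spacer = rand(HAIRPIN_GAP - 4)
    seq = "TC" + rand(internal_len) + hairpin + spacer + THREE_PRIME
    assert len(seq) == length
    hp_start = 2 + internal_len
    protected = (
        frozenset(range(2))
        | frozenset(range(hp_start, hp_start + span))
        | frozenset(range(length - 4, length))
    )
    return MasterElement(label, seq, protected)


# ---------------------------------------------------------------------------
# splicing with truth-ledger coordinate maintenance
# ---------------------------------------------------------------------------


def _shift_interval(iv: Interval, contig: str, pos: int, delta: int) -> Interval:
    if iv.contig_id != contig or iv.start < pos:
        return iv
    return Interval(iv.contig_id, iv.start + delta, iv.end + delta, iv.strand)


def _splice(genomes: list[GenomeSeq], truth: SimTruth, contig: str, pos: int, insert: str) -> list[GenomeSeq]:
    """Insert `insert` at position pos of a contig, shifting truth records."""
    out = []
    for g in genomes:
        if g.contig_id == contig:
            out.append(GenomeSeq(contig, g.sequence[:pos] + insert + g.sequence[pos:]))
        else:
            out.append(g)
    delta = len(insert)
    for pc in truth.copies:
        pc.locus = _shift_interval(pc.locus, contig, pos, delta)
    for cap in truth.captures:
        if cap.source_locus is not None:
            cap.source_locus = _shift_interval(cap.source_locus, contig, pos, delta)
    truth.empty_sites = [
        (_shift_interval(a, contig, pos, delta), _shift_interval(b, contig, pos, delta))
        for a, b in truth.empty_sites
    ]
    return out


def _at_sites(seq: str, rng: np.random.Generator, n: int, forbidden) -> list[int]:
    """Positions i where seq[i-1:i+1] == 'AT' and i is outside forbidden spans."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    hits = np.nonzero((arr[:-1] == ord("A")) & (arr[1:] == ord("T")))[0] + 1
    if len(forbidden):
        ok = np.ones(len(hits), dtype=bool)
        for s, e in forbidden:
            ok &= ~((hits > s - 2) & (hits < e + 2))
        hits = hits[ok]
    if len(hits) < n:
        return []
    chosen = rng.choice(hits, size=n, replace=False)
    return sorted(int(c) for c in chosen)


def plant_copies(
    genomes: list[GenomeSeq],
    master: MasterElement,
    config: SimConfig,
    truth: SimTruth | None = None,
    rng: np.random.Generator | None = None,
    n_copies: int | None = None,
) -> tuple[list[GenomeSeq], SimTruth]:
    """Plant diverged copies of a master element between host A|T dinucleotides.

    Each copy is an independent K2P mutation of the master at the configured
    distance; with probability truncation_prob a uniform 3' suffix within
    truncation_range is lost. Strand is chosen at random; on either strand
    the element-strand host context is A|T. Copies never overlap previously
    planted features. When a contig lacks enough A|T sites, new sites are
    created by writing A + element + T at random positions.
    """
    truth = truth if truth is not None else SimTruth()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    truth.masters.setdefault(master.label, master)
    n = n_copies if n_copies is not None else config.copies_per_element
    per_contig = np.bincount(rng.integers(0, len(genomes), n), minlength=len(genomes))
    for gi, g in enumerate(genomes):
        count = int(per_contig[gi])
        if count == 0:
            continue
        if g.length < count * (len(master.sequence) + 20):
            raise ValueError(f"contig {g.contig_id} too short for {count} copies")
        forbidden = [
            (c.locus.start, c.locus.end)
            for c in truth.copies
            if c.locus.contig_id == g.contig_id
        ]
        sites = _at_sites(g.sequence, rng, count, forbidden)
        created = not sites
        if created:  # fall back: create A|T sites
            sites = sorted(
                int(p)
                for p in rng.choice(g.length - 1, size=count, replace=False)
            )
        offset = 0
        for pos0 in sites:
            pos = pos0 + offset
            seq = mutate_copy(
                master.sequence, config.divergence_d, config.ts_tv_kappa, rng, master.protected
            )
            truncated = bool(rng.random() < config.truncation_prob)
            if truncated:
                lo, hi = config.truncation_range
                cut = int(rng.integers(lo, hi + 1))
                seq = seq[: max(10, len(seq) - cut)]
            strand = "+" if rng.random() < 0.5 else "-"
            payload = seq if strand == "+" else revcomp(seq)
            if created:
                payload = "A" + payload + "T"
                elem_start = pos + 1
            else:
                elem_start = pos
            genomes = _splice(genomes, truth, g.contig_id, pos, payload)
            truth.copies.append(
                PlantedCopy(
                    label=master.label,
                    locus=Interval(g.contig_id, elem_start, elem_start + len(seq), strand),
                    sequence=seq,
                    divergence_d=config.divergence_d,
                    truncated=truncated,
                )
            )
            offset += len(payload)
    return genomes, truth


# ---------------------------------------------------------------------------
# capture series (stepwise acquisition) and empty sites
# ---------------------------------------------------------------------------


def make_capture_series(
    master: MasterElement,
    specs: list[CaptureSpec],
    rng: np.random.Generator,
    source_flank: int = 60,
) -> tuple[list[MasterElement], list[tuple[CaptureSpec, str, str]]]:
    """Build nested exemplar masters and their source-locus sequences.

    Exemplar k+1 equals exemplar k with a random fragment inserted at
    insert_offset. The returned source-locus sequence shares exactly
    junction_len bp with the element on each side of the insertion point
    (the filler-DNA microhomology); the flanking base beyond each junction
    is forced to mismatch so the junctions are maximal.
    """
    masters = {master.label: master}
    ordered = [master]
    sources = []
    for spec in specs:
        parent = masters.get(spec.parent_label)
        if parent is None:
            raise ValueError(f"unknown parent label {spec.parent_label!r}")
        if spec.insert_offset >= len(parent.sequence):
            raise ValueError("insert_offset beyond parent length")
        j = spec.junction_len
        if spec.insert_offset < j or spec.insert_offset + j > len(parent.sequence):
            raise ValueError("insert_offset too close to the element ends for the junction")
        insert = BASES[rng.integers(0, 4, spec.insert_len)].tobytes().decode()
        pseq = parent.sequence
        off = spec.insert_offset
        # unambiguous insertion boundaries: the insert must not begin/end
        # with the parent base it abuts, or the junction position would be
        # ambiguous in any alignment
        insert = (
            _different_base(pseq[off], rng)
            + insert[1:-1]
            + _different_base(pseq[off - 1], rng)
        )
        child_seq = pseq[:off] + insert + pseq[off:]
        # protected positions shift past the insertion point
        protected = frozenset(
            p if p < off else p + spec.insert_len for p in parent.protected
        )
        child = MasterElement(spec.child_label, child_seq, protected)
        masters[spec.child_label] = child
        ordered.append(child)
        left_j = pseq[off - j : off]
        right_j = pseq[off : off + j]
        lflank = BASES[rng.integers(0, 4, source_flank)].tobytes().decode()
        rflank = BASES[rng.integers(0, 4, source_flank)].tobytes().decode()
        # force maximality of the junctions
        lflank = lflank[:-1] + _different_base(pseq[off - j - 1], rng)
        rflank = _different_base(pseq[off + j], rng) + rflank[1:]
        source_seq = lflank + left_j + insert + right_j + rflank
        sources.append((spec, insert, source_seq))
    return ordered, sources


def _different_base(base: str, rng: np.random.Generator) -> str:
    options = [b for b in "ACGT" if b != base]
    return options[int(rng.integers(0, len(options)))]


def plant_capture_series(
    genomes: list[GenomeSeq],
    master: MasterElement,
    specs: list[CaptureSpec],
    rng: np.random.Generator,
    truth: SimTruth | None = None,
) -> tuple[list[GenomeSeq], list[MasterElement], SimTruth]:
    """Build the exemplar series and write each source locus into the genome."""
    truth = truth if truth is not None else SimTruth()
    masters, sources = make_capture_series(master, specs, rng)
    for m in masters:
        truth.masters.setdefault(m.label, m)
    for spec, insert, source_seq in sources:
        gi = int(rng.integers(0, len(genomes)))
        g = genomes[gi]
        forbidden = [
            (c.locus.start, c.locus.end) for c in truth.copies if c.locus.contig_id == g.contig_id
        ]
        pos = int(rng.integers(0, g.length))
        while any(s - 1 <= pos <= e + 1 for s, e in forbidden):
            pos = int(rng.integers(0, g.length))
        genomes = _splice(genomes, truth, g.contig_id, pos, source_seq)
        locus = Interval(g.contig_id, pos, pos + len(source_seq), "+")
        truth.captures.append(PlantedCapture(spec, insert, locus))
    return genomes, masters, truth


def plant_empty_sites(
    genomes: list[GenomeSeq],
    truth: SimTruth,
    n: int,
    rng: np.random.Generator,
    flank: int = 50,
) -> tuple[list[GenomeSeq], SimTruth]:
    """For n planted copies, plant a second locus carrying the joined flanks.

    The empty site is the host sequence around the copy with the element
    absent: left flank + right flank, adjacent, exactly as a pre-insertion
    (or precisely excised) locus would read.
    """
    if n == 0:
        return genomes, truth
    if n > len(truth.copies):
        raise ValueError("more empty sites requested than planted copies")
    chosen = rng.choice(len(truth.copies), size=n, replace=False)
    for ci in sorted(int(c) for c in chosen):
        pc = truth.copies[ci]
        seqs = {g.contig_id: g.sequence for g in genomes}
        src = seqs[pc.locus.contig_id]
        left = src[max(0, pc.locus.start - flank) : pc.locus.start]
        right = src[pc.locus.end : pc.locus.end + flank]
        joined = left + right
        gi = int(rng.integers(0, len(genomes)))
        g = genomes[gi]
        pos = int(rng.integers(0, g.length))
        forbidden = [
            (c.locus.start, c.locus.end) for c in truth.copies if c.locus.contig_id == g.contig_id
        ]
        while any(s - 1 <= pos <= e + 1 for s, e in forbidden):
            pos = int(rng.integers(0, g.length))
        genomes = _splice(genomes, truth, g.contig_id, pos, joined)
        truth.empty_sites.append(
            (pc.locus, Interval(g.contig_id, pos, pos + len(joined), "+"))
        )
    return genomes, truth


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------


def make_gene_models(
    genomes: list[GenomeSeq],
    config: SimConfig,
    rng: np.random.Generator,
    truth: SimTruth | None = None,
) -> list[GeneModel]:
    """Random multi-exon gene models (annotation only; no coding sequence).

    Genes are placed uniformly; exons are 150 bp separated by 500 bp
    introns, with the CDS covering the central part of each exon chain and
    short UTRs at both ends.
    """
    models = []
    exon_len, intron_len, utr_len = 150, 500, 50
    n_ex = max(1, config.exons_per_gene)
    span = n_ex * exon_len + (n_ex - 1) * intron_len
    for i in range(config.n_genes):
        gi = int(rng.integers(0, len(genomes)))
        g = genomes[gi]
        start = int(rng.integers(0, max(1, g.length - span - 1)))
        strand = "+" if rng.random() < 0.5 else "-"
        models.append(_gene_at(g.contig_id, start, strand, f"gene{i + 1}", n_ex, exon_len, intron_len, utr_len))
    if truth is not None:
        truth.gene_models.extend(models)
    return models


def _gene_at(contig, start, strand, gene_id, n_ex, exon_len, intron_len, utr_len) -> GeneModel:
    exons, introns = [], []
    pos = start
    for e in range(n_ex):
        exons.append(Interval(contig, pos, pos + exon_len, strand))
        if e < n_ex - 1:
            introns.append(Interval(contig, pos + exon_len, pos + exon_len + intron_len, strand))
        pos += exon_len + intron_len
    first, last = exons[0], exons[-1]
    cds = [Interval(contig, iv.start, iv.end, strand) for iv in exons]
    cds[0] = Interval(contig, first.start + utr_len, first.end, strand)
    cds[-1] = Interval(contig, last.start, last.end - utr_len, strand)
    left_utr = [Interval(contig, first.start, first.start + utr_len, strand)]
    right_utr = [Interval(contig, last.end - utr_len, last.end, strand)]
    utr5, utr3 = (left_utr, right_utr) if strand == "+" else (right_utr, left_utr)
    return GeneModel(gene_id, contig, strand, exons, cds, utr5, utr3, introns)


def gene_over_copy(copy_locus: Interval, where: str, gene_id: str) -> GeneModel:
    """A gene model constructed so that `copy_locus` falls in a chosen feature.

    `where` is one of intron, CDS, UTR5, UTR3. Used to plant known gene
    contexts around already-planted copies (annotation only, so no
    coordinate shifts are incurred).
    """
    c = copy_locus
    pad = 20
    if where == "intron":
        ex1 = Interval(c.contig_id, max(0, c.start - pad - 150), max(1, c.start - pad), "+")
        ex2 = Interval(c.contig_id, c.end + pad, c.end + pad + 150, "+")
        intron = Interval(c.contig_id, ex1.end, ex2.start, "+")
        return GeneModel(gene_id, c.contig_id, "+", [ex1, ex2], [ex1, ex2], [], [], [intron])
    if where == "CDS":
        ex = Interval(c.contig_id, max(0, c.start - pad), c.end + pad, "+")
        return GeneModel(gene_id, c.contig_id, "+", [ex], [ex], [], [], [])
    if where in ("UTR5", "UTR3"):
        ex = Interval(c.contig_id, max(0, c.start - pad), c.end + pad + 150, "+")
        cds = Interval(c.contig_id, c.end + pad, ex.end, "+")
        utr = Interval(c.contig_id, ex.start, c.end + pad, "+")
        if where == "UTR5":
            return GeneModel(gene_id, c.contig_id, "+", [ex], [cds], [utr], [], [])
        return GeneModel(gene_id, c.contig_id, "-", [ex], [cds], [], [utr], [])
    raise ValueError(f"unknown feature {where!r}")


# ---------------------------------------------------------------------------
# bundle export
# ---------------------------------------------------------------------------


def save_bundle(outdir, genomes: list[GenomeSeq], truth: SimTruth, config: SimConfig) -> None:
    """Write genome FASTA, gene GFF3 (with planted-copy features), truth TSV
    and the YAML config of a simulation."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(genomes, outdir / "genome.fasta")
    write_fasta(
        [(m.label, m.sequence) for m in truth.masters.values()],
        outdir / "masters.fasta",
    )
    copy_lines = [
        f"{c.locus.contig_id}\thelikit-sim\tplanted_copy\t{c.locus.start + 1}\t{c.locus.end}\t.\t"
        f"{c.locus.strand}\t.\tID=copy{i + 1};label={c.label};divergence={c.divergence_d};"
        f"truncated={int(c.truncated)}"
        for i, c in enumerate(truth.copies)
    ]
    write_gff3(truth.gene_models, outdir / "annotation.gff3", extra_lines=copy_lines)
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("label\tcontig\tstart\tend\tstrand\tdivergence\ttruncated\n")
        for c in truth.copies:
            fh.write(
                f"{c.label}\t{c.locus.contig_id}\t{c.locus.start}\t{c.locus.end}\t"
                f"{c.locus.strand}\t{c.divergence_d}\t{int(c.truncated)}\n"
            )
    with open(outdir / "config.yaml", "w") as fh:
        cfg = {k: v for k, v in vars(config).items()}
        cfg["truncation_range"] = list(config.truncation_range)
        yaml.safe_dump(cfg, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# autonomous-element (Rep/helicase) master for reconstruction tests
# ---------------------------------------------------------------------------

# codon choice matters: a FIXED codon table leaves some shifted or
# reverse-strand reading frame systematically stop-free, which fabricates a
# spurious long ORF. Two synonymous codons per amino acid, drawn at random
# per position, give every non-coding frame its expected density of stops
# (CTA/TTA and TCA are the reverse complements of stops, seeding the minus
# strand as well).
_CODON = {
    "A": ("GCA", "GCT"), "R": ("CGC", "CGT"), "N": ("AAC", "AAT"),
    "D": ("GAC", "GAT"), "C": ("TGC", "TGT"), "Q": ("CAG", "CAA"),
    "E": ("GAG", "GAA"), "G": ("GGC", "GGT"), "H": ("CAC", "CAT"),
    "I": ("ATC", "ATT"), "L": ("CTA", "TTA"), "K": ("AAG", "AAA"),
    "M": ("ATG", "ATG"), "F": ("TTC", "TTT"), "P": ("CCA", "CCT"),
    "S": ("TCA", "AGT"), "T": ("ACA", "ACT"), "W": ("TGG", "TGG"),
    "Y": ("TAC", "TAT"), "V": ("GTG", "GTT"),
}
_AA = "ARNDCQEGHILKMFPSTWYV"


def make_rephel_master(
    rng: np.random.Generator, n_aa: int = 1100, utr: int = 60
) -> tuple[str, str]:
    """A synthetic autonomous-element coding region: (dna, protein).

    The protein carries the bundled Rep (two-His, two-Tyr) and eight SF1
    helicase motif blocks in order, separated by random linkers, and is
    back-translated with a fixed codon table (so the DNA has a clean
    ATG..stop ORF). Random untranslated sequence pads both ends.
    """
    from .capture_autonomy import load_motif_blocks

    blocks = load_motif_blocks()
    block_len = sum(len(b.sequence) for b in blocks)
    linker_total = n_aa - 1 - block_len  # minus the initial M
    if linker_total < len(blocks) + 1:
        raise ValueError("n_aa too small for the motif layout")
    cuts = sorted(rng.choice(linker_total - 1, size=len(blocks), replace=False))
    lens = (
        [cuts[0] + 1]
        + [b - a for a, b in zip(cuts, cuts[1:])]
        + [linker_total - 1 - cuts[-1]]
    )
    parts = ["M"]
    for block, ll in zip(blocks, lens[:-1]):
        parts.append("".join(_AA[i] for i in rng.integers(0, 20, ll)))
        parts.append(block.sequence)
    parts.append("".join(_AA[i] for i in rng.integers(0, 20, lens[-1])))
    protein = "".join(parts)
    assert len(protein) == n_aa and protein.startswith("M")
    picks = rng.integers(0, 2, n_aa)
    dna = "".join(_CODON[aa][picks[i]] for i, aa in enumerate(protein)) + "TAA"
    pad5 = BASES[rng.integers(0, 4, utr)].tobytes().decode()
    pad3 = BASES[rng.integers(0, 4, utr)].tobytes().decode()
    # stops in all three frames upstream keep the ORF start unambiguous
    return pad5 + "TAATAATAA" + dna + pad3, protein


def simulate_bundle(config: SimConfig) -> tuple[list[GenomeSeq], SimTruth]:
    """One-call simulation: background, planted copies, genes, empty sites."""
    rng = np.random.default_rng(config.seed)
    genomes = make_background(config, rng)
    master = make_master_element(rng, "Hel1", config.element_len, config.gc_content)
    genomes, truth = plant_copies(genomes, master, config, rng=rng)
    if config.empty_site_pairs:
        genomes, truth = plant_empty_sites(genomes, truth, config.empty_site_pairs, rng)
    if config.n_genes:
        make_gene_models(genomes, config, rng, truth)
    return genomes, truth
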