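"""Seed-and-extend nucleotide homology search.

Finds all genomic fragments similar to a query element. Exact k-mer seeds
(default word size 11) are located through a sorted-array index, clustered
on diagonals, and each cluster with at least two non-overlapping seeds is
extended by gapped local alignment of the query against the surrounding
genomic window. Both strands are searched; identities are reported as
matches / alignment columns with gaps counted as columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .align import local_align
from .core_io import GenomeSeq, HelitronCopy, Interval, revcomp

DEFAULT_WORD_SIZE = 11
MERGE_GAP = 20  # bp; hits closer than this on both axes are merged

_CODE = np.full(256, -1, dtype=np.int8)
for i, base in enumerate("ACGT"):
    _CODE[ord(base)] = i


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _words(codes: np.ndarray, k: int) -> np.ndarray:
    """Rolling 2-bit k-mer codes; -1 where the window contains N."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (windows >= 0).all(axis=1)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    vals = (windows.astype(np.int64) * powers).sum(axis=1)
    vals[~valid] = -1
    return vals


class KmerIndex:
    """Exact-match k-mer lookup over the forward strand of each contig.

    Minus-strand hits are found by searching the reverse complement of the
    query, so indexing one strand suffices. Words containing N are skipped.
    """

    def __init__(self, genomes: Sequence[GenomeSeq], word_size: int = DEFAULT_WORD_SIZE):
        if word_size < 8:
            raise ValueError("word_size must be >= 8")
        self.word_size = word_size
        self.genomes = list(genomes)
        self.sequences: dict[str, str] = {g.contig_id: g.sequence for g in genomes}
        self._index: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for g in genomes:
            vals = _words(_encode(g.sequence), word_size)
            keep = vals >= 0
            positions = np.nonzero(keep)[0]
            vals = vals[keep]
            order = np.argsort(vals, kind="stable")
            self._index[g.contig_id] = (vals[order], positions[order])

    def lookup(self, word_code: int, contig_id: str) -> np.ndarray:
        """Forward-strand positions of a 2-bit-encoded word on one contig."""
        vals, positions = self._index[contig_id]
        lo = np.searchsorted(vals, word_code, side="left")
        hi = np.searchsorted(vals, word_code, side="right")
        return positions[lo:hi]

    def lookup_word(self, word: str, contig_id: str) -> list[int]:
        """Forward-strand positions of a word string on one contig."""
        codes = _encode(word)
        if (codes < 0).any() or len(codes) != self.word_size:
            return []
        k = self.word_size
        powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
        code = int((codes.astype(np.int64) * powers).sum())
        return sorted(int(p) for p in self.lookup(code, contig_id))

    def count(self, word: str, contig_id: str) -> int:
        return len(self.lookup_word(word, contig_id))


def index_genome(genomes: Sequence[GenomeSeq], word_size: int = DEFAULT_WORD_SIZE) -> KmerIndex:
    return KmerIndex(genomes, word_size)


@dataclass(frozen=True)
class Hit:
    """One gapped local alignment of the query to the genome."""

    query_span: Interval  # on the query, in forward-query coordinates
    target_span: Interval  # on the genome, forward-strand coordinates
    identity: float
    aligned_len: int  # alignment columns
    strand: str
    score: float

    def __post_init__(self):
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity outside [0, 1]")


def _cluster_seeds(qpos: np.ndarray, tpos: np.ndarray, word: int, band: int, max_gap: int):
    """Group seed matches into diagonal clusters.

    Seeds fall in one cluster when their diagonals differ by <= band and
    they are separated by <= max_gap on the target. Returns clusters with
    at least two seeds whose target positions do not overlap.
    """
    diag = tpos - qpos
    order = np.lexsort((tpos, diag))
    clusters = []
    current: list[int] = []
    for idx in order:
        if current:
            last = current[-1]
            if diag[idx] - diag[last] <= band and tpos[idx] - tpos[last] <= max_gap:
                current.append(idx)
                continue
            clusters.append(current)
        current = [idx]
    if current:
        clusters.append(current)
    kept = []
    for cl in clusters:
        ts = sorted(tpos[i] for i in cl)
        nonoverlap = 1
        last_end = ts[0] + word
        for t in ts[1:]:
            if t >= last_end:
                nonoverlap += 1
                last_end = t + word
        if nonoverlap >= 2:
            kept.append(cl)
    return kept, diag


def search(
    query: str,
    index: KmerIndex,
    min_identity: float = 0.8,
    min_len: int = 100,
    band: int = 25,
) -> list[Hit]:
    """Find all hits of `query` in the indexed genomes on both strands."""
    query = query.upper()
    if len(query) < min_len:
        raise ValueError(f"query shorter than min_len={min_len}")
    k = index.word_size
    raw: list[Hit] = []
    for strand, qseq in (("+", query), ("-", revcomp(query))):
        qwords = _words(_encode(qseq), k)
        valid_q = np.nonzero(qwords >= 0)[0]
        for contig_id, target in index.sequences.items():
            qpos_list, tpos_list = [], []
            for qp in valid_q:
                hits = index.lookup(int(qwords[qp]), contig_id)
                if len(hits):
                    qpos_list.append(np.full(len(hits), qp))
                    tpos_list.append(hits)
            if not qpos_list:
                continue
            qpos = np.concatenate(qpos_list)
            tpos = np.concatenate(tpos_list)
            clusters, _ = _cluster_seeds(qpos, tpos, k, band, max_gap=len(qseq))
            for cl in clusters:
                hit = _extend_cluster(qseq, target, contig_id, qpos[cl], tpos[cl], strand, len(query))
                if hit is not None:
                    raw.append(hit)
    merged = _dedupe(raw)
    return sorted(
        (
            h
            for h in merged
            if h.identity >= min_identity and h.aligned_len >= min_len
        ),
        key=lambda h: (h.target_span.contig_id, h.target_span.start),
    )


def _extend_cluster(qseq, target, contig_id, qpos, tpos, strand, query_len) -> Hit | None:
    pad = 30 + len(qseq) // 10
    tstart = max(0, int(tpos.min()) - int(qpos.min()) - pad)
    tend = min(len(target), int(tpos.max()) + (len(qseq) - int(qpos.max())) + pad)
    window = target[tstart:tend]
    if not window.strip("N"):
        return None
    res = local_align(qseq, window)
    if res.columns == 0:
        return None
    q0, q1 = res.span_a
    t0, t1 = res.span_b
    if strand == "+":
        q_iv = Interval("query", q0, q1, "+")
    else:  # map back to forward-query coordinates
        q_iv = Interval("query", query_len - q1, query_len - q0, "-")
    t_iv = Interval(contig_id, tstart + t0, tstart + t1, strand)
    return Hit(q_iv, t_iv, res.identity, res.columns, strand, res.score)


def _dedupe(hits: list[Hit]) -> list[Hit]:
    """Collapse duplicate extensions of one copy; merge indel-split fragments.

    Two hits are duplicates when their target spans overlap by more than
    half of the shorter one (the best-scoring is kept). They are fragments
    of one copy only when they are close (< MERGE_GAP) on BOTH the target
    and the query: adjacent but distinct copies overlap on the query and are
    therefore kept separate.
    """
    out: list[Hit] = []
    for h in sorted(hits, key=lambda h: (h.target_span.contig_id, h.target_span.start, -h.score)):
        merged = False
        for i, kept in enumerate(out):
            kt, ht = kept.target_span, h.target_span
            if kt.contig_id != ht.contig_id:
                continue
            t_overlap = min(kt.end, ht.end) - max(kt.start, ht.start)
            if t_overlap > 0.5 * min(kt.length, ht.length):
                if h.score > kept.score:
                    out[i] = h
                merged = True
                break
            t_gap = max(ht.start - kt.end, kt.start - ht.end)
            kq, hq = kept.query_span, h.query_span
            q_gap = max(hq.start - kq.end, kq.start - hq.end)
            if kept.strand == h.strand and -5 <= t_gap < MERGE_GAP and -5 <= q_gap < MERGE_GAP:
                out[i] = _merge_fragments(kept, h)
                merged = True
                break
        if merged:
            continue
        out.append(h)
    return out


def _merge_fragments(a: Hit, b: Hit) -> Hit:
    """Join two fragments of one copy split by a small indel."""
    t = Interval(
        a.target_span.contig_id,
        min(a.target_span.start, b.target_span.start),
        max(a.target_span.end, b.target_span.end),
        a.strand,
    )
    q = Interval(
        "query",
        min(a.query_span.start, b.query_span.start),
        max(a.query_span.end, b.query_span.end),
        a.strand,
    )
    cols = a.aligned_len + b.aligned_len
    ident = (a.identity * a.aligned_len + b.identity * b.aligned_len) / cols
    return Hit(q, t, ident, cols, a.strand, a.score + b.score)


def extract_copy(
    hit: Hit,
    genomes: Sequence[GenomeSeq] | Mapping[str, str],
    flank: int = 200,
    query_len: int | None = None,
) -> HelitronCopy:
    """Extract the element-strand sequence of a hit plus flanking context.

    The host bases recorded are the single nucleotides immediately outside
    the element on its own strand; at a contig edge the missing side is
    reported as N and the flank comes back shorter.
    """
    seqs = genomes if isinstance(genomes, Mapping) else {g.contig_id: g.sequence for g in genomes}
    target = seqs[hit.target_span.contig_id]
    s, e = hit.target_span.start, hit.target_span.end
    if query_len:
        # pad the span by small unaligned query overhangs so local-alignment
        # edge trimming does not clip the element termini; truly truncated
        # copies (large overhangs) are left as aligned
        max_pad = 15
        head = min(max_pad, hit.query_span.start)
        tail = min(max_pad, query_len - hit.query_span.end)
        left_pad, right_pad = (head, tail) if hit.strand == "+" else (tail, head)
        s = max(0, s - left_pad)
        e = min(len(target), e + right_pad)
    core = target[s:e]
    left = target[max(0, s - flank) : s]
    right = target[e : e + flank]
    if hit.strand == "+":
        seq, lf, rf = core, left, right
        lhb = left[-1] if left else "N"
        rhb = right[0] if right else "N"
    else:
        seq = revcomp(core)
        lf, rf = revcomp(right), revcomp(left)
        lhb = revcomp(right[0]) if right else "N"
        rhb = revcomp(left[-1]) if left else "N"
    return HelitronCopy(
        locus=hit.target_span,
        sequence=seq,
        left_flank=lf,
        right_flank=rf,
        left_host_base=lhb,
        right_host_base=rhb,
        identity_to_consensus=hit.identity,
        consensus_coverage=(
            min(1.0, hit.query_span.length / query_len) if query_len else 0.0
        ),
    )


def coverage_of(hit: Hit, query_len: int) -> float:
    """Fraction of the query covered by the hit."""
    return hit.query_span.length / query_len


def write_hits_tsv(hits: Iterable[Hit], path) -> None:
    """Tabular (1-based inclusive) hit export."""
    with open(path, "w") as fh:
        fh.write("contig\tstart\tend\tstrand\tidentity\taligned_len\tq_start\tq_end\n")
        for h in hits:
            t = h.target_span
            q = h.query_span
            fh.write(
                f"{t.contig_id}\t{t.start + 1}\t{t.end}\t{h.strand}\t"
                f"{h.identity:.4f}\t{h.aligned_len}\t{q.start + 1}\t{q.end}\n"
            )
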