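"""Consensus reconstruction from repeat copies.

Copies of one exemplar radiate from a recent master, so a center-star
progressive alignment (pairwise global alignments onto a center sequence,
merged under "once a gap, always a gap") recovers the master's column
structure well at the divergences seen here, and a per-column majority vote
recovers its sequence.
"""

from __future__ import annotations

from .align import global_align
from .core_io import ConsensusElement, HelitronCopy

TIE_ORDER = "ACGT"  # deterministic tie-break: A < C < G < T
DEFAULT_MIN_COPIES = 10
MAX_COPIES_FOR_CONSENSUS = 200


def _pick_center(copies: list[str]) -> int:
    """Center = sequence minimising total alignment distance to the others.

    For large copy sets the quadratic scan is trimmed to the longest
    sequences (the center of a star radiation is almost always a
    full-length copy).
    """
    if len(copies) == 2:
        return 0 if len(copies[0]) >= len(copies[1]) else 1
    candidates = range(len(copies))
    if len(copies) > 20:
        candidates = sorted(candidates, key=lambda i: -len(copies[i]))[:5]
    best_i, best_cost = -1, None
    for i in candidates:
        cost = 0.0
        for j, other in enumerate(copies):
            if i == j:
                continue
            res = global_align(copies[i], other)
            cost += 1.0 - res.identity
        if best_cost is None or cost < best_cost:
            best_i, best_cost = i, cost
    return best_i


def align_copies(copies: list[str], center_index: int | None = None) -> list[str]:
    """Center-star multiple alignment; returns equal-length gapped rows.

    Row order matches the input order. `center_index` overrides the center
    choice (used by the core-inference step, which centers on the shortest
    member).
    """
    if len(copies) < 2:
        raise ValueError("need at least 2 sequences to align")
    if any(not c for c in copies):
        raise ValueError("cannot align an empty sequence")
    if len(set(copies)) == 1:
        return list(copies)
    center = center_index if center_index is not None else _pick_center(copies)
    cseq = copies[center]
    n_bound = len(cseq) + 1  # insertion slots around center positions
    # per row: (chars aligned to each center position, insertions per slot)
    row_chars: list[list[str]] = []
    row_ins: list[list[str]] = []
    for seq in copies:
        if seq is cseq or seq == cseq:
            row_chars.append(list(cseq))
            row_ins.append([""] * n_bound)
            continue
        res = global_align(cseq, seq)
        chars = []
        ins = [""] * n_bound
        cpos = 0
        for a, b in zip(res.aligned_a, res.aligned_b):
            if a == "-":
                ins[cpos] += b
            else:
                chars.append(b)
                cpos += 1
        row_chars.append(chars)
        row_ins.append(ins)
    max_ins = [max(len(r[k]) for r in row_ins) for k in range(n_bound)]
    rows = []
    for chars, ins in zip(row_chars, row_ins):
        parts = []
        for k in range(n_bound):
            parts.append(ins[k].ljust(max_ins[k], "-") if max_ins[k] else "")
            if k < len(cseq):
                parts.append(chars[k])
        rows.append("".join(parts))
    assert len({len(r) for r in rows}) == 1
    return rows


def build_consensus(
    alignment: list[str], min_copies: int = DEFAULT_MIN_COPIES
) -> tuple[str, bool]:
    """Per-column majority consensus; returns (sequence, low_support flag).

    Columns where the gap character wins a strict majority are dropped.
    Base ties are broken A < C < G < T; a gap tying with a base loses to
    the base. Fewer rows than min_copies is allowed but flagged
    low-support (the fallback used when an exemplar has few copies).
    """
    if len(alignment) < 2:
        raise ValueError("need at least 2 aligned rows")
    ncol = len(alignment[0])
    out = []
    nrows = len(alignment)
    for col in range(ncol):
        counts: dict[str, int] = {}
        for row in alignment:
            counts[row[col]] = counts.get(row[col], 0) + 1
        gap_n = counts.pop("-", 0)
        counts.pop("N", None)
        if not counts:
            continue
        best_base = min(
            (b for b in counts), key=lambda b: (-counts[b], TIE_ORDER.index(b))
        )
        if gap_n > nrows - gap_n:  # strict gap majority
            continue
        out.append(best_base)
    return "".join(out), nrows < min_copies


def select_copies(copies: list[HelitronCopy], max_n: int = MAX_COPIES_FOR_CONSENSUS) -> list[HelitronCopy]:
    """Top-N copies entering the consensus, by coverage then identity."""
    ranked = sorted(
        copies,
        key=lambda c: (-c.consensus_coverage, -c.identity_to_consensus, c.locus.contig_id, c.locus.start),
    )
    return ranked[:max_n]


def consensus_from_copies(
    copies: list[HelitronCopy],
    name: str = "consensus",
    min_copies: int = DEFAULT_MIN_COPIES,
    max_n: int = MAX_COPIES_FOR_CONSENSUS,
) -> ConsensusElement:
    """Select copies, align and vote; returns a ConsensusElement."""
    chosen = select_copies(copies, max_n)
    if len(chosen) < 2:
        raise ValueError("need at least 2 copies to build a consensus")
    rows = align_copies([c.sequence for c in chosen])
    seq, low = build_consensus(rows, min_copies)
    return ConsensusElement(
        name=name, sequence=seq, n_copies_used=len(chosen), low_support=low
    )
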