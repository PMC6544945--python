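"""Copy counting, genome fraction and average divergence per exemplar.

Counting rule: every contiguous genomic fragment with >= 80% identity to the
consensus over >= 100 bp is one copy (overlapping fragments collapse to the
best one). Divergence rule: fragments with >= 80% identity over >= 80% of
the consensus length enter the average percentage divergence, computed with
the Kimura two-parameter model copy-vs-consensus and reported x100. When
fewer than 3 copies qualify, or qualifying copies are under 5% of counted
copies (heavy fragmentation), the divergence is not determined (ND).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .align import semiglobal_align
from .core_io import ConsensusElement, HelitronCopy
from .homology_search import Hit

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


class SaturatedDistance(ValueError):
    """K2P distance undefined: 1-2P-Q <= 0 or 1-2Q <= 0."""


@dataclass
class DivergenceReport:
    """One Table-style row: copy count, genome share, average divergence."""

    exemplar_name: str
    consensus_len: int
    n_copies: int
    genome_fraction: float  # percent of genome
    avg_divergence: float | None  # percent, None = ND
    n_copies_for_divergence: int


def count_copies(
    hits: Sequence[Hit], min_identity: float = 0.80, min_len: int = 100
) -> list[Hit]:
    """Filter hits by the counting rule and collapse genomic overlaps.

    Returns pairwise non-overlapping hits sorted by genomic position, each
    representing one counted copy (the best-identity hit of its overlap
    group is kept).
    """
    passing = [h for h in hits if h.identity >= min_identity and h.aligned_len >= min_len]
    passing.sort(key=lambda h: (h.target_span.contig_id, h.target_span.start, -h.identity))
    kept: list[Hit] = []
    for h in passing:
        if kept and kept[-1].target_span.overlaps(h.target_span):
            if h.identity > kept[-1].identity:
                kept[-1] = h
            continue
        kept.append(h)
    return kept


def k2p_distance(a: str, b: str) -> float:
    """Kimura two-parameter distance between two aligned sequences.

    Gap and N columns are excluded. P and Q are the transition and
    transversion proportions over the remaining sites;
    d = -1/2 ln((1-2P-Q) sqrt(1-2Q)). Raises SaturatedDistance outside the
    domain of the logarithm.
    """
    if len(a) != len(b):
        raise ValueError("aligned sequences must have equal length")
    sites = ts = tv = 0
    for x, y in zip(a, b):
        if x in "-N" or y in "-N":
            continue
        sites += 1
        if x == y:
            continue
        if (x, y) in TRANSITIONS:
            ts += 1
        else:
            tv += 1
    if sites == 0:
        raise ValueError("no comparable (ungapped) sites")
    p, q = ts / sites, tv / sites
    w1, w2 = 1.0 - 2.0 * p - q, 1.0 - 2.0 * q
    if w1 <= 0 or w2 <= 0:
        raise SaturatedDistance(f"saturated: P={p:.4f}, Q={q:.4f}")
    return -0.5 * math.log(w1 * math.sqrt(w2))


def copy_divergence(copy_seq: str, consensus_seq: str) -> tuple[float, float, float]:
    """Align one copy to the consensus; return (K2P distance, identity, coverage).

    Coverage is the fraction of the consensus covered by the aligned core
    (end gaps excluded, internal gaps included).
    """
    res = semiglobal_align(consensus_seq, copy_seq)
    span = res.span_a[1] - res.span_a[0]
    coverage = span / len(consensus_seq)
    d = k2p_distance(res.aligned_a, res.aligned_b)
    return d, res.identity, coverage


def average_divergence(
    copies: Sequence[HelitronCopy | str],
    consensus: ConsensusElement | str,
    min_identity: float = 0.80,
    min_cov: float = 0.80,
    min_qualifying: int = 3,
    min_qualifying_fraction: float = 0.05,
) -> tuple[float | None, int]:
    """Average percentage divergence (x100) of qualifying copies vs consensus.

    Returns (value or None for ND, number of qualifying copies). ND is
    reported when fewer than `min_qualifying` copies qualify or when the
    qualifying fraction of counted copies falls below
    `min_qualifying_fraction` (the fragmentation guard).
    """
    cseq = consensus.sequence if isinstance(consensus, ConsensusElement) else consensus
    dists = []
    for c in copies:
        seq = c.sequence if isinstance(c, HelitronCopy) else c
        try:
            d, ident, cov = copy_divergence(seq, cseq)
        except (SaturatedDistance, ValueError):
            continue
        if ident >= min_identity and cov >= min_cov:
            dists.append(d)
    n_q = len(dists)
    if n_q < min_qualifying or (copies and n_q / len(copies) < min_qualifying_fraction):
        return None, n_q
    return 100.0 * sum(dists) / n_q, n_q


def genome_fraction(copies: Sequence[Hit | HelitronCopy], genome_total_bp: int) -> float:
    """Percent of the genome occupied by the counted copies."""
    total = 0
    for c in copies:
        iv = c.target_span if isinstance(c, Hit) else c.locus
        total += iv.length
    return 100.0 * total / genome_total_bp


def shared_5prime_length(
    a: str, b: str, min_identity: float = 0.90, window: int = 30
) -> int:
    """Length of the 5' head shared by two consensus sequences.

    The sequences are globally aligned; the shared head ends at the first
    `window`-column stretch whose identity falls below min_identity (the
    point where exemplar-diagnostic sequence begins). Reported in
    coordinates of the first sequence.
    """
    from .align import global_align

    res = global_align(a, b)
    flags = [
        1 if x == y and x != "-" else 0
        for x, y in zip(res.aligned_a, res.aligned_b)
    ]
    ncol = len(flags)
    boundary = ncol
    running = sum(flags[:window])
    if ncol >= window and running / window < min_identity:
        boundary = 0
    else:
        for c in range(1, ncol - window + 1):
            running += flags[c + window - 1] - flags[c - 1]
            if running / window < min_identity:
                boundary = c
                break
    return sum(1 for x in res.aligned_a[:boundary] if x != "-")


def resolve_family_only(
    counted: Sequence[Hit],
    shared_5prime_len: int,
    exemplar_label: str,
    family_label: str,
    slack: int = 5,
) -> list[str]:
    """Label counted copies exemplar-level or family-level.

    A copy whose alignment to the consensus stays within the 5' block shared
    between exemplars (plus slack) cannot be told apart from the other
    exemplars of the family and is counted at family level only; copies
    extending into exemplar-diagnostic sequence keep the exemplar label.
    """
    labels = []
    for h in counted:
        if h.query_span.end <= shared_5prime_len + slack:
            labels.append(family_label)
        else:
            labels.append(exemplar_label)
    return labels


def make_report(
    name: str,
    consensus: ConsensusElement | str,
    counted: Sequence[Hit],
    copies_for_divergence: Sequence[HelitronCopy | str],
    genome_total_bp: int,
) -> DivergenceReport:
    """Assemble one report row from counted hits and extracted copy sequences."""
    cseq = consensus.sequence if isinstance(consensus, ConsensusElement) else consensus
    div, n_q = average_divergence(copies_for_divergence, cseq)
    return DivergenceReport(
        exemplar_name=name,
        consensus_len=len(cseq),
        n_copies=len(counted),
        genome_fraction=genome_fraction(counted, genome_total_bp),
        avg_divergence=div,
        n_copies_for_divergence=n_q,
    )
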