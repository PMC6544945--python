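"""Pairwise alignment helpers used across the pipeline.

One scoring scheme is used everywhere (match +1, mismatch -2, gap open -4,
gap extend -1) so identities are comparable between the search, the
classification end-comparisons and the divergence estimator. Identity is
always matches / alignment columns, gap columns included.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align

MATCH_SCORE = 1
MISMATCH_SCORE = -2
GAP_OPEN = -4
GAP_EXTEND = -1


def make_aligner(mode: str = "global", free_end_gaps: bool = False) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner(
        mode=mode,
        match_score=MATCH_SCORE,
        mismatch_score=MISMATCH_SCORE,
        open_gap_score=GAP_OPEN,
        extend_gap_score=GAP_EXTEND,
    )
    if free_end_gaps:
        try:
            aligner.open_end_insertion_score = 0
            aligner.extend_end_insertion_score = 0
            aligner.open_end_deletion_score = 0
            aligner.extend_end_deletion_score = 0
        except AttributeError:  # older Biopython naming
            aligner.target_end_open_gap_score = 0
            aligner.target_end_extend_gap_score = 0
            aligner.query_end_open_gap_score = 0
            aligner.query_end_extend_gap_score = 0
    return aligner


_GLOBAL = make_aligner("global")
_SEMIGLOBAL = make_aligner("global", free_end_gaps=True)
_LOCAL = make_aligner("local")


@dataclass(frozen=True)
class PairwiseResult:
    """Summary of one pairwise alignment."""

    identity: float  # matches / columns (gaps are columns)
    columns: int
    matches: int
    mismatches: int
    gaps: int
    score: float
    aligned_a: str  # gapped sequence A
    aligned_b: str  # gapped sequence B
    span_a: tuple[int, int]  # aligned region on A (0-based half-open)
    span_b: tuple[int, int]


def _summarise(alignment) -> PairwiseResult:
    counts = alignment.counts()
    matches, mismatches = counts.identities, counts.mismatches
    gaps = counts.gaps
    columns = matches + mismatches + gaps
    a_blocks, b_blocks = alignment.aligned
    span_a = (int(a_blocks[0][0]), int(a_blocks[-1][1])) if len(a_blocks) else (0, 0)
    span_b = (int(b_blocks[0][0]), int(b_blocks[-1][1])) if len(b_blocks) else (0, 0)
    return PairwiseResult(
        identity=matches / columns if columns else 0.0,
        columns=columns,
        matches=matches,
        mismatches=mismatches,
        gaps=gaps,
        score=alignment.score,
        aligned_a=str(alignment[0]),
        aligned_b=str(alignment[1]),
        span_a=span_a,
        span_b=span_b,
    )


def global_align(a: str, b: str) -> PairwiseResult:
    """Needleman-Wunsch with penalised end gaps."""
    if not a or not b:
        raise ValueError("cannot align empty sequence")
    return _summarise(_GLOBAL.align(a, b)[0])


def semiglobal_align(a: str, b: str) -> PairwiseResult:
    """Global alignment with free end gaps (for partial copies vs consensus).

    End-gap columns are excluded from the identity denominator; only the
    aligned core (first to last matched position) counts.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequence")
    alignment = _SEMIGLOBAL.align(a, b)[0]
    res = _summarise(alignment)
    # strip end-gap columns from the column/gap counts
    sa, sb = res.aligned_a, res.aligned_b
    start = 0
    end = len(sa)
    while start < end and (sa[start] == "-" or sb[start] == "-"):
        start += 1
    while end > start and (sa[end - 1] == "-" or sb[end - 1] == "-"):
        end -= 1
    core_a, core_b = sa[start:end], sb[start:end]
    matches = sum(1 for x, y in zip(core_a, core_b) if x == y and x != "-")
    mismatches = sum(1 for x, y in zip(core_a, core_b) if x != y and x != "-" and y != "-")
    gaps = sum(1 for x, y in zip(core_a, core_b) if x == "-" or y == "-")
    columns = len(core_a)
    return PairwiseResult(
        identity=matches / columns if columns else 0.0,
        columns=columns,
        matches=matches,
        mismatches=mismatches,
        gaps=gaps,
        score=res.score,
        aligned_a=core_a,
        aligned_b=core_b,
        span_a=res.span_a,
        span_b=res.span_b,
    )


def local_align(a: str, b: str) -> PairwiseResult:
    """Smith-Waterman local alignment."""
    if not a or not b:
        raise ValueError("cannot align empty sequence")
    return _summarise(_LOCAL.align(a, b)[0])


def aligned_columns(res: PairwiseResult):
    """Yield (base_a, base_b) per alignment column ('-' for gaps)."""
    return zip(res.aligned_a, res.aligned_b)
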