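"""Structural hallmark validation for candidate Helitron copies.

Helitrons carry a 5'-TC dinucleotide, a 4-bp 3' terminus matching CTRY
(sometimes written CTRR), insert precisely between a host A and T without
target-site duplication, and fold a short palindromic hairpin just upstream
of the 3' terminus. These checks annotate copies; they never modify the
sequence.
"""

from __future__ import annotations

from .core_io import Hairpin, HelitronCopy, revcomp

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}

FIVE_PRIME_MOTIF = "TC"
THREE_PRIME_MOTIF = "CTRY"


def matches_iupac(seq: str, pattern: str) -> bool:
    """True iff seq matches the IUPAC pattern position-wise (N in seq never matches)."""
    if len(seq) != len(pattern):
        return False
    return all(base in IUPAC[p] for base, p in zip(seq, pattern))


def check_termini(
    copy: HelitronCopy,
    five_prime_motif: str = FIVE_PRIME_MOTIF,
    three_prime_motif: str = THREE_PRIME_MOTIF,
) -> HelitronCopy:
    """Flag the 5' and 3' terminal motifs on a copy (in place; returns copy).

    Positions containing N are un-validatable and leave the flag as None
    rather than recording a failure.
    """
    seq = copy.sequence
    if len(seq) < 10:
        raise ValueError("copy sequence too short to test termini")
    head = seq[: len(five_prime_motif)]
    tail = seq[-len(three_prime_motif):]
    copy.has_tc_start = None if "N" in head else matches_iupac(head, five_prime_motif)
    if "N" in tail:
        copy.three_prime_motif = None
    else:
        copy.three_prime_motif = tail if matches_iupac(tail, three_prime_motif) else None
    return copy


def check_host_context(copy: HelitronCopy) -> HelitronCopy:
    """Flag the A|T host integration context (element strand).

    Rolling-circle integration places the element precisely between a host
    A and T; a missing flank (contig edge) leaves the flag unknown (None).
    """
    left, right = copy.left_host_base, copy.right_host_base
    if left == "N" or right == "N" or not copy.left_flank or not copy.right_flank:
        copy.host_context_at = None
    else:
        copy.host_context_at = left == "A" and right == "T"
    return copy


def find_hairpin(
    copy_or_seq,
    window: int = 50,
    stem_min: int = 6,
    loop_range: tuple[int, int] = (3, 10),
    span_range: tuple[int, int] = (16, 20),
    max_mismatch: int = 0,
    terminus_len: int = 4,
) -> Hairpin | None:
    """Best palindromic stem-loop in the window upstream of the 3' terminus.

    The search region is the `window` bp immediately 5' of the terminal
    motif (last `terminus_len` bp). Candidates must have total span within
    span_range, stem >= stem_min with <= max_mismatch stem mismatches; ties
    are broken by longer stem, then proximity to the 3' end. Returns None
    when nothing qualifies.

    The default max_mismatch of 0 keeps the false-positive rate on random
    sequence below 5% (Monte-Carlo calibrated); allowing one stem mismatch
    raises it above 10% and is left opt-in.
    """
    seq = copy_or_seq.sequence if isinstance(copy_or_seq, HelitronCopy) else copy_or_seq
    region_end = len(seq) - terminus_len
    region_start = max(0, region_end - window)
    best: tuple | None = None
    for span in range(span_range[1], span_range[0] - 1, -1):
        for loop in range(loop_range[0], loop_range[1] + 1):
            if (span - loop) % 2:
                continue
            stem = (span - loop) // 2
            if stem < stem_min:
                continue
            for start in range(region_end - span, region_start - 1, -1):
                left = seq[start : start + stem]
                right = seq[start + stem + loop : start + span]
                if "N" in left or "N" in right:
                    continue
                mism = sum(1 for a, b in zip(left, revcomp(right)) if a != b)
                if mism > max_mismatch:
                    continue
                distance = len(seq) - (start + span)
                # rank: longer stem first, then closer to the 3' end
                key = (stem, -distance, -mism)
                if best is None or key > best[0]:
                    best = (key, Hairpin(stem, loop, mism, distance))
    if best is None:
        return None
    hp = best[1]
    if isinstance(copy_or_seq, HelitronCopy):
        copy_or_seq.hairpin = hp
    return hp


def validate_copy(copy: HelitronCopy, **hairpin_kwargs) -> HelitronCopy:
    """Run all three hallmark checks on a copy."""
    check_termini(copy)
    check_host_context(copy)
    find_hairpin(copy, **hairpin_kwargs)
    return copy
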