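"""Classification and nomenclature of Helitron consensus elements.

Families are defined by the 5' terminal 30 bp (>= 80% identity), because the
5' end is the part of the element required for transposition; subfamilies by
the 3' terminal 30 bp (>= 80% identity); exemplars within a subfamily by
> 80% identity of the internal region (everything between the two terminal
blocks). The pairwise >=80% relations are not transitive, so each level is
the single-linkage closure of the relation, which is the minimal partition
containing it.

Names follow the Xxxx_Hel<family><Subfamily><exemplar> convention:
first letter of the genus + first three letters of the epithet, e.g.
("Chilo suppressalis", 1, "A", "a") -> "Csup_Hel1Aa".
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from typing import Sequence

from .align import global_align
from .core_io import ConsensusElement

FAMILY_ONLY = "family-only"


@dataclass(frozen=True)
class ClassificationParams:
    end_len: int = 30
    end_identity_threshold: float = 0.80
    internal_identity_threshold: float = 0.80

    def __post_init__(self):
        if not (0 < self.end_identity_threshold <= 1 and 0 < self.internal_identity_threshold <= 1):
            raise ValueError("identity thresholds must lie in (0, 1]")
        if self.end_len < 10:
            raise ValueError("end_len must be >= 10")


def end_identity(a: str, b: str, which: str, params: ClassificationParams = ClassificationParams()) -> float:
    """Identity (matches / columns) of the two 30 bp terminal blocks."""
    n = params.end_len
    if len(a) < n or len(b) < n:
        raise ValueError(f"end undefined: sequence shorter than end_len={n}")
    if which == "5prime":
        ea, eb = a[:n], b[:n]
    elif which == "3prime":
        ea, eb = a[-n:], b[-n:]
    else:
        raise ValueError("which must be '5prime' or '3prime'")
    return global_align(ea, eb).identity


def internal_identity(a: str, b: str, params: ClassificationParams = ClassificationParams()) -> float:
    """Identity of the internal regions (sequence minus both terminal blocks).

    An empty internal region on either side makes the pair identical by
    definition (single-exemplar rule for consensus <= 2*end_len).
    """
    n = params.end_len
    ia, ib = a[n:-n], b[n:-n]
    if not ia or not ib:
        return 1.0
    return global_align(ia, ib).identity


def _single_linkage(items: Sequence, related) -> list[list]:
    """Connected components (single-linkage closure) of the `related` relation."""
    n = len(items)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if related(items[i], items[j]):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    groups: dict[int, list] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    # stable: groups ordered by first member (discovery order)
    return [g for _, g in sorted(groups.items(), key=lambda kv: min(kv[1]))]


def assign_families(
    consensus_set: Sequence[ConsensusElement],
    params: ClassificationParams = ClassificationParams(),
) -> dict[str, int]:
    """Partition a consensus set into families by 5'-end identity.

    Returns {consensus name: family id}; families are numbered 1, 2, ... by
    decreasing member count (ties by discovery order). family_id is also set
    on the elements.
    """
    seqs = [c.sequence for c in consensus_set]

    def related(i, j):
        return end_identity(seqs[i], seqs[j], "5prime", params) >= params.end_identity_threshold

    groups = _single_linkage(list(range(len(seqs))), related)
    groups.sort(key=lambda g: (-len(g), min(g)))
    out = {}
    for fam_id, group in enumerate(groups, start=1):
        for idx in group:
            consensus_set[idx].family_id = fam_id
            out[consensus_set[idx].name] = fam_id
    return out


def assign_subfamilies(
    family_members: Sequence[ConsensusElement],
    params: ClassificationParams = ClassificationParams(),
) -> dict[str, str]:
    """Partition one family into subfamilies by 3'-end identity (letters A..Z).

    A member whose sequence is too short to expose a 3' terminal block
    (truncated consensus) is assigned the family-only label.
    """
    ok = [c for c in family_members if len(c.sequence) >= 2 * params.end_len]
    out: dict[str, str] = {}
    for c in family_members:
        if c not in ok:
            c.subfamily_letter = FAMILY_ONLY
            out[c.name] = FAMILY_ONLY
    seqs = [c.sequence for c in ok]

    def related(i, j):
        return end_identity(seqs[i], seqs[j], "3prime", params) >= params.end_identity_threshold

    groups = _single_linkage(list(range(len(ok))), related)
    groups.sort(key=lambda g: (-sum(ok[i].n_copies_used for i in g), min(g)))
    for letter, group in zip(string.ascii_uppercase, groups):
        for idx in group:
            ok[idx].subfamily_letter = letter
            out[ok[idx].name] = letter
    return out


def assign_exemplars(
    subfamily_members: Sequence[ConsensusElement],
    params: ClassificationParams = ClassificationParams(),
) -> dict[str, str]:
    """Partition one subfamily into exemplars by internal-region identity."""
    seqs = [c.sequence for c in subfamily_members]

    def related(i, j):
        return internal_identity(seqs[i], seqs[j], params) > params.internal_identity_threshold

    groups = _single_linkage(list(range(len(seqs))), related)
    groups.sort(
        key=lambda g: (-sum(subfamily_members[i].n_copies_used for i in g), min(g))
    )
    out = {}
    for letter, group in zip(string.ascii_lowercase, groups):
        for idx in group:
            subfamily_members[idx].exemplar_letter = letter
            out[subfamily_members[idx].name] = letter
    return out


def name_element(species: str, family_id: int, subfamily_letter: str, exemplar_letter: str) -> str:
    """Build the canonical element name, e.g. Csup_Hel1Aa."""
    parts = species.split()
    if len(parts) < 2:
        raise ValueError("species must be a binomial (genus and epithet)")
    genus, epithet = parts[0], parts[1]
    short = genus[0].upper() + epithet[:3].lower()
    return f"{short}_Hel{family_id}{subfamily_letter}{exemplar_letter}"


def classify_consensus_set(
    consensus_set: Sequence[ConsensusElement],
    species: str | None = None,
    params: ClassificationParams = ClassificationParams(),
) -> list[ConsensusElement]:
    """Run family -> subfamily -> exemplar assignment, then (re)name elements.

    When `species` is given, element names are regenerated from the labels;
    otherwise the existing names are kept and only the labels updated.
    """
    assign_families(consensus_set, params)
    for fam_id in sorted({c.family_id for c in consensus_set}):
        members = [c for c in consensus_set if c.family_id == fam_id]
        assign_subfamilies(members, params)
        for letter in sorted({c.subfamily_letter for c in members}):
            if letter == FAMILY_ONLY:
                continue
            sub = [c for c in members if c.subfamily_letter == letter]
            assign_exemplars(sub, params)
    if species:
        for c in consensus_set:
            c.species = species
            if c.subfamily_letter != FAMILY_ONLY:
                c.name = name_element(species, c.family_id, c.subfamily_letter, c.exemplar_letter)
    return list(consensus_set)


def classification_table(consensus_set: Sequence[ConsensusElement], params=ClassificationParams()):
    """Rows (name, family, subfamily, exemplar, closest neighbour, identities)."""
    rows = []
    for c in consensus_set:
        best_name, best5, best3 = "", 0.0, 0.0
        for other in consensus_set:
            if other is c or len(other.sequence) < params.end_len or len(c.sequence) < params.end_len:
                continue
            i5 = end_identity(c.sequence, other.sequence, "5prime", params)
            if i5 > best5:
                best_name, best5 = other.name, i5
                best3 = (
                    end_identity(c.sequence, other.sequence, "3prime", params)
                    if min(len(c.sequence), len(other.sequence)) >= params.end_len
                    else 0.0
                )
        rows.append(
            {
                "name": c.name,
                "family": c.family_id,
                "subfamily": c.subfamily_letter,
                "exemplar": c.exemplar_letter,
                "closest": best_name,
                "identity_5prime": round(best5, 4),
                "identity_3prime": round(best3, 4),
            }
        )
    return rows
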