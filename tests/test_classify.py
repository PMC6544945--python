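import numpy as np
import pytest

from helikit.classify import (
    FAMILY_ONLY,
    ClassificationParams,
    assign_exemplars,
    assign_families,
    assign_subfamilies,
    classify_consensus_set,
    end_identity,
    internal_identity,
    name_element,
)
from helikit.core_io import ConsensusElement


def _rand(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def _mutate_k(seq, k, rng):
    """Exactly k substitutions at distinct positions."""
    out = list(seq)
    for pos in rng.choice(len(seq), size=k, replace=False):
        out[pos] = "ACGT"[("ACGT".index(out[pos]) + 1 + int(rng.integers(0, 3))) % 4]
    return "".join(out)


class TestEndIdentity:
    def test_identical_ends(self, rng):
        s = _rand(rng, 60)
        assert end_identity(s, s, "5prime") == 1.0
        assert end_identity(s, s, "3prime") == 1.0

    def test_six_differences_is_point_eight(self, rng):
        a = _rand(rng, 30) + _rand(rng, 40)
        b = _mutate_k(a[:30], 6, rng) + _rand(rng, 40)
        assert end_identity(a, b, "5prime") == pytest.approx(0.8)

    def test_short_sequence_errors(self):
        with pytest.raises(ValueError, match="end undefined"):
            end_identity("ACGT", "ACGTACGTACGTACGTACGTACGTACGTACGT", "5prime")


def _element(name, seq, n=10):
    return ConsensusElement(name, seq, n_copies_used=n)


class TestFamilies:
    def test_high_5prime_identity_one_family(self, rng):
        head = _rand(rng, 30)
        a = _element("a", head + _rand(rng, 100))
        b = _element("b", _mutate_k(head, 2, rng) + _rand(rng, 100))  # ~0.93
        fams = assign_families([a, b])
        assert fams["a"] == fams["b"] == 1

    def test_low_5prime_identity_two_families(self, rng):
        head = _rand(rng, 30)
        far = _mutate_k(head, 14, rng)  # well under 80%
        a = _element("a", head + _rand(rng, 100))
        b = _element("b", far + _rand(rng, 100))
        fams = assign_families([a, b])
        assert fams["a"] != fams["b"]

    def test_singleton_is_family_one(self, rng):
        a = _element("solo", _rand(rng, 120))
        assert assign_families([a]) == {"solo": 1}

    def test_numbering_by_member_count(self, rng):
        h1, h2 = _rand(rng, 30), _rand(rng, 30)
        small = [_element("s1", h2 + _rand(rng, 80))]
        big = [_element(f"b{i}", h1 + _rand(rng, 80)) for i in range(3)]
        fams = assign_families(small + big)
        assert fams["b0"] == 1 and fams["s1"] == 2


class TestSubfamilies:
    def test_nine_tail_groups_lettered(self, rng):
        head = _rand(rng, 30)
        tails = [_rand(rng, 30) for _ in range(9)]
        members = []
        for i, t in enumerate(tails):
            for j in range(9 - i):  # group 0 largest -> letter A
                members.append(_element(f"g{i}_{j}", head + _rand(rng, 60) + t))
        assign_families(members)
        letters = assign_subfamilies(members)
        assert letters["g0_0"] == "A" and letters["g8_0"] == "I"
        assert {letters[f"g{i}_0"] for i in range(9)} == set("ABCDEFGHI")

    def test_identical_tails_single_subfamily(self, rng):
        head, tail = _rand(rng, 30), _rand(rng, 30)
        members = [_element(f"m{i}", head + _rand(rng, 50) + tail) for i in range(4)]
        letters = assign_subfamilies(members)
        assert set(letters.values()) == {"A"}

    def test_below_threshold_gets_own_subfamily(self, rng):
        head, tail = _rand(rng, 30), _rand(rng, 30)
        outlier_tail = _mutate_k(tail, 7, rng)  # 23/30 = 0.767 < 0.8
        members = [
            _element("m1", head + _rand(rng, 50) + tail),
            _element("m2", head + _rand(rng, 50) + tail),
            _element("out", head + _rand(rng, 50) + outlier_tail),
        ]
        letters = assign_subfamilies(members)
        assert letters["m1"] == letters["m2"] == "A"
        assert letters["out"] == "B"

    def test_truncated_consensus_family_only(self, rng):
        members = [
            _element("ok", _rand(rng, 120)),
            _element("short", _rand(rng, 40)),  # < 2 * end_len
        ]
        letters = assign_subfamilies(members)
        assert letters["short"] == FAMILY_ONLY


class TestExemplars:
    def test_nested_insert_series_three_exemplars(self, rng):
        core = _rand(rng, 161)
        aa = core
        ab = core[:100] + _rand(rng, 66) + core[100:]
        ac = ab[:130] + _rand(rng, 108) + ab[130:]
        members = [_element("Aa", aa, 60), _element("Ab", ab, 70), _element("Ac", ac, 80)]
        letters = assign_exemplars(members)
        assert len(set(letters.values())) == 3
        assert letters["Ac"] == "a"  # largest copy support first

    def test_identical_internals_one_exemplar(self, rng):
        seq = _rand(rng, 150)
        members = [_element("x", seq), _element("y", seq)]
        assert set(assign_exemplars(members).values()) == {"a"}

    def test_internal_identity_of_short_consensus_is_one(self, rng):
        assert internal_identity(_rand(rng, 55), _rand(rng, 60)) == 1.0


class TestNames:
    @pytest.mark.parametrize(
        "species,fam,sub,ex,expected",
        [
            ("Chilo suppressalis", 1, "A", "a", "Csup_Hel1Aa"),
            ("Parasteatoda tepidariorum", 2, "A", "a", "Ptep_Hel2Aa"),
            ("Nephila clavipes", 1, "A", "a", "Ncla_Hel1Aa"),
        ],
    )
    def test_known_names(self, species, fam, sub, ex, expected):
        assert name_element(species, fam, sub, ex) == expected

    def test_single_word_species_rejected(self):
        with pytest.raises(ValueError):
            name_element("Drosophila", 1, "A", "a")


def _planted_set(rng):
    """2 families x 3 subfamilies x 2 exemplars with clean structure."""
    elements, truth = [], {}
    for f in range(2):
        head = "TC" + _rand(rng, 28)
        for s in range(3):
            tail = _rand(rng, 26) + "CTGT"
            shared = _rand(rng, 150)
            for e in range(2):
                seq = head + shared + _rand(rng, 130) + tail
                name = f"el{f}{s}{e}"
                elements.append(_element(name, seq))
                truth[name] = (f, s, e)
    return elements, truth


def _partition_signature(elements):
    groups = {}
    for el in elements:
        groups.setdefault((el.family_id, el.subfamily_letter, el.exemplar_letter), set()).add(el.name)
    return frozenset(frozenset(v) for v in groups.values())


class TestFullClassification:
    def test_planted_structure_recovered(self, rng):
        elements, truth = _planted_set(rng)
        classify_consensus_set(elements)
        recovered = {}
        for el in elements:
            recovered.setdefault(
                (el.family_id, el.subfamily_letter, el.exemplar_letter), set()
            ).add(el.name)
        expected_groups = {}
        for name, key in truth.items():
            expected_groups.setdefault(key, set()).add(name)
        assert frozenset(map(frozenset, recovered.values())) == frozenset(
            map(frozenset, expected_groups.values())
        )

    def test_order_invariant_up_to_labels(self, rng):
        elements, _ = _planted_set(rng)
        classify_consensus_set(elements)
        sig1 = _partition_signature(elements)
        rng2 = np.random.default_rng(7)
        shuffled, _ = _planted_set(rng)  # fresh identical structure
        # rebuild identical sequences, shuffled input order
        elements2 = [ConsensusElement(e.name, e.sequence, e.n_copies_used) for e in elements]
        order = rng2.permutation(len(elements2))
        elements2 = [elements2[i] for i in order]
        classify_consensus_set(elements2)
        assert _partition_signature(elements2) == sig1

    def test_every_element_in_exactly_one_group(self, rng):
        elements, _ = _planted_set(rng)
        classify_consensus_set(elements, species="Testus example")
        for el in elements:
            assert el.family_id >= 1
            assert el.subfamily_letter and el.exemplar_letter
            assert el.name.startswith("Texa_Hel")
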