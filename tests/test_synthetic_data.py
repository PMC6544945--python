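import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helikit import synthetic_data as sd
from helikit.element_structure import matches_iupac
from helikit.quantify import k2p_distance


class TestBackground:
    def test_gc_within_binomial_bound(self):
        cfg = sd.SimConfig(seed=1, n_contigs=1, contig_len=100_000, gc_content=0.5)
        g = sd.make_background(cfg)[0]
        gc = sum(b in "GC" for b in g.sequence) / g.length
        sd3 = 3 * (0.25 / g.length) ** 0.5
        assert abs(gc - 0.5) < sd3

    def test_same_seed_identical(self):
        cfg = sd.SimConfig(seed=7, n_contigs=2, contig_len=5000)
        a = sd.make_background(cfg)
        b = sd.make_background(cfg)
        assert [g.sequence for g in a] == [g.sequence for g in b]

    def test_gc_zero_is_all_at(self):
        cfg = sd.SimConfig(seed=1, n_contigs=1, contig_len=2000, gc_content=0.0)
        g = sd.make_background(cfg)[0]
        assert set(g.sequence) <= {"A", "T"}


class TestMutateCopy:
    def test_d_zero_returns_master(self, rng):
        master = sd.make_master_element(rng).sequence
        assert sd.mutate_copy(master, 0.0, 2.0, rng) == master

    def test_estimator_consistency(self, rng):
        """Mean re-estimated K2P over 200 replicates within +-0.005 of d."""
        master = sd.make_master_element(rng, length=300)
        ests = [
            k2p_distance(
                master.sequence,
                sd.mutate_copy(master.sequence, 0.05, 2.0, rng, master.protected),
            )
            for _ in range(200)
        ]
        assert abs(float(np.mean(ests)) - 0.05) < 0.005

    def test_kappa_infinity_limit_no_transversions(self, rng):
        master = "A" * 500
        mutated = sd.mutate_copy(master, 0.3, 1e9, rng, protected=frozenset())
        assert set(mutated) <= {"A", "G"}  # transitions only

    def test_saturating_d_rejected(self, rng):
        with pytest.raises(ValueError, match="smaller d"):
            sd.mutate_copy("ACGT" * 100, 50.0, 2.0, rng, protected=frozenset())

    @given(d=st.floats(0.0, 0.3), seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_length_and_alphabet_preserved(self, d, seed):
        master = sd.make_master_element(np.random.default_rng(0)).sequence
        out = sd.mutate_copy(master, d, 2.0, np.random.default_rng(seed))
        assert len(out) == len(master)
        assert set(out) <= set("ACGT")
        assert out[:2] == "TC" and out[-4:] == master[-4:]  # default protection


class TestPlantCopies:
    def test_host_context_and_truth(self, small_bundle):
        cfg, genomes, truth = small_bundle
        assert len(truth.copies) == cfg.copies_per_element
        seqs = {g.contig_id: g.sequence for g in genomes}
        for c in truth.copies:
            s = seqs[c.locus.contig_id]
            planted = s[c.locus.start : c.locus.end]
            if c.locus.strand == "+":
                assert planted == c.sequence
                assert s[c.locus.start - 1] == "A" and s[c.locus.end] == "T"
            else:
                from helikit.core_io import revcomp

                assert revcomp(planted) == c.sequence
                # A|T on the element strand maps to A|T around the genome span too
                assert s[c.locus.start - 1] == "A" and s[c.locus.end] == "T"

    def test_full_truncation_removes_3prime_motif(self, rng):
        cfg = sd.SimConfig(
            seed=3, n_contigs=1, contig_len=60_000, copies_per_element=10,
            divergence_d=0.01, truncation_prob=1.0, truncation_range=(50, 120),
        )
        genomes = sd.make_background(cfg, rng)
        master = sd.make_master_element(rng)
        _, truth = sd.plant_copies(genomes, master, cfg, rng=rng)
        assert all(c.truncated for c in truth.copies)
        # the element's own 3' end (hairpin + terminus) is gone from every copy
        assert all(len(c.sequence) < len(master.sequence) for c in truth.copies)
        assert all(c.sequence[-20:] != master.sequence[-20:] for c in truth.copies)
        # truncation ends on random internal sequence: a chance CTRY match is
        # possible but rare
        chance = sum(matches_iupac(c.sequence[-4:], "CTRY") for c in truth.copies)
        assert chance <= 2

    def test_reproducible_from_config(self):
        cfg = sd.SimConfig(seed=9, n_contigs=1, contig_len=50_000, copies_per_element=8)
        g1, t1 = sd.simulate_bundle(cfg)
        g2, t2 = sd.simulate_bundle(cfg)
        assert [g.sequence for g in g1] == [g.sequence for g in g2]
        assert [(c.locus, c.sequence) for c in t1.copies] == [
            (c.locus, c.sequence) for c in t2.copies
        ]


class TestCaptureSeries:
    def test_lengths_and_nesting(self, rng):
        core = sd.make_master_element(rng, "core", length=161)
        specs = [sd.CaptureSpec("core", "Aa", 35, 130, 6)]
        masters, _ = sd.make_capture_series(core, specs, rng)
        assert [len(m.sequence) for m in masters] == [161, 196]

    def test_empty_specs_returns_master_only(self, rng):
        core = sd.make_master_element(rng, "core")
        masters, sources = sd.make_capture_series(core, [], rng)
        assert [m.label for m in masters] == ["core"] and sources == []

    def test_junction_shared_exactly(self, rng):
        core = sd.make_master_element(rng, "core", length=200)
        spec = sd.CaptureSpec("core", "Aa", 40, 100, junction_len=6)
        masters, sources = sd.make_capture_series(core, [spec], rng)
        _, insert, source_seq = sources[0]
        # source locus shares exactly 6 bp with each insertion boundary
        p = core.sequence
        left_ctx, right_ctx = p[100 - 7 : 100], p[100 : 100 + 7]
        i = source_seq.index(insert)
        assert source_seq[i - 6 : i] == left_ctx[1:]
        assert source_seq[i - 7] != left_ctx[0]
        assert source_seq[i + len(insert) : i + len(insert) + 6] == right_ctx[:6]
        assert source_seq[i + len(insert) + 6] != right_ctx[6]

    def test_junction_range_enforced(self):
        with pytest.raises(ValueError):
            sd.CaptureSpec("a", "b", 30, 50, junction_len=14)
        with pytest.raises(ValueError):
            sd.CaptureSpec("a", "b", 30, 50, junction_len=1)

    def test_offset_beyond_parent_rejected(self, rng):
        core = sd.make_master_element(rng, "core", length=100)
        with pytest.raises(ValueError, match="beyond parent"):
            sd.make_capture_series(core, [sd.CaptureSpec("core", "x", 30, 500, 5)], rng)


class TestEmptySites:
    def test_zero_leaves_genomes_unchanged(self, rng):
        cfg = sd.SimConfig(seed=5, n_contigs=1, contig_len=30_000, copies_per_element=3)
        genomes, truth = sd.simulate_bundle(cfg)
        g2, _ = sd.plant_empty_sites(genomes, truth, 0, rng)
        assert [g.sequence for g in g2] == [g.sequence for g in genomes]

    def test_joined_flanks_present(self, rng):
        cfg = sd.SimConfig(seed=5, n_contigs=1, contig_len=30_000, copies_per_element=3)
        genomes, truth = sd.simulate_bundle(cfg)
        genomes, truth = sd.plant_empty_sites(genomes, truth, 1, rng, flank=50)
        (copy_locus, empty_locus), = truth.empty_sites
        seqs = {g.contig_id: g.sequence for g in genomes}
        empty = seqs[empty_locus.contig_id][empty_locus.start : empty_locus.end]
        src = seqs[copy_locus.contig_id]
        expected = (
            src[copy_locus.start - 50 : copy_locus.start]
            + src[copy_locus.end : copy_locus.end + 50]
        )
        assert empty == expected


def test_save_bundle_outputs(tmp_path):
    cfg = sd.SimConfig(seed=2, n_contigs=1, contig_len=30_000, copies_per_element=4, n_genes=2)
    genomes, truth = sd.simulate_bundle(cfg)
    sd.save_bundle(tmp_path, genomes, truth, cfg)
    for name in ("genome.fasta", "masters.fasta", "annotation.gff3", "truth.tsv", "config.yaml"):
        assert (tmp_path / name).exists()
    assert "planted_copy" in (tmp_path / "annotation.gff3").read_text()
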