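import numpy as np
import pytest

from helikit.capture_autonomy import (
    NoAutonomousPartner,
    NoCoreError,
    find_empty_sites,
    find_source_locus,
    infer_core,
    load_motif_blocks,
    order_exemplars_by_divergence,
    reconstruct_autonomous,
    scan_rep_hel_motifs,
)
from helikit.core_io import GenomeSeq, Interval
from helikit.homology_search import extract_copy, index_genome, search
from helikit.quantify import DivergenceReport
from helikit import synthetic_data as sd


@pytest.fixture(scope="module")
def capture_world():
    """Genome with a planted core -> Aa -> Ab -> Ac capture series."""
    rng = np.random.default_rng(11)
    cfg = sd.SimConfig(seed=11, n_contigs=2, contig_len=100_000)
    genomes = sd.make_background(cfg, rng)
    core = sd.make_master_element(rng, "core", length=200)
    specs = [
        sd.CaptureSpec("core", "Aa", 35, 130, junction_len=6),
        sd.CaptureSpec("Aa", "Ab", 66, 150, junction_len=4),
        sd.CaptureSpec("Ab", "Ac", 108, 170, junction_len=9),
    ]
    truth = sd.SimTruth()
    genomes, masters, truth = sd.plant_capture_series(genomes, core, specs, rng, truth)
    return genomes, masters, truth, specs


class TestInferCore:
    def test_identical_pair_core_is_whole(self, rng):
        seq = sd.make_master_element(rng, length=150).sequence
        core, inserts = infer_core([("a", seq), ("b", seq)])
        assert core == seq
        assert inserts == {"a": [], "b": []}

    def test_unrelated_sequences_no_core(self, rng):
        a = "".join("ACGT"[i] for i in rng.integers(0, 4, 200))
        b = "".join("ACGT"[i] for i in rng.integers(0, 4, 200))
        with pytest.raises(NoCoreError):
            infer_core([("a", a), ("b", b)])

    def test_planted_series_insert_lengths(self, capture_world):
        _, masters, _, _ = capture_world
        core_seq, inserts = infer_core([(m.label, m.sequence) for m in masters])
        assert core_seq == masters[0].sequence
        lengths = {
            name: [e - s for s, e in spans] for name, spans in inserts.items()
        }
        # nested series: each child's non-core region grows by the new insert
        assert lengths == {"core": [], "Aa": [35], "Ab": [35 + 66], "Ac": [35 + 66 + 108]}
        assert inserts["Aa"][0][0] == 130  # at the planted offset


class TestSourceLocus:
    def test_junctions_recovered_exactly(self, capture_world):
        genomes, masters, truth, specs = capture_world
        idx = index_genome(genomes)
        by_label = {m.label: m for m in masters}
        _, inserts = infer_core([(m.label, m.sequence) for m in masters])
        child = by_label["Aa"].sequence
        s, e = inserts["Aa"][0]
        region = find_source_locus(
            child[s:e], child, s, genomes, index=idx, child_exemplar="Aa"
        )
        assert region.source_locus is not None
        assert len(region.left_junction) == 6
        assert len(region.right_junction) == 6
        assert region.junction_in_range
        # junction strings are verifiable substrings of both flanks
        seqs = {g.contig_id: g.sequence for g in genomes}
        contig = seqs[region.source_locus.contig_id]
        assert child[:s].endswith(region.left_junction)
        assert contig[: region.source_locus.start].endswith(region.left_junction)

    def test_absent_insert_unknown_source(self, capture_world, rng):
        genomes, masters, _, _ = capture_world
        idx = index_genome(genomes)
        foreign = "".join("ACGT"[i] for i in rng.integers(0, 4, 60))
        region = find_source_locus(foreign, "A" * 20 + foreign + "A" * 20, 20, genomes, index=idx)
        assert region.source_locus is None
        assert region.left_junction is None

    def test_long_overlap_flagged_out_of_range(self, rng):
        elem_core = "".join("ACGT"[i] for i in rng.integers(0, 4, 120))
        insert = "".join("ACGT"[i] for i in rng.integers(0, 4, 50))
        element = elem_core[:60] + insert + elem_core[60:]
        # source locus shares 15 bp on each side of the insert
        source = (
            "".join("ACGT"[i] for i in rng.integers(0, 4, 40))
            + elem_core[45:60] + insert + elem_core[60:75]
            + "".join("ACGT"[i] for i in rng.integers(0, 4, 40))
        )
        background = "".join("ACGT"[i] for i in rng.integers(0, 4, 5000))
        genome = GenomeSeq("c", background + source + background)
        region = find_source_locus(insert, element, 60, [genome])
        assert region.source_locus is not None
        assert len(region.left_junction) >= 15
        assert not region.junction_in_range

    def test_too_short_insert_rejected(self, capture_world):
        genomes, _, _, _ = capture_world
        with pytest.raises(ValueError):
            find_source_locus("ACGTACGTACGT", "A" * 100, 50, genomes)


class TestOrdering:
    def test_descending_divergence(self):
        reps = [
            DivergenceReport("Ac", 378, 1113, 0.096, 0.016, 69),
            DivergenceReport("Aa", 196, 495, 0.022, 0.852, 60),
            DivergenceReport("Ab", 262, 463, 0.028, 0.164, 86),
        ]
        order, ambiguous = order_exemplars_by_divergence(reps)
        assert order == ["Aa", "Ab", "Ac"]
        assert ambiguous is False

    def test_tie_flagged_ambiguous(self):
        reps = [
            DivergenceReport("x", 1, 1, 0.0, 0.5, 3),
            DivergenceReport("y", 1, 1, 0.0, 0.5, 3),
        ]
        _, ambiguous = order_exemplars_by_divergence(reps)
        assert ambiguous is True

    def test_nd_excluded(self):
        reps = [
            DivergenceReport("x", 1, 1, 0.0, None, 0),
            DivergenceReport("y", 1, 1, 0.0, 0.5, 3),
        ]
        with pytest.raises(ValueError):
            order_exemplars_by_divergence(reps)


class TestReconstruction:
    def test_three_deletion_copies_restored(self, rng):
        dna, protein = sd.make_rephel_master(rng, n_aa=1050)
        copies = [dna[:p] + dna[p + 1 :] for p in (400, 1400, 2400)]
        rdna, rprot = reconstruct_autonomous(copies, min_aa=1000)
        assert rprot.aa_sequence == protein
        assert "*" not in rprot.aa_sequence

    def test_single_copy_with_stops_rejected(self, rng):
        dna, _ = sd.make_rephel_master(rng, n_aa=1050)
        broken = dna[:900] + "TAA" + dna[900:]  # in-frame premature stop
        with pytest.raises(NoAutonomousPartner):
            reconstruct_autonomous([broken], min_aa=1000)

    def test_clean_orf_translated_full_length(self, rng):
        dna, protein = sd.make_rephel_master(rng, n_aa=1200)
        _, rprot = reconstruct_autonomous([dna, dna], min_aa=1000)
        assert len(rprot.aa_sequence) == 1200
        assert rprot.aa_sequence.startswith("M")


class TestMotifScan:
    def test_self_match_finds_everything(self, rng):
        _, protein = sd.make_rephel_master(rng, n_aa=1100)
        res = scan_rep_hel_motifs(protein)
        assert len(res["rep_his_positions"]) == 2
        assert len(res["rep_tyr_positions"]) == 2
        assert res["helicase_motif_count"] == 8
        # the mapped residues really are His / Tyr
        assert all(protein[p] == "H" for p in res["rep_his_positions"])
        assert all(protein[p] == "Y" for p in res["rep_tyr_positions"])

    def test_shuffle_null_calibration(self, rng):
        """Random proteins almost never contain motif blocks (<=1 hit)."""
        aa = "ARNDCQEGHILKMFPSTWYV"
        worst = 0
        for _ in range(50):
            prot = "".join(aa[i] for i in rng.integers(0, 20, 1100))
            res = scan_rep_hel_motifs(prot)
            total = (
                res["helicase_motif_count"]
                + bool(res["rep_his_positions"])
                + bool(res["rep_tyr_positions"])
            )
            worst = max(worst, total)
        assert worst <= 1

    def test_noisy_reconstruction_keeps_most_motifs(self, rng):
        _, protein = sd.make_rephel_master(rng, n_aa=1100)
        aa = "ARNDCQEGHILKMFPSTWYV"
        noisy = list(protein)
        for pos in rng.choice(len(noisy), size=len(noisy) // 20, replace=False):
            noisy[pos] = aa[int(rng.integers(0, 20))]  # ~5% substitutions
        res = scan_rep_hel_motifs("".join(noisy))
        assert res["helicase_motif_count"] >= 7

    def test_blocks_load(self):
        blocks = load_motif_blocks()
        names = {b.name for b in blocks}
        assert "rep_two_his" in names and "rep_two_tyr" in names
        assert sum(n.startswith("hel_") for n in names) == 8


@pytest.fixture(scope="module")
def world():
    cfg = sd.SimConfig(seed=12, n_contigs=2, contig_len=60_000,
                       copies_per_element=5, divergence_d=0.01)
    genomes, truth = sd.simulate_bundle(cfg)
    rng = np.random.default_rng(5)
    genomes, truth = sd.plant_empty_sites(genomes, truth, 2, rng)
    idx = index_genome(genomes)
    master = truth.masters["Hel1"]
    hits = search(master.sequence, idx, 0.8, 100)
    copies = [extract_copy(h, genomes, 200, query_len=300) for h in hits]
    return genomes, truth, idx, copies


class TestEmptySites:
    def test_planted_empty_sites_detected(self, world):
        genomes, truth, idx, copies = world
        planted_empty = {iv.start for _, iv in truth.empty_sites}
        detected = set()
        for c in copies:
            for locus, _, label in find_empty_sites(
                c, {"genomeA": genomes}, "genomeA", indexes={"genomeA": idx}
            ):
                assert label == "paralogous"
                detected.add(locus.start)
        assert len(detected) == 2
        for d in detected:
            assert any(abs(d - p) <= 5 for p in planted_empty)

    def test_no_planted_site_empty_list(self, world):
        genomes, truth, idx, copies = world
        with_site = {iv.contig_id + str(iv.start) for iv, _ in truth.empty_sites}
        misses = [
            c for c in copies
            if c.locus.contig_id + str(c.locus.start) not in with_site
        ]
        assert misses
        for c in misses[:2]:
            assert (
                find_empty_sites(c, {"genomeA": genomes}, "genomeA", indexes={"genomeA": idx})
                == []
            )

    def test_orthologous_label_in_second_genome(self, world, rng):
        genomes, truth, idx, copies = world
        copy_locus, _ = truth.empty_sites[0]
        target = next(
            c for c in copies
            if c.locus.contig_id == copy_locus.contig_id
            and abs(c.locus.start - copy_locus.start) <= 5
        )
        # second genome = empty-site flanks embedded in fresh background
        joined = target.left_flank[-50:] + target.right_flank[:50]
        other = "".join("ACGT"[i] for i in rng.integers(0, 4, 20_000))
        genome_b = [GenomeSeq("bc1", other[:10_000] + joined + other[10_000:])]
        res = find_empty_sites(
            target, {"genomeA": genomes, "genomeB": genome_b}, "genomeA",
            indexes={"genomeA": idx, "genomeB": index_genome(genome_b)},
        )
        labels = {label for _, name, label in res if name == "genomeB"}
        assert labels == {"orthologous"}
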