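"""Rebuild an autonomous Rep/helicase element and draw a copy phylogeny.

Part 1 degrades a synthetic autonomous element (one frameshifting deletion
per copy), restores the uninterrupted ORF by majority vote and scans the
protein for the replication-initiator (two-His, two-Tyr) and the eight SF1
helicase motif blocks. Part 2 builds a neighbor-joining tree with bootstrap
support for copies of two diverged exemplars.
"""

import numpy as np

from helikit import synthetic_data as sd
from helikit.capture_autonomy import reconstruct_autonomous, scan_rep_hel_motifs
from helikit.consensus import align_copies
from helikit.phylo import bootstrap, distance_matrix, nj_tree

rng = np.random.default_rng(17)

# --- autonomous partner -----------------------------------------------------
dna, protein = sd.make_rephel_master(rng, n_aa=1467)
copies = [dna[:p] + dna[p + 1 :] for p in (800, 2300, 3900)]
_, rephel = reconstruct_autonomous(copies, min_aa=1000)
scan_rep_hel_motifs(rephel)
print(f"reconstructed ORF:       {len(rephel.aa_sequence)} aa on strand {rephel.strand}")
print(f"Rep initiator His:       positions {rephel.rep_his_positions}")
print(f"Rep catalytic Tyr:       positions {rephel.rep_tyr_positions}")
print(f"SF1 helicase motifs:     {rephel.helicase_motif_count} / 8")
print("Three copies, each broken by a different single-base deletion, vote")
print("each other's frameshifts away, restoring the full coding sequence.")
print()

# --- copy phylogeny ----------------------------------------------------------
master = sd.make_master_element(rng, length=300)
other = sd.mutate_copy(master.sequence, 0.2, 2.0, rng, master.protected)
rows, labels = [], []
for i in range(4):
    rows.append(sd.mutate_copy(master.sequence, 0.01, 2.0, rng, master.protected))
    labels.append(f"exemplarA_copy{i}")
for i in range(4):
    rows.append(sd.mutate_copy(other, 0.01, 2.0, rng, master.protected))
    labels.append(f"exemplarB_copy{i}")
aln = align_copies(rows)
tree = nj_tree(distance_matrix(aln, labels, model="K2P"), labels)
support = bootstrap(aln, labels, n_replicates=200, seed=17)
split = frozenset(lab for lab in labels if lab.startswith("exemplarB"))
print("NJ tree:", tree)
print(f"bootstrap support for the A|B split: {support[split]:.2f} (200 replicates)")
print("Copies of the two exemplars form two clades separated by the deepest")
print("split, with essentially full bootstrap support.")
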