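"""Simulate a genome with planted Helitron copies, rediscover them, and
build the copy-number / divergence report.

Plants 40 copies of a 300 bp element at 3% per-site divergence into 2 x
100 kb of random background, then runs the seed-and-extend search with the
standard counting rule (>= 80% identity over >= 100 bp) and the K2P
divergence estimator.
"""

from helikit import synthetic_data as sd
from helikit.homology_search import extract_copy, index_genome, search
from helikit.quantify import average_divergence, count_copies, genome_fraction

cfg = sd.SimConfig(
    seed=11, n_contigs=2, contig_len=100_000,
    copies_per_element=40, divergence_d=0.03,
)
genomes, truth = sd.simulate_bundle(cfg)
master = truth.masters["Hel1"]

index = index_genome(genomes)
hits = search(master.sequence, index, min_identity=0.8, min_len=100)
counted = count_copies(hits)
copies = [
    extract_copy(h, genomes, flank=200, query_len=cfg.element_len) for h in counted
]
est, n_used = average_divergence([c.sequence for c in copies], master.sequence)
frac = genome_fraction(counted, sum(g.length for g in genomes))

print(f"planted copies:          {len(truth.copies)}")
print(f"counted copies:          {len(counted)}")
print(f"genome fraction:         {frac:.3f} %")
print(f"average divergence:      {est:.3f} % (from {n_used} qualifying copies)")
print()
print("The count should match the planted 40 exactly at this divergence;")
print("the average divergence estimates the planted 3.0% within sampling noise.")
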