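"""Classify a consensus set into families, subfamilies and exemplars.

The 5'-end-first criteria: same family = 30 bp 5' ends at >= 80% identity;
same subfamily = 30 bp 3' ends at >= 80%; same exemplar = internal region
at > 80%. Names follow the Xxxx_Hel<family><Subfamily><exemplar> pattern.
"""

import numpy as np

from helikit.classify import classify_consensus_set
from helikit.core_io import ConsensusElement

rng = np.random.default_rng(5)


def rand(n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


# two families (distinct 5' heads); within family one shares the 3' tail,
# and one subfamily carries two exemplars that differ internally
elements = []
for fam in range(2):
    head = "TC" + rand(28)
    for sub in range(2):
        tail = rand(26) + "CTGT"
        shared_internal = rand(140)
        for ex in range(2 if sub == 0 else 1):
            seq = head + shared_internal + rand(110) + tail
            elements.append(
                ConsensusElement(f"raw_{fam}{sub}{ex}", seq, n_copies_used=20 + ex)
            )

classify_consensus_set(elements, species="Chilo suppressalis")
print(f"{'name':>14} {'family':>7} {'subfamily':>10} {'exemplar':>9} {'len':>5}")
for el in elements:
    print(
        f"{el.name:>14} {el.family_id:>7} {el.subfamily_letter:>10} "
        f"{el.exemplar_letter:>9} {el.length:>5}"
    )
print()
print("Elements sharing a 5' head fall in one family; 3' tails split the")
print("subfamilies (letters by copy support); divergent internal regions")
print("separate exemplars, giving names like Csup_Hel1Aa / Csup_Hel1Ab.")
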