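"""Clean a reference panel and pick a uniformly spaced SNP subset.

Builds a labeled reference of two simulated breeds, plants one
mislabeled animal, removes it with the multinomial purity filter, and
then selects a 100-SNP uniform panel from the map.
"""

import numpy as np

from gbckit import (
    BreedLabels,
    GenotypeMatrix,
    CrossSimConfig,
    filter_reference,
    select_uniform_snps,
    simulate_crossbreds,
    uniform_snp_map,
)
from gbckit.containers import AlleleFrequencyTable
from gbckit.synth import BreedSimConfig, simulate_breed_frequencies

# two divergent breeds, 30 purebred animals each, one mislabeled animal
cols = [
    simulate_breed_frequencies(BreedSimConfig(M=1000, K=1, F=0.8, seed=k)).freq[:, 0]
    for k in range(2)
]
F = AlleleFrequencyTable([f"snp{i+1}" for i in range(1000)], ["angus", "brahman"],
                         np.column_stack(cols))
herds = [
    simulate_crossbreds(F.subset_breeds([b]), CrossSimConfig(W=[1.0], n=30, seed=10 + k))
    for k, b in enumerate(F.breeds)
]
dosage = np.vstack([h.dosage for h in herds])
ids = [f"angus{i}" for i in range(30)] + [f"brahman{i}" for i in range(30)]
G = GenotypeMatrix(ids, F.snp_ids, dosage, np.zeros_like(dosage, bool))
labels = {a: "angus" for a in ids[:30]} | {a: "brahman" for a in ids[30:]}
labels["brahman0"] = "angus"  # plant a mislabeled animal

retained, excluded = filter_reference(G, BreedLabels(labels), threshold=2.0)
print(f"retained {retained.n_animals}/60 animals")
for p in excluded:
    print(f"excluded {p.animal_id} from {p.breed}: purity score {p.score:.2f} > 2")

snp_map = uniform_snp_map(1000, n_chrom=10)
panel = select_uniform_snps(snp_map, 100)
print(f"uniform panel: {len(panel)} SNPs, first three {panel[:3]}")

# The planted animal is the only exclusion (its score, -2 x mean log10
# genotype probability under its claimed breed, far exceeds the cutoff
# of 2), and the panel holds 10 evenly spaced SNPs per chromosome.
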