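"""Neighbor-joining tree with bootstrap support.

Builds a gapless alignment with two well-separated planted clades, infers
the NJ tree from p-distances, and attaches column-bootstrap supports. The
clade separating A* from B* should approach 100% support; the printed
Newick carries supports as internal-node labels.
"""
import numpy as np

from actinoprint import SequenceRecord, bootstrap_support, write_newick
from actinoprint.dna import random_dna

rng = np.random.default_rng(3)
templates = {"A": random_dna(400, rng), "B": random_dna(400, rng)}
alignment = []
for clade, template in templates.items():
    for k in range(3):
        seq = "".join(
            "ACGT"[rng.integers(4)] if rng.random() < 0.02 else base
            for base in template
        )
        alignment.append(SequenceRecord(f"{clade}{k}", "", seq))

tree = bootstrap_support(alignment, n_reps=200, rng_seed=42)
print(write_newick(tree))
supports = sorted(n.support for n in tree.non_tips(include_self=False))
print(f"\ninternal-edge supports (%): {supports}")
print("high values = the edge appeared in most of the 200 column-resampled trees")
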