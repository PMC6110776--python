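"""Build a bootstrapped Neighbor-Joining tree from an alignment.

Tajima-Nei distances (pairwise deletion of gapped columns), NJ topology,
column-resampling bootstrap supports, outgroup rooting and Newick output.
"""

import numpy as np

from petalsplit.phylo import bootstrap_support, root_with_outgroup, to_newick
from petalsplit.seqio import SequenceRecord
from petalsplit.simdata import _mutate

# a small family: sequences diverged from a common ancestor, plus an
# outgroup diverged further
rng = np.random.default_rng(0)
ancestor = "".join(rng.choice(list("ACGT"), 400))
clade_a = _mutate(ancestor, 0.03, rng)
clade_b = _mutate(ancestor, 0.10, rng)
msa = [
    SequenceRecord("TOE1", _mutate(clade_a, 0.02, rng)),
    SequenceRecord("TOE2", _mutate(clade_a, 0.02, rng)),
    SequenceRecord("AP2a", _mutate(clade_b, 0.02, rng)),
    SequenceRecord("AP2b", _mutate(clade_b, 0.02, rng)),
    SequenceRecord("ANT", _mutate(ancestor, 0.25, rng)),   # outgroup
]

tree = bootstrap_support(msa, n_reps=200, seed=1)
rooted = root_with_outgroup(tree, "ANT")
print(to_newick(rooted))
# Internal-node labels are bootstrap percentages over 200 column
# resamplings; the root splits the ANT pendant edge at its midpoint.
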