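"""Rarefaction curve and core genome of a synthetic pangenome.

The rarefaction curve gives the expected number of distinct protein
families discovered as genomes are sampled without replacement; the
core genome is the set of families present in every genome.
"""

from halopan.pangenome import core_families, rarefy
from halopan.synth import gen_pangenome

_, families, matrix, _, truth = gen_pangenome(
    n_genomes=12, n_core=25, n_accessory=60, seed=3
)

curve = rarefy(matrix, replicates=2000, seed=1)
print("genomes sampled -> mean unique families (closed-form expectation):")
for n, m, e in zip(curve.sample_sizes, curve.mean_unique_families, curve.expected):
    print(f"  {n:2d} -> {m:7.1f}  ({e:7.1f})")
# The Monte-Carlo mean tracks the exact hypergeometric expectation; the
# curve flattening indicates how much of the pangenome sampling has seen.

core = core_families(matrix)
print(f"\ncore families: {len(core)} (planted: {len(truth.truth['core_families'])})")
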