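"""Independent oracles shared by the test suite.

These deliberately avoid the code paths they check: monophyly via
dendropy's bipartition bitmasks, pI via a grid scan over the charge
curve.
"""

import numpy as np

from halopan.pi import EMBOSS_PKA, net_charge


def dendropy_monophyly(newick: str, tag: str) -> bool:
    """Exhaustive edge scan using dendropy's bipartition encoding."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.is_rooted = False
    tree.update_bipartitions(suppress_unifurcations=True)
    tips = {lf.taxon.label for lf in tree.leaf_node_iter()}
    tagged = frozenset(t for t in tips if t.startswith(tag))
    if len(tagged) <= 1 or tagged == tips:
        return True
    ns = tree.taxon_namespace
    want = ns.taxa_bitmask(labels=tagged)
    full = ns.all_taxa_bitmask()
    for bip in tree.bipartition_encoding:
        mask = bip.split_bitmask
        if mask == want or (mask ^ full) == want:
            return True
    return False


def grid_scan_pi(seq: str, pka=EMBOSS_PKA, step: float = 1e-4) -> float:
    """pI by grid scan: bracket the sign change of the (monotone) charge
    curve on a 0.01 grid, then minimize |charge| on a *step* grid inside
    the bracket — equivalent to a full fine scan by monotonicity."""
    coarse = np.arange(0.0, 14.0 + 1e-9, 0.01)
    charges = np.array([net_charge(seq, p, pka) for p in coarse])
    if charges[0] <= 0:
        return 0.0
    if charges[-1] >= 0:
        return 14.0
    k = int(np.argmax(charges <= 0))
    fine = np.arange(coarse[k - 1], coarse[k] + step, step)
    vals = np.abs([net_charge(seq, p, pka) for p in fine])
    return float(fine[int(np.argmin(vals))])
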