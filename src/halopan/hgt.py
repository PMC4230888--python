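"""Gene-tree classification of bacteria-to-haloarchaea transfers.

Gene trees carry domain tags on their tips — H (haloarchaea),
A (other archaea), E ((eu)bacteria) — prepended to the gene ID. A tree
supports a single basal bacterial import only if (1) the H tips form a
monophyletic group (an edge of the unrooted tree separates them from
everything else) and (2) that group attaches among bacterial rather
than archaeal homologs. Families are extended with recruited homologs
before re-testing, and calls are summarized as assessed / basal-import
/ non-monophyly counts with percentages. Bootstrap clade support is
tabulated as the fraction of replicate trees containing each guide-tree
bipartition.
"""

from __future__ import annotations

from collections import Counter, deque
from dataclasses import dataclass, field

import dendropy

from .io import SimilarityEdge

DOMAIN_TAGS = ("H", "A", "E")


class _UTree:
    """Minimal unrooted-tree adjacency structure built from newick."""

    def __init__(self, newick: str):
        tree = dendropy.Tree.get(data=newick, schema="newick")
        self.adj: dict[int, set[int]] = {}
        self.leaf_label: dict[int, str] = {}
        ids: dict[int, int] = {}
        for k, node in enumerate(tree.preorder_node_iter()):
            ids[id(node)] = k
            self.adj[k] = set()
        for node in tree.preorder_node_iter():
            k = ids[id(node)]
            if node.parent_node is not None:
                p = ids[id(node.parent_node)]
                self.adj[k].add(p)
                self.adj[p].add(k)
            if node.is_leaf():
                self.leaf_label[k] = node.taxon.label.replace(" ", "_")
        self._suppress_degree_two()

    def _suppress_degree_two(self) -> None:
        # the newick root is often degree 2; splice it out so the
        # structure is genuinely unrooted
        for node in list(self.adj):
            if node not in self.leaf_label and len(self.adj[node]) == 2:
                a, b = self.adj[node]
                self.adj[a].discard(node)
                self.adj[b].discard(node)
                self.adj[a].add(b)
                self.adj[b].add(a)
                del self.adj[node]

    @property
    def leaves(self) -> list[str]:
        return sorted(self.leaf_label.values())

    def edge_bipartitions(self):
        """Yield (u, v, leafset-under-v-away-from-u) for every edge."""
        root = next(iter(self.adj))
        seen = {root}
        order: list[tuple[int, int]] = []  # (parent, child) in DFS order
        stack = [root]
        parent = {root: None}
        while stack:
            u = stack.pop()
            for w in self.adj[u]:
                if w not in seen:
                    seen.add(w)
                    parent[w] = u
                    order.append((u, w))
                    stack.append(w)
        clade: dict[int, frozenset[str]] = {}
        for u, w in reversed(order):
            if w in self.leaf_label:
                clade[w] = frozenset([self.leaf_label[w]])
            else:
                clade[w] = frozenset().union(
                    *(clade[c] for c in self.adj[w] if c != u)
                )
        for u, w in order:
            yield u, w, clade[w]


@dataclass
class LabeledGeneTree:
    """A gene-tree topology whose tips carry a domain tag in {H, A, E}."""

    newick: str
    family_id: str = ""

    def __post_init__(self) -> None:
        self._tree = _UTree(self.newick)
        tips = self._tree.leaves
        if len(tips) < 3:
            raise ValueError("gene tree needs at least 3 tips")
        self.tags: dict[str, str] = {}
        for t in tips:
            tag = t[0].upper()
            if tag not in DOMAIN_TAGS:
                raise ValueError(f"tip {t!r} lacks an H/A/E tag prefix")
            self.tags[t] = tag

    @property
    def tips(self) -> list[str]:
        return self._tree.leaves

    def tips_with_tag(self, tag: str) -> set[str]:
        return {t for t, g in self.tags.items() if g == tag}


@dataclass
class HgtCall:
    family_id: str
    verdict: str  # basal_import | non_monophyly | excluded_too_large | untestable
    h_monophyletic: bool
    neighbor_composition: Counter = field(default_factory=Counter)

    def __post_init__(self) -> None:
        if self.verdict == "basal_import" and not self.h_monophyletic:
            raise ValueError("basal_import requires H monophyly")


@dataclass
class RecruitmentThresholds:
    max_evalue: float = 1e-10
    min_identity: float = 30.0
    max_family_size: int = 200

    def __post_init__(self) -> None:
        if not (0 < self.min_identity <= 100):
            raise ValueError("min_identity must lie in (0, 100]")
        if self.max_evalue <= 0 or self.max_family_size <= 0:
            raise ValueError("thresholds must be positive")


def is_monophyletic(tree: LabeledGeneTree, tag: str = "H") -> bool:
    """True iff an edge of the unrooted tree separates exactly the
    *tag* tips from all others (trivially true for one tip or all tips)."""
    tagged = tree.tips_with_tag(tag)
    if not tagged:
        raise ValueError(f"tree has no tip with tag {tag!r}")
    all_tips = set(tree.tips)
    if len(tagged) == 1 or tagged == all_tips:
        return True
    target = frozenset(tagged)
    complement = frozenset(all_tips - tagged)
    for _u, _v, clade in tree._tree.edge_bipartitions():
        if clade == target or clade == complement:
            return True
    return False


def _neighbor_tips(tree: LabeledGeneTree, h_set: set[str], neighbor_depth: int) -> Counter:
    """Tags of non-H tips reachable from the H attachment node through
    at most *neighbor_depth* intervening internal nodes."""
    ut = tree._tree
    target = frozenset(h_set)
    complement = frozenset(set(tree.tips) - h_set)
    attach = h_side = None
    for u, v, clade in ut.edge_bipartitions():
        if clade == target:
            attach, h_side = u, v
            break
        if clade == complement:
            attach, h_side = v, u
            break
    assert attach is not None
    comp: Counter = Counter()
    # BFS outward from the attachment node, never crossing back to H
    q: deque[tuple[int, int]] = deque()
    for w in ut.adj[attach]:
        if w != h_side:
            q.append((w, 0))
    visited = {attach, h_side}
    while q:
        node, internals = q.popleft()
        if node in visited:
            continue
        visited.add(node)
        if node in ut.leaf_label:
            comp[tree.tags[ut.leaf_label[node]]] += 1
            continue
        if internals + 1 > neighbor_depth:
            continue
        for w in ut.adj[node]:
            q.append((w, internals + 1))
    return comp


def classify_tree(
    tree: LabeledGeneTree,
    neighbor_depth: int = 1,
    sister_rule: str = "all_bacterial",
) -> HgtCall:
    """Classify a labeled gene tree as basal bacterial import or not.

    If the H tips are not monophyletic the verdict is ``non_monophyly``.
    Otherwise the tree is rooted on the H-separating edge and the tags
    of the nearest non-H tips (those within *neighbor_depth* internal
    nodes of the attachment point) are collected. Under the strict
    ``all_bacterial`` rule the verdict is ``basal_import`` iff that
    composition contains at least one E and no A; ``majority_bacterial``
    requires only more E than A tips.
    """
    h_set = tree.tips_with_tag("H")
    if not h_set:
        raise ValueError("tree contains no H tip")
    if h_set == set(tree.tips):
        return HgtCall(tree.family_id, "untestable", True)
    if not is_monophyletic(tree, "H"):
        return HgtCall(tree.family_id, "non_monophyly", False)
    comp = _neighbor_tips(tree, h_set, neighbor_depth)
    if sister_rule == "all_bacterial":
        basal = comp["E"] >= 1 and comp["A"] == 0
    elif sister_rule == "majority_bacterial":
        basal = comp["E"] >= 1 and comp["E"] > comp["A"]
    else:
        raise ValueError(f"unknown sister_rule {sister_rule!r}")
    verdict = "basal_import" if basal else "non_monophyly"
    return HgtCall(tree.family_id, verdict, True, comp)


#: Backwards-compatible alias for the monophyly predicate.
test_monophyly = is_monophyletic


def extend_family(
    family_proteins: set[str],
    pool: set[str],
    edges: list[SimilarityEdge],
    thresholds: RecruitmentThresholds | None = None,
) -> tuple[set[str], bool]:
    """Recruit pool homologs into a family before re-building its tree.

    A pool protein joins iff it has at least one edge to a family
    member with evalue <= max_evalue and identity >= min_identity.
    Returns (extended member set, excluded_too_large flag).
    """
    t = thresholds or RecruitmentThresholds()
    recruited: set[str] = set()
    for e in edges:
        if e.evalue > t.max_evalue or e.pct_identity < t.min_identity:
            continue
        if e.query_id in family_proteins and e.subject_id in pool:
            recruited.add(e.subject_id)
        elif e.subject_id in family_proteins and e.query_id in pool:
            recruited.add(e.query_id)
    extended = set(family_proteins) | recruited
    return extended, len(extended) > t.max_family_size


def summarize_calls(calls: list[HgtCall], dataset_label: str = "") -> dict:
    """Table-1-style summary row: trees assessed, basal imports and
    non-monophylies with percentages (one-decimal rounding).

    ``excluded_too_large`` and ``untestable`` calls drop out of the
    assessed denominator.
    """
    if not calls:
        raise ValueError("no calls to summarize")
    assessed = [c for c in calls if c.verdict in ("basal_import", "non_monophyly")]
    n = len(assessed)
    basal = sum(c.verdict == "basal_import" for c in assessed)
    nonmono = n - basal
    return {
        "dataset": dataset_label,
        "trees_assessed": n,
        "basal_imports": basal,
        "basal_pct": round(100.0 * basal / n, 1) if n else float("nan"),
        "non_monophylies": nonmono,
        "non_monophyly_pct": round(100.0 * nonmono / n, 1) if n else float("nan"),
        "excluded": len(calls) - n,
    }


# ---------------------------------------------------------------------------
# Bootstrap clade support
# ---------------------------------------------------------------------------

def _bipartition_set(newick: str) -> set[frozenset[str]]:
    """Canonical non-trivial bipartitions of an unrooted tree: each is
    the side NOT containing the lexicographically smallest tip."""
    ut = _UTree(newick)
    tips = set(ut.leaves)
    anchor = min(tips)
    out: set[frozenset[str]] = set()
    for _u, _v, clade in ut.edge_bipartitions():
        side = frozenset(tips - clade) if anchor in clade else clade
        if 2 <= len(side) <= len(tips) - 2:
            out.add(side)
    return out


def clade_support(
    guide: str,
    replicates: list[str],
    *,
    count_mismatched_in_denominator: bool = True,
) -> dict[frozenset[str], float]:
    """Support for each non-trivial guide-tree bipartition: the fraction
    of replicate trees containing that bipartition.

    Replicates whose tip set differs from the guide's are skipped for
    every bipartition; with *count_mismatched_in_denominator* (default)
    they still count in the denominator.
    """
    if len(replicates) < 1:
        raise ValueError("need at least one replicate tree")
    guide_tips = set(_UTree(guide).leaves)
    guide_bips = _bipartition_set(guide)
    counts: Counter = Counter()
    denom = 0
    for rep in replicates:
        rep_tips = set(_UTree(rep).leaves)
        if rep_tips != guide_tips:
            if count_mismatched_in_denominator:
                denom += 1
            continue
        denom += 1
        rep_bips = _bipartition_set(rep)
        for b in guide_bips:
            if b in rep_bips:
                counts[b] += 1
    if denom == 0:
        raise ValueError("no usable replicates")
    return {b: counts[b] / denom for b in guide_bips}
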