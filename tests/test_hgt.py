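"""Monophyly testing, basal-import classification, family extension, support."""

import numpy as np
import pytest

from halopan.hgt import (
    HgtCall,
    LabeledGeneTree,
    RecruitmentThresholds,
    classify_tree,
    clade_support,
    extend_family,
    summarize_calls,
    is_monophyletic,
)
from halopan.io import SimilarityEdge
from halopan.synth import _random_clade, gen_gene_trees


def _edge(q, s, evalue=1e-30, ident=50.0):
    return SimilarityEdge(q, s, evalue, 100.0, ident, 0.9, 0.9, 200, 200)


def _dendropy_monophyly_oracle(newick: str, tag: str) -> bool:
    """Exhaustive edge scan via dendropy's own bipartition machinery."""
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


class TestMonophyly:
    def test_explicit_bipartition(self):
        t = LabeledGeneTree("((H1,H2),(E1,(E2,A1)));")
        assert is_monophyletic(t, "H") is True

    def test_no_separating_edge(self):
        t = LabeledGeneTree("((H1,E1),(H2,A1),E2);")
        assert is_monophyletic(t, "H") is False

    def test_single_tip_and_all_tips_trivially_monophyletic(self):
        assert is_monophyletic(LabeledGeneTree("(H1,(E1,E2));"), "H") is True
        assert is_monophyletic(LabeledGeneTree("(H1,(H2,H3));"), "H") is True

    def test_missing_tag_is_error(self):
        with pytest.raises(ValueError):
            is_monophyletic(LabeledGeneTree("(E1,(E2,E3));"), "H")

    def test_agrees_with_exhaustive_edge_scan(self):
        """500 random 8-12 tip trees vs an independent bipartition oracle."""
        rng = np.random.default_rng(2024)
        for _ in range(500):
            n = int(rng.integers(8, 13))
            tags = rng.choice(["H", "A", "E"], size=n)
            if "H" not in tags:
                tags[0] = "H"
            labels = [f"{t}{i}" for i, t in enumerate(tags)]
            nwk = _random_clade(rng, labels) + ";"
            t = LabeledGeneTree(nwk)
            assert is_monophyletic(t, "H") == _dendropy_monophyly_oracle(nwk, "H")

    def test_invariant_to_newick_rotation(self):
        a = LabeledGeneTree("(((H1,H2),(E1,E2)),(E3,(A1,A2)));")
        b = LabeledGeneTree("((E3,(A2,A1)),((E2,E1),(H2,H1)));")
        assert is_monophyletic(a, "H") == is_monophyletic(b, "H") is True
        assert classify_tree(a).verdict == classify_tree(b).verdict


class TestClassify:
    def test_basal_import_by_construction(self):
        call = classify_tree(LabeledGeneTree("(((H1,H2),(E1,E2)),(E3,(A1,A2)));"))
        assert call.verdict == "basal_import"
        assert call.neighbor_composition["A"] == 0

    def test_archaeal_sister_is_non_monophyly_verdict(self):
        call = classify_tree(LabeledGeneTree("(((H1,H2),(A1,A2)),(E1,E2));"))
        assert call.verdict == "non_monophyly" and call.h_monophyletic

    def test_scattered_h_is_non_monophyly(self):
        call = classify_tree(LabeledGeneTree("((H1,E1),((H2,A1),E2));"))
        assert call.verdict == "non_monophyly" and not call.h_monophyletic

    def test_all_h_untestable(self):
        assert classify_tree(LabeledGeneTree("(H1,(H2,H3));")).verdict == "untestable"

    def test_never_basal_without_monophyly(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            tags = rng.choice(["H", "A", "E"], size=10)
            tags[:2] = "H"
            labels = [f"{t}{i}" for i, t in enumerate(tags)]
            t = LabeledGeneTree(_random_clade(rng, labels) + ";")
            call = classify_tree(t)
            if call.verdict == "basal_import":
                assert is_monophyletic(t, "H")

    @pytest.mark.parametrize(
        "scenario,expected",
        [
            ("basal_transfer", "basal_import"),
            ("multiple_transfer", "non_monophyly"),
            ("no_transfer", "non_monophyly"),
            ("scattered", "non_monophyly"),
        ],
    )
    def test_noise_free_scenarios_perfect(self, scenario, expected):
        for nwk, truth in gen_gene_trees(scenario, n_trees=25, seed=13):
            assert truth == expected
            assert classify_tree(LabeledGeneTree(nwk)).verdict == expected

    def test_majority_rule_is_more_permissive(self):
        # mixed E/A neighborhood at depth 1: one A vetoes the strict
        # rule but bacteria still outnumber archaea
        t = LabeledGeneTree("(((H1,H2),(E1,A1)),(E2,(E3,A2)));")
        strict = classify_tree(t, sister_rule="all_bacterial")
        lenient = classify_tree(t, sister_rule="majority_bacterial")
        assert strict.neighbor_composition == lenient.neighbor_composition
        assert strict.verdict == "non_monophyly"
        assert lenient.verdict == "basal_import"


class TestExtendAndSummarize:
    def test_recruitment_thresholds(self):
        fam = {"f1", "f2"}
        pool = {"x", "y"}
        edges = [_edge("f1", "x", 1e-12, 45.0), _edge("f2", "y", 1e-12, 25.0)]
        extended, flag = extend_family(fam, pool, edges)
        assert extended == {"f1", "f2", "x"} and not flag

    def test_oversize_flag(self):
        fam = {f"f{i}" for i in range(3)}
        pool = {f"x{i}" for i in range(5)}
        edges = [_edge("f0", f"x{i}") for i in range(5)]
        _, flag = extend_family(fam, pool, edges, RecruitmentThresholds(max_family_size=6))
        assert flag

    def test_planted_recruitment_exact(self):
        rng = np.random.default_rng(3)
        fam = {f"f{i}" for i in range(4)}
        pool = {f"p{i}" for i in range(30)}
        should = set()
        edges = []
        for p in sorted(pool):
            ev = float(10.0 ** -rng.integers(5, 30))
            ident = float(rng.uniform(10, 90))
            edges.append(_edge("f0", p, ev, ident))
            if ev <= 1e-10 and ident >= 30.0:
                should.add(p)
        extended, _ = extend_family(fam, pool, edges)
        assert extended == fam | should

    def test_table_style_percentages(self):
        def calls(basal, nonmono):
            return (
                [HgtCall("f", "basal_import", True) for _ in range(basal)]
                + [HgtCall("f", "non_monophyly", False) for _ in range(nonmono)]
            )

        row = summarize_calls(calls(1089, 390), "original")
        assert (row["trees_assessed"], row["basal_pct"]) == (1479, 73.6)
        row = summarize_calls(calls(178, 365), "extended")
        assert row["basal_pct"] == 32.8 and row["non_monophyly_pct"] == 67.2
        row = summarize_calls(calls(0, 10))
        assert row["basal_pct"] == 0.0
        assert row["basal_pct"] + row["non_monophyly_pct"] == pytest.approx(100.0)

    def test_excluded_leave_denominator(self):
        calls = [
            HgtCall("a", "basal_import", True),
            HgtCall("b", "excluded_too_large", True),
            HgtCall("c", "untestable", True),
        ]
        row = summarize_calls(calls)
        assert row["trees_assessed"] == 1 and row["excluded"] == 2


class TestCladeSupport:
    def test_identical_replicates_full_support(self):
        guide = "((H1,H2),(E1,E2),(A1,A2));"
        sup = clade_support(guide, [guide] * 10)
        assert sup and all(v == 1.0 for v in sup.values())

    def test_half_support(self):
        guide = "((A,B),(C,D));"
        alt = "((A,C),(B,D));"
        sup = clade_support(guide, [guide] * 500 + [alt] * 500)
        assert set(sup.values()) == {0.5}

    def test_no_replicates_is_error(self):
        with pytest.raises(ValueError):
            clade_support("((A,B),(C,D));", [])

    def test_agrees_with_bruteforce_bipartition_intersection(self):
        rng = np.random.default_rng(99)
        labels = [f"E{i}" for i in range(8)]
        for _ in range(20):
            guide = _random_clade(rng, labels) + ";"
            reps = [_random_clade(rng, labels) + ";" for _ in range(15)]
            sup = clade_support(guide, reps)
            gb = _dendropy_bipartitions(guide)
            assert set(sup) == gb
            for b in gb:
                brute = sum(b in _dendropy_bipartitions(r) for r in reps) / len(reps)
                assert sup[b] == pytest.approx(brute)


def _dendropy_bipartitions(newick: str) -> set[frozenset[str]]:
    """Independent bipartition enumeration via dendropy bitmasks."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.is_rooted = False
    tree.update_bipartitions(suppress_unifurcations=True)
    taxa = list(tree.taxon_namespace)
    tips = {t.label for t in taxa}
    anchor = min(tips)
    out = set()
    for bip in tree.bipartition_encoding:
        side = frozenset(
            t.label for i, t in enumerate(taxa) if bip.split_bitmask & (1 << i)
        )
        if anchor in side:
            side = frozenset(tips - side)
        if 2 <= len(side) <= len(tips) - 2:
            out.add(side)
    return out
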