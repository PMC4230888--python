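"""Edge filtering, Markov clustering, inflation benchmarking, homolog screens."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from halopan.families import (
    EdgeFilterThresholds,
    FamilySet,
    MclConfig,
    SCREEN_THRESHOLDS,
    benchmark_inflation,
    filter_edges,
    mcl_cluster,
    screen_homologs,
)
from halopan.io import ProteinRecord, SimilarityEdge
from halopan.synth import gen_block_edges, gen_pangenome


def _edge(q, s, evalue=1e-30, qcov=0.9, scov=0.9, qlen=200, slen=210, ident=50.0):
    return SimilarityEdge(q, s, evalue, 100.0, ident, qcov, scov, qlen, slen)


edge_strategy = st.builds(
    _edge,
    q=st.sampled_from([f"p{i}" for i in range(8)]),
    s=st.sampled_from([f"p{i}" for i in range(8)]),
    evalue=st.floats(1e-60, 1e-5),
    qcov=st.floats(0.0, 1.0),
    scov=st.floats(0.0, 1.0),
    qlen=st.integers(50, 400),
    slen=st.integers(50, 400),
)


class TestFilterEdges:
    def test_all_thresholds_satisfied(self):
        assert len(filter_edges([_edge("a", "b", 1e-30, 0.85, 0.90, 200, 210)])) == 1

    def test_evalue_rule(self):
        assert filter_edges([_edge("a", "b", evalue=1e-9)]) == []

    def test_length_ratio_rule(self):
        assert filter_edges([_edge("a", "b", qlen=100, slen=140)]) == []

    def test_self_edges_removed_and_reciprocals_merged(self):
        edges = [
            _edge("a", "a"),
            _edge("a", "b", evalue=1e-20),
            _edge("b", "a", evalue=1e-40),
        ]
        kept = filter_edges(edges)
        assert len(kept) == 1 and kept[0].evalue == 1e-40

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(edges=st.lists(edge_strategy, max_size=30))
    def test_monotone_in_thresholds(self, edges):
        """Relaxing any threshold never removes a previously kept edge."""
        strict = EdgeFilterThresholds(0.85, 0.80, 1e-15)
        relaxed = [
            EdgeFilterThresholds(0.70, 0.80, 1e-15),
            EdgeFilterThresholds(0.85, 0.60, 1e-15),
            EdgeFilterThresholds(0.85, 0.80, 1e-5),
        ]
        key = lambda e: (tuple(sorted((e.query_id, e.subject_id))))
        kept_strict = {key(e) for e in filter_edges(edges, strict)}
        for t in relaxed:
            assert kept_strict <= {key(e) for e in filter_edges(edges, t)}

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(edges=st.lists(edge_strategy, max_size=30))
    def test_agrees_with_bruteforce_thresholds(self, edges):
        t = EdgeFilterThresholds()
        kept_pairs = {
            tuple(sorted((e.query_id, e.subject_id))) for e in filter_edges(edges, t)
        }
        brute = {
            tuple(sorted((e.query_id, e.subject_id)))
            for e in edges
            if e.query_id != e.subject_id
            and min(e.qcov, e.scov) >= t.min_bidir_coverage
            and min(e.qlen, e.slen) / max(e.qlen, e.slen) >= t.min_length_ratio
            and e.evalue <= t.max_evalue
        }
        assert kept_pairs == brute


class TestMcl:
    def test_two_disjoint_cliques(self):
        edges = []
        for grp, members in (("x", range(5)), ("y", range(5, 10))):
            m = [f"p{i}" for i in members]
            edges += [_edge(a, b) for i, a in enumerate(m) for b in m[i + 1:]]
        fs = mcl_cluster(edges)
        sizes = sorted(len(v) for v in fs.families.values())
        assert sizes == [5, 5]

    def test_isolated_protein_is_singleton(self):
        fs = mcl_cluster([_edge("a", "b")], proteins=["a", "b", "lonely"])
        fam = fs.family_of()
        assert len(fs.families[fam["lonely"]]) == 1

    def test_partition_invariant(self):
        edges, _ = gen_block_edges(n=30, seed=5)
        fs = mcl_cluster(edges)
        members = [p for m in fs.families.values() for p in m]
        assert len(members) == len(set(members))
        assert set(members) == {e.query_id for e in edges} | {e.subject_id for e in edges}

    def test_planted_three_block_graph(self):
        edges, labels = gen_block_edges(n=60, n_blocks=3, seed=11)
        fs = mcl_cluster(filter_edges(edges), proteins=sorted(labels))
        nodes = sorted(labels)
        ari = adjusted_rand_score([labels[n] for n in nodes], fs.labels_for(nodes))
        assert ari >= 0.95

    def test_deterministic(self):
        edges, _ = gen_block_edges(n=30, seed=3)
        a = mcl_cluster(edges).families
        b = mcl_cluster(list(reversed(edges))).families
        assert {frozenset(m) for m in a.values()} == {frozenset(m) for m in b.values()}


class TestBenchmarkInflation:
    def _planted(self):
        _, fs, _, edges, _ = gen_pangenome(
            n_genomes=6, n_core=6, n_accessory=10, seed=2
        )
        return edges, fs

    def test_identity_scores_one(self):
        edges, fs = self._planted()
        df = benchmark_inflation(filter_edges(edges), fs, [2.5])
        assert df.ari.iloc[0] == pytest.approx(1.0)

    def test_ari_bound_for_degenerate_curation(self):
        edges, fs = self._planted()
        singletons = FamilySet(
            families={f"s{i}": {p} for i, p in enumerate(sorted(fs.protein_universe))},
            species_of=fs.species_of,
        )
        df = benchmark_inflation(filter_edges(edges), singletons, [2.5])
        assert df.ari.iloc[0] <= 0.0 + 1e-12

    def test_empty_curated_is_error(self):
        edges, _ = self._planted()
        with pytest.raises(ValueError):
            benchmark_inflation(edges, FamilySet(families={}), [2.5])

    def test_argmax_reported(self):
        edges, fs = self._planted()
        df = benchmark_inflation(filter_edges(edges), fs, [1.4, 2.5, 8.0])
        assert df.loc[df.best, "ari"].iloc[0] == df.ari.max()


class TestScreenHomologs:
    def _setup(self):
        queries = [ProteinRecord(f"q{i}", "query_db", "M" * 100) for i in range(4)]
        proteomes = {
            sp: [ProteinRecord(f"{sp}.p{j}", sp, "M" * 100) for j in range(3)]
            for sp in ("spA", "spB")
        }
        return queries, proteomes

    def test_strict_evalue_boundary(self):
        queries, proteomes = self._setup()
        edges = [
            _edge("q0", "spA.p0", evalue=1e-21, qlen=100, slen=100),
            _edge("q1", "spA.p1", evalue=1e-19, qlen=100, slen=100),
        ]
        mat, dropped = screen_homologs(queries, proteomes, edges)
        assert list(mat.index) == ["q0"]
        assert mat.loc["q0", "spA"] == 1 and mat.loc["q0", "spB"] == 0
        assert dropped == 3

    def test_dropped_queries_counted(self):
        """74 queries with 20 matchless ones leave a 54-row matrix."""
        queries = [ProteinRecord(f"q{i}", "db", "M" * 80) for i in range(74)]
        proteomes = {"sp": [ProteinRecord("sp.p0", "sp", "M" * 80)]}
        edges = [
            _edge(f"q{i}", "sp.p0", evalue=1e-30, qlen=80, slen=80)
            for i in range(54)
        ]
        mat, dropped = screen_homologs(queries, proteomes, edges)
        assert mat.shape[0] == 54 and dropped == 20

    def test_unknown_query_is_error(self):
        queries, proteomes = self._setup()
        with pytest.raises(ValueError, match="missing"):
            screen_homologs(
                queries, proteomes, [_edge("ghost", "spA.p0", qlen=100, slen=100)]
            )

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_equals_bruteforce_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        queries = [ProteinRecord(f"q{i}", "db", "M" * 100) for i in range(5)]
        proteomes = {
            sp: [ProteinRecord(f"{sp}.p{j}", sp, "M" * 100) for j in range(4)]
            for sp in ("s1", "s2", "s3")
        }
        pool = [p.protein_id for prots in proteomes.values() for p in prots]
        edges = [
            _edge(
                f"q{rng.integers(5)}", pool[rng.integers(len(pool))],
                evalue=float(10.0 ** -rng.integers(5, 40)),
                qcov=float(rng.uniform(0.5, 1)), scov=float(rng.uniform(0.5, 1)),
                qlen=100, slen=int(rng.integers(60, 140)),
            )
            for _ in range(40)
        ]
        mat, _ = screen_homologs(queries, proteomes, edges)
        t = SCREEN_THRESHOLDS
        for q in queries:
            for sp, prots in proteomes.items():
                expect = any(
                    e.query_id == q.protein_id
                    and any(e.subject_id == p.protein_id for p in prots)
                    and min(e.qcov, e.scov) >= t.min_bidir_coverage
                    and min(e.qlen, e.slen) / max(e.qlen, e.slen) >= t.min_length_ratio
                    and e.evalue <= t.max_evalue
                    for e in edges
                )
                got = (
                    q.protein_id in mat.index and mat.loc[q.protein_id, sp] == 1
                )
                assert got == expect
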