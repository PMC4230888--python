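"""Presence/absence matrices, rarefaction, core/markers, rescue, genus report."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest

from halopan.pangenome import (
    MarkerCriteria,
    PresenceAbsenceMatrix,
    build_matrix,
    core_families,
    discover_markers,
    expected_unique_families,
    genus_report,
    genus_specific_families,
    rarefy,
    rescue_missed_genes,
)
from halopan.synth import gen_missed_gene_case, gen_pangenome


@pytest.fixture(scope="module")
def planted():
    proteomes, fs, mat, edges, truth = gen_pangenome(
        n_genomes=12, n_genera=4, n_core=25, n_accessory=40,
        n_genus_private=8, seed=42,
    )
    return proteomes, fs, mat, truth


def _toy_matrix(seed=0, n_fam=12, n_sp=6):
    rng = np.random.default_rng(seed)
    counts = pd.DataFrame(
        rng.integers(0, 3, size=(n_fam, n_sp)),
        index=[f"f{i}" for i in range(n_fam)],
        columns=[f"s{j}" for j in range(n_sp)],
    )
    counts = counts.loc[counts.sum(axis=1) > 0]
    genus = {f"s{j}": ("gA" if j < 3 else "gB") for j in range(n_sp)}
    return PresenceAbsenceMatrix(counts=counts, genus_map=genus)


class TestBuildMatrix:
    def test_copy_numbers_and_binary(self, planted):
        _, fs, mat, _ = planted
        rebuilt = build_matrix(fs, mat.species, mat.genus_map)
        assert rebuilt.counts.loc[mat.families, mat.species].equals(
            mat.counts.loc[mat.families, mat.species]
        )

    def test_unknown_species_is_error(self, planted):
        _, fs, mat, _ = planted
        with pytest.raises(ValueError):
            build_matrix(fs, mat.species[:2])


class TestRarefaction:
    def test_endpoints(self):
        mat = _toy_matrix()
        curve = rarefy(mat, replicates=50, seed=1)
        assert curve.mean_unique_families[0] == 0
        assert curve.mean_unique_families[-1] == mat.binary().any(axis=1).sum()
        assert (np.diff(curve.expected) >= -1e-9).all()

    def test_closed_form_equals_exhaustive_enumeration(self):
        """E[U(n)] on a 6-genome toy matrix vs averaging over all C(6,n) subsets."""
        mat = _toy_matrix(seed=3)
        binary = mat.binary().to_numpy(bool)
        n_sp = binary.shape[1]
        expected = expected_unique_families(mat)
        for n in range(n_sp + 1):
            subsets = list(itertools.combinations(range(n_sp), n))
            brute = np.mean(
                [binary[:, list(s)].any(axis=1).sum() if s else 0 for s in subsets]
            )
            assert expected[n] == pytest.approx(brute, abs=1e-9)
            assert len(subsets) == comb(n_sp, n)

    def test_monte_carlo_within_three_se(self):
        mat = _toy_matrix(seed=3)
        curve = rarefy(mat, replicates=10_000, seed=9)
        for k, n in enumerate(curve.sample_sizes):
            if n in (0, len(mat.species)):
                assert curve.mean_unique_families[k] == curve.expected[k]
                continue
            se = curve.sd[k] / np.sqrt(curve.replicates)
            assert abs(curve.mean_unique_families[k] - curve.expected[k]) <= 3 * max(se, 1e-12)

    def test_singleton_exclusion(self):
        counts = pd.DataFrame(
            [[1, 1], [1, 0], [2, 0]],
            index=["both", "single_member", "two_copies_one_genome"],
            columns=["s0", "s1"],
        )
        mat = PresenceAbsenceMatrix(counts=counts, genus_map={})
        full = rarefy(mat, replicates=10, seed=0)
        nosing = rarefy(mat, replicates=10, seed=0, family_definition="mcl_no_singletons")
        # singletons are single-MEMBER families, not single-genome ones
        assert full.mean_unique_families[-1] == 3
        assert nosing.mean_unique_families[-1] == 2

    def test_oversized_sample_is_error(self):
        with pytest.raises(ValueError):
            rarefy(_toy_matrix(), replicates=5, seed=0, sample_sizes=[99])


class TestCoreAndMarkers:
    def test_core_on_planted_truth(self, planted):
        _, _, mat, truth = planted
        assert core_families(mat) == set(truth.truth["core_families"])
        assert len(core_families(mat)) == 25

    def test_core_equals_column_intersection(self, planted):
        _, _, mat, _ = planted
        binary = mat.binary()
        per_col = [set(binary.index[binary[c] > 0]) for c in binary.columns]
        assert core_families(mat) == set.intersection(*per_col)

    def test_one_absent_genome_excludes(self):
        mat = _toy_matrix(seed=5)
        binary = mat.binary()
        near = binary.index[binary.sum(axis=1) == len(mat.species) - 1]
        assert not (set(near) & core_families(mat))

    def test_genus_private_recovered(self, planted):
        _, _, mat, truth = planted
        for genus, fams in truth.truth["genus_private"].items():
            got = genus_specific_families(mat, genus)
            assert set(fams) <= got
            # nothing planted as core/accessory-with-outside-members sneaks in
            assert all(f.startswith(("priv", "acc")) for f in got)

    def test_unknown_genus_is_error(self, planted):
        _, _, mat, _ = planted
        with pytest.raises(KeyError):
            genus_specific_families(mat, "Atlantis")

    def test_markers_subset_of_genus_specific(self, planted):
        _, _, mat, _ = planted
        for genus in sorted(set(mat.genus_map.values())):
            markers = discover_markers(mat, MarkerCriteria(genus=genus))
            assert markers <= genus_specific_families(mat, genus)

    def test_single_copy_violation_rejected(self):
        counts = pd.DataFrame(
            [[1, 1, 0], [1, 2, 0], [1, 1, 1]],
            index=["marker", "paralogous", "leaky"],
            columns=["a1", "a2", "b1"],
        )
        mat = PresenceAbsenceMatrix(
            counts=counts, genus_map={"a1": "A", "a2": "A", "b1": "B"}
        )
        assert discover_markers(mat, MarkerCriteria(genus="A")) == {"marker"}


class TestRescue:
    def test_planted_deletion_recovered_exactly(self):
        genomes, feats, fams, seqs, ffam, truth = gen_missed_gene_case(
            n_species=5, deleted_species=(2,), seed=8
        )
        cands = rescue_missed_genes(
            "famA", "famB", "famT", fams, genomes, feats, seqs, ffam
        )
        assert len(cands) == 1
        c = cands[0]
        coords = truth.truth["coordinates"]["sp02"]
        assert (c["species"], c["start"], c["end"]) == (
            "sp02", coords["target_start"], coords["target_end"]
        )
        assert c["identity"] == pytest.approx(100.0)

    def test_no_deletion_reports_nothing(self):
        genomes, feats, fams, seqs, ffam, _ = gen_missed_gene_case(
            n_species=4, deleted_species=(), seed=8
        )
        assert rescue_missed_genes(
            "famA", "famB", "famT", fams, genomes, feats, seqs, ffam
        ) == []

    def test_degraded_identity_rejected(self):
        genomes, feats, fams, seqs, ffam, truth = gen_missed_gene_case(
            n_species=5, deleted_species=(2,), mutation_rate=0.8, seed=8
        )
        attainable = truth.truth["best_member_identity"]["sp02"]
        cands = rescue_missed_genes(
            "famA", "famB", "famT", fams, genomes, feats, seqs, ffam,
            min_identity=30.0,
        )
        if attainable < 30.0:
            assert not any(c["species"] == "sp02" for c in cands)
        else:
            assert any(c["species"] == "sp02" for c in cands)


class TestGenusReport:
    def test_single_member_genus(self):
        mat = _toy_matrix()
        stats = pd.DataFrame({"gc": [60.0] * 6}, index=mat.species)
        mat.genus_map["s5"] = "solo"
        rep = genus_report(mat, stats)
        row = rep[(rep.genus == "solo")].iloc[0]
        assert row.q25 == row["median"] == row.q75 == 60.0

    def test_median_of_five(self):
        counts = pd.DataFrame(
            np.ones((2, 5), dtype=int),
            index=["f0", "f1"], columns=[f"s{i}" for i in range(5)],
        )
        mat = PresenceAbsenceMatrix(counts, {f"s{i}": "G" for i in range(5)})
        stats = pd.DataFrame({"x": [1.0, 2, 3, 4, 5]}, index=mat.species)
        rep = genus_report(mat, stats)
        assert rep.iloc[0]["median"] == 3

    def test_quartiles_match_percentile_oracle(self):
        rng = np.random.default_rng(12)
        vals = rng.normal(size=20)
        counts = pd.DataFrame(
            np.ones((2, 20), dtype=int),
            index=["f0", "f1"], columns=[f"s{i}" for i in range(20)],
        )
        mat = PresenceAbsenceMatrix(counts, {f"s{i}": "G" for i in range(20)})
        rep = genus_report(mat, pd.DataFrame({"x": vals}, index=mat.species))
        q = np.percentile(vals, [25, 50, 75])
        row = rep.iloc[0]
        assert (row.q25, row["median"], row.q75) == pytest.approx(tuple(q))
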