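"""AMOVA, pairwise FST and Mantel tests."""

import numpy as np
import pandas as pd
import pytest

from msatpop import (
    DistanceMatrix,
    MutationModel,
    amova,
    cluster_membership_matrix,
    mantel,
    pairwise_fst,
    partial_mantel,
)
from msatpop.coalescent import DemographicScenario, Merge, SizeChange, simulate_dataset
from msatpop.synthetic import make_null_fixture

from conftest import make_matrix


def random_distance(rng, n=9):
    m = rng.random((n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0)
    return DistanceMatrix([f"s{i}" for i in range(n)], m)


class TestDistanceMatrix:
    def test_rejects_asymmetry(self):
        m = np.array([[0, 1.0], [2.0, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b"], m)

    def test_rejects_nonzero_diagonal(self):
        with pytest.raises(ValueError, match="diagonal"):
            DistanceMatrix(["a", "b"], np.array([[1.0, 0], [0, 0]]))

    def test_align_reorders(self):
        d = DistanceMatrix(["a", "b", "c"],
                           np.array([[0, 1.0, 2], [1, 0, 3], [2, 3, 0.0]]))
        d2 = d.align(["c", "a", "b"])
        assert d2.values[0, 1] == 2.0


class TestPairwiseFst:
    def test_fixed_differences_give_one(self, two_pop_fixed):
        mat, raw = pairwise_fst(two_pop_fixed)
        assert mat.values[0, 1] == pytest.approx(1.0)
        assert raw["fst_raw"].iloc[0] == pytest.approx(1.0)

    def test_panmictic_split_near_zero(self):
        vals = []
        for seed in range(10):
            g = make_null_fixture(2, 15, 8, theta=2.0, seed=seed)
            _, raw = pairwise_fst(g)
            vals.append(raw["fst_raw"].iloc[0])
        assert abs(np.mean(vals)) < 0.03

    def test_increases_with_divergence_time(self):
        means = []
        for t in (100.0, 1000.0, 10000.0):
            scen = DemographicScenario(
                ["a", "b"], {"a": 1000.0, "b": 1000.0}, {"a": 15, "b": 15},
                [Merge(t, "a", "b")],
            )
            models = [MutationModel(5e-4, motif_length=2)] * 8
            vals = []
            for seed in range(15):
                g = simulate_dataset(scen, models, seed=seed)
                _, raw = pairwise_fst(g)
                vals.append(raw["fst_raw"].iloc[0])
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_requires_two_populations(self):
        g = make_matrix({"only": [[(100, 102)], [(102, 102)]]})
        with pytest.raises(ValueError, match=">= 2 populations"):
            pairwise_fst(g)

    def test_rst_variant_runs(self, two_pop_fixed):
        mat, _ = pairwise_fst(two_pop_fixed, distance="rst")
        assert 0 <= mat.values[0, 1] <= 1


class TestAmova:
    def test_identical_individuals_zero_variance(self):
        g = make_matrix(
            {p: [[(100, 100)]] * 3 for p in ("a", "b", "c", "d")}
        )
        with pytest.warns(UserWarning, match="no molecular variance"):
            res = amova(g, {"a": "north", "b": "north", "c": "south", "d": "south"},
                        permutations=0)
        assert res.phi_rt == 0 and res.phi_pt == 0
        assert res.percents["within_pop"] == 100

    def test_percentages_sum_to_100(self, study_fixture):
        g, sites = study_fixture
        res = amova(g, sites, permutations=0)
        assert sum(res.percents.values()) == pytest.approx(100, abs=1e-9)
        assert -1 <= res.phi_rt <= 1 and -1 <= res.phi_pr <= 1

    def test_deep_split_regions_dominate(self):
        # two regions of two demes each; regions separated for 4N generations
        ne = 500.0
        scen = DemographicScenario(
            ["a1", "a2", "b1", "b2"],
            {p: ne for p in ("a1", "a2", "b1", "b2")},
            {p: 8 for p in ("a1", "a2", "b1", "b2")},
            [
                Merge(50.0, "a2", "a1"),
                Merge(50.0, "b2", "b1"),
                Merge(4 * ne, "b1", "a1"),
            ],
        )
        models = [MutationModel(2.5e-4, motif_length=2)] * 8
        pcts = []
        for seed in range(10):
            g = simulate_dataset(scen, models, seed=seed)
            res = amova(g, {"a1": "north", "a2": "north",
                            "b1": "south", "b2": "south"}, permutations=0)
            pcts.append(res.percents["among_region"])
        assert np.mean(pcts) > 30

    def test_collapses_to_pairwise_fst_for_two_sites(self, study_fixture):
        # with one site per region the three-level model loses its middle
        # stratum and Phi-RT equals the two-level pairwise estimator
        g, _ = study_fixture
        sub = g.subset(["FrayJorge", "Cahuil"])
        with pytest.warns(UserWarning, match="single population"):
            res = amova(sub, {"FrayJorge": "north", "Cahuil": "south"},
                        permutations=0)
        mat, raw = pairwise_fst(sub)
        assert res.phi_rt == pytest.approx(raw["fst_raw"].iloc[0], abs=1e-9)

    def test_permutation_pvalues_detect_structure(self, study_fixture):
        g, sites = study_fixture
        res = amova(g, sites, permutations=99, seed=5)
        assert res.p_values["among_region"] <= 0.05

    def test_unassigned_population_rejected(self, study_fixture):
        g, _ = study_fixture
        with pytest.raises(ValueError, match="without region"):
            amova(g, {"FrayJorge": "north"}, permutations=0)


class TestMantel:
    def test_self_correlation_is_one(self):
        a = random_distance(np.random.default_rng(1))
        r, p = mantel(a, a, permutations=99, seed=0)
        assert r == pytest.approx(1.0)
        assert p <= 0.05

    def test_affine_invariance(self):
        a = random_distance(np.random.default_rng(2))
        b = DistanceMatrix(a.labels, 2 * a.values + 3 * (1 - np.eye(9)))
        r, _ = mantel(a, b, permutations=0)
        assert r == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        a = random_distance(np.random.default_rng(3))
        b = DistanceMatrix(a.labels, np.ones((9, 9)) - np.eye(9))
        with pytest.raises(ValueError, match="zero-variance"):
            mantel(a, b, permutations=10)

    def test_needs_four_labels(self):
        a = DistanceMatrix(["x", "y", "z"], np.zeros((3, 3)))
        with pytest.raises(ValueError, match=">= 4"):
            mantel(a, a)

    def test_matches_independent_implementation(self):
        # cross-check r and p against scikit-bio's Mantel test
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(7)
        a, b = random_distance(rng), random_distance(rng)
        r, p = mantel(a, b, permutations=999, seed=1)
        r2, p2, _ = skbio_stats.mantel(
            skbio_stats.DistanceMatrix(a.values, a.labels),
            skbio_stats.DistanceMatrix(b.values, b.labels),
            method="pearson", permutations=999, alternative="greater",
        )
        assert r == pytest.approx(r2, abs=1e-12)
        assert p == pytest.approx(p2, abs=0.08)


class TestPartialMantel:
    def test_controlling_b_by_itself_kills_correlation(self):
        rng = np.random.default_rng(4)
        a, b = random_distance(rng), random_distance(rng)
        with pytest.warns(UserWarning, match="explains b entirely"):
            r, _ = partial_mantel(a, b, b, permutations=0)
        assert abs(r) < 1e-9

    def test_uncorrelated_control_preserves_r(self):
        rng = np.random.default_rng(5)
        base = random_distance(rng)
        noise = random_distance(rng)
        a = base
        b = DistanceMatrix(base.labels, 0.9 * base.values + 0.1 * noise.values)
        c = random_distance(rng)
        r_simple, _ = mantel(a, b, permutations=0)
        r_part, _ = partial_mantel(a, b, c, permutations=0)
        assert r_part == pytest.approx(r_simple, abs=0.15)

    def test_affinely_collinear_control_degenerates_to_zero(self):
        rng = np.random.default_rng(6)
        a, b = random_distance(rng), random_distance(rng)
        c = DistanceMatrix(b.labels, 2 * b.values + 5 * (1 - np.eye(9)))
        with pytest.warns(UserWarning, match="explains b entirely"):
            r, _ = partial_mantel(a, b, c, permutations=0)
        assert r == 0.0

    def test_cluster_structure_beyond_distance(self, study_fixture):
        # the fixture's regional clusters explain genetic distance beyond
        # geography, echoing the study's partial Mantel result
        g, sites = study_fixture
        fst, _ = pairwise_fst(g)
        geo = DistanceMatrix.from_frame(sites.great_circle_km())
        clusters = cluster_membership_matrix(
            {s: sites.region_of()[s] for s in fst.labels}
        )
        r, p = partial_mantel(fst, clusters, geo, permutations=199, seed=2)
        assert r > 0.3
        assert p < 0.05


def test_cluster_membership_matrix_binary():
    m = cluster_membership_matrix({"a": "x", "b": "x", "c": "y"})
    assert m.values[0, 1] == 0 and m.values[0, 2] == 1
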