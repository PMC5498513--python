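"""Coalescent simulator: scenario validation, closed forms, mutation model."""

import numpy as np
import pytest

from msatpop import MutationModel, simulate_dataset, simulate_genealogy
from msatpop.coalescent import (
    Admixture,
    Bottleneck,
    DemographicScenario,
    Genealogy,
    Merge,
    ScenarioError,
    mutate_tree,
    scenario_admixture,
    scenario_divergence,
    scenario_stepping_stone,
)

SIZES = {"north": 5, "center": 5, "south": 5}


class TestScenarioValidation:
    def test_divergence_requires_time_ordering(self):
        with pytest.raises(ScenarioError, match="t_split_cs < t_split_n"):
            scenario_divergence(1000, 1000, 500, 500, 500, 500, SIZES)

    def test_divergence_structure(self):
        s = scenario_divergence(1000, 5000, 500, 500, 500, 800, SIZES)
        assert sum(isinstance(e, Merge) for e in s.events) == 2

    def test_stepping_stone_structure(self):
        s = scenario_stepping_stone(1000, 5000, 500, 500, 500, 800,
                                    nb=50, db=100, sample_sizes=SIZES)
        assert sum(isinstance(e, Merge) for e in s.events) == 2
        assert sum(isinstance(e, Bottleneck) for e in s.events) == 1

    def test_stepping_stone_zero_bottleneck_is_pure(self):
        s = scenario_stepping_stone(1000, 5000, 500, 500, 500, 800,
                                    nb=50, db=0, sample_sizes=SIZES)
        assert not any(isinstance(e, Bottleneck) for e in s.events)

    def test_bottleneck_longer_than_branch_rejected(self):
        with pytest.raises(ScenarioError, match="duration"):
            scenario_stepping_stone(100, 5000, 500, 500, 500, 800,
                                    nb=50, db=100, sample_sizes=SIZES)

    @pytest.mark.parametrize("r", [0.0, 1.0, -0.2, 1.5])
    def test_admixture_rate_bounds(self, r):
        with pytest.raises(ScenarioError, match="r must be"):
            scenario_admixture(100, 5000, r, 500, 500, 500, 800, SIZES)

    def test_admixture_time_ordering(self):
        with pytest.raises(ScenarioError, match="t_adm < t_div"):
            scenario_admixture(5000, 100, 0.5, 500, 500, 500, 800, SIZES)

    def test_stranded_lineages_detected(self):
        with pytest.raises(ScenarioError, match="stranded"):
            DemographicScenario(
                ["a", "b"], {"a": 100.0, "b": 100.0}, {"a": 2, "b": 2}, []
            )

    def test_event_order_enforced(self):
        with pytest.raises(ScenarioError, match="nondecreasing"):
            DemographicScenario(
                ["a", "b"], {"a": 100.0, "b": 100.0}, {"a": 2, "b": 2},
                [Merge(500.0, "a", "b"), Admixture(100.0, "a", "b", "b", 0.5)],
            )


class TestGenealogy:
    def test_pair_tmrca_expectation(self):
        # E[TMRCA] for two gene copies in one population is 2Ne
        ne = 750.0
        scen = DemographicScenario(["a"], {"a": ne}, {"a": 1}, [])
        t = [simulate_genealogy(scen, 1, seed=i)[0].tmrca for i in range(4000)]
        assert np.mean(t) == pytest.approx(2 * ne, rel=0.07)

    def test_single_sample_per_population_waits_for_merges(self):
        scen = DemographicScenario(
            ["a", "b"], {"a": 100.0, "b": 100.0}, {"a": 1, "b": 1},
            [Merge(5000.0, "a", "b")],
        )
        trees = simulate_genealogy(scen, 20, seed=1)
        assert all(t.tmrca > 5000.0 for t in trees)

    def test_severe_bottleneck_coalesces_founders(self):
        # Nb -> 0 limit: every northern lineage coalesces inside the squeeze
        scen = scenario_stepping_stone(
            1000, 5000, 500, 500, 500, 800, nb=1.0, db=200,
            sample_sizes={"north": 5, "center": 0, "south": 0},
        )
        for seed in range(30):
            tree = simulate_genealogy(scen, 1, seed=seed)[0]
            assert tree.tmrca < 1000.0

    def test_leaf_populations_in_scenario_order(self):
        scen = scenario_admixture(100, 5000, 0.5, 500, 500, 500, 800, SIZES)
        tree = simulate_genealogy(scen, 1, seed=0)[0]
        assert tree.n_samples == 30
        assert list(np.bincount(tree.leaf_population)) == [10, 10, 10]

    def test_admixture_symmetry_of_fst(self):
        # r = 0.5 with equal sizes: center equidistant from north and south
        from msatpop import pairwise_fst

        scen = scenario_admixture(500, 20000, 0.5, 1000, 1000, 1000, 1000,
                                  {"north": 12, "center": 12, "south": 12})
        models = [MutationModel(2e-4, motif_length=2)] * 8
        d_nc, d_sc = [], []
        for seed in range(25):
            g = simulate_dataset(scen, models, seed=seed)
            mat, _ = pairwise_fst(g)
            f = mat.to_frame()
            d_nc.append(f.loc["north", "center"])
            d_sc.append(f.loc["south", "center"])
        assert np.mean(d_nc) == pytest.approx(np.mean(d_sc), abs=0.05)

    def test_divergence_ordering_of_fst(self):
        # deep north split, shallow center/south split
        from msatpop import pairwise_fst

        scen = scenario_divergence(500, 20000, 1000, 1000, 1000, 1000,
                                   {"north": 12, "center": 12, "south": 12})
        models = [MutationModel(2e-4, motif_length=2)] * 8
        deep, shallow = [], []
        for seed in range(25):
            g = simulate_dataset(scen, models, seed=seed)
            f = pairwise_fst(g)[0].to_frame()
            deep.append(f.loc["north", "center"])
            shallow.append(f.loc["center", "south"])
        assert np.mean(deep) > np.mean(shallow) + 0.1


def two_leaf_tree(t):
    return Genealogy(
        parent=np.array([2, 2, -1]),
        time=np.array([0.0, 0.0, t]),
        n_samples=2,
        leaf_population=np.array([0, 0]),
    )


class TestMutation:
    def test_smm_pairwise_variance(self):
        # two lineages each t generations from their ancestor: the size
        # difference (repeat units) has variance 2*mu*t under SMM
        mu, t = 5e-4, 20000.0
        rng = np.random.default_rng(0)
        tree = two_leaf_tree(t)
        model = MutationModel(mu=mu, gsm_p=0.0)
        diffs = []
        for _ in range(10000):
            leaves = mutate_tree(tree, model, ancestral_repeats=200, rng=rng)
            diffs.append(leaves[0] - leaves[1])
        assert np.var(diffs) == pytest.approx(2 * mu * t, rel=0.05)

    def test_gsm_inflates_variance(self):
        rng = np.random.default_rng(1)
        tree = two_leaf_tree(20000.0)
        out = {}
        for label, p in (("smm", 0.0), ("gsm", 0.5)):
            rng = np.random.default_rng(1)
            diffs = [
                np.diff(mutate_tree(tree, MutationModel(5e-4, gsm_p=p),
                                    200, rng))[0]
                for _ in range(4000)
            ]
            out[label] = np.var(diffs)
        assert out["gsm"] > 1.5 * out["smm"]

    def test_zero_rate_limit_monomorphic(self):
        scen = DemographicScenario(["a"], {"a": 500.0}, {"a": 10}, [])
        g = simulate_dataset(scen, [MutationModel(1e-12, motif_length=2)], seed=3)
        assert np.unique(g.calls).size == 1

    def test_alleles_respect_motif(self):
        scen = DemographicScenario(["a"], {"a": 500.0}, {"a": 10}, [])
        g = simulate_dataset(
            scen, [MutationModel(1e-3, motif_length=3)], seed=4, validate=True
        )
        assert (g.calls % 3 == 0).all()

    def test_smm_is_gsm_zero(self):
        assert MutationModel(1e-4, gsm_p=0.0).model == "SMM"
        assert MutationModel(1e-4, gsm_p=0.2).model == "GSM"
        with pytest.raises(ValueError):
            MutationModel(0.0)
        with pytest.raises(ValueError):
            MutationModel(1e-4, gsm_p=1.0)


class TestDeterminismAndTheta:
    def test_identical_seed_identical_dataset(self):
        scen = scenario_admixture(100, 5000, 0.5, 500, 500, 500, 800, SIZES)
        models = [MutationModel(1e-4, gsm_p=0.2, motif_length=2)] * 4
        a = simulate_dataset(scen, models, seed=99)
        b = simulate_dataset(scen, models, seed=99)
        assert a == b
        assert (a.calls == b.calls).all()

    def test_heterozygosity_monotone_in_theta(self):
        ne = 1000.0
        hs = []
        for theta in (0.4, 4.0, 40.0):
            mu = theta / (4 * ne)
            scen = DemographicScenario(["a"], {"a": ne}, {"a": 10}, [])
            vals = []
            for seed in range(200):
                g = simulate_dataset(scen, [MutationModel(mu)], seed=seed)
                copies = g.calls[:, 0, :].ravel()
                _, counts = np.unique(copies, return_counts=True)
                p = counts / counts.sum()
                vals.append(1 - np.sum(p**2))
            hs.append(np.mean(vals))
        assert hs[0] < hs[1] < hs[2]
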