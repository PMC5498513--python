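"""Summary statistics, reference tables and ABC estimation."""

import numpy as np
import pandas as pd
import pytest

from msatpop import (
    AbcModel,
    GenotypeMatrix,
    Locus,
    build_reference_table,
    collapse_to_regions,
    default_scenarios,
    generations_to_kya,
    summarize,
)
from msatpop.abc import Parameter, PriorSpec, ReferenceTable, SampleDesign, stat_names

from conftest import make_matrix

DESIGN = SampleDesign({"north": 4, "center": 4, "south": 4})


@pytest.fixture(scope="module")
def small_reference():
    return build_reference_table(default_scenarios(), DESIGN,
                                 n_per_scenario=120, seed=5)


class TestPriors:
    def test_draws_respect_constraints(self):
        spec = next(s for s in default_scenarios() if s.name == "admixture")
        rng = np.random.default_rng(0)
        for _ in range(2000):
            d = spec.prior.draw(rng)
            assert d["t_adm"] < d["t_div"]
            assert 0.05 <= d["r"] <= 0.95

    def test_log_scale_draws_within_bounds(self):
        p = Parameter("ne", 100, 50000, "log10")
        x = p.draw(np.random.default_rng(1), size=5000)
        assert x.min() >= 100 and x.max() <= 50000
        # log-uniform: median near geometric mean, far below midpoint
        assert np.median(x) == pytest.approx(np.sqrt(100 * 50000), rel=0.2)

    def test_empty_constraint_region_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            PriorSpec(
                [Parameter("a", 10, 20), Parameter("b", 1, 5)],
                constraints=[("a", "b")],
            )

    def test_invalid_bounds(self):
        with pytest.raises(ValueError, match="low"):
            Parameter("x", 5, 5)


class TestSummarize:
    def test_identical_populations_no_differentiation(self):
        ind = [[(100, 102), (120, 120)], [(102, 102), (120, 126)]]
        g = make_matrix({"a": ind, "b": [r[:] for r in ind]})
        s = summarize(g)
        assert s["di|a-b|fst"] == 0.0
        assert s["di|a-b|dmu2"] == 0.0

    def test_delta_mu_squared_by_hand(self):
        # fixed 100/100 vs 104/104 bp at a dinucleotide locus:
        # (104 - 100) / 2 = 2 repeat units, squared = 4
        g = make_matrix({"a": [[(100, 100)], [(100, 100)]],
                         "b": [[(104, 104)], [(104, 104)]]})
        s = summarize(g)
        assert s["di|a-b|dmu2"] == pytest.approx(4.0)
        assert s["di|a-b|fst"] == pytest.approx(1.0)

    def test_declared_ordering_contract(self):
        names = stat_names(["di", "tri"], ["n", "c", "s"])
        assert names[:3] == ["di|n|na", "di|n|he", "di|n|var"]
        assert names[-2:] == ["tri|c-s|fst", "tri|c-s|dmu2"]
        # one-sample block first, then pairwise block
        assert len(names) == 2 * 3 * 3 + 2 * 3 * 2

    def test_population_order_permutes_vector(self, study_fixture):
        g, sites = study_fixture
        gr = collapse_to_regions(g, sites)
        s = summarize(gr)
        idx = [gr.individuals.index(i) for i in reversed(gr.individuals)]
        rev = GenotypeMatrix(
            [gr.individuals[i] for i in idx], [gr.populations[i] for i in idx],
            gr.loci, gr.calls[idx], validate=False,
        )
        s2 = summarize(rev)
        # reversed row order reverses population order: south, center, north
        assert list(rev.population_names) == ["south", "center", "north"]
        assert s["di|north|he"] == pytest.approx(s2["di|north|he"])
        assert s["di|north-center|fst"] == pytest.approx(
            s2["di|center-north|fst"]
        )
        assert s["di|center-south|dmu2"] == pytest.approx(
            s2["di|south-center|dmu2"]
        )

    def test_monomorphic_group_flagged_as_zero(self):
        g = make_matrix({"a": [[(100, 100)]], "b": [[(100, 100)]]})
        s = summarize(g)
        assert not s.isna().any()
        assert s["di|a-b|fst"] == 0.0


class TestReferenceTable:
    def test_single_row_per_scenario(self):
        ref = build_reference_table(default_scenarios(), DESIGN, 1, seed=0)
        assert len(ref.table) == 3
        assert set(ref.table["scenario"]) == {
            "divergence", "stepping_stone", "admixture"}

    def test_reproducible_and_chunkable(self):
        full = build_reference_table(default_scenarios(), DESIGN, 6, seed=9)
        again = build_reference_table(default_scenarios(), DESIGN, 6, seed=9)
        pd.testing.assert_frame_equal(full.table, again.table)
        head = build_reference_table(default_scenarios(), DESIGN, 3, seed=9)
        tail = build_reference_table(default_scenarios(), DESIGN, 3, seed=9,
                                     row_offset=3)
        merged = (
            pd.concat([head.table, tail.table])
            .sort_values(["scenario"], kind="stable")
            .reset_index(drop=True)
        )
        expect = (
            full.table.sort_values(["scenario"], kind="stable")
            .reset_index(drop=True)
        )
        pd.testing.assert_frame_equal(
            merged[sorted(merged.columns)], expect[sorted(expect.columns)]
        )

    def test_save_load_round_trip(self, tmp_path, small_reference):
        p = tmp_path / "ref.tsv"
        small_reference.save(p)
        back = ReferenceTable.load(p)
        assert back.stat_columns == small_reference.stat_columns
        assert back.param_columns == small_reference.param_columns
        pd.testing.assert_frame_equal(
            back.table, small_reference.table, check_exact=False, rtol=1e-12
        )


class TestAbcModel:
    def test_posteriors_sum_to_one(self, small_reference):
        obs = small_reference.table[small_reference.stat_columns].iloc[7]
        res = AbcModel(small_reference, obs).fit(
            retain_frac=0.2, n_bootstrap=10, seed=0)
        assert res.scenario_probabilities["prob"].sum() == pytest.approx(1.0)
        sp = res.scenario_probabilities
        assert (sp["lo95"] <= sp["prob"] + 1e-9).all()
        assert (sp["prob"] <= sp["hi95"] + 1e-9).all()

    def test_self_match_recovers_row_scenario(self, small_reference):
        tbl = small_reference.table
        hits = 0
        for i in (0, 130, 250):
            obs = tbl[small_reference.stat_columns].iloc[i]
            res = AbcModel(small_reference, obs).fit(
                retain_frac=0.08, n_bootstrap=5, seed=1)
            hits += res.best_scenario == tbl["scenario"].iloc[i]
        assert hits >= 2

    def test_affine_rescaling_invariance(self, small_reference):
        obs = small_reference.table[small_reference.stat_columns].iloc[40]
        res1 = AbcModel(small_reference, obs).fit(
            retain_frac=0.1, n_bootstrap=5, seed=2)
        scaled = small_reference.table.copy()
        col = small_reference.stat_columns[0]
        scaled[col] = scaled[col] * 7.0 + 3.0
        ref2 = ReferenceTable(scaled, small_reference.stat_columns,
                              small_reference.param_columns,
                              small_reference.priors, seed=5)
        obs2 = obs.copy()
        obs2[col] = obs2[col] * 7.0 + 3.0
        res2 = AbcModel(ref2, obs2).fit(retain_frac=0.1, n_bootstrap=5, seed=2)
        assert np.allclose(
            res1.scenario_probabilities["prob"],
            res2.scenario_probabilities["prob"], atol=1e-6,
        )

    def test_parameter_posteriors_respect_prior_support(self, small_reference):
        obs = small_reference.table[small_reference.stat_columns].iloc[250]
        params = AbcModel(small_reference, obs).estimate_parameters(
            "admixture", retain_frac=0.3)
        r = params.loc["r"]
        assert 0.05 <= r["lo90"] <= r["median"] <= r["hi90"] <= 0.95
        t = params.loc["t_adm"]
        assert 160 <= t["lo90"] <= t["hi90"] <= 20000

    def test_missing_observed_stat_rejected(self, small_reference):
        obs = small_reference.table[small_reference.stat_columns].iloc[0]
        obs = obs.drop(obs.index[0])
        with pytest.raises(ValueError, match="missing entries"):
            AbcModel(small_reference, obs)

    def test_unknown_scenario_rejected(self, small_reference):
        obs = small_reference.table[small_reference.stat_columns].iloc[0]
        with pytest.raises(ValueError, match="not in reference table"):
            AbcModel(small_reference, obs).estimate_parameters("island")

    def test_summary_text(self, small_reference):
        obs = small_reference.table[small_reference.stat_columns].iloc[3]
        res = AbcModel(small_reference, obs).fit(
            retain_frac=0.2, n_bootstrap=5, seed=3)
        text = res.summary()
        assert "ABC model choice" in text
        assert res.best_scenario in text


class TestKyaConversion:
    def test_reported_divergence(self):
        assert generations_to_kya(27800, 5.0) == pytest.approx(139.0, abs=1e-12)

    def test_reported_admixture(self):
        kya = generations_to_kya(6330, 5.0)
        assert kya == pytest.approx(31.65, abs=1e-12)
        assert int(kya) == 31  # the survey rounds down to 31 kya

    def test_zero_and_negative(self):
        assert generations_to_kya(0) == 0.0
        with pytest.raises(ValueError):
            generations_to_kya(-1)
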