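import numpy as np
import pytest

from roambait import ScenarioParams, generate_trial_table, run_sequential_design
from roambait.battery import (
    run_exploratory_suite,
    run_manipulation_checks,
    run_test1,
    run_test2a,
    run_test2b,
    run_test3,
)
from roambait.synth import generate_panas

DRAWS = 10_000


@pytest.fixture(scope="module")
def negativity_movies():
    params = ScenarioParams(scenario="negativity_bias", n_per_group=40,
                            effect_scale=2.0, seed=7)
    return generate_trial_table(params, material="movies")


class TestPrimaryTests:
    def test_test1_detects_planted_negativity_bias(self, negativity_dataset):
        sec = run_test1(negativity_dataset.trial_table, draws=DRAWS, seed=1)
        assert sec["winner"] == "H2"
        tab = sec["tables"]["evidence"]
        assert tab.PostP.sum() == pytest.approx(1.0, abs=1e-9)
        assert tab.set_index("hypothesis").PostP["H2"] > 0.8

    def test_test1_null_scenario_favors_null(self, null_dataset):
        sec = run_test1(null_dataset.trial_table, draws=DRAWS, seed=2)
        assert sec["winner"] == "H0"

    def test_test2a_femg_detects_bias(self, negativity_dataset):
        sec = run_test2a(negativity_dataset.trial_table, "femg", draws=DRAWS, seed=3)
        assert sec["winner"] == "H2"

    def test_test2a_valence_sign_convention(self, negativity_dataset):
        # negativity bias lowers valence on BOTH positive and negative trials
        sec = run_test2a(negativity_dataset.trial_table, "valence", draws=DRAWS, seed=4)
        assert sec["winner"] == "H2"

    def test_test2b_follows_2a_pattern(self, negativity_dataset, negativity_movies):
        sec = run_test2b(negativity_movies.trial_table, "H2", draws=DRAWS, seed=5)
        assert sec["winner"] == "H1"
        tab = sec["tables"]["evidence"]
        assert set(tab.hypothesis) == {"H1", "Hc"}

    def test_test2b_opposite_pattern_favors_complement(self, negativity_movies):
        # asking for the overgeneral pattern on negativity-bias movies
        sec = run_test2b(negativity_movies.trial_table, "H1", draws=DRAWS, seed=6)
        assert sec["winner"] == "Hc"

    @pytest.mark.parametrize("verdict", ["H0", "Hc"])
    def test_test2b_conditional_skip_rule(self, negativity_movies, verdict):
        sec = run_test2b(negativity_movies.trial_table, verdict, draws=DRAWS, seed=7)
        assert sec["winner"] == "skipped"
        assert verdict in sec["notes"]


class TestTest3:
    def test_null_slope_favors_equality(self, null_dataset):
        sec = run_test3(null_dataset.trial_table, "positive", draws=DRAWS, seed=8)
        for label in ("within_dysphoric", "within_non_dysphoric", "within_group_difference"):
            tab = sec["tables"][label].set_index("hypothesis")
            assert tab.PostP.idxmax() == "H0", label

    def test_planted_within_slope_detected_in_one_group(self):
        params = ScenarioParams(scenario="null", n_per_group=40,
                                slope_detail_affect=(8.0, 0.0), seed=31)
        df = generate_trial_table(params).trial_table
        sec = run_test3(df, "positive", draws=DRAWS, seed=9)
        dys = sec["tables"]["within_dysphoric"].set_index("hypothesis")
        assert dys.PostP.idxmax() == "H1"  # gamma_dys > 0
        diff = sec["tables"]["within_group_difference"].set_index("hypothesis")
        assert diff.PostP.idxmax() == "H1"  # gamma_dys > gamma_non


class TestManipulationChecks:
    def test_planted_effects_recovered(self, negativity_dataset):
        sec = run_manipulation_checks(negativity_dataset.trial_table,
                                      draws=DRAWS, seed=10)
        tables = sec["tables"]
        assert len(tables) == 12
        for tag in ("non_zygo", "dys_zygo", "non_corr", "dys_corr"):
            rvb = tables[f"{tag}_recall_vs_baseline"].set_index("hypothesis")
            assert rvb.PostP.idxmax() == "H1", tag  # recall > baseline
            evn = tables[f"{tag}_emotional_vs_neutral"].set_index("hypothesis")
            assert evn.PostP.idxmax() == "H1", tag
            std = tables[f"{tag}_standardized_vs_zero"].set_index("hypothesis")
            if tag != "dys_zygo":
                assert std.PostP.idxmax() == "H1", tag
            else:
                # the planted negativity bias pulls the dysphoric
                # zygomaticus response towards 0, so only the direction
                # can be asserted here
                assert std.PostP.idxmax() != "H2", tag
        for tab in tables.values():
            assert tab.PostP.sum() == pytest.approx(1.0, abs=1e-9)


class TestExploratory:
    def test_attenuation_scenario_favors_attenuation(self):
        params = ScenarioParams(scenario="positive_attenuation", n_per_group=40,
                                effect_scale=2.0, seed=13)
        ds = generate_trial_table(params)
        sec = run_exploratory_suite(ds.trial_table, draws=DRAWS, seed=11)
        tab = sec["tables"]["attenuation_vs_negativity_memories"].set_index("hypothesis")
        assert tab.PostP.idxmax() == "H2"  # attenuation

    def test_negativity_scenario_favors_negativity(self, negativity_dataset):
        sec = run_exploratory_suite(negativity_dataset.trial_table, draws=DRAWS, seed=12)
        tab = sec["tables"]["attenuation_vs_negativity_memories"].set_index("hypothesis")
        assert tab.PostP.idxmax() == "H1"

    def test_flat_trials_favor_habituation_equality(self, null_dataset):
        sec = run_exploratory_suite(null_dataset.trial_table, draws=DRAWS, seed=13)
        for key in ("habituation_non_zygo", "habituation_dys_corr"):
            tab = sec["tables"][key].set_index("hypothesis")
            assert tab.PostP.idxmax() == "H0", key

    def test_panas_tables_present_with_panas_input(self, null_dataset):
        panas = generate_panas(ScenarioParams(n_per_group=40, seed=11))
        sec = run_exploratory_suite(null_dataset.trial_table, panas=panas,
                                    draws=DRAWS, seed=14)
        na = sec["tables"]["panas_na_group"].set_index("hypothesis")
        assert na.PostP.idxmax() == "H1"  # dysphoric report more negative affect
        assert "panas_pa_change" in sec["tables"]


class TestEvidenceConsistency:
    def test_median_bf_nondecreasing_in_sample_size(self):
        # under a true directional hypothesis, evidence accumulates with n
        medians = []
        for n_per_group in (10, 20, 40):
            bfs = []
            for rep in range(10):
                params = ScenarioParams(scenario="negativity_bias",
                                        n_per_group=n_per_group,
                                        effect_scale=1.5, seed=300 + rep)
                table = generate_trial_table(params).trial_table
                tab = run_test1(table, draws=DRAWS, seed=rep)["tables"]["evidence"]
                bfs.append(float(tab.set_index("hypothesis").BF_iu["H2"]))
            medians.append(np.median(bfs))
        assert medians[0] <= medians[1] <= medians[2]


class TestSequentialDesign:
    def test_stops_early_on_joint_evidence(self):
        stream = {40: {"test1": 0.85, "test2a": 0.90}}
        state = run_sequential_design(lambda n: stream[n])
        assert state.current_N == 40
        assert state.stop_reason == "evidence"

    def test_runs_to_max_when_one_test_lags(self):
        def stream(n):
            return {"test1": 0.95, "test2a": 0.79}

        state = run_sequential_design(stream)
        assert state.current_N == 80
        assert state.stop_reason == "max_N"
        assert [t["N"] for t in state.trajectory] == [40, 50, 60, 70, 80]

    def test_mid_course_stop(self):
        def stream(n):
            return {"test1": 0.9, "test2a": 0.70 + 0.02 * (n - 40) / 10}

        state = run_sequential_design(stream)
        assert state.stop_reason == "max_N"

        def stream2(n):
            return {"test1": 0.9, "test2a": 0.5 + 0.1 * (n - 40) / 10}

        state2 = run_sequential_design(stream2)
        assert state2.current_N == 70
        assert state2.stop_reason == "evidence"

    def test_degenerate_criterion_stops_at_minimum(self):
        state = run_sequential_design(lambda n: {"test1": 0.0, "test2a": 0.0},
                                      criterion=0.0)
        assert state.current_N == 40
        assert state.stop_reason == "evidence"

    def test_data_driven_run_on_strong_scenario(self, negativity_dataset):
        state = run_sequential_design(negativity_dataset.trial_table,
                                      draws=DRAWS, seed=15)
        assert state.stop_reason in ("evidence", "max_N")
        assert state.trajectory[0]["N"] == 40

    def test_exhausted_stream_raises(self):
        small = generate_trial_table(ScenarioParams(n_per_group=10, seed=1)).trial_table
        with pytest.raises(ValueError, match="exhausted"):
            run_sequential_design(small, draws=DRAWS, seed=16)
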