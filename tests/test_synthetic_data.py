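import numpy as np
import pytest

from allelosep.data_model import DesignSpec, summarize_groups
from allelosep.decomposition import decomposition_from_observations
from allelosep.synthetic_data import (
    ConfigError,
    SimulationConfig,
    config_from_dict,
    default_recovery_config,
    expected_performance,
    multiplicative_rc_mismatch,
    parameter_recovery_study,
    simulate_competition_experiment,
    simulate_decomposition_experiment,
)

DESIGN = DesignSpec("PI", "BYG", target_count=20, neighbor_count=10)


def _config(**kw):
    return default_recovery_config(**kw)


class TestConfigValidation:
    def test_additive_effects_must_leave_positive_performance(self):
        with pytest.raises(ConfigError, match="c \\+ a < 1"):
            _config(c=0.6, a=0.5)

    def test_multiplicative_allows_larger_sums(self):
        cfg = _config(c=0.6, a=0.5, interference_model="multiplicative")
        assert cfg.effects("BYG", "PI") == (0.6, 0.5)

    def test_negative_noise_rejected(self):
        with pytest.raises(ConfigError):
            _config(noise_cv=-0.1)

    def test_unknown_model_rejected(self):
        with pytest.raises(ConfigError):
            _config(interference_model="quadratic")

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(baseline={("A", "RL"): 0.0})

    def test_nested_dict_form(self):
        cfg = config_from_dict(
            {
                "baseline": {"BYG": {"RL": 7.32}, "PI": {"RL": 8.73}},
                "competition": {"BYG": {"PI": 0.2}},
                "allelopathy": {"BYG": {"PI": 0.3}},
                "noise_cv": 0.0,
                "seed": 3,
            }
        )
        assert cfg.baseline[("BYG", "RL")] == 7.32
        assert cfg.effects("BYG", "PI") == (0.2, 0.3)


class TestExpectedPerformance:
    def test_arm_expectations_additive(self):
        cfg = _config(c=0.2, a=0.3, noise_cv=0.0)
        b = cfg.baseline[("BYG", "RL")]
        assert expected_performance(cfg, "BYG", "RL", "monoculture", "none") == b
        assert expected_performance(cfg, "BYG", "RL", "mixed", "PI") == pytest.approx(b * 0.5)
        assert expected_performance(cfg, "BYG", "RL", "residual_solution", "PI") == pytest.approx(b * 0.7)

    def test_arm_expectations_multiplicative(self):
        cfg = _config(c=0.2, a=0.3, interference_model="multiplicative")
        b = cfg.baseline[("BYG", "RL")]
        assert expected_performance(cfg, "BYG", "RL", "mixed", "PI") == pytest.approx(b * 0.8 * 0.7)


class TestSimulation:
    def test_deterministic_given_seed(self):
        cfg = _config(seed=123)
        assert simulate_decomposition_experiment(cfg, DESIGN) == \
            simulate_decomposition_experiment(cfg, DESIGN)

    def test_adding_an_arm_does_not_perturb_existing_draws(self):
        cfg = _config(seed=9)
        exp1 = simulate_competition_experiment(cfg, DESIGN)
        exp2 = simulate_decomposition_experiment(cfg, DESIGN)
        key = lambda o: (o.species, o.arm, o.partner_species, o.replicate_id, o.trait)
        mono1 = {key(o): o.value for o in exp1 if o.arm == "monoculture"
                 and o.species == "BYG"}
        mono2 = {key(o): o.value for o in exp2 if o.arm == "monoculture"
                 and o.species == "BYG"}
        # receiver monoculture draws coincide despite the extra residual arm
        assert mono1 == mono2

    def test_zero_noise_values_are_exact_expectations(self):
        cfg = _config(c=0.2, a=0.3, noise_cv=0.0)
        obs = simulate_decomposition_experiment(cfg, DESIGN)
        mixed = [o.value for o in obs if o.arm == "mixed" and o.species == "BYG"]
        assert mixed == pytest.approx([7.32 * 0.5] * len(mixed))

    def test_replicate_and_plant_counts_follow_design(self):
        cfg = _config()
        obs = simulate_decomposition_experiment(cfg, DESIGN)
        receiver_mixed = [o for o in obs if o.species == "BYG" and o.arm == "mixed"]
        assert len(receiver_mixed) == DESIGN.neighbor_count * cfg.n_replicates
        donor_mixed = [o for o in obs if o.species == "PI" and o.arm == "mixed"]
        assert len(donor_mixed) == DESIGN.target_count * cfg.n_replicates

    def test_null_effects_leave_arms_indistinguishable(self):
        cfg = _config(c=0.0, a=0.0, noise_cv=0.05, seed=21)
        obs = simulate_competition_experiment(cfg, DESIGN)
        summaries = {s.arm: s for s in summarize_groups(obs, unit="plant")
                     if s.species == "BYG" and s.trait == "RL"}
        n = DESIGN.neighbor_count * cfg.n_replicates
        bound = 3 * 0.05 * 7.32 * np.sqrt(2 / n)
        assert abs(summaries["mixed"].mean - summaries["monoculture"].mean) < bound


class TestPipelineRecovery:
    def test_zero_noise_pipeline_recovers_truth_exactly(self):
        cfg = _config(c=0.2, a=0.3, noise_cv=0.0)
        table = decomposition_from_observations(
            simulate_decomposition_experiment(cfg, DESIGN)
        )
        r = table.result("PI", "RL")
        assert r.tb == pytest.approx(50.0)
        assert r.ae == pytest.approx(30.0)
        assert r.rc == pytest.approx(20.0)
        assert r.ae_share == pytest.approx(60.0)

    def test_facilitation_yields_flagged_negative_rc(self):
        cfg = _config(c=-0.2, a=0.3, noise_cv=0.0)
        table = decomposition_from_observations(
            simulate_decomposition_experiment(cfg, DESIGN)
        )
        r = table.result("PI", "RL")
        assert r.rc == pytest.approx(-20.0)
        assert "negative_rc" in r.flags

    def test_multiplicative_data_bias_matches_closed_form(self):
        c, a = 0.3, 0.4
        cfg = _config(c=c, a=a, noise_cv=0.0, interference_model="multiplicative")
        r = decomposition_from_observations(
            simulate_decomposition_experiment(cfg, DESIGN)
        ).result("PI", "RL")
        # the subtraction split recovers c(1−a) instead of c
        assert r.rc == pytest.approx(100 * c * (1 - a))
        tb = 1 - (1 - c) * (1 - a)
        assert (c - c * (1 - a)) / tb == pytest.approx(multiplicative_rc_mismatch(c, a))

    def test_recovery_study_zero_noise_has_no_error(self):
        study = parameter_recovery_study([_config(noise_cv=0.0)], n_runs=3, seed=5)
        row = study.iloc[0]
        for q in ("tb", "ae", "rc", "ae_share"):
            assert row[f"{q}_bias"] == pytest.approx(0.0, abs=1e-9)
            assert row[f"{q}_rmse"] == pytest.approx(0.0, abs=1e-9)
        assert row["n_failures"] == 0

    def test_recovery_study_is_deterministic(self):
        a = parameter_recovery_study([_config()], n_runs=5, seed=11)
        b = parameter_recovery_study([_config()], n_runs=5, seed=11)
        assert a.equals(b)

    def test_more_replicates_shrink_share_rmse(self):
        configs = [_config(noise_cv=0.08, n_replicates=n) for n in (2, 8, 32)]
        study = parameter_recovery_study(configs, n_runs=60, seed=13)
        rmse = study["ae_share_rmse"].tolist()
        assert rmse[0] > rmse[1] > rmse[2]
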