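import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from xslsim import (
    EbbinghausForgetting,
    NaiveForgetting,
    NoForgetting,
)
from xslsim.experiments import (
    ExperimentConfig,
    DiversityConfig,
    RegimeResult,
    SweepResult,
    as_results_table,
    compare_optima,
    diversity_sweep,
    estimate_regime_boundaries,
    final_measures,
    log_checkpoints,
    run_learning_curve,
    run_single,
    simulate_ensemble,
    sweep_memory_parameter,
    write_results_csv,
)


class TestConfig:
    def test_log_checkpoints_span_the_horizon(self):
        cps = log_checkpoints(10_000)
        assert cps[0] == 1 and cps[-1] == 10_000
        assert all(b > a for a, b in zip(cps, cps[1:]))

    def test_non_increasing_checkpoints_rejected(self):
        with pytest.raises(ValueError):
            ExperimentConfig(checkpoints=(10, 5))

    def test_checkpoints_beyond_horizon_rejected(self):
        with pytest.raises(ValueError):
            ExperimentConfig(t_max=100, checkpoints=(1, 200))

    def test_diversity_validation(self):
        with pytest.raises(ValueError):
            DiversityConfig(n_adults=0)
        with pytest.raises(ValueError):
            DiversityConfig(samples=0)


class TestEngine:
    def test_matches_scalar_reference_statistically(self):
        """The vectorized ensemble and the step-by-step learner driver
        sample the same process: their mean final errors agree within
        Monte-Carlo error."""
        cfg = ExperimentConfig(policy=NaiveForgetting(30), t_max=2000,
                               n_runs=100, seed=9, checkpoints=(2000,))
        eng = simulate_ensemble(cfg)
        e_eng = eng["E_mean"].iloc[-1]
        scalar = []
        for k in range(40):
            _, _, recs = run_single(cfg, rng=np.random.default_rng([9, k]))
            scalar.append(recs[-1].E)
        se = math.sqrt(eng["E_sd"].iloc[-1] ** 2 / cfg.n_runs
                       + np.var(scalar, ddof=1) / len(scalar))
        assert abs(e_eng - np.mean(scalar)) < 4 * se

    def test_deterministic_given_config_and_seed(self, tmp_path):
        cfg = ExperimentConfig(policy=EbbinghausForgetting(0.01, 0.02),
                               t_max=500, n_runs=20, seed=11)
        a, b = simulate_ensemble(cfg), simulate_ensemble(cfg)
        pd.testing.assert_frame_equal(a, b)
        paths = []
        for i, df in enumerate((a, b)):
            p = tmp_path / f"{i}.csv"
            write_results_csv(as_results_table(df, "det", "ebbinghaus"), p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_independent_seeds_agree_within_error(self):
        cfg = ExperimentConfig(policy=NaiveForgetting(30), t_max=2000,
                               n_runs=150, seed=1, checkpoints=(2000,))
        a = simulate_ensemble(cfg)
        b = simulate_ensemble(replace(cfg, seed=2))
        se = math.sqrt(a["E_sd"].iloc[-1] ** 2 / cfg.n_runs
                       + b["E_sd"].iloc[-1] ** 2 / cfg.n_runs)
        assert abs(a["E_mean"].iloc[-1] - b["E_mean"].iloc[-1]) < 4 * se

    def test_ensemble_mean_variance_shrinks_with_runs(self):
        """Quadrupling the ensemble size shrinks the variance of the
        ensemble-mean error by about 4."""
        def mean_vars(n_runs, n_rep):
            finals = []
            for k in range(n_rep):
                cfg = ExperimentConfig(policy=NaiveForgetting(30), t_max=1000,
                                       n_runs=n_runs, seed=1000 + k,
                                       checkpoints=(1000,))
                finals.append(simulate_ensemble(cfg)["E_mean"].iloc[-1])
            return np.var(finals, ddof=1)

        ratio = mean_vars(10, 40) / mean_vars(40, 40)
        assert 2.0 < ratio < 8.0

    def test_fresh_state_conventions_at_first_checkpoint(self):
        """Before any exposure E = 0 and P = 0; one interaction later the
        child has a single (possibly spurious) association."""
        cfg = ExperimentConfig(policy=NoForgetting(), t_max=10, n_runs=30,
                               seed=4, checkpoints=(1, 10))
        df = simulate_ensemble(cfg)
        assert df["t"].iloc[0] == 1
        assert 0.0 <= df["E_mean"].iloc[0] <= 1.0

    def test_ebbinghaus_engine_slow_path_matches_rate_semantics(self):
        """With d1 -> inf the Ebbinghaus policy forgets every token at the
        flat rate 1/d0, so the surviving count stays near the birth-death
        equilibrium instead of growing."""
        cfg = ExperimentConfig(policy=EbbinghausForgetting(0.05, 1e9),
                               t_max=2000, n_runs=50, seed=8,
                               checkpoints=(1000, 2000))
        df = simulate_ensemble(cfg)
        # equilibrium total ~ arrival rate (2/step) / deletion rate
        assert df["tokens_mean"].iloc[-1] == pytest.approx(2 / 0.05, rel=0.25)

    def test_nonuniform_referent_weights_bias_exposure(self):
        w = (0.4, 0.4, 0.05, 0.05, 0.025, 0.025, 0.025, 0.0125, 0.0125, 0.0)
        cfg = ExperimentConfig(policy=NoForgetting(), t_max=2000, n_runs=20,
                               seed=3, referent_weights=w, checkpoints=(2000,))
        state, _, _ = run_single(cfg)
        assert state.n[0] > state.n[4] > 0
        assert state.n[9] == 0  # zero-weight referent is never part of a scene


class TestSweep:
    def test_single_point_grid_reduces_to_learning_curve(self):
        base = ExperimentConfig(policy=NaiveForgetting(40), t_max=400,
                                n_runs=10, seed=21)
        sweep = sweep_memory_parameter(base, [40])
        cfg = replace(base, checkpoints=base.resolve_checkpoints())
        expected = simulate_ensemble(
            cfg, rng=np.random.default_rng(np.random.SeedSequence([21, 0])))
        got = sweep.table.drop(columns=["param_name", "param_value"])
        pd.testing.assert_frame_equal(got.reset_index(drop=True), expected)

    def test_empty_grid_rejected(self):
        base = ExperimentConfig(policy=NaiveForgetting(40))
        with pytest.raises(ValueError):
            sweep_memory_parameter(base, [])

    def test_sweep_needs_a_forgetting_policy(self):
        with pytest.raises(ValueError):
            sweep_memory_parameter(ExperimentConfig(policy=NoForgetting()), [10])

    def test_u_shape_at_small_scale(self):
        """Intermediate forgetting beats both extremes."""
        base = ExperimentConfig(policy=NaiveForgetting(40), t_max=3000,
                                n_runs=60, seed=13)
        cross = final_measures(sweep_memory_parameter(base, [8, 40, 200]))
        e = cross.set_index("param_value")["E_mean"]
        assert e[40] < e[8] and e[40] < e[200]

    def test_ebbinghaus_sweep_varies_inverse_d1(self):
        base = ExperimentConfig(policy=EbbinghausForgetting(0.01, 0.01),
                                t_max=300, n_runs=5, seed=2)
        sweep = sweep_memory_parameter(base, [10, 100])
        assert sweep.param_name == "inv_d1"
        assert set(sweep.table["param_value"]) == {10.0, 100.0}

    def test_final_measures_requires_known_checkpoint(self):
        base = ExperimentConfig(policy=NaiveForgetting(40), t_max=400,
                                n_runs=5, seed=2)
        sweep = sweep_memory_parameter(base, [40])
        with pytest.raises(ValueError):
            final_measures(sweep, 399)


def _synthetic_sweep(curves: dict[float, np.ndarray], t: np.ndarray) -> SweepResult:
    frames = []
    for v, e in curves.items():
        frames.append(pd.DataFrame({
            "param_name": "m", "param_value": v, "t": t, "E_mean": e,
            "E_sd": 0.0, "chi2_mean": 0.0, "chi2_sd": 0.0,
            "pearson_mean": 0.0, "pearson_sd": 0.0,
            "noise_tokens_mean": 0.0, "tokens_mean": 0.0,
            "n_runs": 1, "seed": 0,
        }))
    base = ExperimentConfig(policy=NaiveForgetting(10), t_max=int(t[-1]))
    return SweepResult("m", tuple(curves), pd.concat(frames, ignore_index=True), base)


class TestRegimeClassifier:
    t = np.array([1000, 2000, 4000, 10_000], dtype=float)

    def test_three_regime_classification_and_midpoint_boundaries(self):
        sweep = _synthetic_sweep({
            10.0: np.full(4, 0.03),            # low plateau
            20.0: 0.5 * (self.t / 1000.0) ** -1.0,
            40.0: 0.2 * (self.t / 1000.0) ** -0.8,
            90.0: np.full(4, 0.02),            # high plateau
        }, self.t)
        res = estimate_regime_boundaries(sweep)
        assert res.classes == ("plateau-low", "power-law-decay",
                               "power-law-decay", "plateau-high")
        assert res.m0 == 15.0 and res.m1 == 65.0

    def test_no_decay_found_reports_absent_boundaries(self):
        sweep = _synthetic_sweep({10.0: np.full(4, 0.03),
                                  20.0: np.full(4, 0.02)}, self.t)
        res = estimate_regime_boundaries(sweep)
        assert res.m0 is None and res.m1 is None

    def test_identically_zero_error_counts_as_plateau(self):
        sweep = _synthetic_sweep({1.0: np.zeros(4),
                                  20.0: 0.5 * (self.t / 1000.0) ** -1.0}, self.t)
        res = estimate_regime_boundaries(sweep)
        assert res.classes[0] == "plateau-low"

    def test_boundary_order_enforced(self):
        with pytest.raises(ValueError):
            RegimeResult(param_values=(1.0,), classes=("x",), slopes=(0.0,),
                         final_errors=(0.0,), m0=5.0, m1=4.0,
                         slope_threshold=-0.5)


class TestCompareOptima:
    @staticmethod
    def _sweeps():
        naive = sweep_memory_parameter(
            ExperimentConfig(policy=NaiveForgetting(40), t_max=1000,
                             n_runs=20, seed=5), [20, 40])
        ebb = sweep_memory_parameter(
            ExperimentConfig(policy=EbbinghausForgetting(0.01, 0.01),
                             t_max=1000, n_runs=20, seed=5), [100, 300])
        return naive, ebb

    def test_swapping_inputs_swaps_outputs(self):
        naive, ebb = self._sweeps()
        ab = compare_optima(naive, ebb, n_runs=10)
        ba = compare_optima(ebb, naive, n_runs=10)
        assert ab.first.param_value == ba.second.param_value
        assert ab.second.param_value == ba.first.param_value
        assert ab.diff_final_E == pytest.approx(-ba.diff_final_E)

    def test_mismatched_horizons_rejected(self):
        naive, ebb = self._sweeps()
        short = sweep_memory_parameter(
            ExperimentConfig(policy=NaiveForgetting(40), t_max=500,
                             n_runs=5, seed=5), [40])
        with pytest.raises(ValueError):
            compare_optima(naive, short)


class TestDiversity:
    def test_table_covers_all_levels_and_parameters(self):
        base = ExperimentConfig(policy=NaiveForgetting(40), t_max=500,
                                n_runs=10, seed=3)
        table = diversity_sweep(base, [2, None], [20, 40])
        assert set(table["s"]) == {2.0, math.inf}
        assert set(table["param_value"]) == {20.0, 40.0}
        assert len(table) == 4

    def test_large_s_recovers_no_diversity_results(self):
        """With many samples per referent every idiolect equals the
        auxiliary lexicon, so the diverse population behaves like the
        single shared adult."""
        base = ExperimentConfig(policy=NaiveForgetting(40), t_max=2000,
                                n_runs=120, seed=3,
                                diversity=DiversityConfig(n_adults=5, samples=5))
        table = diversity_sweep(base, [100_000, None], [40])
        big_s = table[table["s"] == 100_000].iloc[0]
        control = table[table["s"] == math.inf].iloc[0]
        se = math.sqrt(big_s["E_sd"] ** 2 / big_s["n_runs"]
                       + control["E_sd"] ** 2 / control["n_runs"])
        assert abs(big_s["E_mean"] - control["E_mean"]) < 4 * se


class TestResultsSerialization:
    def test_canonical_columns_and_order(self, tmp_path):
        cfg = ExperimentConfig(policy=NaiveForgetting(40), t_max=50, n_runs=3,
                               seed=1, checkpoints=(50,))
        table = as_results_table(simulate_ensemble(cfg), "x", "naive")
        path = tmp_path / "r.csv"
        write_results_csv(table, path)
        header = path.read_text().splitlines()[0]
        assert header == ("experiment_id,policy,param_name,param_value,s,t,"
                          "E_mean,E_sd,chi2_mean,chi2_sd,pearson_mean,"
                          "pearson_sd,n_runs,seed")

    def test_missing_columns_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_results_csv(pd.DataFrame({"t": [1]}), tmp_path / "r.csv")
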