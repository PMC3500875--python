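"""Event-history layer: additive hazards, mediator series, decomposition."""

import numpy as np
import pandas as pd
import pytest

import dynpath as dp
from dynpath.errors import EmptyFitError, ValidationError

from conftest import normal_equations_additive


def paired_orthogonal_data():
    """Subjects in (X=0, X=1) pairs with identical mediator values and
    follow-up, so the in-sample mediator-treatment covariance is exactly
    zero on every at-risk set."""
    rows = []
    z_values = [0.2, 0.9, 1.5, 0.5]
    stops = [1.0, 2.0, 3.0, 2.0]
    events = [1, 1, 0, 1]
    sid = 0
    for z, stop, ev in zip(z_values, stops, events):
        for x in (0, 1):
            rows.append({"id": sid, "start": 0.0, "stop": stop, "event": ev,
                         "X": float(x), "Z": z})
            sid += 1
    return dp.CountingProcessData(pd.DataFrame(rows))


class TestCountingProcessData:
    def test_validation_catches_bad_intervals(self):
        df = pd.DataFrame(
            {"id": [1], "start": [1.0], "stop": [1.0], "event": [1], "X": [0.0]}
        )
        with pytest.raises(ValidationError, match="start must be < stop"):
            dp.CountingProcessData(df)

    def test_validation_catches_gap(self):
        df = pd.DataFrame(
            {
                "id": [1, 1],
                "start": [0.0, 1.5],
                "stop": [1.0, 2.0],
                "event": [0, 1],
            }
        )
        with pytest.raises(ValidationError, match="contiguous"):
            dp.CountingProcessData(df)

    def test_validation_event_only_last(self):
        df = pd.DataFrame(
            {
                "id": [1, 1],
                "start": [0.0, 1.0],
                "stop": [1.0, 2.0],
                "event": [1, 1],
            }
        )
        with pytest.raises(ValidationError, match="last interval"):
            dp.CountingProcessData(df)

    def test_hand_fixture_loads(self, hand8):
        assert hand8.n_subjects == 8
        assert hand8.n_events == 6
        assert hand8.covariates == ("X", "Z")


class TestAdditiveHazard:
    def test_intercept_only_is_occurrence_exposure(self, hand8):
        """Intercept-only increments are d_k / r_k, the occurrence/exposure
        (cumulative-hazard) step estimator."""
        fit = dp.fit_additive_hazard(hand8, ())
        assert np.allclose(fit.increments[:, 0], fit.n_events / fit.at_risk)
        assert np.allclose(fit.cumulative[:, 0], np.cumsum(fit.n_events / fit.at_risk))

    def test_intercept_only_matches_lifelines(self, hand8):
        """Independent oracle: Nelson–Aalen with late-entry handling."""
        lifelines = pytest.importorskip("lifelines")
        tbl = hand8.table
        per_subj = tbl.groupby("id").agg(
            entry=("start", "min"), stop=("stop", "max"), event=("event", "max")
        )
        naf = lifelines.NelsonAalenFitter(nelson_aalen_smoothing=False)
        naf.fit(per_subj["stop"], per_subj["event"], entry=per_subj["entry"])
        fit = dp.fit_additive_hazard(hand8, ())
        na = naf.cumulative_hazard_["NA_estimate"]
        for t, cum in zip(fit.event_times, fit.cumulative[:, 0]):
            assert cum == pytest.approx(na.loc[t], abs=1e-12)

    def test_hand_fixture_matches_normal_equations_oracle(self, hand8):
        fit = dp.fit_additive_hazard(hand8, ["X", "Z"])
        times, incs = normal_equations_additive(hand8, ["X", "Z"])
        assert np.allclose(fit.event_times, times)
        assert np.allclose(fit.increments, incs, atol=1e-12)

    def test_group_block_orthogonality(self):
        """With a binary group and events only in group 1, the group-1
        fitted cumulative equals the group-1-only intercept fit."""
        rows = []
        for i, (g, stop, ev) in enumerate(
            [(1, 1.0, 1), (1, 2.0, 1), (1, 3.0, 0), (0, 3.0, 0), (0, 2.5, 0)]
        ):
            rows.append({"id": i, "start": 0.0, "stop": stop, "event": ev, "G": float(g)})
        data = dp.CountingProcessData(pd.DataFrame(rows))
        fit = dp.fit_additive_hazard(data, ["G"])
        group1 = dp.CountingProcessData(
            data.table[data.table["G"] == 1.0].reset_index(drop=True)
        )
        fit1 = dp.fit_additive_hazard(group1, ())
        combined = fit.cumulative[:, 0] + fit.cumulative[:, 1]
        assert np.allclose(combined, fit1.cumulative[:, 0], atol=1e-12)

    def test_singular_design_skipped_and_logged(self):
        """A time where the mediator is constant across the at-risk set is
        skipped (collinear with the intercept), not pseudo-inverted."""
        rows = [
            {"id": 0, "start": 0.0, "stop": 1.0, "event": 1, "Z": 1.0},
            {"id": 1, "start": 0.0, "stop": 1.0, "event": 0, "Z": 1.0},
            {"id": 1, "start": 1.0, "stop": 2.0, "event": 1, "Z": 0.5},
            {"id": 2, "start": 0.0, "stop": 1.0, "event": 0, "Z": 1.0},
            {"id": 2, "start": 1.0, "stop": 2.0, "event": 0, "Z": 0.2},
        ]
        data = dp.CountingProcessData(pd.DataFrame(rows))
        fit = dp.fit_additive_hazard(data, ["Z"])
        assert fit.skipped_times == (1.0,)
        assert fit.event_times.tolist() == [2.0]
        assert fit.skipped_event_fraction == pytest.approx(0.5)

    def test_no_events_raises(self):
        df = pd.DataFrame({"id": [0], "start": [0.0], "stop": [1.0], "event": [0]})
        with pytest.raises(EmptyFitError):
            dp.fit_additive_hazard(dp.CountingProcessData(df), ())

    def test_unknown_regressor_raises(self, hand8):
        with pytest.raises(ValidationError, match="not among covariates"):
            dp.fit_additive_hazard(hand8, ["W"])


class TestMediatorSeries:
    def test_constant_mediator(self, hand8):
        data = dp.CountingProcessData(hand8.table.assign(Z=3.5))
        series = dp.fit_mediator_series(data, "Z", ["X"])
        assert np.allclose(series.coef[:, 0], 3.5)
        assert np.allclose(series.coef[:, 1], 0.0, atol=1e-12)

    def test_exact_linear_mediator(self, hand8):
        data = dp.CountingProcessData(hand8.table.assign(Z=2.0 * hand8.table["X"]))
        series = dp.fit_mediator_series(data, "Z", ["X"])
        assert np.allclose(series.coef[:, series.term_index("X")], 2.0)

    def test_simulation_recovery(self):
        """theta1 = 1.5 recovered within 3 Monte-Carlo SEs at n = 400."""
        rng = np.random.default_rng(31)
        n = 400
        x = rng.binomial(1, 0.5, n).astype(float)
        z = 0.3 + 1.5 * x + rng.normal(0, 0.5, n)
        stop = rng.uniform(0.5, 2.0, n)
        event = rng.random(n) < 0.6
        df = pd.DataFrame(
            {"id": np.arange(n), "start": 0.0, "stop": stop,
             "event": event.astype(int), "X": x, "Z": z}
        )
        series = dp.fit_mediator_series(dp.CountingProcessData(df), "Z", ["X"])
        j = series.term_index("X")
        est = series.coef[:, j]
        mc_se = est.std(ddof=1) / np.sqrt(est.size)
        # per-time estimates are highly correlated (shared sample), so use
        # the mean per-time SE as the scale instead of the naive mean SE
        assert abs(est.mean() - 1.5) < 3 * series.se[:, j].mean()

    def test_at_risk_counts(self, hand8):
        series = dp.fit_mediator_series(hand8, "Z", ["X"])
        fit = dp.fit_additive_hazard(hand8, ())
        assert np.array_equal(series.at_risk, fit.at_risk)


class TestDynamicPath:
    def test_identity_exact_on_hand_fixture(self, hand8):
        fit = dp.fit_dynamic_path(hand8, "X", "Z")
        assert not fit.identity_approximate
        assert np.abs(fit.identity_gap).max() < 1e-12

    def test_identity_against_normal_equations_oracle(self, hand8):
        """Both sides of the decomposition recomputed from the explicit
        normal-equations oracle agree with the fit."""
        fit = dp.fit_dynamic_path(hand8, "X", "Z")
        _, full_incs = normal_equations_additive(hand8, ["X", "Z"])
        _, marg_incs = normal_equations_additive(hand8, ["X"])
        assert np.allclose(fit.full_fit.increments, full_incs, atol=1e-12)
        assert np.allclose(fit.marginal_fit.increments, marg_incs, atol=1e-12)
        assert np.allclose(
            np.cumsum(marg_incs[:, 1]),
            fit.direct + fit.indirect,
            atol=1e-10,
        )

    def test_orthogonal_mediator_gives_zero_indirect(self):
        """When the mediator is exactly orthogonal to treatment on every
        at-risk set, theta1 = 0, the indirect curve vanishes and total
        equals direct exactly."""
        data = paired_orthogonal_data()
        fit = dp.fit_dynamic_path(data, "X", "Z")
        j = fit.theta.term_index("X")
        assert np.allclose(fit.theta.coef[:, j], 0.0, atol=1e-12)
        assert np.allclose(fit.indirect, 0.0, atol=1e-12)
        assert np.allclose(fit.total, fit.direct, atol=1e-12)

    def test_identity_on_simulated_data(self):
        """total - direct - indirect = 0 at machine precision on simulated
        mediation datasets with no skipped times."""
        for seed in (0, 1, 2):
            data = dp.gen_mediation_survival(dp.MediationScenario(n=200, seed=seed))
            fit = dp.fit_dynamic_path(data, "X", "Z")
            assert not fit.identity_approximate
            assert np.abs(fit.identity_gap).max() < 1e-10

    def test_skip_flags_identity_approximate(self):
        """A singular time in the full fit flags the decomposition."""
        rows = [
            {"id": 0, "start": 0.0, "stop": 1.0, "event": 1, "X": 0.0, "Z": 1.0},
            {"id": 1, "start": 0.0, "stop": 1.0, "event": 0, "X": 1.0, "Z": 1.0},
            {"id": 1, "start": 1.0, "stop": 2.0, "event": 1, "X": 1.0, "Z": 0.5},
            {"id": 2, "start": 0.0, "stop": 1.0, "event": 0, "X": 0.0, "Z": 1.0},
            {"id": 2, "start": 1.0, "stop": 2.0, "event": 0, "X": 0.0, "Z": 0.2},
            {"id": 3, "start": 0.0, "stop": 2.0, "event": 0, "X": 1.0, "Z": 1.0},
        ]
        data = dp.CountingProcessData(pd.DataFrame(rows))
        fit = dp.fit_dynamic_path(data, "X", "Z")
        assert fit.identity_approximate
        assert 1.0 in fit.full_fit.skipped_times

    def test_parameter_recovery(self):
        """Constant-coefficient generative model: cumulative slopes recover
        (beta1, beta2) and the indirect slope recovers beta2 * theta1,
        within 3 Monte-Carlo standard errors."""
        R = 60
        direct, med, indirect = [], [], []
        for r in range(R):
            data = dp.gen_mediation_survival(dp.MediationScenario(seed=500 + r))
            fit = dp.fit_dynamic_path(data, "X", "Z")
            direct.append(fit.direct[-1])
            med.append(fit.full_fit.cumulative[-1, fit.full_fit.term_index("Z")])
            indirect.append(fit.indirect[-1])
        for vals, truth in ((direct, 0.3), (med, 0.5), (indirect, 0.5)):
            vals = np.asarray(vals)
            se = vals.std(ddof=1) / np.sqrt(R)
            assert abs(vals.mean() - truth) < 3 * se + 1e-3


class TestBootstrapBands:
    def test_identity_resample_collapses_bands(self):
        data = dp.gen_mediation_survival(dp.MediationScenario(n=120, seed=3))
        bands = dp.bootstrap_bands(
            data, "X", "Z", n_boot=1, seed=0, resample_fn=lambda rng, ids: ids
        )
        for name in ("direct", "indirect", "total"):
            lo, hi = bands[name]
            assert np.allclose(lo, hi)
            assert np.allclose(lo, bands["point"][name])

    def test_seed_determinism(self):
        data = dp.gen_mediation_survival(dp.MediationScenario(n=120, seed=4))
        b1 = dp.bootstrap_bands(data, "X", "Z", n_boot=25, seed=11)
        b2 = dp.bootstrap_bands(data, "X", "Z", n_boot=25, seed=11)
        for name in ("direct", "indirect", "total"):
            assert np.array_equal(b1[name][0], b2[name][0])
            assert np.array_equal(b1[name][1], b2[name][1])

    def test_coverage_of_direct_effect(self):
        """Pointwise 90% percentile band covers the true cumulative direct
        effect at mid-follow-up at roughly the nominal rate."""
        rng_seeds = range(40)
        covered = 0
        for s in rng_seeds:
            data = dp.gen_mediation_survival(dp.MediationScenario(n=150, seed=7000 + s))
            bands = dp.bootstrap_bands(data, "X", "Z", n_boot=60, level=0.90, seed=s)
            times = bands["times"]
            k = np.searchsorted(times, 0.5)
            k = min(k, len(times) - 1)
            truth = 0.3 * times[k]
            lo, hi = bands["direct"]
            covered += lo[k] <= truth <= hi[k]
        rate = covered / len(list(rng_seeds))
        # binomial 3-sigma band around 0.90 with 40 trials, plus bootstrap
        # undercoverage slack at this sample size
        assert rate > 0.90 - 3 * np.sqrt(0.9 * 0.1 / 40) - 0.05
        assert rate <= 1.0

    def test_validation(self, hand8):
        with pytest.raises(ValidationError):
            dp.bootstrap_bands(hand8, "X", "Z", n_boot=0)
        with pytest.raises(ValidationError):
            dp.bootstrap_bands(hand8, "X", "Z", level=1.5)
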