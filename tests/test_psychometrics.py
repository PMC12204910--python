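import logging

import numpy as np
import pandas as pd
import pytest

from varens import design, observer, psychometrics as psy
from varens.errors import (
    EstimationError,
    InsufficientSampleError,
    PoolingError,
    UndefinedJNDError,
    UndefinedPSEError,
)
from varens.psychometrics import (
    PsychometricFit,
    derive_jnd,
    derive_pse,
    fit_logistic,
    pool_fits,
    screen_outliers,
    split_analysis,
    tukey_fences,
)

from _oracles import profile_grid_logistic, type7_quartiles


def _simulate_binary(beta0, beta1, n_per_level, rng, levels=design.LEVELS):
    d = np.repeat(np.asarray(levels, float), n_per_level)
    p = 1.0 / (1.0 + np.exp(-(beta0 + beta1 * d)))
    y = (rng.random(d.size) < p).astype(int)
    return d, y


def _fit(d, y):
    return fit_logistic(list(zip(d, y)))


class TestFitLogistic:
    def test_separation_sentinel_pse_at_midpoint(self):
        """A deterministic responder (more iff d >= 10) has no finite ML fit;
        the sentinel places the PSE between the last all-less and first
        all-more level."""
        d = np.repeat(np.asarray(design.LEVELS, float), 50)
        y = (d >= 10).astype(int)
        fit = _fit(d, y)
        assert not fit.converged
        assert fit.beta1 == np.inf
        assert fit.pse == 9.0
        assert derive_pse(fit) == 9.0

    def test_backwards_separation_gets_negative_infinite_slope(self):
        d = np.repeat(np.asarray(design.LEVELS, float), 10)
        y = (d < 10).astype(int)
        fit = _fit(d, y)
        assert fit.beta1 == -np.inf and fit.pse == 9.0 and not fit.converged

    def test_parameter_recovery_against_grid_oracle(self, rng):
        true_b1 = 0.8
        d, y = _simulate_binary(-9 * true_b1, true_b1, 1000, rng)
        fit = _fit(d, y)
        _, _, pse_oracle = profile_grid_logistic(d, y)
        assert fit.converged
        assert fit.pse == pytest.approx(9.0, abs=0.3)
        assert fit.pse == pytest.approx(pse_oracle, abs=0.05)

    def test_single_response_class_is_an_error(self):
        d = np.repeat(np.asarray(design.LEVELS, float), 5)
        with pytest.raises(EstimationError):
            _fit(d, np.ones_like(d, dtype=int))

    def test_single_level_is_an_error(self):
        with pytest.raises(EstimationError):
            _fit(np.full(20, 8.0), np.tile([0, 1], 10))

    def test_coin_flip_data_give_near_zero_slope(self, rng):
        d, y = _simulate_binary(0.0, 0.0, 500, rng)
        fit = _fit(d, y)
        assert fit.converged
        assert fit.beta1 == pytest.approx(0.0, abs=0.05)

    def test_accepts_trial_dataframe(self, afc_table):
        sub = afc_table[afc_table.participant_id == "s001"]
        fit = fit_logistic(sub, participant_id="s001")
        assert fit.n_trials == len(sub)
        assert fit.converged

    def test_pse_invariant_to_trial_order(self, rng):
        d, y = _simulate_binary(-6.0, 0.6, 100, rng)
        perm = rng.permutation(d.size)
        assert _fit(d, y).pse == pytest.approx(_fit(d[perm], y[perm]).pse, abs=1e-9)

    def test_jnd_invariant_to_level_shift(self, rng):
        d, y = _simulate_binary(-6.0, 0.6, 200, rng)
        a, b = _fit(d, y), _fit(d + 5.0, y)
        assert a.jnd == pytest.approx(b.jnd, rel=1e-6)
        assert b.pse == pytest.approx(a.pse + 5.0, abs=1e-6)


class TestDerived:
    @pytest.mark.parametrize("beta0, beta1, pse", [(-12.0, 1.0, 12.0), (0.0, 2.0, 0.0)])
    def test_pse_closed_form(self, beta0, beta1, pse):
        fit = PsychometricFit("p", "c", beta0, beta1, pse, 1.0, 10, True)
        assert derive_pse(fit) == pse

    def test_pse_undefined_for_flat_fit(self):
        fit = PsychometricFit("p", "c", 0.5, 0.0, np.nan, np.nan, 10, True)
        with pytest.raises(UndefinedPSEError):
            derive_pse(fit)

    def test_jnd_closed_form_and_homogeneity(self):
        f1 = PsychometricFit("p", "c", -1.0, 1.0, 1.0, np.log(3), 10, True)
        f2 = PsychometricFit("p", "c", -1.0, 0.5, 2.0, 2 * np.log(3), 10, True)
        assert derive_jnd(f1) == pytest.approx(np.log(3))
        assert derive_jnd(f2) == pytest.approx(2 * derive_jnd(f1))
        fln3 = PsychometricFit("p", "c", -1.0, np.log(3), 1.0, 1.0, 10, True)
        assert derive_jnd(fln3) == pytest.approx(1.0)

    def test_jnd_undefined_for_nonpositive_slope(self):
        fit = PsychometricFit("p", "c", 1.0, -0.5, 2.0, np.nan, 10, True)
        with pytest.raises(UndefinedJNDError):
            derive_jnd(fit)


def _fit_with(pid, beta1=0.6, pse=12.0):
    beta0 = -pse * beta1
    return PsychometricFit(pid, "c", beta0, beta1, pse, np.log(3) / beta1, 96, True)


class TestScreening:
    def test_fences_match_brute_force_quartiles(self):
        vals = [1.0, 2.0, 3.0, 4.0, 100.0]
        q1, q3 = type7_quartiles(vals)
        lo, hi = tukey_fences(vals, 3.0)
        assert lo == pytest.approx(q1 - 3 * (q3 - q1))
        assert hi == pytest.approx(q3 + 3 * (q3 - q1))

    def test_gross_outlier_flagged(self):
        fits = [_fit_with(f"p{i}", pse=v) for i, v in enumerate([1, 2, 3, 4, 100])]
        report = screen_outliers(fits, k=3.0)
        assert report.flagged == ["p4"]
        assert any("pse" in r for r in report.reasons["p4"])

    def test_identical_participants_never_flagged(self):
        fits = [_fit_with(f"p{i}") for i in range(6)]
        report = screen_outliers(fits, k=3.0)
        assert report.flagged == []

    def test_backwards_responder_flagged_by_sign_check(self):
        fits = [_fit_with(f"p{i}", pse=12 + 0.1 * i) for i in range(6)]
        fits.append(PsychometricFit("back", "c", 7.2, -0.6, 12.0, np.nan, 96, True))
        report = screen_outliers(fits, k=3.0)
        assert "back" in report.flagged
        assert any("backwards" in r for r in report.reasons["back"])

    def test_too_few_participants_is_an_error(self):
        with pytest.raises(InsufficientSampleError):
            screen_outliers([_fit_with("a"), _fit_with("b"), _fit_with("c")], k=3.0)


class TestPooling:
    def test_identical_subjects_degenerate_bootstrap(self):
        fits = [_fit_with(f"p{i}", beta1=0.7, pse=10.0) for i in range(5)]
        pooled = pool_fits(fits, n_bootstrap=500, seed=0)
        assert pooled.pse == pytest.approx(10.0)
        assert pooled.pse_ci[0] == pytest.approx(pooled.pse_ci[1])

    def test_bootstrap_ci_deterministic_under_seed(self, afc_table):
        fits = psy.fit_participants(afc_table, by_condition=False)
        a = pool_fits(fits, n_bootstrap=500, seed=3)
        b = pool_fits(fits, n_bootstrap=500, seed=3)
        c = pool_fits(fits, n_bootstrap=500, seed=4)
        assert a.pse_ci == b.pse_ci
        assert a.pse_ci != c.pse_ci

    def test_pooling_invariant_to_participant_order(self, afc_table):
        fits = psy.fit_participants(afc_table, by_condition=False)
        assert pool_fits(fits, seed=0).pse == pytest.approx(
            pool_fits(fits[::-1], seed=0).pse
        )

    def test_all_nonconverged_is_a_pooling_error(self):
        sentinel = PsychometricFit("p", "c", -np.inf, np.inf, 9.0, 0.0, 10, False)
        with pytest.raises(PoolingError):
            pool_fits([sentinel])

    def test_boundary_biased_population_shifts_pse_below_criterion(self):
        """Repulsion from the sameness boundary inflates low-d percepts, so
        "more" responses start earlier and the pooled PSE drops below 12."""
        d = design.preset("E1", seed=101)
        obs = observer.make_observers(
            20, {"distortion": "boundary", "k": 6.0, "tau": 4.0, "sigma": 3.0,
                 "lapse": 0.0}, seed=55)
        table = observer.simulate_experiment(d, obs)
        pooled = pool_fits(psy.fit_participants(table, by_condition=False), seed=2)
        assert pooled.pse < 12.0
        assert pooled.pse_ci[1] < 12.0


class TestSplits:
    def test_identical_halves_give_zero_difference(self, afc_table):
        doubled = pd.concat(
            [afc_table, afc_table.assign(block=afc_table.block + 6)],
            ignore_index=True,
        )
        res = split_analysis(doubled, "half_by_trial_index", n_bootstrap=300, seed=0)
        assert res.pse_diff == pytest.approx(0.0, abs=1e-9)
        assert res.pse_diff_ci[0] == pytest.approx(0.0, abs=1e-9)

    def test_median_rt_split_runs_and_orders_halves(self, afc_table):
        res = split_analysis(afc_table, "median_rt", n_bootstrap=300, seed=0)
        assert res.first.n_participants == res.second.n_participants > 0

    def test_missing_rts_rejected_for_median_split(self, afc_table):
        broken = afc_table.copy()
        broken.loc[broken.index[:5], "rt_ms"] = np.nan
        with pytest.raises(EstimationError):
            split_analysis(broken, "median_rt")

    def test_drift_toward_anchor_moves_second_half_pse(self):
        """Observers whose early boundary repulsion (PSE below the stimulus
        mean) gives way to central-tendency shrinkage show a second-half PSE
        closer to the anchor 9 — the verbal task's neutral point."""
        d = design.preset("E2", seed=77)
        early = observer.make_observers(
            10, {"distortion": "boundary", "k": 6.0, "tau": 4.0,
                 "sigma": 2.0, "lapse": 0.0}, seed=88)
        late = observer.make_observers(
            10, {"distortion": "central_tendency", "w": 0.3, "anchor": 9.0,
                 "sigma": 2.0, "lapse": 0.0}, seed=88)
        frames = []
        for i, (e, l) in enumerate(zip(early, late)):
            pid = f"s{i + 1:03d}"
            t_e = observer.simulate_observer(d, e, pid)
            t_l = observer.simulate_observer(d, l, pid)
            half = len(t_e) // 2
            frames.append(t_e.iloc[:half])
            frames.append(t_l.iloc[half:])
        table = pd.concat(frames, ignore_index=True)
        res = split_analysis(table, "half_by_trial_index", n_bootstrap=300, seed=1)
        # shrinkage toward 9 raises low-d percepts: criterion crossed earlier
        assert abs(res.second.pse - 9.0) < abs(res.first.pse - 9.0)
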