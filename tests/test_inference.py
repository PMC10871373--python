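"""Terciles and mixed models: bookkeeping, reductions, sign recovery."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit

import neurochron as nc
from neurochron.inference import (
    _MixedLogit,
    fit_tercile_model,
    fit_tonic_outcome,
    fit_trial_logistic,
    partition_terciles,
)

from conftest import behaviour_session


class TestTerciles:
    def test_300_distinct_values_split_100_each(self):
        rng = np.random.default_rng(0)
        part = partition_terciles(rng.normal(size=300), np.zeros(300))
        assert part.counts().tolist() == [100, 100, 100]

    def test_remainder_goes_to_low_end(self):
        part = partition_terciles(np.array([1.0, 2, 3, 4, 5]), np.zeros(5))
        assert list(part.labels) == ["low", "low", "medium", "medium", "high"]

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=100)
        p = np.repeat([0, 1], 50)
        a = partition_terciles(v, p)
        b = partition_terciles(np.exp(3 * v), p)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_counts_conserved(self):
        rng = np.random.default_rng(2)
        for n in (7, 50, 299):
            part = partition_terciles(rng.normal(size=n), np.zeros(n))
            assert part.counts().sum() == n

    def test_all_equal_values_warns_stable_split(self):
        with pytest.warns(UserWarning, match="all-equal"):
            part = partition_terciles(np.ones(9), np.zeros(9))
        assert part.counts().tolist() == [3, 3, 3]
        assert list(part.labels[:3]) == ["low"] * 3  # stable: trial order


class TestMixedLogit:
    def test_marginal_loglik_matches_dense_integration_oracle(self):
        """Adaptive GH equals brute-force trapezoid over the random intercept."""
        rng = np.random.default_rng(3)
        n, g = 120, 4
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        groups = np.repeat(np.arange(g), n // g)
        b_true = rng.normal(0, 0.8, g)
        y = (rng.uniform(size=n) < expit(0.3 * X[:, 1] + b_true[groups])).astype(float)
        ml = _MixedLogit(X, y, groups)
        params = np.array([0.1, 0.4, np.log(0.7)])
        got = -ml.nll(params)
        # oracle: dense trapezoid over b per group
        tau = 0.7
        bgrid = np.linspace(-6 * tau, 6 * tau, 20_001)
        total = 0.0
        eta = X @ params[:-1]
        for gi in range(g):
            m = groups == gi
            ll = (
                y[m][:, None] * (eta[m][:, None] + bgrid[None, :])
                - np.log1p(np.exp(eta[m][:, None] + bgrid[None, :]))
            ).sum(axis=0)
            dens = np.exp(ll) * np.exp(-(bgrid**2) / (2 * tau**2)) / np.sqrt(2 * np.pi * tau**2)
            total += np.log(np.trapezoid(dens, bgrid))
        assert got == pytest.approx(total, abs=1e-6)

    def test_single_participant_reduces_to_plain_logistic(self):
        rec = behaviour_session(30, phasic_coupling=0.08)
        amp = rec.trials["truth_phasic_amp"].to_numpy()
        fit = fit_trial_logistic(rec.trials, amp, np.zeros(300))
        y = (rec.trials["response"] == "long").astype(float).to_numpy()
        dur = rec.trials["duration_s"].to_numpy()
        X = np.column_stack(
            [np.ones(300), (dur - dur.mean()) / dur.std(), (amp - amp.mean()) / amp.std()]
        )
        direct = sm.Logit(y, X).fit(disp=0)
        np.testing.assert_allclose(fit.beta, direct.params, atol=1e-4)

    def test_phasic_coupling_gives_negative_dopamine_beta(self):
        """Truth-amplitude summaries: beta < 0 in >=90% of seeds, 6-patient cohorts."""
        neg = 0
        n_seeds = 20
        for seed in range(n_seeds):
            frames, summaries, pids = [], [], []
            for p in range(3):
                rec = behaviour_session(40_000 + 10 * seed + p, phasic_coupling=0.08)
                frames.append(rec.trials)
                summaries.append(rec.trials["truth_phasic_amp"].to_numpy())
                pids.append(np.full(300, p))
            fit = fit_trial_logistic(
                pd.concat(frames, ignore_index=True),
                np.concatenate(summaries),
                np.concatenate(pids),
            )
            neg += fit.coef("dopamine")[0] < 0
        assert neg >= 0.9 * n_seeds

    def test_null_coupling_ci_covers_zero(self):
        covered = 0
        n_seeds = 30
        for seed in range(n_seeds):
            rec = behaviour_session(50_000 + seed)
            fit = fit_trial_logistic(
                rec.trials, rec.trials["truth_phasic_amp"].to_numpy(), np.zeros(300)
            )
            b, se, _, _ = fit.coef("dopamine")
            covered += (b - 1.96 * se) <= 0 <= (b + 1.96 * se)
        assert covered >= 0.9 * n_seeds

    def test_unit_rescaling_leaves_standardized_beta(self):
        rec = behaviour_session(31, phasic_coupling=0.08)
        amp = rec.trials["truth_phasic_amp"].to_numpy()
        a = fit_trial_logistic(rec.trials, amp, np.zeros(300))
        b = fit_trial_logistic(rec.trials, amp * 1e3, np.zeros(300))  # uM -> nM
        np.testing.assert_allclose(a.beta, b.beta, atol=1e-8)


class TestTercileModel:
    def test_reversed_labels_flip_beta_sign(self):
        rec = behaviour_session(32, phasic_coupling=0.08)
        part = partition_terciles(rec.trials["truth_phasic_amp"].to_numpy(), np.zeros(300))
        fit = fit_tercile_model(rec.trials, part)
        flipped = type(part)(
            labels=part.labels[::-1].copy(), codes=-part.codes, participants=part.participants
        )
        fit2 = fit_tercile_model(rec.trials, flipped)
        assert fit2.coef("tercile")[0] == pytest.approx(-fit.coef("tercile")[0], abs=1e-6)

    def test_injected_coupling_negative_beta_and_bp_ordering(self):
        """High-dopamine terciles: fewer 'long' responses, so beta < 0 and BP rises."""
        neg, ordered = 0, 0
        n_seeds = 20
        for seed in range(n_seeds):
            rec = behaviour_session(60_000 + seed, phasic_coupling=0.1)
            amp = rec.trials["truth_phasic_amp"].to_numpy()
            part = partition_terciles(amp, np.zeros(300))
            fit = fit_tercile_model(rec.trials, part)
            neg += fit.coef("tercile")[0] < 0
            fits = nc.indices_by_group(
                nc.ResponseSet.from_trials(rec.trials), labels=part.labels
            )
            by = {f.label: f.bp for f in fits}
            ordered += by["low"] < by["high"]
        assert neg >= 0.9 * n_seeds
        assert ordered >= 0.8 * n_seeds

    def test_random_terciles_null(self):
        covered = 0
        n_seeds = 20
        rng = np.random.default_rng(7)
        for seed in range(n_seeds):
            rec = behaviour_session(70_000 + seed)
            part = partition_terciles(rng.normal(size=300), np.zeros(300))
            fit = fit_tercile_model(rec.trials, part)
            b, se, _, _ = fit.coef("tercile")
            covered += (b - 1.96 * se) <= 0 <= (b + 1.96 * se)
        assert covered >= 0.9 * n_seeds


class TestTonicOutcome:
    def _cohort(self, seed, tonic_coupling, n_p=4):
        levels, fits, pids = [], [], []
        for p in range(n_p):
            rec = behaviour_session(seed + p, tonic_coupling=tonic_coupling)
            series = nc.ConcentrationSeries(rec.timestamps, rec.truth_da, rec.truth_5ht)
            tonic = nc.compute_tonic(series)
            lv, ft = nc.pf_by_tonic_window(rec.trials, tonic)
            levels.append(lv)
            fits.extend(ft)
            pids.append(np.full(len(lv), p))
        return np.concatenate(levels), fits, np.concatenate(pids)

    def test_tonic_coupling_positive_precision_beta(self):
        pos = 0
        n_seeds = 12
        for seed in range(n_seeds):
            lv, fits, pids = self._cohort(80_000 + 10 * seed, 0.3)
            fit = fit_tonic_outcome(lv, fits, pids, "precision")
            pos += fit.coef("tonic")[0] > 0
        assert pos >= 0.9 * n_seeds

    def test_phasic_only_coupling_accuracy_null(self):
        """Phasic-coupled, tonic-null cohorts: accuracy CI covers 0 in >=90% of seeds.

        120 s tonic windows give ~12 outcome rows per participant so the
        normal-reference CI is close to nominal at this cohort size.
        """
        covered = 0
        n_seeds = 20
        for seed in range(n_seeds):
            levels, fits, pids = [], [], []
            for p in range(6):
                rec = behaviour_session(90_000 + 40 * seed + p, phasic_coupling=0.08)
                series = nc.ConcentrationSeries(rec.timestamps, rec.truth_da, rec.truth_5ht)
                tonic = nc.compute_tonic(series, 120.0)
                lv, ft = nc.pf_by_tonic_window(rec.trials, tonic)
                levels.append(lv)
                fits.extend(ft)
                pids.append(np.full(len(lv), p))
            fit = fit_tonic_outcome(
                np.concatenate(levels), fits, np.concatenate(pids), "accuracy"
            )
            b, se, _, _ = fit.coef("tonic")
            covered += (b - 1.96 * se) <= 0 <= (b + 1.96 * se)
        assert covered >= 0.9 * n_seeds

    def test_constant_tonic_errors(self):
        fits = [
            nc.fit_pf(
                nc.ResponseSet.from_trials(behaviour_session(s).trials)
            )
            for s in range(4)
        ]
        with pytest.raises(ValueError, match="zero variance"):
            fit_tonic_outcome(np.ones(4), fits, np.repeat([0, 1], 2), "precision")

    def test_too_few_windows_errors(self):
        fits = [nc.fit_pf(nc.ResponseSet.from_trials(behaviour_session(0).trials))] * 3
        with pytest.raises(ValueError, match="<2 tonic windows"):
            fit_tonic_outcome(np.array([1.0, 1.1, 1.2]), fits, np.array([0, 0, 1]), "precision")

    def test_sign_consistent_across_window_lengths(self):
        """Coupled data: same-sign precision beta at 120/240/360 s windows."""
        signs = []
        for wl in (120.0, 240.0, 360.0):
            levels, fits, pids = [], [], []
            for p in range(4):
                rec = behaviour_session(95_000 + p, tonic_coupling=0.35)
                series = nc.ConcentrationSeries(rec.timestamps, rec.truth_da, rec.truth_5ht)
                tonic = nc.compute_tonic(series, wl)
                lv, ft = nc.pf_by_tonic_window(rec.trials, tonic)
                levels.append(lv)
                fits.extend(ft)
                pids.append(np.full(len(lv), p))
            fit = fit_tonic_outcome(np.concatenate(levels), fits, np.concatenate(pids), "precision")
            signs.append(np.sign(fit.coef("tonic")[0]))
        assert len(set(signs)) == 1
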