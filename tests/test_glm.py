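"""Design construction, GLM fitting, FIR peak window, t-patterns, gPPI."""

import numpy as np
import pandas as pd
import pytest

from gistmem.design import (
    build_design_matrix,
    canonical_hrf,
    cosine_drift,
    n_drift_terms,
    validate_events,
)
from gistmem.glm import (
    FIRCurve,
    ROITimeSeries,
    build_gppi_model,
    fir_deconvolve,
    fir_peak_window,
    fit_glm,
    fit_gppi,
    long_axis_label,
    relabel_events_by_confidence,
    single_trial_tmaps,
)

TR = 2.5


def event_frame(onsets, condition="old_neutral", duration=0.0):
    return pd.DataFrame({
        "onset": onsets, "duration": duration, "condition": condition,
        "trial_id": [f"t{i}" for i in range(len(onsets))],
    })


class TestDesign:
    def test_impulse_column_equals_sampled_hrf(self):
        X = build_design_matrix(event_frame([0.0]), tr=TR, n_scans=20,
                                add_drift=False, add_constant=False)
        expected = canonical_hrf(np.arange(20) * TR)
        # convolution kernel support is 48 s; beyond that the true HRF is < 1e-6
        assert np.allclose(X.matrix[:, 0], expected, atol=1e-6)
        within = np.arange(20) * TR < 48.0
        assert np.allclose(X.matrix[within, 0], expected[within], atol=1e-12)

    def test_fir_columns_disjoint_for_widely_spaced_events(self):
        events = event_frame(np.arange(0, 200, 25.0))  # > 15 s apart
        X = build_design_matrix(events, tr=TR, n_scans=100, basis="fir",
                                add_drift=False, add_constant=False)
        gram = X.matrix.T @ X.matrix
        off = gram - np.diag(np.diag(gram))
        assert np.all(off == 0)

    def test_drift_term_count_follows_cutoff_rule(self):
        # 832 scans at TR 2.5 s with a 128 s cutoff
        assert n_drift_terms(832, 2.5, 128.0) == int(2 * 832 * 2.5 // 128) + 1

    def test_drift_columns_orthogonal_to_constant(self):
        drift = cosine_drift(100, TR)
        assert np.allclose(drift.sum(axis=0), 0.0, atol=1e-10)

    def test_onset_beyond_run_rejected(self):
        with pytest.raises(ValueError, match="beyond run end"):
            build_design_matrix(event_frame([999.0]), tr=TR, n_scans=20)

    def test_nonincreasing_onsets_rejected(self):
        events = event_frame([10.0, 5.0])
        with pytest.raises(ValueError, match="strictly increasing"):
            validate_events(events)


class TestFitGLM:
    def _design(self, n_scans=120):
        events = event_frame(np.arange(5, n_scans * TR - 30, 20.0))
        return build_design_matrix(events, tr=TR, n_scans=n_scans)

    def test_noiseless_recovery_is_exact(self):
        X = self._design()
        beta_true = np.zeros(X.matrix.shape[1])
        beta_true[0] = 2.0
        beta_true[-1] = 5.0
        y = X.matrix @ beta_true
        fit = fit_glm(y, X)
        assert np.allclose(fit.beta, beta_true, atol=1e-8)

    def test_prewhitening_is_noop_for_white_noise(self, rng):
        X = self._design()
        y = X.matrix[:, 0] * 1.5 + rng.standard_normal(X.n_scans) * 0.01
        plain = fit_glm(y, X, prewhiten_ar1=False)
        white = fit_glm(y, X, prewhiten_ar1=True)
        # phi estimated from near-white residuals is ~0; betas barely move
        assert abs(white.phi) < 0.3
        assert np.allclose(plain.beta, white.beta, atol=1e-3)

    def test_ar1_betas_unbiased(self):
        # simulation oracle: AR(1) noise, phi = 0.4, mean beta within 2 MC SEs
        X = self._design(n_scans=150)
        phi, true_beta = 0.4, 1.0
        betas = []
        for rep in range(200):
            r = np.random.default_rng(rep)
            e = r.standard_normal(X.n_scans)
            noise = np.empty(X.n_scans)
            noise[0] = e[0] / np.sqrt(1 - phi**2)
            for t in range(1, X.n_scans):
                noise[t] = phi * noise[t - 1] + e[t]
            y = X.matrix[:, 0] * true_beta + noise
            betas.append(fit_glm(y, X, prewhiten_ar1=True).beta[0])
        mc_se = np.std(betas, ddof=1) / np.sqrt(len(betas))
        assert abs(np.mean(betas) - true_beta) < 2 * mc_se

    def test_rank_deficiency_names_columns(self):
        X = np.column_stack([np.ones(20), np.ones(20)])
        with pytest.raises(ValueError, match="collinear"):
            fit_glm(np.zeros(20), X, names=["a", "b"])


class TestFIR:
    def test_estimates_equal_selective_averages_when_nonoverlapping(self, rng):
        # events > 15 s apart: FIR bins have disjoint support, so the GLM
        # estimate at each lag equals the event-locked average (after the
        # drift fit, checked on a drift-free series with drift disabled)
        onsets = np.arange(10, 480, 25.0)
        events = event_frame(onsets)
        n_scans = 200
        shape = np.array([0.0, 0.5, 1.0, 0.8, 0.4, 0.1, 0.0])
        y = np.zeros(n_scans)
        scan_idx = np.rint(onsets / TR).astype(int)
        for i0 in scan_idx:
            y[i0:i0 + 7] += shape[: max(0, min(7, n_scans - i0))]
        X = build_design_matrix(events, tr=TR, n_scans=n_scans, basis="fir",
                                add_drift=False)
        fit = fit_glm(y, X)
        est = fit.beta[:7]
        averages = np.array([y[scan_idx + lag].mean() for lag in range(7)])
        assert np.allclose(est, averages, atol=1e-10)
        assert np.allclose(est, shape, atol=1e-10)

    def test_peak_invariant_to_constant_offset(self, rng):
        onsets = np.arange(10, 420, 22.0)
        events = event_frame(onsets)
        y = rng.standard_normal(180)
        ts0 = ROITimeSeries(samples=y, tr=TR)
        ts1 = ROITimeSeries(samples=y + 100.0, tr=TR)
        c0 = fir_deconvolve(ts0, events)
        c1 = fir_deconvolve(ts1, events)
        assert np.allclose(c0.estimates, c1.estimates, atol=1e-8)

    def _curves(self, mean_shape, noise_sd, n_subj=48, seed=0):
        rng = np.random.default_rng(seed)
        out = []
        for _ in range(n_subj):
            est = np.vstack([mean_shape + rng.standard_normal(7) * noise_sd
                             for _ in range(2)])
            out.append(FIRCurve(estimates=est, se=np.ones_like(est),
                                conditions=["a", "b"], tr=TR))
        return out

    def test_flat_curves_select_all_bins(self):
        # each participant's response is constant across bins: no bin can be
        # distinguished from the peak, so the whole window is selected
        rng = np.random.default_rng(0)
        curves = []
        for _ in range(20):
            level = rng.standard_normal()
            est = np.full((2, 7), level)
            curves.append(FIRCurve(estimates=est, se=np.ones_like(est),
                                   conditions=["a", "b"], tr=TR))
        peak = fir_peak_window(curves)
        assert peak.selected_bins == list(range(7))

    def test_single_dominant_bin_selected_alone(self):
        shape = np.array([0.0, 0.0, 50.0, 0.0, 0.0, 0.0, 0.0])
        curves = self._curves(shape, noise_sd=0.1)
        peak = fir_peak_window(curves)
        assert peak.selected_bins == [2]

    def test_plateau_shape_selects_5_and_7p5s_bins(self):
        # hippocampus-like response with a broad 5-7.5 s plateau
        shape = np.array([0.0, 0.35, 1.0, 0.99, 0.45, 0.15, 0.02])
        curves = self._curves(shape, noise_sd=0.2, seed=0)
        peak = fir_peak_window(curves)
        assert peak.selected_bins == [2, 3]  # 5 s and 7.5 s at TR 2.5 s
        assert peak.peak_bin in (2, 3)

    def test_peak_values_average_over_window(self):
        shape = np.array([0.0, 0.35, 1.0, 0.99, 0.45, 0.15, 0.02])
        curves = self._curves(shape, noise_sd=0.2, seed=0)
        peak = fir_peak_window(curves)
        expected = curves[0].estimates[0, peak.selected_bins].mean()
        assert peak.values.iloc[0]["a"] == pytest.approx(expected)

    def test_requires_two_participants(self):
        curves = self._curves(np.zeros(7), 0.1, n_subj=1)
        with pytest.raises(ValueError, match="2 participants"):
            fir_peak_window(curves)


class TestSingleTrialPatterns:
    def test_noiseless_patterns_rank_match_amplitudes(self, rng):
        onsets = np.arange(10, 400, 20.0)
        events = event_frame(onsets)
        n_scans, n_vox = 180, 6
        amp = np.linspace(0.2, 2.0, n_vox)
        ev = events.copy()
        ev["condition"] = ev["trial_id"]
        X = build_design_matrix(ev, tr=TR, n_scans=n_scans,
                                add_drift=False, add_constant=False)
        Y = X.matrix.sum(axis=1, keepdims=True) * amp + 0.001 * rng.standard_normal(
            (n_scans, n_vox))
        pat = single_trial_tmaps(Y, events, tr=TR)
        for row in pat.t_values:
            assert np.array_equal(np.argsort(row), np.argsort(amp))

    def test_pure_noise_mean_t_near_zero(self):
        rng = np.random.default_rng(9)
        onsets = np.arange(10, 400, 20.0)
        events = event_frame(onsets)
        Y = rng.standard_normal((180, 40))
        pat = single_trial_tmaps(Y, events, tr=TR)
        se = pat.t_values.std(ddof=1) / np.sqrt(pat.t_values.size)
        assert abs(pat.t_values.mean()) < 3 * se

    def test_dropped_trial_gives_smaller_matrix(self, rng):
        onsets = np.arange(10, 400, 20.0)
        events = event_frame(onsets).iloc[:-1]  # one trial lost
        Y = rng.standard_normal((180, 10))
        pat = single_trial_tmaps(Y, events, tr=TR)
        assert pat.n_trials == len(onsets) - 1

    def test_duplicate_onsets_rejected(self, rng):
        events = pd.DataFrame({"onset": [10.0, 10.0], "duration": 0.0,
                               "condition": ["a", "b"], "trial_id": ["t0", "t1"]})
        with pytest.raises(ValueError, match="onsets"):
            single_trial_tmaps(np.zeros((50, 4)), events, tr=TR)

    def test_identical_input_bit_identical_output(self, rng):
        onsets = np.arange(10, 300, 20.0)
        events = event_frame(onsets)
        Y = rng.standard_normal((130, 8))
        a = single_trial_tmaps(Y, events, tr=TR)
        b = single_trial_tmaps(Y.copy(), events.copy(), tr=TR)
        assert np.array_equal(a.t_values, b.t_values)


class TestGPPI:
    def _events(self, rng, n_trials=60, n_scans=400):
        conds = [f"{pt}_{emo}" for pt in ("old", "related", "novel")
                 for emo in ("negative", "neutral")]
        onset, rows = 8.0, []
        for i in range(n_trials):
            rows.append({"onset": onset, "duration": 3.5,
                         "condition": conds[i % 6], "trial_id": f"t{i}"})
            onset += 3.5 + 5 + 4 * rng.random()
        return pd.DataFrame(rows)

    def test_zero_seed_gives_zero_interactions(self, rng):
        events = self._events(rng)
        seed = ROITimeSeries(samples=np.zeros(400), tr=TR)
        model = build_gppi_model(seed, events)
        for name in model.interaction_names:
            assert np.all(model.design.column(name) == 0)

    def test_interaction_beta_recovery(self):
        # target = 0.8 x interaction(related_negative) + noise
        recovered = []
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            events = self._events(rng)
            seed_sig = rng.standard_normal(400)
            seed = ROITimeSeries(samples=seed_sig, tr=TR)
            model = build_gppi_model(seed, events)
            inter = model.design.column("ppi_related_negative")
            target = ROITimeSeries(
                samples=0.8 * inter + 0.5 * rng.standard_normal(400), tr=TR)
            betas = fit_gppi(target, model).set_index("condition")["beta"]
            recovered.append(betas["related_negative"])
        se = np.std(recovered, ddof=1) / np.sqrt(len(recovered))
        assert abs(np.mean(recovered) - 0.8) < 3 * se

    def test_null_interactions_centered_on_zero(self):
        vals = []
        for rep in range(20):
            rng = np.random.default_rng(200 + rep)
            events = self._events(rng)
            seed = ROITimeSeries(samples=rng.standard_normal(400), tr=TR)
            model = build_gppi_model(seed, events)
            target = ROITimeSeries(samples=rng.standard_normal(400), tr=TR)
            betas = fit_gppi(target, model)
            vals.extend(betas["beta"].tolist())
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals)) < 3 * se


class TestLongAxis:
    @pytest.mark.parametrize("y,expected", [
        (-35.0, "pHC"), (-40.0, "pHC"), (-30.0, "pHC"),
        (-29.0, "mHC"), (-19.0, "mHC"), (-25.0, "mHC"),
        (-18.0, "aHC"), (-10.0, "aHC"), (-4.0, "aHC"),
        (0.0, "outside"), (-50.0, "outside"), (-29.5, "outside"),
    ])
    def test_band_membership(self, y, expected):
        assert long_axis_label(y) == expected

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            long_axis_label(float("nan"))


class TestConfidenceRelabel:
    def _data(self):
        events = pd.DataFrame({
            "onset": [0.0, 12.0, 24.0, 36.0, 48.0],
            "duration": 3.5,
            "condition": "x",
            "trial_id": ["t0", "t1", "t2", "t3", "t4"],
        })
        responses = pd.DataFrame({
            "trial_id": ["t0", "t1", "t2", "t3", "t4"],
            "picture_type": ["old", "old", "related", "novel", "old"],
            "response": ["yes", "yes", "no", "no", "no"],
            "confidence": [3, 2, None, None, None],
        })
        return events, responses

    def test_five_condition_labels(self):
        events, responses = self._data()
        out = relabel_events_by_confidence(events, responses)
        assert list(out["condition"]) == [
            "high_conf_hit", "low_conf_hit", "related_cr", "novel_cr", "incorrect"]

    def test_counts_conserved(self):
        events, responses = self._data()
        out = relabel_events_by_confidence(events, responses)
        assert len(out) == len(events)

    def test_unmatched_trial_rejected(self):
        events, responses = self._data()
        with pytest.raises(ValueError, match="matching"):
            relabel_events_by_confidence(events, responses.iloc[:3])
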