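"""ROI-level GLM fitting, FIR deconvolution, single-trial patterns and gPPI.

The univariate route mirrors a standard event-related recognition analysis:
six Picture Type x Emotion regressors convolved with the canonical HRF,
cosine drift to a 128 s cutoff, and optional AR(1) prewhitening.  The FIR
route deconvolves the ROI-averaged time course into a 7-bin response shape
per condition and summarizes it by a group-defined peak window: the bins
whose group response (collapsed across conditions) is statistically
indistinguishable (paired t, p > 0.05, uncorrected) from the numerical peak
bin.

Single-trial t-patterns are estimated least-squares-all (one canonical
regressor per trial, all fitted simultaneously) and feed the RSA module.
gPPI interaction regressors are formed at the "neural" level as unconvolved
condition indicators multiplied by the mean-centered seed signal, then
convolved with the HRF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .design import DesignMatrix, build_design_matrix, canonical_hrf, validate_events

__all__ = [
    "ROITimeSeries",
    "GLMFit",
    "FIRCurve",
    "PeakResponse",
    "TrialPatternMatrix",
    "PPIModel",
    "fit_glm",
    "fir_deconvolve",
    "fir_peak_window",
    "single_trial_tmaps",
    "build_gppi_model",
    "fit_gppi",
    "long_axis_label",
    "relabel_events_by_confidence",
]


@dataclass
class ROITimeSeries:
    """ROI-averaged BOLD samples for one run."""

    samples: np.ndarray
    tr: float
    roi_label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("time series contains non-finite values")

    def __len__(self) -> int:
        return self.samples.size


@dataclass
class GLMFit:
    beta: np.ndarray
    se: np.ndarray
    sigma2: float
    df_resid: int
    names: list[str]
    phi: float | None = None  # AR(1) coefficient used for prewhitening

    def coef(self, name: str) -> float:
        return float(self.beta[self.names.index(name)])

    def tstat(self, name: str) -> float:
        i = self.names.index(name)
        return float(self.beta[i] / self.se[i])


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify dependent columns from the pivoted QR diagonal
        _, r, piv = _qr_pivot(X)
        bad = [names[j] for j in piv[rank:]]
        raise ValueError(f"design is rank deficient; collinear columns: {bad}")


def _qr_pivot(X: np.ndarray):
    from scipy.linalg import qr

    q, r, piv = qr(X, mode="economic", pivoting=True)
    return q, r, piv


def _ols(y: np.ndarray, X: np.ndarray):
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, resid


def fit_glm(
    ts: ROITimeSeries | np.ndarray,
    X: DesignMatrix | np.ndarray,
    prewhiten_ar1: bool = False,
    names: list[str] | None = None,
) -> GLMFit:
    """Ordinary least squares with optional one-pass AR(1) prewhitening.

    The AR(1) coefficient is estimated once from the lag-1 autocorrelation
    of the OLS residuals (single pooled value per series); both sides are
    then filtered (Prais-Winsten transform for the first sample) and the
    model refitted.  Standard errors come from the whitened fit.
    """
    y = ts.samples if isinstance(ts, ROITimeSeries) else np.asarray(ts, float).ravel()
    if isinstance(X, DesignMatrix):
        names = X.names
        Xm = X.matrix
    else:
        Xm = np.asarray(X, float)
        names = names or [f"x{i}" for i in range(Xm.shape[1])]
    if y.shape[0] != Xm.shape[0]:
        raise ValueError("time series length does not match design rows")
    _check_rank(Xm, names)

    beta, resid = _ols(y, Xm)
    phi = None
    if prewhiten_ar1:
        denom = float(resid @ resid)
        phi = float(resid[1:] @ resid[:-1] / denom) if denom > 0 else 0.0
        phi = float(np.clip(phi, -0.999, 0.999))
        w0 = np.sqrt(1.0 - phi**2)
        yw = np.empty_like(y)
        Xw = np.empty_like(Xm)
        yw[0] = w0 * y[0]
        Xw[0] = w0 * Xm[0]
        yw[1:] = y[1:] - phi * y[:-1]
        Xw[1:] = Xm[1:] - phi * Xm[:-1]
        beta, resid = _ols(yw, Xw)
        Xm = Xw
    df_resid = y.shape[0] - Xm.shape[1]
    sigma2 = float(resid @ resid) / df_resid
    xtx_inv = np.linalg.inv(Xm.T @ Xm)
    se = np.sqrt(sigma2 * np.diag(xtx_inv))
    return GLMFit(beta=beta, se=se, sigma2=sigma2, df_resid=df_resid, names=list(names), phi=phi)


@dataclass
class FIRCurve:
    """Deconvolved response shape: one row per condition, 7 lag bins."""

    estimates: np.ndarray  # (n_conditions, n_bins)
    se: np.ndarray
    conditions: list[str]
    tr: float

    def __post_init__(self) -> None:
        self.estimates = np.atleast_2d(np.asarray(self.estimates, float))
        self.se = np.atleast_2d(np.asarray(self.se, float))
        if self.estimates.shape != self.se.shape:
            raise ValueError("estimate and SE shapes differ")
        if self.estimates.shape[0] != len(self.conditions):
            raise ValueError("condition labels do not match estimate rows")

    @property
    def n_bins(self) -> int:
        return self.estimates.shape[1]

    @property
    def bin_times(self) -> np.ndarray:
        return np.arange(self.n_bins) * self.tr

    def collapsed(self) -> np.ndarray:
        """Mean response across conditions (one value per bin)."""
        return self.estimates.mean(axis=0)


def fir_deconvolve(
    ts: ROITimeSeries,
    events: pd.DataFrame,
    n_bins: int = 7,
    highpass_s: float = 128.0,
    prewhiten_ar1: bool = False,
) -> FIRCurve:
    """Deconvolve an ROI time course into per-condition FIR estimates."""
    X = build_design_matrix(
        events, tr=ts.tr, n_scans=len(ts), basis="fir", n_fir_bins=n_bins, highpass_s=highpass_s
    )
    fit = fit_glm(ts, X, prewhiten_ar1=prewhiten_ar1)
    # sorted so FIR curves align across participants whatever the trial order
    conditions = sorted(set(validate_events(events)["condition"]))
    est = np.empty((len(conditions), n_bins))
    se = np.empty_like(est)
    for i, cond in enumerate(conditions):
        for lag in range(n_bins):
            j = X.names.index(f"{cond}_fir{lag}")
            est[i, lag] = fit.beta[j]
            se[i, lag] = fit.se[j]
    return FIRCurve(estimates=est, se=se, conditions=conditions, tr=ts.tr)


@dataclass
class PeakResponse:
    """Group-defined peak window and per-participant condition peaks."""

    selected_bins: list[int]
    peak_bin: int
    bin_pvalues: np.ndarray  # paired-t p vs the peak bin (p of peak bin = 1)
    values: pd.DataFrame  # rows: participant, columns: conditions


def fir_peak_window(curves: list[FIRCurve]) -> PeakResponse:
    """Define the peak window across participants and extract peak values.

    Conditions are collapsed per participant; the bin with the largest
    group-mean response is the numerical peak.  Every other bin is compared
    to it with a two-tailed paired t-test across participants; the window
    is the peak bin plus all bins with p > 0.05 (uncorrected).  Each
    participant's per-condition peak value is the mean of that condition's
    estimates over the window.
    """
    if len(curves) < 2:
        raise ValueError("peak-window definition requires at least 2 participants")
    n_bins = curves[0].n_bins
    conditions = curves[0].conditions
    for c in curves[1:]:
        if c.n_bins != n_bins or c.conditions != conditions:
            raise ValueError("participants have inconsistent FIR structure")

    collapsed = np.vstack([c.collapsed() for c in curves])  # (n_subj, n_bins)
    peak_bin = int(np.argmax(collapsed.mean(axis=0)))
    pvals = np.ones(n_bins)
    selected = [peak_bin]
    for b in range(n_bins):
        if b == peak_bin:
            continue
        diff = collapsed[:, b] - collapsed[:, peak_bin]
        if np.allclose(diff, diff[0]):
            # zero-variance difference: identical bins count as indistinguishable
            pvals[b] = 1.0 if np.allclose(diff, 0.0) else 0.0
        else:
            pvals[b] = float(_sps.ttest_rel(collapsed[:, b], collapsed[:, peak_bin]).pvalue)
        if pvals[b] > 0.05:
            selected.append(b)
    selected = sorted(selected)

    rows = {
        cond: [c.estimates[i, selected].mean() for c in curves]
        for i, cond in enumerate(conditions)
    }
    values = pd.DataFrame(rows)
    return PeakResponse(
        selected_bins=selected, peak_bin=peak_bin, bin_pvalues=pvals, values=values
    )


@dataclass
class TrialPatternMatrix:
    """Trial x voxel t-values with per-trial labels."""

    t_values: np.ndarray
    labels: pd.DataFrame  # columns include trial_id, picture_type, emotion, pair_id

    def __post_init__(self) -> None:
        self.t_values = np.asarray(self.t_values, dtype=float)
        if self.t_values.ndim != 2:
            raise ValueError("pattern matrix must be 2-D (trials x voxels)")
        if self.t_values.shape[1] < 2:
            raise ValueError("at least 2 voxels required")
        if len(self.labels) != self.t_values.shape[0]:
            raise ValueError("labels do not match trial rows")
        if not np.all(np.isfinite(self.t_values)):
            raise ValueError("pattern matrix contains non-finite values")

    @property
    def n_trials(self) -> int:
        return self.t_values.shape[0]


def single_trial_tmaps(
    voxel_series: np.ndarray,
    events: pd.DataFrame,
    tr: float,
    method: str = "lsa",
    highpass_s: float = 128.0,
    labels: pd.DataFrame | None = None,
) -> TrialPatternMatrix:
    """Estimate per-trial activity patterns as voxelwise t-values.

    ``lsa`` (default) fits all trial regressors simultaneously in one GLM
    per voxel; ``lss`` fits each trial against the aggregate of all other
    trials.  Rows are ordered by trial onset.
    """
    Y = np.asarray(voxel_series, dtype=float)
    if Y.ndim != 2:
        raise ValueError("voxel series must be n_scans x n_voxels")
    ev = validate_events(events).sort_values("onset").reset_index(drop=True)
    if ev["onset"].duplicated().any():
        raise ValueError("overlapping identical onsets are not estimable per trial")
    n_scans = Y.shape[0]
    trial_events = ev.copy()
    trial_events["condition"] = trial_events["trial_id"].astype(str)

    if method == "lsa":
        X = build_design_matrix(trial_events, tr=tr, n_scans=n_scans, highpass_s=highpass_s)
        B, _, _, _ = np.linalg.lstsq(X.matrix, Y, rcond=None)
        resid = Y - X.matrix @ B
        df = n_scans - X.matrix.shape[1]
        if df <= 0:
            raise ValueError("design has no residual degrees of freedom")
        sigma2 = (resid**2).sum(axis=0) / df
        xtx_inv_diag = np.diag(np.linalg.inv(X.matrix.T @ X.matrix))
        tmat = np.empty((len(trial_events), Y.shape[1]))
        for i, tid in enumerate(trial_events["condition"]):
            j = X.names.index(tid)
            se = np.sqrt(sigma2 * xtx_inv_diag[j])
            tmat[i] = B[j] / se
    elif method == "lss":
        tmat = np.empty((len(trial_events), Y.shape[1]))
        for i in range(len(trial_events)):
            ev_i = trial_events.copy()
            ev_i["condition"] = np.where(
                np.arange(len(ev_i)) == i, "this_trial", "other_trials"
            )
            X = build_design_matrix(ev_i, tr=tr, n_scans=n_scans, highpass_s=highpass_s)
            j = X.names.index("this_trial")
            B, _, _, _ = np.linalg.lstsq(X.matrix, Y, rcond=None)
            resid = Y - X.matrix @ B
            df = n_scans - X.matrix.shape[1]
            sigma2 = (resid**2).sum(axis=0) / df
            se = np.sqrt(sigma2 * np.diag(np.linalg.inv(X.matrix.T @ X.matrix))[j])
            tmat[i] = B[j] / se
    else:
        raise ValueError(f"unknown method {method!r}")

    if labels is None:
        lab = ev[["trial_id", "condition"]].copy()
    else:
        lab = labels.set_index("trial_id").loc[ev["trial_id"]].reset_index()
    return TrialPatternMatrix(t_values=tmat, labels=lab)


@dataclass
class PPIModel:
    """gPPI design: psychological + interaction + seed + nuisance columns."""

    design: DesignMatrix
    psych_names: list[str]
    interaction_names: list[str]
    seed_name: str = "seed"


def build_gppi_model(
    seed: ROITimeSeries,
    events: pd.DataFrame,
    n_scans: int | None = None,
    highpass_s: float = 128.0,
) -> PPIModel:
    """Build a generalized PPI design from a seed series and task events.

    One psychological (HRF-convolved) regressor and one interaction
    regressor per task condition.  The interaction is formed at the neural
    level as (unconvolved condition boxcar) x (mean-centered seed), then
    convolved with the canonical HRF.  The raw seed time course enters as
    its own regressor; cosine drift and a constant complete the model.
    """
    n_scans = n_scans or len(seed)
    if len(seed) != n_scans:
        raise ValueError("seed length does not match the design")
    ev = validate_events(events)
    task = build_design_matrix(
        ev, tr=seed.tr, n_scans=n_scans, basis="canonical",
        highpass_s=highpass_s, add_drift=False, add_constant=False,
    )
    conditions = list(task.names)
    t_scan = np.arange(n_scans) * seed.tr
    hrf = canonical_hrf(np.arange(0.0, 48.0, seed.tr))
    seed_c = seed.samples - seed.samples.mean()

    cols = [task.matrix[:, i] for i in range(task.matrix.shape[1])]
    names = [f"psych_{c}" for c in conditions]
    inter_names = []
    for cond in conditions:
        grp = ev[ev["condition"] == cond]
        indicator = np.zeros(n_scans, dtype=bool)
        for onset, duration in zip(grp["onset"], grp["duration"]):
            dur = max(duration, seed.tr)
            indicator |= (t_scan >= onset) & (t_scan < onset + dur)
        inter = np.convolve(indicator.astype(float) * seed_c, hrf)[:n_scans]
        cols.append(inter)
        name = f"ppi_{cond}"
        names.append(name)
        inter_names.append(name)
    cols.append(seed.samples)
    names.append("seed")

    from .design import cosine_drift

    drift = cosine_drift(n_scans, seed.tr, highpass_s)
    for j in range(drift.shape[1]):
        cols.append(drift[:, j])
        names.append(f"drift{j + 1}")
    cols.append(np.ones(n_scans))
    names.append("constant")

    design = DesignMatrix(
        matrix=np.column_stack(cols), names=names, tr=seed.tr,
        highpass_s=highpass_s, n_task=2 * len(conditions),
    )
    return PPIModel(
        design=design,
        psych_names=[f"psych_{c}" for c in conditions],
        interaction_names=inter_names,
    )


def fit_gppi(
    target: ROITimeSeries, model: PPIModel, prewhiten_ar1: bool = False
) -> pd.DataFrame:
    """Fit the gPPI model to a target ROI; returns interaction betas + SEs."""
    fit = fit_glm(target, model.design, prewhiten_ar1=prewhiten_ar1)
    rows = []
    for name in model.interaction_names:
        i = model.design.names.index(name)
        rows.append(
            {
                "condition": name.removeprefix("ppi_"),
                "beta": fit.beta[i],
                "se": fit.se[i],
                "t": fit.beta[i] / fit.se[i],
            }
        )
    return pd.DataFrame(rows)


# MNI Y-coordinate bands for the hippocampal long axis (inclusive, mm)
LONG_AXIS_BANDS = {
    "pHC": (-40.0, -30.0),
    "mHC": (-29.0, -19.0),
    "aHC": (-18.0, -4.0),
}


def long_axis_label(y_mni: float) -> str:
    """Label an MNI Y coordinate as aHC / mHC / pHC / outside."""
    if not np.isfinite(y_mni):
        raise ValueError("Y coordinate must be finite")
    for label, (lo, hi) in LONG_AXIS_BANDS.items():
        if lo <= y_mni <= hi:
            return label
    return "outside"


def relabel_events_by_confidence(
    events: pd.DataFrame, responses: pd.DataFrame
) -> pd.DataFrame:
    """Relabel task events into five behavior-conditioned conditions.

    High-confidence hits (hit with confidence 3), low-confidence hits
    (confidence 0-2), related correct rejections, novel correct rejections,
    and all incorrect answers (misses, false alarms and non-responses).
    """
    ev = validate_events(events)
    resp = responses.set_index("trial_id")
    missing = [t for t in ev["trial_id"] if t not in resp.index]
    if missing:
        raise ValueError(f"events without matching responses: {missing[:5]}")

    labels = []
    for tid in ev["trial_id"]:
        r = resp.loc[tid]
        ptype, answer = r["picture_type"], r["response"]
        if ptype == "old" and answer == "yes":
            conf = r["confidence"]
            if pd.isna(conf):
                raise ValueError(f"hit without confidence rating on trial {tid}")
            labels.append("high_conf_hit" if int(conf) == 3 else "low_conf_hit")
        elif ptype == "related" and answer == "no":
            labels.append("related_cr")
        elif ptype == "novel" and answer == "no":
            labels.append("novel_cr")
        else:
            labels.append("incorrect")
    out = ev.copy()
    out["condition"] = labels
    return out
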