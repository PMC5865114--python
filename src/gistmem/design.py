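"""Hemodynamic response, drift bases and GLM design construction.

Designs are built for a single event-related run sampled at the repetition
time TR.  Two task bases are supported:

``canonical``
    duration boxcars (impulses for zero-duration events) convolved with the
    canonical double-gamma HRF on an oversampled grid, then sampled at scan
    times;
``fir``
    finite-impulse-response sticks, one column per condition and
    post-stimulus lag (default 7 lags of one TR, covering 0-15 s at
    TR = 2.5 s), estimating the response shape without assuming an HRF.

Low-frequency drift is modelled with a discrete-cosine basis inside the
design (cutoff default 128 s) rather than by pre-filtering, which keeps
ordinary least squares exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _sps

EVENT_COLUMNS = ("onset", "duration", "condition", "trial_id")

__all__ = [
    "EVENT_COLUMNS",
    "DesignMatrix",
    "canonical_hrf",
    "validate_events",
    "n_drift_terms",
    "cosine_drift",
    "build_design_matrix",
]


def _raw_hrf(t: np.ndarray) -> np.ndarray:
    # double gamma: response peak ~5-6 s, undershoot ~16 s, ratio 1/6
    h = _sps.gamma.pdf(t, 6.0) - _sps.gamma.pdf(t, 16.0) / 6.0
    return np.where(t < 0, 0.0, h)


# unit-peak normalization constant, computed once on a fine grid
_HRF_PEAK = float(_raw_hrf(np.arange(0.0, 32.0, 1e-3)).max())


def canonical_hrf(t) -> np.ndarray:
    """Canonical double-gamma HRF, normalized to unit peak amplitude.

    Parameters
    ----------
    t : array-like
        Time points in seconds (values < 0 map to 0).
    """
    return _raw_hrf(np.asarray(t, dtype=float)) / _HRF_PEAK


def validate_events(events: pd.DataFrame) -> pd.DataFrame:
    """Validate an event table (onset/duration/condition/trial_id).

    Onsets must be nonnegative and strictly increasing within each
    condition; durations must be nonnegative.  Returns the table with
    columns coerced to the expected dtypes.
    """
    missing = [c for c in ("onset", "duration", "condition") if c not in events.columns]
    if missing:
        raise ValueError(f"event table missing columns: {missing}")
    ev = events.copy()
    ev["onset"] = ev["onset"].astype(float)
    ev["duration"] = ev["duration"].astype(float)
    if "trial_id" not in ev.columns:
        ev["trial_id"] = [f"trial{i:04d}" for i in range(len(ev))]
    if (ev["onset"] < 0).any():
        raise ValueError("event onsets must be nonnegative")
    if (ev["duration"] < 0).any():
        raise ValueError("event durations must be nonnegative")
    for cond, grp in ev.groupby("condition", sort=False):
        if not np.all(np.diff(grp["onset"].to_numpy()) > 0):
            raise ValueError(f"onsets not strictly increasing within condition {cond!r}")
    return ev


def n_drift_terms(n_scans: int, tr: float, highpass_s: float = 128.0) -> int:
    """Number of cosine drift regressors for a given run length and cutoff.

    Rule: ``floor(2 * n_scans * TR / cutoff) + 1`` non-constant cosines,
    so every cosine with period longer than the cutoff is represented.
    """
    return int(np.floor(2.0 * n_scans * tr / highpass_s)) + 1


def cosine_drift(n_scans: int, tr: float, highpass_s: float = 128.0) -> np.ndarray:
    """Discrete-cosine drift basis (columns are zero-mean, unit-norm)."""
    k = n_drift_terms(n_scans, tr, highpass_s)
    i = np.arange(n_scans)
    cols = [
        np.sqrt(2.0 / n_scans) * np.cos(np.pi * j * (2 * i + 1) / (2.0 * n_scans))
        for j in range(1, k + 1)
    ]
    return np.column_stack(cols)


@dataclass
class DesignMatrix:
    """A run-level GLM design: matrix, column names and sampling info."""

    matrix: np.ndarray
    names: list[str]
    tr: float
    highpass_s: float = 128.0
    n_task: int = 0  # leading columns that model the task

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.names):
            raise ValueError("design matrix shape does not match column names")

    @property
    def n_scans(self) -> int:
        return self.matrix.shape[0]

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.names)

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]


def _condition_regressor_fine(
    events: pd.DataFrame, n_fine: int, dt: float
) -> np.ndarray:
    """Neural-level signal on the oversampled grid.

    Zero-duration events are unit impulses; positive durations are unit
    boxcars scaled by dt so that their convolution approximates the
    integral of the HRF over the stimulus window.
    """
    s = np.zeros(n_fine)
    for onset, duration in zip(events["onset"], events["duration"]):
        i0 = int(round(onset / dt))
        if i0 >= n_fine:
            raise ValueError(f"event onset {onset} s beyond run end")
        if duration <= dt:
            s[i0] += 1.0
        else:
            i1 = min(int(round((onset + duration) / dt)), n_fine)
            s[i0:i1] += dt
    return s


def build_design_matrix(
    events: pd.DataFrame,
    tr: float,
    n_scans: int,
    basis: str = "canonical",
    n_fir_bins: int = 7,
    highpass_s: float = 128.0,
    oversample: int = 16,
    add_drift: bool = True,
    add_constant: bool = True,
    extra_regressors: dict[str, np.ndarray] | None = None,
) -> DesignMatrix:
    """Build a GLM design for one run.

    Parameters
    ----------
    events : DataFrame
        Columns onset, duration, condition (and optionally trial_id).
    basis : {"canonical", "fir"}
        Canonical double-gamma convolution or FIR sticks at lags
        0..n_fir_bins-1 TRs (events assigned to the nearest scan).
    extra_regressors : dict, optional
        Named nuisance columns appended after the task columns.
    """
    if tr <= 0:
        raise ValueError("TR must be positive")
    ev = validate_events(events)
    run_end = n_scans * tr
    if (ev["onset"] >= run_end).any():
        bad = ev.loc[ev["onset"] >= run_end, "onset"].iloc[0]
        raise ValueError(f"event onset {bad} s beyond run end ({run_end} s)")

    conditions = list(dict.fromkeys(ev["condition"]))
    cols: list[np.ndarray] = []
    names: list[str] = []

    if basis == "canonical":
        dt = tr / oversample
        n_fine = n_scans * oversample
        hrf = canonical_hrf(np.arange(0.0, 48.0, dt))
        for cond in conditions:
            s = _condition_regressor_fine(ev[ev["condition"] == cond], n_fine, dt)
            reg = np.convolve(s, hrf)[:n_fine]
            cols.append(reg[:: oversample])
            names.append(str(cond))
    elif basis == "fir":
        for cond in conditions:
            onsets = ev.loc[ev["condition"] == cond, "onset"].to_numpy()
            scan_idx = np.rint(onsets / tr).astype(int)
            for lag in range(n_fir_bins):
                col = np.zeros(n_scans)
                idx = scan_idx + lag
                idx = idx[idx < n_scans]
                np.add.at(col, idx, 1.0)
                cols.append(col)
                names.append(f"{cond}_fir{lag}")
    else:
        raise ValueError(f"unknown basis {basis!r}")

    n_task = len(cols)
    for name, col in zip(names[:n_task], cols[:n_task]):
        if not np.any(col):
            raise ValueError(f"task column {name!r} is all zero")

    if extra_regressors:
        for name, col in extra_regressors.items():
            col = np.asarray(col, dtype=float)
            if col.shape != (n_scans,):
                raise ValueError(f"extra regressor {name!r} has wrong length")
            cols.append(col)
            names.append(name)

    if add_drift:
        drift = cosine_drift(n_scans, tr, highpass_s)
        for j in range(drift.shape[1]):
            cols.append(drift[:, j])
            names.append(f"drift{j + 1}")
    if add_constant:
        cols.append(np.ones(n_scans))
        names.append("constant")

    return DesignMatrix(
        matrix=np.column_stack(cols),
        names=names,
        tr=tr,
        highpass_s=highpass_s,
        n_task=n_task,
    )
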