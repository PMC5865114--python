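"""Synthetic cohorts for the recognition-memory pipeline.

Emulates the study design the downstream analyses assume: two groups
(recognition test 1 day vs 28 days after encoding) of 24 subjects; 180
recognition trials per subject (60 old pictures, 60 related lures sharing
an old picture's gist, 60 novel lures; half negative, half neutral);
group-dependent rates of detailed / gist (transformed) / forgotten pairs;
voxel patterns in three hippocampal-like ROIs with a tunable pair-level
gist component; and BOLD series at TR 2.5 s with jittered inter-trial
intervals of 7 +/- 2 s, low-frequency drift and AR(1) noise.

Latent memory states drive the behavior:

* ``detailed``  -> "yes" to the old picture (high confidence), "no" to the lure;
* ``gist``      -> "yes" to the related lure (a gist false alarm; the old
  picture is also endorsed with probability ``gist_old_yes_prob``);
* ``forgotten`` -> "no" to both.

Voxel patterns follow ``pattern = c*h_all + oc*h_old + a*g(pair) + b*u(trial)
+ eps`` with all latents standard normal per voxel: ``h_all`` shared by every
trial, ``h_old`` by all old trials, ``g`` by an old picture and its related
lure (novel trials draw their own), ``u`` trial-unique and ``eps`` i.i.d.
Gaussian noise.  With only the gist term active, the expected Pearson r
between an old picture and its lure is a^2 / (a^2 + b^2 + sigma^2).

All numeric defaults are free parameters chosen to reproduce the
qualitative group pattern (fewer detailed, more transformed and forgotten
pairs after 28 days; weaker anterior activity and more gist-like posterior
patterns at the long delay); see docs/methods.md.

Each subject draws from an independent RNG stream derived from the master
seed and the subject's (group, index), so any subject is reproducible in
isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .behavior import SubjectBehavior
from .design import build_design_matrix, cosine_drift
from .glm import ROITimeSeries, TrialPatternMatrix

__all__ = [
    "SimulationConfig",
    "simulate_memory_states",
    "generate_responses",
    "generate_patterns",
    "generate_events",
    "generate_bold",
    "generate_voxel_bold",
    "simulate_subject",
    "simulate_cohort",
    "subject_rng",
]

GROUPS = ("1d", "28d")
STATES = ("detailed", "gist", "forgotten")
ROIS = ("aHC", "mHC", "pHC")


def _per(value, *keys, default=0.0):
    """Resolve a scalar or nested dict keyed by ROI and/or group."""
    v = value
    for key in keys:
        if isinstance(v, dict):
            v = v.get(key, v.get(None, default))
    if isinstance(v, dict):
        raise KeyError(f"no entry for {keys} in {value!r}")
    return float(v)


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort; defaults are the study conditions."""

    n_per_group: int = 24
    n_pairs: int = 60
    n_novel: int = 60
    # (p_detailed, p_gist, p_forgotten) per group; must sum to 1
    state_probs: dict = field(
        default_factory=lambda: {"1d": (0.70, 0.15, 0.15), "28d": (0.30, 0.35, 0.35)}
    )
    # additive log-odds shift of (gist, forgotten) rates for negative items
    emotion_shift: tuple = (0.3, -0.3)
    gist_old_yes_prob: float = 0.75
    novel_fa_prob: dict = field(default_factory=lambda: {"1d": 0.02, "28d": 0.05})
    # confidence distributions over ratings 0-3 for "yes" responses
    confidence_probs: dict = field(
        default_factory=lambda: {
            "detailed": (0.0, 0.05, 0.20, 0.75),
            "gist": (0.10, 0.45, 0.35, 0.10),
            "novel_fa": (0.30, 0.40, 0.20, 0.10),
        }
    )
    # pattern-model weights; nested dicts keyed by ROI then group
    gist_weight: dict = field(
        default_factory=lambda: {
            "aHC": {"1d": 0.2, "28d": 0.3},
            "mHC": {"1d": 0.3, "28d": 0.6},
            "pHC": {"1d": 0.4, "28d": 0.8},
        }
    )
    old_common_weight: dict = field(
        default_factory=lambda: {
            "aHC": {"1d": 0.8, "28d": 0.3},
            "mHC": {"1d": 0.6, "28d": 0.3},
            "pHC": {"1d": 0.4, "28d": 0.2},
        }
    )
    # component shared by all old AND related trials (set-level gist):
    # the representational regime the "Old and Related Similar" model expects
    memory_set_weight: dict = field(
        default_factory=lambda: {
            "aHC": {"1d": 0.0, "28d": 0.1},
            "mHC": {"1d": 0.0, "28d": 0.3},
            "pHC": {"1d": 0.1, "28d": 0.5},
        }
    )
    common_weight: dict = field(
        default_factory=lambda: {"aHC": 0.1, "mHC": 0.35, "pHC": 0.7}
    )
    item_weight: float = 1.0
    pattern_noise_sd: float = 1.0
    n_voxels: int = 120
    rois: tuple = ROIS
    # BOLD timing and noise
    tr_seconds: float = 2.5
    n_scans: int = 832
    stim_duration_s: float = 3.5
    iti_mean_s: float = 7.0
    iti_jitter_s: float = 2.0  # uniform on mean +/- jitter
    ar1_phi: float = 0.3
    bold_noise_sd: float = 1.0
    drift_amplitude: float = 0.5
    # per-ROI, per-group event amplitude of the ROI-mean response
    roi_activation: dict = field(
        default_factory=lambda: {
            "aHC": {"1d": 1.0, "28d": 0.5},
            "mHC": {"1d": 1.0, "28d": 0.7},
            "pHC": {"1d": 0.9, "28d": 0.9},
        }
    )
    rng_seed: int = 0

    def validate(self) -> None:
        for group, probs in self.state_probs.items():
            p = np.asarray(probs, float)
            if p.size != 3 or np.any(p < 0) or np.any(p > 1):
                raise ValueError(f"state_probs[{group}] must be 3 probabilities in [0,1]")
            if abs(p.sum() - 1.0) > 1e-12:
                raise ValueError(f"state_probs[{group}] must sum to 1 (got {p.sum()})")
        if self.item_weight < 0 or self.pattern_noise_sd < 0:
            raise ValueError("item_weight and pattern_noise_sd must be nonnegative")
        for roi in self.rois:
            if _per(self.gist_weight, roi, "1d") < 0:
                raise ValueError("gist_weight must be nonnegative")
        if self.n_voxels < 2:
            raise ValueError("n_voxels must be >= 2")
        if self.tr_seconds <= 0:
            raise ValueError("TR must be positive")
        if not -1.0 < self.ar1_phi < 1.0:
            raise ValueError("ar1_phi must lie in (-1, 1)")

    def to_dict(self) -> dict:
        return asdict(self)


def subject_rng(config: SimulationConfig, group: str, subject_index: int) -> np.random.Generator:
    """Independent, reproducible RNG stream for one subject."""
    gi = GROUPS.index(group)
    ss = np.random.SeedSequence(entropy=config.rng_seed, spawn_key=(gi, subject_index))
    return np.random.default_rng(ss)


def simulate_memory_states(
    config: SimulationConfig, group: str, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw one latent memory state per pair from the group's distribution.

    The first half of the pairs is negative, the second half neutral; for
    negative pairs the gist and forgotten probabilities are shifted on the
    log scale by ``emotion_shift`` and renormalized.
    """
    config.validate()
    if group not in config.state_probs:
        raise KeyError(f"unknown group {group!r}; known: {list(config.state_probs)}")
    base = np.asarray(config.state_probs[group], float)
    d_gist, d_forg = config.emotion_shift
    shifted = base * np.exp([0.0, d_gist, d_forg])
    shifted = shifted / shifted.sum()

    n = config.n_pairs
    rows = []
    for i in range(n):
        emotion = "negative" if i < n // 2 else "neutral"
        probs = shifted if emotion == "negative" else base
        state = STATES[rng.choice(3, p=probs)]
        rows.append({"pair_id": f"p{i:03d}", "emotion": emotion, "state": state})
    return pd.DataFrame(rows)


def _trial_labels(states: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Canonical 180-trial label table (old block, related block, novel block)."""
    rows = []
    for _, s in states.iterrows():
        rows.append({"trial_id": f"old_{s.pair_id}", "picture_id": f"old_{s.pair_id}",
                     "picture_type": "old", "emotion": s.emotion, "pair_id": s.pair_id})
        rows.append({"trial_id": f"rel_{s.pair_id}", "picture_id": f"rel_{s.pair_id}",
                     "picture_type": "related", "emotion": s.emotion, "pair_id": s.pair_id})
    for i in range(config.n_novel):
        emotion = "negative" if i < config.n_novel // 2 else "neutral"
        rows.append({"trial_id": f"nov_{i:03d}", "picture_id": f"nov_{i:03d}",
                     "picture_type": "novel", "emotion": emotion, "pair_id": None})
    df = pd.DataFrame(rows)
    return pd.concat(
        [df[df.picture_type == "old"], df[df.picture_type == "related"],
         df[df.picture_type == "novel"]],
        ignore_index=True,
    )


def generate_responses(
    states: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
    subject_id: str = "s000",
    group: str = "1d",
    shuffle: bool = True,
) -> SubjectBehavior:
    """Turn latent pair states into a subject's trial-by-trial responses."""
    labels = _trial_labels(states, config)
    state_by_pair = states.set_index("pair_id")["state"]
    fa_p = _per(config.novel_fa_prob, group)

    def draw_conf(kind: str) -> int:
        return int(rng.choice(4, p=np.asarray(config.confidence_probs[kind], float)))

    records = []
    for _, t in labels.iterrows():
        resp, conf = "no", None
        if t.picture_type == "old":
            st = state_by_pair[t.pair_id]
            if st == "detailed":
                resp, conf = "yes", draw_conf("detailed")
            elif st == "gist" and rng.random() < config.gist_old_yes_prob:
                resp, conf = "yes", draw_conf("gist")
        elif t.picture_type == "related":
            if state_by_pair[t.pair_id] == "gist":
                resp, conf = "yes", draw_conf("gist")
        else:  # novel
            if rng.random() < fa_p:
                resp, conf = "yes", draw_conf("novel_fa")
        records.append({**t.to_dict(), "response": resp, "confidence": conf})
    trials = pd.DataFrame(records)
    if shuffle:
        trials = trials.sample(frac=1.0, random_state=rng.integers(2**31)).reset_index(drop=True)
    return SubjectBehavior(subject_id=subject_id, group=group, trials=trials)


def generate_patterns(
    states: pd.DataFrame,
    config: SimulationConfig,
    roi_label: str,
    rng: np.random.Generator,
    group: str = "1d",
    labels: pd.DataFrame | None = None,
) -> TrialPatternMatrix:
    """Simulate trial x voxel activity patterns for one ROI.

    ``labels`` overrides the canonical trial ordering (rows must carry
    trial_id / picture_type / pair_id), e.g. to match event order.
    """
    config.validate()
    if labels is None:
        labels = _trial_labels(states, config)
    nv = config.n_voxels
    a = _per(config.gist_weight, roi_label, group)
    oc = _per(config.old_common_weight, roi_label, group)
    ms = _per(config.memory_set_weight, roi_label, group)
    c = _per(config.common_weight, roi_label, group)
    b = config.item_weight
    sd = config.pattern_noise_sd

    h_all = rng.standard_normal(nv)
    h_old = rng.standard_normal(nv)
    h_set = rng.standard_normal(nv)
    gist = {pid: rng.standard_normal(nv) for pid in states["pair_id"]}

    rows = []
    for _, t in labels.iterrows():
        if t.picture_type in ("old", "related"):
            g = gist[t.pair_id]
        else:
            g = rng.standard_normal(nv)  # novel: own gist-level latent
        pat = c * h_all + a * g + b * rng.standard_normal(nv)
        if t.picture_type == "old":
            pat = pat + oc * h_old
        if t.picture_type in ("old", "related"):
            pat = pat + ms * h_set
        if sd > 0:
            pat = pat + sd * rng.standard_normal(nv)
        rows.append(pat)
    return TrialPatternMatrix(t_values=np.vstack(rows), labels=labels.reset_index(drop=True))


def generate_events(
    trials: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Jittered event onsets for a trial table, in presentation order.

    Stimulus duration ``stim_duration_s``; inter-trial interval uniform on
    ``iti_mean_s +/- iti_jitter_s``.  Conditions are picture_type x emotion.
    Raises if the run would overrun ``n_scans * TR``.
    """
    run_end = config.n_scans * config.tr_seconds
    onset = 0.0
    rows = []
    for _, t in trials.iterrows():
        if onset >= run_end - 20.0:
            raise ValueError("events overrun the scan; increase n_scans or shorten ITI")
        rows.append({"onset": round(onset, 3), "duration": config.stim_duration_s,
                     "condition": f"{t.picture_type}_{t.emotion}", "trial_id": t.trial_id})
        iti = config.iti_mean_s + config.iti_jitter_s * (2.0 * rng.random() - 1.0)
        onset += config.stim_duration_s + iti
    return pd.DataFrame(rows)


def _ar1_noise(n: int, phi: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """AR(1) noise initialized from its stationary distribution."""
    e = rng.standard_normal(n) * sd
    x = np.empty(n)
    x[0] = e[0] / np.sqrt(1.0 - phi**2)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + e[t]
    return x


def _drift(config: SimulationConfig, rng: np.random.Generator, n_slow: int = 3) -> np.ndarray:
    basis = cosine_drift(config.n_scans, config.tr_seconds, 256.0)[:, :n_slow]
    coefs = rng.standard_normal(n_slow)
    return config.drift_amplitude * np.sqrt(config.n_scans) * (basis @ coefs)


def generate_bold(
    events: pd.DataFrame,
    amplitudes: dict,
    config: SimulationConfig,
    rng: np.random.Generator,
    roi_label: str = "",
) -> ROITimeSeries:
    """ROI-mean BOLD: HRF-convolved events + drift + AR(1) noise."""
    config.validate()
    X = build_design_matrix(
        events, tr=config.tr_seconds, n_scans=config.n_scans,
        basis="canonical", add_drift=False, add_constant=False,
    )
    missing = [c for c in X.names if c not in amplitudes]
    if missing:
        raise ValueError(f"no amplitude given for conditions: {missing}")
    amp = np.array([amplitudes[c] for c in X.names])
    clean = X.matrix @ amp
    noise = (
        _ar1_noise(config.n_scans, config.ar1_phi, config.bold_noise_sd, rng)
        if config.bold_noise_sd > 0
        else np.zeros(config.n_scans)
    )
    drift = _drift(config, rng) if config.drift_amplitude > 0 else np.zeros(config.n_scans)
    return ROITimeSeries(samples=clean + drift + noise, tr=config.tr_seconds, roi_label=roi_label)


def generate_voxel_bold(
    events: pd.DataFrame,
    patterns: TrialPatternMatrix,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Voxel-wise BOLD (n_scans x n_voxels) driven by per-trial patterns.

    Each trial's regressor is scaled per voxel by the pattern value, so a
    single-trial GLM recovers (a noisy version of) the planted patterns.
    """
    ev = events.copy()
    ev["condition"] = ev["trial_id"].astype(str)
    X = build_design_matrix(
        ev, tr=config.tr_seconds, n_scans=config.n_scans,
        basis="canonical", add_drift=False, add_constant=False,
    )
    order = [X.names.index(str(t)) for t in patterns.labels["trial_id"]]
    D = X.matrix[:, order]
    Y = D @ patterns.t_values
    for v in range(Y.shape[1]):
        Y[:, v] += _drift(config, rng) + _ar1_noise(
            config.n_scans, config.ar1_phi, config.bold_noise_sd, rng
        )
    return Y


def simulate_subject(
    config: SimulationConfig,
    group: str,
    subject_index: int,
    with_patterns: bool = True,
    with_bold: bool = False,
) -> dict:
    """Simulate one subject: behavior, events and (optionally) fMRI data.

    Returns a dict with keys ``behavior`` (SubjectBehavior), ``states``,
    ``events``, and when requested ``patterns`` (per ROI) and ``bold``
    (per-ROI ROITimeSeries of the ROI-mean response).
    """
    rng = subject_rng(config, group, subject_index)
    states = simulate_memory_states(config, group, rng)
    subject_id = f"{group}_s{subject_index:02d}"
    behavior = generate_responses(states, config, rng, subject_id=subject_id, group=group)
    events = generate_events(behavior.trials, config, rng)
    out = {"subject_id": subject_id, "group": group, "states": states,
           "behavior": behavior, "events": events}
    if with_patterns:
        out["patterns"] = {
            roi: generate_patterns(
                states, config, roi, rng, group=group,
                labels=behavior.trials[["trial_id", "picture_id", "picture_type",
                                        "emotion", "pair_id"]],
            )
            for roi in config.rois
        }
    if with_bold:
        conditions = [f"{pt}_{emo}" for pt in ("old", "related", "novel")
                      for emo in ("negative", "neutral")]
        out["bold"] = {}
        for roi in config.rois:
            act = _per(config.roi_activation, roi, group)
            amps = {c: act for c in conditions}
            out["bold"][roi] = generate_bold(events, amps, config, rng, roi_label=roi)
    return out


def simulate_cohort(
    config: SimulationConfig, with_patterns: bool = True, with_bold: bool = False
) -> list[dict]:
    """Simulate the full two-group cohort (n_per_group subjects per group)."""
    config.validate()
    return [
        simulate_subject(config, group, i, with_patterns=with_patterns, with_bold=with_bold)
        for group in GROUPS
        for i in range(config.n_per_group)
    ]
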