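"""File I/O and the end-to-end pipeline.

Canonical tabular dialect is TSV (tab-delimited, UTF-8, header row); CSV is
accepted on read.  Numeric matrices (pattern matrices, time series) are
plain whitespace text.  ``run_pipeline`` chains the stages —
simulate -> behavior -> FIR -> RSA -> gPPI -> stats — on a synthetic
cohort and emits a manifest with the config snapshot, seed, output paths
and SHA-256 digests, so a rerun with the same seed is hash-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as bhv
from . import glm, rsa, stats
from .behavior import SubjectBehavior
from .simulate import GROUPS, SimulationConfig, simulate_cohort

__all__ = [
    "read_table",
    "write_responses",
    "read_responses",
    "write_events",
    "read_events",
    "write_matrix",
    "read_matrix",
    "RunManifest",
    "run_pipeline",
]

RESPONSE_COLUMNS = (
    "subject_id", "group", "trial_id", "picture_id", "pair_id", "picture_type",
    "emotion", "response", "confidence",
)


def read_table(path) -> pd.DataFrame:
    """Read a TSV (or CSV) table with a header row."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep)


def write_responses(subjects: list[SubjectBehavior], path) -> Path:
    """Write all subjects' trial records to one responses TSV."""
    rows = []
    for s in subjects:
        t = s.trials.copy()
        t.insert(0, "subject_id", s.subject_id)
        t.insert(1, "group", s.group)
        rows.append(t[list(RESPONSE_COLUMNS)])
    path = Path(path)
    pd.concat(rows, ignore_index=True).to_csv(path, sep="\t", index=False)
    return path


def read_responses(path) -> list[SubjectBehavior]:
    """Read a responses TSV back into validated per-subject records.

    Raises with the offending row/column on schema violations (missing
    columns, confidence on a non-"yes" response, ...).
    """
    df = read_table(path)
    missing = [c for c in RESPONSE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"responses file missing columns: {missing}")
    subjects = []
    for (sid, group), grp in df.groupby(["subject_id", "group"], sort=False):
        trials = grp.drop(columns=["subject_id", "group"]).reset_index(drop=True)
        try:
            subjects.append(SubjectBehavior(subject_id=str(sid), group=str(group), trials=trials))
        except ValueError as err:
            raise ValueError(f"subject {sid!r}: {err}") from err
    return subjects


def write_events(events: pd.DataFrame, path) -> Path:
    path = Path(path)
    events.to_csv(path, sep="\t", index=False)
    return path


def read_events(path) -> pd.DataFrame:
    from .design import validate_events

    return validate_events(read_table(path))


def write_matrix(matrix: np.ndarray, path) -> Path:
    path = Path(path)
    np.savetxt(path, np.asarray(matrix, float), fmt="%.10g")
    return path


def read_matrix(path) -> np.ndarray:
    return np.loadtxt(path)


def read_nifti_roi_series(image_path, mask_path, tr: float) -> dict:
    """ROI-mean time series from a 4-D NIfTI and an integer-labelled mask.

    Returns ``{label: ROITimeSeries}`` for every nonzero mask label.
    Requires nibabel (optional dependency).
    """
    import nibabel as nib

    from .glm import ROITimeSeries

    img = np.asanyarray(nib.load(str(image_path)).dataobj)
    mask = np.asanyarray(nib.load(str(mask_path)).dataobj)
    if img.ndim != 4:
        raise ValueError("expected a 4-D functional image")
    if mask.shape != img.shape[:3]:
        raise ValueError("mask shape does not match image volumes")
    out = {}
    for label in np.unique(mask):
        if label == 0:
            continue
        voxels = img[mask == label]  # (n_voxels, n_scans)
        out[int(label)] = ROITimeSeries(
            samples=voxels.mean(axis=0), tr=tr, roi_label=str(int(label))
        )
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record for one pipeline run."""

    seed: int
    config: dict
    outputs: dict = field(default_factory=dict)  # name -> {path, sha256}
    version: str = ""

    def add(self, name: str, path: Path) -> None:
        self.outputs[name] = {"path": str(path), "sha256": _sha256(Path(path))}

    def write(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(
            {"seed": self.seed, "version": self.version, "config": self.config,
             "outputs": self.outputs}, indent=2, default=str))
        return path


def _behavior_stage(subjects, out: Path, manifest: RunManifest) -> pd.DataFrame:
    table = bhv.group_behavior_table(subjects)
    p = out / "behavior_long.tsv"
    table.to_csv(p, sep="\t", index=False)
    manifest.add("behavior_long", p)
    return table


def _fir_stage(cohort, config, out: Path, manifest: RunManifest) -> pd.DataFrame:
    rows = []
    for roi in config.rois:
        curves, meta = [], []
        for subj in cohort:
            curve = glm.fir_deconvolve(subj["bold"][roi], subj["events"])
            curves.append(curve)
            meta.append((subj["subject_id"], subj["group"]))
        peak = glm.fir_peak_window(curves)
        for (sid, group), (_, vals) in zip(meta, peak.values.iterrows()):
            for cond, value in vals.items():
                ptype, emotion = cond.rsplit("_", 1)
                rows.append({"subject_id": sid, "group": group, "roi": roi,
                             "picture_type": ptype, "emotion": emotion,
                             "peak": value,
                             "window_bins": ",".join(map(str, peak.selected_bins))})
    df = pd.DataFrame(rows)
    p = out / "fir_peaks.tsv"
    df.to_csv(p, sep="\t", index=False)
    manifest.add("fir_peaks", p)
    return df


def _rsa_stage(cohort, config, out: Path, manifest: RunManifest) -> pd.DataFrame:
    rows = []
    rdms = {roi: {} for roi in config.rois}
    for subj in cohort:
        for roi in config.rois:
            rdm = rsa.compute_rdm(subj["patterns"][roi])
            rdms[roi][subj["subject_id"]] = (subj["group"], rdm)
            fits = {}
            for model_name in rsa.MODEL_NAMES:
                model = rsa.build_model_rdm(rdm.labels["picture_type"], model_name)
                fits[model_name] = rsa.model_fit(rdm, model)
            rows.append({"subject_id": subj["subject_id"], "group": subj["group"],
                         "roi": roi,
                         "mean_similarity": rsa.mean_pattern_similarity(rdm),
                         **{f"fit_{m}": v for m, v in fits.items()}})
    df = pd.DataFrame(rows)
    # cross-group similarity: 28d single-subject RDMs vs 1d group average
    cross = []
    for roi in config.rois:
        ref = rsa.average_rdm(
            [r for g, r in rdms[roi].values() if g == "1d"]
        )
        for sid, (g, r) in rdms[roi].items():
            if g == "28d":
                cross.append({"subject_id": sid, "roi": roi,
                              "spearman_vs_1d_avg": rsa.cross_group_similarity(r, ref)})
    p = out / "rsa_summary.tsv"
    df.to_csv(p, sep="\t", index=False)
    manifest.add("rsa_summary", p)
    p2 = out / "rsa_cross_group.tsv"
    pd.DataFrame(cross).to_csv(p2, sep="\t", index=False)
    manifest.add("rsa_cross_group", p2)
    return df


def _ppi_stage(cohort, config, out: Path, manifest: RunManifest,
               seed_roi: str = "aHC", target_roi: str = "pHC") -> pd.DataFrame:
    rows = []
    for subj in cohort:
        model = glm.build_gppi_model(subj["bold"][seed_roi], subj["events"])
        betas = glm.fit_gppi(subj["bold"][target_roi], model)
        for _, r in betas.iterrows():
            rows.append({"subject_id": subj["subject_id"], "group": subj["group"],
                         "seed": seed_roi, "target": target_roi,
                         "condition": r["condition"], "beta": r["beta"], "t": r["t"]})
    df = pd.DataFrame(rows)
    p = out / "ppi_betas.tsv"
    df.to_csv(p, sep="\t", index=False)
    manifest.add("ppi_betas", p)
    return df


def _stats_stage(behavior_table, fir_df, rsa_df, out: Path, manifest: RunManifest) -> pd.DataFrame:
    results = []

    def record(analysis, table):
        for _, r in table.iterrows():
            results.append({"analysis": analysis, **r.to_dict()})

    hits = behavior_table.query("measure == 'hit_pct' and emotion != 'all'")
    record("hits_group_x_emotion", stats.mixed_anova(
        hits, dv="value", subject="subject_id", between="group", within=["emotion"]))
    fa = behavior_table.query("measure == 'fa_pct' and emotion != 'all'")
    record("fa_group_x_type_x_emotion", stats.mixed_anova(
        fa, dv="value", subject="subject_id", between="group",
        within=["picture_type", "emotion"]))
    conf = behavior_table.query("measure == 'confidence_score'")
    record("confidence_group", stats.mixed_anova(
        conf, dv="value", subject="subject_id", between="group"))
    if fir_df is not None and len(fir_df):
        for roi, grp in fir_df.groupby("roi"):
            record(f"fir_peak_{roi}", stats.mixed_anova(
                grp, dv="peak", subject="subject_id", between="group",
                within=["picture_type", "emotion"]))
        collapsed = fir_df.groupby(["subject_id", "group", "roi"], as_index=False)["peak"].mean()
        record("fir_peak_group_x_axis", stats.mixed_anova(
            collapsed, dv="peak", subject="subject_id", between="group", within=["roi"]))
    if rsa_df is not None and len(rsa_df):
        record("similarity_group_x_axis", stats.mixed_anova(
            rsa_df, dv="mean_similarity", subject="subject_id",
            between="group", within=["roi"]))
    df = pd.DataFrame(results)
    p = out / "stats_results.tsv"
    df.to_csv(p, sep="\t", index=False)
    manifest.add("stats_results", p)
    return df


def run_pipeline(
    config: SimulationConfig | None = None,
    out_dir="gistmem_out",
    seed: int | None = None,
    with_bold: bool = True,
) -> RunManifest:
    """Run simulate -> behavior -> FIR -> RSA -> gPPI -> stats end to end.

    Every source of randomness flows from the manifest seed.  Stage
    failures abort with the stage name and cause.
    """
    config = config or SimulationConfig()
    if seed is not None:
        config.rng_seed = seed
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from importlib.metadata import version as _v

    try:
        pkg_version = _v("gistmem")
    except Exception:
        pkg_version = "unknown"
    manifest = RunManifest(seed=config.rng_seed, config=config.to_dict(), version=pkg_version)

    stage = "simulate"
    try:
        cohort = simulate_cohort(config, with_patterns=True, with_bold=with_bold)
        subjects = [s["behavior"] for s in cohort]
        manifest.add("responses", write_responses(subjects, out / "responses.tsv"))
        stage = "behavior"
        behavior_table = _behavior_stage(subjects, out, manifest)
        fir_df = ppi_df = rsa_df = None
        if with_bold:
            stage = "fir"
            fir_df = _fir_stage(cohort, config, out, manifest)
            stage = "ppi"
            ppi_df = _ppi_stage(cohort, config, out, manifest)
        stage = "rsa"
        rsa_df = _rsa_stage(cohort, config, out, manifest)
        stage = "stats"
        _stats_stage(behavior_table, fir_df, rsa_df, out, manifest)
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    manifest.write(out / "manifest.json")
    return manifest
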