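"""Representational similarity analysis on single-trial activity patterns.

Dissimilarity between two trials is the correlation distance 1 - r
(Pearson) between their voxel patterns.  RDMs are summarized by the mean
pattern similarity (mean of 1 - d over the strictly lower triangle),
compared across groups by Spearman correlation of single-subject RDMs with
a reference (group-average) RDM, and fitted against two categorical model
RDMs:

``old_distinct``
    old trials share a pattern that is distinct from related and novel
    trials (old-old cells 0, all other cells 1);
``old_related_similar``
    old and related trials share a pattern distinct from novel trials
    (cells within {old, related} 0, any cell involving a novel trial 1).

The prose behind these models does not constrain related-related or
novel-novel cells under ``old_distinct``; the default fills every
non-"similar" cell with 1, and a masked variant excludes the unconstrained
cells from the fit.  Lower-triangle vectorization is row-major over i > j
throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _sps

__all__ = [
    "RDM",
    "ModelRDM",
    "compute_rdm",
    "mean_pattern_similarity",
    "average_rdm",
    "rank_scale_rdm",
    "cross_group_similarity",
    "build_model_rdm",
    "model_fit",
    "compare_model_fits",
    "lower_triangle",
    "plot_rdm",
]

MODEL_NAMES = ("old_distinct", "old_related_similar")


@dataclass
class RDM:
    """Square symmetric trial dissimilarity matrix (1 - Pearson r)."""

    values: np.ndarray
    labels: pd.DataFrame | None = None  # per-trial labels aligned to rows

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("RDM must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("RDM must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("RDM diagonal must be zero")
        self.values = v
        if self.labels is not None and len(self.labels) != v.shape[0]:
            raise ValueError("labels do not match RDM size")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class ModelRDM:
    """Categorical (0/1) dissimilarity hypothesis over the same trials."""

    values: np.ndarray
    name: str
    mask: np.ndarray | None = None  # True where the model constrains the cell

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape does not match model")


def lower_triangle(matrix: np.ndarray) -> np.ndarray:
    """Strictly-lower-triangle cells, row-major over i > j."""
    m = np.asarray(matrix)
    i, j = np.tril_indices(m.shape[0], k=-1)
    return m[i, j]


def compute_rdm(patterns) -> RDM:
    """Trial x trial correlation-distance RDM from a pattern matrix.

    Accepts a :class:`~gistmem.glm.TrialPatternMatrix` or a plain
    (n_trials x n_voxels) array; entry (i, j) = 1 - Pearson r between the
    two trial patterns.
    """
    labels = getattr(patterns, "labels", None)
    X = np.asarray(getattr(patterns, "t_values", patterns), dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 trials and 2 voxels")
    sd = X.std(axis=1)
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"trial {bad} has a constant pattern (zero variance)")
    d = 1.0 - np.corrcoef(X)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return RDM(values=d, labels=labels)


def mean_pattern_similarity(rdm: RDM) -> float:
    """Mean similarity r = mean of (1 - d) over the lower triangle."""
    if rdm.n < 2:
        raise ValueError("mean similarity undefined for a 1x1 RDM")
    return float(np.mean(1.0 - lower_triangle(rdm.values)))


def average_rdm(rdms: list[RDM]) -> RDM:
    """Cell-wise mean of same-sized, same-ordered RDMs."""
    if not rdms:
        raise ValueError("no RDMs to average")
    n = rdms[0].n
    if any(r.n != n for r in rdms):
        sizes = sorted({r.n for r in rdms})
        raise ValueError(f"RDMs have mixed sizes {sizes}; exclude before averaging")
    return RDM(values=np.mean([r.values for r in rdms], axis=0), labels=rdms[0].labels)


def rank_scale_rdm(rdm: RDM) -> RDM:
    """Rank-transform the off-diagonal cells and scale them into [0, 1].

    Used for visualization only: average ranks for ties, so rank order is
    preserved and any strictly monotone transform of the input yields the
    same output.  The diagonal stays 0.
    """
    vec = lower_triangle(rdm.values)
    if np.allclose(vec, vec[0]):
        raise ValueError("all off-diagonal values identical; rank scaling undefined")
    ranks = _sps.rankdata(vec, method="average")
    scaled = (ranks - 1.0) / (len(vec) - 1.0)
    out = np.zeros_like(rdm.values)
    i, j = np.tril_indices(rdm.n, k=-1)
    out[i, j] = scaled
    out[j, i] = scaled
    return RDM(values=out, labels=rdm.labels)


def cross_group_similarity(single: RDM, reference: RDM) -> float:
    """Spearman correlation of two RDMs' lower-triangle vectors."""
    if single.n != reference.n:
        raise ValueError("RDM sizes differ")
    rho = _sps.spearmanr(lower_triangle(single.values), lower_triangle(reference.values))
    return float(rho.statistic)


def build_model_rdm(
    picture_types, model: str, masked: bool = False
) -> ModelRDM:
    """Build a categorical model RDM from per-trial picture-type labels.

    ``old_distinct``: 0 for old-old cells, 1 elsewhere.
    ``old_related_similar``: 0 for cells within {old, related}, 1 for any
    cell involving a novel trial.  With ``masked=True``, cells the model
    prose leaves unconstrained (within-related and within-novel for
    ``old_distinct``; within-novel for ``old_related_similar``) are
    excluded from fitting.
    """
    types = np.asarray(
        picture_types["picture_type"] if isinstance(picture_types, pd.DataFrame) else picture_types
    )
    unknown = set(types) - {"old", "related", "novel"}
    if unknown:
        raise ValueError(f"unknown picture types: {sorted(unknown)}")
    if model not in MODEL_NAMES:
        raise ValueError(f"model must be one of {MODEL_NAMES}")

    old = types == "old"
    related = types == "related"
    novel = types == "novel"
    if model == "old_distinct":
        similar = np.outer(old, old)
        unconstrained = np.outer(related, related) | np.outer(novel, novel)
    else:
        memb = old | related
        similar = np.outer(memb, memb)
        unconstrained = np.outer(novel, novel)
    values = np.where(similar, 0.0, 1.0)
    np.fill_diagonal(values, 0.0)
    mask = None
    if masked:
        mask = ~unconstrained
        np.fill_diagonal(mask, False)
    return ModelRDM(values=values, name=model, mask=mask)


def model_fit(rdm: RDM, model: ModelRDM) -> float:
    """Spearman correlation between a brain RDM and a model RDM.

    Computed over the strictly-lower-triangle cells; cells excluded by the
    model's mask are dropped from both vectors.
    """
    if rdm.values.shape != model.values.shape:
        raise ValueError("RDM and model dimensions differ")
    x = lower_triangle(rdm.values)
    y = lower_triangle(model.values)
    if model.mask is not None:
        keep = lower_triangle(model.mask)
        x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("fewer than 3 usable cells")
    return float(_sps.spearmanr(x, y).statistic)


def compare_model_fits(
    fits_a, fits_b, direction: str = "greater"
) -> dict:
    """One-tailed paired t-test comparing per-subject model fits.

    ``direction="greater"`` tests fits_a > fits_b.  Returns t, df,
    one-tailed p, and Cohen's d (mean difference / SD of differences).
    """
    a = np.asarray(fits_a, float)
    b = np.asarray(fits_b, float)
    if a.shape != b.shape:
        raise ValueError("paired fit vectors have different lengths")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    diff = a - b
    sd = diff.std(ddof=1)
    if sd == 0:
        if np.allclose(diff, 0.0):
            # identical fits: no evidence either way
            return {"t": 0.0, "df": a.size - 1, "p": 0.5, "cohen_d": 0.0}
        raise ValueError("zero variance of paired differences; t undefined")
    n = a.size
    t = diff.mean() / (sd / np.sqrt(n))
    df = n - 1
    if direction == "greater":
        p = float(_sps.t.sf(t, df))
    elif direction == "less":
        p = float(_sps.t.cdf(t, df))
    else:
        raise ValueError("direction must be 'greater' or 'less'")
    return {"t": float(t), "df": df, "p": p, "cohen_d": float(diff.mean() / sd)}


def plot_rdm(rdm: RDM, ax=None, rank_scaled: bool = True, **imshow_kw):
    """Heatmap of a (by default rank-scaled) RDM; requires matplotlib."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    shown = rank_scale_rdm(rdm) if rank_scaled else rdm
    im = ax.imshow(shown.values, cmap="viridis", **imshow_kw)
    ax.set_xlabel("trial")
    ax.set_ylabel("trial")
    return im
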