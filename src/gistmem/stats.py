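"""Inferential statistics for the behavioral and ROI-level analyses.

The workhorse is a balanced mixed-design ANOVA (one between-subject factor,
up to two within-subject factors) reporting generalized eta squared and,
for within effects with more than 1 numerator df, Mauchly's sphericity test
with Greenhouse-Geisser corrected p-values.  Sums of squares use the
classical balanced-design decomposition (with a complete, balanced grid the
Type I/II/III distinctions vanish).

Also provided: Welch and paired t-tests with Cohen's d, the Pearson
correlation t-test, the Shapiro-Wilk normality test, and the Pearson-Filon
(1898) z-test for comparing two overlapping dependent correlations that
share one variable.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats as _sps

__all__ = [
    "mixed_anova",
    "welch_t",
    "paired_t",
    "pearson_test",
    "pearson_filon_z",
    "shapiro_wilk",
    "bonferroni",
]


def _u_sum(df: pd.DataFrame, dv: str, by: list[str]) -> float:
    """Uncorrected sum of squares: sum over cells of (cell total)^2 / n_cell."""
    if not by:
        return float(df[dv].sum() ** 2 / len(df))
    g = df.groupby(by, observed=True)[dv].agg(["sum", "count"])
    return float((g["sum"] ** 2 / g["count"]).sum())


def _orthonormal_contrast(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrast matrix orthogonal to the constant."""
    # QR of the centering projector yields an orthonormal basis of contrasts
    helmert = np.zeros((k - 1, k))
    for i in range(k - 1):
        helmert[i, : i + 1] = 1.0
        helmert[i, i + 1] = -(i + 1.0)
    q, _ = np.linalg.qr(helmert.T)
    return q.T  # (k-1) x k, rows orthonormal, row sums 0


def _sphericity(
    cell_means: pd.DataFrame, contrast: np.ndarray, groups: pd.Series
) -> dict:
    """Greenhouse-Geisser epsilon and Mauchly test from subject x cell scores.

    ``cell_means``: subjects x within-cells matrix; ``contrast``: k x cells
    orthonormal contrast for the effect; ``groups``: between level per
    subject (pooled within-group covariance).
    """
    Z = cell_means.to_numpy() @ contrast.T  # subjects x k
    k = Z.shape[1]
    glabels = groups.loc[cell_means.index]
    Zc = Z - np.vstack([Z[(glabels == g).to_numpy()].mean(axis=0) for g in glabels])
    n_groups = glabels.nunique()
    d_err = Z.shape[0] - n_groups
    if d_err <= k:
        return {"W": np.nan, "chi2": np.nan, "p_sphericity": np.nan, "epsilon": np.nan}
    S = Zc.T @ Zc / d_err
    tr = np.trace(S)
    tr2 = np.trace(S @ S)
    eps = float(tr**2 / (k * tr2)) if tr2 > 0 else np.nan
    det = np.linalg.det(S)
    if det <= 0 or tr <= 0:
        return {"W": 0.0, "chi2": np.inf, "p_sphericity": 0.0, "epsilon": eps}
    W = float(det / (tr / k) ** k)
    f = 1.0 - (2.0 * k**2 + k + 2.0) / (6.0 * k * d_err)
    chi2 = float(-f * d_err * np.log(W))
    df = k * (k + 1) // 2 - 1
    p = float(_sps.chi2.sf(chi2, df)) if df > 0 else 1.0
    return {"W": W, "chi2": chi2, "p_sphericity": p, "epsilon": eps}


def _validate_layout(
    data: pd.DataFrame, dv: str, subject: str, between: str | None, within: list[str]
) -> None:
    cols = [dv, subject] + ([between] if between else []) + within
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"table missing columns: {missing}")
    if data[cols].isna().any().any():
        raise ValueError("table contains missing values")
    if between:
        per_subj = data.groupby(subject, observed=True)[between].nunique()
        if (per_subj > 1).any():
            bad = per_subj[per_subj > 1].index.tolist()
            raise ValueError(f"subjects appear in more than one group: {bad}")
    if within:
        counts = data.groupby([subject] + within, observed=True)[dv].count()
        if (counts != 1).any():
            raise ValueError("need exactly one observation per subject x within-cell")
        levels = [sorted(data[w].unique()) for w in within]
        full = set(itertools.product(*levels))
        missing_cells = []
        for subj, grp in data.groupby(subject, observed=True):
            have = set(map(tuple, grp[within].itertuples(index=False)))
            if have != full:
                missing_cells.append((subj, sorted(full - have)))
        if missing_cells:
            raise ValueError(f"missing within-cells: {missing_cells[:5]}")
    if between:
        sizes = data.groupby(between, observed=True)[subject].nunique()
        if sizes.nunique() > 1:
            raise ValueError(f"unbalanced groups: {sizes.to_dict()} (balanced design required)")


def mixed_anova(
    data: pd.DataFrame,
    dv: str,
    subject: str,
    between: str | None = None,
    within: list[str] | str | None = None,
) -> pd.DataFrame:
    """Balanced mixed-design ANOVA with generalized eta squared.

    Supports one optional between-subject factor and up to two
    within-subject factors with one observation per subject x cell.
    Between-subject effects are tested against subjects-within-groups;
    each within effect against its own factor-by-subject interaction.
    Generalized eta squared divides each effect SS by itself plus the sum
    of all subject-level error SS.  For within effects with numerator
    df > 1, Mauchly's test and the Greenhouse-Geisser corrected p are
    reported alongside the uncorrected p.

    Returns a tidy DataFrame with one row per effect.
    """
    if isinstance(within, str):
        within = [within]
    within = list(within or [])
    if len(within) > 2:
        raise ValueError("at most two within-subject factors supported")
    _validate_layout(data, dv, subject, between, within)
    df = data.copy()

    N_subj = df[subject].nunique()
    n_groups = df[between].nunique() if between else 1
    U = lambda by: _u_sum(df, dv, by)
    U0 = U([])
    ss_total = float((df[dv] ** 2).sum()) - U0

    G = [between] if between else []
    rows: list[dict] = []
    error_ss: dict[str, tuple[float, int]] = {}

    if not within:
        if not between:
            raise ValueError("need at least one factor")
        ss_g = U(G) - U0
        ss_err = ss_total - ss_g
        df_g, df_err = n_groups - 1, N_subj - n_groups
        rows.append({"effect": between, "ss": ss_g, "df1": df_g, "df2": df_err,
                     "error_ss": ss_err})
        error_ss["between"] = (ss_err, df_err)
    else:
        levels = {w: df[w].nunique() for w in within}
        n_per = N_subj // n_groups
        # between-subject stratum
        ss_s = U([subject]) - U0
        if between:
            ss_g = U(G) - U0
            ss_sg = ss_s - ss_g
            df_sg = n_groups * (n_per - 1)
            rows.append({"effect": between, "ss": ss_g, "df1": n_groups - 1,
                         "df2": df_sg, "error_ss": ss_sg})
        else:
            ss_sg = ss_s
            df_sg = N_subj - 1
        error_ss["subjects"] = (ss_sg, df_sg)

        used_ss = ss_s
        for w in within:
            a = levels[w]
            ss_w = U([w]) - U0
            if between:
                ss_gw = U(G + [w]) - U(G) - U([w]) + U0
                ss_ws = U([subject, w]) - U([subject]) - U(G + [w]) + U(G)
            else:
                ss_gw = 0.0
                ss_ws = U([subject, w]) - U([subject]) - U([w]) + U0
            df_w = a - 1
            df_ws = (N_subj - n_groups) * (a - 1)
            error_ss[f"err_{w}"] = (ss_ws, df_ws)
            rows.append({"effect": w, "ss": ss_w, "df1": df_w, "df2": df_ws,
                         "error_ss": ss_ws, "_within": (w,)})
            if between:
                rows.append({"effect": f"{between} * {w}", "ss": ss_gw,
                             "df1": (n_groups - 1) * df_w, "df2": df_ws,
                             "error_ss": ss_ws, "_within": (w,)})
            used_ss += ss_w + ss_gw + ss_ws

        if len(within) == 2:
            w1, w2 = within
            a, b = levels[w1], levels[w2]
            ss_ab = U([w1, w2]) - U([w1]) - U([w2]) + U0
            if between:
                ss_gab = (
                    U(G + [w1, w2]) - U(G + [w1]) - U(G + [w2]) - U([w1, w2])
                    + U([w1]) + U([w2]) + U(G) - U0
                )
            else:
                ss_gab = 0.0
            ss_abs = ss_total - used_ss - ss_ab - ss_gab
            df_ab = (a - 1) * (b - 1)
            df_abs = (N_subj - n_groups) * df_ab
            error_ss["err_interaction"] = (ss_abs, df_abs)
            rows.append({"effect": f"{w1} * {w2}", "ss": ss_ab, "df1": df_ab,
                         "df2": df_abs, "error_ss": ss_abs, "_within": (w1, w2)})
            if between:
                rows.append({"effect": f"{between} * {w1} * {w2}", "ss": ss_gab,
                             "df1": (n_groups - 1) * df_ab, "df2": df_abs,
                             "error_ss": ss_abs, "_within": (w1, w2)})

    total_error = sum(ss for ss, _ in error_ss.values())
    groups_per_subj = (
        df.groupby(subject, observed=True)[between].first()
        if between
        else pd.Series("all", index=df[subject].unique())
    )

    out = []
    for row in rows:
        ss, df1, df2, err = row["ss"], row["df1"], row["df2"], row["error_ss"]
        ms_eff = ss / df1 if df1 > 0 else np.nan
        ms_err = err / df2 if df2 > 0 else np.nan
        F = ms_eff / ms_err if (ms_err and ms_err > 0) else np.nan
        p = float(_sps.f.sf(F, df1, df2)) if np.isfinite(F) else np.nan
        ges = ss / (ss + total_error) if (ss + total_error) > 0 else np.nan
        rec = {"effect": row["effect"], "ss": ss, "df1": df1, "df2": df2,
               "F": F, "p": p, "ges": ges,
               "sphericity_W": np.nan, "sphericity_p": np.nan,
               "gg_epsilon": np.nan, "p_gg": np.nan}
        wfac = row.get("_within")
        if wfac is not None:
            k = int(np.prod([df[w].nunique() - 1 for w in wfac]))
            if k > 1 and np.isfinite(F):
                cells = (
                    df.groupby([subject] + list(wfac), observed=True)[dv]
                    .mean()
                    .unstack(list(wfac))
                    .sort_index(axis=1)
                )
                contrasts = [_orthonormal_contrast(df[w].nunique()) for w in wfac]
                C = contrasts[0]
                for c2 in contrasts[1:]:
                    C = np.kron(C, c2)
                sph = _sphericity(cells, C, groups_per_subj)
                rec["sphericity_W"] = sph["W"]
                rec["sphericity_p"] = sph["p_sphericity"]
                eps = sph["epsilon"]
                rec["gg_epsilon"] = eps
                if np.isfinite(eps):
                    rec["p_gg"] = float(_sps.f.sf(F, eps * df1, eps * df2))
        out.append(rec)
    return pd.DataFrame(out)


def _cohen_d_pooled(x: np.ndarray, y: np.ndarray) -> float:
    nx, ny = len(x), len(y)
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    return float((x.mean() - y.mean()) / np.sqrt(sp2))


def welch_t(x, y, tails: str = "two-sided") -> dict:
    """Welch's unequal-variance t-test with pooled-SD Cohen's d."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 observations per sample")
    res = _sps.ttest_ind(x, y, equal_var=False, alternative=tails)
    return {"t": float(res.statistic), "df": float(res.df), "p": float(res.pvalue),
            "cohen_d": _cohen_d_pooled(x, y)}


def paired_t(x, y, tails: str = "two-sided") -> dict:
    """Paired t-test; Cohen's d = mean difference / SD of differences."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("paired samples have different lengths")
    if len(x) < 2:
        raise ValueError("need at least 2 pairs")
    diff = x - y
    sd = diff.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance of paired differences; t undefined")
    res = _sps.ttest_rel(x, y, alternative=tails)
    return {"t": float(res.statistic), "df": len(x) - 1, "p": float(res.pvalue),
            "cohen_d": float(diff.mean() / sd)}


def pearson_test(x, y) -> dict:
    """Pearson correlation with its t-test (df = n - 2)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input")
    r, p = _sps.pearsonr(x, y)
    if abs(r) < 1.0:
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r**2)
    else:
        t = np.inf * np.sign(r)
    return {"r": float(r), "t": float(t), "df": n - 2, "p": float(p)}


def pearson_filon_z(r12: float, r13: float, r23: float, n: int) -> dict:
    """Pearson-Filon (1898) z for two overlapping dependent correlations.

    Tests H0: rho12 = rho13 where variable 1 is shared by both
    correlations and variables 2, 3 are correlated r23 in the same sample
    of size n.  Returns the asymptotic z and its two-tailed normal p.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    R = np.array([[1.0, r12, r13], [r12, 1.0, r23], [r13, r23, 1.0]])
    if np.any(np.abs(R) > 1):
        raise ValueError("correlations must lie in [-1, 1]")
    if np.linalg.eigvalsh(R).min() < -1e-10:
        raise ValueError("correlation triple is not positive semidefinite")
    k = r23 * (1.0 - r12**2 - r13**2) - 0.5 * r12 * r13 * (
        1.0 - r12**2 - r13**2 - r23**2
    )
    var = (1.0 - r12**2) ** 2 + (1.0 - r13**2) ** 2 - 2.0 * k
    if var <= 0:
        raise ValueError("degenerate correlation triple (zero asymptotic variance)")
    z = float(np.sqrt(n) * (r12 - r13) / np.sqrt(var))
    p = float(2.0 * _sps.norm.sf(abs(z)))
    return {"z": z, "p": p}


def shapiro_wilk(x) -> dict:
    """Shapiro-Wilk normality test (3 <= n <= 5000)."""
    x = np.asarray(x, float)
    if not 3 <= len(x) <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if x.std() == 0:
        raise ValueError("constant input")
    W, p = _sps.shapiro(x)
    return {"W": float(W), "p": float(p)}


def bonferroni(pvalues, m: int | None = None) -> np.ndarray:
    """Bonferroni-adjusted p-values (default m = number of tests)."""
    p = np.asarray(pvalues, float)
    m = m or p.size
    return np.minimum(p * m, 1.0)
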