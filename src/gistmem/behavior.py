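"""Behavioral scoring for the old/related/novel recognition task.

A subject sees 60 studied (old) pictures, 60 related lures that share the
semantic gist of a studied picture, and 60 novel lures, and answers yes/no
("seen during encoding?") with a 0-3 confidence rating after every "yes".
From the trial records this module computes

* hit and false-alarm percentages by picture type and emotion,
* the Confidence Score (sum of per-hit confidence weights 0-3; with 60 old
  pictures the ceiling is 180), and
* the pair trichotomy: for each old picture and its related lure, the pair
  is *detailed* (old endorsed, lure rejected), *transformed* (lure
  endorsed, irrespective of the old response) or *forgotten* (both
  rejected).  A pair with a missing response on either member is
  *unclassified*.

Non-response trials are excluded from rate denominators; a type with no
responded trials yields a missing value rather than zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TRIAL_COLUMNS",
    "SubjectBehavior",
    "BehaviorSummary",
    "validate_trials",
    "score_recognition",
    "confidence_score",
    "categorize_pairs",
    "group_behavior_table",
    "summaries_from_table",
]

TRIAL_COLUMNS = (
    "picture_id",
    "pair_id",
    "picture_type",
    "emotion",
    "response",
    "confidence",
)

PICTURE_TYPES = ("old", "related", "novel")
EMOTIONS = ("negative", "neutral")
PAIR_CATEGORIES = ("detailed", "transformed", "forgotten", "unclassified")


def validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Validate per-trial recognition records.

    Confidence must be present iff the response is "yes"; pair_id must be
    present iff the picture is old or related.
    """
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    t = trials.copy()
    bad_type = set(t["picture_type"]) - set(PICTURE_TYPES)
    if bad_type:
        raise ValueError(f"unknown picture types: {sorted(bad_type)}")
    bad_emo = set(t["emotion"]) - set(EMOTIONS)
    if bad_emo:
        raise ValueError(f"unknown emotions: {sorted(bad_emo)}")
    bad_resp = set(t["response"]) - {"yes", "no", "none"}
    if bad_resp:
        raise ValueError(f"unknown responses: {sorted(bad_resp)}")

    yes = t["response"] == "yes"
    conf_present = t["confidence"].notna()
    wrong = t.index[yes != conf_present]
    if len(wrong):
        raise ValueError(
            f"confidence must be present iff response is 'yes'; offending rows: "
            f"{list(wrong[:5])}"
        )
    if conf_present.any():
        conf = t.loc[conf_present, "confidence"].astype(float)
        if not conf.isin([0, 1, 2, 3]).all():
            raise ValueError("confidence must be an integer 0-3")
    paired = t["picture_type"].isin(["old", "related"])
    if t.loc[paired, "pair_id"].isna().any():
        raise ValueError("old/related trials must carry a pair_id")
    if t.loc[~paired, "pair_id"].notna().any():
        raise ValueError("novel trials must not carry a pair_id")
    return t


@dataclass
class SubjectBehavior:
    """One subject's group assignment and trial records."""

    subject_id: str
    group: str
    trials: pd.DataFrame

    def __post_init__(self) -> None:
        self.trials = validate_trials(self.trials)


@dataclass
class BehaviorSummary:
    subject_id: str
    group: str
    hit_pct: float
    fa_related_pct: float
    fa_novel_pct: float
    by_emotion: pd.DataFrame  # rows: measure x emotion percentages
    confidence_score: int | None = None
    n_detailed: int | None = None
    n_transformed: int | None = None
    n_forgotten: int | None = None
    n_unclassified: int | None = None


def _yes_rate(trials: pd.DataFrame) -> float:
    responded = trials[trials["response"] != "none"]
    if len(responded) == 0:
        return np.nan  # flagged missing, not zero
    return 100.0 * (responded["response"] == "yes").mean()


def score_recognition(subject: SubjectBehavior) -> BehaviorSummary:
    """Hit and false-alarm percentages, overall and per emotion.

    Denominators count only responded trials of the given type (and
    emotion, for the splits); a zero denominator yields NaN.
    """
    t = subject.trials
    if len(t) == 0:
        raise ValueError("subject has no trials")
    rates = {ptype: _yes_rate(t[t["picture_type"] == ptype]) for ptype in PICTURE_TYPES}
    rows = []
    for ptype in PICTURE_TYPES:
        for emo in EMOTIONS:
            sel = t[(t["picture_type"] == ptype) & (t["emotion"] == emo)]
            rows.append({"picture_type": ptype, "emotion": emo, "pct_yes": _yes_rate(sel)})
    return BehaviorSummary(
        subject_id=subject.subject_id,
        group=subject.group,
        hit_pct=rates["old"],
        fa_related_pct=rates["related"],
        fa_novel_pct=rates["novel"],
        by_emotion=pd.DataFrame(rows),
    )


def confidence_score(subject: SubjectBehavior) -> int:
    """Sum of confidence weights (0-3) over hits; ceiling 3 x n_old."""
    old = subject.trials[subject.trials["picture_type"] == "old"]
    hits = old[old["response"] == "yes"]
    if hits["confidence"].isna().any():
        bad = hits.loc[hits["confidence"].isna(), "picture_id"].iloc[0]
        raise ValueError(f"hit without confidence rating (picture {bad})")
    return int(hits["confidence"].astype(int).sum())


def categorize_pairs(subject: SubjectBehavior) -> pd.DataFrame:
    """Classify each old/related pair as detailed, transformed, forgotten
    or unclassified.

    Rules: related endorsed -> transformed (irrespective of the old
    response); related rejected and old endorsed -> detailed; both
    rejected -> forgotten; missing response on either member ->
    unclassified.
    """
    t = subject.trials
    paired = t[t["picture_type"].isin(["old", "related"])]
    out = []
    for pair_id, grp in paired.groupby("pair_id", sort=True):
        old = grp[grp["picture_type"] == "old"]
        rel = grp[grp["picture_type"] == "related"]
        if len(old) != 1 or len(rel) != 1:
            raise ValueError(f"pair {pair_id!r} must have exactly one old and one related trial")
        r_old = old["response"].iloc[0]
        r_rel = rel["response"].iloc[0]
        if r_old == "none" or r_rel == "none":
            cat = "unclassified"
        elif r_rel == "yes":
            cat = "transformed"
        elif r_old == "yes":
            cat = "detailed"
        else:
            cat = "forgotten"
        out.append({"pair_id": pair_id, "emotion": old["emotion"].iloc[0], "category": cat})
    return pd.DataFrame(out)


def summarize_subject(subject: SubjectBehavior) -> BehaviorSummary:
    """Full behavioral summary: rates, Confidence Score and pair counts."""
    summary = score_recognition(subject)
    summary.confidence_score = confidence_score(subject)
    cats = categorize_pairs(subject)["category"].value_counts()
    summary.n_detailed = int(cats.get("detailed", 0))
    summary.n_transformed = int(cats.get("transformed", 0))
    summary.n_forgotten = int(cats.get("forgotten", 0))
    summary.n_unclassified = int(cats.get("unclassified", 0))
    return summary


def group_behavior_table(subjects: list[SubjectBehavior]) -> pd.DataFrame:
    """Long-format table of all behavioral measures across subjects.

    One row per subject x measure x (picture type, emotion) cell, suitable
    for the mixed ANOVAs.  Rate measures appear per emotion and overall
    (emotion = "all"); the Confidence Score and pair-category counts are
    subject-level rows.
    """
    if not subjects:
        raise ValueError("no subjects given")
    ids = [s.subject_id for s in subjects]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicated subject ids: {dup}")

    rows = []
    for s in subjects:
        summ = summarize_subject(s)
        base = {"subject_id": s.subject_id, "group": s.group}
        for ptype, value in [
            ("old", summ.hit_pct),
            ("related", summ.fa_related_pct),
            ("novel", summ.fa_novel_pct),
        ]:
            measure = "hit_pct" if ptype == "old" else "fa_pct"
            rows.append({**base, "measure": measure, "picture_type": ptype,
                         "emotion": "all", "value": value})
        for _, r in summ.by_emotion.iterrows():
            measure = "hit_pct" if r["picture_type"] == "old" else "fa_pct"
            rows.append({**base, "measure": measure, "picture_type": r["picture_type"],
                         "emotion": r["emotion"], "value": r["pct_yes"]})
        rows.append({**base, "measure": "confidence_score", "picture_type": "old",
                     "emotion": "all", "value": summ.confidence_score})
        n_pairs = summ.n_detailed + summ.n_transformed + summ.n_forgotten + summ.n_unclassified
        for cat, n in [("detailed", summ.n_detailed), ("transformed", summ.n_transformed),
                       ("forgotten", summ.n_forgotten), ("unclassified", summ.n_unclassified)]:
            rows.append({**base, "measure": f"n_{cat}", "picture_type": "pair",
                         "emotion": "all", "value": n})
            rows.append({**base, "measure": f"pct_{cat}", "picture_type": "pair",
                         "emotion": "all", "value": 100.0 * n / n_pairs if n_pairs else np.nan})
    return pd.DataFrame(rows)


def summaries_from_table(table: pd.DataFrame) -> pd.DataFrame:
    """Reconstruct per-subject wide summaries from the long-format table."""
    overall = table[(table["emotion"] == "all")]
    wide = overall.pivot_table(
        index=["subject_id", "group"], columns=["measure", "picture_type"],
        values="value", aggfunc="first",
    )
    wide.columns = [
        {"hit_pct": "hit_pct", "fa_pct": f"fa_{pt}_pct"}.get(m, m)
        for m, pt in wide.columns
    ]
    return wide.reset_index()
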