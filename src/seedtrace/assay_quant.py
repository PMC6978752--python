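"""Quantification of the reporter, chemotaxis, qPCR and clinical readouts.

Formulas:
  RLU               = firefly / renilla
  percent chemotaxis = 100 * migrated / control_migrated (control == 100%)
  relative expression = 2 ** -(Ct_target - Ct_reference)   (2^-dCt)
  clinical curve     = per-day mean +/- SEM over mice (integer scores 0-5)
Group comparison is the equal-variance two-tailed Student's t-test with the
conventional star thresholds (0.05 / 0.01 / 0.001 / 0.0001).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

CLINICAL_SCORES = frozenset(range(6))  # 0 asymptomatic ... 5 moribund/death

STAR_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def rlu(firefly: float, renilla: float) -> float:
    """Relative luminescence units: Firefly normalized to Renilla."""
    if firefly < 0 or renilla < 0:
        raise ValueError("luminescence counts must be >= 0")
    if renilla == 0:
        raise ValueError("Renilla activity of 0 leaves RLU undefined")
    return firefly / renilla


def percent_chemotaxis(migrated: float, control_migrated: float) -> float:
    """Migration as percent of the media-only control (control == 100%)."""
    if migrated < 0 or control_migrated < 0:
        raise ValueError("cell counts must be >= 0")
    if control_migrated == 0:
        raise ValueError("control well with zero migrated cells")
    return 100.0 * migrated / control_migrated


def relative_expression(ct_target: float, ct_reference: float) -> float:
    """Fold expression relative to the reference gene, 2^-(dCt)."""
    if not (math.isfinite(ct_target) and math.isfinite(ct_reference)):
        raise ValueError("Ct values must be finite")
    return 2.0 ** -(ct_target - ct_reference)


def significance_stars(p_value: float) -> str:
    """Map a p-value onto the star convention; 'ns' above 0.05."""
    for threshold, stars in STAR_THRESHOLDS:
        if p_value < threshold:
            return stars
    return "ns"


@dataclass
class GroupComparison:
    t_statistic: float
    p_value: float
    stars: str


def group_compare(
    values_a: Sequence[float], values_b: Sequence[float]
) -> GroupComparison:
    """Equal-variance two-tailed Student's t-test between two groups."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    if np.isnan(p):  # both groups constant and equal: zero variance, zero t
        t, p = 0.0, 1.0
    return GroupComparison(float(t), float(p), significance_stars(float(p)))


def mean_clinical_score(scores: pd.DataFrame) -> pd.DataFrame:
    """Per-day mean +/- SEM disease curve.

    ``scores`` is tidy with columns day, mouse_id, score (integers 0-5).
    Mice missing on a day are excluded from that day's n (no carry-forward)
    and the day is flagged ``incomplete``. SEM with n=1 is reported as 0
    with ``sem_undefined`` set.
    """
    required = {"day", "mouse_id", "score"}
    if not required <= set(scores.columns):
        raise ValueError(f"clinical table lacks columns {sorted(required - set(scores.columns))}")
    bad = set(scores["score"]) - CLINICAL_SCORES
    if bad:
        raise ValueError(f"scores outside the 0-5 clinical scale: {sorted(bad)}")
    n_mice = scores["mouse_id"].nunique()
    rows = []
    for day, grp in scores.groupby("day", sort=True):
        vals = grp["score"].to_numpy(dtype=float)
        n = len(vals)
        sem = 0.0 if n == 1 else float(np.std(vals, ddof=1) / np.sqrt(n))
        rows.append(
            {
                "day": day,
                "mean_score": float(np.mean(vals)),
                "sem": sem,
                "n": n,
                "incomplete": n < n_mice,
                "sem_undefined": n == 1,
            }
        )
    return pd.DataFrame(rows)


def quantify_luciferase(table: pd.DataFrame) -> pd.DataFrame:
    """Add an ``rlu`` column and summarize mean +/- SEM per group.

    Input columns: sample_id, group_label, replicate_index, firefly, renilla.
    """
    out = table.copy()
    out["rlu"] = [rlu(f, r) for f, r in zip(out["firefly"], out["renilla"])]
    return _summarize(out, "rlu")


def quantify_transwell(table: pd.DataFrame, control_label: str = "media") -> pd.DataFrame:
    """Normalize migrated counts to the media-only control per replicate set.

    Input columns: sample_id, group_label, condition, replicate_index,
    migrated_count. Each group must include a ``control_label`` condition;
    its mean count is the 100% denominator for that group.
    """
    out = table.copy()
    controls = (
        out[out["condition"] == control_label]
        .groupby("group_label")["migrated_count"]
        .mean()
    )
    missing = set(out["group_label"]) - set(controls.index)
    if missing:
        raise ValueError(f"groups without a media-only control: {sorted(missing)}")
    out["percent_migration"] = [
        percent_chemotaxis(row.migrated_count, controls[row.group_label])
        for row in out.itertuples(index=False)
    ]
    grouped = (
        out.groupby(["group_label", "condition"])["percent_migration"]
        .agg(["mean", "sem", "count"])
        .reset_index()
        .rename(columns={"count": "n"})
    )
    grouped["sem"] = grouped["sem"].fillna(0.0)
    return grouped


def quantify_qpcr(table: pd.DataFrame) -> pd.DataFrame:
    """2^-dCt fold expression relative to the reference gene.

    Input columns: sample_id, group_label, gene, replicate_index, ct_target,
    ct_reference.
    """
    out = table.copy()
    out["fold_expression"] = [
        relative_expression(t, r) for t, r in zip(out["ct_target"], out["ct_reference"])
    ]
    grouped = (
        out.groupby(["group_label", "gene"])["fold_expression"]
        .agg(["mean", "sem", "count"])
        .reset_index()
        .rename(columns={"count": "n"})
    )
    grouped["sem"] = grouped["sem"].fillna(0.0)
    return grouped


def _summarize(table: pd.DataFrame, value_column: str) -> pd.DataFrame:
    grouped = (
        table.groupby("group_label")[value_column]
        .agg(["mean", "sem", "count"])
        .reset_index()
        .rename(columns={"count": "n"})
    )
    grouped["sem"] = grouped["sem"].fillna(0.0)
    return grouped
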