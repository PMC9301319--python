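"""Reliability and validity checks on ordinal rating matrices.

Reliability is Cronbach's alpha with raters as items and stimuli as cases.
Validity filtering removes, per stimulus and attribute, ratings beyond
``k_sd`` standard deviations of the rater mean (default 1.5) and imputes
the mean of the retained ratings so the matrix stays complete for the
successive-categories scaling stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import RatingMatrix


def cronbach_alpha(table: pd.DataFrame) -> float:
    """Cronbach's alpha of a stimulus × rater table.

    alpha = k/(k-1) * (1 - sum of per-rater variances / variance of the
    per-stimulus total score), with k raters as items and stimuli as cases.

    Raises
    ------
    ValueError
        If fewer than 2 raters or stimuli, or the total score has zero
        variance (alpha undefined).
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need at least 2 stimuli and 2 raters")
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite ratings")
    k = arr.shape[1]
    item_vars = arr.var(axis=0, ddof=1)
    total_var = arr.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("total-score variance is zero; alpha undefined")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


@dataclass
class QCReport:
    """Outcome of reliability and validity checks."""

    alpha: dict = field(default_factory=dict)  # attribute -> alpha
    k_sd: float = 1.5
    n_cells: int = 0
    n_removed: int = 0
    removed: list = field(default_factory=list)  # (rater, stimulus, attribute, value)
    imputed: list = field(default_factory=list)  # (rater, stimulus, attribute, value)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "alpha": self.alpha,
            "k_sd": self.k_sd,
            "n_cells": self.n_cells,
            "n_removed": self.n_removed,
            "removed": [list(r) for r in self.removed],
            "imputed": [list(r) for r in self.imputed],
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def rating_reliability(ratings: RatingMatrix) -> dict:
    """Cronbach's alpha per attribute (raters as items, stimuli as cases).

    Attributes whose alpha is undefined (single stimulus, zero total-score
    variance) map to None.
    """
    out = {}
    for attr in ratings.attributes:
        try:
            out[attr] = cronbach_alpha(ratings.pivot(attr))
        except ValueError:
            out[attr] = None
    return out


def validity_filter(
    ratings: RatingMatrix,
    k_sd: float = 1.5,
    round_imputed: bool = False,
) -> tuple[RatingMatrix, QCReport]:
    """Remove outlying ratings and impute the retained mean.

    For each stimulus × attribute cell group, ratings outside
    ``mean ± k_sd * SD`` (SD across raters, ddof=1) are marked invalid and
    replaced by the mean of the retained ratings. Bounds are computed once
    (single pass). A zero-SD group removes nothing. Imputed values are
    real-valued unless ``round_imputed``.

    Raises
    ------
    ValueError
        If any group has fewer than 3 raters, or filtering would remove
        every rating in a group.
    """
    df = ratings.data.copy()
    df["category"] = df["category"].astype(float)
    report = QCReport(k_sd=k_sd, n_cells=len(df))
    report.alpha = rating_reliability(ratings)

    grouped = df.groupby(["stimulus_id", "attribute"], sort=False)
    for (sid, attr), idx in grouped.groups.items():
        vals = df.loc[idx, "category"].to_numpy()
        if len(vals) < 3:
            raise ValueError(
                f"stimulus {sid!r}/{attr}: need >= 3 raters for the filter")
        sd = vals.std(ddof=1)
        if sd == 0:
            continue
        mean = vals.mean()
        lo, hi = mean - k_sd * sd, mean + k_sd * sd
        outliers = (vals < lo) | (vals > hi)
        if not outliers.any():
            continue
        if outliers.all():
            raise ValueError(
                f"stimulus {sid!r}/{attr}: all ratings outside bounds")
        fill = vals[~outliers].mean()
        if round_imputed:
            fill = float(np.clip(round(fill), 1, ratings.n_categories))
        out_idx = np.asarray(idx)[outliers]
        for i in out_idx:
            report.removed.append((df.at[i, "rater_id"], sid, attr,
                                   float(df.at[i, "category"])))
            report.imputed.append((df.at[i, "rater_id"], sid, attr, float(fill)))
        df.loc[out_idx, "category"] = fill
    report.n_removed = len(report.removed)
    return RatingMatrix(df, n_categories=ratings.n_categories), report
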