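"""Thurstonian scaling by the method of successive categories.

Ordinal category responses are converted to psychological scale values
f(a_j) per stimulus and category boundaries t_g, using the category
judgment model: the inverse-normal transform z_gj = Phi^-1(P_gj) of the
cumulative response proportions satisfies z_gj = t_g - f(a_j), so with
the identifiability constraint mean_j f(a_j) = 0 the boundary estimates
are column means of the z-table and the scale values follow from row
means:

    t_g = mean_j z_gj
    f(a_j) = mean_g t_g - mean_g z_gj

Extreme proportions (0 or 1) carry no finite z; by default they are
clipped to [1/(2N), 1 - 1/(2N)] for N raters, or dropped (treated as
missing, with nan-aware means) when ``extreme="drop"``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm


@dataclass
class PsychScale:
    """Estimated psychological scale for one attribute.

    ``scale_z`` holds zero-mean scale values f(a_j) in z-units indexed by
    stimulus; ``boundaries`` the m-1 category cut points t_g; ``cum_prop``
    and ``z_table`` the intermediate stimulus × boundary tables.
    ``scale_cat`` is filled by :func:`rescale_to_categories`.
    """

    attribute: str
    scale_z: pd.Series
    boundaries: np.ndarray
    cum_prop: pd.DataFrame
    z_table: pd.DataFrame
    n_categories: int
    n_raters: int
    flagged: list = field(default_factory=list)
    scale_cat: pd.Series | None = None
    boundaries_cat: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"stimulus_id": self.scale_z.index,
                           "attribute": self.attribute,
                           "scale_z": self.scale_z.to_numpy()})
        if self.scale_cat is not None:
            df["scale_cat"] = self.scale_cat.to_numpy()
        return df

    def boundaries_json(self, path: str | Path) -> None:
        payload = {"attribute": self.attribute,
                   "boundaries_z": list(map(float, self.boundaries))}
        if self.boundaries_cat is not None:
            payload["boundaries_cat"] = list(map(float, self.boundaries_cat))
        Path(path).write_text(json.dumps(payload, indent=2))


def fit_successive_categories(
    table: pd.DataFrame,
    n_categories: int = 9,
    attribute: str = "",
    extreme: str = "clip",
) -> PsychScale:
    """Estimate scale values and boundaries from a stimulus × rater table.

    Parameters
    ----------
    table : stimulus × rater responses; categories in [1, m], possibly
        non-integer after imputation (a response counts as "<= g" when it
        is < g + 0.5).
    extreme : "clip" (default) clips cumulative proportions to
        [1/(2N), 1-1/(2N)]; "drop" treats 0/1 proportions as missing cells.

    Raises
    ------
    ValueError
        On fewer than 2 stimuli, fewer than 3 categories, missing values,
        or (with ``extreme="drop"``) fewer than 2 usable boundary columns.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need at least 2 stimuli")
    if n_categories < 3:
        raise ValueError("need at least 3 categories")
    if not np.all(np.isfinite(arr)):
        raise ValueError("ratings must be complete (no missing values)")
    if extreme not in ("clip", "drop"):
        raise ValueError(f"unknown extreme-proportion mode {extreme!r}")

    n_raters = arr.shape[1]
    bounds_g = np.arange(1, n_categories)  # g = 1..m-1
    # P_gj: fraction of rater responses <= g (ties at g+0.5 resolved by <)
    cum = np.stack([(arr < g + 0.5).mean(axis=1) for g in bounds_g], axis=1)
    cum_prop = pd.DataFrame(cum, index=table.index,
                            columns=[f"C{g}" for g in bounds_g])
    return fit_from_proportions(cum_prop, n_raters,
                                n_categories=n_categories,
                                attribute=attribute, extreme=extreme)


def fit_from_proportions(
    cum_prop: pd.DataFrame,
    n_raters: int,
    n_categories: int | None = None,
    attribute: str = "",
    extreme: str = "clip",
) -> PsychScale:
    """Estimate the scale from a stimulus × boundary cumulative-proportion table.

    ``cum_prop[j, g]`` is the fraction of responses to stimulus j in
    category <= g, for g = 1..m-1. This is the estimator core; see
    :func:`fit_successive_categories` for the ratings-level entry point.
    """
    cum = np.asarray(cum_prop, dtype=float)
    if n_categories is None:
        n_categories = cum.shape[1] + 1
    if cum.shape[1] != n_categories - 1:
        raise ValueError("cumulative table must have m-1 columns")

    flagged = [sid for sid, row in zip(cum_prop.index, cum)
               if np.all((row == 0) | (row == 1))]

    eps = 1.0 / (2.0 * n_raters)
    if extreme == "clip":
        z = norm.ppf(np.clip(cum, eps, 1.0 - eps))
    else:
        z = np.where((cum > 0) & (cum < 1), norm.ppf(np.clip(cum, eps, 1 - eps)),
                     np.nan)
        usable_cols = np.sum(~np.all(np.isnan(z), axis=0))
        if usable_cols < 2:
            raise ValueError("fewer than 2 usable boundary columns")
    z_table = pd.DataFrame(z, index=cum_prop.index, columns=cum_prop.columns)

    with np.errstate(invalid="ignore"):
        t_g = np.nanmean(z, axis=0)  # column means: t_g - mean_j f = t_g
        row_means = np.nanmean(
            np.where(np.isnan(z), np.nan, z - t_g[None, :]), axis=1)
    # z_gj - t_g averages to -f(a_j); recenter to a zero-mean scale
    f = -(row_means - np.nanmean(row_means))
    scale_z = pd.Series(f, index=cum_prop.index, name="scale_z")

    return PsychScale(attribute=attribute, scale_z=scale_z,
                      boundaries=t_g, cum_prop=cum_prop, z_table=z_table,
                      n_categories=n_categories, n_raters=n_raters,
                      flagged=flagged)


def rescale_to_categories(scale: PsychScale) -> PsychScale:
    """Map z-unit scale values to category units (1..m).

    Fits the least-squares affine map from the estimated boundaries t_g to
    their nominal positions g + 0.5 and applies it to scale values and
    boundaries. Order-preserving (the fitted slope must be positive).
    """
    t = np.asarray(scale.boundaries, dtype=float)
    ok = np.isfinite(t)
    if ok.sum() < 2:
        raise ValueError("need at least 2 finite boundaries")
    targets = np.arange(1, scale.n_categories)[ok] + 0.5
    t_fit = t[ok]
    if np.ptp(t_fit) == 0:
        raise ValueError("degenerate boundaries (all equal)")
    slope, intercept = np.polyfit(t_fit, targets, 1)
    if slope <= 0:
        raise ValueError("non-monotone boundary map")
    scale.scale_cat = scale.scale_z * slope + intercept
    scale.scale_cat.name = "scale_cat"
    scale.boundaries_cat = t * slope + intercept
    return scale


def fit_all_attributes(
    ratings, extreme: str = "clip", rescale: bool = True
) -> dict[str, PsychScale]:
    """Fit one :class:`PsychScale` per attribute of a rating matrix."""
    out = {}
    for attr in ratings.attributes:
        ps = fit_successive_categories(ratings.pivot(attr),
                                       n_categories=ratings.n_categories,
                                       attribute=attr, extreme=extreme)
        out[attr] = rescale_to_categories(ps) if rescale else ps
    return out


def scales_frame(scales: dict[str, PsychScale]) -> pd.DataFrame:
    """Long-form table of all attributes' scale values."""
    return pd.concat([s.to_frame() for s in scales.values()],
                     ignore_index=True)
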