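"""Statistical battery over psychological scales.

Category frequency tables, normal P-P coordinates, one-way and two-way
ANOVA (Type III sums of squares with sum-to-zero contrasts for the
unbalanced two-factor design), Student-Newman-Keuls homogeneous subsets,
attribute correlations, and a two-dimensional multidimensional preference
map (standardized principal components with attribute loadings expressed
as attribute-dimension correlations).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .containers import ATTRIBUTES


@dataclass
class AnovaResult:
    """ANOVA summary: one row per model term plus the residual."""

    terms: pd.DataFrame  # index: term; columns: sum_sq, df, F, p
    residual_df: int
    residual_ss: float

    def f(self, term: str) -> float:
        return float(self.terms.loc[term, "F"])

    def p(self, term: str) -> float:
        return float(self.terms.loc[term, "p"])


def category_frequencies(
    values: pd.Series,
    groups: pd.Series,
    n_categories: int = 9,
    known_groups: tuple | None = None,
) -> pd.DataFrame:
    """Counts and percentages of stimuli per category C1..Cm per group.

    Continuous (category-unit) scale values are binned to the nearest
    integer category, clipped to [1, m].
    """
    if len(values) == 0:
        raise ValueError("empty input")
    if known_groups is not None:
        unknown = set(groups.unique()) - set(known_groups)
        if unknown:
            raise ValueError(f"unknown group label(s): {sorted(unknown)}")
    cats = np.clip(np.round(np.asarray(values, dtype=float)), 1, n_categories)
    df = pd.DataFrame({"group": np.asarray(groups), "category": cats.astype(int)})
    rows = []
    for g, sub in df.groupby("group"):
        counts = sub["category"].value_counts().reindex(
            range(1, n_categories + 1), fill_value=0)
        for c, n in counts.items():
            rows.append({"group": g, "category": f"C{c}", "count": int(n),
                         "percent": 100.0 * n / len(sub)})
    return pd.DataFrame(rows)


def normality_pp(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Normal P-P plot coordinates.

    Returns (empirical cumulative probability, fitted-normal cumulative
    probability) at the sorted observations; both sequences are
    nondecreasing in [0, 1], and exact normality puts the points on the
    identity line.
    """
    x = np.sort(np.asarray(values, dtype=float))
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance")
    empirical = (np.arange(1, len(x) + 1) - 0.5) / len(x)
    model = stats.norm.cdf((x - x.mean()) / sd)
    return empirical, model


def one_way_anova(values: pd.Series, factor: pd.Series) -> AnovaResult:
    """One-way between-groups ANOVA by direct sums-of-squares decomposition."""
    y = np.asarray(values, dtype=float)
    f = np.asarray(factor)
    levels = pd.unique(f)
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    grand = y.mean()
    ss_total = np.sum((y - grand) ** 2)
    ss_between = 0.0
    for lev in levels:
        g = y[f == lev]
        ss_between += len(g) * (g.mean() - grand) ** 2
    ss_within = ss_total - ss_between
    df_b = len(levels) - 1
    df_w = len(y) - len(levels)
    if df_w <= 0:
        raise ValueError("no residual degrees of freedom")
    F = (ss_between / df_b) / (ss_within / df_w)
    p = stats.f.sf(F, df_b, df_w)
    terms = pd.DataFrame({"sum_sq": [ss_between], "df": [df_b],
                          "F": [F], "p": [p]}, index=["factor"])
    return AnovaResult(terms=terms, residual_df=df_w, residual_ss=ss_within)


def two_way_anova(
    values: pd.Series,
    factor_a: pd.Series,
    factor_b: pd.Series,
    names: tuple[str, str] = ("envelope", "culture"),
    alpha: float = 0.05,
) -> tuple[AnovaResult, AnovaResult | None]:
    """Two-way ANOVA with interaction, Type III SS, sum-to-zero contrasts.

    Returns the full model first; if the interaction is not significant at
    ``alpha``, also returns the main-effects-only refit (else ``None``).
    """
    df = pd.DataFrame({"y": np.asarray(values, dtype=float),
                       "A": np.asarray(factor_a), "B": np.asarray(factor_b)})
    cells = df.groupby(["A", "B"]).size()
    expected = len(df["A"].unique()) * len(df["B"].unique())
    if len(cells) < expected or (cells == 0).any():
        all_cells = pd.MultiIndex.from_product(
            [df["A"].unique(), df["B"].unique()])
        empty = sorted(set(all_cells) - set(cells.index))
        raise ValueError(f"empty design cell(s): {empty}")

    def _fit(formula: str) -> tuple[AnovaResult, object]:
        model = smf.ols(formula, data=df).fit()
        tab = sm.stats.anova_lm(model, typ=3)
        tab = tab.rename(columns={"PR(>F)": "p"})
        resid = tab.loc["Residual"]
        keep = tab.drop(index=[i for i in ("Intercept", "Residual")
                               if i in tab.index])
        rename = {"C(A, Sum)": names[0], "C(B, Sum)": names[1],
                  "C(A, Sum):C(B, Sum)": f"{names[0]}:{names[1]}"}
        keep = keep.rename(index=rename)
        return AnovaResult(terms=keep[["sum_sq", "df", "F", "p"]],
                           residual_df=int(resid["df"]),
                           residual_ss=float(resid["sum_sq"])), model

    full, _ = _fit("y ~ C(A, Sum) * C(B, Sum)")
    interaction = f"{names[0]}:{names[1]}"
    refit = None
    if full.p(interaction) > alpha:
        refit, _ = _fit("y ~ C(A, Sum) + C(B, Sum)")
    return full, refit


def snk_groups(
    values: pd.Series,
    factor: pd.Series,
    alpha: float = 0.05,
) -> list[list]:
    """Student-Newman-Keuls homogeneous subsets of group means.

    Groups are ordered by mean; a contiguous stretch of r ordered means is
    homogeneous when its studentized range statistic does not exceed the
    critical value q(alpha, r, df_error). Subsets are formed greedily from
    the smallest mean upward, yielding an exhaustive non-overlapping
    partition. Unequal group sizes use the harmonic mean n.

    Returns a list of subsets, each a list of group labels ordered by mean.
    """
    y = np.asarray(values, dtype=float)
    f = np.asarray(factor)
    levels = pd.unique(f)
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    sizes = {lev: int(np.sum(f == lev)) for lev in levels}
    if any(n < 2 for n in sizes.values()):
        small = [lev for lev, n in sizes.items() if n < 2]
        raise ValueError(f"group(s) with < 2 observations: {small}")

    anova = one_way_anova(values, factor)
    mse = anova.residual_ss / anova.residual_df
    df_err = anova.residual_df
    means = {lev: float(y[f == lev].mean()) for lev in levels}
    ordered = sorted(levels, key=lambda lev: means[lev])
    n_h = len(levels) / np.sum([1.0 / sizes[lev] for lev in levels])
    se = np.sqrt(mse / n_h)

    def homogeneous(i: int, j: int) -> bool:
        if i == j:
            return True
        r = j - i + 1
        if se == 0:
            return means[ordered[j]] == means[ordered[i]]
        q_obs = (means[ordered[j]] - means[ordered[i]]) / se
        q_crit = stats.studentized_range.ppf(1 - alpha, r, df_err)
        return q_obs <= q_crit

    subsets: list[list] = []
    i = 0
    while i < len(ordered):
        j = i
        # extend while every sub-range within [i, j+1] passes its range test
        while j + 1 < len(ordered) and all(
                homogeneous(a, j + 1) for a in range(i, j + 1)):
            j += 1
        subsets.append(ordered[i:j + 1])
        i = j + 1
    return subsets


def attribute_correlations(
    scales: pd.DataFrame,
    attributes: tuple = ATTRIBUTES,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlation matrix and two-tailed p-values across attributes.

    ``scales`` is a stimulus × attribute table of per-stimulus scale
    values. Zero-variance attributes raise.
    """
    cols = [a for a in attributes if a in scales.columns]
    if len(scales) < 3:
        raise ValueError("need at least 3 stimuli")
    X = scales[cols].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite scale values")
    zero_var = [c for c, s in zip(cols, X.std(axis=0)) if s == 0]
    if zero_var:
        raise ValueError(f"zero-variance attribute(s): {zero_var}")
    k = len(cols)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            rij, pij = stats.pearsonr(X[:, i], X[:, j])
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
    return (pd.DataFrame(r, index=cols, columns=cols),
            pd.DataFrame(p, index=cols, columns=cols))


@dataclass
class PreferenceMap:
    """Two-dimensional preference space of attributes and stimuli."""

    loadings: pd.DataFrame          # attribute × dimension correlations
    stimulus_coords: pd.DataFrame   # stimulus × dimension scores
    centroids: pd.DataFrame         # group × dimension centroid coordinates
    variance_explained: np.ndarray  # fraction per dimension
    orientation: dict = field(default_factory=dict)


def mdpref_map(
    scales: pd.DataFrame,
    metadata: pd.DataFrame | None = None,
    n_dims: int = 2,
    orient_attribute: str = "fusion",
) -> PreferenceMap:
    """Multidimensional preference map by standardized principal components.

    Columns of ``scales`` (stimulus × attribute) are z-standardized and
    decomposed by SVD; attribute loadings are the correlations between
    each attribute and each dimension's stimulus scores, so |loading| <= 1.
    Dimension 1 is oriented so that ``orient_attribute`` loads positively;
    dimension 2 so that its largest-|loading| attribute loads positively.
    Class centroids (envelope class and culture) are computed when
    ``metadata`` is given.
    """
    cols = list(scales.columns)
    X = scales.to_numpy(dtype=float)
    if X.shape[0] < 3 or X.shape[1] < 2:
        raise ValueError("need at least 3 stimuli and 2 attributes")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("zero-variance attribute")
    Z = (X - X.mean(axis=0)) / sd
    u, s, vt = np.linalg.svd(Z, full_matrices=False)
    if np.sum(s > 1e-10 * s[0]) < n_dims:
        raise ValueError(f"matrix rank below {n_dims}")
    var_exp = (s ** 2) / np.sum(s ** 2)

    scores = u[:, :n_dims] * s[:n_dims]
    # loadings as attribute-dimension correlations
    load = np.empty((len(cols), n_dims))
    for d in range(n_dims):
        for a in range(len(cols)):
            load[a, d] = np.corrcoef(Z[:, a], scores[:, d])[0, 1]

    signs = np.ones(n_dims)
    if orient_attribute in cols:
        a0 = cols.index(orient_attribute)
        if load[a0, 0] < 0:
            signs[0] = -1
    for d in range(1, n_dims):
        a_top = int(np.argmax(np.abs(load[:, d])))
        if load[a_top, d] < 0:
            signs[d] = -1
    load = load * signs
    scores = scores * signs

    dims = [f"dim{d + 1}" for d in range(n_dims)]
    loadings = pd.DataFrame(load, index=cols, columns=dims)
    coords = pd.DataFrame(scores, index=scales.index, columns=dims)

    centroid_rows = []
    if metadata is not None:
        meta = metadata.set_index("stimulus_id").loc[scales.index]
        for col in ("envelope_class", "culture"):
            if col in meta.columns:
                for lev, sub in coords.groupby(meta[col]):
                    row = {"group": lev, "kind": col}
                    row.update(sub.mean().to_dict())
                    centroid_rows.append(row)
    centroids = pd.DataFrame(centroid_rows)

    return PreferenceMap(loadings=loadings, stimulus_coords=coords,
                         centroids=centroids,
                         variance_explained=var_exp[:n_dims],
                         orientation={"dim1_positive": orient_attribute})
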