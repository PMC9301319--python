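"""Fusion-prediction models over the 45-feature vectors.

Three model kinds — lasso linear regression, random forest (10 trees,
6 max features per split), and a one-hidden-layer MLP (ReLU, SGD,
learning rate 0.001) — evaluated by 4-fold cross-validated R², plus
extraction of the large-coefficient linear fusion equation (standardized
coefficients with |c| above a threshold, default 4).

Features are z-standardized inside every fit, so linear coefficients are
per-SD-of-feature and the |c| > threshold rule is scale-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import Lasso, LassoCV, LinearRegression
from sklearn.model_selection import KFold
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

MODEL_KINDS = ("linear_lasso", "random_forest", "mlp")


def r_squared(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Goodness of fit R² = 1 - SSE/SST = 1 - Σ(y-ŷ)² / Σ(y-ȳ)².

    Equals 1 for perfect prediction; can be negative out-of-sample when
    the model predicts worse than the training-set mean.
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.size < 2:
        raise ValueError("need equal-length vectors of size >= 2")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise ValueError("constant observed vector; R² undefined")
    sse = float(np.sum((y - y_hat) ** 2))
    return 1.0 - sse / sst


@dataclass
class ModelResult:
    """A fitted fusion model and its evaluation."""

    kind: str
    estimator: object
    r2_insample: float
    coefficients: pd.Series | None  # standardized, linear models only
    hyperparams: dict
    seed: int
    fold_r2: list = field(default_factory=list)

    @property
    def mean_r2(self) -> float:
        if not self.fold_r2:
            raise ValueError("no cross-validation folds recorded")
        return float(np.mean(self.fold_r2))


def _build_estimator(kind: str, config: dict, seed: int) -> Pipeline:
    config = dict(config or {})
    if kind == "linear_lasso":
        alpha = config.get("alpha")
        if alpha is None:
            reg = LassoCV(cv=config.get("inner_folds", 4),
                          alphas=config.get("n_alphas", 50),
                          random_state=seed, max_iter=50_000)
        else:
            reg = Lasso(alpha=alpha, max_iter=50_000)
    elif kind == "random_forest":
        reg = RandomForestRegressor(
            n_estimators=config.get("n_trees", 10),
            max_features=config.get("max_features", 6),
            random_state=seed)
    elif kind == "mlp":
        reg = MLPRegressor(
            hidden_layer_sizes=(config.get("hidden_units", 32),),
            activation="relu", solver="sgd",
            learning_rate_init=config.get("learning_rate", 0.001),
            max_iter=config.get("max_iter", 500),
            random_state=seed)
    else:
        raise ValueError(f"unknown model kind {kind!r}; "
                         f"expected one of {MODEL_KINDS}")
    return Pipeline([("scale", StandardScaler()), ("reg", reg)])


def fit_model(
    features: pd.DataFrame,
    target: np.ndarray,
    kind: str = "linear_lasso",
    config: dict | None = None,
    seed: int = 0,
) -> ModelResult:
    """Fit one model on the full data and report in-sample R².

    For linear kinds, ``coefficients`` are on z-standardized features.
    With ``config={"refit_ols": True}`` the lasso support is refit by
    unpenalized least squares on the standardized features (coefficients
    of the refit are reported; zero-support features stay zero).
    """
    config = dict(config or {})
    X = features.to_numpy(dtype=float)
    y = np.asarray(target, dtype=float)
    if len(X) < 10:
        raise ValueError("need at least 10 observations")
    if not np.all(np.isfinite(X)):
        bad = features.columns[~np.isfinite(X).all(axis=0)].tolist()
        raise ValueError(f"non-finite feature column(s): {bad}")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite target")

    pipe = _build_estimator(kind, config, seed)
    pipe.fit(X, y)
    r2 = r_squared(y, pipe.predict(X))

    coefs = None
    if kind == "linear_lasso":
        reg = pipe.named_steps["reg"]
        coef = np.asarray(reg.coef_, dtype=float)
        if config.get("refit_ols", False):
            support = coef != 0
            if support.any():
                Z = pipe.named_steps["scale"].transform(X)[:, support]
                ols = LinearRegression().fit(Z, y)
                coef = np.zeros_like(coef)
                coef[support] = ols.coef_
        coefs = pd.Series(coef, index=features.columns, name="coef")

    hyper = dict(config)
    if kind == "linear_lasso" and "alpha" not in hyper:
        hyper["alpha_"] = float(pipe.named_steps["reg"].alpha_)
    return ModelResult(kind=kind, estimator=pipe, r2_insample=r2,
                       coefficients=coefs, hyperparams=hyper, seed=seed)


def cross_validate(
    features: pd.DataFrame,
    target: np.ndarray,
    kind: str = "linear_lasso",
    k: int = 4,
    config: dict | None = None,
    seed: int = 0,
) -> tuple[float, list[float]]:
    """Seeded k-fold cross-validation; returns (mean R², per-fold R²s).

    Each fold is predicted by a model trained on the remaining folds; the
    fold R² compares held-out observations with their predictions.
    """
    if k < 2:
        raise ValueError("need k >= 2 folds")
    X = features.to_numpy(dtype=float)
    y = np.asarray(target, dtype=float)
    if len(X) < k:
        raise ValueError(f"n={len(X)} smaller than {k} folds")
    folds = []
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    for train, test in kf.split(X):
        pipe = _build_estimator(kind, config or {}, seed)
        pipe.fit(X[train], y[train])
        folds.append(r_squared(y[test], pipe.predict(X[test])))
    return float(np.mean(folds)), folds


@dataclass
class FusionEquation:
    """The retained-term linear fusion equation for one stimulus subset."""

    terms: list  # (feature name, signed coefficient), |coef| descending
    threshold: float
    target_label: str = "all"

    def render(self) -> str:
        """Equation text, e.g. ``F_all = 14.2·X_harmonic_energy_mean − ...``."""
        if not self.terms:
            return f"F_{self.target_label} = 0 (no |coefficient| > {self.threshold})"
        parts = []
        for i, (name, c) in enumerate(self.terms):
            mag = f"{abs(c):.1f}·X_{name}"
            if i == 0:
                parts.append(mag if c >= 0 else f"−{mag}")
            else:
                parts.append(("+ " if c >= 0 else "− ") + mag)
        return f"F_{self.target_label} = " + " ".join(parts)


def extract_fusion_equation(
    result: ModelResult,
    threshold: float = 4.0,
    target_label: str = "all",
) -> FusionEquation:
    """Retain standardized coefficients with |c| > threshold, largest first."""
    if result.coefficients is None:
        raise ValueError("equation extraction needs a linear model")
    coefs = result.coefficients
    kept = coefs[coefs.abs() > threshold]
    if kept.empty:
        import warnings

        warnings.warn(f"no coefficients exceed |c| > {threshold}; "
                      "empty fusion equation")
    kept = kept.reindex(kept.abs().sort_values(ascending=False).index)
    return FusionEquation(terms=list(kept.items()), threshold=threshold,
                          target_label=target_label)


def run_grouped_models(
    features: pd.DataFrame,
    target: pd.Series,
    metadata: pd.DataFrame,
    kinds: tuple = MODEL_KINDS,
    k: int = 4,
    config: dict | None = None,
    seed: int = 0,
    coef_threshold: float = 4.0,
) -> dict:
    """Fit every model kind on Chinese-only, Western-only and pooled subsets.

    Returns ``{"results": {(subset, kind): {...}}, "equations": {...},
    "table": DataFrame}`` where the table is the model × subset grid of
    cross-validated mean R².
    """
    meta = metadata.set_index("stimulus_id")
    if not set(features.index) <= set(meta.index):
        raise ValueError("metadata does not label every stimulus")
    culture = meta.loc[features.index, "culture"]

    subsets = {"all": features.index,
               "Chinese": features.index[culture == "Chinese"],
               "Western": features.index[culture == "Western"]}
    results: dict = {}
    equations: dict = {}
    for label, idx in subsets.items():
        if len(idx) < k:
            raise ValueError(f"subset {label!r} smaller than {k} folds")
        Xs = features.loc[idx]
        ys = target.loc[idx].to_numpy(dtype=float)
        for kind in kinds:
            mean_r2, folds = cross_validate(Xs, ys, kind=kind, k=k,
                                            config=config, seed=seed)
            entry = {"mean_r2": mean_r2, "fold_r2": folds}
            if kind == "linear_lasso":
                fitted = fit_model(Xs, ys, kind=kind, config=config, seed=seed)
                eq = extract_fusion_equation(fitted, threshold=coef_threshold,
                                             target_label=label)
                equations[label] = eq
                entry["r2_insample"] = fitted.r2_insample
            results[(label, kind)] = entry

    table = pd.DataFrame(
        {label: {kind: results[(label, kind)]["mean_r2"] for kind in kinds}
         for label in subsets})
    table.index.name = "model"
    return {"results": results, "equations": equations, "table": table}
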