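"""Explainable SVR analytics for tract-level disease prevalence.

The modelling pipeline mirrors standard epidemiological practice for
small-area prevalence modelling: Spearman rank screening of candidate
SDoH features against the outcome, variance-inflation-factor (VIF)
multicollinearity filtering, an 85/15 train/test split with
training-only standardization, a linear-kernel epsilon-insensitive
support vector regression tuned by seeded 5-fold grid-search
cross-validation, RMSE/R-squared evaluation, 0-100 min-max scaled
feature importance from the standardized coefficients, and closed-form
interventional Shapley attribution for a focus neighborhood.

The statsmodels-style entry point is :class:`SdohSvr` (model) /
:class:`SdohSvrResults` (fit results with ``summary()``); the individual
pipeline stages are exposed as functions for reuse and testing.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVR

from upho.tracts import FEATURES, OUTCOME

__all__ = [
    "AnalyticsConfig",
    "CorrelationResult",
    "VifResult",
    "SvrModel",
    "ModelEvaluation",
    "ImportanceResult",
    "AttributionResult",
    "PipelineError",
    "spearman",
    "compute_vif",
    "apply_vif_threshold",
    "split_standardize",
    "fit_svr_linear",
    "grid_search_cv",
    "evaluate",
    "importance",
    "shapley_linear",
    "run_analytics",
    "SdohSvr",
    "SdohSvrResults",
]


class PipelineError(RuntimeError):
    """Unrecoverable analytics-pipeline failure (e.g. no features survive
    screening)."""


@dataclass
class AnalyticsConfig:
    """Tunables of the analytics pipeline.

    Defaults: 85/15 split, 5-fold CV, VIF threshold 10, Spearman screen at
    alpha 0.05, and a small hyperparameter grid spanning under- to
    over-regularization on standardized features.
    """

    train_fraction: float = 0.85
    cv_folds: int = 5
    split_seed: int = 0
    c_grid: tuple[float, ...] = (0.25, 0.5, 1.0, 2.0, 4.0)
    epsilon_grid: tuple[float, ...] = (0.01, 0.1, 0.2, 0.5)
    vif_threshold: float = 10.0
    significance_alpha: float = 0.05

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if any(c <= 0 for c in self.c_grid):
            raise ValueError("C grid values must be positive")
        if any(e < 0 for e in self.epsilon_grid):
            raise ValueError("epsilon grid values must be nonnegative")


@dataclass
class CorrelationResult:
    rho: dict[str, float]
    p_value: dict[str, float]


@dataclass
class VifResult:
    vif: dict[str, float]
    retained: list[str]


@dataclass
class SvrModel:
    """Linear epsilon-SVR in standardized feature space.

    ``weights``/``intercept`` act on standardized features; prediction of a
    raw-space row standardizes with the stored training statistics first.
    """

    features: tuple[str, ...]
    weights: np.ndarray  # standardized space
    intercept: float
    C: float
    epsilon: float
    scaling_mean: np.ndarray
    scaling_sd: np.ndarray

    def predict_standardized(self, x_std: np.ndarray) -> np.ndarray:
        return np.asarray(x_std) @ self.weights + self.intercept

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        x = table[list(self.features)].to_numpy(dtype=float)
        return self.predict_standardized(
            (x - self.scaling_mean) / self.scaling_sd
        )

    @property
    def raw_weights(self) -> np.ndarray:
        """Weights expressed in unstandardized (per-unit-feature) space."""
        return self.weights / self.scaling_sd


@dataclass
class ModelEvaluation:
    rmse_train: float
    r2_train: float
    rmse_test: float
    r2_test: float


@dataclass
class ImportanceResult:
    raw: dict[str, float]
    scaled: dict[str, float]

    def ranking(self) -> list[str]:
        """Features from most to least important (ties alphabetical)."""
        return sorted(self.scaled, key=lambda f: (-self.scaled[f], f))


@dataclass
class AttributionResult:
    geoid: str
    phi: dict[str, float]
    baseline_prediction: float
    instance_prediction: float


# --- pipeline stages ----------------------------------------------------

def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with midranks for ties; p-value from the
    t approximation with n-2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def compute_vif(table: pd.DataFrame, features: list[str],
                threshold: float = 10.0) -> VifResult:
    """VIF_j = 1 / (1 - R^2_j) from least squares of feature j on the
    remaining features plus an intercept; exact collinearity reports
    +infinity and the feature is dropped."""
    features = list(features)
    if len(features) < 2:
        raise ValueError("VIF needs at least 2 features")
    x = table[features].to_numpy(dtype=float)
    n, p = x.shape
    if n <= p + 1:
        raise ValueError("VIF needs more rows than features + 1")
    vifs: dict[str, float] = {}
    for j, f in enumerate(features):
        yj = x[:, j]
        design = np.column_stack(
            [np.ones(n), np.delete(x, j, axis=1)]
        )
        coef, *_ = np.linalg.lstsq(design, yj, rcond=None)
        resid = yj - design @ coef
        ss_tot = float(np.sum((yj - yj.mean()) ** 2))
        if ss_tot == 0.0:
            vifs[f] = float("inf")
            continue
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
        if r2 >= 1.0 - 1e-12:
            vifs[f] = float("inf")
        else:
            vifs[f] = float(1.0 / (1.0 - r2))
    return VifResult(vif=vifs,
                     retained=apply_vif_threshold(vifs, threshold))


def apply_vif_threshold(vifs: dict[str, float],
                        threshold: float) -> list[str]:
    """Features whose VIF does not exceed the threshold, input order kept."""
    return [f for f, v in vifs.items() if v <= threshold]


def split_standardize(table: pd.DataFrame, outcome: str,
                      features: list[str], config: AnalyticsConfig):
    """Seeded train/test split plus training-only standardization.

    Train size is round-half-up of ``n * train_fraction``.  Features are
    centred/scaled by training mean and (population) SD; the outcome stays
    in its native units.  Returns
    ``(X_train, y_train, X_test, y_test, scaling_mean, scaling_sd,
    train_idx, test_idx)``.
    """
    n = len(table)
    n_train = int(np.floor(n * config.train_fraction + 0.5))
    if n_train >= n or n_train < 1:
        raise ValueError(
            f"split leaves an empty portion (n={n}, train={n_train})"
        )
    rng = np.random.default_rng(config.split_seed)
    perm = rng.permutation(n)
    train_idx, test_idx = np.sort(perm[:n_train]), np.sort(perm[n_train:])
    x = table[list(features)].to_numpy(dtype=float)
    y = table[outcome].to_numpy(dtype=float)
    mean = x[train_idx].mean(axis=0)
    sd = x[train_idx].std(axis=0)
    if np.any(sd <= 0):
        bad = [f for f, s in zip(features, sd) if s <= 0]
        raise ValueError(f"zero training variance in features {bad}")
    xs = (x - mean) / sd
    return (xs[train_idx], y[train_idx], xs[test_idx], y[test_idx],
            mean, sd, train_idx, test_idx)


def fit_svr_linear(x: np.ndarray, y: np.ndarray, c: float, epsilon: float,
                   features: tuple[str, ...] | None = None,
                   scaling_mean: np.ndarray | None = None,
                   scaling_sd: np.ndarray | None = None,
                   tol: float = 1e-5) -> SvrModel:
    """Fit a linear-kernel epsilon-SVR minimizing
    ``0.5 * ||w||^2 + C * sum(max(0, |y - w.x - b| - epsilon))``.

    The dual solver occasionally stalls near its optimum at tight
    tolerances on strongly collinear designs; if the iteration cap is hit
    the fit is retried at a 10x and 100x looser tolerance before a
    non-convergence error is raised.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    svr = None
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=UserWarning)
        last = None
        for t in (tol, 10 * tol, 100 * tol):
            try:
                svr = SVR(kernel="linear", C=c, epsilon=epsilon, tol=t,
                          max_iter=5_000_000).fit(x, y)
                break
            except UserWarning as exc:  # libsvm ran out of iterations
                last = exc
        if svr is None:
            raise PipelineError(
                f"SVR did not converge (C={c}, epsilon={epsilon}): {last}"
            ) from None
    p = x.shape[1]
    if features is None:
        features = tuple(f"x{i}" for i in range(p))
    return SvrModel(
        features=tuple(features),
        weights=np.asarray(svr.coef_, dtype=float).ravel(),
        intercept=float(svr.intercept_[0]),
        C=float(c),
        epsilon=float(epsilon),
        scaling_mean=(np.zeros(p) if scaling_mean is None
                      else np.asarray(scaling_mean, dtype=float)),
        scaling_sd=(np.ones(p) if scaling_sd is None
                    else np.asarray(scaling_sd, dtype=float)),
    )


def svr_objective(model: SvrModel, x: np.ndarray, y: np.ndarray) -> float:
    """Primal objective value of a fitted model on its training data."""
    resid = np.abs(y - (x @ model.weights + model.intercept))
    loss = np.maximum(0.0, resid - model.epsilon).sum()
    return float(0.5 * model.weights @ model.weights + model.C * loss)


def cv_folds(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Seeded shuffle, then contiguous blocks; remainder rows go one per
    leading fold."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    base, extra = divmod(n, k)
    folds, start = [], 0
    for i in range(k):
        size = base + (1 if i < extra else 0)
        folds.append(perm[start:start + size])
        start += size
    return folds


def grid_search_cv(x: np.ndarray, y: np.ndarray,
                   config: AnalyticsConfig):
    """Exhaustive grid search minimizing mean CV RMSE.

    Ties break toward smaller C, then smaller epsilon.  Returns
    ``((best_c, best_epsilon), cv_table)`` where the table maps
    ``(C, epsilon) -> mean RMSE``.
    """
    if not config.c_grid or not config.epsilon_grid:
        raise ValueError("hyperparameter grid is empty")
    n = len(y)
    folds = cv_folds(n, config.cv_folds, config.split_seed)
    if min(len(f) for f in folds) < 2:
        raise ValueError("a CV fold has fewer than 2 observations")
    cv_table: dict[tuple[float, float], float] = {}
    for c in config.c_grid:
        for eps in config.epsilon_grid:
            rmses = []
            for i, hold in enumerate(folds):
                keep = np.concatenate(
                    [f for j, f in enumerate(folds) if j != i]
                )
                m = fit_svr_linear(x[keep], y[keep], c, eps)
                pred = m.predict_standardized(x[hold])
                rmses.append(
                    float(np.sqrt(np.mean((y[hold] - pred) ** 2)))
                )
            cv_table[(c, eps)] = float(np.mean(rmses))
    best = min(cv_table, key=lambda k: (cv_table[k], k[0], k[1]))
    return best, cv_table


def evaluate(model: SvrModel, x: np.ndarray, y: np.ndarray):
    """RMSE and R-squared (about the sample mean of y) on one split."""
    y = np.asarray(y, dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("R^2 undefined for zero-variance outcome")
    pred = model.predict_standardized(np.asarray(x, dtype=float))
    rmse = float(np.sqrt(np.mean((y - pred) ** 2)))
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return rmse, 1.0 - ss_res / ss_tot


def importance(model: SvrModel) -> ImportanceResult:
    """Data-set-level importance: |standardized coefficient|, min-max
    scaled to [0, 100].  Degenerate (all-equal) magnitudes scale to 0 with
    a warning."""
    raw = np.abs(model.weights)
    lo, hi = float(raw.min()), float(raw.max())
    if hi - lo <= 0:
        warnings.warn(
            "all coefficient magnitudes equal; scaled importances set to 0",
            stacklevel=2,
        )
        scaled = np.zeros_like(raw)
    else:
        scaled = 100.0 * (raw - lo) / (hi - lo)
    return ImportanceResult(
        raw={f: float(r) for f, r in zip(model.features, raw)},
        scaled={f: float(s) for f, s in zip(model.features, scaled)},
    )


def shapley_linear(model: SvrModel, instance: pd.Series | dict,
                   background_table: pd.DataFrame) -> AttributionResult:
    """Closed-form interventional Shapley values for a linear model.

    With independent features, ``phi_j = w'_j * (x_j - mean(bg_j))`` where
    ``w'`` are the raw-space weights; efficiency
    ``sum(phi) = f(x) - f(bg mean)`` holds exactly.
    """
    if isinstance(instance, dict):
        instance = pd.Series(instance)
    missing = [f for f in model.features if f not in instance.index]
    if missing:
        raise ValueError(f"instance missing features {missing}")
    x = instance[list(model.features)].to_numpy(dtype=float)
    bg = background_table[list(model.features)].to_numpy(dtype=float)
    bg_mean = bg.mean(axis=0)
    w_raw = model.raw_weights
    phi = w_raw * (x - bg_mean)
    baseline = float(
        model.predict_standardized(
            (bg_mean - model.scaling_mean) / model.scaling_sd
        )
    )
    pred = float(
        model.predict_standardized(
            (x - model.scaling_mean) / model.scaling_sd
        )
    )
    geoid = str(instance.get("geoid", ""))
    return AttributionResult(
        geoid=geoid,
        phi={f: float(v) for f, v in zip(model.features, phi)},
        baseline_prediction=baseline,
        instance_prediction=pred,
    )


# --- statsmodels-style surface ------------------------------------------

class SdohSvr:
    """Explainable SVR model of a tract-level prevalence outcome.

    Parameters
    ----------
    data : DataFrame
        Tract table with a ``geoid`` column, the outcome, and features.
    outcome : str
        Outcome column (percent prevalence).
    features : sequence of str, optional
        Candidate features; defaults to the canonical SDoH feature set
        intersected with the table's columns.
    config : AnalyticsConfig, optional
    """

    def __init__(self, data: pd.DataFrame, outcome: str = OUTCOME,
                 features=None, config: AnalyticsConfig | None = None):
        self.data = data.reset_index(drop=True)
        self.outcome = outcome
        if features is None:
            features = [f for f in FEATURES if f in data.columns]
        self.candidate_features = list(features)
        if outcome not in data.columns:
            raise PipelineError(f"outcome column {outcome!r} not in table")
        missing = [f for f in self.candidate_features
                   if f not in data.columns]
        if missing:
            raise PipelineError(f"feature columns missing: {missing}")
        self.config = config or AnalyticsConfig()

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, outcome: str = OUTCOME,
                       features=None,
                       config: AnalyticsConfig | None = None) -> "SdohSvr":
        return cls(data, outcome, features, config)

    def fit(self, focus_geoid: str | None = None) -> "SdohSvrResults":
        """Run the full pipeline: Spearman screen → VIF filter → split &
        standardize → grid-search CV → final SVR fit → evaluation →
        importance → (optional) focus-tract Shapley attribution."""
        cfg = self.config
        y_all = self.data[self.outcome].to_numpy(dtype=float)
        rho, pval = {}, {}
        screened = []
        for f in self.candidate_features:
            r, p = spearman(self.data[f].to_numpy(dtype=float), y_all)
            rho[f], pval[f] = r, p
            if p <= cfg.significance_alpha:
                screened.append(f)
        corr = CorrelationResult(rho=rho, p_value=pval)
        if len(screened) < 2:
            raise PipelineError(
                f"only {len(screened)} features pass the Spearman screen"
            )
        vif = compute_vif(self.data, screened, cfg.vif_threshold)
        feats = vif.retained
        if len(feats) < 2:
            raise PipelineError(
                f"only {len(feats)} features survive the VIF filter"
            )
        (x_tr, y_tr, x_te, y_te, mean, sd,
         train_idx, test_idx) = split_standardize(
            self.data, self.outcome, feats, cfg
        )
        (best_c, best_eps), cv_table = grid_search_cv(x_tr, y_tr, cfg)
        model = fit_svr_linear(x_tr, y_tr, best_c, best_eps,
                               features=tuple(feats),
                               scaling_mean=mean, scaling_sd=sd)
        rmse_tr, r2_tr = evaluate(model, x_tr, y_tr)
        rmse_te, r2_te = evaluate(model, x_te, y_te)
        ev = ModelEvaluation(rmse_train=rmse_tr, r2_train=r2_tr,
                             rmse_test=rmse_te, r2_test=r2_te)
        imp = importance(model)
        attribution = None
        if focus_geoid is not None:
            rows = self.data[self.data["geoid"].astype(str)
                             == str(focus_geoid)]
            if rows.empty:
                raise PipelineError(
                    f"focus geoid {focus_geoid!r} not in table"
                )
            attribution = shapley_linear(model, rows.iloc[0], self.data)
        return SdohSvrResults(
            model=self, correlations=corr, vif=vif, svr=model,
            evaluation=ev, importance=imp, attribution=attribution,
            cv_table=cv_table, train_idx=train_idx, test_idx=test_idx,
        )


@dataclass
class SdohSvrResults:
    """Fit results: every pipeline stage's output plus a summary table."""

    model: SdohSvr
    correlations: CorrelationResult
    vif: VifResult
    svr: SvrModel
    evaluation: ModelEvaluation
    importance: ImportanceResult
    attribution: AttributionResult | None
    cv_table: dict[tuple[float, float], float]
    train_idx: np.ndarray = field(repr=False, default=None)
    test_idx: np.ndarray = field(repr=False, default=None)

    def summary(self) -> str:
        ev, imp = self.evaluation, self.importance
        lines = [
            "SDoH linear-kernel epsilon-SVR results",
            "=" * 54,
            f"outcome: {self.model.outcome}   n = {len(self.model.data)} "
            f"(train {len(self.train_idx)} / test {len(self.test_idx)})",
            f"hyperparameters: C = {self.svr.C:g}, "
            f"epsilon = {self.svr.epsilon:g} (5-fold grid-search CV)",
            f"RMSE  train {ev.rmse_train:.3f}   test {ev.rmse_test:.3f}",
            f"R^2   train {ev.r2_train:.3f}   test {ev.r2_test:.3f}",
            "",
            f"{'feature':<26}{'spearman':>9}{'VIF':>8}"
            f"{'coef(std)':>11}{'imp 0-100':>11}",
            "-" * 65,
        ]
        for f in imp.ranking():
            i = self.svr.features.index(f)
            lines.append(
                f"{f:<26}{self.correlations.rho[f]:>9.2f}"
                f"{self.vif.vif[f]:>8.2f}"
                f"{self.svr.weights[i]:>11.3f}"
                f"{imp.scaled[f]:>11.2f}"
            )
        if self.attribution is not None:
            a = self.attribution
            lines += [
                "",
                f"Shapley attribution for tract {a.geoid} "
                f"(baseline {a.baseline_prediction:.2f}, "
                f"prediction {a.instance_prediction:.2f}):",
            ]
            for f, v in sorted(a.phi.items(), key=lambda kv: -abs(kv[1])):
                lines.append(f"  {f:<26}{v:>+9.3f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        out = {
            "outcome": self.model.outcome,
            "features": list(self.svr.features),
            "correlations": {
                "rho": self.correlations.rho,
                "p_value": self.correlations.p_value,
            },
            "vif": self.vif.vif,
            "retained": self.vif.retained,
            "hyperparameters": {"C": self.svr.C,
                                "epsilon": self.svr.epsilon},
            "coefficients": {
                f: float(w) for f, w in zip(self.svr.features,
                                            self.svr.weights)
            },
            "intercept": self.svr.intercept,
            "evaluation": {
                "rmse_train": self.evaluation.rmse_train,
                "r2_train": self.evaluation.r2_train,
                "rmse_test": self.evaluation.rmse_test,
                "r2_test": self.evaluation.r2_test,
            },
            "importance": {
                "raw": self.importance.raw,
                "scaled": self.importance.scaled,
            },
            "cv_table": [
                {"C": c, "epsilon": e, "mean_rmse": r}
                for (c, e), r in sorted(self.cv_table.items())
            ],
        }
        if self.attribution is not None:
            a = self.attribution
            out["attribution"] = {
                "geoid": a.geoid,
                "phi": a.phi,
                "baseline_prediction": a.baseline_prediction,
                "instance_prediction": a.instance_prediction,
            }
        return out

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 1)
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)


def run_analytics(table: pd.DataFrame, outcome: str = OUTCOME,
                  features=None, focus_geoid: str | None = None,
                  config: AnalyticsConfig | None = None) -> SdohSvrResults:
    """Functional wrapper over :class:`SdohSvr` running the whole
    pipeline in one call."""
    return SdohSvr(table, outcome, features, config).fit(focus_geoid)
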