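"""Survival predictors of decreasing explainability.

Three estimator families for death-censored graft survival, exposed as
scikit-learn-style estimators (``fit`` / ``predict_survival_prob`` /
``predict_rmst``, ``get_params``/``set_params``, fitted attributes with a
trailing underscore):

* :class:`CoxPHModel` — Cox proportional hazards, partial likelihood with
  Breslow tie handling and Breslow baseline (high explainability);
* :class:`SurvivalTreeModel` — recursive log-rank splitting with
  Kaplan–Meier leaf curves (high explainability);
* :class:`RandomSurvivalForestModel` — bootstrap ensemble of such trees with
  random feature subsets, ensemble-average survival curve (low
  explainability).

Fitting is backed by scikit-survival; the prediction contracts (probability
in [0, 1] and non-increasing in t, RMST by trapezoidal integration on the
model's survival-curve grid) are enforced and tested here. The module also
provides leakage-free single imputation, the Monte-Carlo cross-validation
protocol (default ten repetitions of an 80/20 split), and subpopulation
undersampling used for the data-imbalance check.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, clone
from sksurv.ensemble import RandomSurvivalForest
from sksurv.linear_model import CoxPHSurvivalAnalysis
from sksurv.nonparametric import kaplan_meier_estimator
from sksurv.tree import SurvivalTree
from sksurv.util import Surv

from .errors import ConfigurationError, DataError, UnfitError

__all__ = [
    "EXPLAINABILITY_LABELS",
    "CVProtocol",
    "SingleImputer",
    "single_impute",
    "BaseSurvivalModel",
    "CoxPHModel",
    "SurvivalTreeModel",
    "RandomSurvivalForestModel",
    "ConstantRMSTModel",
    "make_model",
    "survival_target",
    "monte_carlo_cv",
    "undersample_to_group",
]

logger = logging.getLogger(__name__)

# Explainability tier per family, fixed by construction of the families:
# Cox and single survival trees are transparent, forests are not.
EXPLAINABILITY_LABELS = {
    "cox": "high",
    "survival_tree": "high",
    "random_survival_forest": "low",
}


def survival_target(df: pd.DataFrame, time_col: str = "time_days",
                    event_col: str = "event") -> np.ndarray:
    """Structured (event, time) array from a registry frame."""
    return Surv.from_arrays(
        event=df[event_col].to_numpy().astype(bool),
        time=df[time_col].to_numpy(dtype=float),
    )


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------


class SingleImputer(BaseEstimator):
    """Single imputation: training-split median (numeric) or mode (other).

    Values are learned on the training split only and reused verbatim on any
    later split, so no information leaks from test to train.
    """

    def __init__(self, columns: list[str] | None = None):
        self.columns = columns

    def fit(self, df: pd.DataFrame, y=None) -> "SingleImputer":
        cols = self.columns if self.columns is not None else list(df.columns)
        fill = {}
        for col in cols:
            s = df[col]
            if s.notna().sum() == 0:
                raise DataError(f"feature {col!r} entirely missing in training split")
            if pd.api.types.is_numeric_dtype(s):
                fill[col] = float(s.median())
            else:
                fill[col] = s.mode(dropna=True).iloc[0]
        self.fill_values_ = fill
        return self

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        for col, value in self.fill_values_.items():
            if col in out.columns:
                out[col] = out[col].fillna(value)
        return out

    def fit_transform(self, df: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(df).transform(df)


def single_impute(
    train: pd.DataFrame, test: pd.DataFrame | None = None,
    columns: list[str] | None = None,
):
    """Impute feature columns; returns train (and test, if given) filled."""
    imputer = SingleImputer(columns=columns).fit(train)
    if test is None:
        return imputer.transform(train)
    return imputer.transform(train), imputer.transform(test)


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------


def _check_matrix(X: np.ndarray) -> np.ndarray:
    if not np.all(np.isfinite(X)):
        raise DataError("non-finite feature value passed to survival model")
    return X


def _rmst_from_curves(times: np.ndarray, surv: np.ndarray, horizon: float) -> np.ndarray:
    """Trapezoidal ∫₀^H S(t) dt on the curve grid, per row of ``surv``.

    The grid is [0] ∪ {curve times ≤ H} ∪ [H]; S(0) = 1 and the curve value
    is carried forward to H.
    """
    surv = np.atleast_2d(surv)
    keep = times <= horizon
    t = np.concatenate([[0.0], times[keep], [horizon]])
    s = np.concatenate(
        [np.ones((surv.shape[0], 1)), surv[:, keep],
         (surv[:, keep][:, -1:] if keep.any() else np.ones((surv.shape[0], 1)))],
        axis=1,
    )
    return np.trapezoid(s, t, axis=1)


class BaseSurvivalModel(BaseEstimator):
    """Shared contract for the three predictor families."""

    family: str = ""

    @property
    def explainability_label(self) -> str:
        return EXPLAINABILITY_LABELS[self.family]

    # subclasses set: feature_names_, event_times_
    def _validate_fit_inputs(self, X: pd.DataFrame, y) -> np.ndarray:
        if int(y["event"].sum()) < 2:
            raise UnfitError("need at least 2 observed events to fit a survival model")
        self.feature_names_ = list(X.columns)
        return _check_matrix(X.to_numpy(dtype=float))

    def _matrix(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [c for c in self.feature_names_ if c not in X.columns]
            if missing:
                raise DataError(f"missing feature column(s): {missing}")
            return _check_matrix(X[self.feature_names_].to_numpy(dtype=float))
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.feature_names_):
            raise DataError(
                f"expected {len(self.feature_names_)} features, got {X.shape[1]}"
            )
        return _check_matrix(X)

    # -- prediction contract ---------------------------------------------
    def predict_survival_curves(self, X) -> tuple[np.ndarray, np.ndarray]:
        """(times, S) with S of shape (n_samples, n_times)."""
        raise NotImplementedError

    def predict_survival_prob(self, X, t_days: float) -> np.ndarray:
        """P(graft survives past t) per sample; 1 at t=0, non-increasing in t."""
        if t_days < 0:
            raise DataError("t_days must be >= 0")
        times, surv = self.predict_survival_curves(X)
        idx = np.searchsorted(times, t_days, side="right") - 1
        if idx < 0:
            return np.ones(surv.shape[0])
        return surv[:, idx]

    def predict_rmst(self, X, horizon_days: float) -> np.ndarray:
        """Restricted mean survival time ∫₀^H S(t) dt, in [0, H] days."""
        if horizon_days <= 0:
            raise DataError("horizon_days must be > 0")
        times, surv = self.predict_survival_curves(X)
        return _rmst_from_curves(times, surv, horizon_days)


class CoxPHModel(BaseSurvivalModel):
    """Cox proportional hazards with Breslow ties and Breslow baseline.

    ``S(t | x) = S0(t)^{exp(xᵀβ)}``. The fast paths used by the allocation
    simulator evaluate the baseline step function directly and interpolate an
    exact precomputed map from relative hazard to RMST.
    """

    family = "cox"

    def __init__(self, alpha: float = 0.0):
        self.alpha = alpha

    def fit(self, X: pd.DataFrame, y) -> "CoxPHModel":
        Xm = self._validate_fit_inputs(X, y)
        self._est = CoxPHSurvivalAnalysis(alpha=self.alpha)
        self._est.fit(Xm, y)
        self.coef_ = self._est.coef_
        ch = self._est.cum_baseline_hazard_
        self.event_times_ = np.asarray(ch.x, dtype=float)
        self.baseline_survival_ = np.exp(-np.asarray(ch.y, dtype=float))
        self._rmst_cache: dict[float, tuple[np.ndarray, np.ndarray]] = {}
        return self

    def linear_predictor(self, X) -> np.ndarray:
        return self._matrix(X) @ self.coef_

    def predict_survival_curves(self, X):
        lp = self.linear_predictor(X)
        return self.event_times_, np.power(
            self.baseline_survival_[None, :], np.exp(lp)[:, None]
        )

    def predict_survival_prob(self, X, t_days: float) -> np.ndarray:
        if t_days < 0:
            raise DataError("t_days must be >= 0")
        idx = np.searchsorted(self.event_times_, t_days, side="right") - 1
        s0 = self.baseline_survival_[idx] if idx >= 0 else 1.0
        return np.power(s0, np.exp(self.linear_predictor(X)))

    # -- fast RMST path ---------------------------------------------------
    def _rmst_table(self, horizon: float) -> tuple[np.ndarray, np.ndarray]:
        """Exact RMST(e) = ∫ S0(t)^e dt on a dense log-spaced grid of e."""
        if horizon not in self._rmst_cache:
            log_e = np.linspace(np.log(1e-6), np.log(1e6), 4097)
            e = np.exp(log_e)
            keep = self.event_times_ <= horizon
            t = np.concatenate([[0.0], self.event_times_[keep], [horizon]])
            s0 = np.concatenate(
                [[1.0], self.baseline_survival_[keep],
                 self.baseline_survival_[keep][-1:] if keep.any() else [1.0]]
            )
            with np.errstate(divide="ignore"):
                log_s0 = np.log(np.clip(s0, 1e-300, 1.0))
            curves = np.exp(e[:, None] * log_s0[None, :])
            self._rmst_cache[horizon] = (log_e, np.trapezoid(curves, t, axis=1))
        return self._rmst_cache[horizon]

    def predict_rmst(self, X, horizon_days: float) -> np.ndarray:
        if horizon_days <= 0:
            raise DataError("horizon_days must be > 0")
        return self.rmst_from_linear_predictor(self.linear_predictor(X), horizon_days)

    def rmst_from_linear_predictor(self, lp: np.ndarray, horizon_days: float) -> np.ndarray:
        log_e_grid, rmst_grid = self._rmst_table(horizon_days)
        log_e = np.clip(np.asarray(lp, dtype=float), log_e_grid[0], log_e_grid[-1])
        return np.interp(log_e, log_e_grid, rmst_grid)


class _PooledKM:
    """Degenerate single-leaf tree: the pooled Kaplan–Meier curve."""

    def __init__(self, y):
        times, probs = kaplan_meier_estimator(y["event"], y["time"])
        self.times = np.asarray(times, dtype=float)
        self.probs = np.asarray(probs, dtype=float)


class SurvivalTreeModel(BaseSurvivalModel):
    """Survival decision tree: log-rank splits, Kaplan–Meier leaf curves.

    ``max_depth=0`` gives the degenerate single-leaf tree whose prediction is
    the pooled Kaplan–Meier curve of the training data. Deterministic given
    the data.
    """

    family = "survival_tree"

    def __init__(self, max_depth: int | None = None, min_leaf_size: int = 50):
        self.max_depth = max_depth
        self.min_leaf_size = min_leaf_size

    def fit(self, X: pd.DataFrame, y) -> "SurvivalTreeModel":
        if self.min_leaf_size < 1:
            raise ConfigurationError("min_leaf_size must be >= 1")
        if self.max_depth is not None and self.max_depth < 0:
            raise ConfigurationError("max_depth must be >= 0")
        Xm = self._validate_fit_inputs(X, y)
        if self.max_depth == 0:
            self._km = _PooledKM(y)
            self.event_times_ = self._km.times
            self._est = None
            return self
        self._km = None
        self._est = SurvivalTree(
            max_depth=self.max_depth,
            min_samples_leaf=self.min_leaf_size,
            random_state=0,
        )
        self._est.fit(Xm, y)
        self.event_times_ = np.asarray(self._est.unique_times_, dtype=float)
        # Per-leaf survival curves via one representative training row per leaf.
        leaves = self._est.apply(Xm.astype(np.float32))
        uniq, first = np.unique(leaves, return_index=True)
        reps = Xm[first]
        curves = self._est.predict_survival_function(reps, return_array=True)
        self._leaf_index = {int(l): i for i, l in enumerate(uniq)}
        self._leaf_curves = np.asarray(curves, dtype=float)
        return self

    def predict_survival_curves(self, X):
        Xm = self._matrix(X)
        if self._est is None:
            return self._km.times, np.tile(self._km.probs, (Xm.shape[0], 1))
        leaves = self._est.apply(Xm.astype(np.float32))
        rows = np.array([self._leaf_index[int(l)] for l in leaves])
        return self.event_times_, self._leaf_curves[rows]


class RandomSurvivalForestModel(BaseSurvivalModel):
    """Random survival forest: bootstrap ensemble of log-rank trees.

    Prediction is the ensemble-average survival curve; deterministic given
    ``random_state``. Classified as non-explainable.
    """

    family = "random_survival_forest"

    def __init__(
        self,
        n_trees: int = 100,
        max_features: str | int | float | None = "sqrt",
        bootstrap: bool = True,
        min_leaf_size: int = 15,
        max_depth: int | None = None,
        random_state: int = 0,
    ):
        self.n_trees = n_trees
        self.max_features = max_features
        self.bootstrap = bootstrap
        self.min_leaf_size = min_leaf_size
        self.max_depth = max_depth
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y) -> "RandomSurvivalForestModel":
        if self.n_trees < 1:
            raise ConfigurationError("n_trees must be >= 1")
        Xm = self._validate_fit_inputs(X, y)
        self._est = RandomSurvivalForest(
            n_estimators=self.n_trees,
            max_features=self.max_features,
            bootstrap=self.bootstrap,
            min_samples_leaf=self.min_leaf_size,
            max_depth=self.max_depth,
            random_state=self.random_state,
            n_jobs=1,
        )
        self._est.fit(Xm, y)
        self.event_times_ = np.asarray(self._est.unique_times_, dtype=float)
        return self

    def predict_survival_curves(self, X):
        Xm = self._matrix(X)
        surv = self._est.predict_survival_function(Xm, return_array=True)
        return self.event_times_, np.asarray(surv, dtype=float)


class ConstantRMSTModel(BaseSurvivalModel):
    """Predicts one fixed exponential survival curve for every input.

    Useful as a null model: under it every allocation-policy score ties, so
    survival-maximizing and hybrid policies reduce to their waiting-time tie
    rules.
    """

    family = "cox"  # label only; transparent by construction

    def __init__(self, rmst_days: float = 2000.0):
        self.rmst_days = rmst_days

    def fit(self, X=None, y=None) -> "ConstantRMSTModel":
        self.feature_names_ = list(X.columns) if isinstance(X, pd.DataFrame) else []
        self.event_times_ = np.linspace(0.0, 10 * self.rmst_days, 512)
        self._curve = np.exp(-self.event_times_ / self.rmst_days)
        return self

    def _n(self, X) -> int:
        if isinstance(X, pd.DataFrame):
            return len(X)
        return np.atleast_2d(np.asarray(X)).shape[0]

    def predict_survival_curves(self, X):
        n = self._n(X)
        return self.event_times_, np.tile(self._curve, (n, 1))

    def predict_rmst(self, X, horizon_days: float) -> np.ndarray:
        if horizon_days <= 0:
            raise DataError("horizon_days must be > 0")
        # closed form for the exponential curve; constant across inputs
        lam = 1.0 / self.rmst_days
        value = (1.0 - np.exp(-lam * horizon_days)) / lam
        return np.full(self._n(X), value)


def make_model(family: str, **hyperparameters) -> BaseSurvivalModel:
    """Factory keyed by family name (``cox`` / ``survival_tree`` /
    ``random_survival_forest``)."""
    families = {
        "cox": CoxPHModel,
        "survival_tree": SurvivalTreeModel,
        "random_survival_forest": RandomSurvivalForestModel,
    }
    if family not in families:
        raise ConfigurationError(f"unknown model family {family!r}")
    return families[family](**hyperparameters)


# ---------------------------------------------------------------------------
# Monte-Carlo cross-validation
# ---------------------------------------------------------------------------


@dataclass
class CVProtocol:
    """Repeated random train/test splitting (default 10 × 80/20)."""

    n_reps: int = 10
    train_fraction: float = 0.80
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ConfigurationError("train_fraction must be in (0, 1)")
        if self.n_reps < 1:
            raise ConfigurationError("n_reps must be >= 1")


def monte_carlo_cv(
    records: pd.DataFrame,
    models: dict[str, BaseSurvivalModel],
    protocol: CVProtocol,
    feature_cols: list[str],
    eval_time_days: float = 1826.0,
    rmst_horizon_days: float = 3650.0,
    group_cols: list[str] | None = None,
    max_redraws: int = 10,
) -> pd.DataFrame:
    """Per-repetition, per-model test-set predictions.

    Each repetition draws a seeded random 80/20 split, learns imputation on
    the training split, fits every model on the same split, and stores the
    test-set predictions (survival probability at ``eval_time_days`` and RMST
    at ``rmst_horizon_days``). Splits with fewer than two observed events on
    either side are redrawn (logged, at most ``max_redraws`` times).

    Returns a long frame with columns: rep, model, record_id, any group
    columns, time_days, event, pred_prob, pred_rmst.
    """
    if len(records) < 10:
        raise DataError("monte_carlo_cv needs at least 10 records")
    n = len(records)
    n_train = int(round(protocol.train_fraction * n))
    rep_seeds = np.random.SeedSequence(protocol.seed).generate_state(
        protocol.n_reps * (max_redraws + 1)
    ) % (2**31)
    rows = []
    seed_iter = iter(rep_seeds.tolist())
    for rep in range(protocol.n_reps):
        for attempt in range(max_redraws + 1):
            rng = np.random.default_rng(next(seed_iter))
            perm = rng.permutation(n)
            train_idx, test_idx = perm[:n_train], perm[n_train:]
            ev = records["event"].to_numpy()
            if ev[train_idx].sum() >= 2 and ev[test_idx].sum() >= 2:
                break
            logger.warning("rep %d split redrawn (attempt %d): too few events",
                           rep, attempt + 1)
        else:
            raise DataError(f"rep {rep}: could not draw a split with enough events")
        train = records.iloc[train_idx]
        test = records.iloc[test_idx]
        imputer = SingleImputer(columns=feature_cols).fit(train)
        train_f, test_f = imputer.transform(train), imputer.transform(test)
        y_train = survival_target(train_f)
        for name, model in models.items():
            fitted = clone(model).fit(train_f[feature_cols], y_train)
            prob = fitted.predict_survival_prob(test_f[feature_cols], eval_time_days)
            rmst = fitted.predict_rmst(test_f[feature_cols], rmst_horizon_days)
            out = pd.DataFrame(
                {
                    "rep": rep,
                    "model": name,
                    "record_id": test["record_id"].to_numpy(),
                    "time_days": test["time_days"].to_numpy(dtype=float),
                    "event": test["event"].to_numpy(dtype=int),
                    "pred_prob": np.asarray(prob, dtype=float),
                    "pred_rmst": np.asarray(rmst, dtype=float),
                }
            )
            for col in group_cols or []:
                out[col] = test[col].to_numpy()
            rows.append(out)
    return pd.concat(rows, ignore_index=True)


def group_dummy_features(
    df: pd.DataFrame, group_col: str, levels: list | None = None
) -> tuple[pd.DataFrame, list[str]]:
    """Append 0/1 indicator columns for a group dimension's levels.

    Group labels are not observed covariates by default, but a model may
    deliberately include them (points-style allocation scores historically
    did); the returned column names can be added to a model's feature set.
    Reference coding: the first level is dropped.
    """
    levels = levels if levels is not None else sorted(pd.unique(df[group_col]))
    out = df.copy()
    names = []
    for level in levels[1:]:
        name = f"{group_col}_{level}"
        out[name] = (df[group_col] == level).astype(float)
        names.append(name)
    return out, names


def undersample_to_group(
    records: pd.DataFrame,
    groups_to_shrink: list,
    reference_group,
    group_col: str,
    seed: int = 0,
) -> pd.DataFrame:
    """Downsample listed groups to the reference group's size.

    Sampling is without replacement; groups already no larger than the
    reference are left untouched (with a warning). Used to test whether
    prediction biases stem from data imbalance.
    """
    ref_n = int((records[group_col] == reference_group).sum())
    if ref_n == 0:
        raise DataError(f"reference group {reference_group!r} is empty")
    rng = np.random.default_rng(seed)
    keep = np.ones(len(records), dtype=bool)
    values = records[group_col].to_numpy()
    for g in groups_to_shrink:
        idx = np.flatnonzero(values == g)
        if idx.size <= ref_n:
            if idx.size < ref_n:
                warnings.warn(
                    f"group {g!r} ({idx.size}) smaller than reference ({ref_n}); left untouched"
                )
            continue
        drop = rng.choice(idx, size=idx.size - ref_n, replace=False)
        keep[drop] = False
    return records.iloc[np.flatnonzero(keep)].reset_index(drop=True)
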