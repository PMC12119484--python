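"""Prediction-performance and prediction-equity metrics.

Calibration (IPCW Brier score, IPCW mean signed error) and discrimination
(Harrell's C-index) for right-censored 5-year survival predictions, plus the
*subpopulation C-index*: Harrell's C restricted to comparable pairs with at
least one member in the subpopulation, so a group's discrimination is scored
on exactly the orderings that involve it.

Sign convention for the mean signed error: the weighted mean of
(𝟙[T > t] − p̂), so a NEGATIVE group value means the group's survival is
overestimated by the model.

:func:`group_metric_table` aggregates all metrics per subpopulation across
cross-validation repetitions into a mean/SD table and flags group cells whose
deviation from the overall row is significant under a family-wise-controlled
paired rule (see :func:`_flag_threshold`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sksurv.nonparametric import kaplan_meier_estimator

from .errors import DataError, UndefinedMetricError

__all__ = [
    "MetricConfig",
    "ipcw_weights",
    "brier_score",
    "mean_signed_error",
    "c_index",
    "subpopulation_c_index",
    "group_metric_table",
    "write_metric_table_csv",
    "read_metric_table_csv",
]

logger = logging.getLogger(__name__)


@dataclass
class MetricConfig:
    """Evaluation horizon and bias-flag rule.

    ``eval_time_days`` defaults to 1826 ≈ 5 years. ``flag_k`` sets the base
    two-sided normal level of the flag rule (k = 2 ≈ 4.6%), which is then
    Bonferroni-adjusted across the group cells of a table.
    """

    eval_time_days: float = 1826.0
    flag_k: float = 2.0

    def __post_init__(self) -> None:
        if self.eval_time_days <= 0:
            raise DataError("eval_time_days must be > 0")
        if self.flag_k <= 0:
            raise DataError("flag_k must be > 0")


# ---------------------------------------------------------------------------
# IPCW
# ---------------------------------------------------------------------------


def _censoring_survival(time: np.ndarray, event: np.ndarray):
    """Kaplan–Meier estimate Ĝ of the censoring distribution (event ↔ censor)."""
    times, probs = kaplan_meier_estimator((event == 0), time)
    return np.asarray(times, dtype=float), np.asarray(probs, dtype=float)


def _step_left(times: np.ndarray, probs: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Left-continuous evaluation Ĝ(q⁻) of a right-continuous step function."""
    idx = np.searchsorted(times, q, side="left") - 1
    out = np.where(idx >= 0, probs[np.clip(idx, 0, len(probs) - 1)], 1.0)
    return out


def _step_right(times: np.ndarray, probs: np.ndarray, q) -> np.ndarray:
    idx = np.searchsorted(times, q, side="right") - 1
    return np.where(idx >= 0, probs[np.clip(idx, 0, len(probs) - 1)], 1.0)


def ipcw_weights(time: np.ndarray, event: np.ndarray, t: float) -> np.ndarray:
    """Inverse-probability-of-censoring weights at horizon ``t``.

    Records observed to fail by ``t`` get 1/Ĝ(Tᵢ⁻); records followed past
    ``t`` get 1/Ĝ(t); records censored before ``t`` get 0. Positive weights
    are ≥ 1, and the weighted at-risk count is unbiased for the uncensored
    population size.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    g_times, g_probs = _censoring_survival(time, event)
    g_at_t = float(_step_right(g_times, g_probs, t))
    if g_at_t <= 0:
        raise UndefinedMetricError(
            f"censoring survival reaches 0 before t={t}; choose a smaller horizon"
        )
    w = np.zeros_like(time)
    failed = (time <= t) & (event == 1)
    past = time > t
    g_left = _step_left(g_times, g_probs, time[failed])
    w[failed] = 1.0 / g_left
    w[past] = 1.0 / g_at_t
    return w


def _check_predictions(pred: np.ndarray) -> np.ndarray:
    pred = np.asarray(pred, dtype=float)
    if np.any(pred < 0) or np.any(pred > 1) or not np.all(np.isfinite(pred)):
        raise DataError("survival-probability predictions must lie in [0, 1]")
    return pred


def brier_score(pred_prob, time, event, config: MetricConfig | None = None) -> float:
    """IPCW-weighted Brier score of 𝟙[T > t] against p̂; in [0, 1], lower better."""
    config = config or MetricConfig()
    t = config.eval_time_days
    p = _check_predictions(pred_prob)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    w = ipcw_weights(time, event, t)
    alive = (time > t).astype(float)
    return float(np.sum(w * (alive - p) ** 2) / len(p))


def mean_signed_error(pred_prob, time, event, config: MetricConfig | None = None) -> float:
    """IPCW-weighted mean of (𝟙[T > t] − p̂); negative ⇔ survival overestimated."""
    config = config or MetricConfig()
    t = config.eval_time_days
    p = _check_predictions(pred_prob)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    w = ipcw_weights(time, event, t)
    alive = (time > t).astype(float)
    return float(np.sum(w * (alive - p)) / len(p))


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------


def _concordance(pred_surv, time, event, pair_mask=None) -> float:
    """Harrell's C over comparable pairs, vectorized.

    A pair (i, j) with Tᵢ < Tⱼ is comparable iff record i's event is
    observed. Higher predicted survival means lower risk; prediction ties
    count ½. ``pair_mask[i, j]`` optionally restricts the pair set further
    (symmetric usage: mask applied to the ordered comparable pairs).
    """
    p = np.asarray(pred_surv, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int).astype(bool)
    n = len(p)
    if n != len(time) or n != len(event):
        raise DataError("predictions, times and events must align")
    shorter = time[:, None] < time[None, :]
    comparable = shorter & event[:, None]
    if pair_mask is not None:
        comparable = comparable & pair_mask
    n_comp = int(comparable.sum())
    if n_comp == 0:
        raise UndefinedMetricError("no comparable pairs; concordance undefined")
    # concordant: the shorter-lived record i has higher risk = lower predicted survival
    lower = p[:, None] < p[None, :]
    tied = p[:, None] == p[None, :]
    concordant = float((comparable & lower).sum())
    half = float((comparable & tied).sum())
    return (concordant + 0.5 * half) / n_comp


def c_index(pred_surv, time, event) -> float:
    """Overall Harrell concordance index with right censoring, in [0, 1]."""
    return _concordance(pred_surv, time, event)


def subpopulation_c_index(pred_surv, time, event, group_mask) -> float:
    """C-index over comparable pairs with ≥ 1 member in the subpopulation.

    With the whole population as the group this equals the overall C-index
    exactly; with no qualifying comparable pairs the metric is undefined and
    an :class:`UndefinedMetricError` is raised (small groups may have no
    reportable cell).
    """
    g = np.asarray(group_mask, dtype=bool)
    if g.sum() == 0:
        raise UndefinedMetricError("subpopulation is empty")
    pair_mask = g[:, None] | g[None, :]
    return _concordance(pred_surv, time, event, pair_mask=pair_mask)


# ---------------------------------------------------------------------------
# group table
# ---------------------------------------------------------------------------

_FAVORABLE_HIGH = {"c_index": True, "subpop_c_index": True, "brier": False}


def _flag_threshold(k: float, n_cells: int, df: int) -> float:
    """Critical value for the bias flag.

    Base two-sided normal level α = 2(1 − Φ(k)) is Bonferroni-divided by the
    number of group cells in the table, then converted to a Student-t
    quantile with rep−1 degrees of freedom, so a fully exchangeable table
    rarely produces any flag while genuine biases (many SE) always do.
    """
    alpha = 2.0 * stats.norm.sf(k)
    return float(stats.t.ppf(1.0 - alpha / (2.0 * max(n_cells, 1)), df))


def group_metric_table(
    predictions: pd.DataFrame,
    group_cols: list[str],
    config: MetricConfig | None = None,
) -> pd.DataFrame:
    """Per-metric × per-group mean/SD table across CV repetitions, with flags.

    ``predictions`` is the long frame produced by
    :func:`equialloc.survival.monte_carlo_cv` (columns rep, model,
    pred_prob, time_days, event plus the group columns). Groups are the
    levels of each listed column (dimensions are not crossed), plus an
    ``Overall`` row per metric.

    Calibration metrics (Brier, mean signed error) are computed on the
    group's own records with IPCW learned per repetition on the full test
    set; discrimination uses the overall C-index and the subpopulation
    C-index. A group cell is flagged ``positive``/``negative`` when its mean
    deviates from the overall mean by more than the family-wise-adjusted
    multiple of the paired SE; direction follows whether the deviation is
    favorable for the metric (signed error keeps the sign of the deviation).
    """
    config = config or MetricConfig()
    if predictions["rep"].nunique() < 2:
        logger.warning("single repetition: SDs reported as 0 and no flags")
    metric_names = ["brier", "mean_signed_error", "c_index", "subpop_c_index"]
    records = []
    for model, mdf in predictions.groupby("model", sort=False):
        # per-rep metric values
        per_rep: dict[tuple[str, str], list[float]] = {}
        for rep, rdf in mdf.groupby("rep", sort=True):
            t = rdf["time_days"].to_numpy()
            e = rdf["event"].to_numpy()
            p = rdf["pred_prob"].to_numpy()
            w_all = ipcw_weights(t, e, config.eval_time_days)
            alive = (t > config.eval_time_days).astype(float)

            def _cal(mask):
                nm = int(mask.sum())
                return (
                    float(np.sum(w_all[mask] * (alive[mask] - p[mask]) ** 2) / nm),
                    float(np.sum(w_all[mask] * (alive[mask] - p[mask])) / nm),
                )

            b, m = _cal(np.ones(len(rdf), dtype=bool))
            per_rep.setdefault(("Overall", "brier"), []).append(b)
            per_rep.setdefault(("Overall", "mean_signed_error"), []).append(m)
            try:
                c = c_index(p, t, e)
                per_rep.setdefault(("Overall", "c_index"), []).append(c)
                per_rep.setdefault(("Overall", "subpop_c_index"), []).append(c)
            except UndefinedMetricError:
                pass
            for col in group_cols:
                values = rdf[col].to_numpy()
                for level in pd.unique(values):
                    mask = values == level
                    if mask.sum() == 0:
                        continue
                    b, m = _cal(mask)
                    per_rep.setdefault((level, "brier"), []).append(b)
                    per_rep.setdefault((level, "mean_signed_error"), []).append(m)
                    try:
                        per_rep.setdefault((level, "c_index"), []).append(
                            c_index(p[mask], t[mask], e[mask])
                        )
                    except UndefinedMetricError:
                        logger.warning("c_index undefined for group %r", level)
                    try:
                        per_rep.setdefault((level, "subpop_c_index"), []).append(
                            subpopulation_c_index(p, t, e, mask)
                        )
                    except UndefinedMetricError:
                        logger.warning("subpopulation c_index undefined for group %r", level)

        groups = [g for g in dict.fromkeys(k[0] for k in per_rep) if g != "Overall"]
        n_cells = sum(
            1 for (g, _m) in per_rep if g != "Overall" and len(per_rep[(g, _m)]) >= 2
        )
        for metric in metric_names:
            overall_vals = np.asarray(per_rep.get(("Overall", metric), []), dtype=float)
            if overall_vals.size == 0:
                continue
            records.append(
                {
                    "model": model, "metric": metric, "group": "Overall",
                    "mean": overall_vals.mean(),
                    "sd": overall_vals.std(ddof=1) if overall_vals.size > 1 else 0.0,
                    "n_reps": overall_vals.size, "flag": "none",
                }
            )
            for g in groups:
                vals = np.asarray(per_rep.get((g, metric), []), dtype=float)
                if vals.size == 0:
                    continue
                flag = "none"
                n_pair = min(vals.size, overall_vals.size)
                if n_pair >= 2:
                    diffs = vals[:n_pair] - overall_vals[:n_pair]
                    se = diffs.std(ddof=1) / np.sqrt(n_pair)
                    crit = _flag_threshold(config.flag_k, n_cells, n_pair - 1)
                    if se > 0 and abs(diffs.mean()) > crit * se:
                        delta = diffs.mean()
                        if metric == "mean_signed_error":
                            flag = "positive" if delta > 0 else "negative"
                        else:
                            favorable = (delta > 0) == _FAVORABLE_HIGH[metric]
                            flag = "positive" if favorable else "negative"
                records.append(
                    {
                        "model": model, "metric": metric, "group": g,
                        "mean": vals.mean(),
                        "sd": vals.std(ddof=1) if vals.size > 1 else 0.0,
                        "n_reps": vals.size, "flag": flag,
                    }
                )
    return pd.DataFrame.from_records(records)


def write_metric_table_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_metric_table_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"model", "metric", "group", "mean", "sd", "flag"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"metric table CSV missing columns: {sorted(missing)}")
    return df
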