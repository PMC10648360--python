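"""Goodness-of-fit, agreement, ranking and cross-validation machinery.

Model selection in mapping studies works over seven indicators: RMSE,
MAE, ME (errors ``e = observed - predicted``), Lin's concordance
correlation coefficient, the proportions of absolute errors exceeding
0.05 and 0.10 utility units (strict inequality), and AIC/BIC.  Models
are compared by their *average rank value* (ARV): within an estimator
class each indicator ranks the models (lower-better for everything but
CCC; ties share mean ranks) and the ARV is the mean rank across
indicators.  Because AIC/BIC are not comparable between direct and
indirect families, cross-class comparison drops them and ranks on the
five data-based metrics only.

Conventions, each following its literature: CCC uses population
(n-divisor) moments; Bland–Altman limits use the sample SD (n-1) with
mean ± 1.96·SD and closed-interval membership; cross-validation fold
metrics are arithmetically averaged across folds (not pooled).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold

__all__ = [
    "MetricsReport",
    "CVReport",
    "BlandAltmanResult",
    "prediction_metrics",
    "concordance_ccc",
    "information_criteria",
    "spearman_overlap",
    "correlation_band",
    "average_rank",
    "kfold_cv",
    "bland_altman",
    "ecdf_compare",
]

#: Ranking direction per indicator: ``False`` = lower is better.
METRIC_DIRECTIONS = {
    "rmse": False,
    "mae": False,
    "me": False,
    "ccc": True,
    "ae_gt_010": False,
    "ae_gt_005": False,
    "aic": False,
    "bic": False,
}

#: The five cross-class (data-based) indicators.
DATA_METRICS = ("rmse", "mae", "ccc", "ae_gt_010", "ae_gt_005")

#: The seven within-class indicators.
CLASS_METRICS = ("rmse", "mae", "ccc", "ae_gt_010", "ae_gt_005", "aic", "bic")


@dataclass
class MetricsReport:
    rmse: float
    mae: float
    me: float
    ccc: float
    ae_gt_010: float
    ae_gt_005: float
    n_obs: int
    aic: float | None = None
    bic: float | None = None

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


@dataclass
class CVReport:
    k: int
    seed: int
    fold_assignments: np.ndarray
    fold_metrics: list[MetricsReport]
    averaged: MetricsReport
    failures: list[int] = field(default_factory=list)


@dataclass
class BlandAltmanResult:
    mean_diff: float
    sd_diff: float
    lower_limit: float
    upper_limit: float
    pct_outside: float
    means: np.ndarray
    diffs: np.ndarray


def _nanmean_quiet(values) -> float:
    vals = np.asarray(values, dtype=float)
    vals = vals[~np.isnan(vals)]
    return float(vals.mean()) if len(vals) else float("nan")


def _paired(observed, predicted):
    o = np.asarray(observed, dtype=float).ravel()
    p = np.asarray(predicted, dtype=float).ravel()
    if len(o) != len(p):
        raise ValueError("observed and predicted lengths differ")
    if len(o) == 0:
        raise ValueError("empty series")
    return o, p


def prediction_metrics(
    observed, predicted, thresholds: tuple[float, float] = (0.05, 0.10)
) -> MetricsReport:
    """RMSE, MAE, ME, CCC and absolute-error exceedance percentages."""
    o, p = _paired(observed, predicted)
    e = o - p
    t_lo, t_hi = sorted(thresholds)
    try:
        ccc = concordance_ccc(o, p)
    except ValueError:
        ccc = float("nan")  # undefined for a single pair or two constants
    return MetricsReport(
        rmse=float(np.sqrt(np.mean(e**2))),
        mae=float(np.mean(np.abs(e))),
        me=float(np.mean(e)),
        ccc=ccc,
        ae_gt_010=float(100.0 * np.mean(np.abs(e) > t_hi)),
        ae_gt_005=float(100.0 * np.mean(np.abs(e) > t_lo)),
        n_obs=len(o),
    )


def concordance_ccc(x, y) -> float:
    """Lin's concordance correlation coefficient (population moments).

    ``2 cov(x,y) / (var x + var y + (mean x - mean y)^2)``; penalises both
    dispersion and location shift, so CCC <= |Pearson r| with equality only
    on the identity line.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need two equal-length series with >= 2 points")
    vx, vy = x.var(), y.var()  # population (n-divisor)
    if vx == 0 and vy == 0:
        raise ValueError("both series are constant; CCC undefined")
    cov = float(np.mean((x - x.mean()) * (y - y.mean())))
    return float(2.0 * cov / (vx + vy + (x.mean() - y.mean()) ** 2))


def information_criteria(loglik: float, k: int, n: int) -> tuple[float, float]:
    """AIC = -2 loglik + 2k; BIC = -2 loglik + k ln n."""
    if n < 1 or k < 1:
        raise ValueError("need n >= 1 and k >= 1")
    return (-2.0 * loglik + 2.0 * k, -2.0 * loglik + k * np.log(n))


#: Named strength bands for |Spearman rho|.
_BANDS = (
    (0.20, "very weak"),
    (0.40, "weak"),
    (0.60, "moderate"),
    (0.80, "strong"),
    (1.01, "very strong"),
)


def correlation_band(rho: float) -> str:
    """Strength label for a rank correlation: very weak (<0.20) ... very strong."""
    a = abs(rho)
    for cut, label in _BANDS:
        if a < cut:
            return label
    return "very strong"


def spearman_overlap(
    factl_block: pd.DataFrame, sf6d_block: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman correlations between two variable blocks, with bands.

    Ties receive average ranks.  A constant column yields NaN and the band
    ``"undefined"`` for its pairs.
    """
    if len(factl_block) != len(sf6d_block) or len(factl_block) < 3:
        raise ValueError("need >= 3 paired observations")
    rho = pd.DataFrame(
        index=sf6d_block.columns, columns=factl_block.columns, dtype=float
    )
    bands = rho.copy().astype(object)
    for a in factl_block.columns:
        for b in sf6d_block.columns:
            x = factl_block[a].to_numpy(dtype=float)
            y = sf6d_block[b].to_numpy(dtype=float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                rho.loc[b, a] = np.nan
                bands.loc[b, a] = "undefined"
                continue
            r = stats.spearmanr(x, y).statistic
            rho.loc[b, a] = r
            bands.loc[b, a] = correlation_band(r)
    return rho, bands


def average_rank(
    metric_table: pd.DataFrame,
    directions: dict[str, bool] | None = None,
    class_labels: pd.Series | dict | None = None,
) -> pd.DataFrame:
    """Per-metric ranks and the average rank value (ARV) per model.

    ``metric_table`` is indexed by model with one column per indicator.
    ``directions`` maps indicator -> higher-is-better flag (defaults to the
    standard map).  When ``class_labels`` is given, ranking happens within
    each estimator class separately.  Ties share mean ranks.
    """
    directions = {**METRIC_DIRECTIONS, **(directions or {})}
    if metric_table.isna().any().any():
        missing = metric_table.isna().stack()
        cell = missing[missing].index[0]
        raise ValueError(f"missing metric cell {cell}")
    unknown = [c for c in metric_table.columns if c not in directions]
    if unknown:
        raise ValueError(f"no ranking direction for metrics {unknown}")
    if class_labels is None:
        groups = pd.Series("all", index=metric_table.index)
    else:
        groups = pd.Series(class_labels, index=metric_table.index)

    ranks = pd.DataFrame(index=metric_table.index, columns=metric_table.columns, dtype=float)
    for _, idx in metric_table.groupby(groups).groups.items():
        sub = metric_table.loc[idx]
        for col in sub.columns:
            vals = sub[col].to_numpy(dtype=float)
            if directions[col]:
                vals = -vals
            ranks.loc[idx, col] = stats.rankdata(vals, method="average")
    out = ranks.copy()
    out["arv"] = ranks.mean(axis=1)
    return out


def kfold_cv(
    subjects: pd.DataFrame,
    model_recipes: dict,
    k: int = 5,
    seed: int = 0,
) -> dict[str, CVReport]:
    """Seeded k-fold cross-validation of mapping recipes.

    Each recipe is a callable ``recipe(train_df) -> predict_fn`` where
    ``predict_fn(test_df)`` returns predicted utilities; out-of-fold
    metrics are computed against the ``utility`` column and averaged
    arithmetically across folds.  A failing fold is recorded and skipped
    with a warning.
    """
    n = len(subjects)
    if n < k:
        raise ValueError(f"need at least k={k} subjects, got {n}")
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    assignments = np.empty(n, dtype=int)
    folds = list(splitter.split(np.arange(n)))
    for f, (_, test_idx) in enumerate(folds):
        assignments[test_idx] = f

    reports: dict[str, CVReport] = {}
    for name, recipe in model_recipes.items():
        fold_metrics: list[MetricsReport] = []
        failures: list[int] = []
        for f, (train_idx, test_idx) in enumerate(folds):
            train = subjects.iloc[train_idx]
            test = subjects.iloc[test_idx]
            try:
                predict_fn = recipe(train)
                pred = np.asarray(predict_fn(test), dtype=float)
                fold_metrics.append(prediction_metrics(test["utility"], pred))
            except Exception as exc:
                failures.append(f)
                warnings.warn(
                    f"recipe {name!r}: fold {f} failed ({exc}); averaging over "
                    "the remaining folds",
                    stacklevel=2,
                )
        if not fold_metrics:
            raise RuntimeError(f"recipe {name!r} failed on every fold")
        avg = MetricsReport(
            rmse=float(np.mean([m.rmse for m in fold_metrics])),
            mae=float(np.mean([m.mae for m in fold_metrics])),
            me=float(np.mean([m.me for m in fold_metrics])),
            ccc=_nanmean_quiet([m.ccc for m in fold_metrics]),
            ae_gt_010=float(np.mean([m.ae_gt_010 for m in fold_metrics])),
            ae_gt_005=float(np.mean([m.ae_gt_005 for m in fold_metrics])),
            n_obs=int(sum(m.n_obs for m in fold_metrics)),
        )
        reports[name] = CVReport(
            k=k,
            seed=seed,
            fold_assignments=assignments,
            fold_metrics=fold_metrics,
            averaged=avg,
            failures=failures,
        )
    return reports


def bland_altman(observed, predicted) -> BlandAltmanResult:
    """Limits of agreement: mean difference ± 1.96 sample SD."""
    o, p = _paired(observed, predicted)
    if len(o) < 2:
        raise ValueError("need >= 2 pairs")
    diffs = o - p
    means = (o + p) / 2.0
    md = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    lo, hi = md - 1.96 * sd, md + 1.96 * sd
    outside = (diffs < lo) | (diffs > hi)  # closed-interval membership
    return BlandAltmanResult(
        mean_diff=md,
        sd_diff=sd,
        lower_limit=lo,
        upper_limit=hi,
        pct_outside=float(100.0 * outside.mean()),
        means=means,
        diffs=diffs,
    )


def ecdf_compare(observed, predicted, grid=None) -> pd.DataFrame:
    """Empirical CDFs of both series on a shared grid, plus the max gap.

    Returns a DataFrame with columns ``grid``, ``cdf_observed``,
    ``cdf_predicted``; the maximum vertical gap is stored in
    ``frame.attrs["max_gap"]``.
    """
    o, p = _paired(observed, predicted)
    if grid is None:
        grid = np.unique(np.concatenate([o, p]))
    grid = np.asarray(grid, dtype=float)
    cdf_o = np.searchsorted(np.sort(o), grid, side="right") / len(o)
    cdf_p = np.searchsorted(np.sort(p), grid, side="right") / len(p)
    frame = pd.DataFrame({"grid": grid, "cdf_observed": cdf_o, "cdf_predicted": cdf_p})
    frame.attrs["max_gap"] = float(np.max(np.abs(cdf_o - cdf_p)))
    return frame
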