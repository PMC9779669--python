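"""Per-gene expression noise and the mean-adjusted noise statistic.

Noise is quantified as the coefficient of variation (CV = sd/mean) across
cells. Because CV depends strongly on the mean, a polynomial trend of CV
versus ln(mean) is fitted and each gene's *mean-adjusted noise* is its
vertical distance from that trend. Genes are then stratified into noise bins
whose interior edges are equally spaced, with open-ended first and last bins
so extreme genes are not dropped.

The trend fit follows a statsmodels-style Model/Results split:
`NoiseTrendModel(cv, log_mean).fit()` returns a `NoiseTrendResults` carrying
the selected polynomial order, coefficients, per-order cross-validation
scores, a 95% confidence band, and the residual (adjusted-noise) machinery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.model_selection import KFold

__all__ = [
    "compute_cv",
    "NoiseTrendModel",
    "NoiseTrendResults",
    "fit_trend",
    "adjusted_noise",
    "bin_by_noise",
    "running_median_dm",
]


def compute_cv(expression: pd.DataFrame) -> pd.DataFrame:
    """Per-gene mean, sample sd (n−1) and CV from a genes × cells table.

    Genes with zero mean are flagged (`zero_mean`) and carry undefined CV;
    they are excluded from trend fitting downstream.
    """
    if expression.shape[1] < 2:
        raise ValueError("need at least 2 cells per gene to compute a CV")
    values = expression.to_numpy(dtype=float)
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / mean, np.nan)
    return pd.DataFrame(
        {"mean": mean, "sd": sd, "cv": cv, "zero_mean": mean == 0},
        index=expression.index,
    )


class NoiseTrendModel:
    """Polynomial trend of CV on ln(mean) with data-driven order selection.

    Candidate orders are scored by 10-fold cross-validated mean squared
    error; the selected order is the smallest whose CV-MSE is within one
    standard error of the minimum (the usual parsimony rule for nested
    candidates). Orders with more parameters than training points are
    refused.
    """

    def __init__(
        self,
        cv: np.ndarray | pd.Series,
        log_mean: np.ndarray | pd.Series,
        candidate_orders: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7),
        n_folds: int = 10,
        seed: int = 0,
    ):
        cv = np.asarray(cv, dtype=float)
        log_mean = np.asarray(log_mean, dtype=float)
        keep = np.isfinite(cv) & np.isfinite(log_mean)
        self.cv = cv[keep]
        self.log_mean = log_mean[keep]
        self.candidate_orders = tuple(sorted(candidate_orders))
        if min(self.candidate_orders) < 1:
            raise ValueError("polynomial order must be >= 1")
        self.n_folds = n_folds
        self.seed = seed
        if len(self.cv) < max(self.candidate_orders) + 2:
            raise ValueError(
                "too few genes with defined CV for the largest candidate order"
            )

    @classmethod
    def from_records(cls, records: pd.DataFrame, **kwargs) -> "NoiseTrendModel":
        ok = records["mean"] > 0
        return cls(records.loc[ok, "cv"], np.log(records.loc[ok, "mean"]), **kwargs)

    @staticmethod
    def _design(x: np.ndarray, order: int) -> np.ndarray:
        return np.vander(x, order + 1, increasing=True)

    def fit(self) -> "NoiseTrendResults":
        folds = KFold(self.n_folds, shuffle=True, random_state=self.seed)
        scores = []
        for order in self.candidate_orders:
            if len(self.cv) * (1 - 1 / self.n_folds) < order + 2:
                warnings.warn(f"order {order} refused: too few training points")
                continue
            fold_mse = []
            for train, test in folds.split(self.cv):
                coef, *_ = np.linalg.lstsq(
                    self._design(self.log_mean[train], order), self.cv[train], rcond=None
                )
                pred = self._design(self.log_mean[test], order) @ coef
                fold_mse.append(np.mean((self.cv[test] - pred) ** 2))
            fold_mse = np.asarray(fold_mse)
            scores.append(
                {
                    "order": order,
                    "cv_mse": fold_mse.mean(),
                    "cv_mse_se": fold_mse.std(ddof=1) / np.sqrt(len(fold_mse)),
                }
            )
        if not scores:
            raise ValueError("no candidate order could be fitted")
        table = pd.DataFrame(scores).set_index("order")
        best = table["cv_mse"].idxmin()
        threshold = table.loc[best, "cv_mse"] + table.loc[best, "cv_mse_se"]
        order = int(table.index[table["cv_mse"] <= threshold].min())
        ols = sm.OLS(self.cv, self._design(self.log_mean, order)).fit()
        return NoiseTrendResults(model=self, order=order, ols=ols, order_scores=table)


@dataclass
class NoiseTrendResults:
    """Fitted CV-vs-ln(mean) trend."""

    model: NoiseTrendModel
    order: int
    ols: object  # statsmodels RegressionResults
    order_scores: pd.DataFrame

    @property
    def coefficients(self) -> np.ndarray:
        """Ascending polynomial coefficients in ln(mean)."""
        return np.asarray(self.ols.params)

    def predict(self, log_mean: np.ndarray) -> np.ndarray:
        x = np.asarray(log_mean, dtype=float)
        return NoiseTrendModel._design(x, self.order) @ self.coefficients

    def confidence_band(self, log_mean: np.ndarray, alpha: float = 0.05) -> pd.DataFrame:
        """Pointwise confidence interval of the fitted trend."""
        x = np.asarray(log_mean, dtype=float)
        pred = self.ols.get_prediction(NoiseTrendModel._design(x, self.order))
        lo, hi = pred.conf_int(alpha=alpha).T
        return pd.DataFrame({"fit": pred.predicted_mean, "lower": lo, "upper": hi})

    def adjusted_noise(self, cv: np.ndarray, log_mean: np.ndarray) -> np.ndarray:
        """Vertical distance of each gene's CV from the fitted trend."""
        return np.asarray(cv, dtype=float) - self.predict(log_mean)

    def summary(self) -> str:
        lines = [
            "Mean-adjusted noise trend (CV ~ polynomial in ln mean)",
            f"  n genes fitted : {len(self.model.cv)}",
            f"  selected order : {self.order} "
            f"(10-fold CV MSE, one-SE rule over orders {self.model.candidate_orders})",
            "  per-order CV MSE:",
        ]
        for order, row in self.order_scores.iterrows():
            marker = " <-- selected" if order == self.order else ""
            lines.append(
                f"    order {order}: {row['cv_mse']:.6g} (se {row['cv_mse_se']:.2g}){marker}"
            )
        lines.append(f"  coefficients (ascending): {np.array2string(self.coefficients, precision=4)}")
        return "\n".join(lines)


def fit_trend(
    records: pd.DataFrame, candidate_orders: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7), seed: int = 0
) -> NoiseTrendResults:
    """Functional wrapper: fit the trend from a `compute_cv` table."""
    return NoiseTrendModel.from_records(
        records, candidate_orders=candidate_orders, seed=seed
    ).fit()


def adjusted_noise(records: pd.DataFrame, trend: NoiseTrendResults) -> pd.DataFrame:
    """Append the mean-adjusted noise column to a `compute_cv` table."""
    out = records.copy()
    ok = records["mean"] > 0
    out["adjusted_noise"] = np.nan
    out.loc[ok, "adjusted_noise"] = trend.adjusted_noise(
        records.loc[ok, "cv"], np.log(records.loc[ok, "mean"])
    )
    return out


def bin_by_noise(
    values: np.ndarray | pd.Series,
    n_bins: int = 20,
    central_percentiles: tuple[float, float] = (2.5, 97.5),
) -> np.ndarray:
    """Assign noise values to `n_bins` bins with open-ended extremes.

    The n_bins−1 interior edges are equally spaced over the central
    percentile range of the data, so interior bins are equal width while the
    first and last bins are open-ended (avoiding near-empty extreme bins).
    Returns integer bins in 1..n_bins; NaN values get bin 0 (unassigned).
    """
    if n_bins < 3:
        raise ValueError("n_bins must be >= 3")
    v = np.asarray(values, dtype=float)
    finite = v[np.isfinite(v)]
    lo, hi = np.percentile(finite, central_percentiles)
    if lo == hi:
        warnings.warn("all noise values identical: single-bin degenerate result")
        return np.where(np.isfinite(v), 1, 0)
    edges = np.linspace(lo, hi, n_bins - 1)
    bins = np.searchsorted(edges, v, side="right") + 1
    return np.where(np.isfinite(v), bins, 0)


def running_median_dm(
    mean: np.ndarray | pd.Series,
    cv: np.ndarray | pd.Series,
    window_fraction: float = 0.1,
) -> np.ndarray:
    """Distance-to-median noise measure (non-canonical convenience).

    Vertical distance of each gene's CV from a running median of CV in a
    sliding window (a fraction of the genes, ordered by mean). This mimics
    the shape of the classic protein-noise DM statistic but is NOT the
    published procedure; published DM values should be supplied as an
    external noise column when available.
    """
    mean = np.asarray(mean, dtype=float)
    cv = np.asarray(cv, dtype=float)
    order = np.argsort(mean)
    half = max(1, int(len(mean) * window_fraction / 2))
    med = np.empty(len(mean))
    sorted_cv = cv[order]
    for i in range(len(mean)):
        lo, hi = max(0, i - half), min(len(mean), i + half + 1)
        med[i] = np.nanmedian(sorted_cv[lo:hi])
    out = np.empty(len(mean))
    out[order] = sorted_cv - med
    return out
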