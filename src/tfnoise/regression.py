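"""Noise-prediction regression protocol: scaling, selection, repeated splits.

The protocol quantifies how well molecular features predict gene-expression
noise. Features are z-score standardized, candidate features are selected by
penalized regression (lasso at the 10-fold-CV-optimal penalty, or ridge with
coefficient significance on effective degrees of freedom) followed by
bidirectional stepwise search minimizing AIC, and the final model is scored
over repeated random 80/20 train/test splits:

* fraction of variation explained — the training-set R²,
* predicted R² — 1 − SSE/SST on the held-out split (SST around the
  held-out mean),

both reported as mean ± sd over the repeats. `NoiseRegression` /
`NoiseRegressionResults` wrap the full protocol statsmodels-style.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LassoCV, Ridge, RidgeCV

__all__ = [
    "standardize",
    "ModelReport",
    "single_feature_model",
    "multi_feature_model",
    "select_features",
    "stepwise_aic",
    "filter_features",
    "rank_features",
    "NoiseRegression",
    "NoiseRegressionResults",
]


def standardize(
    matrix: pd.DataFrame, stats_from: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Column-wise z-score standardization.

    Returns the standardized matrix and the (mean, sd) table used, so the
    same transform can be reapplied to held-out data. Constant columns are
    dropped with a warning.
    """
    if stats_from is None:
        mean = matrix.mean()
        sd = matrix.std(ddof=1)
        stats_from = pd.DataFrame({"mean": mean, "sd": sd})
    constant = stats_from["sd"] == 0
    if constant.any():
        warnings.warn(f"dropping constant columns: {list(stats_from.index[constant])}")
    keep = stats_from.index[~constant].intersection(matrix.columns)
    out = (matrix[keep] - stats_from.loc[keep, "mean"]) / stats_from.loc[keep, "sd"]
    return out, stats_from.loc[keep]


@dataclass
class ModelReport:
    """Repeated-split performance report of one feature set."""

    feature_set: tuple[str, ...]
    fraction_variation_explained: float
    fraction_variation_explained_sd: float
    predicted_r2: float
    predicted_r2_sd: float
    n_repeats: int
    split: float
    coefficients: pd.Series = field(repr=False)  # full-data fit, incl. intercept
    engine: str = "linear"

    def to_dict(self) -> dict:
        return {
            "features": list(self.feature_set),
            "fraction_variation_explained": self.fraction_variation_explained,
            "fraction_variation_explained_sd": self.fraction_variation_explained_sd,
            "predicted_r2": self.predicted_r2,
            "predicted_r2_sd": self.predicted_r2_sd,
            "n_repeats": self.n_repeats,
            "split": self.split,
            "engine": self.engine,
            "coefficients": self.coefficients.to_dict(),
        }


def _complete_cases(X: pd.DataFrame, y: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    data = pd.concat([X, y], axis=1)
    data = data.dropna()
    return data.iloc[:, :-1].to_numpy(float), data.iloc[:, -1].to_numpy(float)


def _ols_r2(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    design = np.column_stack([np.ones(len(y)), X])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    sst = np.sum((y - y.mean()) ** 2)
    return coef, 1.0 - np.sum(resid**2) / sst if sst > 0 else np.nan


def _repeated_splits(
    X: np.ndarray,
    y: np.ndarray,
    n_repeats: int,
    split: float,
    seed: int | None,
    engine: str,
    rf_kwargs: dict | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    n = len(y)
    n_train = int(round(split * n))
    frac = np.empty(n_repeats)
    pred = np.empty(n_repeats)
    for rep in range(n_repeats):
        perm = rng.permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
        if engine == "linear":
            design = np.column_stack([np.ones(len(tr)), X[tr]])
            coef, *_ = np.linalg.lstsq(design, y[tr], rcond=None)
            fit_tr = design @ coef
            fit_te = np.column_stack([np.ones(len(te)), X[te]]) @ coef
        else:
            model = RandomForestRegressor(
                random_state=int(rng.integers(2**31)), **(rf_kwargs or {"n_estimators": 100})
            )
            model.fit(X[tr], y[tr])
            fit_tr = model.predict(X[tr])
            fit_te = model.predict(X[te])
        sst_tr = np.sum((y[tr] - y[tr].mean()) ** 2)
        frac[rep] = 1.0 - np.sum((y[tr] - fit_tr) ** 2) / sst_tr
        sst_te = np.sum((y[te] - y[te].mean()) ** 2)
        pred[rep] = 1.0 - np.sum((y[te] - fit_te) ** 2) / sst_te
    return frac, pred


def multi_feature_model(
    matrix: pd.DataFrame,
    response: pd.Series,
    features: list[str],
    n_repeats: int = 1000,
    split: float = 0.8,
    engine: str = "linear",
    seed: int | None = None,
    rf_kwargs: dict | None = None,
    impute_median: bool = False,
) -> ModelReport:
    """Repeated-split report for a feature set (linear or random forest)."""
    X_df = matrix[features]
    if impute_median:
        X_df = X_df.fillna(X_df.median())
    X, y = _complete_cases(X_df, response)
    if len(y) < max(20, X.shape[1] + 2):
        raise ValueError("too few complete cases for the requested feature set")
    frac, pred = _repeated_splits(X, y, n_repeats, split, seed, engine, rf_kwargs)
    if engine == "linear":
        coef, _ = _ols_r2(X, y)
        coefficients = pd.Series(coef, index=["intercept", *features])
    else:
        coefficients = pd.Series(dtype=float)
    return ModelReport(
        feature_set=tuple(features),
        fraction_variation_explained=float(frac.mean()),
        fraction_variation_explained_sd=float(frac.std(ddof=1)) if n_repeats > 1 else 0.0,
        predicted_r2=float(pred.mean()),
        predicted_r2_sd=float(pred.std(ddof=1)) if n_repeats > 1 else 0.0,
        n_repeats=n_repeats,
        split=split,
        coefficients=coefficients,
        engine=engine,
    )


def single_feature_model(
    matrix: pd.DataFrame,
    response: pd.Series,
    feature: str,
    n_repeats: int = 1000,
    split: float = 0.8,
    seed: int | None = None,
) -> ModelReport:
    """Repeated-split report of the one-feature model noise = b0 + b1·x + e."""
    return multi_feature_model(matrix, response, [feature], n_repeats, split, "linear", seed)


def select_features(
    matrix: pd.DataFrame,
    response: pd.Series,
    method: str = "lasso",
    rule: str = "min",
    alpha: float = 0.05,
    n_folds: int = 10,
    seed: int | None = None,
) -> list[str]:
    """Candidate features by penalized regression.

    lasso: 10-fold CV over the penalty path; at the CV-optimal penalty
    (`rule="min"`; `"1se"` for the sparser one-SE choice) the features with
    nonzero coefficients are returned. ridge: penalty by generalized CV,
    then coefficients tested with t-statistics on the ridge fit's effective
    degrees of freedom; features significant at `alpha` are returned.
    """
    X, y = _complete_cases(matrix, response)
    names = list(matrix.columns)
    if method == "lasso":
        model = LassoCV(cv=n_folds, random_state=seed).fit(X, y)
        if rule == "1se":
            mse = model.mse_path_.mean(axis=1)
            se = model.mse_path_.std(axis=1, ddof=1) / np.sqrt(model.mse_path_.shape[1])
            best = mse.argmin()
            alphas = model.alphas_
            ok = mse <= mse[best] + se[best]
            chosen = alphas[ok].max()
            model = LassoCV(alphas=[chosen], cv=n_folds, random_state=seed).fit(X, y)
        coefs = model.coef_
        # coordinate descent can leave O(eps) dust on redundant columns
        tol = 1e-10 * max(1.0, np.abs(coefs).max())
        return [n for n, c in zip(names, coefs) if abs(c) > tol]
    if method == "ridge":
        lam = RidgeCV(alphas=np.logspace(-3, 3, 25)).fit(X, y).alpha_
        ridge = Ridge(alpha=lam).fit(X, y)
        n, p = X.shape
        xtx = X.T @ X
        inv = np.linalg.inv(xtx + lam * np.eye(p))
        edf = float(np.trace(X @ inv @ X.T))
        resid = y - ridge.predict(X)
        dof = max(n - edf, 1.0)
        sigma2 = resid @ resid / dof
        cov = sigma2 * inv @ xtx @ inv
        t = ridge.coef_ / np.sqrt(np.diag(cov))
        pvals = 2 * stats.t.sf(np.abs(t), dof)
        return [n_ for n_, p_ in zip(names, pvals) if p_ < alpha]
    raise ValueError("method must be 'lasso' or 'ridge'")


def _aic(X: pd.DataFrame, y: pd.Series, features: tuple[str, ...]) -> float:
    design = sm.add_constant(X[list(features)]) if features else np.ones((len(y), 1))
    return float(sm.OLS(y, design).fit().aic)


def stepwise_aic(
    matrix: pd.DataFrame, response: pd.Series, candidates: list[str]
) -> list[str]:
    """Bidirectional stepwise search minimizing AIC.

    Starting from the empty model, the single addition or removal that most
    reduces AIC is applied until no move improves; the search is repeated
    from the full candidate model and the better endpoint is returned
    (guaranteeing AIC ≤ the full model's). Deterministic: ties break by
    feature name.
    """
    data = pd.concat([matrix[candidates], response], axis=1).dropna()
    X, y = data[candidates], data.iloc[:, -1]

    def search(current: set[str]) -> tuple[float, set[str]]:
        best_aic = _aic(X, y, tuple(sorted(current)))
        improved = True
        while improved:
            improved = False
            moves = []
            for f in sorted(set(candidates) - current):
                moves.append((_aic(X, y, tuple(sorted(current | {f}))), "add", f))
            for f in sorted(current):
                moves.append((_aic(X, y, tuple(sorted(current - {f}))), "drop", f))
            if not moves:
                break
            moves.sort(key=lambda m: (m[0], m[2]))
            aic, op, f = moves[0]
            if aic < best_aic - 1e-10:
                best_aic = aic
                current = current | {f} if op == "add" else current - {f}
                improved = True
        return best_aic, current

    aic_empty, from_empty = search(set())
    aic_full, from_full = search(set(candidates))
    chosen = from_empty if aic_empty <= aic_full else from_full
    return sorted(chosen)


def filter_features(
    matrix: pd.DataFrame,
    response: pd.Series,
    mode: str = "correlation",
    alpha: float = 0.05,
    min_fraction: float = 0.05,
    min_predicted_r2: float = 0.05,
    n_repeats: int = 100,
    seed: int | None = None,
) -> pd.DataFrame:
    """Reduce the feature matrix by correlation or single-feature impact.

    correlation mode keeps features with Pearson p < alpha against the
    response; impact mode keeps features whose single-feature model explains
    at least `min_fraction` of the variation OR has predicted R² at least
    `min_predicted_r2`.
    """
    keep = []
    for f in matrix.columns:
        pair = pd.concat([matrix[f], response], axis=1).dropna()
        if mode == "correlation":
            if len(pair) > 2 and pair.iloc[:, 0].std() > 0:
                _, p = stats.pearsonr(pair.iloc[:, 0], pair.iloc[:, 1])
                if p < alpha:
                    keep.append(f)
        elif mode == "impact":
            rep = single_feature_model(matrix, response, f, n_repeats=n_repeats, seed=seed)
            if (
                rep.fraction_variation_explained >= min_fraction
                or rep.predicted_r2 >= min_predicted_r2
            ):
                keep.append(f)
        else:
            raise ValueError("mode must be 'correlation' or 'impact'")
    return matrix[keep]


def rank_features(
    matrix: pd.DataFrame,
    response: pd.Series,
    response_b: pd.Series | None = None,
    n_repeats: int = 100,
    seed: int | None = None,
) -> dict:
    """Rank features by fraction explained and by predicted R².

    With a second response vector the Spearman correlation between the two
    datasets' rankings (by fraction explained) is reported, quantifying how
    concordant the feature importance orderings are.
    """
    def table(y: pd.Series) -> pd.DataFrame:
        rows = []
        for f in matrix.columns:
            rep = single_feature_model(matrix, y, f, n_repeats=n_repeats, seed=seed)
            rows.append(
                {
                    "feature": f,
                    "fraction_variation_explained": rep.fraction_variation_explained,
                    "predicted_r2": rep.predicted_r2,
                }
            )
        df = pd.DataFrame(rows).set_index("feature")
        df["rank_by_fraction"] = df["fraction_variation_explained"].rank(ascending=False)
        df["rank_by_predicted_r2"] = df["predicted_r2"].rank(ascending=False)
        return df

    out = {"ranking": table(response)}
    if response_b is not None:
        out["ranking_b"] = table(response_b)
        rho, p = stats.spearmanr(
            out["ranking"]["fraction_variation_explained"],
            out["ranking_b"]["fraction_variation_explained"],
        )
        out["rank_correlation"] = float(rho)
        out["rank_correlation_p"] = float(p)
    return out


class NoiseRegression:
    """statsmodels-style wrapper around the full selection + scoring protocol."""

    def __init__(self, matrix: pd.DataFrame, response: pd.Series):
        self.raw_matrix = matrix
        self.response = response
        self.matrix, self.scaling = standardize(matrix)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, response_col: str) -> "NoiseRegression":
        return cls(data.drop(columns=[response_col]), data[response_col])

    def fit(
        self,
        select: str | None = "lasso",
        stepwise: bool = True,
        n_repeats: int = 1000,
        split: float = 0.8,
        engine: str = "linear",
        seed: int | None = None,
    ) -> "NoiseRegressionResults":
        features = list(self.matrix.columns)
        if select is not None:
            features = select_features(self.matrix, self.response, method=select, seed=seed)
        if stepwise and features:
            features = stepwise_aic(self.matrix, self.response, features)
        if not features:
            raise ValueError("no features survive selection")
        report = multi_feature_model(
            self.matrix, self.response, features,
            n_repeats=n_repeats, split=split, engine=engine, seed=seed,
        )
        return NoiseRegressionResults(model=self, report=report, selected=features)


@dataclass
class NoiseRegressionResults:
    model: NoiseRegression
    report: ModelReport
    selected: list[str]

    @property
    def fraction_variation_explained(self) -> float:
        return self.report.fraction_variation_explained

    @property
    def predicted_r2(self) -> float:
        return self.report.predicted_r2

    def summary(self) -> str:
        r = self.report
        lines = [
            "Noise regression (repeated 80/20 splits)",
            f"  engine                 : {r.engine}",
            f"  n repeats              : {r.n_repeats}",
            f"  selected features ({len(self.selected)}) : {', '.join(self.selected)}",
            f"  fraction of variation explained : {r.fraction_variation_explained:.4f} "
            f"± {r.fraction_variation_explained_sd:.4f}",
            f"  predicted R²           : {r.predicted_r2:.4f} ± {r.predicted_r2_sd:.4f}",
        ]
        if len(r.coefficients):
            lines.append("  coefficients:")
            for name, val in r.coefficients.items():
                lines.append(f"    {name:<20s} {val:+.4f}")
        return "\n".join(lines)
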