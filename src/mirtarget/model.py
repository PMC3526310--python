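"""Feature combination and relative importance.

Individual features are combined with ordinary least squares on
z-scored predictors.  The share of explained variance attributed to
each feature uses the CAR decomposition: with R the feature
correlation matrix and r the vector of marginal feature-response
correlations, the importances are

    omega = (R^{-1/2} r)^2,

whose sum is exactly the model R^2.  Unlike raw squared marginal
correlations, this accounts for correlated predictors, and it is
invariant to affine rescaling of any feature.

Per-transcript aggregation of multi-site scores offers the best
(min/max depending on the feature's sign), the sum, and a smooth
maximum (log-sum-exp).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = [
    "LinearModel",
    "ImportanceResult",
    "fit_linear",
    "car_importance",
    "aggregate_sites",
    "quantile_report",
]


@dataclass
class LinearModel:
    """OLS fit on internally standardised features."""

    feature_names: list[str]
    coefficients: np.ndarray  # on the original (unstandardised) scale
    intercept: float
    r_squared: float
    n: int
    means: np.ndarray
    scales: np.ndarray

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        x = table[self.feature_names].to_numpy(dtype=float)
        return x @ self.coefficients + self.intercept

    def to_text(self) -> str:
        lines = [f"n\t{self.n}", f"r_squared\t{float(self.r_squared)!r}",
                 f"intercept\t{float(self.intercept)!r}"]
        for i, name in enumerate(self.feature_names):
            lines.append(
                f"feature\t{name}\t{float(self.coefficients[i])!r}\t"
                f"{float(self.means[i])!r}\t{float(self.scales[i])!r}"
            )
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "LinearModel":
        n = 0
        r2 = intercept = 0.0
        names, coefs, means, scales = [], [], [], []
        for line in text.splitlines():
            if not line.strip():
                continue
            parts = line.split("\t")
            if parts[0] == "n":
                n = int(parts[1])
            elif parts[0] == "r_squared":
                r2 = float(parts[1])
            elif parts[0] == "intercept":
                intercept = float(parts[1])
            elif parts[0] == "feature":
                names.append(parts[1])
                coefs.append(float(parts[2]))
                means.append(float(parts[3]))
                scales.append(float(parts[4]))
        return cls(names, np.array(coefs), intercept, r2, n,
                   np.array(means), np.array(scales))


@dataclass
class ImportanceResult:
    """CAR variance decomposition; importances sum to the model R^2."""

    feature_names: list[str]
    importances: np.ndarray
    r_squared: float

    @property
    def percentages(self) -> np.ndarray:
        if self.r_squared == 0:
            return np.zeros_like(self.importances)
        return 100.0 * self.importances / self.r_squared


def _design(table: pd.DataFrame, response: str, features: list[str] | None):
    if features is None:
        features = [c for c in table.columns if c != response]
    if len(set(features)) != len(features):
        dupes = sorted({f for f in features if features.count(f) > 1})
        raise ValueError(f"duplicated feature columns: {dupes}")
    if response not in table.columns:
        raise ValueError(f"response column {response!r} missing")
    sub = table[features + [response]]
    if sub.isna().any().any():
        bad = sorted(sub.columns[sub.isna().any()])
        raise ValueError(f"missing values in fitting columns: {bad}")
    x = sub[features].to_numpy(dtype=float)
    y = sub[response].to_numpy(dtype=float)
    return x, y, features


def fit_linear(
    table: pd.DataFrame,
    response: str = "response",
    features: list[str] | None = None,
) -> LinearModel:
    """OLS of ``response`` on the feature columns (z-scored internally)."""
    x, y, features = _design(table, response, features)
    n, p = x.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 rows, got n={n}, p={p}")
    means = x.mean(axis=0)
    scales = x.std(axis=0, ddof=0)
    zero = scales <= 0
    if zero.any():
        raise ValueError(
            f"constant feature column(s): {[features[i] for i in np.where(zero)[0]]}"
        )
    xs = (x - means) / scales
    # detect collinearity before solving
    _, sv, vt = np.linalg.svd(xs, full_matrices=False)
    if sv[-1] < 1e-10 * sv[0]:
        null = np.abs(vt[-1])
        cols = [features[i] for i in np.where(null > 0.3)[0]]
        raise ValueError(f"collinear feature columns: {cols}")
    design = np.column_stack([np.ones(n), xs])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ beta
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    coef_std = beta[1:]
    coefficients = coef_std / scales
    intercept = float(beta[0] - np.dot(coefficients, means))
    return LinearModel(
        feature_names=features,
        coefficients=coefficients,
        intercept=intercept,
        r_squared=float(r2),
        n=n,
        means=means,
        scales=scales,
    )


def car_importance(
    table: pd.DataFrame,
    response: str = "response",
    features: list[str] | None = None,
) -> ImportanceResult:
    """CAR importances ``(R^{-1/2} r)^2`` (sum equals the OLS R^2)."""
    x, y, features = _design(table, response, features)
    if np.any(x.std(axis=0) <= 0):
        bad = [features[i] for i in np.where(x.std(axis=0) <= 0)[0]]
        raise ValueError(f"constant feature column(s): {bad}")
    p = x.shape[1]
    corr = np.corrcoef(x, rowvar=False)
    corr = np.atleast_2d(corr)
    r = np.array([np.corrcoef(x[:, i], y)[0, 1] for i in range(p)])
    w, u = np.linalg.eigh(corr)
    if w.min() < 1e-10:
        lam = 1e-8 * np.trace(corr) / p
        warnings.warn(
            f"singular feature correlation matrix; ridge-regularising with "
            f"lambda={lam:.2e}"
        )
        w, u = np.linalg.eigh(corr + lam * np.eye(p))
    inv_sqrt = u @ np.diag(1.0 / np.sqrt(w)) @ u.T
    omega = (inv_sqrt @ r) ** 2
    return ImportanceResult(features, omega, float(omega.sum()))


def aggregate_sites(
    site_scores: list[float] | np.ndarray,
    method: str = "sum",
    sign: int = 1,
) -> float:
    """Combine per-site scores into one transcript-level score.

    ``best`` takes the extreme in the predictive direction (minimum
    for negatively correlated features such as energies, maximum
    otherwise); ``sum`` adds scores; ``logsumexp`` is a smooth
    maximum, computed stably.
    """
    scores = np.asarray(site_scores, dtype=float)
    if scores.size == 0:
        raise ValueError("no site scores to aggregate")
    if method == "best":
        return float(scores.min() if sign < 0 else scores.max())
    if method == "sum":
        return float(scores.sum())
    if method == "logsumexp":
        return float(logsumexp(scores))
    raise ValueError(f"unknown aggregation method {method!r}")


def quantile_report(
    predictions: np.ndarray,
    responses: np.ndarray,
    q: int = 10,
) -> pd.DataFrame:
    """Mean response per prediction-rank bin.

    Rows are sorted by prediction (stable, so ties keep input order)
    and split into ``q`` near-equal bins; the report gives each bin's
    size, mean prediction and mean response.
    """
    predictions = np.asarray(predictions, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if predictions.shape != responses.shape:
        raise ValueError("predictions and responses must have equal length")
    n = len(predictions)
    if n < q:
        raise ValueError(f"need at least q={q} observations, got {n}")
    order = np.argsort(predictions, kind="stable")
    bins = np.array_split(order, q)
    rows = []
    for b, idx in enumerate(bins):
        rows.append(
            {
                "bin": b + 1,
                "n": len(idx),
                "mean_prediction": float(predictions[idx].mean()),
                "mean_response": float(responses[idx].mean()),
            }
        )
    return pd.DataFrame(rows)
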