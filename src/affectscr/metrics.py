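"""Model evaluation metrics and feature screening.

Models are scored against observations by Pearson's r (with a t-based
p-value and an approximate Fisher-z 95% CI), the mean squared error, and the
combined selection score

    Index = r / MSE,

which increases with accuracy on both axes (bigger r, smaller MSE).  One-way
ANOVA screens SCR feature columns for between-class differences before any
column enters a regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import (
    EmptyInputError,
    SchemaError,
    UndefinedCorrelationError,
)

__all__ = [
    "EvalReport",
    "AnovaResult",
    "pearson_r",
    "mse",
    "index",
    "one_way_anova",
    "evaluate",
    "evaluate_arrays",
]


@dataclass(frozen=True)
class EvalReport:
    """Metrics of one model on one data set.

    ``index`` is ``inf`` when the fit is exact (MSE = 0) — a documented
    sentinel, not an error.  The CI is the Fisher-z interval, which is
    approximate; it is reported for context, never used for selection.
    """

    r: float
    r_ci: tuple[float, float]
    p_value: float
    mse: float
    index: float
    n: int

    def as_row(self, model_id: str = "") -> dict:
        return {
            "model_id": model_id, "n": self.n, "r": self.r,
            "ci_low": self.r_ci[0], "ci_high": self.r_ci[1],
            "p": self.p_value, "mse": self.mse, "index": self.index,
        }


@dataclass(frozen=True)
class AnovaResult:
    """One-way ANOVA decomposition for a feature column across classes."""

    F: float
    df_between: int
    df_within: int
    p_value: float


def pearson_r(observed, predicted, ci_level: float = 0.95):
    """Pearson correlation with two-sided p-value and Fisher-z CI.

    The p-value is the classical t-transform test with n-2 degrees of
    freedom; the CI uses the Fisher z transform with a 1/sqrt(n-3) standard
    error (NaN bounds when n <= 3).

    Raises
    ------
    UndefinedCorrelationError
        If either input has zero variance.
    """
    x = np.asarray(observed, dtype=float).ravel()
    y = np.asarray(predicted, dtype=float).ravel()
    if len(x) != len(y):
        raise SchemaError("observed and predicted lengths differ")
    if len(x) < 3:
        raise EmptyInputError("need at least 3 points for a correlation test")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero-variance input: r is undefined")
    res = stats.pearsonr(x, y)
    r, p = float(res.statistic), float(res.pvalue)
    n = len(x)
    if n > 3 and abs(r) < 1:
        z = np.arctanh(r)
        half = stats.norm.ppf(0.5 + ci_level / 2.0) / np.sqrt(n - 3)
        ci = (float(np.tanh(z - half)), float(np.tanh(z + half)))
    else:
        ci = (np.nan, np.nan)
    return r, p, ci


def mse(observed, predicted) -> float:
    """Mean squared error between observations and predictions."""
    x = np.asarray(observed, dtype=float).ravel()
    y = np.asarray(predicted, dtype=float).ravel()
    if len(x) != len(y):
        raise SchemaError("observed and predicted lengths differ")
    if len(x) == 0:
        raise EmptyInputError("mse of empty vectors is undefined")
    return float(np.mean((x - y) ** 2))


def index(r: float, mse_value: float) -> float:
    """Model-selection score Index = r / MSE (larger is better).

    An exact fit (MSE = 0) returns ``inf`` as a sentinel.
    """
    if mse_value < 0:
        raise SchemaError("mse must be non-negative")
    if mse_value == 0.0:
        return float(np.inf) if r >= 0 else float(-np.inf)
    return float(r) / float(mse_value)


def one_way_anova(values, group_labels) -> AnovaResult:
    """Classical one-way ANOVA across the groups in ``group_labels``.

    F = (SSB/(k-1)) / (SSW/(N-k)); the p-value comes from the F(k-1, N-k)
    distribution.
    """
    values = np.asarray(values, dtype=float).ravel()
    labels = np.asarray(group_labels).ravel()
    if len(values) != len(labels):
        raise SchemaError("values and group_labels lengths differ")
    uniq = list(dict.fromkeys(labels.tolist()))
    if len(uniq) < 2:
        raise EmptyInputError("one-way ANOVA needs at least 2 groups")
    groups = [values[labels == u] for u in uniq]
    if any(len(g) == 0 for g in groups):
        raise EmptyInputError("every group needs at least one value")
    n_total, k = len(values), len(uniq)
    if n_total <= k:
        raise EmptyInputError("need more observations than groups")
    F, p = stats.f_oneway(*groups)
    return AnovaResult(F=float(F), df_between=k - 1, df_within=n_total - k,
                       p_value=float(p))


def evaluate_arrays(observed, predicted) -> EvalReport:
    """Bundle r, CI, p, MSE and Index for one observed/predicted pair."""
    r, p, ci = pearson_r(observed, predicted)
    m = mse(observed, predicted)
    return EvalReport(r=r, r_ci=ci, p_value=p, mse=m, index=index(r, m),
                      n=len(np.asarray(observed).ravel()))


def evaluate(model, table, target_label: str, variables=None) -> EvalReport:
    """Evaluate a fitted polynomial model against a feature table.

    ``variables`` defaults to the model's own input-variable names, which
    must be columns of ``table``; ``target_label`` names the observed column.
    """
    from .hmpr import predict  # deferred: avoid import cycle

    poly = getattr(model, "poly", model)
    variables = list(variables) if variables is not None else list(poly.var_names)
    missing = [c for c in [target_label, *variables] if c not in table.columns]
    if missing:
        raise SchemaError(f"table missing columns: {missing}")
    X = table[variables].to_numpy(dtype=float)
    yhat = predict(poly, X)
    return evaluate_arrays(table[target_label].to_numpy(dtype=float), yhat)
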