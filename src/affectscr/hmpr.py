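"""Higher-order multivariable polynomial regression (HMPR).

A p-th order polynomial in m variables,

    y = sum_{|e| <= p} beta_e * x1^e1 * ... * xm^em,

is linear in its coefficients, so it is fitted by linear least squares on the
monomial design matrix.  High orders make the design numerically singular;
the solver therefore uses the singular value decomposition with truncation
(tLS): singular values below ``singular_criterion`` times the largest are
zeroed and the minimum-norm solution over the retained subspace is returned.
Coefficients whose two-sided t-test p-value exceeds ``significance_level``
are pruned by backward elimination (one term per refit; the intercept is
exempt), yielding sparse interpretable surfaces whose gradient fields can be
analyzed analytically.

The module exposes both the functional building blocks
(:func:`monomial_exponents`, :func:`build_design`, :func:`truncated_ls`,
:func:`fit_hmpm`, :func:`predict`, :func:`gradient`, ...) and a
statsmodels-style :class:`HMPR` model class whose :meth:`HMPR.fit` returns an
:class:`HMPRResults` object.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from itertools import product
from math import comb
from pathlib import Path

import numpy as np
from scipy import stats

from .exceptions import (
    EmptyInputError,
    InvalidDataError,
    InvalidParameterError,
    SchemaError,
)

__all__ = [
    "FitConfig",
    "PolynomialModel",
    "HMPR",
    "HMPRResults",
    "monomial_exponents",
    "build_design",
    "truncated_ls",
    "prune_insignificant",
    "fit_hmpm",
    "predict",
    "gradient",
    "gradient_field",
    "select_order",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class FitConfig:
    """Numerical and statistical settings for one HMPR fit.

    singular_criterion
        Relative singular-value cutoff: directions with s_i < criterion * s_max
        are truncated.  Default 1e-8.
    significance_level
        Two-sided p-value above which a coefficient is eliminated.
        Default 1e-4.
    max_order
        Upper bound for order sweeps.
    standardize
        Equilibrate design columns to unit norm before the SVD (conditioning
        aid for high orders on raw units); coefficients are mapped back to
        raw units, so only the truncation decision changes.  Off by default.
    """

    singular_criterion: float = 1e-8
    significance_level: float = 1e-4
    max_order: int = 10
    standardize: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.significance_level < 1.0):
            raise InvalidParameterError("significance_level must be in (0, 1)")
        if self.singular_criterion <= 0:
            raise InvalidParameterError("singular_criterion must be positive")


@dataclass(frozen=True)
class PolynomialModel:
    """A fitted (possibly pruned) multivariable polynomial.

    ``exponents[k]`` is the m-tuple of powers of the k-th retained monomial
    and ``coefficients[k]`` its coefficient; ``coef_se``/``coef_p`` carry the
    tLS standard errors and two-sided p-values (NaN when the residual degrees
    of freedom are exhausted).
    """

    num_vars: int
    order: int
    exponents: tuple[tuple[int, ...], ...]
    coefficients: np.ndarray
    coef_se: np.ndarray
    coef_p: np.ndarray
    target_label: str = ""
    var_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "coefficients",
                           np.asarray(self.coefficients, dtype=float))
        object.__setattr__(self, "coef_se", np.asarray(self.coef_se, dtype=float))
        object.__setattr__(self, "coef_p", np.asarray(self.coef_p, dtype=float))
        exps = tuple(tuple(int(v) for v in e) for e in self.exponents)
        object.__setattr__(self, "exponents", exps)
        if len(set(exps)) != len(exps):
            raise SchemaError("duplicate exponent tuples")
        if any(len(e) != self.num_vars for e in exps):
            raise SchemaError("exponent tuple arity != num_vars")
        if any(sum(e) > self.order for e in exps):
            raise SchemaError("exponent tuple degree exceeds model order")
        if len(self.coefficients) != len(exps):
            raise SchemaError("one coefficient per exponent tuple required")


def monomial_exponents(m: int, p: int) -> list[tuple[int, ...]]:
    """All m-tuples of non-negative integer powers with sum <= p.

    Graded-lexicographic order: ascending total degree, and within a degree
    descending lexicographic (so for m=2, p=1: (0,0), (1,0), (0,1)).  The
    count is C(m+p, m).
    """
    if m < 1 or p < 0:
        raise InvalidParameterError("need m >= 1 and p >= 0")
    out: list[tuple[int, ...]] = []
    for d in range(p + 1):
        layer = [e for e in product(range(d + 1), repeat=m) if sum(e) == d]
        out.extend(sorted(layer, reverse=True))
    assert len(out) == comb(m + p, m)
    return out


def build_design(X, exponents) -> np.ndarray:
    """Monomial design matrix: entry (i, k) = prod_v X[i, v] ** exponents[k][v]."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if not np.all(np.isfinite(X)):
        raise InvalidDataError("design input contains non-finite values")
    E = np.asarray(list(exponents), dtype=float)
    if E.ndim != 2 or E.shape[1] != X.shape[1]:
        raise SchemaError(
            f"exponent arity {E.shape[-1] if E.ndim == 2 else '?'} does not "
            f"match {X.shape[1]} input variables"
        )
    with np.errstate(divide="ignore"):
        A = np.prod(X[:, None, :] ** E[None, :, :], axis=2)
    return A


def truncated_ls(A, y, singular_criterion: float = 1e-8):
    """Truncated-SVD least squares with t-based coefficient inference.

    Singular values below ``singular_criterion * s_max`` are zeroed; the
    returned solution is the minimum-norm least-squares solution over the
    retained subspace (identical to ordinary LS when the design is well
    conditioned).  Standard errors come from the truncated pseudoinverse
    covariance with residual degrees of freedom n - rank; when df <= 0 the
    standard errors and p-values are NaN (flagged undefined, not an error).

    Returns ``(coefficients, coef_se, coef_p, rank)``.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if A.shape[0] == 0:
        raise EmptyInputError("design matrix has zero rows")
    if A.shape[0] != len(y):
        raise SchemaError("design rows and response length differ")
    n, k = A.shape
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    if s.size == 0 or s[0] == 0.0:
        keep = np.zeros_like(s, dtype=bool)
    else:
        keep = s > singular_criterion * s[0]
    rank = int(keep.sum())
    if rank == 0:
        coef = np.zeros(k)
    else:
        coef = Vt[keep].T @ ((U[:, keep].T @ y) / s[keep])
    resid = y - A @ coef
    sse = float(resid @ resid)
    df = n - rank
    if df > 0:
        sigma2 = sse / df
        var = sigma2 * np.sum(Vt[keep].T ** 2 / s[keep] ** 2, axis=1) if rank else \
            np.zeros(k)
        se = np.sqrt(var)
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = np.where(se > 0, coef / se, np.inf * np.sign(coef))
        p = np.where(
            se > 0,
            2.0 * stats.t.sf(np.abs(np.where(se > 0, tvals, 0.0)), df),
            np.where(coef == 0.0, np.nan, 0.0),
        )
    else:
        se = np.full(k, np.nan)
        p = np.full(k, np.nan)
    return coef, se, p, rank


def _fit_fixed_basis(X, y, exponents, config: FitConfig,
                     target_label: str, var_names, order: int) -> PolynomialModel:
    A = build_design(X, exponents)
    if config.standardize:
        norms = np.linalg.norm(A, axis=0)
        norms[norms == 0] = 1.0
        coef, se, p, _ = truncated_ls(A / norms, y, config.singular_criterion)
        coef, se = coef / norms, se / norms
    else:
        coef, se, p, _ = truncated_ls(A, y, config.singular_criterion)
    return PolynomialModel(
        num_vars=X.shape[1], order=order, exponents=tuple(exponents),
        coefficients=coef, coef_se=se, coef_p=p,
        target_label=target_label, var_names=tuple(var_names),
    )


def prune_insignificant(model: PolynomialModel, X, y,
                        config: FitConfig | None = None) -> PolynomialModel:
    """Backward elimination of insignificant terms.

    Repeatedly drops the single term with the largest p-value above
    ``significance_level`` and refits, until every retained term is
    significant or only the intercept remains.  The intercept (all-zero
    exponent tuple) is never removed.  Terms with undefined (NaN) p-values
    are kept: they cannot be assessed.
    """
    config = config or FitConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    current = model
    intercept = tuple([0] * model.num_vars)
    for _ in range(len(model.exponents)):
        removable = [
            (pv, idx) for idx, (e, pv) in
            enumerate(zip(current.exponents, current.coef_p))
            if e != intercept and np.isfinite(pv) and pv > config.significance_level
        ]
        if not removable:
            break
        _, worst = max(removable)
        exps = [e for i, e in enumerate(current.exponents) if i != worst]
        if not exps:
            break
        current = _fit_fixed_basis(X, y, exps, config, current.target_label,
                                   current.var_names, current.order)
    return current


def fit_hmpm(X, y, order: int, config: FitConfig | None = None,
             prune: bool = True, target_label: str = "",
             var_names=None) -> PolynomialModel:
    """Fit a p-th order multivariable polynomial model.

    Composes basis enumeration, design construction, truncated-SVD least
    squares and (optionally) backward elimination.  A first-order fit is an
    ordinary multivariate linear regression.
    """
    config = config or FitConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if var_names is None:
        var_names = tuple(f"x{i+1}" for i in range(X.shape[1]))
    exps = monomial_exponents(X.shape[1], order)
    model = _fit_fixed_basis(X, y, exps, config, target_label, var_names, order)
    if prune:
        model = prune_insignificant(model, X, y, config)
    return model


def predict(model: PolynomialModel, X) -> np.ndarray:
    """Evaluate the polynomial at rows of X."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.num_vars:
        raise SchemaError(
            f"model expects {model.num_vars} variables, got {X.shape[1]}"
        )
    return build_design(X, model.exponents) @ model.coefficients


def gradient(model: PolynomialModel, point) -> np.ndarray:
    """Analytic gradient of the polynomial at one point."""
    point = np.asarray(point, dtype=float).ravel()
    if len(point) != model.num_vars:
        raise SchemaError(
            f"model expects {model.num_vars} variables, got {len(point)}"
        )
    grad = np.zeros(model.num_vars)
    for coef, e in zip(model.coefficients, model.exponents):
        for v, ev in enumerate(e):
            if ev == 0:
                continue
            shifted = list(e)
            shifted[v] -= 1
            term = coef * ev
            for u, eu in enumerate(shifted):
                if eu:
                    term *= point[u] ** eu
            grad[v] += term
    return grad


def gradient_field(model: PolynomialModel, bounds, num=20):
    """Gradient evaluated on a rectangular grid.

    Parameters
    ----------
    bounds
        Sequence of (low, high) per variable.
    num
        Nodes per axis (int or per-axis sequence).

    Returns
    -------
    (points, vectors)
        Both (N, m) arrays, N the number of grid nodes in row-major order.
    """
    bounds = [tuple(map(float, b)) for b in bounds]
    if len(bounds) != model.num_vars:
        raise SchemaError("one (low, high) bound pair per model variable required")
    nums = [int(num)] * len(bounds) if np.isscalar(num) else [int(v) for v in num]
    if any(v < 1 for v in nums):
        raise EmptyInputError("grid must have at least one node per axis")
    axes = [np.linspace(lo, hi, nv) for (lo, hi), nv in zip(bounds, nums)]
    mesh = np.meshgrid(*axes, indexing="ij")
    points = np.stack([m.ravel() for m in mesh], axis=1)
    vectors = np.array([gradient(model, pt) for pt in points])
    return points, vectors


def select_order(X_train, y_train, X_eval, y_eval, orders,
                 config: FitConfig | None = None, target_label: str = "",
                 var_names=None):
    """Sweep polynomial orders; keep the model with the largest Index.

    Each candidate order is fitted (with pruning) on the training set and
    scored on the evaluation set by Index = r / MSE.  Ties (non-strict
    improvements) break toward the lower order.  Models whose predictions on
    the evaluation set are constant (Pearson r undefined) are reported with
    NaN metrics and never selected.

    Returns ``(best_model, reports)`` with ``reports`` an order-keyed dict of
    :class:`~affectscr.metrics.EvalReport`.
    """
    from . import metrics  # local import: metrics depends on predict()

    orders = list(orders)
    if not orders:
        raise EmptyInputError("orders list is empty")
    config = config or FitConfig()
    best_model, best_index = None, -np.inf
    reports = {}
    for p in sorted(orders):
        model = fit_hmpm(X_train, y_train, order=p, config=config,
                         target_label=target_label, var_names=var_names)
        try:
            report = metrics.evaluate_arrays(
                np.asarray(y_eval, dtype=float), predict(model, X_eval))
            score = report.index
        except metrics.UndefinedCorrelationError:
            report = metrics.EvalReport(
                r=np.nan, r_ci=(np.nan, np.nan), p_value=np.nan,
                mse=float(np.mean((np.asarray(y_eval, float)
                                   - predict(model, X_eval)) ** 2)),
                index=np.nan, n=len(np.asarray(y_eval).ravel()))
            score = -np.inf
        reports[p] = report
        if score > best_index:
            best_model, best_index = model, score
    return best_model, reports


# --- serialization ----------------------------------------------------------

_MODEL_HEADER = "# affectscr polynomial model v1"


def save_model(model: PolynomialModel, path) -> None:
    """Write a model as delimited text (repr floats: lossless round-trip)."""
    lines = [
        _MODEL_HEADER,
        f"# target: {model.target_label}",
        f"# num_vars: {model.num_vars}",
        f"# order: {model.order}",
        f"# variables: {','.join(model.var_names)}",
        "exponents\tcoefficient\tse\tp",
    ]
    for e, c, s, p in zip(model.exponents, model.coefficients,
                          model.coef_se, model.coef_p):
        etxt = ";".join(str(v) for v in e)
        lines.append(f"{etxt}\t{float(c)!r}\t{float(s)!r}\t{float(p)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_model(path) -> PolynomialModel:
    """Read a model written by :func:`save_model`."""
    text = Path(path).read_text()
    meta = {}
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("# ")
            if ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip()] = val.strip()
            continue
        if line.startswith("exponents"):
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise SchemaError(f"malformed model row: {line!r}")
        exp = tuple(int(v) for v in parts[0].split(";"))
        rows.append((exp, float(parts[1]), float(parts[2]), float(parts[3])))
    if not rows:
        raise SchemaError("model file contains no coefficient rows")
    try:
        num_vars = int(meta["num_vars"])
        order = int(meta["order"])
    except KeyError as exc:
        raise SchemaError(f"model file missing header field {exc}") from exc
    var_names = tuple(v for v in meta.get("variables", "").split(",") if v)
    return PolynomialModel(
        num_vars=num_vars, order=order,
        exponents=tuple(r[0] for r in rows),
        coefficients=np.array([r[1] for r in rows]),
        coef_se=np.array([r[2] for r in rows]),
        coef_p=np.array([r[3] for r in rows]),
        target_label=meta.get("target", ""),
        var_names=var_names or tuple(f"x{i+1}" for i in range(num_vars)),
    )


# --- statsmodels-style surface ---------------------------------------------


class HMPR:
    """Higher-order multivariable polynomial regression model.

    Parameters
    ----------
    endog : array-like
        Response vector (e.g. valence or arousal ratings).
    exog : array-like, shape (n, m)
        Input variables (e.g. columns gain and decay time constant).
    order : int
        Polynomial order p.
    config : FitConfig, optional
    var_names, target_label : optional labels carried into results.

    Examples
    --------
    >>> model = HMPR(y, X, order=3)
    >>> res = model.fit()
    >>> res.predict(X_new)
    """

    def __init__(self, endog, exog, order: int,
                 config: FitConfig | None = None,
                 var_names=None, target_label: str = ""):
        self.endog = np.asarray(endog, dtype=float).ravel()
        self.exog = np.atleast_2d(np.asarray(exog, dtype=float))
        if self.exog.shape[0] != len(self.endog):
            raise SchemaError("endog and exog row counts differ")
        self.order = int(order)
        self.config = config or FitConfig()
        self.var_names = tuple(var_names) if var_names is not None else \
            tuple(f"x{i+1}" for i in range(self.exog.shape[1]))
        self.target_label = target_label

    @classmethod
    def from_dataframe(cls, df, target: str, variables, order: int,
                       config: FitConfig | None = None) -> "HMPR":
        variables = list(variables)
        missing = [c for c in [target, *variables] if c not in df.columns]
        if missing:
            raise SchemaError(f"dataframe missing columns: {missing}")
        return cls(df[target].to_numpy(dtype=float),
                   df[variables].to_numpy(dtype=float),
                   order=order, config=config,
                   var_names=variables, target_label=target)

    def fit(self, prune: bool = True) -> "HMPRResults":
        model = fit_hmpm(self.exog, self.endog, order=self.order,
                         config=self.config, prune=prune,
                         target_label=self.target_label,
                         var_names=self.var_names)
        return HMPRResults(self, model)


@dataclass
class HMPRResults:
    """Fitted-model results: coefficients, uncertainties, diagnostics."""

    model_spec: HMPR
    poly: PolynomialModel
    sse: float = field(init=False)
    mse_resid: float = field(init=False)

    def __post_init__(self) -> None:
        resid = self.resid
        self.sse = float(resid @ resid)
        self.mse_resid = self.sse / len(resid)

    # statsmodels-flavoured accessors
    @property
    def params(self) -> np.ndarray:
        return self.poly.coefficients

    @property
    def bse(self) -> np.ndarray:
        return self.poly.coef_se

    @property
    def pvalues(self) -> np.ndarray:
        return self.poly.coef_p

    @property
    def exponents(self):
        return self.poly.exponents

    @property
    def nobs(self) -> int:
        return len(self.model_spec.endog)

    @property
    def fittedvalues(self) -> np.ndarray:
        return predict(self.poly, self.model_spec.exog)

    @property
    def resid(self) -> np.ndarray:
        return self.model_spec.endog - self.fittedvalues

    def predict(self, X) -> np.ndarray:
        return predict(self.poly, X)

    def gradient(self, point) -> np.ndarray:
        return gradient(self.poly, point)

    def gradient_field(self, bounds, num=20):
        return gradient_field(self.poly, bounds, num=num)

    def save(self, path) -> None:
        save_model(self.poly, path)

    def summary(self) -> str:
        """Plain-text coefficient table with fit diagnostics."""
        buf = io.StringIO()
        name = self.poly.target_label or "y"
        buf.write(f"HMPR results — target: {name}\n")
        buf.write(f"order: {self.poly.order}   variables: "
                  f"{', '.join(self.poly.var_names)}\n")
        buf.write(f"nobs: {self.nobs}   retained terms: "
                  f"{len(self.poly.exponents)}   SSE: {self.sse:.6g}\n")
        buf.write(f"{'term':<24}{'coef':>14}{'se':>14}{'p':>12}\n")
        for e, c, s, p in zip(self.poly.exponents, self.params,
                              self.bse, self.pvalues):
            term = "*".join(
                f"{v}^{ev}" if ev > 1 else v
                for v, ev in zip(self.poly.var_names, e) if ev
            ) or "const"
            buf.write(f"{term:<24}{c:>14.6g}{s:>14.6g}{p:>12.3g}\n")
        return buf.getvalue()

    def plot_gradient_field(self, bounds, num=20, ax=None):
        """Quiver plot of the fitted surface's gradient field (2-D models)."""
        if self.poly.num_vars != 2:
            raise SchemaError("gradient-field plotting requires a 2-variable model")
        import matplotlib.pyplot as plt

        points, vectors = self.gradient_field(bounds, num=num)
        if ax is None:
            _, ax = plt.subplots()
        ax.quiver(points[:, 0], points[:, 1], vectors[:, 0], vectors[:, 1])
        ax.set_xlabel(self.poly.var_names[0])
        ax.set_ylabel(self.poly.var_names[1])
        ax.set_title(f"gradient field: {self.poly.target_label or 'y'}")
        return ax
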