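"""Parameter estimation by discretized log-difference regression.

Integrating the per-capita (log-derivative) form of the gLV equations
over one sampling interval [t_k, t_{k+1}] with the implicit trapezoid
rule gives, per taxon i,

    (ln x_i(t_{k+1}) - ln x_i(t_k)) / dt_k
        ~= r_i + sum_j alpha_ij * (x_j(t_{k+1}) + x_j(t_k)) / 2

which is a linear regression of the log-difference rate on the
interval-midpoint abundances: the intercept estimates r_i and the
coefficients the row alpha_i.  Each taxon is fitted independently
against one shared design matrix.

Two fitting modes are provided: unconstrained partial least squares
(full latent components reproduce ordinary least squares on full-rank
designs) and a constrained least-squares fit enforcing the biological
realism constraints r_i >= 0 and alpha_ii <= 0.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import lsq_linear
from sklearn.cross_decomposition import PLSRegression

from .core import GLVModel
from .errors import UnderdeterminedSystemError, ValidationError
from .tables import AbundanceTable

__all__ = [
    "RegressionSystem",
    "EstimationResult",
    "build_regression_system",
    "estimate_unconstrained",
    "estimate_constrained",
]


@dataclass
class RegressionSystem:
    """The shared design matrix and per-taxon responses of the fit.

    ``design`` has one row per interval and one column per taxon
    (trapezoid midpoints).  ``responses[taxon]`` holds that taxon's
    log-difference rates for its *usable* intervals only; ``masks``
    records which intervals those are, and ``dropped_intervals`` the
    excluded ones (a zero abundance at either endpoint makes the log
    difference undefined for the focal taxon).
    """

    taxa: list[str]
    design: np.ndarray
    responses: dict[str, np.ndarray]
    masks: dict[str, np.ndarray]
    interval_times: list[tuple[float, float]]
    dropped_intervals: dict[str, list[int]]

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_intervals(self) -> int:
        return int(self.design.shape[0])


@dataclass
class EstimationResult:
    """A fitted model plus per-taxon goodness-of-fit bookkeeping."""

    model: GLVModel
    residual_norms: dict[str, float]
    feasible: bool
    settings: dict
    warnings: list[str] = field(default_factory=list)


def build_regression_system(
    table: AbundanceTable,
    taxa_subset: list[str] | None = None,
    window: tuple[int, int] | None = None,
    pseudocount: float | None = None,
    allow_underdetermined: bool = False,
) -> RegressionSystem:
    """Discretize an abundance table into the regression system.

    Parameters
    ----------
    table
        Observed abundances.
    taxa_subset
        Taxa to model (default: all), in the given order.
    window
        Inclusive (start_index, end_index) pair of time-point indices
        restricting the intervals used.
    pseudocount
        If given (or ``0`` meaning "auto": half the smallest positive
        value in the table), added to every abundance before taking
        logs instead of dropping zero-endpoint intervals.
    allow_underdetermined
        Skip the identifiability check (n+1 parameters per taxon need
        at least n+1 usable intervals).
    """
    if taxa_subset is not None:
        table = table.subset(list(taxa_subset))
    if window is not None:
        start, end = window
        table = table.window(int(start), int(end))
    n = table.n_taxa
    if table.n_times < 2:
        raise ValidationError("need at least 2 time points to form an interval")

    x = table.values
    if pseudocount is not None:
        eps = float(pseudocount)
        if eps == 0.0:
            positive = x[x > 0]
            if positive.size == 0:
                raise ValidationError("all-zero table; no pseudocount derivable")
            eps = float(positive.min()) / 2.0
        x = x + eps

    dts = np.diff(table.times)
    design = (x[1:] + x[:-1]) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        log_x = np.log(x)
        rates = (log_x[1:] - log_x[:-1]) / dts[:, None]

    interval_times = [
        (float(a), float(b)) for a, b in zip(table.times[:-1], table.times[1:])
    ]
    responses: dict[str, np.ndarray] = {}
    masks: dict[str, np.ndarray] = {}
    dropped: dict[str, list[int]] = {}
    n_params = n + 1
    for j, taxon in enumerate(table.taxa):
        usable = (x[1:, j] > 0) & (x[:-1, j] > 0)
        responses[taxon] = rates[usable, j]
        masks[taxon] = usable
        dropped[taxon] = [int(k) for k in np.nonzero(~usable)[0]]
        if not allow_underdetermined and int(usable.sum()) < n_params:
            raise UnderdeterminedSystemError(
                f"taxon {taxon!r} has {int(usable.sum())} usable intervals "
                f"but {n_params} parameters (intercept + {n} interactions) "
                "must be identified; widen the window or reduce taxa"
            )
    return RegressionSystem(
        taxa=list(table.taxa),
        design=design,
        responses=responses,
        masks=masks,
        interval_times=interval_times,
        dropped_intervals=dropped,
    )


def _pls_fit(X: np.ndarray, y: np.ndarray, k: int) -> tuple[np.ndarray, float]:
    """PLS coefficients and intercept; min-norm lstsq on degenerate input.

    PLS is undefined when the response or every predictor is constant
    (zero centered variance); the least-norm least-squares solution of
    the interceptful system is the natural continuous completion there.
    """
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    degenerate = not np.any(yc) or not np.any(Xc)
    coef = None
    if not degenerate:
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            pls = PLSRegression(n_components=k, scale=False)
            try:
                pls.fit(X, y)
                coef = pls.coef_.ravel()
                intercept = float(y.mean() - X.mean(axis=0) @ coef)
            except Exception:  # noqa: BLE001 - degenerate numerics
                coef = None
        if coef is not None and not np.all(np.isfinite(coef)):
            coef = None
    if coef is None:
        A = np.column_stack([np.ones(len(y)), X])
        sol, *_ = np.linalg.lstsq(A, y, rcond=None)
        intercept, coef = float(sol[0]), sol[1:]
    return np.asarray(coef, dtype=float), float(intercept)


def estimate_unconstrained(
    system: RegressionSystem, n_components: int | str = "auto"
) -> EstimationResult:
    """Fit each taxon's (r_i, alpha_i) by partial least squares.

    ``n_components="auto"`` uses min(n_taxa, usable_intervals - 1) per
    taxon; with full components on a full-column-rank design the fit
    coincides with ordinary least squares.
    """
    n = system.n_taxa
    if isinstance(n_components, int) and n_components > n:
        raise ValidationError(
            f"n_components={n_components} exceeds the {n} predictors"
        )
    rates = np.empty(n)
    alpha = np.empty((n, n))
    residuals: dict[str, float] = {}
    warn: list[str] = []
    for i, taxon in enumerate(system.taxa):
        y = system.responses[taxon]
        X = system.design[system.masks[taxon]]
        if y.size == 0:
            raise UnderdeterminedSystemError(
                f"taxon {taxon!r} has no usable intervals"
            )
        k = (
            min(n, max(y.size - 1, 1))
            if n_components == "auto"
            else int(n_components)
        )
        k = max(min(k, y.size), 1)
        coef, intercept = _pls_fit(X, y, k)
        rates[i] = intercept
        alpha[i] = coef
        residuals[taxon] = float(np.sum((y - (intercept + X @ coef)) ** 2))
        if not np.any(y - y.mean()) or not np.any(X - X.mean(axis=0)):
            warn.append(
                f"taxon {taxon!r}: degenerate (constant) regression; "
                "parameters are non-unique, minimum-norm solution returned"
            )
    model = GLVModel(
        taxa=list(system.taxa),
        growth_rates=rates,
        interactions=alpha,
        method_tag="unconstrained",
    )
    return EstimationResult(
        model=model,
        residual_norms=residuals,
        feasible=True,
        settings={"method": "pls", "n_components": n_components},
        warnings=warn,
    )


def estimate_constrained(system: RegressionSystem) -> EstimationResult:
    """Constrained least squares: r_i >= 0 and alpha_ii <= 0.

    Solves, per taxon, min ||intercept + design @ coeffs - response||^2
    subject to intercept >= 0 and the self-interaction coefficient
    <= 0 (off-diagonals free), via bounded-variable least squares.
    ``feasible`` is False if the solver fails for any taxon; the
    returned model then falls back to the unconstrained fit and the
    caller decides what to do.
    """
    n = system.n_taxa
    rates = np.empty(n)
    alpha = np.empty((n, n))
    residuals: dict[str, float] = {}
    warn: list[str] = []
    feasible = True
    for i, taxon in enumerate(system.taxa):
        y = system.responses[taxon]
        X = system.design[system.masks[taxon]]
        if y.size == 0:
            raise UnderdeterminedSystemError(
                f"taxon {taxon!r} has no usable intervals"
            )
        A = np.column_stack([np.ones(y.size), X])
        lb = np.full(n + 1, -np.inf)
        ub = np.full(n + 1, np.inf)
        lb[0] = 0.0       # intrinsic growth r_i >= 0
        ub[1 + i] = 0.0   # self interaction alpha_ii <= 0
        try:
            res = lsq_linear(A, y, bounds=(lb, ub), method="bvls")
            if not res.success and res.status <= 0:
                raise RuntimeError(res.message)
            sol = res.x
        except Exception as exc:  # noqa: BLE001 - report infeasibility
            feasible = False
            warn.append(f"constrained fit failed for {taxon!r}: {exc}")
            sol, *_ = np.linalg.lstsq(A, y, rcond=None)
        rates[i] = sol[0]
        alpha[i] = sol[1:]
        residuals[taxon] = float(np.sum((A @ sol - y) ** 2))
    model = GLVModel(
        taxa=list(system.taxa),
        growth_rates=rates,
        interactions=alpha,
        method_tag="constrained" if feasible else "unconstrained",
    )
    return EstimationResult(
        model=model,
        residual_norms=residuals,
        feasible=feasible,
        settings={"method": "constrained-lsq"},
        warnings=warn,
    )
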