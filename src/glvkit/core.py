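"""Generalized Lotka-Volterra dynamics and numerical simulation.

The model couples ``n`` taxa through

    dx_i/dt = x_i * (r_i + sum_j alpha_ij * x_j)

where ``r_i`` is the intrinsic per-capita growth rate of taxon ``i``
(units 1/time) and ``alpha_ij`` the per-abundance effect of taxon ``j``
on taxon ``i``'s growth rate (units 1/(abundance*time)).  A positive
off-diagonal entry is a beneficial interaction, a negative one
inhibitory, zero means no interaction; the diagonal encodes
self-limitation (carrying capacity ``-r_i/alpha_ii`` for one species).

Simulation integrates the initial-value problem with an adaptive-step
solver and interpolates the dense solution onto a regular output grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .errors import SimulationError, ValidationError

__all__ = [
    "GLVModel",
    "SimulationSpec",
    "Trajectory",
    "glv_rhs",
    "simulate",
    "integrate_on",
    "SOLVERS",
    "DEFAULT_SPECIES_CAP",
    "DEFAULT_OUTPUT_POINTS_CAP",
]

#: Map from glvkit solver identifiers to scipy ``solve_ivp`` methods.
#: ``rk45`` is the classic adaptive Runge-Kutta 4(5) (the "ODE45"
#: analogue) and the default.
SOLVERS: dict[str, str] = {
    "rk45": "RK45",
    "rk23": "RK23",
    "lsoda": "LSODA",
    "bdf": "BDF",
}

DEFAULT_SPECIES_CAP = 10
DEFAULT_OUTPUT_POINTS_CAP = 100

#: Values in (-NEGATIVE_FLOOR, 0) from floating-point integration are
#: snapped to 0; anything at or below -NEGATIVE_FLOOR is a solver
#: failure (the continuous model preserves nonnegativity exactly).
NEGATIVE_FLOOR = 1e-8


@dataclass
class GLVModel:
    """Growth rates and interaction matrix for a community of taxa."""

    taxa: list[str]
    growth_rates: np.ndarray
    interactions: np.ndarray
    method_tag: str = "user_supplied"

    def __post_init__(self) -> None:
        self.taxa = [str(t).strip() for t in self.taxa]
        self.growth_rates = np.asarray(self.growth_rates, dtype=float).ravel()
        self.interactions = np.atleast_2d(
            np.asarray(self.interactions, dtype=float)
        )
        n = len(self.taxa)
        if n == 0:
            raise ValidationError("model needs at least one taxon")
        if len(set(self.taxa)) != n:
            raise ValidationError("duplicate taxon names in model")
        if self.growth_rates.size != n:
            raise ValidationError(
                f"{self.growth_rates.size} growth rates for {n} taxa"
            )
        if self.interactions.shape != (n, n):
            raise ValidationError(
                f"interaction matrix shape {self.interactions.shape}, "
                f"expected ({n}, {n})"
            )
        if not (
            np.all(np.isfinite(self.growth_rates))
            and np.all(np.isfinite(self.interactions))
        ):
            raise ValidationError("non-finite model parameter")
        if self.method_tag not in {"unconstrained", "constrained", "user_supplied"}:
            raise ValidationError(f"unknown method_tag {self.method_tag!r}")
        if self.method_tag == "constrained":
            if np.any(self.growth_rates < 0):
                raise ValidationError("constrained model requires r_i >= 0")
            if np.any(np.diag(self.interactions) > 0):
                raise ValidationError(
                    "constrained model requires alpha_ii <= 0"
                )

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)


@dataclass
class SimulationSpec:
    """Settings for one numerical simulation run."""

    initial_state: np.ndarray
    t_start: float = 0.0
    duration: float = 30.0
    step: float = 0.1
    solver_id: str = "rk45"
    rtol: float = 1e-8
    atol: float = 1e-11
    species_cap: int = DEFAULT_SPECIES_CAP
    output_points_cap: int = DEFAULT_OUTPUT_POINTS_CAP
    enforce_caps: bool = False

    def __post_init__(self) -> None:
        self.initial_state = np.asarray(self.initial_state, dtype=float).ravel()
        if self.duration <= 0:
            raise ValidationError("duration must be > 0")
        if self.step <= 0:
            raise ValidationError("step must be > 0")
        if self.solver_id not in SOLVERS:
            raise ValidationError(
                f"unknown solver {self.solver_id!r}; choose from "
                f"{sorted(SOLVERS)}"
            )
        if not np.all(np.isfinite(self.initial_state)):
            raise ValidationError("non-finite initial state")
        if np.any(self.initial_state < 0):
            raise ValidationError("initial abundances must be >= 0")

    def time_grid(self) -> np.ndarray:
        n_steps = int(round(self.duration / self.step))
        return self.t_start + self.step * np.arange(n_steps + 1)


@dataclass
class Trajectory:
    """Simulated abundances on a regular time grid."""

    taxa: list[str]
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if len(self.taxa) == 0:
            raise ValidationError("trajectory needs at least one taxon")
        if self.values.shape != (self.times.size, len(self.taxa)):
            raise ValidationError("trajectory shape mismatch")
        dt = np.diff(self.times)
        if self.times.size > 1 and not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
            raise ValidationError("trajectory grid must have constant spacing")
        if np.any(dt <= 0):
            raise ValidationError("trajectory times must be increasing")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValidationError("trajectory values must be finite and >= 0")

    def series(self, taxon: str) -> np.ndarray:
        try:
            j = self.taxa.index(taxon)
        except ValueError:
            raise ValidationError(f"unknown taxon {taxon!r}") from None
        return self.values[:, j].copy()


def glv_rhs(state: np.ndarray, model: GLVModel) -> np.ndarray:
    """Right-hand side dx_i/dt = x_i * (r_i + sum_j alpha_ij x_j)."""
    state = np.asarray(state, dtype=float).ravel()
    if state.size != model.n_taxa:
        raise ValidationError(
            f"state length {state.size} does not match {model.n_taxa} taxa"
        )
    if not np.all(np.isfinite(state)):
        raise ValidationError("non-finite state")
    return state * (model.growth_rates + model.interactions @ state)


def simulate(model: GLVModel, spec: SimulationSpec) -> Trajectory:
    """Integrate the gLV system and sample it on a regular grid.

    The first output row equals the initial state exactly.  Taxa that
    start at exactly 0 are held at exactly 0 (extinction is invariant
    under the dynamics).  Tiny negative excursions from floating-point
    integration are floored to 0; larger ones raise
    :class:`~glvkit.errors.SimulationError`.
    """
    if spec.initial_state.size != model.n_taxa:
        raise ValidationError(
            f"initial state length {spec.initial_state.size} does not "
            f"match {model.n_taxa} taxa"
        )
    grid = spec.time_grid()
    if spec.enforce_caps:
        if model.n_taxa > spec.species_cap:
            raise ValidationError(
                f"{model.n_taxa} taxa exceeds the {spec.species_cap}-species cap"
            )
        if grid.size > spec.output_points_cap:
            raise ValidationError(
                f"{grid.size} output points exceeds the "
                f"{spec.output_points_cap}-point cap"
            )

    values = integrate_on(
        model,
        spec.initial_state,
        grid,
        solver_id=spec.solver_id,
        rtol=spec.rtol,
        atol=spec.atol,
    )
    return Trajectory(taxa=list(model.taxa), times=grid, values=values)


def integrate_on(
    model: GLVModel,
    initial_state: np.ndarray,
    times: np.ndarray,
    solver_id: str = "rk45",
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> np.ndarray:
    """Integrate the gLV ODE and evaluate on the given (possibly
    irregular) strictly increasing time points; returns the abundance
    matrix.  The first row equals ``initial_state`` exactly and taxa
    starting at 0 stay at 0."""
    times = np.asarray(times, dtype=float)
    x0 = np.asarray(initial_state, dtype=float).ravel()
    if x0.size != model.n_taxa:
        raise ValidationError("initial state does not match model taxa")
    extinct = x0 == 0.0

    def rhs(_t: float, y: np.ndarray) -> np.ndarray:
        return y * (model.growth_rates + model.interactions @ y)

    sol = solve_ivp(
        rhs,
        (times[0], times[-1]),
        x0,
        method=SOLVERS[solver_id],
        t_eval=times,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success or sol.y.shape[1] != times.size:
        last = float(sol.t[-1]) if sol.t.size else float(times[0])
        raise SimulationError(
            f"solver {solver_id!r} failed: {sol.message} "
            f"(last valid time {last:g}); no trajectories generated",
            last_valid_time=last,
        )
    values = sol.y.T.copy()
    values[0] = x0
    values[:, extinct] = 0.0
    bad = values <= -NEGATIVE_FLOOR
    if np.any(bad):
        first_bad = int(np.nonzero(bad.any(axis=1))[0][0])
        raise SimulationError(
            f"integration produced abundance {values[bad].min():.3g} <= "
            f"-{NEGATIVE_FLOOR:g} at t={times[first_bad]:g}; solver failure",
            last_valid_time=float(times[max(first_bad - 1, 0)]),
        )
    np.clip(values, 0.0, None, out=values)
    return values
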