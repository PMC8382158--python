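"""Explicit finite-difference time stepping for the three-species model.

Space is discretized on a uniform 1D mesh with the conservative interface
fluxes of :func:`gbmpop.model.diffusive_flux`; time uses forward Euler.
Zero-flux boundaries are imposed by setting the boundary interface fluxes to
zero, which makes the plain nodal sum of each field an exactly conserved
quantity when proliferation is switched off.  Mutation events (the seeding
of the amplified populations) are delta-in-time sources realized as an
instantaneous addition of the standard Gaussian bump at the end of the first
step where the trigger condition holds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .model import ModelParams, TumourState, initial_profile

__all__ = [
    "Mesh",
    "SolverConfig",
    "SimulationTrace",
    "SimulationError",
    "StabilityError",
    "BlowUpError",
    "step",
    "total_population",
    "introduce_population",
    "run",
]


class SimulationError(RuntimeError):
    """Base class for solver failures."""


class StabilityError(SimulationError):
    """Time step violates the explicit diffusion stability bound."""


class BlowUpError(SimulationError):
    """Non-finite values appeared during time stepping."""


@dataclass(frozen=True)
class Mesh:
    """Uniform 1D mesh on [0, L] with node 0 at x=0 and the last node at x=L."""

    L: float = 200.0
    dx: float = 0.25

    def __post_init__(self) -> None:
        if self.L <= 0 or self.dx <= 0:
            raise ValueError("L and dx must be positive")
        n = self.L / self.dx
        if abs(n - round(n)) > 1e-9:
            raise ValueError("dx must divide L evenly")

    @property
    def n_nodes(self) -> int:
        return int(round(self.L / self.dx)) + 1

    @property
    def x(self) -> np.ndarray:
        return np.linspace(0.0, self.L, self.n_nodes)


@dataclass(frozen=True)
class SolverConfig:
    """Numerical and stopping settings.

    ``dt`` is the forward-Euler step (years).  Simulations stop at the first
    step where the width of the total population above
    ``detection_density_fraction * K`` reaches ``target_width`` (the imaging
    proxy for size at diagnosis), or at ``max_time`` -- hitting max_time is a
    reported outcome, not an exception.  Set ``target_width=None`` to run
    purely to max_time (fixed-horizon studies).
    """

    dt: float = 1.0 / 1500.0
    max_time: float = 50.0
    detection_density_fraction: float = 0.8
    target_width: Optional[float] = 36.2
    width_sample_interval: int = 100

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.max_time <= 0:
            raise ValueError("max_time must be positive")
        if not 0.0 < self.detection_density_fraction < 1.0:
            raise ValueError("detection_density_fraction must be in (0,1)")

    def check_stability(self, params: ModelParams, mesh: Mesh) -> None:
        """Reject dt beyond the forward-Euler diffusion bound dt <= dx^2/(2 D).

        The bound is taken at the exact CFL limit so that the full clinical
        parameter box (D up to 45 mm^2/year with dt = 1/1500, dx = 0.25,
        giving 2*D*dt/dx^2 = 0.96) remains admissible.
        """
        if mesh.L <= (self.target_width or 0.0):
            raise ValueError("target_width must be smaller than the domain")
        r = 2.0 * params.max_diffusion * self.dt / mesh.dx**2
        if r > 1.0:
            raise StabilityError(
                f"dt={self.dt} unstable: 2*D*dt/dx^2 = {r:.3f} > 1 "
                f"for D={params.max_diffusion}"
            )


@dataclass
class SimulationTrace:
    """Outcome of one simulation run."""

    final_state: TumourState
    t_star_E: Optional[float]
    t_star_P: Optional[float]
    stop_time: float
    stop_reason: str  # "target_width" or "max_time"
    widths: List[Tuple[float, float]] = field(default_factory=list)

    @property
    def reached_target(self) -> bool:
        return self.stop_reason == "target_width"


def total_population(fld: np.ndarray, mesh: Mesh) -> float:
    """Trapezoidal line density of a field over [0, L], cells/mm^2."""
    return float(np.trapezoid(np.asarray(fld, float), dx=mesh.dx))


def _euler_update(E, P, N, params: ModelParams, dx: float, dt: float) -> None:
    """One in-place forward-Euler update of the three fields.

    Conservative divergence of the volume-filling interface fluxes with
    zero-flux boundaries, plus the pointwise reactions; fields are floored
    at zero afterwards so that strongly negative modified proliferation
    (net death) cannot produce negative densities.
    """
    K = params.K
    inv_dx = 1.0 / dx
    dE = np.diff(E) * inv_dx
    dP = np.diff(P) * inv_dx
    dN = np.diff(N) * inv_dx
    aE = 0.5 * (E[1:] + E[:-1]) / K
    aP = 0.5 * (P[1:] + P[:-1]) / K
    aN = 0.5 * (N[1:] + N[:-1]) / K
    # A = -J: the quantity inside the divergence of the governing equations.
    # grouped sums keep the update bitwise symmetric under the E<->P swap
    A_E = params.D_E * ((1.0 - (aP + aN)) * dE + aE * (dP + dN))
    A_P = params.D_P * ((1.0 - (aE + aN)) * dP + aP * (dE + dN))
    A_N = params.D_N * ((1.0 - (aE + aP)) * dN + aN * (dE + dP))

    room = 1.0 - (E + P + N) / K
    f_E = params.rho_E * E * (1.0 + params.alpha_PE * P / K) * room
    f_P = params.rho_P * P * (1.0 + params.alpha_EP * E / K) * room
    f_N = params.rho_N * N * room

    for fld, A, f in ((E, A_E, f_E), (P, A_P, f_P), (N, A_N, f_N)):
        fld[1:-1] += dt * ((A[1:] - A[:-1]) * inv_dx + f[1:-1])
        fld[0] += dt * (A[0] * inv_dx + f[0])
        fld[-1] += dt * (-A[-1] * inv_dx + f[-1])
    np.maximum(E, 0.0, out=E)
    np.maximum(P, 0.0, out=P)
    np.maximum(N, 0.0, out=N)


def step(state: TumourState, params: ModelParams, mesh: Mesh, dt: float) -> TumourState:
    """One forward-Euler step; returns a new state with the clock advanced."""
    r = 2.0 * params.max_diffusion * dt / mesh.dx**2
    if r > 1.0:
        raise StabilityError(f"2*D*dt/dx^2 = {r:.3f} > 1")
    new = state.copy()
    _euler_update(new.E, new.P, new.N, params, mesh.dx, dt)
    if not (np.isfinite(new.E).all() and np.isfinite(new.P).all()
            and np.isfinite(new.N).all()):
        raise BlowUpError(f"non-finite field values at t={state.t + dt:.4f}")
    new.t = state.t + dt
    return new


def introduce_population(
    state: TumourState, which: str, centre: float, mesh: Mesh
) -> TumourState:
    """Seed an amplified population as a Gaussian bump at the current time.

    Adds the standard 100 cells/mm^2 profile to the chosen field in place,
    sets the introduced flag, and leaves the other two fields untouched.
    Raises on double introduction.
    """
    if which == "E":
        if state.introduced_E:
            raise SimulationError("E population already introduced")
        state.E += initial_profile(mesh.x, centre)
        state.introduced_E = True
    elif which == "P":
        if state.introduced_P:
            raise SimulationError("P population already introduced")
        state.P += initial_profile(mesh.x, centre)
        state.introduced_P = True
    else:
        raise ValueError("which must be 'E' or 'P'")
    return state


def initial_state(params: ModelParams, mesh: Mesh) -> TumourState:
    """The pre-mutation state: a single Gaussian bump of N cells, E = P = 0."""
    params.validate_centres(mesh.L)
    n = mesh.n_nodes
    return TumourState(
        E=np.zeros(n), P=np.zeros(n),
        N=initial_profile(mesh.x, params.x_star_N),
    )


def _width(T: np.ndarray, mesh: Mesh, threshold: float) -> float:
    return float(np.count_nonzero(T > threshold)) * mesh.dx


def run(params: ModelParams, mesh: Mesh, config: SolverConfig) -> SimulationTrace:
    """Advance from the initial condition until diagnosis size or max_time.

    After each Euler step the solver (a) fires the introduction events --
    size-triggered at the first step where the trapezoidal line density of N
    meets N_E / N_P, or time-triggered when the clock passes t_star_E /
    t_star_P -- and (b) checks the stopping rule: width of T = E + P + N
    above ``detection_density_fraction * K`` at least ``target_width``.
    """
    config.check_stability(params, mesh)
    state = initial_state(params, mesh)
    E, P, N = state.E, state.P, state.N
    dx, dt, K = mesh.dx, config.dt, params.K
    x = mesh.x

    threshold = config.detection_density_fraction * K
    max_steps = int(math.ceil(config.max_time / dt))
    t_star_E: Optional[float] = None
    t_star_P: Optional[float] = None
    widths: List[Tuple[float, float]] = []
    t = 0.0
    stop_reason = "max_time"

    want_E = params.N_E is not None or params.t_star_E is not None
    want_P = params.N_P is not None or params.t_star_P is not None

    for istep in range(1, max_steps + 1):
        _euler_update(E, P, N, params, dx, dt)
        t = istep * dt

        if want_E and not state.introduced_E:
            fire = (
                total_population(N, mesh) >= params.N_E
                if params.N_E is not None
                else t >= params.t_star_E - 1e-12
            )
            if fire:
                E += initial_profile(x, params.x_star_E)
                state.introduced_E = True
                t_star_E = t
        if want_P and not state.introduced_P:
            fire = (
                total_population(N, mesh) >= params.N_P
                if params.N_P is not None
                else t >= params.t_star_P - 1e-12
            )
            if fire:
                P += initial_profile(x, params.x_star_P)
                state.introduced_P = True
                t_star_P = t

        T = E + P + N
        Tmax = T.max()
        if not np.isfinite(Tmax):
            raise BlowUpError(f"non-finite field values at t={t:.4f} years")

        if config.target_width is not None or istep % config.width_sample_interval == 0:
            w = _width(T, mesh, threshold)
            if istep % config.width_sample_interval == 0:
                widths.append((t, w))
            if config.target_width is not None and w >= config.target_width:
                if istep % config.width_sample_interval != 0:
                    widths.append((t, w))
                stop_reason = "target_width"
                break

    state.t = t
    if stop_reason == "max_time" and (not widths or widths[-1][0] < t):
        widths.append((t, _width(E + P + N, mesh, threshold)))
    return SimulationTrace(
        final_state=state,
        t_star_E=t_star_E,
        t_star_P=t_star_P,
        stop_time=t,
        stop_reason=stop_reason,
        widths=widths,
    )
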