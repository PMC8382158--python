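"""Three-species volume-filling model of glioblastoma sub-population dynamics.

The tumour is described by three cell concentrations on a 1D transect
(cells/mm^3): ``E`` (EGFR-amplified), ``P`` (PDGFRA-amplified) and ``N``
(non-amplified).  Each species migrates by volume-filling diffusion -- net
motility is damped by total local crowding relative to the carrying capacity
``K`` -- and proliferates logistically in the shared space, with the net
proliferation of each amplified species modified by the density of the other
through the dimensionless interaction coefficients ``alpha_EP`` (effect of E
on P) and ``alpha_PE`` (effect of P on E).  The sign pair of the two
coefficients defines the ecological interaction type (competition,
cooperation, parasitism, ...).

This module holds the parameter set, the state container, and the pointwise
reaction and interface-flux laws; time stepping lives in
:mod:`gbmpop.solver`.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "CELL_RADIUS_UM",
    "K_DEFAULT",
    "INITIAL_MASS",
    "ModelParams",
    "TumourState",
    "InteractionType",
    "carrying_capacity",
    "classify_interaction",
    "reaction_terms",
    "diffusive_flux",
    "initial_profile",
]

#: Default tumour cell radius, micrometres.
CELL_RADIUS_UM = 10.0


def carrying_capacity(cell_radius_um: float = CELL_RADIUS_UM) -> float:
    """Maximum packing density (cells/mm^3) for spherical cells of given radius.

    One cell occupies (4/3)*pi*r^3; the capacity is the reciprocal volume
    converted from um^3 to mm^3 (1 mm^3 = 1e9 um^3).  A 10 um radius gives
    a cell volume of ~4.189e3 um^3 and K ~ 2.39e5 cells/mm^3.
    """
    if cell_radius_um <= 0:
        raise ValueError("cell radius must be positive")
    volume_um3 = (4.0 / 3.0) * math.pi * cell_radius_um**3
    return 1e9 / volume_um3


#: Carrying capacity for 10 um cells, cells/mm^3.
K_DEFAULT = carrying_capacity()

#: Line-integral mass of every introduced Gaussian bump, cells/mm^2.
INITIAL_MASS = 100.0


class InteractionType(enum.Enum):
    """Ecological interaction implied by the signs of (alpha_EP, alpha_PE)."""

    NEUTRALISM = "Neutralism"
    AMENSALISM_E_ON_P = "Amensalism: E negatively affects P"
    AMENSALISM_P_ON_E = "Amensalism: P negatively affects E"
    COMPETITION = "Competition"
    COMMENSALISM_E_ON_P = "Commensalism: E positively affects P"
    COMMENSALISM_P_ON_E = "Commensalism: P positively affects E"
    COOPERATION = "Cooperation"
    PARASITISM_P_ON_E = "Parasitism: of P on E"
    PARASITISM_E_ON_P = "Parasitism: of E on P"

    @property
    def label(self) -> str:
        return self.value


def classify_interaction(alpha_EP: float, alpha_PE: float) -> InteractionType:
    """Map the sign pair of the interaction coefficients to its taxonomy label.

    ``alpha_EP`` is the effect of the E population on P's proliferation and
    ``alpha_PE`` the converse.  Zero means exactly zero (neutral in that
    direction).
    """
    if not (math.isfinite(alpha_EP) and math.isfinite(alpha_PE)):
        raise ValueError("interaction coefficients must be finite")
    se, sp = np.sign(alpha_EP), np.sign(alpha_PE)
    table = {
        (0, 0): InteractionType.NEUTRALISM,
        (-1, 0): InteractionType.AMENSALISM_E_ON_P,
        (0, -1): InteractionType.AMENSALISM_P_ON_E,
        (-1, -1): InteractionType.COMPETITION,
        (1, 0): InteractionType.COMMENSALISM_E_ON_P,
        (0, 1): InteractionType.COMMENSALISM_P_ON_E,
        (1, 1): InteractionType.COOPERATION,
        (1, -1): InteractionType.PARASITISM_P_ON_E,
        (-1, 1): InteractionType.PARASITISM_E_ON_P,
    }
    return table[(int(se), int(sp))]


@dataclass(frozen=True)
class ModelParams:
    """All rate, interaction, capacity and introduction parameters.

    Units: diffusion coefficients mm^2/year; proliferation rates 1/year;
    ``K`` cells/mm^3; introduction centres mm; size triggers ``N_E``/``N_P``
    cells/mm^2 (line density of the N population at which the corresponding
    amplified population is seeded); time triggers ``t_star_E``/``t_star_P``
    years.  For each amplified population at most one trigger mode may be
    set; with neither set that population is never introduced.
    """

    D_E: float = 30.0
    D_P: float = 30.0
    D_N: float = 30.0
    rho_E: float = 30.0
    rho_P: float = 30.0
    rho_N: float = 30.0
    alpha_EP: float = 0.0
    alpha_PE: float = 0.0
    K: float = K_DEFAULT
    x_star_N: float = 100.0
    x_star_E: float = 100.0
    x_star_P: float = 100.0
    N_E: Optional[float] = None
    N_P: Optional[float] = None
    t_star_E: Optional[float] = None
    t_star_P: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("D_E", "D_P", "D_N", "rho_E", "rho_P", "rho_N", "K"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.N_E is not None and self.t_star_E is not None:
            raise ValueError("E population: set N_E or t_star_E, not both")
        if self.N_P is not None and self.t_star_P is not None:
            raise ValueError("P population: set N_P or t_star_P, not both")
        for name in ("N_E", "N_P"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive when set")

    @property
    def max_diffusion(self) -> float:
        return max(self.D_E, self.D_P, self.D_N)

    def validate_centres(self, L: float) -> None:
        """Check every introduction centre lies inside the domain [0, L]."""
        for name in ("x_star_N", "x_star_E", "x_star_P"):
            c = getattr(self, name)
            if not 0.0 <= c <= L:
                raise ValueError(f"{name}={c} outside domain [0, {L}]")

    def swapped(self) -> "ModelParams":
        """Parameter set with the roles of E and P exchanged."""
        return replace(
            self,
            D_E=self.D_P, D_P=self.D_E,
            rho_E=self.rho_P, rho_P=self.rho_E,
            alpha_EP=self.alpha_PE, alpha_PE=self.alpha_EP,
            x_star_E=self.x_star_P, x_star_P=self.x_star_E,
            N_E=self.N_P, N_P=self.N_E,
            t_star_E=self.t_star_P, t_star_P=self.t_star_E,
        )


@dataclass
class TumourState:
    """Concentration fields on the mesh plus the simulation clock.

    ``E``, ``P``, ``N`` are cells/mm^3 sampled at the mesh nodes; ``t`` is in
    years.  The ``introduced_*`` flags record whether the corresponding
    mutation event has fired; they are monotone in time (never reset).
    """

    E: np.ndarray
    P: np.ndarray
    N: np.ndarray
    t: float = 0.0
    introduced_E: bool = False
    introduced_P: bool = False

    def __post_init__(self) -> None:
        self.E = np.asarray(self.E, dtype=float)
        self.P = np.asarray(self.P, dtype=float)
        self.N = np.asarray(self.N, dtype=float)
        n = self.E.shape
        if self.P.shape != n or self.N.shape != n:
            raise ValueError("E, P, N must share a common mesh")
        if (self.E < 0).any() or (self.P < 0).any() or (self.N < 0).any():
            raise ValueError("concentration fields must be non-negative")

    @property
    def total(self) -> np.ndarray:
        """Total tumour cell density T = E + P + N."""
        return self.E + self.P + self.N

    def copy(self) -> "TumourState":
        return TumourState(
            self.E.copy(), self.P.copy(), self.N.copy(),
            self.t, self.introduced_E, self.introduced_P,
        )


def reaction_terms(E, P, N, params: ModelParams):
    """Pointwise net proliferation of the three species (cells/mm^3/year).

    f_E = rho_E*E*(1 + alpha_PE*P/K)*(1 - T/K), analogously for P with
    alpha_EP*E, and plain logistic for N; T = E + P + N.  The modified rate
    factor may be negative (net death) for strongly negative alpha.  Mutation
    source terms are discrete events handled by the solver, not here.
    """
    K = params.K
    E, P, N = np.asarray(E, float), np.asarray(P, float), np.asarray(N, float)
    room = 1.0 - (E + P + N) / K
    f_E = params.rho_E * E * (1.0 + params.alpha_PE * P / K) * room
    f_P = params.rho_P * P * (1.0 + params.alpha_EP * E / K) * room
    f_N = params.rho_N * N * room
    return f_E, f_P, f_N


def diffusive_flux(E, P, N, params: ModelParams, dx: float):
    """Volume-filling diffusive fluxes at the n-1 interior cell interfaces.

    For species E the flux is

        J_E = -D_E * [ (1 - (P+N)/K) dE/dx + (E/K) (dP/dx + dN/dx) ]

    and analogously with the species permuted for J_P and J_N.  Gradients are
    central differences across each interface and coefficient fields are
    arithmetically averaged onto it, which preserves the algebraic identity
    that with equal diffusivities the three fluxes sum to the plain Fickian
    flux of T = E + P + N.  Positive flux points toward increasing x; the
    divergence update of node i is -(J_{i+1/2} - J_{i-1/2})/dx.
    """
    E, P, N = np.asarray(E, float), np.asarray(P, float), np.asarray(N, float)
    if E.size < 2:
        raise ValueError("mesh must have at least 2 nodes")
    if dx <= 0:
        raise ValueError("dx must be positive")
    K = params.K
    dE = np.diff(E) / dx
    dP = np.diff(P) / dx
    dN = np.diff(N) / dx
    aE = 0.5 * (E[1:] + E[:-1])
    aP = 0.5 * (P[1:] + P[:-1])
    aN = 0.5 * (N[1:] + N[:-1])
    J_E = -params.D_E * ((1.0 - (aP + aN) / K) * dE + (aE / K) * (dP + dN))
    J_P = -params.D_P * ((1.0 - (aE + aN) / K) * dP + (aP / K) * (dE + dN))
    J_N = -params.D_N * ((1.0 - (aE + aP) / K) * dN + (aN / K) * (dE + dP))
    return J_E, J_P, J_N


def initial_profile(x: np.ndarray, centre: float) -> np.ndarray:
    """Gaussian seed profile (cells/mm^3) with unit-variance-like width.

    Returns A*exp(-(x-centre)^2) with A = 100/sqrt(pi), the unique amplitude
    whose continuum line integral is exactly 100 cells/mm^2.  The same
    profile seeds the initial N population and both mutation events, so the
    initial line density N_I = 100 and triggers expressed as multiples of
    N_I are well defined.
    """
    x = np.asarray(x, dtype=float)
    if not (x[0] <= centre <= x[-1]):
        raise ValueError(f"centre {centre} outside domain [{x[0]}, {x[-1]}]")
    amplitude = INITIAL_MASS / math.sqrt(math.pi)
    return amplitude * np.exp(-((x - centre) ** 2))
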