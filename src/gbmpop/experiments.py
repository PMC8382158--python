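"""Scenario studies: cohort averaging and the interaction/advantage/timing/
location sweeps.

A patient cohort is emulated by running each scenario with four baseline
(rho, D) pairs -- {3, 30}/year x {3, 30} mm^2/year -- spanning low and high
proliferative and invasive potential, and averaging the resulting
amplification proportions with equal weight.  Scenarios differ from the
symmetric baseline (identical amplified and non-amplified dynamics, both
mutations at the tumour centre when the founding population has grown
6-fold) through selection-advantage multipliers, introduction-trigger sizes
and introduction-location offsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .metrics import CATEGORIES, AmplificationProportions, amplified_proportions
from .model import ModelParams, initial_profile
from .solver import Mesh, SimulationTrace, SolverConfig, run, total_population

__all__ = [
    "DEFAULT_COHORT",
    "ADVANTAGE_CONFIGS",
    "CohortSpec",
    "Scenario",
    "reference_mass",
    "build_params",
    "mean_proportions",
    "interaction_sweep",
    "advantage_sweep",
    "timing_sweep",
    "location_sweep",
]

#: The four (rho [1/year], D [mm^2/year]) pairs used for cohort averaging.
DEFAULT_COHORT: Tuple[Tuple[float, float], ...] = (
    (3.0, 3.0), (3.0, 30.0), (30.0, 3.0), (30.0, 30.0),
)

#: Selection-advantage menu: multipliers (v_rho_E, v_rho_P, v_D_E, v_D_P).
#: (a) EGFR 50% invasive advantage; (b) EGFR 50% proliferative + invasive;
#: (c) as (b) plus PDGFRA 50% invasive; (d) as (b) plus PDGFRA 50%
#: proliferative.
ADVANTAGE_CONFIGS: Dict[str, Tuple[float, float, float, float]] = {
    "a": (1.0, 1.0, 1.5, 1.0),
    "b": (1.5, 1.0, 1.5, 1.0),
    "c": (1.5, 1.0, 1.5, 1.5),
    "d": (1.5, 1.5, 1.5, 1.0),
}


@dataclass(frozen=True)
class CohortSpec:
    """Non-empty list of positive (rho, D) pairs to average over."""

    pairs: Tuple[Tuple[float, float], ...] = DEFAULT_COHORT

    def __post_init__(self) -> None:
        if len(self.pairs) == 0:
            raise ValueError("cohort must contain at least one (rho, D) pair")
        for rho, D in self.pairs:
            if rho <= 0 or D <= 0:
                raise ValueError("cohort rho and D must be positive")


@dataclass(frozen=True)
class Scenario:
    """One cell of a scenario study, relative to the symmetric baseline.

    ``alpha_EP``/``alpha_PE`` are the interaction coefficients (the studies
    use a symmetric alpha in {-5, 0, 5}); the ``v_*`` multipliers (>= 1 in
    the advantage sweeps) scale the amplified populations' rates relative to
    the non-amplified ones; ``trigger_multiple_*`` give the introduction
    trigger as a multiple of the initial line density N_I (>= 3 in the
    sweeps); ``offset_*`` displace the introduction centres from the tumour
    centre x_c (mm).
    """

    alpha_EP: float = 0.0
    alpha_PE: float = 0.0
    v_rho_E: float = 1.0
    v_rho_P: float = 1.0
    v_D_E: float = 1.0
    v_D_P: float = 1.0
    trigger_multiple_E: float = 6.0
    trigger_multiple_P: float = 6.0
    offset_E: float = 0.0
    offset_P: float = 0.0

    @classmethod
    def symmetric(cls, alpha: float, **kw) -> "Scenario":
        return cls(alpha_EP=alpha, alpha_PE=alpha, **kw)


def reference_mass(mesh: Mesh, centre: float | None = None) -> float:
    """N_I: trapezoidal line density of the standard seed profile on the mesh.

    Using the solver's own quadrature (rather than the continuum value 100)
    makes 'the tumour has grown to k times its initial size' exact under the
    discrete trigger rule.
    """
    centre = mesh.L / 2.0 if centre is None else centre
    return total_population(initial_profile(mesh.x, centre), mesh)


def tumour_centre(mesh: Mesh) -> float:
    """x_c: the mesh node nearest the domain midpoint."""
    x = mesh.x
    return float(x[np.argmin(np.abs(x - mesh.L / 2.0))])


def build_params(scenario: Scenario, rho: float, D: float, mesh: Mesh) -> ModelParams:
    """Materialize a full parameter set for one (rho, D) cohort member."""
    x_c = tumour_centre(mesh)
    N_I = reference_mass(mesh, x_c)
    return ModelParams(
        D_E=scenario.v_D_E * D,
        D_P=scenario.v_D_P * D,
        D_N=D,
        rho_E=scenario.v_rho_E * rho,
        rho_P=scenario.v_rho_P * rho,
        rho_N=rho,
        alpha_EP=scenario.alpha_EP,
        alpha_PE=scenario.alpha_PE,
        x_star_N=x_c,
        x_star_E=x_c + scenario.offset_E,
        x_star_P=x_c + scenario.offset_P,
        N_E=scenario.trigger_multiple_E * N_I,
        N_P=scenario.trigger_multiple_P * N_I,
    )


def _run_member(scenario, rho, D, mesh, config) -> SimulationTrace:
    trace = run(build_params(scenario, rho, D, mesh), mesh, config)
    if config.target_width is not None and not trace.reached_target:
        raise RuntimeError(
            f"cohort member (rho={rho}, D={D}) failed to reach the target "
            f"width within max_time={config.max_time} years"
        )
    return trace


def mean_proportions(
    scenario: Scenario,
    cohort: CohortSpec | None = None,
    mesh: Mesh | None = None,
    config: SolverConfig | None = None,
) -> AmplificationProportions:
    """Cohort-mean amplification proportions for one scenario.

    Runs one simulation per (rho, D) pair to the diagnosis-size stopping
    rule, scores each final state and returns the unweighted arithmetic mean
    of the four proportions.  Raises if any member fails to reach the
    target width.
    """
    cohort = cohort or CohortSpec()
    mesh = mesh or Mesh()
    config = config or SolverConfig()
    rows = []
    for rho, D in cohort.pairs:
        trace = _run_member(scenario, rho, D, mesh, config)
        rows.append(amplified_proportions(trace.final_state, mesh).as_array())
    m = np.mean(rows, axis=0)
    return AmplificationProportions(*m)


def _table(cells: Iterable[Tuple[dict, AmplificationProportions]]) -> pd.DataFrame:
    records = []
    for meta, props in cells:
        rec = dict(meta)
        rec.update(props.as_dict())
        records.append(rec)
    return pd.DataFrame.from_records(records)


def interaction_sweep(
    cohort: CohortSpec | None = None,
    alphas: Sequence[float] = (-5.0, 0.0, 5.0),
    base: Scenario | None = None,
    mesh: Mesh | None = None,
    config: SolverConfig | None = None,
) -> pd.DataFrame:
    """Baseline symmetric-interaction study over alpha in {-5, 0, 5}.

    Competition (-5), neutralism (0) and cooperation (+5) with otherwise
    identical sub-population dynamics; one row of cohort-mean proportions
    per alpha.
    """
    base = base or Scenario()
    cells = []
    for a in alphas:
        sc = replace(base, alpha_EP=a, alpha_PE=a)
        cells.append(({"alpha": a}, mean_proportions(sc, cohort, mesh, config)))
    return _table(cells)


def advantage_sweep(
    cohort: CohortSpec | None = None,
    configs: Sequence[str] = ("a", "b", "c", "d"),
    alphas: Sequence[float] = (-5.0, 0.0, 5.0),
    mesh: Mesh | None = None,
    config: SolverConfig | None = None,
) -> pd.DataFrame:
    """Selection-advantage study: one row per (advantage config, alpha)."""
    cells = []
    for name in configs:
        v_rho_E, v_rho_P, v_D_E, v_D_P = ADVANTAGE_CONFIGS[name]
        for a in alphas:
            sc = Scenario(
                alpha_EP=a, alpha_PE=a,
                v_rho_E=v_rho_E, v_rho_P=v_rho_P, v_D_E=v_D_E, v_D_P=v_D_P,
            )
            cells.append((
                {"config": name, "alpha": a},
                mean_proportions(sc, cohort, mesh, config),
            ))
    return _table(cells)


def timing_sweep(
    cohort: CohortSpec | None = None,
    alphas: Sequence[float] = (-5.0, 0.0, 5.0),
    i_values: Sequence[int] = range(1, 8),
    fixed_P_index: int = 4,
    mesh: Mesh | None = None,
    config: SolverConfig | None = None,
) -> pd.DataFrame:
    """Phylogenetic-ordering study.

    The P population is introduced at the fixed trigger t*_4 (tumour grown
    to 6 N_I) while E's introduction runs over the seven triggers t*_i,
    fired when the founding population reaches (i+2) N_I, i = 1..7.  The
    i = 4 rows coincide with the corresponding interaction_sweep rows (same
    computation, hence bitwise identical under identical numerics).
    """
    cells = []
    for a in alphas:
        for i in i_values:
            sc = Scenario.symmetric(
                a,
                trigger_multiple_E=float(i + 2),
                trigger_multiple_P=float(fixed_P_index + 2),
            )
            cells.append((
                {"alpha": a, "i": i, "trigger_multiple_E": float(i + 2)},
                mean_proportions(sc, cohort, mesh, config),
            ))
    return _table(cells)


def location_sweep(
    cohort: CohortSpec | None = None,
    alphas: Sequence[float] = (-5.0, 0.0, 5.0),
    offsets: Sequence[Tuple[float, float]] = ((-0.5, 0.5), (-1.0, 1.0)),
    mesh: Mesh | None = None,
    config: SolverConfig | None = None,
) -> pd.DataFrame:
    """Mutation-location study: (offset_E, offset_P) displacements in mm.

    Offsets are limited to +/- 1.5 mm of the tumour centre -- at
    introduction the bulk of the founding tumour spans only ~3 mm, so
    mutations are unlikely to establish further out.
    """
    for oE, oP in offsets:
        if abs(oE) > 1.5 or abs(oP) > 1.5:
            raise ValueError("offsets must lie within +/-1.5 mm of the centre")
    cells = []
    for a in alphas:
        for oE, oP in offsets:
            sc = Scenario.symmetric(a, offset_E=oE, offset_P=oP)
            cells.append((
                {"alpha": a, "offset_E": oE, "offset_P": oP},
                mean_proportions(sc, cohort, mesh, config),
            ))
    return _table(cells)
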