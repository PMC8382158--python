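"""Latin hypercube sampling and partial rank correlation (LHS-PRCC).

Global sensitivity of the four amplification-pattern outputs to the 12
model parameters: the selection-advantage multipliers v_rho_E, v_rho_P,
v_D_E, v_D_P in [1, 1.5]; the introduction triggers N_E, N_P in [3, 9]
multiples of the initial mass N_I; the introduction locations x*_E, x*_P
within +/-1.5 mm of the tumour centre; the founding population's rates
rho_N in [3, 30]/year and D_N in [3, 30] mm^2/year; and the interaction
coefficients alpha_PE, alpha_EP in [-5, 5].  Each parameter carries an
independent uniform density, sampled by stratified (Latin hypercube)
draws; inputs and outputs are rank-transformed and partial correlations
computed conditioning on all other parameters, with two-sided t-test
significance at the 0.05 / 0.01 / 0.001 tiers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .experiments import reference_mass, tumour_centre
from .metrics import CATEGORIES, amplified_proportions
from .model import ModelParams
from .solver import Mesh, SimulationError, SolverConfig, run

__all__ = [
    "ParameterDistribution",
    "LHSDesign",
    "PRCCResult",
    "SensitivityResult",
    "default_distributions",
    "lhs_sample",
    "materialize_params",
    "prcc",
    "run_sensitivity",
    "split_nonmonotone",
]

logger = logging.getLogger(__name__)

PARAM_NAMES = (
    "v_rho_E", "v_rho_P", "v_D_E", "v_D_P",
    "N_E", "N_P", "x_star_E", "x_star_P",
    "rho_N", "D_N", "alpha_PE", "alpha_EP",
)


@dataclass(frozen=True)
class ParameterDistribution:
    """Independent uniform density on [lower, upper] for one parameter."""

    name: str
    lower: float
    upper: float
    units: str = ""

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"{self.name}: lower must be < upper")


def default_distributions(mesh: Mesh | None = None) -> List[ParameterDistribution]:
    """The 12-parameter box of the sensitivity study (uniform densities)."""
    mesh = mesh or Mesh()
    x_c = tumour_centre(mesh)
    N_I = reference_mass(mesh, x_c)
    return [
        ParameterDistribution("v_rho_E", 1.0, 1.5, "unitless"),
        ParameterDistribution("v_rho_P", 1.0, 1.5, "unitless"),
        ParameterDistribution("v_D_E", 1.0, 1.5, "unitless"),
        ParameterDistribution("v_D_P", 1.0, 1.5, "unitless"),
        ParameterDistribution("N_E", 3.0 * N_I, 9.0 * N_I, "cells/mm^2"),
        ParameterDistribution("N_P", 3.0 * N_I, 9.0 * N_I, "cells/mm^2"),
        ParameterDistribution("x_star_E", x_c - 1.5, x_c + 1.5, "mm"),
        ParameterDistribution("x_star_P", x_c - 1.5, x_c + 1.5, "mm"),
        ParameterDistribution("rho_N", 3.0, 30.0, "1/year"),
        ParameterDistribution("D_N", 3.0, 30.0, "mm^2/year"),
        ParameterDistribution("alpha_PE", -5.0, 5.0, "unitless"),
        ParameterDistribution("alpha_EP", -5.0, 5.0, "unitless"),
    ]


@dataclass
class LHSDesign:
    """A Latin hypercube sample: per column exactly one draw per stratum."""

    samples: pd.DataFrame
    seed: int
    distributions: Tuple[ParameterDistribution, ...]

    @property
    def n(self) -> int:
        return len(self.samples)


def lhs_sample(
    distributions: Sequence[ParameterDistribution], n: int, seed: int
) -> LHSDesign:
    """Stratified uniform draws, independently permuted across columns.

    Each parameter's range is divided into n intervals of equal probability;
    one draw is taken uniformly within each interval and the n draws are
    randomly grouped across parameters by independent seeded permutations.
    """
    if n < 2:
        raise ValueError("n must be at least 2")
    rng = np.random.default_rng(seed)
    cols = {}
    for dist in distributions:
        u = (np.arange(n) + rng.random(n)) / n
        u = rng.permutation(u)
        cols[dist.name] = dist.lower + u * (dist.upper - dist.lower)
    return LHSDesign(
        samples=pd.DataFrame(cols),
        seed=seed,
        distributions=tuple(distributions),
    )


def materialize_params(row, mesh: Mesh | None = None) -> ModelParams:
    """Build the full model parameter set from one design row.

    rho_E = v_rho_E * rho_N, D_E = v_D_E * D_N (and likewise for P);
    triggers and centres are taken directly; everything else at module
    defaults.  ``row`` is any mapping with the 12 parameter names.
    """
    mesh = mesh or Mesh()
    return ModelParams(
        D_E=row["v_D_E"] * row["D_N"],
        D_P=row["v_D_P"] * row["D_N"],
        D_N=row["D_N"],
        rho_E=row["v_rho_E"] * row["rho_N"],
        rho_P=row["v_rho_P"] * row["rho_N"],
        rho_N=row["rho_N"],
        alpha_EP=row["alpha_EP"],
        alpha_PE=row["alpha_PE"],
        x_star_N=tumour_centre(mesh),
        x_star_E=row["x_star_E"],
        x_star_P=row["x_star_P"],
        N_E=row["N_E"],
        N_P=row["N_P"],
    )


@dataclass
class PRCCResult:
    """PRCC values with two-sided t-test p-values and significance tiers.

    ``prcc`` and ``p_value`` are parameter x output DataFrames; ``tier``
    holds 0 (not significant at 0.05), 1 (<0.05), 2 (<0.01), 3 (<0.001).
    """

    prcc: pd.DataFrame
    p_value: pd.DataFrame
    n: int

    @property
    def tier(self) -> pd.DataFrame:
        p = self.p_value
        return ((p < 0.05).astype(int) + (p < 0.01).astype(int)
                + (p < 0.001).astype(int))

    def stars(self) -> pd.DataFrame:
        return self.tier.map(lambda t: "*" * int(t))

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-form table: parameter, output, prcc, p_value, tier."""
        rows = []
        for out in self.prcc.columns:
            for par in self.prcc.index:
                rows.append({
                    "parameter": par, "output": out,
                    "prcc": self.prcc.loc[par, out],
                    "p_value": self.p_value.loc[par, out],
                    "tier": int(self.tier.loc[par, out]),
                })
        return pd.DataFrame(rows)


def _residualize(ranks: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Residuals of target regressed (with intercept) on the rank columns."""
    Z = np.column_stack([np.ones(len(target)), ranks])
    beta, *_ = np.linalg.lstsq(Z, target, rcond=None)
    return target - Z @ beta


def prcc(design_inputs: pd.DataFrame, outputs) -> PRCCResult:
    """Partial rank correlation of each input with each output.

    All columns are rank-transformed (average ranks on ties); for each
    parameter the partial correlation with an output is the Pearson
    correlation of the residuals of both rank vectors after regressing out
    the ranks of all other parameters.  Significance from the t statistic
    r*sqrt(df/(1-r^2)) with df = n - 2 - p, where p is the number of
    conditioned parameters; two-sided.
    """
    X = pd.DataFrame(design_inputs)
    if isinstance(outputs, pd.Series):
        Y = outputs.to_frame()
    else:
        Y = pd.DataFrame(outputs)
    n, k = X.shape
    if n < k + 3:
        raise ValueError(f"need at least {k + 3} rows for {k} parameters")
    for df_ in (X, Y):
        for col in df_.columns:
            if df_[col].nunique() < 2:
                raise ValueError(f"degenerate (constant) column: {col!r}")
    RX = np.column_stack(
        [stats.rankdata(X[c].to_numpy()) for c in X.columns]
    )
    dof = n - 2 - (k - 1)
    if dof < 1:
        raise ValueError("not enough rows for the degrees of freedom")
    vals = pd.DataFrame(index=X.columns, columns=Y.columns, dtype=float)
    pvals = pd.DataFrame(index=X.columns, columns=Y.columns, dtype=float)
    for out in Y.columns:
        ry = stats.rankdata(Y[out].to_numpy())
        for j, par in enumerate(X.columns):
            others = np.delete(np.arange(k), j, axis=0)
            cond = RX[:, others]
            rx_res = _residualize(cond, RX[:, j])
            ry_res = _residualize(cond, ry)
            denom = np.linalg.norm(rx_res) * np.linalg.norm(ry_res)
            r = float(rx_res @ ry_res / denom) if denom > 0 else 0.0
            r = max(-1.0, min(1.0, r))
            t = r * np.sqrt(dof / max(1.0 - r * r, 1e-300))
            vals.loc[par, out] = r
            pvals.loc[par, out] = 2.0 * stats.t.sf(abs(t), dof)
    return PRCCResult(prcc=vals, p_value=pvals, n=n)


@dataclass
class SensitivityResult:
    """Design, per-row outputs and the PRCC table of one LHS-PRCC study."""

    design: LHSDesign
    outputs: pd.DataFrame  # one row per successful simulation
    prcc: PRCCResult
    n_failed: int
    failed_rows: List[int] = field(default_factory=list)


def run_sensitivity(
    n: int = 2000,
    seed: int = 0,
    mesh: Mesh | None = None,
    config: SolverConfig | None = None,
    distributions: Sequence[ParameterDistribution] | None = None,
) -> SensitivityResult:
    """Full LHS-PRCC study: one simulation per design row.

    Each row materializes a parameter set (rho_N and D_N are sampled per
    row, not cohort-averaged), is simulated to the diagnosis-size stopping
    rule, and scored by the four amplification proportions.  Rows whose
    simulation blows up or fails to reach the target width are dropped
    listwise with a logged count.
    """
    mesh = mesh or Mesh()
    config = config or SolverConfig()
    distributions = distributions or default_distributions(mesh)
    design = lhs_sample(distributions, n, seed)
    rows, ok_index, failed = [], [], []
    for i, row in design.samples.iterrows():
        try:
            trace = run(materialize_params(row, mesh), mesh, config)
            if config.target_width is not None and not trace.reached_target:
                raise SimulationError("did not reach target width")
            props = amplified_proportions(trace.final_state, mesh)
        except (SimulationError, ValueError) as exc:
            failed.append(int(i))
            logger.warning("design row %d excluded: %s", i, exc)
            continue
        rows.append(props.as_dict())
        ok_index.append(int(i))
    if failed:
        logger.warning("%d of %d simulations excluded", len(failed), n)
    outputs = pd.DataFrame(rows, index=ok_index)
    result = prcc(design.samples.loc[ok_index], outputs)
    return SensitivityResult(
        design=design, outputs=outputs, prcc=result,
        n_failed=len(failed), failed_rows=failed,
    )


def split_nonmonotone(
    design_inputs: pd.DataFrame,
    outputs: pd.DataFrame,
    parameter: str,
    split_point: float,
) -> Dict[str, PRCCResult]:
    """Recompute PRCCs on the two sides of a split of one parameter's range.

    Removes a non-monotone (e.g. V-shaped) dependence on ``parameter`` --
    such as distance-to-centre effects of the introduction locations -- by
    partitioning rows at ``split_point`` and running the full PRCC analysis
    within each half; all other parameters' results are reported alongside
    for consistency checking.  Raises if a half is too small for the
    degrees of freedom.
    """
    X = pd.DataFrame(design_inputs)
    if parameter not in X.columns:
        raise KeyError(parameter)
    lo, hi = X[parameter].min(), X[parameter].max()
    if not lo < split_point < hi:
        raise ValueError("split point must lie inside the parameter's range")
    mask = X[parameter] <= split_point
    out = {}
    for label, m in (("low", mask), ("high", ~mask)):
        out[label] = prcc(X.loc[m], pd.DataFrame(outputs).loc[m])
    return out
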