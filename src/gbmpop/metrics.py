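"""Biopsy-style scoring of a simulated tumour.

Two node-counting statistics connect simulations to what imaging and tissue
analysis can see.  ``tumour_width`` measures the extent of the region where
the total density exceeds a fraction of carrying capacity (0.8K is the proxy
for the enhancing volume on a T1Gd MRI).  ``amplified_proportions`` splits
the detectable tumour (T > 0.1K, mirroring a 10%-of-tissue detection limit
for copy-number signal) into the four amplification categories: neither,
only EGFR, only PDGFRA, both.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import TumourState
from .solver import Mesh

__all__ = ["AmplificationProportions", "tumour_width", "amplified_proportions"]

CATEGORIES = ("neither", "egfr_only", "pdgfra_only", "both")


@dataclass(frozen=True)
class AmplificationProportions:
    """Four-way partition of a detectable tumour (or biopsy set).

    ``neither`` (A_N), ``egfr_only`` (A_E), ``pdgfra_only`` (A_P) and
    ``both`` (A_B) each lie in [0, 1] and sum to 1 whenever the underlying
    region or sample set is non-empty.
    """

    neither: float
    egfr_only: float
    pdgfra_only: float
    both: float

    def __post_init__(self) -> None:
        vals = self.as_array()
        if (vals < -1e-12).any() or (vals > 1 + 1e-12).any():
            raise ValueError("proportions must lie in [0, 1]")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError("proportions must sum to 1")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.neither, self.egfr_only, self.pdgfra_only, self.both]
        )

    def as_dict(self) -> dict:
        return dict(zip(CATEGORIES, self.as_array()))


def tumour_width(state: TumourState, mesh: Mesh, density_fraction: float = 0.8,
                 K: float | None = None) -> float:
    """Width (mm) of the region where T = E+P+N exceeds ``density_fraction*K``.

    Node-counting approximation: (number of nodes strictly above the
    threshold) * dx; an empty super-level set yields 0.  ``K`` defaults to
    the standard carrying capacity.
    """
    if not 0.0 < density_fraction < 1.0:
        raise ValueError("density_fraction must be in (0,1)")
    from .model import K_DEFAULT

    K = K_DEFAULT if K is None else K
    return float(np.count_nonzero(state.total > density_fraction * K)) * mesh.dx


def amplified_proportions(
    state: TumourState, mesh: Mesh, detect_fraction: float = 0.1,
    K: float | None = None,
) -> AmplificationProportions:
    """Amplification-category proportions of the detectable tumour.

    Over the nodes where T > detect_fraction*K:

        A_E = #{E > 0.1K and P <= 0.1K} / #{T > 0.1K}

    mirrored for A_P, A_B the both-above fraction and A_N the remainder
    (tumour detectable but neither amplified population above threshold --
    including sub-threshold edge nodes).  Equality with the threshold counts
    as not amplified / not detectable (strict >).  The detectable region
    need not be contiguous.  Raises if it is empty.
    """
    from .model import K_DEFAULT

    K = K_DEFAULT if K is None else K
    thr = detect_fraction * K
    detect = state.total > thr
    n_det = int(np.count_nonzero(detect))
    if n_det == 0:
        raise ValueError("detectable region (T > threshold) is empty")
    e_amp = state.E > thr
    p_amp = state.P > thr
    n_E = int(np.count_nonzero(detect & e_amp & ~p_amp))
    n_P = int(np.count_nonzero(detect & p_amp & ~e_amp))
    n_B = int(np.count_nonzero(detect & e_amp & p_amp))
    n_N = n_det - n_E - n_P - n_B
    return AmplificationProportions(
        neither=n_N / n_det,
        egfr_only=n_E / n_det,
        pdgfra_only=n_P / n_det,
        both=n_B / n_det,
    )
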