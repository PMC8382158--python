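import numpy as np
import pytest

import gbmpop as g


@pytest.fixture(scope="session")
def mesh():
    return g.Mesh()


@pytest.fixture(scope="session")
def fast_trace(mesh):
    """Baseline symmetric simulation with the fast (rho, D) = (30, 30) pair.

    Shared across metric and biopsy tests: a tumour at diagnosis size with
    E and P introduced together at the centre (identical fields).
    """
    params = g.build_params(g.Scenario.symmetric(0.0), 30.0, 30.0, mesh)
    return g.run(params, mesh, g.SolverConfig())


@pytest.fixture(scope="session")
def asymmetric_trace(mesh):
    """A diagnosis-size tumour with distinct E and P spatial structure."""
    sc = g.Scenario(
        alpha_EP=-2.0, alpha_PE=1.0,
        v_rho_E=1.3, v_D_E=1.2,
        trigger_multiple_E=4.0, trigger_multiple_P=7.0,
        offset_E=-1.0, offset_P=1.0,
    )
    params = g.build_params(sc, 30.0, 30.0, mesh)
    return g.run(params, mesh, g.SolverConfig())
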