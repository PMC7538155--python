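import numpy as np
import pytest

from iknm.geometry import GrowthLaw, ShellGeometry
from iknm.linear import solve_eigenproblem


@pytest.fixture(scope="session")
def geom():
    """Default tissue geometry: 55 µm thick half shell."""
    return ShellGeometry(a=100.0, b=45.0)


@pytest.fixture(scope="session")
def growth():
    return GrowthLaw(N0=100, TP=300.0)


@pytest.fixture(scope="session")
def eigensystem(geom):
    """Shared 8-mode eigensystem for the default geometry."""
    return solve_eigenproblem(geom.rho, M=8)


@pytest.fixture(scope="session")
def crowded_field(geom, growth):
    """Nonlinear-model concentration field with a crowded apical layer.

    Used by the Langevin tests: influx on, concentrations approaching cmax
    near the apical surface.
    """
    from iknm.nonlinear import solve_nonlinear

    cmax = 4.12e-3
    ic = lambda x: 0.6 * cmax * np.exp((x - 1.0) * 8.0) + 2e-4
    t_grid = np.arange(0.0, 400.0 + 1e-9, 2.0)
    return solve_nonlinear(ic, 0.09, cmax, geom, growth, t_grid, n_nodes=200)
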