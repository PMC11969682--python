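"""Shared fixtures.

The flow solves are the expensive part; session-scoped fixtures compute
each configuration once and share it between the unit suite and the
acceptance checks.
"""

from __future__ import annotations

import numpy as np
import pytest

from denticleflow import (DenticleParams, make_idealized_profile,
                          build_domain, rasterize_graded)
from denticleflow.experiment import (RunSpec, default_grid, run_experiment,
                                     run_single, independence_test)
from denticleflow import validation as V


@pytest.fixture(scope="session")
def idealized_profile():
    return make_idealized_profile(DenticleParams())


@pytest.fixture(scope="session")
def small_profile():
    return make_idealized_profile(DenticleParams(n_denticles=10))


@pytest.fixture(scope="session")
def grid8_report():
    """The full 2x2x2 experiment at desk scale, h = 1e-5 m near-body."""
    return run_experiment(default_grid(scale="small", seed=1))


@pytest.fixture(scope="session")
def fine_runs():
    """Idealized rostral runs at both inlet speeds on the finest grid of
    the independence sequence (h = 5e-6 m), the metric-reporting protocol."""
    out = {}
    for U in (0.05, 0.5):
        spec = RunSpec(geometry="idealized", orientation="rostral",
                       inlet_velocity=U, scale="small", spacing_h=5e-6)
        out[U] = run_single(spec)
    return out


@pytest.fixture(scope="session")
def independence_spacing():
    base = RunSpec(geometry="idealized", orientation="rostral",
                   inlet_velocity=0.05, scale="small")
    return independence_test(base, "spacing_h", [2e-5, 1e-5, 5e-6])


@pytest.fixture(scope="session")
def poiseuille_result():
    err, sol = V.poiseuille_case()
    return err, sol


@pytest.fixture(scope="session")
def couette_result():
    err, sol = V.couette_case()
    return err, sol


@pytest.fixture(scope="session")
def wall_drag_result():
    return V.poiseuille_wall_drag_case()


@pytest.fixture(scope="session")
def mirror_error():
    return V.mirror_equivalence_error()


@pytest.fixture(scope="session")
def stokes_error():
    return V.stokes_linearity_error()
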