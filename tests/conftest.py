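"""Shared fixtures.

The expensive random-walk simulations are session-scoped so that the
acceptance checks and the physical property tests share one run each.
Problem sizes follow the desk-scale protocol: 2000-4000 molecules,
durations ~1.5-2x the plateau onset, 20 ns steps.
"""

from __future__ import annotations

import numpy as np
import pytest

import sheetvoid as sv

D_FREE = 1.11e-5 * 1e8  # µm²/s, TMA at 37 °C
D_VISC = 7.71e-6 * 1e8  # µm²/s, with viscous tortuosity 1.2 folded in


def make_ccv_ensemble(a: float, w: float, phi: float, n: int,
                      b: float | None = None) -> sv.EnsembleGeometry:
    """CCV ensemble from (a, w, phi); b solved unless given explicitly."""
    if b is None:
        b = sv.ccv_void_width(a, w, phi)
    dims = sv.CellDims(a, b, w)
    phi_implied = sv.porosity_of_dims(dims, sv.ModelKind.CCV)
    cell = sv.build_cell(
        sv.ModelSpec(sv.ModelKind.CCV, phi_implied, w), dims
    )
    return sv.build_ensemble(cell, n)


def make_uniform_ensemble(phi: float, w: float, n: int) -> sv.EnsembleGeometry:
    a = sv.uniform_cell_halfwidth(phi, w)
    dims = sv.CellDims(a, 0.0, w)
    phi_implied = sv.porosity_of_dims(dims, sv.ModelKind.UNIFORM)
    cell = sv.build_cell(
        sv.ModelSpec(sv.ModelKind.UNIFORM, phi_implied, w), dims
    )
    return sv.build_ensemble(cell, n)


def make_etv_ensemble(a: float, w: float, phi: float, n: int) -> sv.EnsembleGeometry:
    b = sv.etv_void_width(a, w, phi)
    dims = sv.CellDims(a, b, w)
    phi_implied = sv.porosity_of_dims(dims, sv.ModelKind.ETV)
    cell = sv.build_cell(
        sv.ModelSpec(sv.ModelKind.ETV, phi_implied, w), dims
    )
    return sv.build_ensemble(cell, n)


@pytest.fixture(scope="session")
def ccv_reference_ensemble():
    """The corner-void geometry that produced tau_g = 1.328 at phi=0.2:
    a = 0.416 µm, b = 0.1785 µm, w = 20 nm."""
    return make_ccv_ensemble(0.416, 0.020, 0.2, n=64, b=0.1785)


@pytest.fixture(scope="session")
def tc_ccv_viscous(ccv_reference_ensemble):
    """Time course for the reference CCV run (viscous-case diffusivity)."""
    cfg = sv.SimConfig(
        d=D_VISC, dt=2e-8, n_molecules=2000, duration=6e-3, seed=1,
        output_every=2000,
    )
    return sv.run_simulation(
        ccv_reference_ensemble, cfg, snapshot_times=[cfg.duration]
    )


@pytest.fixture(scope="session")
def tc_uniform_pair():
    """Uniform phi=0.2 lattice simulated at both literature diffusivities
    (same geometry, same seed), for the D-independence check."""
    ens = make_uniform_ensemble(0.2, 0.020, n=64)
    out = {}
    for d in (D_FREE, D_VISC):
        cfg = sv.SimConfig(
            d=d, dt=2e-8, n_molecules=2500, duration=6e-3, seed=1,
            output_every=2000,
        )
        out[d] = sv.run_simulation(ens, cfg)
    return out


@pytest.fixture(scope="session")
def tc_sleep_trial():
    """CCV trial point of the asleep state: phi=0.234, Omega=4.0, w=20 nm."""
    spec = sv.ModelSpec(sv.ModelKind.CCV, 0.234, 0.020)
    dims = sv.dims_from_omega(spec, 4.0)
    ens = make_ccv_ensemble(dims.a, 0.020, 0.234, n=32, b=dims.b)
    cfg = sv.SimConfig(
        d=D_VISC, dt=2e-8, n_molecules=2000, duration=2.4e-2, seed=1,
        output_every=5000,
    )
    return sv.run_simulation(ens, cfg)


@pytest.fixture(scope="session")
def ccv_slope_points(tc_ccv_viscous):
    """Three simulated (Omega, tau_g²) points on the phi=0.2 corner-void
    line, for the scaled re-estimate of the linear slope m1."""
    pts = []
    omega_ref = sv.omega_of_geometry(0.416, 0.020, 0.2)
    tau_ref = sv.steady_state_tau(tc_ccv_viscous)
    pts.append((omega_ref, tau_ref**2))
    spec = sv.ModelSpec(sv.ModelKind.CCV, 0.2, 0.020)
    for omega, duration, n in ((1.0, 6e-3, 64), (1.608, 1.0e-2, 64)):
        dims = sv.dims_from_omega(spec, omega)
        ens = make_ccv_ensemble(dims.a, 0.020, 0.2, n=n, b=dims.b)
        cfg = sv.SimConfig(
            d=D_FREE, dt=2e-8, n_molecules=2000, duration=duration, seed=1,
            output_every=2000,
        )
        tc = sv.run_simulation(ens, cfg)
        pts.append((omega, sv.steady_state_tau(tc) ** 2))
    return pts
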