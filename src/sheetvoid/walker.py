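"""Reflecting Brownian random-walk simulator for sheet-and-void lattices.

Molecules are released instantaneously from a point source at the
central lattice vertex (the cavity where 8 corner voids meet) and take
fixed-time-step Gaussian displacements with per-axis variance 2 D dt.
Any step segment that would enter a solid cell is specularly reflected
at its first intersection with a solid face, iterating until the step
is consumed; membranes are impermeable, so no endpoint may lie inside a
solid.

The outer ensemble boundary is NOT reflecting: a molecule leaving the
bounds is an error condition (the ensemble must simply be made large
enough), mirroring the containment check of the original Monte Carlo
protocol.

All solid faces are axis-aligned planes at local coordinates ±a or
±(a - b) folded by the lattice period, so first intersections are
closed-form: candidate plane crossings along the segment are
enumerated, and the step is piecewise classified between consecutive
crossings (the solid/ISS label can only change on a plane).  Gaussian
increments come from numpy's PCG64 generator in chunks; the hot loop is
JIT-compiled with numba and allocates nothing per step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .ensemble import EnsembleGeometry, Region, classify_point
from .errors import ConfigError, ContainmentError, GeometryError

__all__ = [
    "SimConfig",
    "WalkerState",
    "TimeCourse",
    "mean_radial_step",
    "init_release",
    "advance_step",
    "run_simulation",
    "radial_stats",
    "snapshot_slice",
]

_VOID_NONE = 0  # b == 0 (uniform lattice)
_VOID_CORNER = 1  # CCV: void where all 3 local coords exceed a-b
_VOID_EDGE = 2  # ETV: void where >= 2 local coords exceed a-b


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters.  Lengths µm, times s, diffusivity µm²/s.

    ``d`` is the free diffusivity (a cm²/s literature value is
    converted by x1e8 at the configuration boundary).  ``dt`` must keep
    the mean radial step  l_r = sqrt(4 D dt / pi)  at most 2w divided by
    ``safety_factor`` (default 4), so steps stay much smaller than the
    sheet width.
    """

    d: float
    dt: float
    n_molecules: int
    duration: float
    seed: int = 1
    output_every: int = 1000
    max_reflections: int = 32
    safety_factor: float = 4.0

    def __post_init__(self):
        if self.d <= 0 or self.dt <= 0 or self.duration <= 0:
            raise ConfigError("d, dt and duration must be positive")
        if self.n_molecules < 1:
            raise ConfigError("need at least one molecule")
        steps = self.duration / self.dt
        if abs(steps - round(steps)) > 1e-6:
            raise ConfigError(
                f"duration/dt = {steps} is not an integer number of steps"
            )
        if self.safety_factor < 4.0:
            raise ConfigError("safety_factor must be >= 4")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))

    @property
    def sigma(self) -> float:
        """Per-axis step standard deviation sqrt(2 D dt), µm."""
        return math.sqrt(2.0 * self.d * self.dt)

    def validate_for(self, ens: EnsembleGeometry | None) -> None:
        """Check the time-step constraint against the sheet width."""
        if ens is None:
            return
        lr = mean_radial_step(self.d, self.dt)
        w = ens.cell.dims.w
        if lr > 2.0 * w / self.safety_factor:
            raise ConfigError(
                f"time step too large: mean radial step l_r = {lr * 1e3:.3g} nm "
                f"exceeds 2w/{self.safety_factor:g} = "
                f"{2 * w / self.safety_factor * 1e3:.3g} nm"
            )


def mean_radial_step(d: float, dt: float) -> float:
    """Mean radial displacement per step, sqrt(4 D dt / pi), µm."""
    return math.sqrt(4.0 * d * dt / math.pi)


@dataclass
class WalkerState:
    """Positions (n, 3) µm at a given time, plus release bookkeeping."""

    positions: np.ndarray
    time: float
    origin: np.ndarray
    left_count: int = 0


@dataclass
class TimeCourse:
    """Trajectory statistics sampled at the output cadence.

    ``d_star = msd / (6 t)`` pointwise and ``tau_g = sqrt(D / D*)``;
    before the plateau these are time-dependent apparent values, only
    the steady-state average is a true tortuosity.
    """

    times: np.ndarray
    msd: np.ndarray
    d: float
    seed: int
    left_count: int = 0
    reflection_cap_events: int = 0
    snapshots: dict = field(default_factory=dict)

    @property
    def d_star(self) -> np.ndarray:
        return self.msd / (6.0 * self.times)

    @property
    def tau_g(self) -> np.ndarray:
        return np.sqrt(self.d / self.d_star)

    @property
    def r_2rms(self) -> np.ndarray:
        return 2.0 * np.sqrt(self.msd)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t_s": self.times,
                "msd_um2": self.msd,
                "d_star_cm2_s": self.d_star * 1e-8,
                "tau_g": self.tau_g,
                "r_2rms_um": self.r_2rms,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always")
def _is_solid(x, y, z, p, inv_twop, a, inner, void_rule):
    """Classify a point (global frame) as solid after period folding."""
    lx = abs(x - (2.0 * math.floor(x * inv_twop) + 1.0) * p)
    ly = abs(y - (2.0 * math.floor(y * inv_twop) + 1.0) * p)
    lz = abs(z - (2.0 * math.floor(z * inv_twop) + 1.0) * p)
    if lx > a or ly > a or lz > a:
        return False  # sheet
    if void_rule == _VOID_NONE:
        return True
    outer = 0
    if lx > inner:
        outer += 1
    if ly > inner:
        outer += 1
    if lz > inner:
        outer += 1
    if void_rule == _VOID_CORNER:
        return outer < 3
    return outer < 2  # edge-tunnel rule


@njit(cache=True)
def _advance(x, y, z, vx, vy, vz, p, inv_twop, a, inner, void_rule,
             max_reflections, ts, axs, pls):
    """Move one molecule by (vx, vy, vz) with specular reflections.

    Returns (x, y, z, n_bounces, path_length, ok).  ok = False when the
    reflection cap was reached or the start point misclassified; the
    caller then discards the step (and logs the event).  ``ts``, ``axs``
    and ``pls`` are caller-provided scratch buffers of length >= 32 (so
    the hot loop allocates nothing).
    """
    path = 0.0
    bounces = 0
    for _ in range(max_reflections + 1):
        # enumerate candidate crossings of solid-face planes
        m = 0
        for d in range(3):
            if d == 0:
                u, vd = x, vx
            elif d == 1:
                u, vd = y, vy
            else:
                u, vd = z, vz
            if vd == 0.0:
                continue
            lo = u if vd > 0.0 else u + vd
            hi = u + vd if vd > 0.0 else u
            k0 = int(math.floor(lo * inv_twop))
            k1 = int(math.floor(hi * inv_twop))
            for k in range(k0, k1 + 1):
                c = (2.0 * k + 1.0) * p
                for s in range(4):
                    if s == 0:
                        off = -a
                    elif s == 1:
                        off = -inner
                    elif s == 2:
                        off = inner
                    else:
                        off = a
                    if void_rule == _VOID_NONE and (s == 1 or s == 2):
                        continue
                    plane = c + off
                    if lo < plane < hi:
                        t = (plane - u) / vd
                        if 1e-13 < t < 1.0 and m < 32:
                            ts[m] = t
                            axs[m] = d
                            pls[m] = plane
                            m += 1
        if m == 0:
            # no plane crossed: classification is constant along the
            # whole segment, which started in the ISS
            path += math.sqrt(vx * vx + vy * vy + vz * vz)
            return x + vx, y + vy, z + vz, bounces, path, True
        # insertion sort of the (at most 32) crossings
        for i in range(1, m):
            tv, av, pv = ts[i], axs[i], pls[i]
            j = i - 1
            while j >= 0 and ts[j] > tv:
                ts[j + 1] = ts[j]
                axs[j + 1] = axs[j]
                pls[j + 1] = pls[j]
                j -= 1
            ts[j + 1] = tv
            axs[j + 1] = av
            pls[j + 1] = pv
        # classify sub-intervals between crossings at their midpoints
        hit = -2  # -2: no solid interval; -1: start itself classifies solid
        prev = 0.0
        for i in range(m + 1):
            tn = ts[i] if i < m else 1.0
            if tn - prev > 1e-14:
                tm = 0.5 * (prev + tn)
                if _is_solid(
                    x + tm * vx, y + tm * vy, z + tm * vz,
                    p, inv_twop, a, inner, void_rule,
                ):
                    hit = i - 1
                    break
            prev = tn
        if hit == -2:
            path += math.sqrt(vx * vx + vy * vy + vz * vz)
            return x + vx, y + vy, z + vz, bounces, path, True
        if hit == -1:
            # first sub-interval classified solid: invalid start state
            return x, y, z, bounces, path, False
        th = ts[hit]
        path += th * math.sqrt(vx * vx + vy * vy + vz * vz)
        x += th * vx
        y += th * vy
        z += th * vz
        rem = 1.0 - th
        vx *= rem
        vy *= rem
        vz *= rem
        d = axs[hit]
        if d == 0:
            x = pls[hit]  # snap exactly onto the face
            vx = -vx
        elif d == 1:
            y = pls[hit]
            vy = -vy
        else:
            z = pls[hit]
            vz = -vz
        bounces += 1
    return x, y, z, bounces, path, False


@njit(cache=True)
def _run_chunk(
    pos,
    normals,
    sigma,
    p,
    a,
    inner,
    void_rule,
    free_space,
    step0,
    out_every,
    msd_out,
    bound,
    snap_steps,
    snaps,
    snap_ptr,
    max_reflections,
):
    """Advance all molecules through one chunk of pre-drawn normals.

    ``normals`` has shape (chunk_steps, n, 3); global step numbering is
    1-based via ``step0``.  Output rows of ``msd_out`` are filled for
    every global step divisible by ``out_every``.  Returns
    (first_escape_step, cap_events, snap_ptr).
    """
    ts = np.empty(32)
    axs = np.empty(32, dtype=np.int64)
    pls = np.empty(32)
    inv_twop = 1.0 / (2.0 * p)
    n = pos.shape[0]
    cap_events = 0
    first_escape = -1
    for s in range(normals.shape[0]):
        g = step0 + s + 1
        if free_space:
            for i in range(n):
                pos[i, 0] += sigma * normals[s, i, 0]
                pos[i, 1] += sigma * normals[s, i, 1]
                pos[i, 2] += sigma * normals[s, i, 2]
        else:
            for i in range(n):
                x, y, z, nb, pl, ok = _advance(
                    pos[i, 0],
                    pos[i, 1],
                    pos[i, 2],
                    sigma * normals[s, i, 0],
                    sigma * normals[s, i, 1],
                    sigma * normals[s, i, 2],
                    p,
                    inv_twop,
                    a,
                    inner,
                    void_rule,
                    max_reflections,
                    ts,
                    axs,
                    pls,
                )
                if ok:
                    pos[i, 0] = x
                    pos[i, 1] = y
                    pos[i, 2] = z
                else:
                    cap_events += 1  # step discarded, molecule stays put
        if snap_ptr < snap_steps.shape[0] and g == snap_steps[snap_ptr]:
            snaps[snap_ptr, :, :] = pos
            snap_ptr += 1
        if g % out_every == 0:
            acc = 0.0
            escaped = 0
            for i in range(n):
                x = pos[i, 0]
                y = pos[i, 1]
                z = pos[i, 2]
                acc += x * x + y * y + z * z
                if abs(x) > bound or abs(y) > bound or abs(z) > bound:
                    escaped += 1
            msd_out[g // out_every - 1] = acc / n
            if escaped > 0 and first_escape < 0:
                first_escape = g
    return first_escape, cap_events, snap_ptr


def _scratch():
    """Fresh scratch buffers for a python-level _advance call."""
    return np.empty(32), np.empty(32, dtype=np.int64), np.empty(32)


def _void_rule(ens: EnsembleGeometry) -> int:
    from .relations import ModelKind

    if ens.cell.dims.b == 0.0:
        return _VOID_NONE
    if ens.cell.model_kind is ModelKind.CCV:
        return _VOID_CORNER
    return _VOID_EDGE


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def init_release(ens: EnsembleGeometry | None, cfg: SimConfig) -> WalkerState:
    """All molecules at the release origin (central lattice vertex) at t=0."""
    origin = np.zeros(3)
    if ens is not None:
        region = classify_point(ens, origin)
        if region not in (Region.VOID, Region.SHEET):
            raise GeometryError(
                f"release origin classifies as {region.name}; must be in the ISS"
            )
        origin = ens.release_origin.copy()
    positions = np.tile(origin, (cfg.n_molecules, 1)).astype(float)
    return WalkerState(positions=positions, time=0.0, origin=origin)


def advance_step(
    state: WalkerState,
    ens: EnsembleGeometry | None,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> WalkerState:
    """Advance every molecule by one Gaussian step (python-level, for
    small-scale tests and inspection; :func:`run_simulation` uses the
    compiled chunk loop)."""
    steps = rng.normal(0.0, cfg.sigma, size=state.positions.shape)
    if ens is None:
        state.positions += steps
    else:
        p = ens.cell.dims.p
        a = ens.cell.dims.a
        inner = a - ens.cell.dims.b
        rule = _void_rule(ens)
        for i in range(len(state.positions)):
            x, y, z, nb, pl, ok = _advance(
                state.positions[i, 0],
                state.positions[i, 1],
                state.positions[i, 2],
                steps[i, 0],
                steps[i, 1],
                steps[i, 2],
                p,
                1.0 / (2.0 * p),
                a,
                inner,
                rule,
                cfg.max_reflections,
                *_scratch(),
            )
            if ok:
                state.positions[i] = (x, y, z)
        bound = ens.half_extent
        state.left_count = int(np.sum(np.abs(state.positions).max(axis=1) > bound))
    state.time += cfg.dt
    return state


def reflect_segment(ens: EnsembleGeometry, start, step, max_reflections: int = 32):
    """Trace one displacement segment with reflections (test/inspection
    helper).  Returns (end_point, n_bounces, traversed_path_length, ok)."""
    p = ens.cell.dims.p
    a = ens.cell.dims.a
    inner = a - ens.cell.dims.b
    rule = _void_rule(ens)
    x, y, z, nb, pl, ok = _advance(
        float(start[0]),
        float(start[1]),
        float(start[2]),
        float(step[0]),
        float(step[1]),
        float(step[2]),
        p,
        1.0 / (2.0 * p),
        a,
        inner,
        rule,
        max_reflections,
        *_scratch(),
    )
    return np.array([x, y, z]), nb, pl, ok


def run_simulation(
    ens: EnsembleGeometry | None,
    cfg: SimConfig,
    snapshot_times=None,
    chunk_steps: int = 128,
) -> TimeCourse:
    """Run a full point-release simulation and return its time course.

    Parameters
    ----------
    ens:
        Ensemble geometry, or None for free (unbounded, obstacle-free)
        diffusion -- the tau_g = 1 reference case.
    cfg:
        Simulation configuration; ``cfg.seed`` fully determines the run.
    snapshot_times:
        Optional times (s) at which to record molecule positions; they
        are rounded to the nearest step.
    chunk_steps:
        Steps per pre-drawn Gaussian block (memory/speed trade-off
        only; does not affect results).

    Raises
    ------
    ContainmentError
        If any molecule left the ensemble bounds (the ensemble is too
        small for the requested duration).
    """
    cfg.validate_for(ens)
    state = init_release(ens, cfg)
    if ens is None:
        p = a = inner = 1.0
        rule = _VOID_NONE
        free = True
        bound = np.inf
    else:
        p = ens.cell.dims.p
        a = ens.cell.dims.a
        inner = a - ens.cell.dims.b
        rule = _void_rule(ens)
        free = False
        bound = ens.half_extent
    if snapshot_times is None:
        snap_steps = np.empty(0, dtype=np.int64)
    else:
        snap_steps = np.unique(
            np.clip(np.rint(np.asarray(snapshot_times) / cfg.dt), 1, cfg.n_steps)
        ).astype(np.int64)
    snaps = np.zeros((len(snap_steps), cfg.n_molecules, 3))
    n_out = cfg.n_steps // cfg.output_every
    msd = np.zeros(n_out)
    rng = np.random.default_rng(cfg.seed)
    pos = state.positions
    step0 = 0
    snap_ptr = 0
    cap_events = 0
    first_escape = -1
    while step0 < cfg.n_steps:
        nsteps = min(chunk_steps, cfg.n_steps - step0)
        normals = rng.standard_normal((nsteps, cfg.n_molecules, 3))
        fe, cap, snap_ptr = _run_chunk(
            pos,
            normals,
            cfg.sigma,
            p,
            a,
            inner,
            rule,
            free,
            step0,
            cfg.output_every,
            msd,
            bound,
            snap_steps,
            snaps,
            snap_ptr,
            cfg.max_reflections,
        )
        cap_events += cap
        if fe > 0 and first_escape < 0:
            first_escape = fe
        step0 += nsteps
    left = (
        0
        if ens is None
        else int(np.sum(np.abs(pos).max(axis=1) > bound))
    )
    times = np.arange(1, n_out + 1) * cfg.output_every * cfg.dt
    tc = TimeCourse(
        times=times,
        msd=msd,
        d=cfg.d,
        seed=cfg.seed,
        left_count=left,
        reflection_cap_events=int(cap_events),
        snapshots={
            float(st * cfg.dt): snaps[i] for i, st in enumerate(snap_steps)
        },
    )
    if left > 0 or first_escape > 0:
        t_esc = first_escape * cfg.dt if first_escape > 0 else times[-1]
        raise ContainmentError(
            f"{max(left, 1)} molecule(s) left the ensemble; earliest escape by "
            f"t = {t_esc:.6g} s -- use a larger ensemble",
            first_escape_time=t_esc,
            left_count=max(left, 1),
        )
    return tc


def radial_stats(state: WalkerState) -> tuple[float, float]:
    """Mean squared radial distance from the origin and 2 x RMS distance."""
    if len(state.positions) < 1:
        raise ConfigError("need at least one molecule")
    disp = state.positions - state.origin
    msd = float(np.mean(np.sum(disp * disp, axis=1)))
    return msd, 2.0 * math.sqrt(msd)


def snapshot_slice(
    positions: np.ndarray, half_thickness: float
) -> np.ndarray:
    """x-y coordinates of molecules within |z| <= half_thickness.

    Emulates the visualisation slice through the ensemble centred on the
    x-y plane (default half-thickness p).
    """
    if half_thickness <= 0:
        raise ConfigError("half_thickness must be positive")
    positions = np.asarray(positions)
    keep = np.abs(positions[:, 2]) <= half_thickness
    return positions[keep, :2]
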