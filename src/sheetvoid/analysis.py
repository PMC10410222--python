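"""Reduction of time courses to tortuosities, structure-transport fits
and their inversion, and the asleep/awake two-state inference.

The pipeline is:

1. a simulation time course ⟨r²⟩(t) is reduced to an effective
   diffusivity D* = ⟨r²⟩/(6t) and geometrical tortuosity
   tau_g = sqrt(D/D*), averaged over the steady-state plateau;
2. (Omega, tau_g²) points are fitted to a polynomial -- linear for the
   corner-void model at normal porosities, cubic at high porosities,
   quartic for the edge-tunnel model;
3. the fit is inverted for a target tortuosity, and the geometry
   relations turn the resulting Omega into cell dimensions (a, b) for
   any sheet half-width w.

The asleep/awake analysis anchors a straight line in (Omega, tau²) at
the zero-void tortuosity of the corrected cubic-lattice relation and at
one simulated trial point per brain state, then solves each line for a
shared target tortuosity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    ConfigError,
    DomainError,
    NotConvergedError,
    TortuosityUnreachableError,
)
from .relations import (
    constant_bounding_w,
    scale_factor_A,
    tau_uniform_cubes,
    void_ratio_B,
)
from .walker import TimeCourse

__all__ = [
    "SteadyState",
    "GaussianityReport",
    "FitCoefficients",
    "TortuosityTarget",
    "SleepWakeScenario",
    "effective_diffusivity",
    "tortuosity_of",
    "detect_steady_state",
    "gaussianity_r2",
    "fit_polynomial",
    "omega_at_tau",
    "solve_geometry_table",
    "sleepwake_analysis",
]


def effective_diffusivity(msd: float, t: float):
    """Effective diffusivity D* = ⟨r²⟩ / (6 t), µm²/s."""
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise DomainError("time must be positive")
    return np.asarray(msd, dtype=float) / (6.0 * t)


def tortuosity_of(d: float, d_star: float):
    """Geometrical tortuosity tau_g = sqrt(D / D*)."""
    d_star = np.asarray(d_star, dtype=float)
    if d <= 0 or np.any(d_star <= 0):
        raise DomainError("diffusivities must be positive")
    return np.sqrt(d / d_star)


@dataclass(frozen=True)
class SteadyState:
    """Plateau window of a tortuosity time course and its average."""

    t_onset: float
    t_end: float
    tau_mean: float
    tau_sd: float
    n_window: int


def detect_steady_state(
    tc: TimeCourse,
    rel_slope_tol: float = 0.01,
    window_decades: float = 0.5,
) -> SteadyState:
    """Locate the tau_g plateau of a time course and average over it.

    The onset is the earliest output time, after the early tortuosity
    peak, at which the log-log slope |d ln tau² / d ln t| fitted over
    the trailing ``window_decades``-wide window stays below
    ``rel_slope_tol``.  The plateau mean is taken from the onset to the
    end of the run.
    """
    tau = np.asarray(tc.tau_g)
    times = np.asarray(tc.times)
    if len(times) < 8:
        raise NotConvergedError("time course too short for plateau detection")
    i_peak = int(np.argmax(tau))
    log_t = np.log(times)
    log_tau2 = 2.0 * np.log(tau)
    onset_idx = None
    for i in range(max(i_peak, 1), len(times)):
        sel = (log_t >= log_t[i]) & (log_t <= log_t[i] + window_decades * math.log(10))
        if sel.sum() < 3:
            break
        x = log_t[sel]
        y = log_tau2[sel]
        slope = np.polyfit(x, y, 1)[0]
        if abs(slope) < rel_slope_tol:
            onset_idx = i
            break
    if onset_idx is None:
        raise NotConvergedError(
            "no steady-state plateau found: run the simulation longer"
        )
    window = tau[onset_idx:]
    return SteadyState(
        t_onset=float(times[onset_idx]),
        t_end=float(times[-1]),
        tau_mean=float(window.mean()),
        tau_sd=float(window.std(ddof=1)) if len(window) > 1 else 0.0,
        n_window=int(len(window)),
    )


def steady_state_tau(tc: TimeCourse, **kwargs) -> float:
    """Convenience: plateau-averaged tau_g of a time course."""
    return detect_steady_state(tc, **kwargs).tau_mean


@dataclass(frozen=True)
class GaussianityReport:
    """Per-axis histogram comparison against the diffusion Gaussian.

    The reference curve for each axis is the Gaussian with variance
    2 D* t (independently generated, not fitted), scaled to the total
    molecule count; R² follows
    R² = 1 - (||residuals|| / ||Y - mean(Y)||)².
    """

    bin_width: float
    bin_centres: np.ndarray = field(repr=False)
    counts: np.ndarray = field(repr=False)  # (3, n_bins)
    expected: np.ndarray = field(repr=False)
    r2: tuple  # per axis


def _r2(y: np.ndarray, fit: np.ndarray) -> float:
    resid = np.linalg.norm(y - fit)
    spread = np.linalg.norm(y - y.mean())
    if spread == 0:
        raise DomainError("degenerate data: zero variance")
    return 1.0 - (resid / spread) ** 2


def gaussianity_r2(
    positions: np.ndarray, d_star: float, t: float, bin_width: float
) -> GaussianityReport:
    """Compare per-axis molecule histograms with the diffusion Gaussian.

    At steady state the coordinate marginals of a point release should
    be Gaussian with variance 2 D* t; high R² per axis confirms that D*
    is a classic diffusivity.
    """
    positions = np.asarray(positions)
    n = len(positions)
    if n < 1000:
        raise ConfigError("need at least 1000 molecules for histograms")
    if bin_width <= 0 or t <= 0 or d_star <= 0:
        raise DomainError("bin_width, t and d_star must be positive")
    sigma2 = 2.0 * d_star * t
    half = bin_width * math.ceil(4.0 * math.sqrt(sigma2) / bin_width)
    edges = np.arange(-half, half + bin_width / 2, bin_width)
    centres = 0.5 * (edges[:-1] + edges[1:])
    expected = (
        n * bin_width / math.sqrt(2.0 * math.pi * sigma2)
        * np.exp(-(centres**2) / (2.0 * sigma2))
    )
    counts = np.stack(
        [np.histogram(positions[:, ax], bins=edges)[0] for ax in range(3)]
    )
    r2 = tuple(_r2(counts[ax].astype(float), expected) for ax in range(3))
    return GaussianityReport(
        bin_width=bin_width,
        bin_centres=centres,
        counts=counts,
        expected=expected,
        r2=r2,
    )


@dataclass(frozen=True)
class FitCoefficients:
    """Polynomial tau_g² = tau_g0² + m1 Ω + m2 Ω² + m3 Ω³ + m4 Ω⁴.

    ``order`` is 1 (corner voids, phi <= 0.4), 3 (corner voids,
    phi >= 0.6) or 4 (edge tunnels); higher coefficients are None when
    absent.  ``omega_range`` records the fitted interval -- the curve
    has no physical meaning beyond its data.
    """

    order: int
    tau_g0_sq: float
    m1: float
    m2: float | None = None
    m3: float | None = None
    m4: float | None = None
    r2: float | None = None
    omega_range: tuple = (0.0, np.inf)
    phi: float | None = None

    def __post_init__(self):
        if self.order not in (1, 3, 4):
            raise DomainError(f"order must be 1, 3 or 4, got {self.order}")
        need = {1: ("m2", "m3", "m4"), 3: ("m4",), 4: ()}[self.order]
        for name in need:
            if getattr(self, name) is not None:
                raise DomainError(f"order {self.order} fit cannot carry {name}")

    @property
    def coeffs(self) -> np.ndarray:
        """Ascending coefficient vector of length order+1."""
        full = [self.tau_g0_sq, self.m1, self.m2, self.m3, self.m4]
        return np.array([c for c in full[: self.order + 1]], dtype=float)

    def __call__(self, omega):
        return np.polynomial.polynomial.polyval(omega, self.coeffs)


def fit_polynomial(points, order: int, phi: float | None = None) -> FitCoefficients:
    """Least-squares polynomial fit of tau_g² against Omega.

    ``points`` is a sequence of (Omega, tau_g²) pairs; at least
    order + 2 points are required so that R² is meaningful.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise DomainError("points must be (Omega, tau_g^2) pairs")
    if len(pts) < order + 2:
        raise DomainError(
            f"need at least {order + 2} points for an order-{order} fit"
        )
    omega, tau2 = pts[:, 0], pts[:, 1]
    coeffs = np.polynomial.polynomial.polyfit(omega, tau2, order)
    fitted = np.polynomial.polynomial.polyval(omega, coeffs)
    r2 = _r2(tau2, fitted)
    named = dict(zip(("m1", "m2", "m3", "m4"), coeffs[1:]))
    return FitCoefficients(
        order=order,
        tau_g0_sq=float(coeffs[0]),
        r2=r2,
        omega_range=(float(omega.min()), float(omega.max())),
        phi=phi,
        **{k: float(v) for k, v in named.items()},
    )


@dataclass(frozen=True)
class TortuosityTarget:
    """A measured tortuosity, optionally split into geometric x viscous.

    When a viscous component is present the geometric part to be
    matched by the lattice is tau_g = tau_measured / tau_viscous
    (tortuosities multiply); with tau_viscous = None the measured value
    is taken as purely geometric.
    """

    tau_measured: float
    tau_viscous: float | None = None

    @property
    def tau_g(self) -> float:
        tau = (
            self.tau_measured / self.tau_viscous
            if self.tau_viscous is not None
            else self.tau_measured
        )
        if tau < 1.0:
            raise DomainError(f"geometric tortuosity {tau} < 1 is unphysical")
        return tau


def omega_at_tau(
    fit: FitCoefficients,
    target: TortuosityTarget | float,
    extrapolation_margin: float = 0.05,
) -> float:
    """Invert a fitted curve for the Omega reaching a target tortuosity.

    Order 1 is solved in closed form; orders 3/4 take the smallest real
    root >= 0 inside the fitted Omega range (slightly enlarged by
    ``extrapolation_margin`` relative, to absorb printed rounding).
    """
    tau_g = target.tau_g if isinstance(target, TortuosityTarget) else float(target)
    tau2 = tau_g * tau_g
    if fit.order == 1:
        if fit.m1 == 0:
            raise TortuosityUnreachableError("flat line cannot be inverted")
        omega = (tau2 - fit.tau_g0_sq) / fit.m1
        if -1e-12 * max(1.0, abs(tau2)) < omega < 0.0:
            return 0.0
        if omega < 0:
            raise TortuosityUnreachableError(
                f"target tau_g = {tau_g} lies below the zero-void anchor"
            )
        return omega
    coeffs = fit.coeffs.copy()
    coeffs[0] -= tau2
    roots = np.polynomial.polynomial.polyroots(coeffs)
    real = np.sort(roots[np.abs(roots.imag) < 1e-9].real)
    lo, hi = fit.omega_range
    span = (hi - lo) if np.isfinite(hi) else 0.0
    hi_ext = hi + extrapolation_margin * span if np.isfinite(hi) else np.inf
    admissible = [r for r in real if -1e-9 <= r <= hi_ext]
    if not admissible:
        raise TortuosityUnreachableError(
            f"tortuosity tau_g = {tau_g} unreachable on the fitted range "
            f"{fit.omega_range}; real roots at {list(real)}"
        )
    return float(max(admissible[0], 0.0))


def solve_geometry_table(
    phis,
    ws,
    targets,
    fits,
) -> pd.DataFrame:
    """Cell dimensions for every (porosity, target, sheet width) combination.

    ``fits`` maps porosity -> :class:`FitCoefficients`.  For each
    porosity and tortuosity target the fitted curve is inverted for
    Omega, then a = A(Omega, phi) w and b = B(Omega, phi) a give the
    corner-void geometry for each sheet half-width in ``ws`` (µm).
    Returns rows (phi, tau_g, w_um, Omega, a_um, b_um, p_um).
    """
    rows = []
    for phi in phis:
        fit = fits[phi]
        for target in targets:
            tau_g = (
                target.tau_g if isinstance(target, TortuosityTarget) else float(target)
            )
            omega = omega_at_tau(fit, tau_g)
            A = scale_factor_A(omega, phi)
            B = void_ratio_B(omega, phi)
            for w in ws:
                a = A * w
                rows.append(
                    {
                        "phi": phi,
                        "tau_g": tau_g,
                        "w_um": w,
                        "Omega": omega,
                        "a_um": a,
                        "b_um": B * a,
                        "p_um": a + w,
                    }
                )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class StateLine:
    """One brain state's linear tau²(Omega) law and solved geometry."""

    phi: float
    tau0: float
    trial_omega: float
    trial_tau: float
    slope: float
    omega: float
    A: float
    B: float


@dataclass(frozen=True)
class SleepWakeScenario:
    """Two-state (asleep/awake) inference record.

    Each state's line tau² = tau0² + m Omega is anchored at the
    zero-void tortuosity from the corrected cubic-lattice relation and
    at one simulated trial point, then solved for the shared target
    tortuosity ``tau_sw``.  ``geometry`` tabulates (a, b, p) per sheet
    half-width for both states, including the constant-bounding-cube
    row where the awake sheet width is chosen so p stays equal to the
    sleep reference.
    """

    tau_sw: float
    sleep: StateLine
    wake: StateLine
    geometry: pd.DataFrame
    p_ref: float


def _state_line(phi: float, trial_omega: float, trial_tau: float,
                tau_sw: float) -> StateLine:
    tau0 = tau_uniform_cubes(phi, corrected=True)
    if tau_sw < tau0:
        raise TortuosityUnreachableError(
            f"target tau = {tau_sw} below the zero-void anchor {tau0:.4f} "
            f"at phi = {phi}: no positive Omega exists"
        )
    slope = (trial_tau**2 - tau0**2) / trial_omega
    omega = (tau_sw**2 - tau0**2) / slope
    return StateLine(
        phi=phi,
        tau0=tau0,
        trial_omega=trial_omega,
        trial_tau=trial_tau,
        slope=slope,
        omega=omega,
        A=scale_factor_A(omega, phi),
        B=void_ratio_B(omega, phi),
    )


def sleepwake_analysis(
    phi_s: float,
    phi_w: float,
    tau_sw: float,
    trial_s: tuple,
    trial_w: tuple,
    ws=(0.010, 0.020, 0.040),
    p_ref_w: float = 0.020,
) -> SleepWakeScenario:
    """Two-point linear inference of asleep/awake void geometry.

    Parameters
    ----------
    phi_s, phi_w:
        Porosities in the asleep and awake states.
    tau_sw:
        Shared target geometrical tortuosity for both states.
    trial_s, trial_w:
        One (Omega, simulated tau_g) trial point per state.
    ws:
        Sheet half-widths (µm) for the geometry table.
    p_ref_w:
        The sleep-state sheet half-width whose bounding cube serves as
        the constant-volume reference (default 20 nm).

    Returns a scenario whose geometry table mirrors the per-state
    layout (w_nm, a_um, b_um, p_um), with a final awake row at the
    sheet width that keeps the bounding cube identical to the sleep
    reference.
    """
    sleep = _state_line(phi_s, *trial_s, tau_sw=tau_sw)
    wake = _state_line(phi_w, *trial_w, tau_sw=tau_sw)
    rows = []
    for state_name, line in (("sleep", sleep), ("awake", wake)):
        for w in ws:
            a = line.A * w
            rows.append(
                {
                    "state": state_name,
                    "w_nm": w * 1e3,
                    "a_um": a,
                    "b_um": line.B * a,
                    "p_um": a + w,
                    "constant_p": False,
                }
            )
    p_ref = (sleep.A + 1.0) * p_ref_w
    w_const = constant_bounding_w(p_ref, wake.A)
    a_const = wake.A * w_const
    rows.append(
        {
            "state": "awake",
            "w_nm": w_const * 1e3,
            "a_um": a_const,
            "b_um": wake.B * a_const,
            "p_um": a_const + w_const,
            "constant_p": True,
        }
    )
    return SleepWakeScenario(
        tau_sw=tau_sw,
        sleep=sleep,
        wake=wake,
        geometry=pd.DataFrame(rows),
        p_ref=p_ref,
    )
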