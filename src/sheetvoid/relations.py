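"""Closed-form geometry calculus for sheet-and-void models of brain ISS.

The brain interstitial space (ISS) is treated as the pore space of a
periodic porous medium built from cubic cells of half-width ``a``,
separated by fluid sheets of half-width ``w`` (adjacent cells are 2w
apart), optionally carved with voids of width ``b``:

* **UNIFORM** -- plain cubic lattice, no voids (b = 0).
* **CCV** (corner cubic void) -- a cubic void of side b cut into each of
  the 8 corners of the basic cell.
* **ETV** (edge tunnel void) -- square tunnels of cross-section b x b
  along all 12 edges, joined by the 8 corner cubes.

Each cell plus its half-sheets occupies a bounding cube of half-width
``p = a + w``; these bounding cubes tile space.  The porosity ``phi`` is
the ISS (sheet + void) fraction of the bounding cube, and
``Omega = V_v / V_s`` is the ratio of void volume to sheet volume, the
dimensionless predictor of tortuosity used throughout the package.

All lengths are in micrometres (µm), volumes in µm³.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

from scipy.optimize import brentq

from .errors import DomainError, GeometryError, NoVoidSolutionError

__all__ = [
    "ModelKind",
    "ModelSpec",
    "CellDims",
    "VolumeBudget",
    "GeometrySolution",
    "tau_uniform_cubes",
    "uniform_cell_halfwidth",
    "omega_of_geometry",
    "scale_factor_A",
    "void_ratio_B",
    "ccv_void_width",
    "etv_void_width",
    "etv_void_volume",
    "porosity_of_dims",
    "constant_bounding_w",
    "volume_budget",
    "dims_from_omega",
    "dims_from_a",
]


class ModelKind(str, enum.Enum):
    """The three lattice families handled by the package."""

    UNIFORM = "uniform"
    CCV = "ccv"
    ETV = "etv"


@dataclass(frozen=True)
class ModelSpec:
    """Model family plus the two quantities fixed in every analysis.

    Parameters
    ----------
    model_kind:
        Which lattice family the spec describes.
    phi:
        Porosity (ISS volume fraction of the bounding cube), in (0, 1).
    w:
        Sheet half-width in µm; adjacent cells are separated by 2w.
    """

    model_kind: ModelKind
    phi: float
    w: float

    def __post_init__(self):
        if not (0.0 < self.phi < 1.0):
            raise DomainError(f"porosity must lie in (0, 1), got {self.phi}")
        if self.w <= 0.0:
            raise DomainError(f"sheet half-width must be positive, got {self.w}")


@dataclass(frozen=True)
class CellDims:
    """Length quartet describing one cell: (a, b, w, p) in µm.

    ``a`` is the basic cubic cell half-width, ``b`` the void width
    (corner-cube side, and tunnel cross-section side for ETV; 0 for a
    uniform lattice), ``w`` the sheet half-width and ``p = a + w`` the
    bounding cube half-width.
    """

    a: float
    b: float
    w: float

    def __post_init__(self):
        if self.a <= 0 or self.w <= 0:
            raise DomainError("a and w must be positive")
        if not (0.0 <= self.b < self.a):
            raise GeometryError(
                f"void width must satisfy 0 <= b < a, got b={self.b}, a={self.a}"
            )

    @property
    def p(self) -> float:
        """Bounding cube half-width, exactly a + w."""
        return self.a + self.w


@dataclass(frozen=True)
class VolumeBudget:
    """Volumes (µm³) inside one bounding cube, and the void/sheet ratio."""

    V_a: float  # basic cell volume, 8 a^3
    V_p: float  # bounding cube volume, 8 p^3
    V_s: float  # sheet volume, V_p - V_a
    V_v: float  # total void volume
    Omega: float  # V_v / V_s


@dataclass(frozen=True)
class GeometrySolution:
    """Dimensionless solution of the inverse geometry problem.

    ``A = a / w`` (scale factor), ``B = b / a`` (CCV void ratio; None for
    models where the factorisation does not apply), and the intermediate
    ``gamma = (1 - phi)^(1/3)`` of the uniform-lattice limit.
    """

    A: float
    B: float | None
    gamma: float


def tau_uniform_cubes(phi: float, corrected: bool = True) -> float:
    """Geometrical tortuosity of a zero-void uniform cubic lattice.

    The uncorrected form is ``tau_g = sqrt((3 - phi)/2)``; the corrected
    form adds the small Monte Carlo refinement ``0.07 phi (1 - phi)``.
    Both tend to sqrt(3/2) ~ 1.2247 as phi -> 0 and to 1 as phi -> 1.
    """
    if not (0.0 <= phi <= 1.0):
        raise DomainError(f"porosity must lie in [0, 1], got {phi}")
    tau = math.sqrt((3.0 - phi) / 2.0)
    if corrected:
        tau += 0.07 * phi * (1.0 - phi)
    return tau


def _gamma(phi: float) -> float:
    return (1.0 - phi) ** (1.0 / 3.0)


def uniform_cell_halfwidth(phi: float, w: float) -> float:
    """Cell half-width a for a uniform cubic lattice of porosity phi.

    Solves a/w = gamma / (1 - gamma) with gamma = (1 - phi)^(1/3):
    the unique zero-void lattice with sheet half-width ``w``.
    """
    if not (0.0 < phi < 1.0):
        raise DomainError(f"porosity must lie in (0, 1), got {phi}")
    if w <= 0:
        raise DomainError(f"sheet half-width must be positive, got {w}")
    g = _gamma(phi)
    return w * g / (1.0 - g)


def omega_of_geometry(a: float, w: float, phi: float, exact: bool = True) -> float:
    """Void/sheet volume ratio Omega implied by (a, w, phi).

    With p = a + w,

        Omega = (a^3 - (1 - phi) p^3) / (p^3 - a^3)           (exact)
        Omega ~ (a/w) * phi/3 - (1 - phi)                     (approximate)

    The approximation holds for a/w >> 1.  A negative exact Omega means
    the requested porosity is reached by sheets alone before any void is
    carved; that is reported as :class:`NoVoidSolutionError` with the
    offending value attached.
    """
    if a <= 0 or w <= 0:
        raise DomainError("a and w must be positive")
    if not (0.0 < phi < 1.0):
        raise DomainError(f"porosity must lie in (0, 1), got {phi}")
    if not exact:
        return (a / w) * phi / 3.0 - (1.0 - phi)
    p3 = (a + w) ** 3
    a3 = a**3
    omega = (a3 - (1.0 - phi) * p3) / (p3 - a3)
    if -1e-10 < omega < 0.0:  # cancellation at the uniform-lattice limit
        return 0.0
    if omega < 0.0:
        raise NoVoidSolutionError(
            f"geometry has no voids at this porosity (Omega = {omega:.6g} < 0); "
            "the sheets alone exceed the requested ISS fraction",
            value=omega,
        )
    return omega


def scale_factor_A(omega: float, phi: float) -> float:
    """Dimensionless scale factor A = a/w reproducing Omega at porosity phi.

    A = { [ (1 + Omega) / (1 + Omega - phi) ]^(1/3) - 1 }^(-1).

    At Omega = 0 this reduces to the uniform-lattice ratio
    gamma / (1 - gamma).  Valid for any sheet half-width: a = A w.
    """
    if omega < 0:
        raise DomainError(f"Omega must be non-negative, got {omega}")
    if not (0.0 < phi < 1.0):
        raise DomainError(f"porosity must lie in (0, 1), got {phi}")
    denom = 1.0 + omega - phi
    if denom <= 0.0:
        raise DomainError(f"need 1 + Omega - phi > 0, got {denom}")
    root = ((1.0 + omega) / denom) ** (1.0 / 3.0) - 1.0
    if root <= 0.0:
        raise DomainError("scale factor undefined: (1+Omega)/(1+Omega-phi) <= 1")
    return 1.0 / root


def void_ratio_B(omega: float, phi: float) -> float:
    """CCV void ratio B = b/a = { Omega phi / (1 + Omega - phi) }^(1/3)."""
    if omega < 0:
        raise DomainError(f"Omega must be non-negative, got {omega}")
    if not (0.0 < phi < 1.0):
        raise DomainError(f"porosity must lie in (0, 1), got {phi}")
    denom = 1.0 + omega - phi
    if denom <= 0.0:
        raise DomainError(f"need 1 + Omega - phi > 0, got {denom}")
    return (omega * phi / denom) ** (1.0 / 3.0)


def ccv_void_width(a: float, w: float, phi: float) -> float:
    """Corner-cube void side b for the CCV model.

    b = a { 1 - (1 - phi) (1 + w/a)^3 }^(1/3); the brace term is the
    void volume fraction of the basic cell and must be non-negative.
    """
    if a <= 0 or w <= 0:
        raise DomainError("a and w must be positive")
    if not (0.0 < phi < 1.0):
        raise DomainError(f"porosity must lie in (0, 1), got {phi}")
    brace = 1.0 - (1.0 - phi) * (1.0 + w / a) ** 3
    if -1e-9 < brace < 0.0:  # cancellation at the uniform-lattice limit
        return 0.0
    if brace < 0.0:
        raise NoVoidSolutionError(
            f"no CCV solution: sheets alone exceed porosity {phi} "
            f"(brace term {brace:.6g} < 0)",
            value=brace,
        )
    b = a * brace ** (1.0 / 3.0)
    if b >= a:
        raise GeometryError(
            f"CCV voids would consume the cell (b={b:.6g} >= a={a:.6g})"
        )
    return b


def etv_void_volume(a: float, b: float) -> float:
    """Total ETV void volume: 12 edge tunnels of volume 2(a-b)b² plus
    8 corner cubes of volume b³, i.e. V_v = 8(3a - 2b)b²."""
    return 8.0 * (3.0 * a - 2.0 * b) * b * b


def etv_void_width(a: float, w: float, phi: float, xtol: float = 1e-14) -> float:
    """Tunnel/corner void width b for the ETV model.

    Solves the cubic  2b³ - 3ab² + c = 0  with
    c = a³ - (1 - phi)(a + w)³, taking the unique root in (0, a): the
    polynomial is strictly decreasing there (derivative 6b(b - a) < 0),
    so when 0 < c < a³ exactly one physically admissible root exists.
    c = 0 is the uniform-lattice limit and returns b = 0.
    """
    if a <= 0 or w <= 0:
        raise DomainError("a and w must be positive")
    if not (0.0 < phi < 1.0):
        raise DomainError(f"porosity must lie in (0, 1), got {phi}")
    c = a**3 - (1.0 - phi) * (a + w) ** 3
    if c < 0.0:
        raise NoVoidSolutionError(
            f"no ETV solution: sheets alone exceed porosity {phi} "
            f"(constant term {c:.6g} < 0)",
            value=c,
        )
    if c == 0.0:
        return 0.0
    if c >= a**3:
        raise GeometryError(
            f"ETV voids would consume the cell (constant term {c:.6g} >= a^3)"
        )

    def f(b: float) -> float:
        return 2.0 * b**3 - 3.0 * a * b**2 + c

    # f(0) = c > 0, f(a) = c - a^3 < 0, strictly decreasing in between.
    return float(brentq(f, 0.0, a, xtol=xtol, rtol=8.881784197001252e-16))


def porosity_of_dims(dims: CellDims, model_kind: ModelKind) -> float:
    """Porosity implied by a cell dimension quartet (round-trip check).

    CCV:     phi = 1 - (a³ - b³) / p³
    ETV:     phi = 1 - (2b³ - 3ab² + a³) / p³
    UNIFORM: the CCV formula with b = 0.
    """
    a, b, p = dims.a, dims.b, dims.p
    if model_kind is ModelKind.UNIFORM:
        if b != 0.0:
            raise GeometryError("uniform lattice requires b = 0")
        solid = a**3
    elif model_kind is ModelKind.CCV:
        solid = a**3 - b**3
    elif model_kind is ModelKind.ETV:
        solid = 2.0 * b**3 - 3.0 * a * b**2 + a**3
    else:  # pragma: no cover - enum is exhaustive
        raise DomainError(f"unknown model kind {model_kind}")
    return 1.0 - solid / p**3


def constant_bounding_w(p_ref: float, A_state: float) -> float:
    """Sheet half-width keeping the bounding cube fixed across a state change.

    If a brain-state transition must preserve the bounding cube half-width
    ``p_ref`` while the new state has scale factor ``A_state = a/w``, then
    p = a + w = (A + 1) w forces  w = p_ref / (1 + A_state).
    """
    if p_ref < 0:
        raise DomainError(f"reference p must be non-negative, got {p_ref}")
    if A_state <= 0:
        raise DomainError(f"scale factor must be positive, got {A_state}")
    return p_ref / (1.0 + A_state)


def solid_volume(dims: CellDims, model_kind: ModelKind) -> float:
    """Volume of the solid cell (basic cube minus voids), µm³."""
    a, b = dims.a, dims.b
    if model_kind is ModelKind.UNIFORM:
        return 8.0 * a**3
    if model_kind is ModelKind.CCV:
        return 8.0 * a**3 - 8.0 * b**3
    if model_kind is ModelKind.ETV:
        return 8.0 * a**3 - etv_void_volume(a, b)
    raise DomainError(f"unknown model kind {model_kind}")  # pragma: no cover


def volume_budget(dims: CellDims, model_kind: ModelKind) -> VolumeBudget:
    """Volume bookkeeping for one bounding cube."""
    a, p = dims.a, dims.p
    V_a = 8.0 * a**3
    V_p = 8.0 * p**3
    V_s = V_p - V_a
    V_v = V_a - solid_volume(dims, model_kind)
    if V_v < 0:
        raise GeometryError(f"negative void volume {V_v}")
    return VolumeBudget(V_a=V_a, V_p=V_p, V_s=V_s, V_v=V_v, Omega=V_v / V_s)


def dims_from_omega(spec: ModelSpec, omega: float) -> CellDims:
    """Resolve (a, b) from (model, phi, w, Omega) via the scale factor A."""
    A = scale_factor_A(omega, spec.phi)
    a = A * spec.w
    return dims_from_a(spec, a)


def dims_from_a(spec: ModelSpec, a: float) -> CellDims:
    """Resolve the void width b from (model, phi, w, a)."""
    if spec.model_kind is ModelKind.UNIFORM:
        # a is determined by (phi, w); accept only a consistent value.
        a_expected = uniform_cell_halfwidth(spec.phi, spec.w)
        if abs(a - a_expected) > 1e-9 * a_expected:
            raise GeometryError(
                f"uniform lattice at phi={spec.phi}, w={spec.w} requires "
                f"a={a_expected:.9g}, got {a:.9g}"
            )
        return CellDims(a=a, b=0.0, w=spec.w)
    if spec.model_kind is ModelKind.CCV:
        b = ccv_void_width(a, spec.w, spec.phi)
    else:
        b = etv_void_width(a, spec.w, spec.phi)
    return CellDims(a=a, b=b, w=spec.w)


def geometry_solution(spec: ModelSpec, omega: float) -> GeometrySolution:
    """Dimensionless (A, B, gamma) record for a spec at a given Omega."""
    A = scale_factor_A(omega, spec.phi)
    B = void_ratio_B(omega, spec.phi) if spec.model_kind is ModelKind.CCV else None
    return GeometrySolution(A=A, B=B, gamma=_gamma(spec.phi))
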