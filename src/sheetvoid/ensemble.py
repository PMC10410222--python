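"""Periodic 3-D ensembles of solid cells with an ISS complement.

One solid cell is a cube of half-width ``a`` with voids cut out of it
(8 corner cubes for CCV; those plus 12 edge prisms for ETV).  Cells sit
at lattice positions ((2i+1)p, (2j+1)p, (2k+1)p) so that the ensemble
centre -- the release point of every simulation -- is a lattice VERTEX
where the corner cavities of 8 neighbouring cells and three crossing
sheets meet.

Geometry is stored once in the local frame of a single cell; all
spatial queries fold coordinates by the lattice period 2p, so memory is
O(1) in ensemble size.

Because every solid boundary face lies on one of the local planes
x_i = ±a or x_i = ±(a - b), the cell decomposes exactly into a 3x3x3
grid of axis-aligned blocks with breakpoints (-a, -(a-b), a-b, a) per
axis.  Classification, meshing and the walker's ray tracing all exploit
this block structure.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DomainError, GeometryError
from .relations import (
    CellDims,
    ModelKind,
    ModelSpec,
    porosity_of_dims,
    solid_volume,
)

__all__ = [
    "Region",
    "CellGeometry",
    "EnsembleGeometry",
    "build_cell",
    "build_ensemble",
    "classify_point",
    "classify_points",
    "estimate_porosity_mc",
    "export_mesh",
]


class Region(enum.IntEnum):
    """Point taxonomy: solid cell interior, void cut-out, ISS sheet, or
    beyond the ensemble bounds."""

    SOLID = 0
    VOID = 1
    SHEET = 2
    OUTSIDE = 3


def _solid_mask(model_kind: ModelKind) -> np.ndarray:
    """3x3x3 boolean mask of the cell blocks that are solid.

    Block index 1 is the central slab [-(a-b), a-b]; indices 0 and 2 are
    the outer slabs of thickness b.  A block is a void cut-out when all
    three indices are outer (CCV corner cube) or at least two are outer
    (ETV corner cube or edge prism).
    """
    mask = np.ones((3, 3, 3), dtype=bool)
    for i in range(3):
        for j in range(3):
            for k in range(3):
                outer = (i != 1) + (j != 1) + (k != 1)
                if model_kind is ModelKind.CCV and outer == 3:
                    mask[i, j, k] = False
                elif model_kind is ModelKind.ETV and outer >= 2:
                    mask[i, j, k] = False
    return mask


@dataclass(frozen=True)
class CellGeometry:
    """One solid cell in its local frame, with its void cut-out boxes.

    ``cut_boxes`` lists the axis-aligned void boxes as (lo, hi) corner
    pairs; ``breaks`` are the per-axis block breakpoints
    (-a, -(a-b), a-b, a) and ``solid_blocks`` the 3x3x3 occupancy mask.
    """

    spec: ModelSpec
    dims: CellDims
    cut_boxes: tuple = field(repr=False)
    breaks: np.ndarray = field(repr=False)
    solid_blocks: np.ndarray = field(repr=False)

    @property
    def model_kind(self) -> ModelKind:
        return self.spec.model_kind

    @property
    def solid_volume(self) -> float:
        return solid_volume(self.dims, self.model_kind)


def _cut_boxes(dims: CellDims, model_kind: ModelKind) -> tuple:
    a, b = dims.a, dims.b
    if model_kind is ModelKind.UNIFORM or b == 0.0:
        return ()
    boxes = []
    inner = a - b
    signs = [-1.0, 1.0]
    # 8 corner cubes of side b, one per octant, occupying [a-b, a] in
    # each signed coordinate.
    for sx in signs:
        for sy in signs:
            for sz in signs:
                lo = np.minimum([sx * inner, sy * inner, sz * inner],
                                [sx * a, sy * a, sz * a])
                hi = np.maximum([sx * inner, sy * inner, sz * inner],
                                [sx * a, sy * a, sz * a])
                boxes.append((lo, hi))
    if model_kind is ModelKind.ETV:
        # 12 edge prisms of cross-section b x b and length 2(a-b),
        # centred on each cube edge; they meet the corner cubes at
        # shared faces without overlap.
        for axis in range(3):
            u, v = [d for d in range(3) if d != axis]
            for su in signs:
                for sv in signs:
                    lo = np.empty(3)
                    hi = np.empty(3)
                    lo[axis], hi[axis] = -inner, inner
                    lo[u], hi[u] = sorted((su * inner, su * a))
                    lo[v], hi[v] = sorted((sv * inner, sv * a))
                    boxes.append((np.asarray(lo), np.asarray(hi)))
    return tuple((np.asarray(lo, float), np.asarray(hi, float)) for lo, hi in boxes)


def build_cell(spec: ModelSpec, dims: CellDims) -> CellGeometry:
    """Construct the solid-cell geometry, validating spec/dims consistency.

    The dimensions must reproduce the spec porosity through the model's
    porosity formula to within 1e-6 (round-trip check).
    """
    if dims.w != spec.w:
        raise GeometryError(
            f"dims.w = {dims.w} does not match spec.w = {spec.w}"
        )
    phi_implied = porosity_of_dims(dims, spec.model_kind)
    if abs(phi_implied - spec.phi) > 1e-6:
        raise GeometryError(
            f"dims imply porosity {phi_implied:.8f} but spec requires "
            f"{spec.phi:.8f} (violated relation: phi = 1 - V_solid / (8 p^3))"
        )
    a, b = dims.a, dims.b
    breaks = np.array([-a, -(a - b), a - b, a])
    return CellGeometry(
        spec=spec,
        dims=dims,
        cut_boxes=_cut_boxes(dims, spec.model_kind),
        breaks=breaks,
        solid_blocks=_solid_mask(spec.model_kind),
    )


@dataclass(frozen=True)
class EnsembleGeometry:
    """n x n x n periodic lattice of solid cells centred on the origin.

    The origin is a lattice vertex (cell centres at odd multiples of p),
    and is also the release point of point-source simulations: the
    cavity where the corner voids of 8 cells and three sheets meet.
    """

    cell: CellGeometry
    n: int

    @property
    def period(self) -> float:
        return 2.0 * self.cell.dims.p

    @property
    def half_extent(self) -> float:
        """Half-width of the outer bounding box, n * p."""
        return self.n * self.cell.dims.p

    @property
    def release_origin(self) -> np.ndarray:
        return np.zeros(3)

    @property
    def n_cells(self) -> int:
        return self.n**3

    @property
    def phi(self) -> float:
        """Analytic ISS fraction of one period cube."""
        return 1.0 - self.cell.solid_volume / self.period**3


def build_ensemble(cell: CellGeometry, n: int) -> EnsembleGeometry:
    """Assemble an n³ ensemble; n must be even so that the centre of the
    ensemble is a lattice vertex (odd n would put it inside a solid cell)."""
    if n <= 0 or n % 2 != 0:
        raise GeometryError(
            f"cell count per axis must be a positive even number, got {n}: "
            "an odd count would place the release point inside a solid cell"
        )
    return EnsembleGeometry(cell=cell, n=n)


def _classify_local(cell: CellGeometry, loc: np.ndarray) -> Region:
    """Classify a point given in the local frame of one cell."""
    a = cell.dims.a
    ax = np.abs(loc)
    if ax.max() > a:
        return Region.SHEET
    b = cell.dims.b
    if b == 0.0:
        return Region.SOLID
    inner = a - b
    outer = int(ax[0] > inner) + int(ax[1] > inner) + int(ax[2] > inner)
    if cell.model_kind is ModelKind.CCV:
        return Region.VOID if outer == 3 else Region.SOLID
    return Region.VOID if outer >= 2 else Region.SOLID


def classify_point(ens: EnsembleGeometry, xyz) -> Region:
    """Classify a point as SOLID, VOID, SHEET or OUTSIDE.

    Points beyond the ensemble bounds are OUTSIDE; interior points are
    folded into the local frame of the nearest cell.
    """
    xyz = np.asarray(xyz, dtype=float)
    if np.abs(xyz).max() > ens.half_extent:
        return Region.OUTSIDE
    period = ens.period
    p = ens.cell.dims.p
    idx = np.floor(xyz / period)
    centre = (2.0 * idx + 1.0) * p
    return _classify_local(ens.cell, xyz - centre)


def classify_points(ens: EnsembleGeometry, xyz: np.ndarray) -> np.ndarray:
    """Vectorised :func:`classify_point` for an (n, 3) array."""
    xyz = np.asarray(xyz, dtype=float)
    p = ens.cell.dims.p
    a, b = ens.cell.dims.a, ens.cell.dims.b
    out = np.full(len(xyz), int(Region.SOLID), dtype=np.int8)
    outside = np.abs(xyz).max(axis=1) > ens.half_extent
    centre = (2.0 * np.floor(xyz / ens.period) + 1.0) * p
    loc = np.abs(xyz - centre)
    sheet = loc.max(axis=1) > a
    if b > 0.0:
        outer = (loc > (a - b)).sum(axis=1)
        if ens.cell.model_kind is ModelKind.CCV:
            void = outer == 3
        else:
            void = outer >= 2
        out[void] = int(Region.VOID)
    out[sheet] = int(Region.SHEET)
    out[outside] = int(Region.OUTSIDE)
    return out


@dataclass(frozen=True)
class PorosityEstimate:
    phi_hat: float
    ci_low: float
    ci_high: float
    n_samples: int


def estimate_porosity_mc(
    ens: EnsembleGeometry, n_samples: int = 100_000, seed: int = 0
) -> PorosityEstimate:
    """Monte Carlo porosity of one period cube with a 95% binomial CI.

    Uniform random points in a single period cube are classified; the
    ISS fraction (VOID or SHEET) estimates phi.  Validates that the
    constructed geometry realises the analytic porosity.
    """
    if n_samples < 1:
        raise DomainError("need at least one sample")
    rng = np.random.default_rng(seed)
    p = ens.cell.dims.p
    pts = rng.uniform(-p, p, size=(n_samples, 3))
    regions = classify_points(ens, pts)
    k = int(np.sum((regions == int(Region.VOID)) | (regions == int(Region.SHEET))))
    phi_hat = k / n_samples
    se = math.sqrt(max(phi_hat * (1.0 - phi_hat), 1e-12) / n_samples)
    return PorosityEstimate(
        phi_hat=phi_hat,
        ci_low=phi_hat - 1.96 * se,
        ci_high=phi_hat + 1.96 * se,
        n_samples=n_samples,
    )


# ---------------------------------------------------------------------------
# Mesh export
# ---------------------------------------------------------------------------

def _cell_boundary_quads(cell: CellGeometry):
    """Boundary rectangles of the solid, as (axis, sign, plane, (u0,u1,v0,v1)).

    Works on the 3x3x3 block decomposition: a block face belongs to the
    boundary when the block is solid and its neighbour across that face
    is not (or lies outside the cube).  Degenerate zero-area faces (b=0)
    are skipped.
    """
    br = cell.breaks
    solid = cell.solid_blocks
    quads = []
    for axis in range(3):
        u, v = (axis + 1) % 3, (axis + 2) % 3  # right-handed (u, v, axis)
        for i in range(3):
            for j in range(3):
                for k in range(3):
                    if not solid[i, j, k]:
                        continue
                    idx = [i, j, k]
                    for sign in (-1, 1):
                        nidx = idx.copy()
                        nidx[axis] += sign
                        if 0 <= nidx[axis] < 3 and solid[tuple(nidx)]:
                            continue  # interior face
                        plane = br[idx[axis] + (1 if sign > 0 else 0)]
                        u0, u1 = br[idx[u]], br[idx[u] + 1]
                        v0, v1 = br[idx[v]], br[idx[v] + 1]
                        if u1 - u0 <= 0 or v1 - v0 <= 0:
                            continue
                        quads.append((axis, sign, plane, (u0, u1, v0, v1)))
    return quads


def _quads_to_mesh(quads, offset=np.zeros(3)):
    """Triangulate boundary quads with outward-facing winding."""
    verts = []
    faces = []
    for axis, sign, plane, (u0, u1, v0, v1) in quads:
        u, v = (axis + 1) % 3, (axis + 2) % 3
        corners = []
        for uu, vv in ((u0, v0), (u1, v0), (u1, v1), (u0, v1)):
            c = np.zeros(3)
            c[axis] = plane
            c[u] = uu
            c[v] = vv
            corners.append(c + offset)
        i0 = len(verts)
        verts.extend(corners)
        # Counter-clockwise seen from the outward normal direction.
        if sign > 0:
            faces.append((i0, i0 + 1, i0 + 2))
            faces.append((i0, i0 + 2, i0 + 3))
        else:
            faces.append((i0, i0 + 2, i0 + 1))
            faces.append((i0, i0 + 3, i0 + 2))
    return np.asarray(verts), np.asarray(faces, dtype=int)


def mesh_arrays(obj: CellGeometry | EnsembleGeometry):
    """Triangle mesh (vertices, faces) of the solid surface(s), µm units.

    For an ensemble the single-cell mesh is replicated at every cell
    centre.
    """
    if isinstance(obj, CellGeometry):
        return _quads_to_mesh(_cell_boundary_quads(obj))
    cell = obj.cell
    quads = _cell_boundary_quads(cell)
    p = cell.dims.p
    all_v, all_f = [], []
    base = 0
    half = obj.n // 2
    for i in range(-half, half):
        for j in range(-half, half):
            for k in range(-half, half):
                centre = np.array([(2 * i + 1) * p, (2 * j + 1) * p, (2 * k + 1) * p])
                v, f = _quads_to_mesh(quads, offset=centre)
                all_v.append(v)
                all_f.append(f + base)
                base += len(v)
    return np.concatenate(all_v), np.concatenate(all_f)


def mesh_enclosed_volume(verts: np.ndarray, faces: np.ndarray) -> float:
    """Enclosed volume by the divergence theorem (signed tetrahedra sum)."""
    v0 = verts[faces[:, 0]]
    v1 = verts[faces[:, 1]]
    v2 = verts[faces[:, 2]]
    return float(np.sum(np.einsum("ij,ij->i", v0, np.cross(v1, v2))) / 6.0)


def export_mesh(obj: CellGeometry | EnsembleGeometry, path) -> Path:
    """Write a watertight ASCII OBJ mesh (v/f records, µm coordinates)."""
    verts, faces = mesh_arrays(obj)
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# sheetvoid solid surface mesh (units: micrometres)\n")
        for v in verts:
            fh.write(f"v {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        for f in faces:
            fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")
    return path


def geometry_summary(ens: EnsembleGeometry) -> dict:
    """JSON-serialisable summary of an ensemble's geometry."""
    d = ens.cell.dims
    return {
        "model": ens.cell.model_kind.value,
        "phi": ens.phi,
        "w_um": d.w,
        "a_um": d.a,
        "b_um": d.b,
        "p_um": d.p,
        "n_cells": ens.n_cells,
        "solid_volume_um3": ens.cell.solid_volume,
    }


def write_geometry_summary(ens: EnsembleGeometry, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(geometry_summary(ens), indent=2) + "\n")
    return path
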