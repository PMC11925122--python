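"""Electrode-array and brain-mesh geometry.

Intracranial electrodes come in three hardware kinds: subdural ``grid``
arrays (a regular rows x cols lattice on the cortical surface), subdural
``strip`` arrays (a single line of contacts), and penetrating ``depth``
probes (a collinear run of contacts along a stereotactic trajectory).
All coordinates are millimetres in a right-handed RAS frame (+x right,
+y anterior, +z superior); indices are 0-based and grid contacts are
stored row-major.

Depth probes are displayed on "omni-planar" slices: 2D image planes that
contain the probe trajectory, so every contact of the probe lies in the
slice and deep activity can be annotated like a surface view.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import trimesh

__all__ = [
    "ArrayKind",
    "ElectrodeArray",
    "SurfaceMesh",
    "OmniplanarPlane",
    "GeometryError",
    "build_grid_array",
    "build_depth_array",
    "build_strip_array",
    "omniplanar_basis",
    "read_electrode_table",
    "write_electrode_table",
    "load_mesh",
]

#: Tolerance (mm) for spacing and collinearity checks on real hardware tables.
SPACING_TOL_MM = 1e-6


class GeometryError(ValueError):
    """Raised for invalid electrode/plane geometry."""


class ArrayKind(str, Enum):
    GRID = "grid"
    STRIP = "strip"
    DEPTH = "depth"


@dataclass(frozen=True)
class ElectrodeArray:
    """One implanted electrode component.

    Parameters
    ----------
    array_id
        Hardware identifier, e.g. ``"G1"`` or ``"LAH"``.
    kind
        Grid, strip or depth.
    contacts
        ``(n, 3)`` contact positions in mm (RAS), ordered row-major for
        grids and tip-to-tail for strips/depths.
    spacing_mm
        Nominal inter-contact spacing along rows/columns (grids) or along
        the trajectory (strips/depths).
    grid_shape
        ``(rows, cols)`` for grids; ``(n, 1)`` for strips and depths.
    channel_labels
        One recording-channel label per contact.
    """

    array_id: str
    kind: ArrayKind
    contacts: np.ndarray
    spacing_mm: float
    grid_shape: tuple[int, int]
    channel_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        contacts = np.asarray(self.contacts, dtype=float)
        if contacts.ndim != 2 or contacts.shape[1] != 3:
            raise GeometryError("contacts must be an (n, 3) array")
        if not np.isfinite(contacts).all():
            raise GeometryError("contact coordinates must be finite")
        if self.spacing_mm <= 0:
            raise GeometryError("spacing_mm must be positive")
        object.__setattr__(self, "contacts", contacts)
        object.__setattr__(self, "kind", ArrayKind(self.kind))
        rows, cols = self.grid_shape
        if rows * cols != len(contacts):
            raise GeometryError(
                f"grid_shape {self.grid_shape} inconsistent with "
                f"{len(contacts)} contacts"
            )
        if not self.channel_labels:
            labels = tuple(f"{self.array_id}{i + 1}" for i in range(len(contacts)))
            object.__setattr__(self, "channel_labels", labels)
        elif len(self.channel_labels) != len(contacts):
            raise GeometryError("one channel label per contact required")
        self._check_spacing()

    # spacing/collinearity invariants; tolerance SPACING_TOL_MM
    def _check_spacing(self) -> None:
        c = self.contacts
        if len(c) < 2:
            return
        if self.kind is ArrayKind.GRID:
            rows, cols = self.grid_shape
            lat = c.reshape(rows, cols, 3)
            for diffs in (np.diff(lat, axis=0), np.diff(lat, axis=1)):
                if diffs.size:
                    d = np.linalg.norm(diffs, axis=-1)
                    if np.abs(d - self.spacing_mm).max() > SPACING_TOL_MM:
                        raise GeometryError(
                            f"{self.array_id}: adjacent grid contacts not "
                            f"{self.spacing_mm} mm apart"
                        )
        else:
            d = np.linalg.norm(np.diff(c, axis=0), axis=-1)
            if np.abs(d - self.spacing_mm).max() > SPACING_TOL_MM:
                raise GeometryError(
                    f"{self.array_id}: consecutive contacts not "
                    f"{self.spacing_mm} mm apart"
                )
            if self.kind is ArrayKind.DEPTH and len(c) > 2:
                centred = c - c.mean(axis=0)
                s = np.linalg.svd(centred, compute_uv=False)
                if s[1] > SPACING_TOL_MM:
                    raise GeometryError(f"{self.array_id}: depth contacts not collinear")

    @property
    def n_contacts(self) -> int:
        return len(self.contacts)

    @property
    def direction(self) -> np.ndarray:
        """Unit vector along a strip/depth trajectory (first -> last contact)."""
        if self.kind is ArrayKind.GRID:
            raise GeometryError("direction undefined for grids")
        if self.n_contacts < 2:
            raise GeometryError("direction undefined for a single contact")
        v = self.contacts[-1] - self.contacts[0]
        return v / np.linalg.norm(v)


@dataclass(frozen=True)
class SurfaceMesh:
    """Triangulated brain surface (vertices mm RAS, faces 0-based)."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        f = np.asarray(self.faces, dtype=int)
        if v.ndim != 2 or v.shape[1] != 3:
            raise GeometryError("vertices must be (n, 3)")
        if f.ndim != 2 or f.shape[1] != 3:
            raise GeometryError("faces must be (m, 3) triangles")
        if f.size and (f.min() < 0 or f.max() >= len(v)):
            raise GeometryError("face indices out of range")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)


@dataclass(frozen=True)
class OmniplanarPlane:
    """Slice plane parallel to a depth-probe trajectory.

    ``u`` runs along the probe, ``v`` is perpendicular in-plane; pixels are
    laid out on ``origin + (i*res)*u + (j*res)*v`` over ``extent_mm``.
    """

    origin: np.ndarray
    u: np.ndarray
    v: np.ndarray
    extent_mm: tuple[float, float] = (100.0, 100.0)
    resolution_mm: float = 1.0

    def __post_init__(self) -> None:
        o = np.asarray(self.origin, dtype=float)
        u = np.asarray(self.u, dtype=float)
        v = np.asarray(self.v, dtype=float)
        if abs(np.linalg.norm(u) - 1) > 1e-9 or abs(np.linalg.norm(v) - 1) > 1e-9:
            raise GeometryError("plane axes must be unit vectors")
        if abs(float(u @ v)) > 1e-9:
            raise GeometryError("plane axes must be orthogonal")
        if self.resolution_mm <= 0:
            raise GeometryError("resolution_mm must be positive")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "u", u)
        object.__setattr__(self, "v", v)

    @property
    def normal(self) -> np.ndarray:
        return np.cross(self.u, self.v)

    def pixel_positions(self) -> np.ndarray:
        """3D position of every pixel centre, shape ``(nu, nv, 3)``.

        The grid is centred on ``origin`` so the probe runs through the
        middle of the slice.
        """
        eu, ev = self.extent_mm
        su = np.arange(-eu / 2, eu / 2 + 1e-9, self.resolution_mm)
        sv = np.arange(-ev / 2, ev / 2 + 1e-9, self.resolution_mm)
        return (
            self.origin[None, None, :]
            + su[:, None, None] * self.u[None, None, :]
            + sv[None, :, None] * self.v[None, None, :]
        )

    def distance_to_plane(self, points: np.ndarray) -> np.ndarray:
        return np.abs((np.asarray(points, float) - self.origin) @ self.normal)


def _orthonormal(axes: Sequence[np.ndarray]) -> bool:
    a1, a2 = (np.asarray(a, float) for a in axes)
    return (
        abs(np.linalg.norm(a1) - 1) < 1e-9
        and abs(np.linalg.norm(a2) - 1) < 1e-9
        and abs(float(a1 @ a2)) < 1e-9
    )


def build_grid_array(
    rows: int,
    cols: int,
    spacing_mm: float,
    origin: Sequence[float] = (0.0, 0.0, 0.0),
    axes: tuple[Sequence[float], Sequence[float]] = ((1, 0, 0), (0, 1, 0)),
    array_id: str = "G",
) -> ElectrodeArray:
    """Regular rows x cols subdural grid, row-major on the lattice
    ``origin + i*spacing*axes[0] + j*spacing*axes[1]``."""
    if rows < 1 or cols < 1:
        raise GeometryError("rows and cols must be >= 1")
    if not _orthonormal(axes):
        raise GeometryError("grid axes must be orthonormal")
    a1, a2 = (np.asarray(a, float) for a in axes)
    ii, jj = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    contacts = (
        np.asarray(origin, float)[None, :]
        + spacing_mm * ii.ravel()[:, None] * a1
        + spacing_mm * jj.ravel()[:, None] * a2
    )
    return ElectrodeArray(array_id, ArrayKind.GRID, contacts, spacing_mm, (rows, cols))


def build_depth_array(
    n_contacts: int,
    spacing_mm: float,
    entry: Sequence[float] = (0.0, 0.0, 0.0),
    direction: Sequence[float] = (0.0, 0.0, 1.0),
    array_id: str = "D",
) -> ElectrodeArray:
    """Collinear depth probe from ``entry`` along ``direction``; total span
    ``(n_contacts - 1) * spacing_mm``."""
    if n_contacts < 1:
        raise GeometryError("n_contacts must be >= 1")
    d = np.asarray(direction, float)
    norm = np.linalg.norm(d)
    if norm < 1e-12:
        raise GeometryError("direction must be a nonzero vector")
    d = d / norm
    contacts = np.asarray(entry, float)[None, :] + spacing_mm * np.arange(n_contacts)[:, None] * d
    return ElectrodeArray(array_id, ArrayKind.DEPTH, contacts, spacing_mm, (n_contacts, 1))


def build_strip_array(
    n_contacts: int,
    spacing_mm: float,
    entry: Sequence[float] = (0.0, 0.0, 0.0),
    direction: Sequence[float] = (1.0, 0.0, 0.0),
    array_id: str = "S",
) -> ElectrodeArray:
    arr = build_depth_array(n_contacts, spacing_mm, entry, direction, array_id)
    return ElectrodeArray(
        array_id, ArrayKind.STRIP, arr.contacts, spacing_mm, (n_contacts, 1)
    )


def omniplanar_basis(
    depth: ElectrodeArray,
    normal_hint: Sequence[float] = (0.0, 1.0, 0.0),
    extent_mm: tuple[float, float] = (100.0, 100.0),
    resolution_mm: float = 1.0,
) -> OmniplanarPlane:
    """Slice plane containing a depth-probe trajectory.

    ``u`` is the probe direction; ``v`` is the hint vector Gram-Schmidt
    orthogonalised against ``u``. The hint fixes the roll of the slice
    about the probe, which the hardware does not constrain.
    """
    if depth.kind is not ArrayKind.DEPTH:
        raise GeometryError("omniplanar planes are defined for depth probes")
    if depth.n_contacts < 2:
        raise GeometryError("need >= 2 contacts to define a trajectory")
    u = depth.direction
    hint = np.asarray(normal_hint, float)
    v = hint - (hint @ u) * u
    nv = np.linalg.norm(v)
    if nv < 1e-9:
        raise GeometryError("normal_hint is parallel to the probe axis")
    v = v / nv
    origin = depth.contacts.mean(axis=0)
    return OmniplanarPlane(origin, u, v, extent_mm, resolution_mm)


# ---------------------------------------------------------------------------
# I/O: electrode tables (CSV) and surface meshes (PLY)

_TABLE_COLUMNS = ["label", "x", "y", "z", "array_id", "kind", "row", "col"]


def write_electrode_table(arrays: Sequence[ElectrodeArray], path: str | Path) -> None:
    rows = []
    for arr in arrays:
        _, cols = arr.grid_shape
        for i, (label, pos) in enumerate(zip(arr.channel_labels, arr.contacts)):
            if arr.kind is ArrayKind.GRID:
                r, c = divmod(i, cols)
            else:
                r, c = None, None
            rows.append(
                dict(
                    label=label, x=pos[0], y=pos[1], z=pos[2],
                    array_id=arr.array_id, kind=arr.kind.value, row=r, col=c,
                )
            )
    pd.DataFrame(rows, columns=_TABLE_COLUMNS).to_csv(path, index=False)


def read_electrode_table(path: str | Path) -> list[ElectrodeArray]:
    """Read a contact table (columns label,x,y,z,array_id,kind,row,col) and
    reassemble per-array geometry, inferring spacing from consecutive
    contacts."""
    df = pd.read_csv(path)
    missing = set(_TABLE_COLUMNS[:6]) - set(df.columns)
    if missing:
        raise GeometryError(f"electrode table missing columns: {sorted(missing)}")
    arrays = []
    for array_id, grp in df.groupby("array_id", sort=False):
        kind = ArrayKind(grp["kind"].iloc[0])
        contacts = grp[["x", "y", "z"]].to_numpy(float)
        if kind is ArrayKind.GRID:
            order = np.lexsort((grp["col"].to_numpy(), grp["row"].to_numpy()))
            grp = grp.iloc[order]
            contacts = contacts[order]
            rows = int(grp["row"].max()) + 1
            cols = int(grp["col"].max()) + 1
            shape = (rows, cols)
            spacing = float(np.linalg.norm(contacts[1] - contacts[0])) if cols > 1 else (
                float(np.linalg.norm(contacts[cols] - contacts[0])) if rows > 1 else 1.0
            )
        else:
            shape = (len(contacts), 1)
            spacing = (
                float(np.linalg.norm(contacts[1] - contacts[0]))
                if len(contacts) > 1
                else 1.0
            )
        arrays.append(
            ElectrodeArray(
                str(array_id), kind, contacts, spacing, shape,
                tuple(grp["label"].astype(str)),
            )
        )
    return arrays


def load_mesh(path: str | Path) -> SurfaceMesh:
    """Load a triangulated surface from PLY (ASCII or binary little-endian)."""
    tm = trimesh.load_mesh(str(path), process=False)
    return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces))


def save_mesh(mesh: SurfaceMesh, path: str | Path, ascii_ply: bool = True) -> None:
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    tm.export(str(path), encoding="ascii" if ascii_ply else "binary")


def validate_arrays(arrays: Sequence[ElectrodeArray]) -> list[str]:
    """Human-readable summary lines; construction already enforced invariants."""
    lines = []
    for arr in arrays:
        span = math.dist(arr.contacts[0], arr.contacts[-1]) if arr.n_contacts > 1 else 0.0
        lines.append(
            f"{arr.array_id}: {arr.kind.value}, {arr.n_contacts} contacts, "
            f"{arr.spacing_mm:g} mm spacing, shape {arr.grid_shape}, "
            f"span {span:.1f} mm"
        )
    return lines
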