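"""Contour-stitched surface reconstruction and enclosed-volume computation.

Per-slice binary masks are turned into a closed triangle mesh in four steps:
sub-pixel boundary extraction (marching squares at iso-level 0.5), uniform
arc-length resampling, cyclic point correspondence between adjacent slices,
and quad-strip stitching with centroid-fan end caps. The synovial tissue
volume is the volume enclosed by the resulting watertight surface, computed
by the divergence theorem as a signed sum of origin tetrahedra.

All coordinates are physical millimetres: (x, y) in the transverse plane,
z along the probe sweep. Contours are counter-clockwise when viewed from
+z, which makes all face normals point outward.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from skimage import measure

__all__ = [
    "Contour",
    "ContourStack",
    "StitchedSurface",
    "GeometryError",
    "OpenSurfaceError",
    "ReconstructionError",
    "extract_contours",
    "largest_contour",
    "resample_contour",
    "align_contours",
    "stitch",
    "enclosed_volume",
    "masks_to_surface",
    "save_mesh",
    "contours_to_json",
]


class GeometryError(ValueError):
    """Degenerate geometry (zero-perimeter contour, too few points)."""


class OpenSurfaceError(ValueError):
    """Enclosed volume requested for a surface that is not watertight."""


class ReconstructionError(ValueError):
    """Not enough usable slices to reconstruct a surface."""


def _signed_area(points: np.ndarray) -> float:
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass(frozen=True)
class Contour:
    """Closed CCW polyline in its transverse plane.

    ``points`` is an (n, 2) array of (x, y) in mm, without the closing
    duplicate of the first point; ``z`` is the plane position in mm.
    """

    points: np.ndarray
    z: float

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
            raise GeometryError(f"contour needs >= 3 (x, y) points, got {pts.shape}")
        closed = np.vstack([pts, pts[:1]])
        if (np.linalg.norm(np.diff(closed, axis=0), axis=1) == 0).any():
            raise GeometryError("contour has consecutive duplicate points")
        if _signed_area(pts) <= 0:
            raise GeometryError("contour must be counter-clockwise (signed area > 0)")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "z", float(self.z))

    def __len__(self) -> int:
        return len(self.points)

    @property
    def area(self) -> float:
        """Enclosed polygon area, mm^2 (shoelace)."""
        return _signed_area(self.points)

    @property
    def perimeter(self) -> float:
        closed = np.vstack([self.points, self.points[:1]])
        return float(np.linalg.norm(np.diff(closed, axis=0), axis=1).sum())

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)


@dataclass(frozen=True)
class ContourStack:
    """Contours ordered by strictly increasing z, one point count."""

    contours: list

    def __post_init__(self) -> None:
        cs = list(self.contours)
        if len(cs) >= 2:
            zs = [c.z for c in cs]
            if any(b <= a for a, b in zip(zs, zs[1:])):
                raise ValueError("contour z positions must be strictly increasing")
        counts = {len(c) for c in cs}
        if len(counts) > 1:
            raise ValueError(f"contours must share one point count, got {counts}")
        object.__setattr__(self, "contours", cs)

    def __len__(self) -> int:
        return len(self.contours)

    def __iter__(self):
        return iter(self.contours)


@dataclass(frozen=True)
class StitchedSurface:
    """Triangle mesh; vertices (V, 3) mm, faces (F, 3) vertex indices."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=np.float64)
        f = np.asarray(self.faces, dtype=np.int64)
        if v.ndim != 2 or v.shape[1] != 3 or f.ndim != 2 or f.shape[1] != 3:
            raise ValueError("vertices must be (V, 3), faces (F, 3)")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    def edge_counts(self) -> dict:
        counts: dict[tuple[int, int], int] = {}
        for a, b, c in self.faces:
            for e in ((a, b), (b, c), (c, a)):
                key = (min(e), max(e))
                counts[key] = counts.get(key, 0) + 1
        return counts

    @property
    def closed(self) -> bool:
        """Watertight: every undirected edge borders exactly two faces."""
        return all(n == 2 for n in self.edge_counts().values())

    def euler_characteristic(self) -> int:
        used = np.unique(self.faces)
        return int(used.size - len(self.edge_counts()) + len(self.faces))


# ---------------------------------------------------------------------------
# contour extraction and processing

def extract_contours(
    mask: np.ndarray, z: float, spacing: tuple[float, float]
) -> list[Contour]:
    """Sub-pixel iso-contours of a binary mask at level 0.5, in mm, CCW.

    ``spacing`` is (dy, dx). The mask is zero-padded by one pixel first so
    foreground touching the image edge still yields closed loops. Components
    tracing to fewer than 3 distinct points are discarded.
    """
    m = (np.asarray(mask) > 0.5).astype(np.float64)
    if not m.any():
        return []
    dy, dx = spacing
    padded = np.pad(m, 1)
    out: list[Contour] = []
    for rc in measure.find_contours(padded, 0.5):
        if len(rc) < 4 or not np.allclose(rc[0], rc[-1]):
            continue  # open trace (cannot occur after padding) or degenerate
        rc = rc[:-1] - 1.0  # drop closing duplicate, undo pad offset
        pts = np.column_stack([rc[:, 1] * dx, rc[:, 0] * dy])
        # drop consecutive duplicates introduced by exact grid crossings
        keep = np.ones(len(pts), dtype=bool)
        keep[1:] = np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-12
        if np.linalg.norm(pts[0] - pts[keep][-1]) <= 1e-12:
            keep[np.nonzero(keep)[0][-1]] = False
        pts = pts[keep]
        if len(pts) < 3:
            continue
        if _signed_area(pts) < 0:
            pts = pts[::-1]
        if _signed_area(pts) == 0:
            continue
        out.append(Contour(points=pts, z=z))
    return out


def largest_contour(contours: list) -> Contour | None:
    """Contour of maximal enclosed area; ties keep the first in scan order.

    Returns ``None`` for an empty list (empty-slice signal, not an error).
    """
    if not contours:
        return None
    areas = [c.area for c in contours]
    return contours[int(np.argmax(areas))]


def resample_contour(c: Contour, n_points: int) -> Contour:
    """``n_points`` equally spaced by arc length, starting at point 0."""
    if n_points < 3:
        raise ValueError("n_points must be >= 3")
    closed = np.vstack([c.points, c.points[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    perimeter = s[-1]
    if perimeter <= 0:
        raise GeometryError("zero-perimeter contour cannot be resampled")
    targets = np.arange(n_points) * perimeter / n_points
    x = np.interp(targets, s, closed[:, 0])
    y = np.interp(targets, s, closed[:, 1])
    return Contour(points=np.column_stack([x, y]), z=c.z)


def align_contours(c1: Contour, c2: Contour) -> int:
    """Cyclic offset k minimising sum_i |c1[i] - c2[(i+k) % n]|^2.

    Exhaustive over all n offsets (orientation is preserved); ties resolve
    to the smallest offset.
    """
    if len(c1) != len(c2):
        raise ValueError(f"point counts differ: {len(c1)} vs {len(c2)}")
    n = len(c1)
    p1, p2 = c1.points, c2.points
    costs = np.empty(n)
    for k in range(n):
        d = p1 - np.roll(p2, -k, axis=0)
        costs[k] = np.einsum("ij,ij->", d, d)
    return int(np.argmin(costs))


# ---------------------------------------------------------------------------
# stitching

def _ring_vertices(c: Contour) -> np.ndarray:
    return np.column_stack([c.points, np.full(len(c), c.z)])


def stitch(stack: ContourStack) -> StitchedSurface:
    """Join adjacent contours as triangulated quad strips; cap both ends.

    Adjacent rings are first brought into cyclic correspondence with
    :func:`align_contours` (offsets accumulate down the stack). End caps are
    triangle fans to the ring centroid. With CCW rings the construction
    yields consistently outward-facing normals and a watertight mesh.
    """
    if len(stack) < 2:
        raise ReconstructionError("stitching needs at least 2 contours")
    n = len(stack.contours[0])
    rings = []
    prev = None
    for c in stack:
        pts = c.points
        if prev is not None:
            k = align_contours(prev, c)
            pts = np.roll(pts, -k, axis=0)
            c = Contour(points=pts, z=c.z)
        rings.append(c)
        prev = c

    verts = [_ring_vertices(c) for c in rings]
    vertices = np.vstack(verts)
    faces = []
    for r in range(len(rings) - 1):
        b = r * n  # bottom ring offset
        t = (r + 1) * n
        for i in range(n):
            j = (i + 1) % n
            faces.append((b + i, b + j, t + j))
            faces.append((b + i, t + j, t + i))

    # end caps: fan to centroid; bottom wound to face -z, top to face +z
    c_bot = rings[0].centroid
    c_top = rings[-1].centroid
    bot_idx = len(vertices)
    top_idx = len(vertices) + 1
    vertices = np.vstack([
        vertices,
        [c_bot[0], c_bot[1], rings[0].z],
        [c_top[0], c_top[1], rings[-1].z],
    ])
    base_top = (len(rings) - 1) * n
    for i in range(n):
        j = (i + 1) % n
        faces.append((bot_idx, j, i))
        faces.append((top_idx, base_top + i, base_top + j))

    return StitchedSurface(vertices=vertices, faces=np.asarray(faces))


def enclosed_volume(surface: StitchedSurface) -> float:
    """Enclosed volume in mm^3 via the divergence theorem.

    Signed volumes of tetrahedra from the origin to each face are summed;
    the absolute value makes the result independent of global orientation,
    and the construction is exactly invariant to rigid motion.
    """
    if not surface.closed:
        raise OpenSurfaceError("surface is not watertight; volume is undefined")
    v = surface.vertices
    a = v[surface.faces[:, 0]]
    b = v[surface.faces[:, 1]]
    c = v[surface.faces[:, 2]]
    return abs(float(np.einsum("ij,ij->", a, np.cross(b, c))) / 6.0)


# ---------------------------------------------------------------------------
# full mask-stack pipeline

def _interpolate_ring(c1: Contour, c2: Contour, z: float) -> Contour:
    """Linear blend of two aligned rings at intermediate z."""
    t = (z - c1.z) / (c2.z - c1.z)
    k = align_contours(c1, c2)
    p2 = np.roll(c2.points, -k, axis=0)
    return Contour(points=(1 - t) * c1.points + t * p2, z=z)


def masks_to_surface(
    stack,
    masks,
    interpolate_gaps: bool = True,
    n_points: int = 64,
) -> tuple[StitchedSurface, float, list[str]]:
    """Reconstruct a closed surface and its volume from per-slice masks.

    Pipeline: extract -> largest component -> resample -> stitch -> volume.
    Empty slices at the ends are dropped. Interior empty slices are bridged
    by linearly interpolating the two flanking rings when
    ``interpolate_gaps``; otherwise the stack is split at the gap and the
    largest sub-surface is reported. Returns (surface, volume mm^3,
    warnings).
    """
    if len(masks) != len(stack):
        raise ValueError(f"need {len(stack)} masks, got {len(masks)}")
    warnings: list[str] = []
    zs = stack.z_positions_mm()
    rings: list[Contour | None] = []
    for i, (mask, z) in enumerate(zip(masks, zs)):
        cs = extract_contours(mask, float(z), stack.in_plane_spacing)
        best = largest_contour(cs)
        if best is None:
            rings.append(None)
            warnings.append(f"slice {i}: empty mask")
            continue
        if len(cs) > 1:
            warnings.append(
                f"slice {i}: {len(cs) - 1} smaller component(s) dropped"
            )
        rings.append(resample_contour(best, n_points))

    present = [i for i, r in enumerate(rings) if r is not None]
    if len(present) < 2:
        raise ReconstructionError(
            f"only {len(present)} nonempty slice(s); need at least 2"
        )
    first, last = present[0], present[-1]
    rings = rings[first: last + 1]
    zs_used = zs[first: last + 1]

    if interpolate_gaps:
        filled = []
        for i, r in enumerate(rings):
            if r is not None:
                filled.append(r)
                continue
            prev_i = max(j for j in range(i) if rings[j] is not None)
            next_i = min(j for j in range(i + 1, len(rings)) if rings[j] is not None)
            filled.append(
                _interpolate_ring(rings[prev_i], rings[next_i], float(zs_used[i]))
            )
            warnings.append(f"slice {first + i}: gap bridged by interpolation")
        surface = stitch(ContourStack(contours=filled))
        return surface, enclosed_volume(surface), warnings

    # split at gaps, keep the largest sub-surface
    runs: list[list[Contour]] = [[]]
    for r in rings:
        if r is None:
            if runs[-1]:
                runs.append([])
        else:
            runs[-1].append(r)
    candidates = [run for run in runs if len(run) >= 2]
    if not candidates:
        raise ReconstructionError("no contiguous run of >= 2 nonempty slices")
    best_surface, best_volume = None, -1.0
    for run in candidates:
        s = stitch(ContourStack(contours=run))
        v = enclosed_volume(s)
        if v > best_volume:
            best_surface, best_volume = s, v
    if len(candidates) > 1:
        warnings.append(
            f"stack split into {len(candidates)} runs; largest volume reported"
        )
    return best_surface, best_volume, warnings


# ---------------------------------------------------------------------------
# export

def save_mesh(surface: StitchedSurface, path: str) -> None:
    """Write an ASCII OBJ or PLY mesh, by file extension."""
    p = str(path)
    if p.endswith(".obj"):
        with open(p, "w") as fh:
            for v in surface.vertices:
                fh.write(f"v {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
            for f in surface.faces:
                fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")
    elif p.endswith(".ply"):
        with open(p, "w") as fh:
            fh.write(
                "ply\nformat ascii 1.0\n"
                f"element vertex {len(surface.vertices)}\n"
                "property float x\nproperty float y\nproperty float z\n"
                f"element face {len(surface.faces)}\n"
                "property list uchar int vertex_indices\nend_header\n"
            )
            for v in surface.vertices:
                fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
            for f in surface.faces:
                fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
    else:
        raise ValueError(f"unsupported mesh format: {p} (use .obj or .ply)")


def contours_to_json(stack: ContourStack, path: str) -> None:
    payload = [
        {"z_mm": c.z, "points_mm": c.points.tolist()} for c in stack
    ]
    with open(str(path), "w") as fh:
        json.dump(payload, fh)
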