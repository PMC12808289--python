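"""En-face alignment and orthographic silhouettes.

The measurement view looks down the bone's centerline: a two-point line
whose proximal endpoint sits anterior to the epiphysis and whose distal
endpoint lies inside the metaphysis.  When the scene is viewed along that
line the two endpoints project onto the same image point — the clinical
"line collapses to a point" criterion — and the proximal end-plate is seen
face-on.  Areas are measured on orthographic silhouettes so that the
epiphysis/metaphysis pixel-count ratio is independent of the rendering
resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np

from .errors import GeometryError, LabelError
from .grids import LabelGrid, _as_vec3

@dataclass(frozen=True)
class Centerline:
    """Ordered pair of physical points (mm): proximal, then distal."""

    proximal: Tuple[float, float, float]
    distal: Tuple[float, float, float]

    def __post_init__(self):
        p = _as_vec3(self.proximal, "proximal")
        d = _as_vec3(self.distal, "distal")
        object.__setattr__(self, "proximal", tuple(float(x) for x in p))
        object.__setattr__(self, "distal", tuple(float(x) for x in d))
        if self.length <= 1.0:
            raise GeometryError(
                f"centerline endpoints coincide or are closer than 1 mm (length {self.length:.3g})"
            )

    @property
    def direction(self) -> np.ndarray:
        """Unit vector from distal toward proximal (the viewing direction)."""
        v = np.asarray(self.proximal) - np.asarray(self.distal)
        return v / np.linalg.norm(v)

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.asarray(self.proximal) - np.asarray(self.distal)))


@dataclass(frozen=True)
class EnFaceFrame:
    """Right-handed orthonormal viewing frame: (u, v, view_axis)."""

    view_axis: np.ndarray
    in_plane_u: np.ndarray
    in_plane_v: np.ndarray
    pixel_size: float

    def __post_init__(self):
        for name in ("view_axis", "in_plane_u", "in_plane_v"):
            object.__setattr__(self, name, _as_vec3(getattr(self, name), name))
        if self.pixel_size <= 0:
            raise GeometryError("pixel_size must be positive")
        triad = np.column_stack([self.in_plane_u, self.in_plane_v, self.view_axis])
        if not np.allclose(triad.T @ triad, np.eye(3), atol=1e-9):
            raise GeometryError("frame triad is not orthonormal")
        if not np.allclose(np.cross(self.in_plane_u, self.in_plane_v), self.view_axis, atol=1e-9):
            raise GeometryError("frame triad is not right-handed")

    def plane_coords(self, points: np.ndarray) -> np.ndarray:
        """(u, v) image-plane coordinates of physical points (..., 3)."""
        p = np.asarray(points, dtype=float)
        return np.stack([p @ self.in_plane_u, p @ self.in_plane_v], axis=-1)

    def axis_coord(self, points: np.ndarray) -> np.ndarray:
        """Signed coordinate along the view axis (larger = more proximal)."""
        return np.asarray(points, dtype=float) @ self.view_axis


@dataclass
class Silhouette:
    """Binary orthographic projection with its pixel geometry."""

    pixels: np.ndarray
    pixel_size: float
    frame: EnFaceFrame
    origin_uv: Tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise GeometryError("silhouette pixels must be a 2-D grid")

    @property
    def pixel_count(self) -> int:
        return int(self.pixels.sum())

    @property
    def area_mm2(self) -> float:
        return self.pixel_count * self.pixel_size ** 2


def make_en_face_frame(line: Centerline, pixel_size: float) -> EnFaceFrame:
    """Viewing frame whose axis runs along the centerline (distal → proximal).

    The in-plane basis is fixed deterministically: ``u`` is the grid axis
    least parallel to the view axis, orthogonalised against it
    (Gram–Schmidt); ``v`` completes the right-handed triad.  For an
    axis-aligned centerline this reproduces the remaining two grid axes.
    """
    a = line.direction
    g = np.zeros(3)
    g[int(np.argmin(np.abs(a)))] = 1.0
    u = g - np.dot(g, a) * a
    nu = np.linalg.norm(u)
    if nu < 1e-12:
        raise GeometryError("cannot build in-plane basis (degenerate direction)")
    u /= nu
    v = np.cross(a, u)
    return EnFaceFrame(view_axis=a, in_plane_u=u, in_plane_v=v, pixel_size=float(pixel_size))


def check_en_face(line: Centerline, frame: EnFaceFrame, tol_pixels: float = 1.0) -> bool:
    """True when the centerline collapses to (almost) a single image point.

    The two endpoints are projected onto the frame's image plane; the view
    is accepted when their separation is at most ``tol_pixels`` pixels.
    """
    uv = frame.plane_coords(np.array([line.proximal, line.distal]))
    sep = float(np.linalg.norm(uv[0] - uv[1]))
    return sep <= tol_pixels * frame.pixel_size


def endpoint_separation_mm(line: Centerline, frame: EnFaceFrame) -> float:
    """Image-plane distance (mm) between the projected centerline endpoints."""
    uv = frame.plane_coords(np.array([line.proximal, line.distal]))
    return float(np.linalg.norm(uv[0] - uv[1]))


def _labeled_points(seg: LabelGrid, labels) -> np.ndarray:
    ids = list(labels) if not np.isscalar(labels) else [labels]
    missing = [l for l in ids if l not in seg.legend]
    if missing:
        raise LabelError(f"labels {missing} absent from legend")
    support = seg.support(ids)
    if not support.any():
        raise LabelError(f"labels {sorted(ids)} have empty support")
    idx = np.argwhere(support)
    return seg.index_to_physical(idx)


def project_silhouette(seg: LabelGrid, labels, frame: EnFaceFrame) -> Silhouette:
    """Orthographic occupancy silhouette of the given labels.

    A pixel is set when the parallel ray bundle through its footprint
    contains at least one voxel center carrying a requested label, i.e.
    labeled voxel centers are orthographically projected onto the image
    plane and binned into the pixel lattice.  Using voxel centers (not
    voxel cubes) keeps the measured area free of the orientation-dependent
    half-voxel dilation a cube-intersection test would introduce.  Image
    bounds fit the projected bounding box plus a one-pixel margin; the
    lattice is anchored so that pixel centers coincide with projected
    voxel centers in the axis-aligned case.
    """
    ids = sorted(set(list(labels) if not np.isscalar(labels) else [labels]))
    pts = _labeled_points(seg, ids)
    px = frame.pixel_size

    uv = frame.plane_coords(pts)
    u_min, v_min = uv.min(axis=0) - 1.5 * px
    nu = int(np.ceil((uv[:, 0].max() + 1.5 * px - u_min) / px)) + 1
    nv = int(np.ceil((uv[:, 1].max() + 1.5 * px - v_min) / px)) + 1
    i = np.floor((uv[:, 0] - u_min) / px).astype(int)
    j = np.floor((uv[:, 1] - v_min) / px).astype(int)
    hit = np.zeros((nu, nv), dtype=bool)
    hit[i, j] = True
    return Silhouette(pixels=hit, pixel_size=px, frame=frame,
                      origin_uv=(float(u_min), float(v_min)))
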