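"""Quantitative outputs: area ratio, cross-section profile, distal cut,
volumes and the volume ratio.

Axial convention
----------------
Profile positions are measured along the centerline axis starting at the
*proximal* extent of the profiled labels and increasing *distally* (into
the shaft).  The distal boundary of the metaphysis is then the position of
its greatest cross-sectional diameter plus one third of the radius there:
``cut_position = s_star + d_max / 6``, and clipping removes every voxel
whose center lies distal to that plane.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .errors import ConsistencyError, GeometryError, LabelError
from .geometry import EnFaceFrame, Silhouette
from .grids import LabelGrid


@dataclass
class CrossSectionProfile:
    """Sampled metaphyseal cross-sections along the centerline axis.

    ``positions`` are mm from the proximal extent of the profiled labels,
    increasing distally; ``axis_anchor`` is the raw view-axis coordinate of
    position 0 so that cut planes can be mapped back to physical space.
    """

    positions: np.ndarray
    areas: np.ndarray
    diameters: np.ndarray
    axis_anchor: float

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.areas = np.asarray(self.areas, dtype=float)
        self.diameters = np.asarray(self.diameters, dtype=float)
        n = len(self.positions)
        if len(self.areas) != n or len(self.diameters) != n:
            raise GeometryError("profile arrays must have equal length")
        if n and np.any(np.diff(self.positions) <= 0):
            raise GeometryError("profile positions must be strictly increasing")
        if np.any(self.areas < 0) or np.any(self.diameters < 0):
            raise GeometryError("profile areas/diameters must be non-negative")


@dataclass(frozen=True)
class DistalCut:
    """The distal-boundary rule: greatest diameter plus one third of its radius."""

    s_star: float
    d_max: float
    cut_position: float
    axis_anchor: float = 0.0

    def __post_init__(self):
        if self.d_max <= 0:
            raise ConsistencyError("greatest diameter must be positive")
        if self.cut_position <= self.s_star:
            raise ConsistencyError("cut must lie distal to the greatest-diameter plane")


def _max_feret(points_uv: np.ndarray, footprint: float) -> float:
    """Greatest caliper distance across occupied voxel centers, plus one
    voxel footprint to account for the voxels' own extent."""
    if len(points_uv) == 0:
        return 0.0
    if len(points_uv) == 1:
        return footprint
    pts = points_uv
    if len(pts) > 3:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # collinear; pairwise on all points is still cheap
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.max())) + footprint


def cross_section_profile(seg: LabelGrid, labels, frame: EnFaceFrame,
                          step: float = 0.5) -> CrossSectionProfile:
    """Sample cross-sectional area and max Feret diameter along the axis.

    Each position owns the slab of labeled voxels whose centers project
    within half a step of it along the view axis (slabs tile the axis, so
    every voxel is counted exactly once); area is the slab's voxel count
    times voxel volume divided by the slab thickness, and the diameter is
    the greatest in-plane caliper distance across the slab's voxel centers
    plus one voxel footprint.
    """
    if step <= 0:
        raise GeometryError("profile step must be positive")
    ids = sorted(set(list(labels) if not np.isscalar(labels) else [labels]))
    missing = [l for l in ids if l not in seg.legend]
    if missing:
        raise LabelError(f"labels {missing} absent from legend")
    support = seg.support(ids)
    if not support.any():
        raise LabelError(f"labels {ids} have empty support")

    pts = seg.index_to_physical(np.argwhere(support))
    uv = frame.plane_coords(pts)
    ax = frame.axis_coord(pts)
    h = float(seg.spacing.mean())
    # Anchor at the material surface: voxels are cells, so the proximal
    # extent lies half a voxel beyond the outermost voxel center.  This
    # keeps clip-retained voxel counts unbiased with respect to the cut.
    anchor = float(ax.max()) + 0.5 * h
    t = anchor - ax  # distally increasing axial coordinate per voxel
    t_max = float(t.max())
    width = max(step, h)  # slab thickness; >= step so no voxel layer is missed
    positions, areas, diameters = [], [], []
    pos = 0.0
    while pos <= t_max + 1e-9:
        in_slab = np.abs(t - pos) <= 0.5 * width
        count = int(in_slab.sum())
        positions.append(pos)
        areas.append(count * seg.voxel_volume / width)
        diameters.append(_max_feret(uv[in_slab], h) if count else 0.0)
        pos += step
    return CrossSectionProfile(
        positions=np.array(positions),
        areas=np.array(areas),
        diameters=np.array(diameters),
        axis_anchor=anchor,
    )


def find_distal_cut(profile: CrossSectionProfile,
                    tie_tolerance: float = 0.0) -> DistalCut:
    """Locate the greatest-diameter plane and place the cut one third of a
    radius distal to it.

    Ties in the maximal diameter resolve to the most proximal position,
    which yields the smallest (most conservative) metaphyseal volume.
    ``tie_tolerance`` (mm) widens the tie: measured Feret diameters are
    quantized at the voxel-footprint scale, so diameters within that
    tolerance of the maximum are indistinguishable and the most proximal
    of them wins.
    """
    if len(profile.positions) == 0:
        raise ConsistencyError("empty cross-section profile")
    d_max = float(profile.diameters.max())
    if d_max <= 0:
        raise ConsistencyError("profile has no positive diameter")
    tied = np.flatnonzero(profile.diameters >= d_max - tie_tolerance)
    i_star = int(tied[0])  # most proximal among (near-)maximal diameters
    s_star = float(profile.positions[i_star])
    return DistalCut(
        s_star=s_star,
        d_max=d_max,
        cut_position=s_star + d_max / 6.0,
        axis_anchor=profile.axis_anchor,
    )


def clip_at_cut(seg: LabelGrid, frame: EnFaceFrame, cut: DistalCut) -> LabelGrid:
    """Remove every voxel whose center lies distal to the cut plane."""
    idx = np.stack(np.meshgrid(*[np.arange(s) for s in seg.shape], indexing="ij"), axis=-1)
    ax = frame.axis_coord(seg.index_to_physical(idx.reshape(-1, 3))).reshape(seg.shape)
    distal_side = ax < (cut.axis_anchor - cut.cut_position)
    if not distal_side.any():
        warnings.warn("cut plane lies beyond the grid extent; nothing clipped")
        return seg.with_labels(seg.labels.copy())
    out = seg.labels.copy()
    out[distal_side] = 0
    return seg.with_labels(out)


def segment_volume(seg: LabelGrid, labels) -> float:
    """Volume in mm³ by voxel counting: count × spacing product."""
    ids = sorted(set(list(labels) if not np.isscalar(labels) else [labels]))
    missing = [l for l in ids if l not in seg.legend]
    if missing:
        raise LabelError(f"labels {missing} absent from legend")
    return seg.count(ids) * seg.voxel_volume


def area_ratio(epi: Silhouette, meta: Silhouette) -> float:
    """Dimensionless epiphysis/metaphysis silhouette ratio by raw pixel count.

    Both silhouettes must come from the same frame and pixel size, so the
    rendering resolution cancels exactly.  An empty epiphysis gives 0 (the
    pre-ossification analogue); an empty metaphysis is a degenerate
    denominator and raises.
    """
    if abs(epi.pixel_size - meta.pixel_size) > 1e-12:
        raise GeometryError("silhouettes have different pixel sizes")
    if not (
        np.allclose(epi.frame.view_axis, meta.frame.view_axis, atol=1e-9)
        and np.allclose(epi.frame.in_plane_u, meta.frame.in_plane_u, atol=1e-9)
    ):
        raise GeometryError("silhouettes were rendered from different frames")
    if meta.pixel_count == 0:
        raise ConsistencyError("metaphysis silhouette is empty (degenerate denominator)")
    return epi.pixel_count / meta.pixel_count


def epiphysis_volume_by_subtraction(v_combined: float, v_metaphysis: float) -> float:
    """Epiphyseal volume as combined minus metaphyseal volume.

    A negative difference means the erase step removed more than the
    combined model contained — an inconsistency that is surfaced, not
    clamped.
    """
    if v_combined < 0 or v_metaphysis < 0:
        raise ConsistencyError("volumes must be non-negative")
    if v_metaphysis > v_combined:
        raise ConsistencyError(
            f"metaphysis volume ({v_metaphysis:.3f} mm³) exceeds combined volume "
            f"({v_combined:.3f} mm³): inconsistent erase"
        )
    return v_combined - v_metaphysis


@dataclass
class MorphometricResult:
    """The measured areas, volumes and dimensionless ratios of one clavicle.

    When no epiphyseal structure is separable (fully fused bone) the
    ratios are ``None`` and ``assessable`` is False.
    """

    area_epiphysis_px: int
    area_metaphysis_px: int
    area_ratio: Optional[float]
    volume_combined_mm3: float
    volume_metaphysis_mm3: float
    volume_epiphysis_mm3: float
    volume_ratio: Optional[float]
    n_ossification_centers: int
    assessable: bool = True
    provenance: Dict[str, object] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "area_epiphysis_px": self.area_epiphysis_px,
            "area_metaphysis_px": self.area_metaphysis_px,
            "area_ratio": self.area_ratio,
            "volume_combined_mm3": self.volume_combined_mm3,
            "volume_metaphysis_mm3": self.volume_metaphysis_mm3,
            "volume_epiphysis_mm3": self.volume_epiphysis_mm3,
            "volume_ratio": self.volume_ratio,
            "n_ossification_centers": self.n_ossification_centers,
            "assessable": self.assessable,
            "provenance": self.provenance,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)
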