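"""Synthetic medial-clavicle CT phantoms with exact ground truth.

The phantom emulates the anatomy the measurement pipeline targets: an
elongated, tapering metaphysis/shaft (optionally bent and with a
metaphyseal concavity, the "bowl" norm variant), one or more ellipsoidal
epiphyseal ossification centers proximal to the end-plate, and an optional
cylindrical fusion bridge between each center and the face.  Solids are
rasterized to Hounsfield units, blurred to mimic partial-volume averaging,
and corrupted with additive white Gaussian noise; the truth label grid is
rasterized without blur or noise.

Model frame: the metaphyseal end-plate (face) is the plane x = 0 with the
shaft extending toward +x (distally) and the epiphysis at x < 0
(proximally).  An optional rigid rotation is applied to the whole scene —
solids, centerline and seeds together — so rotation invariance can be
exercised without resampling artifacts.

Analytic truths are closed-form constructive-solid-geometry volumes/areas,
independent of the rasterization; only the fusion-bridge/concavity overlap
term falls back to 2-D quadrature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import integrate, ndimage
from scipy.spatial.transform import Rotation

from .errors import PhantomSpecError
from .geometry import Centerline
from .grids import (
    ROLE_EPIPHYSIS,
    ROLE_FUSION,
    ROLE_METAPHYSIS,
    LabelGrid,
    ScalarVolume,
)
from .segmentation import Seed, SeedSet

LABEL_METAPHYSIS = 1


@dataclass(frozen=True)
class EpiphysealCenter:
    """One ellipsoidal ossification center.

    ``offset`` is the ellipsoid center in model mm coordinates (x < 0 is
    proximal of the end-plate); ``radii`` are the semi-axes (a along the
    bone axis, b and c in-plane).  The center must lie entirely proximal
    of the face plane.
    """

    offset: Tuple[float, float, float] = (-5.0, 0.0, 0.0)
    radii: Tuple[float, float, float] = (4.0, 6.0, 6.0)

    def __post_init__(self):
        object.__setattr__(self, "offset", tuple(float(x) for x in self.offset))
        object.__setattr__(self, "radii", tuple(float(x) for x in self.radii))
        if any(r <= 0 for r in self.radii):
            raise PhantomSpecError(f"ellipsoid radii must be positive, got {self.radii}")
        if self.offset[0] + self.radii[0] > 1e-9:
            raise PhantomSpecError(
                "ossification center must lie proximal of the face plane "
                f"(offset_x + a = {self.offset[0] + self.radii[0]:.3g} > 0)"
            )

    @property
    def gap(self) -> float:
        """Clearance between the ellipsoid's distal pole and the face plane."""
        return -(self.offset[0] + self.radii[0])

    @property
    def volume(self) -> float:
        a, b, c = self.radii
        return 4.0 / 3.0 * math.pi * a * b * c

    @property
    def projected_area(self) -> float:
        """En-face silhouette area (ellipse spanned by the in-plane semi-axes)."""
        return math.pi * self.radii[1] * self.radii[2]

    def scaled(self, f: float, keep_gap: bool = False) -> "EpiphysealCenter":
        a, b, c = (r * f for r in self.radii)
        if keep_gap:
            off = (-(self.gap + a), self.offset[1], self.offset[2])
        else:
            off = tuple(o * f for o in self.offset)
        return EpiphysealCenter(offset=off, radii=(a, b, c))


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic clavicle.

    Geometric defaults approximate an adolescent medial clavicle: a 40 mm
    metaphysis/shaft segment whose end-plate (radius 10 mm, i.e. a 20 mm
    greatest diameter) flares steeply down to a 5.5 mm shaft over the
    first 6 mm and then tapers gently to 5 mm, with a single lens-shaped
    ossification center (4 × 6 × 6 mm semi-axes) 1 mm proximal of the
    face.  HU levels (bone 700, center 500, soft tissue −50) straddle the
    300-HU bone threshold; blur 0.5 mm and noise SD 50 HU mimic a clinical
    thin-slice reconstruction.
    """

    shaft_length: float = 40.0
    shaft_proximal_radius: float = 5.5
    shaft_distal_radius: float = 5.0
    bend_angle_deg: float = 0.0
    face_radius: Optional[float] = 10.0  # None: no flare (= shaft_proximal_radius)
    flare_length: float = 6.0
    concavity_depth: float = 0.0
    concavity_radius: Optional[float] = None  # default: 0.7 * face radius
    centers: Tuple[EpiphysealCenter, ...] = (EpiphysealCenter(),)
    fusion_fraction: float = 0.0
    bone_hu: float = 700.0
    center_hu: float = 500.0
    background_hu: float = -50.0
    blur_sigma_mm: float = 0.5
    noise_sd_hu: float = 50.0
    spacing: float = 0.4
    seed: int = 0
    rotation_deg: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    margin_mm: float = 4.0

    def __post_init__(self):
        object.__setattr__(self, "centers",
                           tuple(c if isinstance(c, EpiphysealCenter) else EpiphysealCenter(**c)
                                 for c in self.centers))
        errs = []
        if self.shaft_length <= 0:
            errs.append("shaft_length must be positive")
        for name in ("shaft_proximal_radius", "shaft_distal_radius", "spacing"):
            if getattr(self, name) <= 0:
                errs.append(f"{name} must be positive")
        if not 0.0 <= self.fusion_fraction <= 1.0:
            errs.append("fusion_fraction must lie in [0, 1]")
        if self.concavity_depth < 0:
            errs.append("concavity_depth must be non-negative")
        if self.concavity_depth >= max(self.shaft_proximal_radius,
                                       self.face_radius or 0.0):
            errs.append("concavity_depth must be smaller than the end-plate radius")
        if self.flare_length <= 0 or self.flare_length >= self.shaft_length:
            errs.append("flare_length must lie in (0, shaft_length)")
        if self.blur_sigma_mm < 0 or self.noise_sd_hu < 0:
            errs.append("blur_sigma_mm and noise_sd_hu must be non-negative")
        if errs:
            raise PhantomSpecError(errs[0] if len(errs) == 1 else "; ".join(errs))
        self._check_center_overlap()

    # -- derived geometry -------------------------------------------------
    @property
    def face_r(self) -> float:
        return self.shaft_proximal_radius if self.face_radius is None else self.face_radius

    @property
    def bowl_r(self) -> float:
        return 0.7 * self.face_r if self.concavity_radius is None else self.concavity_radius

    def radius_at(self, s):
        """Shaft radius (mm) at axial position ``s`` (0 = face, L = distal end).

        A gentle linear taper (proximal → distal shaft radius) plus a
        metaphyseal flare that raises the radius to the end-plate value at
        s = 0 and dies out at ``flare_length``.  The flare profile
        (1 − (s/flare)²)² has zero slope at the face, giving the rounded
        rim of a real end-plate rather than a knife edge.
        """
        s = np.asarray(s, dtype=float)
        L = self.shaft_length
        base = self.shaft_proximal_radius + (
            self.shaft_distal_radius - self.shaft_proximal_radius
        ) * s / L
        bump = (self.face_r - self.shaft_proximal_radius) * np.clip(
            1.0 - (s / self.flare_length) ** 2, 0.0, None
        ) ** 2
        return base + bump

    def bowl_height(self, rho):
        """Depth of the concavity void above the face plane at in-plane radius rho."""
        if self.concavity_depth <= 0:
            return np.zeros_like(np.asarray(rho, dtype=float))
        rho = np.asarray(rho, dtype=float)
        return self.concavity_depth * np.clip(1.0 - (rho / self.bowl_r) ** 2, 0.0, None)

    @property
    def rotation(self) -> Rotation:
        return Rotation.from_euler("xyz", self.rotation_deg, degrees=True)

    def _check_center_overlap(self):
        # Convexity heuristic: sample the segment between each pair of
        # ellipsoid centers; a shared point flags overlapping centers.
        cs = self.centers
        for i in range(len(cs)):
            for j in range(i + 1, len(cs)):
                a, b = cs[i], cs[j]
                for t in np.linspace(0.0, 1.0, 101):
                    p = (1 - t) * np.asarray(a.offset) + t * np.asarray(b.offset)
                    if _in_ellipsoid(p, a) and _in_ellipsoid(p, b):
                        raise PhantomSpecError(
                            f"ossification centers {i} and {j} overlap"
                        )

    def scaled(self, f: float) -> "PhantomSpec":
        """Isotropically scale the phantom: all geometric lengths and the
        voxel spacing scale together (the dimensionless ratios are
        invariant under body size by construction); HU levels, blur and
        noise are scanner properties and stay fixed."""
        if f <= 0:
            raise PhantomSpecError("scale factor must be positive")
        return replace(
            self,
            spacing=self.spacing * f,
            margin_mm=self.margin_mm * f,
            shaft_length=self.shaft_length * f,
            shaft_proximal_radius=self.shaft_proximal_radius * f,
            shaft_distal_radius=self.shaft_distal_radius * f,
            face_radius=None if self.face_radius is None else self.face_radius * f,
            flare_length=self.flare_length * f,
            concavity_depth=self.concavity_depth * f,
            concavity_radius=None if self.concavity_radius is None else self.concavity_radius * f,
            centers=tuple(c.scaled(f) for c in self.centers),
        )


def _in_ellipsoid(p, c: EpiphysealCenter) -> bool:
    d = (np.asarray(p) - np.asarray(c.offset)) / np.asarray(c.radii)
    return float(np.dot(d, d)) <= 1.0


@dataclass
class PhantomTruth:
    """Ground truth accompanying a generated phantom."""

    label_grid: LabelGrid
    centerline: Centerline
    analytic: Dict[str, float]
    spec: PhantomSpec

    def suggest_seeds(self, erosion_voxels: int = 2, stride: int = 2) -> SeedSet:
        """Paint-like seeds: each truth structure eroded and subsampled.

        Erosion keeps seeds safely interior (robust to partial-volume blur
        at the threshold step); the stride thins them like painting on
        every other slice.  A structure whose erosion vanishes falls back
        to its single deepest voxel.
        """
        seeds: List[Seed] = []
        labels = self.label_grid.labels
        for label, role in sorted(self.label_grid.legend.items()):
            support = labels == label
            if not support.any():
                continue
            core = ndimage.binary_erosion(support, structure=np.ones((3, 3, 3)),
                                          iterations=erosion_voxels)
            if not core.any():
                # deepest voxel; plateau ties resolved toward the centroid
                dist = ndimage.distance_transform_edt(support)
                deep = np.argwhere(dist >= dist.max() - 0.5)
                centroid = np.argwhere(support).mean(axis=0)
                idx = deep[np.argmin(np.sum((deep - centroid) ** 2, axis=1))]
                seeds.append(Seed(index=tuple(int(x) for x in idx), label=label, role=role))
                continue
            pts = np.argwhere(core)
            thin = pts[np.all(pts % stride == 0, axis=1)]
            if len(thin) == 0:
                thin = pts[:1]
            for ijk in thin:
                seeds.append(Seed(index=tuple(int(x) for x in ijk), label=label, role=role))
        return SeedSet(seeds)


# ---------------------------------------------------------------------------
# analytic truths


def _bridge_radius(spec: PhantomSpec, c: EpiphysealCenter) -> float:
    return spec.fusion_fraction * min(c.radii[1], c.radii[2])


def _bridge_volume(spec: PhantomSpec, c: EpiphysealCenter) -> float:
    """Volume of the fusion bridge: cylinder from the ellipsoid's distal
    pole plane to the face, extended into the concavity bowl where present.

    The ellipsoid never protrudes past its pole plane, so the cylinder/
    ellipsoid overlap is exactly zero and the flat-face volume is
    π r_f² · gap; the bowl extension adds a quadrature term.
    """
    r_f = _bridge_radius(spec, c)
    if r_f <= 0:
        return 0.0
    v = math.pi * r_f ** 2 * c.gap
    if spec.concavity_depth > 0:
        cy, cz = c.offset[1], c.offset[2]
        if math.hypot(cy, cz) - r_f < spec.bowl_r:  # bridge disc reaches the bowl
            extra, _ = integrate.dblquad(
                lambda z, y: float(spec.bowl_height(math.hypot(y, z))),
                cy - r_f, cy + r_f,
                lambda y: cz - math.sqrt(max(0.0, r_f ** 2 - (y - cy) ** 2)),
                lambda y: cz + math.sqrt(max(0.0, r_f ** 2 - (y - cy) ** 2)),
                epsabs=1e-8,
            )
            v += extra
    return v


def _shaft_volume_to(spec: PhantomSpec, cut: float) -> float:
    """π ∫ r(s)² ds over [0, cut], minus the concavity void inside that range."""
    cut = min(cut, spec.shaft_length)
    v, _ = integrate.quad(lambda s: math.pi * float(spec.radius_at(s)) ** 2, 0.0, cut,
                          limit=200)
    if spec.concavity_depth > 0:
        void, _ = integrate.quad(
            lambda rho: 2 * math.pi * rho * min(float(spec.bowl_height(rho)), cut),
            0.0, spec.bowl_r, limit=200,
        )
        v -= void
    return v


def _distal_cut_truth(spec: PhantomSpec) -> Tuple[float, float, float]:
    """(s_star, d_max, cut_position) from the analytic radius profile."""
    s_grid = np.linspace(0.0, spec.shaft_length, 2001)
    radii = np.asarray(spec.radius_at(s_grid), dtype=float)
    r_max = float(radii.max())
    s_star = float(s_grid[int(np.argmax(radii))])  # first max = most proximal tie
    return s_star, 2 * r_max, s_star + r_max / 3.0


def _analytic_truth(spec: PhantomSpec) -> Dict[str, float]:
    s_star, d_max, cut = _distal_cut_truth(spec)
    v_meta = _shaft_volume_to(spec, cut)
    v_epi = sum(c.volume for c in spec.centers) + sum(
        _bridge_volume(spec, c) for c in spec.centers
    )
    a_meta = math.pi * (d_max / 2.0) ** 2
    a_epi = sum(c.projected_area for c in spec.centers)
    truth = {
        "v_epiphysis_mm3": v_epi,
        "v_metaphysis_to_cut_mm3": v_meta,
        "a_epiphysis_mm2": a_epi,
        "a_metaphysis_mm2": a_meta,
        "expected_area_ratio": a_epi / a_meta,
        "expected_volume_ratio": v_epi / v_meta if v_meta > 0 else float("nan"),
        "n_centers": len(spec.centers),
        "s_star_mm": s_star,
        "d_max_mm": d_max,
        "cut_position_mm": cut,
        "exact": spec.bend_angle_deg == 0.0,
    }
    return truth


# ---------------------------------------------------------------------------
# rasterization


def _arc_coords(spec: PhantomSpec, q: np.ndarray):
    """(s, rho) shaft coordinates of canonical points q (N, 3).

    For a straight shaft s = x and rho is the distance to the x-axis; for a
    bent shaft the axis is a circular arc of radius L/θ in the x–y plane.
    """
    x, y, z = q[:, 0], q[:, 1], q[:, 2]
    beta = math.radians(spec.bend_angle_deg)
    if abs(beta) < 1e-9:
        s = x
        y_loc = y
    else:
        R_b = spec.shaft_length / beta
        theta = np.arctan2(x, R_b - y)
        s = R_b * theta
        y_loc = R_b - np.sqrt(x ** 2 + (R_b - y) ** 2)
    rho = np.sqrt(y_loc ** 2 + z ** 2)
    return s, rho


def _axis_point(spec: PhantomSpec, s: float) -> np.ndarray:
    """Canonical coordinates of the shaft axis at arc length s."""
    beta = math.radians(spec.bend_angle_deg)
    if abs(beta) < 1e-9 or s <= 0:
        return np.array([s, 0.0, 0.0])
    R_b = spec.shaft_length / beta
    theta = s / R_b
    return np.array([R_b * math.sin(theta), R_b * (1 - math.cos(theta)), 0.0])


def _canonical_bbox(spec: PhantomSpec) -> Tuple[np.ndarray, np.ndarray]:
    pts = []
    for s in np.linspace(0.0, spec.shaft_length, 100):
        p = _axis_point(spec, s)
        r = float(spec.radius_at(s))
        pts.append(p - r)
        pts.append(p + r)
    for c in spec.centers:
        o, r = np.asarray(c.offset), np.asarray(c.radii)
        pts.append(o - r)
        pts.append(o + r)
    pts = np.asarray(pts)
    return pts.min(axis=0), pts.max(axis=0)


def generate_phantom(spec: PhantomSpec) -> Tuple[ScalarVolume, PhantomTruth]:
    """Rasterize the phantom to HU and produce its ground truth.

    The HU volume is the rasterized solids Gaussian-blurred by
    ``blur_sigma_mm`` with additive N(0, noise_sd_hu²) noise from the
    spec's integer seed; the truth label grid carries no blur or noise.
    The same spec and seed reproduce the volume bit for bit.
    """
    lo, hi = _canonical_bbox(spec)
    margin = spec.margin_mm + 3.0 * spec.blur_sigma_mm
    R = spec.rotation.as_matrix()
    corners = np.array([[lo[i] if b & (1 << i) else hi[i] for i in range(3)]
                        for b in range(8)])
    rc = corners @ R.T
    wlo, whi = rc.min(axis=0) - margin, rc.max(axis=0) + margin

    h = spec.spacing
    shape = np.maximum(2, np.ceil((whi - wlo) / h)).astype(int)
    origin = wlo + 0.5 * h

    ii, jj, kk = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    world = origin + h * np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
    q = world @ R  # canonical coordinates (R^T applied to rows)

    s, rho = _arc_coords(spec, q)
    x, y, z = q[:, 0], q[:, 1], q[:, 2]
    in_shaft = (s >= 0) & (s <= spec.shaft_length) & (rho <= spec.radius_at(s))
    if spec.concavity_depth > 0:
        in_shaft &= s >= spec.bowl_height(rho)

    labels = np.zeros(q.shape[0], dtype=np.int32)
    labels[in_shaft] = LABEL_METAPHYSIS
    legend = {LABEL_METAPHYSIS: ROLE_METAPHYSIS}

    for i, c in enumerate(spec.centers):
        d = (q - np.asarray(c.offset)) / np.asarray(c.radii)
        inside = np.einsum("ij,ij->i", d, d) <= 1.0
        lab = 2 + i
        labels[inside & (labels == 0)] = lab
        legend[lab] = ROLE_EPIPHYSIS

    fusion_label = 2 + len(spec.centers)
    any_fusion = False
    if spec.fusion_fraction > 0:
        rho_face = np.sqrt(y ** 2 + z ** 2)
        x_end = spec.bowl_height(rho_face) if spec.concavity_depth > 0 else np.zeros_like(x)
        for c in spec.centers:
            r_f = _bridge_radius(spec, c)
            if r_f <= 0:
                continue
            in_cyl = (y - c.offset[1]) ** 2 + (z - c.offset[2]) ** 2 <= r_f ** 2
            in_bridge = in_cyl & (x >= c.offset[0] + c.radii[0] - 1e-12) & (x < x_end)
            sel = in_bridge & (labels == 0)
            if sel.any():
                any_fusion = True
            labels[sel] = fusion_label
    if any_fusion:
        legend[fusion_label] = ROLE_FUSION

    labels = labels.reshape(shape)
    hu = np.full(labels.shape, spec.background_hu, dtype=float)
    hu[labels == LABEL_METAPHYSIS] = spec.bone_hu
    hu[labels >= 2] = spec.center_hu

    if spec.blur_sigma_mm > 0:
        hu = ndimage.gaussian_filter(hu, sigma=spec.blur_sigma_mm / h)
    if spec.noise_sd_hu > 0:
        rng = np.random.default_rng(spec.seed)
        hu = hu + rng.normal(0.0, spec.noise_sd_hu, size=hu.shape)

    common = dict(spacing=np.full(3, h), origin=origin, direction=np.eye(3))
    vol = ScalarVolume(values=hu, meta={"phantom_seed": spec.seed}, **common)
    truth_grid = LabelGrid(labels=labels, legend=legend, **common)

    if spec.centers:
        x_prox = min(c.offset[0] - c.radii[0] for c in spec.centers) - 3.0
    else:
        x_prox = -5.0
    proximal = R @ np.array([x_prox, 0.0, 0.0])
    distal = R @ _axis_point(spec, 0.6 * spec.shaft_length)
    line = Centerline(proximal=tuple(proximal), distal=tuple(distal))

    truth = PhantomTruth(
        label_grid=truth_grid,
        centerline=line,
        analytic=_analytic_truth(spec),
        spec=spec,
    )
    return vol, truth


def default_spec(**overrides) -> PhantomSpec:
    """The reference single-center phantom (clinical-like blur and noise)."""
    return PhantomSpec(**overrides)


def noise_free_spec(**overrides) -> PhantomSpec:
    """Reference phantom rendered without blur or noise."""
    overrides.setdefault("blur_sigma_mm", 0.0)
    overrides.setdefault("noise_sd_hu", 0.0)
    return PhantomSpec(**overrides)


def multi_center_spec(**overrides) -> PhantomSpec:
    """Norm-variant phantom with three disjoint ossification centers."""
    centers = (
        EpiphysealCenter(offset=(-3.4, 0.0, 0.0), radii=(2.4, 2.2, 2.2)),
        EpiphysealCenter(offset=(-3.4, 5.2, 0.0), radii=(2.4, 2.2, 2.2)),
        EpiphysealCenter(offset=(-3.4, -2.6, 4.6), radii=(2.4, 2.2, 2.2)),
    )
    overrides.setdefault("centers", centers)
    return PhantomSpec(**overrides)


def concavity_spec(**overrides) -> PhantomSpec:
    """Norm-variant phantom with a metaphyseal "bowl" concavity and a
    single center embedded in front of it."""
    overrides.setdefault("concavity_depth", 2.5)
    overrides.setdefault(
        "centers", (EpiphysealCenter(offset=(-3.6, 0.0, 0.0), radii=(3.0, 5.0, 5.0)),)
    )
    return PhantomSpec(**overrides)


def stage_series(base: PhantomSpec, stages: Sequence) -> List[PhantomSpec]:
    """A developmental series of specs with growing ossification.

    ``stages`` is a sequence of ``(center_scale, fusion_fraction)`` pairs
    (or mappings with those keys) whose ``center_scale`` values must be
    strictly increasing; each stage scales every ossification center
    (preserving its clearance from the face) and sets the fusion fraction.
    The analytic expected volume ratios are strictly increasing.
    """
    parsed = []
    for st in stages:
        if isinstance(st, dict):
            parsed.append((float(st["center_scale"]), float(st.get("fusion_fraction", base.fusion_fraction))))
        else:
            scale, frac = st
            parsed.append((float(scale), float(frac)))
    scales = [p[0] for p in parsed]
    if any(b <= a for a, b in zip(scales, scales[1:])):
        raise PhantomSpecError(f"center scales must be strictly increasing, got {scales}")
    out = []
    for scale, frac in parsed:
        spec = replace(
            base,
            centers=tuple(c.scaled(scale, keep_gap=True) for c in base.centers),
            fusion_fraction=frac,
        )
        out.append(spec)
    ratios = [_analytic_truth(s)["expected_volume_ratio"] for s in out]
    if any(b <= a for a, b in zip(ratios, ratios[1:])):
        raise PhantomSpecError("stage series does not yield strictly increasing volume ratios")
    return out
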