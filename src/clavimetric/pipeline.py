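"""Pipeline orchestration: config validation, the measurement sequence, and
reporting.

The measurement sequence mirrors the clinical workflow:
load → crop → resample → threshold → grow from seeds → solidify →
component labeling of ossification centers → en-face frame + alignment
check → silhouettes → area ratio → cross-section profile → distal cut →
clip → combined volume → erase epiphyseal structures → metaphysis volume →
epiphysis volume by subtraction → volume ratio.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
import pydantic
import yaml
from pydantic import BaseModel, Field

from . import __version__
from .errors import AlignmentError, ConfigError, IOFailure
from .geometry import (
    Centerline,
    check_en_face,
    endpoint_separation_mm,
    make_en_face_frame,
    project_silhouette,
)
from .grids import (
    ROLE_EPIPHYSIS,
    ROLE_FUSION,
    ROLE_METAPHYSIS,
    BinaryMask,
    RoiBox,
    ScalarVolume,
    crop_roi,
    resample_isotropic,
)
from .io import load_volume, save_labels
from .metrics import (
    MorphometricResult,
    area_ratio,
    clip_at_cut,
    cross_section_profile,
    epiphysis_volume_by_subtraction,
    find_distal_cut,
    segment_volume,
)
from .segmentation import (
    Seed,
    SeedSet,
    erase_region,
    grow_from_seeds,
    label_components,
    solidify,
    threshold_mask,
)

log = logging.getLogger("clavimetric")

#: fixed column order of metrics.csv
METRIC_COLUMNS = [
    "area_epiphysis_px",
    "area_metaphysis_px",
    "area_ratio",
    "volume_combined_mm3",
    "volume_metaphysis_mm3",
    "volume_epiphysis_mm3",
    "volume_ratio",
    "n_ossification_centers",
    "assessable",
]


# ---------------------------------------------------------------------------
# configuration


class SeedConfig(BaseModel):
    """One painted seed, by voxel index of the input volume or physical mm."""

    index: Optional[Tuple[int, int, int]] = None
    point_mm: Optional[Tuple[float, float, float]] = None
    label: int = Field(ge=1)
    role: str = ROLE_METAPHYSIS

    @pydantic.model_validator(mode="after")
    def _one_location(self):
        if (self.index is None) == (self.point_mm is None):
            raise ValueError("seed needs exactly one of 'index' or 'point_mm'")
        return self


class RoiConfig(BaseModel):
    """Region of interest, as voxel indices or physical corner points."""

    lower: Optional[Tuple[int, int, int]] = None
    upper: Optional[Tuple[int, int, int]] = None
    lower_mm: Optional[Tuple[float, float, float]] = None
    upper_mm: Optional[Tuple[float, float, float]] = None

    @pydantic.model_validator(mode="after")
    def _consistent(self):
        voxel = self.lower is not None and self.upper is not None
        mm = self.lower_mm is not None and self.upper_mm is not None
        if voxel == mm:
            raise ValueError("roi needs either voxel (lower/upper) or mm (lower_mm/upper_mm) corners")
        return self


class CenterlineConfig(BaseModel):
    proximal_mm: Tuple[float, float, float]
    distal_mm: Tuple[float, float, float]


class PipelineConfig(BaseModel):
    """Fully validated pipeline configuration."""

    volume: Optional[Path] = None
    dicom_dir: Optional[Path] = None
    roi: Optional[RoiConfig] = None
    seeds: List[SeedConfig] = Field(min_length=1)
    centerline: CenterlineConfig
    min_hu: float = 300.0
    pixel_size: Optional[float] = Field(default=None, gt=0)
    profile_step_mm: float = Field(default=0.5, gt=0)
    target_spacing_mm: Optional[float] = Field(default=None, gt=0)
    solidify_labels: bool = True
    drop_seeds_outside_mask: bool = True
    en_face_tol_pixels: float = Field(default=1.0, gt=0)
    output_dir: Path = Path("clavimetric_out")
    log_level: str = "INFO"
    seed: int = 0

    @pydantic.model_validator(mode="after")
    def _exactly_one_input(self):
        if (self.volume is None) == (self.dicom_dir is None):
            raise ValueError("exactly one of 'volume' (file) or 'dicom_dir' (DICOM series) is required")
        return self


def validate_config(raw) -> PipelineConfig:
    """Validate a raw mapping (parsed YAML/JSON) into a PipelineConfig.

    All violations are collected and reported together, including
    missing-input-path checks.
    """
    if not isinstance(raw, dict):
        raise ConfigError(["configuration must be a mapping"])
    try:
        cfg = PipelineConfig(**raw)
    except pydantic.ValidationError as e:
        raise ConfigError(
            [f"{'.'.join(str(x) for x in err['loc'])}: {err['msg']}" for err in e.errors()]
        )
    problems = []
    for name in ("volume", "dicom_dir"):
        p = getattr(cfg, name)
        if p is not None and not Path(p).exists():
            problems.append(f"{name}: path does not exist: {p}")
    if problems:
        raise ConfigError(problems)
    return cfg


def load_config(path) -> PipelineConfig:
    path = Path(path)
    if not path.exists():
        raise ConfigError([f"config file not found: {path}"])
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return validate_config(raw)


# ---------------------------------------------------------------------------
# in-memory measurement


def measure(
    vol: ScalarVolume,
    seeds: SeedSet,
    centerline: Centerline,
    *,
    min_hu: float = 300.0,
    target_spacing: Optional[float] = None,
    pixel_size: Optional[float] = None,
    profile_step: float = 0.5,
    solidify_labels: bool = True,
    drop_seeds_outside_mask: bool = True,
    en_face_tol_pixels: float = 1.0,
    keep_intermediates: bool = False,
) -> MorphometricResult:
    """Run the measurement sequence on an in-memory volume.

    ``seeds`` are voxel indices on the lattice of ``vol`` *after* isotropic
    resampling to ``target_spacing`` (default: the minimum input spacing).
    Returns a :class:`MorphometricResult`; intermediate grids are attached
    to ``result.provenance['intermediates']`` when requested.
    """


    target = float(target_spacing) if target_spacing else float(vol.spacing.min())
    iso = resample_isotropic(vol, target)
    log.info("resample: %s -> %s voxels at %.3g mm", vol.shape, iso.shape, target)

    mask = threshold_mask(iso, min_hu)
    log.info("threshold >= %.0f HU: %d voxels in mask", min_hu, int(mask.mask.sum()))

    if drop_seeds_outside_mask:
        seeds = seeds.restrict_to_mask(mask)
    seg = grow_from_seeds(mask, seeds)
    log.info("grow_from_seeds: %d labeled voxels from %d seeds",
             int((seg.labels > 0).sum()), len(seeds))

    if solidify_labels:
        for label in sorted(seg.legend):
            if (seg.labels == label).any():
                seg = solidify(seg, label)
        log.info("solidify: %d labeled voxels", int((seg.labels > 0).sum()))

    n_centers = 0
    if seg.labels_for_role(ROLE_EPIPHYSIS):
        seg, n_centers = label_components(seg, ROLE_EPIPHYSIS)
    log.info("ossification centers: %d", n_centers)

    px = float(pixel_size) if pixel_size else target
    frame = make_en_face_frame(centerline, px)
    if not check_en_face(centerline, frame, tol_pixels=en_face_tol_pixels):
        raise AlignmentError(
            f"en-face check failed: endpoint separation "
            f"{endpoint_separation_mm(centerline, frame):.3g} mm exceeds "
            f"{en_face_tol_pixels} px at {px:.3g} mm/px"
        )

    meta_labels = seg.labels_for_role(ROLE_METAPHYSIS)
    epi_labels = seg.labels_for_role(ROLE_EPIPHYSIS) + seg.labels_for_role(ROLE_FUSION)
    epi_labels = [l for l in epi_labels if (seg.labels == l).any()]

    sil_meta = project_silhouette(seg, meta_labels, frame)
    assessable = bool(epi_labels)
    if assessable:
        sil_epi = project_silhouette(seg, epi_labels, frame)
        a_ratio = area_ratio(sil_epi, sil_meta)
        epi_px = sil_epi.pixel_count
    else:
        sil_epi, a_ratio, epi_px = None, None, 0
    log.info("silhouettes: epiphysis %d px, metaphysis %d px", epi_px, sil_meta.pixel_count)

    profile = cross_section_profile(seg, meta_labels, frame, step=profile_step)
    # Feret diameters are quantized at the voxel-footprint scale; treat
    # differences below it as ties (resolved toward the proximal end).
    cut = find_distal_cut(profile, tie_tolerance=float(seg.spacing.mean()))
    log.info("distal cut: s*=%.2f mm, d_max=%.2f mm, cut=%.2f mm",
             cut.s_star, cut.d_max, cut.cut_position)

    clipped = clip_at_cut(seg, frame, cut)
    all_labels = [l for l in clipped.legend if (clipped.labels == l).any()]
    v_combined = segment_volume(clipped, all_labels) if all_labels else 0.0

    if epi_labels:
        region = BinaryMask(
            spacing=clipped.spacing.copy(), origin=clipped.origin.copy(),
            direction=clipped.direction.copy(), mask=clipped.support(epi_labels),
        )
        meta_only = erase_region(clipped, region)
    else:
        meta_only = clipped
    v_meta = segment_volume(meta_only, meta_labels)
    v_epi = epiphysis_volume_by_subtraction(v_combined, v_meta)
    v_ratio = (v_epi / v_meta) if (assessable and v_meta > 0) else None
    log.info("volumes: combined %.1f, metaphysis %.1f, epiphysis %.1f mm3",
             v_combined, v_meta, v_epi)

    result = MorphometricResult(
        area_epiphysis_px=epi_px,
        area_metaphysis_px=sil_meta.pixel_count,
        area_ratio=a_ratio,
        volume_combined_mm3=v_combined,
        volume_metaphysis_mm3=v_meta,
        volume_epiphysis_mm3=v_epi,
        volume_ratio=v_ratio,
        n_ossification_centers=n_centers,
        assessable=assessable,
        provenance={
            "software": {"name": "clavimetric", "version": __version__},
            "parameters": {
                "min_hu": min_hu,
                "target_spacing_mm": target,
                "pixel_size_mm": px,
                "profile_step_mm": profile_step,
                "solidify_labels": solidify_labels,
                "en_face_tol_pixels": en_face_tol_pixels,
            },
            "centerline": {"proximal_mm": list(centerline.proximal),
                           "distal_mm": list(centerline.distal)},
            "n_seeds": len(seeds),
            "distal_cut": {"s_star_mm": cut.s_star, "d_max_mm": cut.d_max,
                           "cut_position_mm": cut.cut_position},
        },
    )
    if keep_intermediates:
        result.provenance["intermediates"] = {
            "segmentation": seg,
            "clipped": clipped,
            "metaphysis_only": meta_only,
            "silhouette_epiphysis": sil_epi,
            "silhouette_metaphysis": sil_meta,
            "profile": profile,
        }
    return result


# ---------------------------------------------------------------------------
# file-level pipeline


def _seed_set_for(cfg: PipelineConfig, input_vol: ScalarVolume, iso_like) -> SeedSet:
    seeds = []
    for sc in cfg.seeds:
        if sc.point_mm is not None:
            p = np.asarray(sc.point_mm, dtype=float)
        else:
            p = input_vol.index_to_physical(np.asarray(sc.index, dtype=float))
        idx = tuple(int(i) for i in np.rint(iso_like.physical_to_index(p)))
        seeds.append(Seed(index=idx, label=sc.label, role=sc.role))
    return SeedSet(seeds)


def run_pipeline(config: PipelineConfig, write_outputs: bool = True) -> MorphometricResult:
    """Execute the full workflow described by a validated config."""


    if isinstance(config, dict):
        config = validate_config(config)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    src = config.volume if config.volume is not None else config.dicom_dir
    vol = load_volume(src)
    log.info("load: %s, shape %s, spacing %s", src, vol.shape, np.round(vol.spacing, 3))
    input_vol = vol

    if config.roi is not None:
        if config.roi.lower is not None:
            box = RoiBox(config.roi.lower, config.roi.upper)
        else:
            box = RoiBox.from_physical(vol, config.roi.lower_mm, config.roi.upper_mm)
        vol = crop_roi(vol, box)
        log.info("crop: %s -> %s", input_vol.shape, vol.shape)

    target = config.target_spacing_mm or float(vol.spacing.min())
    iso = resample_isotropic(vol, target)
    seeds = _seed_set_for(config, input_vol, iso)
    line = Centerline(proximal=config.centerline.proximal_mm,
                      distal=config.centerline.distal_mm)

    result = measure(
        vol,
        seeds,
        line,
        min_hu=config.min_hu,
        target_spacing=target,
        pixel_size=config.pixel_size,
        profile_step=config.profile_step_mm,
        solidify_labels=config.solidify_labels,
        drop_seeds_outside_mask=config.drop_seeds_outside_mask,
        en_face_tol_pixels=config.en_face_tol_pixels,
        keep_intermediates=write_outputs,
    )
    result.provenance["config"] = json.loads(config.model_dump_json())
    if config.volume is not None and Path(config.volume).is_file():
        result.provenance["input_sha256"] = _sha256(config.volume)

    if write_outputs:
        report(result, config.output_dir)
    else:
        result.provenance.pop("intermediates", None)
    return result


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _save_png(silhouette, path):
    from PIL import Image

    img = (silhouette.pixels.T[::-1].astype(np.uint8)) * 255
    Image.fromarray(img, mode="L").save(path)
    with open(str(path) + ".json", "w") as fh:
        json.dump({"pixel_size_mm": silhouette.pixel_size,
                   "pixel_count": silhouette.pixel_count,
                   "area_mm2": silhouette.area_mm2}, fh, indent=2)


def report(result: MorphometricResult, out_dir) -> List[Path]:
    """Write result.json, metrics.csv and a human-readable summary.

    When the result still carries intermediate grids they are exported too
    (silhouette PNGs, profile.csv, label grids as NRRD).
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as e:
        raise IOFailure(f"cannot create output directory {out}: {e}")
    if not os_access_writable(out):
        raise IOFailure(f"output directory {out} is not writable")

    written = []
    intermediates = result.provenance.pop("intermediates", None)

    d = result.to_dict()
    with open(out / "result.json", "w") as fh:
        json.dump(d, fh, indent=2, sort_keys=True)
    written.append(out / "result.json")

    row = {k: d[k] for k in METRIC_COLUMNS}
    pd.DataFrame([row], columns=METRIC_COLUMNS).to_csv(
        out / "metrics.csv", index=False, float_format="%.6f"
    )
    written.append(out / "metrics.csv")

    lines = ["clavimetric morphometric summary", "-" * 32]
    if result.assessable:
        lines += [
            f"ossification centers : {result.n_ossification_centers}",
            f"area ratio (epi/meta): {result.area_ratio:.4f}",
            f"volume ratio         : {result.volume_ratio:.4f}",
            f"epiphysis volume     : {result.volume_epiphysis_mm3:.1f} mm3",
            f"metaphysis volume    : {result.volume_metaphysis_mm3:.1f} mm3",
        ]
    else:
        lines += ["no separable epiphyseal structure: not assessable",
                  f"metaphysis volume    : {result.volume_metaphysis_mm3:.1f} mm3"]
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
    written.append(out / "summary.txt")

    if intermediates:
        if intermediates.get("silhouette_epiphysis") is not None:
            _save_png(intermediates["silhouette_epiphysis"], out / "enface_epiphysis.png")
        _save_png(intermediates["silhouette_metaphysis"], out / "enface_metaphysis.png")
        prof = intermediates["profile"]
        pd.DataFrame({
            "position_mm": prof.positions,
            "area_mm2": prof.areas,
            "feret_diameter_mm": prof.diameters,
        }).to_csv(out / "profile.csv", index=False, float_format="%.6f")
        for name in ("segmentation", "clipped", "metaphysis_only"):
            save_labels(intermediates[name], out / f"{name}.nrrd")
        written += [out / "profile.csv"]
    return written


def os_access_writable(path: Path) -> bool:
    import os

    return os.access(path, os.W_OK)
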