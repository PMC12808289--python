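"""Deterministic re-implementations of the interactive segment-editor steps.

The clinical workflow thresholds bone at 300 HU, paints seeds for each
structure, grows labels from the seeds, solidifies enclosed cavities and
combines/erases labels.  Here every step is a pure function of its inputs:

* thresholding is inclusive at the minimum HU;
* growing assigns each masked voxel to the *geodesically nearest* seed,
  measured in chessboard steps through the mask with 26-connectivity,
  ties broken toward the smaller label id;
* cavity detection pairs 6-connectivity for background with
  26-connectivity for foreground.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np
from scipy import ndimage

from .errors import LabelError, SeedError, ValidationError
from .grids import ROLE_EPIPHYSIS, ROLE_METAPHYSIS, BinaryMask, LabelGrid, ScalarVolume

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)
_STRUCT6 = ndimage.generate_binary_structure(3, 1)


@dataclass(frozen=True)
class Seed:
    """One painted seed voxel."""

    index: Tuple[int, int, int]
    label: int
    role: str = ROLE_METAPHYSIS

    def __post_init__(self):
        object.__setattr__(self, "index", tuple(int(i) for i in self.index))
        if self.label < 1:
            raise SeedError(f"seed label must be >= 1, got {self.label}")


@dataclass
class SeedSet:
    """Painted seeds, one or more per intended segment."""

    seeds: List[Seed] = field(default_factory=list)

    def __post_init__(self):
        self.seeds = [s if isinstance(s, Seed) else Seed(**s) for s in self.seeds]

    def __len__(self):
        return len(self.seeds)

    def __iter__(self):
        return iter(self.seeds)

    @property
    def legend(self) -> dict:
        out = {}
        for s in self.seeds:
            if s.label in out and out[s.label] != s.role:
                raise ValidationError(
                    f"label {s.label} used with conflicting roles "
                    f"{out[s.label]!r} and {s.role!r}"
                )
            out[s.label] = s.role
        return out

    def restrict_to_mask(self, mask: BinaryMask) -> "SeedSet":
        """Drop seeds that fall outside the mask.

        Raises ``SeedError`` if any label would lose all of its seeds:
        a structure without a surviving seed cannot be grown.
        """
        kept = [s for s in self.seeds if _inside(mask.mask, s.index) and mask.mask[s.index]]
        lost = set(s.label for s in self.seeds) - set(s.label for s in kept)
        if lost:
            raise SeedError(f"all seeds of label(s) {sorted(lost)} fall outside the mask")
        return SeedSet(kept)


def _inside(arr: np.ndarray, idx) -> bool:
    return all(0 <= i < s for i, s in zip(idx, arr.shape))


def threshold_mask(vol: ScalarVolume, min_hu: float = 300.0) -> BinaryMask:
    """Bone mask: true exactly where HU >= ``min_hu`` (inclusive bound)."""
    return BinaryMask(
        spacing=vol.spacing.copy(),
        origin=vol.origin.copy(),
        direction=vol.direction.copy(),
        mask=vol.values >= min_hu,
    )


def grow_from_seeds(mask: BinaryMask, seeds: SeedSet) -> LabelGrid:
    """Multi-label geodesic growth of seeds through a binary mask.

    Every mask voxel reachable from at least one seed receives the label of
    the geodesically nearest seed (chessboard metric, 26-connectivity,
    paths confined to the mask); equidistant voxels take the smaller label
    id.  Unreachable mask voxels and background stay 0.
    """
    if len(seeds) == 0:
        raise SeedError("empty seed set")
    m = mask.mask
    labels = np.zeros(m.shape, dtype=np.int32)
    for s in seeds:
        if not _inside(m, s.index):
            raise SeedError(f"seed {s.index} outside grid {m.shape}")
        if not m[s.index]:
            raise SeedError(f"seed {s.index} (label {s.label}) lies outside the mask")
    # Seed voxels themselves: smaller label wins on collision.
    for s in sorted(seeds, key=lambda s: s.label, reverse=True):
        labels[s.index] = s.label

    label_ids = sorted(set(s.label for s in seeds))
    frontiers = {l: labels == l for l in label_ids}
    unassigned = m & (labels == 0)
    while unassigned.any():
        claimed_this_round = np.zeros(m.shape, dtype=bool)
        new_frontiers = {}
        for l in label_ids:  # ascending: ties go to the smaller label id
            f = frontiers[l]
            if not f.any():
                new_frontiers[l] = f
                continue
            grown = ndimage.binary_dilation(f, structure=_STRUCT26) & unassigned & ~claimed_this_round
            new_frontiers[l] = grown
            claimed_this_round |= grown
            labels[grown] = l
        if not claimed_this_round.any():
            break  # remaining mask voxels unreachable
        unassigned &= ~claimed_this_round
        frontiers = new_frontiers

    return LabelGrid(
        spacing=mask.spacing.copy(),
        origin=mask.origin.copy(),
        direction=mask.direction.copy(),
        labels=labels,
        legend=seeds.legend,
    )


def solidify(seg: LabelGrid, label: int) -> LabelGrid:
    """Fill internal cavities enclosed by ``label``.

    A cavity is a background component (6-connectivity) with no path to the
    grid border; it is filled with ``label`` when its 26-neighbourhood
    touches that label and no other.  Labeled voxels are never removed.
    """
    if label not in set(np.unique(seg.labels).tolist()):
        raise LabelError(f"label {label} not present in grid")
    background = seg.labels == 0
    comp, n = ndimage.label(background, structure=_STRUCT6)
    if n == 0:
        return seg.with_labels(seg.labels.copy())
    border_ids = set()
    for axis in range(3):
        for sl in (0, -1):
            face = np.take(comp, sl, axis=axis)
            border_ids.update(np.unique(face).tolist())
    border_ids.discard(0)

    out = seg.labels.copy()
    for cid in range(1, n + 1):
        if cid in border_ids:
            continue
        cavity = comp == cid
        shell = ndimage.binary_dilation(cavity, structure=_STRUCT26) & ~cavity
        touching = set(np.unique(seg.labels[shell]).tolist()) - {0}
        if touching == {label}:
            out[cavity] = label
    return seg.with_labels(out)


def logical_combine(a: LabelGrid, b: LabelGrid, op: str, out_label: int,
                    out_role: str | None = None) -> LabelGrid:
    """Set algebra on the nonzero supports of two label grids.

    ``op`` is one of ``union``, ``intersect``, ``subtract``; the result is
    written as ``out_label``.  The role of ``out_label`` is taken from
    ``a``'s legend (then ``b``'s) unless given explicitly.
    """
    a.require_same_lattice(b, "operands of logical_combine")
    sa, sb = a.labels > 0, b.labels > 0
    if op == "union":
        res = sa | sb
    elif op == "intersect":
        res = sa & sb
    elif op == "subtract":
        res = sa & ~sb
    else:
        raise ValidationError(f"unknown logical op {op!r}")
    if out_role is None:
        out_role = a.legend.get(out_label, b.legend.get(out_label, ROLE_METAPHYSIS))
    labels = np.where(res, np.int32(out_label), np.int32(0))
    return a.with_labels(labels, legend={out_label: out_role})


def erase_region(seg: LabelGrid, region: BinaryMask) -> LabelGrid:
    """Set labels to background inside ``region``; everything else unchanged."""
    seg.require_same_lattice(region, "label grid and erase region")
    out = seg.labels.copy()
    out[region.mask] = 0
    return seg.with_labels(out)


def label_components(seg: LabelGrid, role: str = ROLE_EPIPHYSIS) -> Tuple[LabelGrid, int]:
    """Split all voxels of ``role`` into 26-connected components.

    Each component receives a fresh label (appended after the current
    maximum label id, in array scan order); the legend is updated and the
    component count returned alongside the relabeled grid.
    """
    role_labels = seg.labels_for_role(role)
    if not role_labels:
        raise LabelError(f"role {role!r} absent from legend")
    support = seg.support(role_labels)
    comp, n = ndimage.label(support, structure=_STRUCT26)
    out = seg.labels.copy()
    out[support] = 0
    legend = {l: r for l, r in seg.legend.items() if l not in role_labels}
    base = max(legend, default=0)
    for cid in range(1, n + 1):
        new_label = base + cid
        out[comp == cid] = new_label
        legend[new_label] = role
    return seg.with_labels(out, legend=legend), n
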