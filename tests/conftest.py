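"""Shared fixtures and small grid builders."""

from __future__ import annotations

import numpy as np
import pytest

from clavimetric import (
    LabelGrid,
    ScalarVolume,
    generate_phantom,
    measure,
    noise_free_spec,
)


def make_volume(values, spacing=1.0, origin=(0.0, 0.0, 0.0)) -> ScalarVolume:
    values = np.asarray(values, dtype=float)
    return ScalarVolume(
        values=values,
        spacing=np.full(3, float(spacing)) if np.isscalar(spacing) else np.asarray(spacing),
        origin=np.asarray(origin, dtype=float),
        direction=np.eye(3),
    )


def make_labels(labels, legend, spacing=1.0, origin=(0.0, 0.0, 0.0)) -> LabelGrid:
    return LabelGrid(
        labels=np.asarray(labels, dtype=np.int32),
        legend=legend,
        spacing=np.full(3, float(spacing)) if np.isscalar(spacing) else np.asarray(spacing),
        origin=np.asarray(origin, dtype=float),
        direction=np.eye(3),
    )


def ball_mask(shape, center, radius, spacing=1.0):
    """Boolean voxel-center ball on an isotropic lattice."""
    idx = np.stack(np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), axis=-1)
    d2 = np.sum(((idx - np.asarray(center)) * spacing) ** 2, axis=-1)
    return d2 <= radius**2


@pytest.fixture(scope="session")
def noise_free_run():
    """Full pipeline on the reference noise-free phantom, shared session-wide."""
    spec = noise_free_spec()
    vol, truth = generate_phantom(spec)
    result = measure(vol, truth.suggest_seeds(), truth.centerline)
    return spec, truth, result
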