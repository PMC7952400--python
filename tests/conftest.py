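"""Shared phantom fixtures.

Heavy artefacts (phantom sequences, registrations) are session-scoped so
the cost is paid once.
"""

from __future__ import annotations

import numpy as np
import pytest

from cctstrain import imaging, phantom
from cctstrain.imaging import ImageVolume


@pytest.fixture(scope="session")
def default_phantom():
    """The default 64^3, 10-frame contracting ventricle and its truth."""
    spec = phantom.PhantomSpec()
    frames, truth = phantom.generate_phantom_sequence(spec)
    return spec, frames, truth


@pytest.fixture(scope="session")
def small_static_phantom():
    """A 48^3 non-contracting phantom pair (two noise realisations)."""
    spec = phantom.PhantomSpec(grid_shape=(48, 48, 48), a_short=12.0,
                               a_long=18.0, lam_c_peak=1.0, lam_l_peak=1.0,
                               n_frames=2, seed=1)
    frames, truth = phantom.generate_phantom_sequence(spec)
    return spec, frames, truth


@pytest.fixture(scope="session")
def translated_pair(small_static_phantom):
    """Reference frame plus a copy translated by 3 voxels on every axis.

    The translated frame uses the second noise realisation so reference
    and target noise are independent, as in consecutive gated frames.
    """
    spec, frames, _ = small_static_phantom
    ref = frames[0]
    shifted = np.roll(frames[1].data, (3, 3, 3), axis=(0, 1, 2))
    tgt = ImageVolume(shifted, ref.spacing, ref.origin, frame_index=1)
    return spec, ref, tgt


@pytest.fixture(scope="session")
def ventricle_mask_48(small_static_phantom):
    """Boolean voxel mask of the ventricle (cavity + wall) of the 48^3 phantom."""
    spec, _, _ = small_static_phantom
    idx = np.stack(np.meshgrid(*[np.arange(s) for s in spec.grid_shape],
                               indexing="ij"), axis=-1).astype(float)
    semi = np.array([spec.a_short + spec.wall_thickness,
                     spec.a_short + spec.wall_thickness,
                     spec.a_long + spec.wall_thickness])
    rho = np.linalg.norm((idx * spec.voxel_size - spec.centre) / semi, axis=-1)
    return rho <= 1.0


@pytest.fixture(scope="session")
def reference_segmentation(default_phantom):
    """Region-grown blood pool and smoothed endocardial mesh of frame 0."""
    spec, frames, _ = default_phantom
    mask = imaging.region_grow(frames[0], phantom.default_seeds(spec),
                               margin=30.0)
    mesh = imaging.smooth_mesh(imaging.extract_surface(mask), iterations=10)
    return mask, mesh
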