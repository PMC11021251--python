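"""Signed force images modulating WM-surface deformation.

Convention: positive values drive the surface inward along its normal,
negative values outward.  Magnitudes are normalised to [-1, 1]; the mesh
solver that consumes them is external, so only the spatial supports and
signs matter here.

The first force pushes the surface out of the WM label (-1 inside WM) and
inward away from CSF and the brain boundary (+1 there), with a linear
taper to 0 over ``decay_mm``.  The second is an outward force along thin
strands of relatively bright voxels just outside the WM label — the
partial-volume gyri the first deformation pass misses — restricted to the
pericalcarine zone, where such penetration failures concentrate and where
applying the force globally would cause errors elsewhere.
"""

from __future__ import annotations

import numpy as np

from . import imageops
from .labels import DEFAULT_REGIONS, RegionCodes
from .types import InvalidArgumentError, LabelVolume, Volume, as_mask


def wm_region_force(
    regions: LabelVolume,
    brain: np.ndarray,
    decay_mm: float = 2.0,
    codes: RegionCodes = DEFAULT_REGIONS,
) -> Volume:
    """Region-driven force: -1 inside hemisphere WM, +1 in CSF and within
    ``decay_mm`` of the brain-mask boundary, linear ramp to 0 in between;
    zero outside the brain."""
    brain = as_mask(brain)
    if brain.shape != regions.shape:
        raise InvalidArgumentError("brain mask and regions geometries differ")
    if decay_mm <= 0:
        raise InvalidArgumentError("decay must be positive")
    sp = regions.spacing
    wm = regions.mask(codes.wm_left, codes.wm_right)
    # CSF: brain voxels carrying no region class (the regions image keeps
    # only the six surface-relevant classes)
    csf = brain & (regions.data == codes.background)
    boundary_band = brain & (
        imageops.euclidean_distance(~brain, sp) <= decay_mm + 1e-9
        if not brain.all()
        else np.zeros_like(brain)
    )
    inward = csf | boundary_band

    out = np.zeros(regions.shape, dtype=float)
    if wm.any():
        out -= np.clip(1.0 - imageops.euclidean_distance(wm, sp) / decay_mm, 0.0, 1.0)
    if inward.any():
        out += np.clip(1.0 - imageops.euclidean_distance(inward, sp) / decay_mm, 0.0, 1.0)
    out[inward & ~wm] = 1.0
    out[wm] = -1.0  # WM keeps its outward pull even next to the band
    out[~brain] = 0.0
    return Volume(data=out, spacing=sp, affine=regions.affine)


def thin_strand_force(
    t2: Volume,
    wm_mask: np.ndarray,
    pericalcarine: np.ndarray,
    sigma_mm: float = 1.0,
    depth_mm: float = 2.0,
) -> Volume:
    """Outward force (-1) on thin bright strands just outside the WM label,
    restricted to the dilated pericalcarine zone.  Candidates are locally
    bright voxels (negative second directional derivative) not in WM,
    within ``depth_mm`` outside the WM boundary, inside the dilated
    pericalcarine mask.  Empty pericalcarine -> all-zero force."""
    wm_mask = as_mask(wm_mask)
    pericalcarine = as_mask(pericalcarine)
    if wm_mask.shape != t2.shape or pericalcarine.shape != t2.shape:
        raise InvalidArgumentError("mask geometry differs from image")
    out = np.zeros(t2.shape, dtype=float)
    if not pericalcarine.any() or not wm_mask.any():
        return Volume(data=out, spacing=t2.spacing, affine=t2.affine)
    d2 = imageops.directional_second_derivative(t2, sigma_mm).data
    band = (
        ~wm_mask
        & (imageops.euclidean_distance(wm_mask, t2.spacing) <= depth_mm + 1e-9)
    )
    zone = imageops.dilate_ball(pericalcarine, depth_mm, t2.spacing)
    out[(d2 < 0) & band & zone] = -1.0
    return Volume(data=out, spacing=t2.spacing, affine=t2.affine)
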