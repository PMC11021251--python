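"""Approximate structure masks that guide registration and label fusion.

These masks do not need to be accurate segmentations — they are guides
(fissure, cortical GM, septum pellucidum, lateral ventricles) plus the
auxiliary non-brain training labels (extra-cranial background, skull).
All operators are contrast-driven: they respond to local bright/dark
structure, so adding a global intensity constant leaves every output
unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import imageops
from .types import InvalidArgumentError, Volume, as_mask


@dataclass
class MaskBundle:
    """All maskgen outputs on one geometry."""

    fissure: np.ndarray
    gm: np.ndarray
    sp_left: np.ndarray
    sp_right: np.ndarray
    ventricles: np.ndarray
    cc: np.ndarray
    extracranial_bg: np.ndarray
    skull: np.ndarray


def make_fissure_mask(
    brain: np.ndarray, template_fissure_warped: np.ndarray,
    spacing, dilate_mm: float = 5.0,
) -> np.ndarray:
    """Occipital interhemispheric fissure guide: voxels inside the convex
    hull of the brain mask but not in the brain mask, restricted to the
    dilated warped template fissure mask (removing non-occipital hull
    voxels)."""
    brain = as_mask(brain)
    if not brain.any():
        raise InvalidArgumentError("brain mask is empty")
    tmpl = as_mask(template_fissure_warped)
    if brain.shape != tmpl.shape:
        raise InvalidArgumentError("brain and template mask geometries differ")
    hull_diff = imageops.convex_hull_mask(brain) & ~brain
    if not tmpl.any():
        return np.zeros_like(brain)
    return hull_diff & imageops.dilate_ball(tmpl, dilate_mm, spacing)


def make_gm_mask(
    t2: Volume,
    tissue_gm: np.ndarray,
    sigma_mm: float = 1.0,
    neighbor_dilate_mm: float = 1.0,
    threshold: float = 0.2,
    canny_low_frac: float = 0.5,
    canny_high_frac: float = 0.8,
) -> np.ndarray:
    """Cortical-GM guide mask from the locally-dark stripe response.

    Candidates are voxels with positive second directional derivative
    (locally dark), minus Canny edge voxels.  Each candidate connected
    component is scored by the fraction of its face-neighbour perimeter
    lying in the slightly dilated coarse tissue GM; components scoring at
    least ``threshold`` are kept.  This removes dark periventricular WM
    while retaining the cortical ribbon.

    Canny thresholds are fractions of the maximum gradient magnitude,
    keeping the mask invariant under global intensity offsets.
    """
    tissue_gm = as_mask(tissue_gm)
    if tissue_gm.shape != t2.shape:
        raise InvalidArgumentError("tissue GM and image geometries differ")
    d2 = imageops.directional_second_derivative(t2, sigma_mm).data
    candidates = d2 > 0
    if not candidates.any():
        return candidates

    data = np.asarray(t2.data, dtype=float)
    sig = tuple(sigma_mm / s for s in t2.spacing)
    g = [
        ndimage.gaussian_filter(data, sig, order=tuple(1 if a == i else 0 for a in range(3)))
        / t2.spacing[i]
        for i in range(3)
    ]
    gmax = float(np.sqrt(g[0] ** 2 + g[1] ** 2 + g[2] ** 2).max())
    if gmax > 0:
        edges = imageops.edge_mask(
            t2, low=canny_low_frac * gmax, high=canny_high_frac * gmax, sigma_mm=sigma_mm
        )
        candidates = candidates & ~edges

    ref = imageops.dilate_ball(tissue_gm, neighbor_dilate_mm, t2.spacing)
    labels, sizes = imageops.connected_components(candidates, connectivity=26)
    out = np.zeros_like(candidates)
    for code in range(1, len(sizes) + 1):
        comp = labels == code
        if imageops.component_perimeter_fraction(comp, ref) >= threshold:
            out |= comp
    return out


def make_sp_mask(
    t2: Volume,
    template_sp_warped: np.ndarray,
    side: str,
    max_search_mm: float = 10.0,
    sigma_mm: float = 1.0,
    tau: float | None = None,
    brain: np.ndarray | None = None,
) -> np.ndarray:
    """Septum-pellucidum guide: from each warped template-seed voxel march
    laterally (away from the midline: -x for the left side, +x for the
    right) and add the first relatively dark voxel — positive LoG, or
    intensity below the 3 mm neighbourhood mean minus ``tau``.

    ``tau`` defaults to 0.5 x the within-brain intensity SD (whole-grid SD
    when no brain mask is given).  Seeds with no dark voxel within
    ``max_search_mm`` contribute nothing.
    """
    if side not in ("left", "right"):
        raise InvalidArgumentError(f"side must be 'left' or 'right', got {side!r}")
    tmpl = as_mask(template_sp_warped)
    out = np.zeros_like(tmpl)
    if not tmpl.any():
        return out
    data = np.asarray(t2.data, dtype=float)
    if tau is None:
        vals = data[as_mask(brain)] if brain is not None else data
        tau = 0.5 * float(vals.std())
    log = imageops.laplacian_of_gaussian(t2, sigma_mm).data
    size = [max(1, int(round(3.0 / s)) * 2 + 1) for s in t2.spacing]
    local_mean = ndimage.uniform_filter(data, size=size, mode="nearest")
    dark = (log > 0) | (data < local_mean - tau)

    step = -1 if side == "left" else +1
    max_steps = int(np.floor(max_search_mm / t2.spacing[0]))
    seeds = np.argwhere(tmpl)
    nx = tmpl.shape[0]
    for i, j, k in seeds:
        for s in range(0, max_steps + 1):
            xi = i + step * s
            if xi < 0 or xi >= nx:
                break
            if dark[xi, j, k]:
                out[xi, j, k] = True
                break
    return out


def make_ventricle_mask(
    tissue_ventricles: np.ndarray,
    majority_lv: np.ndarray,
    t2: Volume,
    periventricular: np.ndarray,
    sigma_mm: float = 1.0,
) -> np.ndarray:
    """Lateral-ventricle guide: components of the coarse ventricle tissue
    label that intersect the majority-vote lateral-ventricle labels, minus
    relatively dark voxels (positive LoG — the dark rim) and the dark
    periventricular stripe label."""
    tissue_ventricles = as_mask(tissue_ventricles)
    majority_lv = as_mask(majority_lv)
    labels, sizes = imageops.connected_components(tissue_ventricles, connectivity=26)
    out = np.zeros_like(tissue_ventricles)
    for code in range(1, len(sizes) + 1):
        comp = labels == code
        if (comp & majority_lv).any():
            out |= comp
    if not out.any():
        return out
    log = imageops.laplacian_of_gaussian(t2, sigma_mm).data
    out &= ~(log > 0)
    out &= ~as_mask(periventricular)
    return out


def make_extracranial_bg(brain: np.ndarray, spacing, width_mm: float = 3.0) -> np.ndarray:
    """Voxels outside the brain within ``width_mm`` of its boundary."""
    brain = as_mask(brain)
    if width_mm <= 0 or not brain.any() or brain.all():
        return np.zeros_like(brain)
    d = imageops.euclidean_distance(brain, spacing)
    return (~brain) & (d <= width_mm + 1e-9)


def make_skull_label(t2: Volume, brain: np.ndarray, sigma_mm: float = 1.0) -> np.ndarray:
    """Bright non-brain stripes: negative second directional derivative
    (locally bright) outside the brain mask."""
    brain = as_mask(brain)
    if brain.shape != t2.shape:
        raise InvalidArgumentError("brain mask and image geometries differ")
    d2 = imageops.directional_second_derivative(t2, sigma_mm).data
    return (d2 < 0) & ~brain


def make_cc_mask(majority_cc_warped: np.ndarray) -> np.ndarray:
    """Corpus-callosum guide: passthrough of the warped majority-vote CC
    label (no computation beyond the resampling done upstream)."""
    return as_mask(majority_cc_warped).copy()
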