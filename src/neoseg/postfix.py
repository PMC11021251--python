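"""Rule-based correction of label-fusion outputs and regions-image
construction for surface extraction.

Fusion errors concentrate near the cortex, where folding patterns align
imperfectly and the bright-dark-bright intensity signature of a sulcus is
easily confused with that of a gyrus.  Three deterministic fixes are
applied, in this order:

1. sentinel protection — manually edited WM voxels marked 254/255 are
   rewritten to the ordinary LH/RH WM codes and frozen so no later
   automated step can overwrite them;
2. CSF-island reassignment — CSF components face-touching a hemisphere's
   main WM component become that hemisphere's WM (components touching both
   are split by Chessboard distance);
3. sulcal-bank splitting — WM voxels inside the dilation overlap of a
   configured pair of cortical parcels (opposite banks of a sulcus) are
   reset to CSF.

Finally the regions image is built: a WM composite per hemisphere (WM plus
closing-bridged CC/thalamus, the subcortical absorption set, and the
dilated third ventricle), assigned left/right by Chessboard distance to
the warped ribbon labels, alongside pass-through cortical GM,
brainstem+cerebellum and lateral-ventricle classes.
"""

from __future__ import annotations

import numpy as np

from . import imageops
from .labels import (
    DEFAULT_REGIONS,
    DEFAULT_SCHEME,
    DEFAULT_SULCAL_PAIRS,
    SENTINEL_LH_WM,
    SENTINEL_RH_WM,
    LabelScheme,
    RegionCodes,
)
from .types import InvalidArgumentError, LabelVolume, as_mask

FACE = 6  # "touch" means face adjacency, preventing diagonal leakage


def apply_sentinels(
    labels: LabelVolume, scheme: LabelScheme = DEFAULT_SCHEME
) -> tuple[LabelVolume, np.ndarray]:
    """Rewrite sentinel codes to their WM codes and return the protected
    mask.  Later postfix operations must leave protected voxels unchanged."""
    data = labels.data.copy()
    protected = np.isin(data, list(scheme.sentinel_map))
    for sentinel, code in scheme.sentinel_map.items():
        data[labels.data == sentinel] = code
    return labels.with_data(data), protected


def _main_wm_components(data: np.ndarray, scheme: LabelScheme):
    out = {}
    for side, code in zip(("left", "right"), scheme.wm_codes):
        m = data == code
        out[side] = imageops.largest_component(m, connectivity=26) if m.any() else None
    return out


def reassign_csf_islands(
    labels: LabelVolume,
    scheme: LabelScheme = DEFAULT_SCHEME,
    protected: np.ndarray | None = None,
) -> LabelVolume:
    """Reassign CSF components face-touching the main WM component of a
    hemisphere to that hemisphere's WM.  Components touching both main
    components are split voxelwise by Chessboard distance (ties go left,
    the lower code).  No WM present -> no-op."""
    data = labels.data.copy()
    protected = as_mask(protected) if protected is not None else np.zeros(data.shape, bool)
    main = _main_wm_components(data, scheme)
    if main["left"] is None and main["right"] is None:
        return labels.with_data(data)

    struct = imageops.structure_for_connectivity(FACE)
    halo = {
        s: imageops.binary_dilate(m, struct) if m is not None else None
        for s, m in main.items()
    }
    dist = {}
    csf = data == scheme.csf
    comps, sizes = imageops.connected_components(csf, connectivity=FACE)
    for code in range(1, len(sizes) + 1):
        comp = comps == code
        touch_l = halo["left"] is not None and (comp & halo["left"]).any()
        touch_r = halo["right"] is not None and (comp & halo["right"]).any()
        target = comp & ~protected
        if touch_l and touch_r:
            for side, m in main.items():
                if side not in dist:
                    dist[side] = imageops.chessboard_distance(m)
            go_left = dist["left"] <= dist["right"]  # tie -> left (lower code)
            data[target & go_left] = scheme.wm_left
            data[target & ~go_left] = scheme.wm_right
        elif touch_l:
            data[target] = scheme.wm_left
        elif touch_r:
            data[target] = scheme.wm_right
    return labels.with_data(data)


def split_sulcal_banks(
    labels: LabelVolume,
    pair_list=DEFAULT_SULCAL_PAIRS,
    dilate_mm: float = 2.0,
    scheme: LabelScheme = DEFAULT_SCHEME,
    protected: np.ndarray | None = None,
) -> LabelVolume:
    """Reset WM voxels in the dilation overlap of each configured parcel
    pair to CSF.  The pair list enumerates parcels that face each other
    across a sulcus; the overlap localises inter-bank WM bridges."""
    data = labels.data.copy()
    protected = as_mask(protected) if protected is not None else np.zeros(data.shape, bool)
    elem = imageops.spherical_element(dilate_mm, labels.spacing)
    wm = np.isin(data, scheme.wm_codes)
    for a, b in pair_list:
        ma, mb = data == a, data == b
        if not ma.any() or not mb.any():
            continue
        overlap = imageops.binary_dilate(ma, elem) & imageops.binary_dilate(mb, elem)
        reset = overlap & wm & ~protected
        data[reset] = scheme.csf
    return labels.with_data(data)


def build_regions_image(
    labels: LabelVolume,
    ribbon_warped: LabelVolume,
    scheme: LabelScheme = DEFAULT_SCHEME,
    regions: RegionCodes = DEFAULT_REGIONS,
    close_iters: int = 25,
    v3_dilate_iters: int = 2,
) -> LabelVolume:
    """Build the 6-class regions image consumed by surface extraction.

    The WM composite is the hemisphere WM labels, the voxels added by
    morphological closing (``close_iters`` iterations of the unit
    6-neighbourhood element) of CC plus thalamus — bridging the hemispheres
    at the midline so their border approximates the medial wall — the
    subcortical absorption set, and the third ventricle dilated
    ``v3_dilate_iters`` iterations.  Composite voxels are assigned to the
    hemisphere whose warped ribbon label has the lower Chessboard distance
    (ties go left).  Cortical GM, brainstem+cerebellum and lateral
    ventricles are translated directly from the fusion output.
    """
    if not labels.same_geometry(ribbon_warped):
        raise InvalidArgumentError("ribbon geometry differs from labels")
    rib_l = ribbon_warped.data == scheme.wm_left
    rib_r = ribbon_warped.data == scheme.wm_right
    if not rib_l.any() or not rib_r.any():
        raise InvalidArgumentError("ribbon image must contain both hemisphere WM labels")

    data = labels.data
    composite = np.isin(data, scheme.wm_codes)
    cc_thal = np.isin(
        data, (scheme.cc, scheme.thalamus_left, scheme.thalamus_right)
    )
    if cc_thal.any():
        composite |= imageops.binary_closing(cc_thal, iterations=close_iters)
    composite |= np.isin(data, scheme.wm_absorbed_codes)
    v3 = data == scheme.third_ventricle
    if v3.any():
        composite |= imageops.binary_dilate(v3, iterations=v3_dilate_iters)

    d_l = imageops.chessboard_distance(rib_l)
    d_r = imageops.chessboard_distance(rib_r)
    go_left = d_l <= d_r  # tie -> left

    out = np.zeros(data.shape, dtype=np.int32)
    out[composite & go_left] = regions.wm_left
    out[composite & ~go_left] = regions.wm_right
    out[np.isin(data, scheme.cortical_gm_codes)] = regions.cortical_gm
    out[np.isin(data, scheme.brainstem_cerebellum_codes)] = regions.brainstem_cerebellum
    # lateral ventricles pass through on top of the WM composite
    lv_l = data == scheme.ventricle_left
    lv_r = data == scheme.ventricle_right
    out[lv_l] = regions.ventricle_left
    out[lv_r] = regions.ventricle_right

    table = {
        regions.brainstem_cerebellum: "brainstem+cerebellum",
        regions.cortical_gm: "cortical_gm",
        regions.wm_left: "wm_left",
        regions.wm_right: "wm_right",
        regions.ventricle_left: "lateral_ventricle_left",
        regions.ventricle_right: "lateral_ventricle_right",
    }
    return LabelVolume(
        data=out, spacing=labels.spacing, table=table, affine=labels.affine
    )


def run_postfix(
    labels: LabelVolume,
    ribbon_warped: LabelVolume,
    scheme: LabelScheme = DEFAULT_SCHEME,
    pair_list=DEFAULT_SULCAL_PAIRS,
    sulcal_dilate_mm: float = 2.0,
    regions: RegionCodes = DEFAULT_REGIONS,
    close_iters: int = 25,
    v3_dilate_iters: int = 2,
) -> tuple[LabelVolume, LabelVolume, np.ndarray]:
    """Full postprocessing stage: sentinels -> CSF islands -> sulcal banks
    -> regions image.  Returns (corrected labels, regions, protected)."""
    fixed, protected = apply_sentinels(labels, scheme)
    fixed = reassign_csf_islands(fixed, scheme, protected)
    fixed = split_sulcal_banks(fixed, pair_list, sulcal_dilate_mm, scheme, protected)
    region_img = build_regions_image(
        fixed, ribbon_warped, scheme, regions, close_iters, v3_dilate_iters
    )
    return fixed, region_img, protected
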