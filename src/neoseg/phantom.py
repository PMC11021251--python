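"""Synthetic neonatal-T2 brain phantom with exhaustive ground truth.

The phantom emulates the contrast conventions of a neonatal T2-weighted
scan: unmyelinated WM is bright, the cortical GM ribbon is a dark stripe,
CSF is brightest, and a bright extra-cranial "skull" stripe surrounds the
head.  Geometry: two ellipsoidal hemispheres separated by a CSF midline
gap with a posterior interhemispheric notch; a sinusoidally folded GM
ribbon with one deep sulcus (parcellated banks) and one thin bright gyral
strand inside a designated pericalcarine zone; bright lateral ventricles
wrapped in a dark periventricular stripe; dark septum pellucidum slabs
offset laterally from their template seeds; a corpus-callosum bridge
crossing the midline; a cerebellum+brainstem blob; smooth multiplicative
bias and additive Gaussian noise.

Everything downstream (skull-strip refinement, mask generation, fusion,
postprocessing, force images) is tested against the ground truth produced
here.  Generation is fully deterministic from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import imageops
from .labels import DEFAULT_SCHEME, LabelScheme
from .types import InvalidArgumentError, LabelVolume, Volume

DEFAULT_MEANS = {
    "background": 10.0,
    "skull": 90.0,
    "csf": 100.0,
    "gm": 40.0,
    "wm": 70.0,
    "ventricle": 100.0,
    "periventricular": 30.0,
    "septum": 30.0,
    "thalamus": 70.0,
    "cerebellum": 55.0,
    "third_ventricle": 100.0,
    "cc": 70.0,
}


@dataclass
class PhantomSpec:
    """Generation parameters.  Intensity means are on an arbitrary scale
    chosen so adjacent tissue classes are separated by at least three
    default noise SDs (GM < WM < CSF, the T2 neonatal ordering)."""

    size: int = 64
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    means: dict = field(default_factory=lambda: dict(DEFAULT_MEANS))
    noise_sd: float = 3.0
    bias_amplitude: float = 0.05
    n_folds: int = 6
    fold_amplitude: float = 0.055
    ribbon_mm: float = 3.0
    rim_mm: float = 3.0
    thin_gyrus_width_mm: float = 1.0
    notch_depth_mm: float = 8.0
    sp_offset_vox: int = 2
    seed: int = 0


@dataclass
class PhantomTruth:
    """Ground-truth bundle consumed by the pipeline stages and their tests."""

    t2: Volume
    labels: LabelVolume
    brain: np.ndarray
    tissue_gm: np.ndarray          # DrawEM-style coarse GM (with a planted gap)
    tissue_ventricles: np.ndarray  # DrawEM-style ventricles (with a false blob)
    ribbon: LabelVolume            # LH/RH WM codes meeting at the midline
    template_fissure: np.ndarray
    template_sp_left: np.ndarray
    template_sp_right: np.ndarray
    skull_stripe: np.ndarray       # bright shell following the head envelope
    scalp_bridge: np.ndarray       # bright attachment connecting shell to head
    thin_strand: np.ndarray        # bright GM-labelled strand (pericalcarine)
    scheme: LabelScheme = field(default_factory=lambda: DEFAULT_SCHEME)
    spec: PhantomSpec = field(default_factory=PhantomSpec)

    @property
    def wm_mask(self) -> np.ndarray:
        return self.labels.mask(*self.scheme.wm_codes)

    @property
    def gm_mask(self) -> np.ndarray:
        return self.labels.mask(*self.scheme.cortical_gm_codes)

    @property
    def ventricle_mask(self) -> np.ndarray:
        return self.labels.mask(*self.scheme.ventricle_codes)

    @property
    def csf_mask(self) -> np.ndarray:
        return self.labels.mask(self.scheme.csf)


def _smooth_noise(rng, shape, sigma_vox):
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma_vox)
    m = np.abs(f).max()
    return f / m if m > 0 else f


def make_phantom(spec: PhantomSpec | None = None) -> PhantomTruth:
    """Build the phantom; see the module docstring for the geometry."""
    spec = spec or PhantomSpec()
    n = spec.size
    if n < 48:
        raise InvalidArgumentError(f"grid of {n}^3 too small to host all structures (need >= 48)")
    sp = tuple(float(s) for s in spec.spacing)
    if any(s <= 0 for s in sp):
        raise InvalidArgumentError(f"spacing must be positive, got {sp}")
    sch = DEFAULT_SCHEME
    rng = np.random.default_rng(spec.seed)

    cx, cy, cz = (n - 1) / 2.0, (n - 1) / 2.0, (n - 1) / 2.0
    x, y, z = np.meshgrid(np.arange(n), np.arange(n), np.arange(n), indexing="ij")
    xm, ym, zm = x * sp[0], y * sp[1], z * sp[2]  # mm coordinates
    cxm, cym, czm = cx * sp[0], cy * sp[1], cz * sp[2]

    ax, ay, az = 0.19 * n * sp[0], 0.36 * n * sp[1], 0.33 * n * sp[2]
    gap_mm = 1.0 * sp[0]  # half-width of the midline CSF gap
    theta = np.arctan2(zm - czm, ym - cym)

    labels = np.zeros((n, n, n), dtype=np.int32)
    t2 = np.full((n, n, n), spec.means["background"], dtype=float)

    # per-hemisphere radial anatomy ------------------------------------
    hemi_depth = {}
    for side, sgn in (("left", -1), ("right", +1)):
        hx = cxm + sgn * (ax + gap_mm)
        ux, uy, uz = (xm - hx) / ax, (ym - cym) / ay, (zm - czm) / az
        rho = np.sqrt(ux * ux + uy * uy + uz * uz)
        rho_b = 1.0 + spec.fold_amplitude * np.sin(spec.n_folds * theta)
        pr = np.sqrt((xm - hx) ** 2 + (ym - cym) ** 2 + (zm - czm) ** 2)
        rdir = pr / np.maximum(rho, 1e-9)
        depth = rdir * (rho_b - rho)  # mm inward from the folded boundary
        depth[rho < 1e-9] = min(ax, ay, az)
        hemi_depth[side] = depth

    depth_l, depth_r = hemi_depth["left"], hemi_depth["right"]
    depth = np.maximum(depth_l, depth_r)
    in_left = depth_l >= depth_r

    rim, rib = spec.rim_mm, spec.rim_mm + spec.ribbon_mm
    hemi = depth >= 0
    labels[hemi] = sch.csf
    gm_shell = hemi & (depth >= rim) & (depth < rib)
    labels[gm_shell & in_left] = sch.gm_left
    labels[gm_shell & ~in_left] = sch.gm_right
    wm_core = hemi & (depth >= rib)
    labels[wm_core & in_left] = sch.wm_left
    labels[wm_core & ~in_left] = sch.wm_right

    # deep sulcus with parcellated banks (superior temporal / supramarginal);
    # an inferior planar groove, kept well clear of the periventricular
    # stripe so the dark structures stay disconnected
    theta_s = -np.pi / 2
    r_yz = np.sqrt((ym - cym) ** 2 + (zm - czm) ** 2)
    dtheta = np.mod(theta - theta_s + np.pi, 2 * np.pi) - np.pi
    arc = dtheta * r_yz  # mm, used for bank sidedness
    # distance to the plane through the x-axis at angle theta_s, windowed
    # in angle so the groove is a localized fold, not a full ring
    plane_dist = np.abs(
        -(ym - cym) * np.sin(theta_s) + (zm - czm) * np.cos(theta_s)
    )
    slit_depth = rib + 2.0 * min(sp)
    r_slit = 0.36 * min(ay, az)  # outer convex shell only, off the medial wall
    slit = (
        hemi & (plane_dist < 1.0 * min(sp)) & (np.abs(dtheta) < 0.6)
        & (depth < slit_depth) & (r_yz > r_slit)
    )
    labels[slit] = sch.csf
    # re-line the carved sulcus with GM so CSF never touches WM
    lining = imageops.binary_dilate(slit, iterations=2) & np.isin(labels, sch.wm_codes)
    labels[lining & in_left] = sch.gm_left
    labels[lining & ~in_left] = sch.gm_right

    # cortical parcels on the two banks of the sulcus
    parcel_w = 0.45
    gm_now = np.isin(labels, (sch.gm_left, sch.gm_right))
    # banks exclude the sulcal fundus so the two parcels only face each
    # other across the slit CSF, never through WM underneath it
    bank_depth = slit_depth - 1.0
    banks_r = r_yz > r_slit + 2.0 * min(sp)  # only where the slit separates them
    bankA = gm_now & banks_r & (arc < 0) & ((theta_s - theta) < parcel_w) & (depth < bank_depth)
    bankB = gm_now & banks_r & (arc >= 0) & ((theta - theta_s) < parcel_w) & (depth < bank_depth)
    labels[bankA & in_left] = sch.superior_temporal_left
    labels[bankA & ~in_left] = sch.superior_temporal_right
    labels[bankB & in_left] = sch.supramarginal_left
    labels[bankB & ~in_left] = sch.supramarginal_right

    # pericalcarine zone (posterior-inferior) with a thin bright gyral strand
    theta_pc = -np.pi + np.pi / 2 / spec.n_folds  # posterior-inferior window
    d_pc = np.abs(np.mod(theta - theta_pc + np.pi, 2 * np.pi) - np.pi)
    pc_zone = gm_now & (d_pc < 0.5)
    labels[pc_zone & in_left] = sch.pericalcarine_left
    labels[pc_zone & ~in_left] = sch.pericalcarine_right
    strand = np.zeros_like(hemi)
    for side, sgn in (("left", -1), ("right", +1)):
        hx = cxm + sgn * (ax + gap_mm)
        slab = np.abs(xm - hx) <= spec.thin_gyrus_width_mm / 2.0
        strand |= (
            slab & (d_pc < 0.15)
            & np.isin(labels, (sch.pericalcarine_left, sch.pericalcarine_right))
        )

    # midline gap: CSF inside the brain, except the posterior fissure notch
    gap = (np.abs(xm - cxm) < gap_mm) & (r_yz < 0.95 * min(ay, az)) & (depth < 0)
    y_notch = (ym - cym) < -(ay - spec.notch_depth_mm)
    notch = gap & y_notch
    labels[gap & ~notch] = sch.csf

    # lateral ventricles + dark periventricular stripe
    vent = np.zeros_like(hemi)
    for side, sgn in (("left", -1), ("right", +1)):
        vx = cxm + sgn * (ax + gap_mm)  # above the deep hemisphere core
        v = (
            ((xm - vx) / (0.12 * ax * 2)) ** 2
            + ((ym - cym - 1.0) / (0.28 * ay)) ** 2
            + ((zm - czm - 3.0) / (0.17 * az)) ** 2
        ) <= 1.0
        v &= depth >= rib + 3.0  # deep inside WM, clear of the GM ribbon
        code = sch.ventricle_left if side == "left" else sch.ventricle_right
        labels[v] = code
        vent |= v
    stripe = imageops.binary_dilate(vent, iterations=1) & ~vent & np.isin(labels, sch.wm_codes)
    labels[stripe & in_left] = sch.periventricular_left
    labels[stripe & ~in_left] = sch.periventricular_right

    # corpus callosum bridge + third ventricle at the midline
    cc = (
        (np.abs(xm - cxm) <= ax * 0.5 + gap_mm)
        & (np.abs(ym - cym) <= 3.0)
        & (zm - czm >= 0.0) & (zm - czm <= 4.0)
    )
    labels[cc] = sch.cc
    v3 = (
        (np.abs(xm - cxm) <= 1.0)
        & (np.abs(ym - cym) <= 2.0)
        & (zm - czm >= -4.0) & (zm - czm <= -1.0)
    )
    labels[v3] = sch.third_ventricle

    # thalami inside deep WM, flanking the third ventricle
    for side, sgn in (("left", -1), ("right", +1)):
        tx = cxm + sgn * (gap_mm + 0.30 * ax)
        th = (
            ((xm - tx) / 2.5) ** 2 + ((ym - cym) / 3.5) ** 2 + ((zm - czm + 2.0) / 3.0) ** 2
        ) <= 1.0
        th &= depth >= rib
        labels[th] = sch.thalamus_left if side == "left" else sch.thalamus_right

    # septum pellucidum: template seeds near the midline, true dark slabs
    # offset laterally (the typical template-to-subject mismatch)
    tmpl_sp = {}
    slab_yz = (np.abs(ym - cym - 1.0) <= 2.0) & (np.abs(zm - czm + 5.0) <= 1.5)
    for side, sgn in (("left", -1), ("right", +1)):
        # anchor the true dark slab one column deep into the medial WM wall;
        # the template seed sits sp_offset_vox columns closer to the midline
        hemi_side = (x < cx) if side == "left" else (x > cx)
        wm_cols = np.argwhere(slab_yz & hemi_side & np.isin(labels, sch.wm_codes))[:, 0]
        # slab three columns into the WM wall; the seed sits between the
        # slab and the midline, inside bright WM, so the lateral march
        # crosses bright voxels before reaching the dark slab
        if side == "left":
            x_t = wm_cols.max() - 3
        else:
            x_t = wm_cols.min() + 3
        x_s = x_t - sgn * spec.sp_offset_vox
        seed_slab = (x == x_s) & slab_yz
        tmpl_sp[side] = seed_slab
        true_slab = (x == x_t) & slab_yz & np.isin(labels, sch.wm_codes)
        labels[true_slab] = sch.septum_left if side == "left" else sch.septum_right

    # cerebellum + brainstem blob, overlapping the inferior-posterior brain
    cb = (
        ((xm - cxm) / (0.20 * n * sp[0])) ** 2
        + ((ym - cym + 0.20 * n * sp[1]) / (0.14 * n * sp[1])) ** 2
        + ((zm - czm + 0.24 * n * sp[2]) / (0.10 * n * sp[2])) ** 2
    ) <= 1.0
    labels[cb & (labels == 0)] = sch.brainstem

    # enforce the adjacency invariant: no CSF voxel face-adjacent to WM
    for _ in range(4):
        bad = (
            imageops.binary_dilate(labels == sch.csf, imageops.structure_for_connectivity(6))
            & np.isin(labels, sch.wm_codes)
        )
        if not bad.any():
            break
        labels[bad & in_left] = sch.gm_left
        labels[bad & ~in_left] = sch.gm_right

    brain = labels > 0

    # extra-cranial bright skull stripe, 2-4 mm off the head envelope (the
    # skull follows the head's convex shape, not the brain's concavities)
    envelope = imageops.close_ball(brain, 10.0, sp)
    d_env = ndimage.distance_transform_edt(~envelope, sampling=sp)
    skull_stripe = (d_env >= 2.0) & (d_env <= 4.0)
    # bright bridge attaching the stripe to the head (BET-style leftover)
    bridge = (
        ~brain & (d_env < 4.0)
        & (np.abs(zm - czm - 0.30 * n * sp[2]) <= 1.0) & (np.abs(ym - cym) <= 1.0)
        & (xm > cxm)
    )

    # intensities --------------------------------------------------------
    m = spec.means
    code_mean = {
        sch.csf: m["csf"],
        sch.gm_left: m["gm"], sch.gm_right: m["gm"],
        sch.wm_left: m["wm"], sch.wm_right: m["wm"],
        sch.ventricle_left: m["ventricle"], sch.ventricle_right: m["ventricle"],
        sch.periventricular_left: m["periventricular"],
        sch.periventricular_right: m["periventricular"],
        sch.septum_left: m["septum"], sch.septum_right: m["septum"],
        sch.thalamus_left: m["thalamus"], sch.thalamus_right: m["thalamus"],
        sch.cc: m["cc"], sch.third_ventricle: m["third_ventricle"],
        sch.brainstem: m["cerebellum"],
        sch.pericalcarine_left: m["gm"], sch.pericalcarine_right: m["gm"],
        sch.superior_temporal_left: m["gm"], sch.superior_temporal_right: m["gm"],
        sch.supramarginal_left: m["gm"], sch.supramarginal_right: m["gm"],
    }
    for code, mean in code_mean.items():
        t2[labels == code] = mean
    t2[strand] = m["wm"]        # the thin gyrus is bright but GM-labelled
    t2[notch] = m["csf"]        # fissure CSF outside the brain mask
    t2[skull_stripe | bridge] = m["skull"]

    if spec.bias_amplitude > 0:
        bias = 1.0 + spec.bias_amplitude * _smooth_noise(
            rng, t2.shape, tuple(12.0 / s for s in sp)
        )
        t2 = t2 * bias
    if spec.noise_sd > 0:
        t2 = t2 + rng.normal(0.0, spec.noise_sd, t2.shape)

    # DrawEM-style coarse stand-ins -------------------------------------
    gm_all = np.isin(labels, sch.cortical_gm_codes)
    missing = (d_pc > 2.2) & (d_pc < 2.6)  # planted DrawEM gap
    tissue_gm = gm_all & ~missing
    false_blob = (
        ((xm - cxm - 0.55 * ax - gap_mm) / 2.0) ** 2
        + ((ym - cym + 0.45 * ay) / 2.0) ** 2 + ((zm - czm) / 2.0) ** 2
    ) <= 1.0
    false_blob &= np.isin(labels, sch.wm_codes)
    tissue_ventricles = vent | false_blob

    ribbon_data = np.zeros_like(labels)
    rib_zone = imageops.binary_dilate(brain, iterations=2)
    ribbon_data[rib_zone & (xm < cxm)] = sch.wm_left
    ribbon_data[rib_zone & (xm >= cxm)] = sch.wm_right

    tmpl_fissure = imageops.binary_dilate(notch, iterations=2) if notch.any() else notch

    geom = dict(spacing=sp)
    vol = Volume(data=t2, **geom)
    return PhantomTruth(
        t2=vol,
        labels=LabelVolume(data=labels, table=sch.names(), **geom),
        brain=brain,
        tissue_gm=tissue_gm,
        tissue_ventricles=tissue_ventricles,
        ribbon=LabelVolume(data=ribbon_data, table=sch.names(), **geom),
        template_fissure=tmpl_fissure,
        template_sp_left=tmpl_sp["left"],
        template_sp_right=tmpl_sp["right"],
        skull_stripe=skull_stripe,
        scalp_bridge=bridge,
        thin_strand=strand,
        scheme=sch,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# atlas simulation
# ---------------------------------------------------------------------------

def warp_volume(data: np.ndarray, disp_vox: list[np.ndarray], order: int) -> np.ndarray:
    idx = np.indices(data.shape, dtype=float)
    coords = [idx[i] + disp_vox[i] for i in range(3)]
    return ndimage.map_coordinates(data, coords, order=order, mode="nearest")


def random_displacement(rng, shape, spacing, warp_mm: float, smooth_mm: float = 8.0):
    """Smooth random displacement field with max magnitude ``warp_mm``."""
    fields = [
        ndimage.gaussian_filter(rng.standard_normal(shape), tuple(smooth_mm / s for s in spacing))
        for _ in range(3)
    ]
    mag = np.sqrt(sum((f * spacing[i]) ** 2 for i, f in enumerate(fields)))
    peak = mag.max()
    scale = warp_mm / peak if peak > 0 else 0.0
    return [f * scale for f in fields]


def make_atlas_set(
    truth: PhantomTruth, n: int = 5, warp_mm: float = 1.0,
    noise_sd: float = 5.0, seed: int = 0,
) -> list[tuple[Volume, LabelVolume]]:
    """n copies of (t2, labels) under independent smooth random warps plus
    intensity noise — the residual misalignment left by atlas-to-subject
    registration.  Labels are resampled nearest-neighbour, intensities
    trilinearly."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        disp = random_displacement(rng, truth.t2.shape, truth.t2.spacing, warp_mm)
        disp_vox = [d / truth.t2.spacing[i] for i, d in enumerate(disp)]
        inten = warp_volume(truth.t2.data, disp_vox, order=1)
        if noise_sd > 0:
            inten = inten + rng.normal(0.0, noise_sd, inten.shape)
        lab = warp_volume(truth.labels.data, disp_vox, order=0)
        out.append(
            (truth.t2.with_data(inten), truth.labels.with_data(lab.astype(np.int32)))
        )
    return out


# ---------------------------------------------------------------------------
# planted corruptions for the postprocessing round-trips
# ---------------------------------------------------------------------------

def corrupt_labels(
    truth: PhantomTruth, mode: str | None, seed: int = 0,
    sulcal_dilate_mm: float = 2.0,
) -> tuple[LabelVolume, np.ndarray]:
    """Plant one of the error patterns the postprocessing rules repair.

    Returns ``(labels, planted)`` where ``planted`` marks the altered
    voxels.  Modes: ``csf_island`` (a CSF pocket inside the main LH WM
    component), ``sulcal_bridge`` (inter-bank sulcal CSF filled with WM),
    ``pial5_occlusion`` (a gyral WM strand cut to GM, the manual-edit
    scenario).  ``None`` returns the labels unchanged.
    """
    sch = truth.scheme
    data = truth.labels.data.copy()
    planted = np.zeros(data.shape, dtype=bool)
    if mode is None:
        return truth.labels.with_data(data), planted
    rng = np.random.default_rng(seed)

    if mode == "csf_island":
        wm = data == sch.wm_left
        core = imageops.binary_erode(wm, iterations=3)
        if not core.any():
            raise InvalidArgumentError("phantom WM too thin to host a CSF island")
        cand = np.argwhere(core)
        i, j, k = cand[rng.integers(len(cand))]
        sl = (slice(i - 1, i + 2), slice(j - 1, j + 2), slice(k - 1, k + 2))
        pocket = np.zeros_like(wm)
        pocket[sl] = True
        pocket &= wm
        data[pocket] = sch.csf
        planted = pocket
    elif mode == "sulcal_bridge":
        sp = truth.labels.spacing
        elem = imageops.spherical_element(sulcal_dilate_mm, sp)
        inter_l = (
            imageops.binary_dilate(data == sch.superior_temporal_left, elem)
            & imageops.binary_dilate(data == sch.supramarginal_left, elem)
        )
        inter_r = (
            imageops.binary_dilate(data == sch.superior_temporal_right, elem)
            & imageops.binary_dilate(data == sch.supramarginal_right, elem)
        )
        bridge_l = inter_l & (data == sch.csf)
        bridge_r = inter_r & (data == sch.csf)
        data[bridge_l] = sch.wm_left
        data[bridge_r] = sch.wm_right
        planted = bridge_l | bridge_r
        if not planted.any():
            raise InvalidArgumentError("no sulcal CSF between the configured parcel pairs")
    elif mode == "pial5_occlusion":
        cut = truth.thin_strand & (truth.labels.data > 0)
        # the strand is GM-labelled bright WM; the occlusion error labels
        # the adjacent true-WM crown as GM, severing the gyral WM strand
        crown = (
            imageops.binary_dilate(truth.thin_strand, iterations=1)
            & np.isin(data, sch.wm_codes)
        )
        if not crown.any():
            crown = cut
        lh = data == sch.wm_left
        planted = crown.copy()
        data[crown & lh] = sch.gm_left
        data[crown & ~lh] = sch.gm_right
        if not planted.any():
            raise InvalidArgumentError("no gyral WM strand found to occlude")
    else:
        raise InvalidArgumentError(f"unknown corruption mode {mode!r}")
    return truth.labels.with_data(data), planted
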