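"""Pipeline staging: directory layout, stage execution and provenance.

Layout (per subject id, relative to a base directory):

    RawT2/<id>.nii.gz                           raw T2-weighted input
    TissueSegMCRIBS/<id>/...                    masks, atlases, fusion output
    SurfReconDeformable/<id>/recon/regions.nii.gz   surface-extraction input
    stage_status.tsv                            subject id -> last file made

Stages run in the order skullstrip -> maskgen -> fuse -> postfix -> forces;
each records the last file it wrote so failures are diagnosable.  If
``<id>_labelfusion_dkt_edited.nii.gz`` is newer than the fusion output,
downstream stages consume the edited file and honour its sentinel codes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import forces as forces_mod
from . import fusion, maskgen, phantom, postfix, skullstrip
from .labels import DEFAULT_SCHEME, DEFAULT_SULCAL_PAIRS
from .nifti import (
    read_labels,
    read_mask,
    read_volume,
    write_labels,
    write_mask,
    write_volume,
)
from .types import StageDependencyError

STAGES = ("skullstrip", "maskgen", "fuse", "postfix", "forces")


@dataclass
class PipelineConfig:
    subject: str
    base: Path
    seed: int = 0
    n_atlases: int = 5
    patch_mm: float = 2.0
    r_near: float = 2.0
    r_far: float = 1.0
    beta: float = 2.0
    open_mm: float = 4.0
    close_mm: float = 7.0
    k: int = 4
    sulcal_dilate_mm: float = 2.0
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.base = Path(self.base)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        cfg = yaml.safe_load(Path(path).read_text())
        return cls(**cfg)

    # -- paths -----------------------------------------------------------
    @property
    def raw_t2(self) -> Path:
        return self.base / "RawT2" / f"{self.subject}.nii.gz"

    @property
    def tisdir(self) -> Path:
        return self.base / "TissueSegMCRIBS" / self.subject

    @property
    def recondir(self) -> Path:
        return self.base / "SurfReconDeformable" / self.subject / "recon"

    def tis(self, suffix: str) -> Path:
        return self.tisdir / f"{self.subject}_{suffix}"

    @property
    def fusion_out(self) -> Path:
        return self.tis("labelfusion_dkt.nii.gz")

    @property
    def fusion_edited(self) -> Path:
        return self.tis("labelfusion_dkt_edited.nii.gz")

    @property
    def status_file(self) -> Path:
        return self.base / "stage_status.tsv"


def _record(cfg: PipelineConfig, stage: str, last_file: Path) -> None:
    cfg.status_file.parent.mkdir(parents=True, exist_ok=True)
    with cfg.status_file.open("a") as fh:
        fh.write(f"{cfg.subject}\t{stage}\t{last_file}\n")


def _log_provenance(cfg: PipelineConfig, stage: str, params: dict, inputs: list[Path]) -> None:
    entry = {
        "stage": stage,
        "seed": cfg.seed,
        "params": {k: str(v) for k, v in params.items()},
        "inputs": {
            str(p): hashlib.sha256(p.read_bytes()).hexdigest()[:16]
            for p in inputs if p.exists()
        },
    }
    log = cfg.tisdir / f"{cfg.subject}_provenance.jsonl"
    log.parent.mkdir(parents=True, exist_ok=True)
    with log.open("a") as fh:
        fh.write(json.dumps(entry, sort_keys=True) + "\n")


def _require(*paths: Path) -> None:
    missing = [str(p) for p in paths if not p.exists()]
    if missing:
        raise StageDependencyError(
            "missing prerequisite output(s): " + ", ".join(missing)
        )


def write_phantom_subject(cfg: PipelineConfig, spec: phantom.PhantomSpec | None = None):
    """Generate a phantom subject under the pipeline layout, standing in
    for the external inputs (raw T2, BET mask, coarse tissue labels,
    registered atlases, warped template masks, majority-vote labels)."""
    spec = spec or phantom.PhantomSpec(seed=cfg.seed)
    truth = phantom.make_phantom(spec)
    sch = truth.scheme
    sp = truth.t2.spacing
    write_volume(truth.t2, cfg.raw_t2)
    t = cfg.tis
    # BET stand-in: ground-truth brain dilated 3 mm plus attached bright
    # scalp fragments (the over-inclusion of a conservative BET threshold)
    from . import imageops

    init = (
        imageops.dilate_ball(truth.brain, 3.0, sp)
        | truth.skull_stripe | truth.scalp_bridge
    )
    write_mask(init, truth.t2, t("init_brain_mask.nii.gz"))
    write_mask(truth.brain, truth.t2, t("truth_brain_mask.nii.gz"))
    write_labels(truth.labels, t("truth_labels.nii.gz"))
    write_mask(truth.tissue_gm, truth.t2, t("tissue_gm.nii.gz"))
    write_mask(truth.tissue_ventricles, truth.t2, t("tissue_ventricles.nii.gz"))
    write_mask(truth.labels.mask(*sch.ventricle_codes), truth.t2, t("majority_lv.nii.gz"))
    write_mask(truth.labels.mask(sch.cc), truth.t2, t("majority_cc.nii.gz"))
    write_mask(
        truth.labels.mask(sch.periventricular_left, sch.periventricular_right),
        truth.t2, t("periventricular.nii.gz"),
    )
    write_mask(truth.template_fissure, truth.t2, t("template_fissure.nii.gz"))
    write_mask(truth.template_sp_left, truth.t2, t("template_sp_left.nii.gz"))
    write_mask(truth.template_sp_right, truth.t2, t("template_sp_right.nii.gz"))
    write_labels(truth.ribbon, t("ribbon.nii.gz"))
    atlases = phantom.make_atlas_set(truth, n=cfg.n_atlases, seed=cfg.seed + 1)
    for i, (inten, lab) in enumerate(atlases):
        write_volume(inten, t(f"atlas{i}_t2.nii.gz"))
        write_labels(lab, t(f"atlas{i}_labels.nii.gz"))
    manifest = {
        "seed": spec.seed, "size": spec.size, "n_atlases": cfg.n_atlases,
        "noise_sd": spec.noise_sd, "bias_amplitude": spec.bias_amplitude,
    }
    (cfg.tisdir / f"{cfg.subject}_phantom_manifest.json").write_text(
        json.dumps(manifest, indent=2)
    )
    return truth


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_skullstrip(cfg: PipelineConfig) -> Path:
    _require(cfg.raw_t2, cfg.tis("init_brain_mask.nii.gz"))
    t2 = read_volume(cfg.raw_t2)
    init = read_mask(cfg.tis("init_brain_mask.nii.gz"))
    mask = skullstrip.refine_brain_mask(
        t2, init, k=cfg.k, open_mm=cfg.open_mm, close_mm=cfg.close_mm, seed=cfg.seed
    )
    write_mask(mask, t2, cfg.tis("brain_mask.nii.gz"))
    crop = skullstrip.crop_and_resample(t2, mask, "volume-preserving", pad_mm=2.0)
    last = write_volume(crop.cropped, cfg.tis("t2_cropped.nii.gz"))
    _log_provenance(cfg, "skullstrip",
                    dict(k=cfg.k, open_mm=cfg.open_mm, close_mm=cfg.close_mm),
                    [cfg.raw_t2])
    _record(cfg, "skullstrip", last)
    return last


def stage_maskgen(cfg: PipelineConfig) -> Path:
    t = cfg.tis
    _require(cfg.raw_t2, t("brain_mask.nii.gz"), t("tissue_gm.nii.gz"),
             t("tissue_ventricles.nii.gz"), t("template_fissure.nii.gz"),
             t("template_sp_left.nii.gz"), t("template_sp_right.nii.gz"),
             t("majority_lv.nii.gz"), t("majority_cc.nii.gz"))
    t2 = read_volume(cfg.raw_t2)
    brain = read_mask(t("brain_mask.nii.gz"))
    sp = t2.spacing
    bundle = maskgen.MaskBundle(
        fissure=maskgen.make_fissure_mask(
            brain, read_mask(t("template_fissure.nii.gz")), sp
        ),
        gm=maskgen.make_gm_mask(t2, read_mask(t("tissue_gm.nii.gz"))),
        sp_left=maskgen.make_sp_mask(
            t2, read_mask(t("template_sp_left.nii.gz")), "left", brain=brain
        ),
        sp_right=maskgen.make_sp_mask(
            t2, read_mask(t("template_sp_right.nii.gz")), "right", brain=brain
        ),
        ventricles=maskgen.make_ventricle_mask(
            read_mask(t("tissue_ventricles.nii.gz")),
            read_mask(t("majority_lv.nii.gz")),
            t2,
            read_mask(t("periventricular.nii.gz"))
            if t("periventricular.nii.gz").exists()
            else np.zeros(t2.shape, dtype=bool),
        ),
        cc=maskgen.make_cc_mask(read_mask(t("majority_cc.nii.gz"))),
        extracranial_bg=maskgen.make_extracranial_bg(brain, sp),
        skull=maskgen.make_skull_label(t2, brain),
    )
    last = None
    for name in ("fissure", "gm", "sp_left", "sp_right", "ventricles", "cc",
                 "extracranial_bg", "skull"):
        last = write_mask(getattr(bundle, name), t2, t(f"mask_{name}.nii.gz"))
    _log_provenance(cfg, "maskgen", dict(), [cfg.raw_t2, t("brain_mask.nii.gz")])
    _record(cfg, "maskgen", last)
    return last


def stage_fuse(cfg: PipelineConfig) -> Path:
    t = cfg.tis
    _require(cfg.raw_t2, t("mask_gm.nii.gz"), t("atlas0_t2.nii.gz"))
    t2 = read_volume(cfg.raw_t2)
    atlases = []
    i = 0
    while t(f"atlas{i}_t2.nii.gz").exists():
        atlases.append(
            (read_volume(t(f"atlas{i}_t2.nii.gz")), read_labels(t(f"atlas{i}_labels.nii.gz")))
        )
        i += 1
    gm = read_mask(t("mask_gm.nii.gz"))
    rmap = fusion.build_radius_map(gm, t2.spacing, r_near=cfg.r_near, r_far=cfg.r_far)
    labels, conf = fusion.fuse_labels(
        t2, atlases, patch_mm=cfg.patch_mm, radius_map=rmap, beta=cfg.beta
    )
    write_labels(labels, cfg.fusion_out)
    # the fusion output is copied immediately so manual edits have a
    # canonical place to live without clobbering the raw result
    write_labels(labels, cfg.fusion_edited)
    last = write_volume(conf, t("labelfusion_confidence.nii.gz"))
    _log_provenance(cfg, "fuse",
                    dict(patch_mm=cfg.patch_mm, r_near=cfg.r_near,
                         r_far=cfg.r_far, beta=cfg.beta, n_atlases=len(atlases)),
                    [cfg.raw_t2])
    _record(cfg, "fuse", last)
    return last


def _fusion_input(cfg: PipelineConfig) -> Path:
    """Edited-file precedence: consume the edited fusion labels when they
    are at least as new as the raw fusion output."""
    if cfg.fusion_edited.exists() and (
        not cfg.fusion_out.exists()
        or cfg.fusion_edited.stat().st_mtime >= cfg.fusion_out.stat().st_mtime
    ):
        return cfg.fusion_edited
    return cfg.fusion_out


def stage_postfix(cfg: PipelineConfig) -> Path:
    t = cfg.tis
    src = _fusion_input(cfg)
    _require(src, t("ribbon.nii.gz"))
    labels = read_labels(src, table=DEFAULT_SCHEME.names())
    ribbon = read_labels(t("ribbon.nii.gz"))
    fixed, regions, protected = postfix.run_postfix(
        labels, ribbon, DEFAULT_SCHEME, DEFAULT_SULCAL_PAIRS, cfg.sulcal_dilate_mm
    )
    write_labels(fixed, t("labelfusion_dkt_fixed.nii.gz"))
    write_mask(protected, labels, t("protected.nii.gz"))
    last = write_labels(regions, cfg.recondir / "regions.nii.gz")
    _log_provenance(cfg, "postfix", dict(sulcal_dilate_mm=cfg.sulcal_dilate_mm), [src])
    _record(cfg, "postfix", last)
    return last


def stage_forces(cfg: PipelineConfig) -> Path:
    t = cfg.tis
    regions_path = cfg.recondir / "regions.nii.gz"
    _require(cfg.raw_t2, regions_path, t("brain_mask.nii.gz"))
    t2 = read_volume(cfg.raw_t2)
    regions = read_labels(regions_path)
    brain = read_mask(t("brain_mask.nii.gz"))
    f1 = forces_mod.wm_region_force(regions, brain)
    src = _fusion_input(cfg)
    labels = read_labels(src) if src.exists() else None
    sch = DEFAULT_SCHEME
    if labels is not None:
        wm = labels.mask(*sch.wm_codes)
        pc = labels.mask(sch.pericalcarine_left, sch.pericalcarine_right)
    else:
        from .labels import DEFAULT_REGIONS

        wm = regions.mask(DEFAULT_REGIONS.wm_left, DEFAULT_REGIONS.wm_right)
        pc = np.zeros(regions.shape, dtype=bool)
    f2 = forces_mod.thin_strand_force(t2, wm, pc)
    write_volume(f1, cfg.recondir / "wm_force.nii.gz")
    last = write_volume(f2, cfg.recondir / "thin_strand_force.nii.gz")
    _log_provenance(cfg, "forces", dict(), [regions_path])
    _record(cfg, "forces", last)
    return last


_STAGE_FNS = {
    "skullstrip": stage_skullstrip,
    "maskgen": stage_maskgen,
    "fuse": stage_fuse,
    "postfix": stage_postfix,
    "forces": stage_forces,
}


def run_pipeline(cfg: PipelineConfig, directives: list[str]) -> dict[str, Path]:
    """Execute the requested stage directives in canonical order."""
    unknown = [d for d in directives if d not in _STAGE_FNS]
    if unknown:
        raise StageDependencyError(f"unknown directives: {unknown}")
    if not cfg.raw_t2.exists():
        raise StageDependencyError(f"missing raw input {cfg.raw_t2}")
    out = {}
    for stage in STAGES:
        if stage in directives:
            out[stage] = _STAGE_FNS[stage](cfg)
    return out
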