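"""Label scheme: structure codes used by fusion outputs and postprocessing.

Codes follow the FreeSurfer colour-table convention (LH WM = 2, RH WM = 41,
lateral ventricles 4/43, subcortical nuclei in the 10-60 range, DKT
cortical parcels at 1000+/2000+).  Codes 254 and 255 are reserved sentinels
marking manually edited LH/RH WM voxels that automated fixes must never
overwrite; because of that reservation the corpus callosum uses the single
FreeSurfer code 192 rather than the 251-255 subdivision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

SENTINEL_LH_WM = 254
SENTINEL_RH_WM = 255


@dataclass(frozen=True)
class LabelScheme:
    """Code map for the structures the postprocessing rules manipulate."""

    csf: int = 24
    wm_left: int = 2
    wm_right: int = 41
    gm_left: int = 3
    gm_right: int = 42
    brainstem: int = 16
    cerebellum_left: int = 7
    cerebellum_right: int = 46
    ventricle_left: int = 4
    ventricle_right: int = 43
    thalamus_left: int = 10
    thalamus_right: int = 49
    caudate_left: int = 11
    caudate_right: int = 50
    putamen_left: int = 12
    putamen_right: int = 51
    hippocampus_left: int = 17
    hippocampus_right: int = 53
    choroid_left: int = 31
    choroid_right: int = 63
    amygdala_left: int = 18
    amygdala_right: int = 54
    accumbens_left: int = 26
    accumbens_right: int = 58
    ventral_dc_left: int = 28
    ventral_dc_right: int = 60
    third_ventricle: int = 14
    septum_left: int = 80
    septum_right: int = 81
    periventricular_left: int = 82
    periventricular_right: int = 83
    cc: int = 192
    pericalcarine_left: int = 1021
    pericalcarine_right: int = 2021
    superior_temporal_left: int = 1030
    superior_temporal_right: int = 2030
    supramarginal_left: int = 1031
    supramarginal_right: int = 2031
    extracranial_bg: int = 90
    skull: int = 91
    sentinel_map: dict = field(
        default_factory=lambda: {SENTINEL_LH_WM: 2, SENTINEL_RH_WM: 41}
    )

    def __post_init__(self):
        codes = [
            v for k, v in self.__dict__.items()
            if isinstance(v, int) and not k.startswith("_")
        ]
        if len(codes) != len(set(codes)):
            raise ValueError("label scheme codes must be unique")
        for s in (SENTINEL_LH_WM, SENTINEL_RH_WM):
            if s not in self.sentinel_map:
                raise ValueError(f"sentinel {s} has no mapping")

    # -- grouped views used by postprocessing rules ----------------------
    @property
    def wm_codes(self) -> tuple[int, int]:
        return (self.wm_left, self.wm_right)

    @property
    def cortical_gm_codes(self) -> tuple[int, ...]:
        return (
            self.gm_left, self.gm_right,
            self.pericalcarine_left, self.pericalcarine_right,
            self.superior_temporal_left, self.superior_temporal_right,
            self.supramarginal_left, self.supramarginal_right,
        )

    @property
    def brainstem_cerebellum_codes(self) -> tuple[int, ...]:
        return (self.brainstem, self.cerebellum_left, self.cerebellum_right)

    @property
    def ventricle_codes(self) -> tuple[int, int]:
        return (self.ventricle_left, self.ventricle_right)

    @property
    def wm_absorbed_codes(self) -> tuple[int, ...]:
        """Subcortical labels folded into the WM composite of the regions
        image (lateral ventricles, thalamus, caudate, putamen, hippocampus,
        choroid plexus, amygdala, accumbens, ventral diencephalon)."""
        return (
            self.ventricle_left, self.ventricle_right,
            self.thalamus_left, self.thalamus_right,
            self.caudate_left, self.caudate_right,
            self.putamen_left, self.putamen_right,
            self.hippocampus_left, self.hippocampus_right,
            self.choroid_left, self.choroid_right,
            self.amygdala_left, self.amygdala_right,
            self.accumbens_left, self.accumbens_right,
            self.ventral_dc_left, self.ventral_dc_right,
        )

    def names(self) -> dict[int, str]:
        out = {}
        for k, v in self.__dict__.items():
            if isinstance(v, int) and not k.startswith("_"):
                out[v] = k
        out[SENTINEL_LH_WM] = "sentinel_lh_wm"
        out[SENTINEL_RH_WM] = "sentinel_rh_wm"
        return out


# Regions-image codes consumed by surface extraction: brainstem+cerebellum,
# cortical GM, per-hemisphere WM and lateral ventricles, background 0.
@dataclass(frozen=True)
class RegionCodes:
    background: int = 0
    brainstem_cerebellum: int = 1
    cortical_gm: int = 2
    wm_left: int = 3
    wm_right: int = 4
    ventricle_left: int = 5
    ventricle_right: int = 6


DEFAULT_SCHEME = LabelScheme()
DEFAULT_REGIONS = RegionCodes()

# Sulcal-bank label pairs for the dilation-overlap CSF reset.  The full
# list ships as user configuration; this default covers the canonical
# superior-temporal / supramarginal case per hemisphere.
DEFAULT_SULCAL_PAIRS: tuple[tuple[int, int], ...] = (
    (DEFAULT_SCHEME.superior_temporal_left, DEFAULT_SCHEME.supramarginal_left),
    (DEFAULT_SCHEME.superior_temporal_right, DEFAULT_SCHEME.supramarginal_right),
)


def write_lut(scheme: LabelScheme, path) -> Path:
    """FreeSurfer-style tab-separated lookup table (code, name, R G B A)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = []
    for code, name in sorted(scheme.names().items()):
        r, g, b = (code * 37) % 256, (code * 91) % 256, (code * 53) % 256
        lines.append(f"{code}\t{name}\t{r}\t{g}\t{b}\t0")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_lut(path) -> dict[int, str]:
    table = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        table[int(parts[0])] = parts[1]
    return table
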