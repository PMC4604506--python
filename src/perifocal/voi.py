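"""Construction of the two per-hemisphere temporal-lobe VOIs.

Two volumes of interest are defined per hemisphere from the label volume:

* ``A_H_PH`` — the medial gathering of amygdala, hippocampus and
  parahippocampal gyrus;
* ``TL`` — the whole temporal lobe: superior, middle and inferior temporal,
  fusiform, temporal pole and transverse temporal neocortex plus entorhinal
  and parahippocampal cortex, hippocampus and amygdala.

When cortical areas are included (the TL VOI), both the cortical ribbon and
the subcortical white matter within 5 mm of that ribbon belong to the VOI;
the 5 mm band is measured as Euclidean distance in world mm (inclusive
threshold) over white-matter-labelled voxels of the same hemisphere. The
mesial A_H_PH VOI adds no white matter.

Hemisphere assignment always comes from the label dictionary, never from
voxel coordinates, so tilted real-world volumes behave the same as the
axis-aligned phantom.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from scipy import ndimage

from .volumes import BinaryMask, Hemisphere, LabelVolume, volume_mm3

__all__ = [
    "VOIDefinition",
    "VOIMaskPair",
    "A_H_PH_STRUCTURES",
    "TL_STRUCTURES",
    "TL_CORTICAL_STRUCTURES",
    "DEFAULT_WM_STRUCTURES",
    "build_voi",
    "voi_volumes",
]

A_H_PH_STRUCTURES: tuple[str, ...] = ("amygdala", "hippocampus", "parahippocampal")

TL_CORTICAL_STRUCTURES: tuple[str, ...] = (
    "superior-temporal",
    "middle-temporal",
    "inferior-temporal",
    "fusiform",
    "temporal-pole",
    "transverse-temporal",
    "entorhinal",
    "parahippocampal",
)

TL_STRUCTURES: tuple[str, ...] = TL_CORTICAL_STRUCTURES + ("hippocampus", "amygdala")

DEFAULT_WM_STRUCTURES: tuple[str, ...] = ("temporal-white-matter",)


def _default_structures(kind: str) -> tuple[str, ...]:
    return A_H_PH_STRUCTURES if kind == "A_H_PH" else TL_STRUCTURES


@dataclass
class VOIDefinition:
    """Which structures make up a VOI on one side, plus the white-matter rule.

    ``structure_list`` defaults to the standard list for ``kind``; the
    mesial list is a subset of the temporal-lobe list by construction.
    ``wm_margin_mm`` only matters for VOIs containing cortical areas.
    """

    kind: Literal["A_H_PH", "TL"]
    side: Literal["left", "right"]
    structure_list: tuple[str, ...] = ()
    wm_margin_mm: float = 5.0
    wm_structures: tuple[str, ...] = DEFAULT_WM_STRUCTURES
    cortical_structures: tuple[str, ...] = TL_CORTICAL_STRUCTURES

    def __post_init__(self) -> None:
        if not self.structure_list:
            self.structure_list = _default_structures(self.kind)

    def mirrored(self) -> "VOIDefinition":
        other: Hemisphere = "right" if self.side == "left" else "left"
        return VOIDefinition(
            kind=self.kind, side=other, structure_list=self.structure_list,
            wm_margin_mm=self.wm_margin_mm, wm_structures=self.wm_structures,
            cortical_structures=self.cortical_structures,
        )


@dataclass
class VOIMaskPair:
    """Ipsilateral/contralateral VOI masks with pre- and post-surgical volumes."""

    definition: VOIDefinition
    ipsilateral: BinaryMask
    contralateral: BinaryMask
    pre_mm3: dict[str, float]
    post_mm3: dict[str, float]


def build_voi(labels: LabelVolume, voi: VOIDefinition) -> BinaryMask:
    """Union of the VOI's structures on one side, plus the white-matter band.

    For a VOI containing cortical areas, white-matter voxels of the same
    hemisphere whose Euclidean distance to the nearest included
    cortical-ribbon voxel is at most ``wm_margin_mm`` are added. A VOI with
    no cortical structures (A_H_PH) never gains white matter, as does a
    margin of zero.
    """
    core = labels.structure_mask(set(voi.structure_list), voi.side)
    cortical = set(voi.structure_list) & set(voi.cortical_structures)
    # the white-matter band applies to the whole-temporal-lobe VOI only; the
    # mesial gathering is defined without one even though it contains
    # parahippocampal cortex
    if voi.kind != "TL" or not cortical or voi.wm_margin_mm <= 0:
        return core
    present_wm = {
        n for _, (n, h) in labels.label_map.items()
        if n in set(voi.wm_structures) and h == voi.side
    }
    if not present_wm:
        return core
    ribbon = labels.structure_mask(cortical, voi.side).data
    if not ribbon.any():
        return core
    # distance from every voxel to the nearest ribbon voxel, in world mm
    dist = ndimage.distance_transform_edt(
        ~ribbon, sampling=labels.grid.voxel_size_mm
    )
    wm = labels.structure_mask(present_wm, voi.side).data
    band = wm & (dist <= voi.wm_margin_mm)
    return BinaryMask(labels.grid, core.data | band)


def voi_volumes(
    pre_labels: LabelVolume, resvol: BinaryMask, voi: VOIDefinition
) -> VOIMaskPair:
    """Pre- and post-surgical volumes of a VOI on both sides.

    The VOI is defined once, on the pre-surgical labels; its post-surgical
    volume is what remains of that same voxel set on the derived
    post-surgical label volume (labels zeroed inside the estimated cavity),
    i.e. ``pre_mm3 - |VOI ∩ resVol|``. A cavity confined to one hemisphere
    therefore leaves the contralateral volume untouched.
    """
    if not pre_labels.grid.same_geometry(resvol.grid):
        raise ValueError("labels and resection mask must share a grid")
    ipsi = build_voi(pre_labels, voi)
    contra = build_voi(pre_labels, voi.mirrored())
    post_ipsi = ipsi - resvol
    post_contra = contra - resvol
    return VOIMaskPair(
        definition=voi,
        ipsilateral=ipsi,
        contralateral=contra,
        pre_mm3={"ipsi": volume_mm3(ipsi), "contra": volume_mm3(contra)},
        post_mm3={"ipsi": volume_mm3(post_ipsi), "contra": volume_mm3(post_contra)},
    )
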