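"""Asymmetry-based classification of perifocal PET abnormalities.

The classifier is deliberately simple and fully automated. For each tracer
(FDG or FMZ) and each VOI (mesial A_H_PH or whole temporal lobe):

1. compute the mean uptake Ū over the homotopic VOI *contralateral* to the
   resected side;
2. mark every voxel u_res of the ipsilateral VOI whose uptake falls more
   than 10 % below that mean (``u_res < (1 - f) * Ū`` with f = 0.10,
   strict inequality) as a perifocal abnormality.

This yields one pre-surgical abnormality mask per tracer and VOI; the
non-resected abnormality is its set difference with the resection cavity,
``nonResAbnVol = abnVol \\ resVol``, also expressed as a percentage of the
total abnormality volume. By construction only ipsilateral-lower asymmetry
is detectable — a bilaterally symmetric deficit cancels out of Ū and yields
an empty mask — which is why cohorts analysed this way exclude bilateral
homotopic abnormalities.

Dynamic FMZ scans are first collapsed to a static volume by time-weighted
averaging of the frames overlapping a fixed window (10-20 min by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .voi import VOIDefinition, build_voi
from .volumes import BinaryMask, LabelVolume, PETVolume, Tracer, volume_mm3

__all__ = [
    "AbnormalityResult",
    "average_frames",
    "contralateral_mean",
    "classify_abnormal",
    "nonresected_abnormality",
    "subject_abnormality_profile",
    "ASYMMETRY_THRESHOLD",
    "FMZ_WINDOW_S",
]

# fractional deficit below the contralateral mean that defines an abnormal voxel
ASYMMETRY_THRESHOLD = 0.10
# averaging window for dynamic FMZ: tenth to twentieth minute of the scan
FMZ_WINDOW_S = (600.0, 1200.0)


@dataclass
class AbnormalityResult:
    """Per-tracer, per-VOI abnormality volumetrics for one subject.

    Satisfies, exactly: ``abn_mask ⊆ ipsilateral VOI``,
    ``nonres_abn_mask = abn_mask \\ resVol`` and
    ``resected_abn_mm3 + nonres_abn_mm3 = pre_abn_mm3``; the two
    percentages sum to 100 whenever any abnormality exists.
    """

    tracer: Tracer
    voi_kind: Literal["A_H_PH", "TL"]
    contralateral_mean: float
    abn_mask: BinaryMask
    pre_abn_mm3: float
    resected_abn_mm3: float
    nonres_abn_mask: BinaryMask
    nonres_abn_mm3: float
    nonres_pct: float
    resected_pct: float

    def check(self, voi_ipsi: BinaryMask, resvol: BinaryMask) -> None:
        assert self.abn_mask.issubset(voi_ipsi)
        assert not (self.nonres_abn_mask & resvol).data.any()
        assert abs(self.resected_abn_mm3 + self.nonres_abn_mm3 - self.pre_abn_mm3) < 1e-6
        if self.pre_abn_mm3 > 0:
            assert abs(self.resected_pct + self.nonres_pct - 100.0) < 1e-9


def average_frames(
    dyn: PETVolume, t_start_s: float = FMZ_WINDOW_S[0], t_end_s: float = FMZ_WINDOW_S[1]
) -> PETVolume:
    """Collapse a dynamic PET volume to a static one over a time window.

    The result is the voxel-wise time-weighted mean of the frames
    overlapping ``[t_start_s, t_end_s]``, each weighted by its overlap
    duration. A static input whose (single) frame covers the window is
    returned unchanged.
    """
    if t_end_s <= t_start_s:
        raise ValueError("empty averaging window")
    if not dyn.is_dynamic:
        return dyn
    weights = np.array(
        [max(0.0, min(e, t_end_s) - max(s, t_start_s)) for s, e in dyn.frame_times_s or []]
    )
    if weights.sum() <= 0:
        raise ValueError(
            f"no frame overlaps the window [{t_start_s}, {t_end_s}] s"
        )
    w = weights / weights.sum()
    static = np.tensordot(w, dyn.data, axes=(0, 0))
    return PETVolume(dyn.grid, static, tracer=dyn.tracer)


def contralateral_mean(pet: PETVolume, voi_contra: BinaryMask) -> float:
    """Mean uptake Ū over the contralateral homotopic VOI."""
    if pet.is_dynamic:
        raise ValueError("contralateral mean requires a static volume; average frames first")
    if not pet.grid.same_geometry(voi_contra.grid):
        raise ValueError("PET and VOI must share a grid")
    if not voi_contra.data.any():
        raise ValueError("contralateral VOI is empty")
    return float(pet.data[voi_contra.data].mean())


def classify_abnormal(
    pet: PETVolume,
    voi_ipsi: BinaryMask,
    u_bar: float,
    threshold_fraction: float = ASYMMETRY_THRESHOLD,
) -> BinaryMask:
    """Mark ipsilateral VOI voxels whose uptake is more than
    ``threshold_fraction`` below the contralateral mean.

    Strict comparison: a voxel at exactly ``(1 - f) * Ū`` is normal.
    """
    if pet.is_dynamic:
        raise ValueError("classification requires a static volume; average frames first")
    if not pet.grid.same_geometry(voi_ipsi.grid):
        raise ValueError("PET and VOI must share a grid")
    if u_bar <= 0:
        raise ValueError("nonpositive contralateral mean (corrupt uptake normalisation)")
    if not 0 < threshold_fraction < 1:
        raise ValueError("threshold_fraction must be in (0, 1)")
    return BinaryMask(
        voi_ipsi.grid, voi_ipsi.data & (pet.data < (1.0 - threshold_fraction) * u_bar)
    )


def nonresected_abnormality(
    abn: BinaryMask, resvol: BinaryMask
) -> tuple[BinaryMask, float, float]:
    """Abnormality left in place after resection: ``abn \\ resVol``.

    Returns the mask, its volume in mm³ and the percentage of the total
    abnormality volume it represents; the percentage is undefined (error)
    for an empty abnormality.
    """
    mask = abn - resvol
    mm3 = volume_mm3(mask)
    total = volume_mm3(abn)
    if total <= 0:
        raise ValueError("empty abnormality volume: percentage undefined")
    return mask, mm3, 100.0 * mm3 / total


def _one_result(
    pet: PETVolume,
    labels: LabelVolume,
    resvol: BinaryMask,
    voi_def: VOIDefinition,
    threshold_fraction: float,
) -> AbnormalityResult:
    voi_ipsi = build_voi(labels, voi_def)
    voi_contra = build_voi(labels, voi_def.mirrored())
    u_bar = contralateral_mean(pet, voi_contra)
    abn = classify_abnormal(pet, voi_ipsi, u_bar, threshold_fraction)
    pre_mm3 = volume_mm3(abn)
    nonres = abn - resvol
    nonres_mm3 = volume_mm3(nonres)
    res_mm3 = pre_mm3 - nonres_mm3
    if pre_mm3 > 0:
        nonres_pct = 100.0 * nonres_mm3 / pre_mm3
        res_pct = 100.0 - nonres_pct
    else:
        nonres_pct = res_pct = 0.0
    result = AbnormalityResult(
        tracer=pet.tracer,
        voi_kind=voi_def.kind,
        contralateral_mean=u_bar,
        abn_mask=abn,
        pre_abn_mm3=pre_mm3,
        resected_abn_mm3=res_mm3,
        nonres_abn_mask=nonres,
        nonres_abn_mm3=nonres_mm3,
        nonres_pct=nonres_pct,
        resected_pct=res_pct,
    )
    result.check(voi_ipsi, resvol)
    return result


def subject_abnormality_profile(
    labels: LabelVolume,
    resvol: BinaryMask,
    fdg: PETVolume,
    fmz: PETVolume,
    side: Literal["left", "right"],
    threshold_fraction: float = ASYMMETRY_THRESHOLD,
    fmz_window_s: tuple[float, float] = FMZ_WINDOW_S,
    wm_margin_mm: float = 5.0,
) -> dict[tuple[str, str], AbnormalityResult]:
    """The four abnormality records of one subject: {FDG, FMZ} × {A_H_PH, TL}.

    ``side`` is the resected side; a dynamic FMZ volume is averaged over
    ``fmz_window_s`` first. Keys are ``(tracer, voi_kind)``.
    """
    fmz_static = average_frames(fmz, *fmz_window_s) if fmz.is_dynamic else fmz
    results: dict[tuple[str, str], AbnormalityResult] = {}
    for pet in (fdg, fmz_static):
        for kind in ("A_H_PH", "TL"):
            voi_def = VOIDefinition(kind=kind, side=side, wm_margin_mm=wm_margin_mm)
            results[(pet.tracer, kind)] = _one_result(
                pet, labels, resvol, voi_def, threshold_fraction
            )
    return results
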