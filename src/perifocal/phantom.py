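"""Synthetic phantom subjects with full ground truth.

No patient imaging ships with this package, so every pipeline stage is
exercised on phantoms: a bilaterally labelled brain with temporal-lobe
structures, a contiguous anterior-temporal resection, and PET uptake with a
planted ipsilateral deficit of configurable depth and extent.

The phantom is deliberately geometric — boxes and ellipsoids, mirror-exact
across the midsagittal plane — rather than anatomically realistic. Exact
mirror symmetry guarantees homotopic VOIs have identical voxel counts, so
any asymmetry the classifier reports is the planted one, and every truth
mask (resection cavity, deficit region) is returned alongside the volumes
it was painted into.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import expit, logit

from .volumes import BinaryMask, LabelVolume, PETVolume, Tracer, VoxelGrid

__all__ = [
    "StructureGeom",
    "PhantomSpec",
    "ResectionSpec",
    "DeficitSpec",
    "OutcomeModelSpec",
    "make_phantom_labels",
    "make_post_volume",
    "make_pet",
    "make_cohort",
    "LATERAL_STRUCTURES",
    "MESIAL_STRUCTURES",
    "WHITE_MATTER",
]

# structure vocabulary follows FreeSurfer-style naming so VOI configs written
# for the phantom transfer to real label tables
MESIAL_STRUCTURES = ("amygdala", "hippocampus", "parahippocampal", "entorhinal")
LATERAL_STRUCTURES = (
    "superior-temporal",
    "middle-temporal",
    "inferior-temporal",
    "fusiform",
    "temporal-pole",
    "transverse-temporal",
)
WHITE_MATTER = "temporal-white-matter"
FILLER = "extratemporal"


@dataclass(frozen=True)
class StructureGeom:
    """One painted structure: an axis-aligned box or an ellipsoid.

    ``center_mm`` and ``semi_axes_mm`` are in world mm on the phantom grid;
    a box contains voxels with ``|x - c| <= a`` per axis, an ellipsoid those
    with ``sum(((x - c)/a)^2) <= 1``.
    """

    shape: Literal["box", "ellipsoid"]
    center_mm: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]


def _default_geometry() -> dict[str, StructureGeom]:
    """Right-hemisphere geometry on the default 96 mm grid (x = left-right).

    Lateral gyri are stacked slabs at the lateral surface, mesial structures
    a contiguous block medially; temporal white matter is the envelope fill
    between them so anterior resections are single connected components.
    """
    box = lambda c, a: StructureGeom("box", c, a)
    return {
        "superior-temporal": box((76, 51, 45), (4, 23, 3)),
        "middle-temporal": box((76, 51, 38), (4, 23, 3)),
        "inferior-temporal": box((76, 51, 31), (4, 23, 3)),
        "fusiform": box((67.5, 49, 27), (3.5, 21, 3)),
        "temporal-pole": box((72, 78.5, 36), (8, 3.5, 10)),
        "transverse-temporal": box((68, 39, 49), (2, 5, 1)),
        "amygdala": box((58.5, 64.5, 35.5), (4.5, 4.5, 4.5)),
        "hippocampus": box((58.5, 47.5, 33.5), (4.5, 11.5, 4.5)),
        "entorhinal": box((58.5, 65, 27), (4.5, 5, 3)),
        "parahippocampal": box((58.5, 44.5, 26), (4.5, 14.5, 2)),
        FILLER: box((65, 49, 64), (15, 35, 12)),
    }


# envelope box whose unlabeled voxels become temporal white matter
_WM_ENVELOPE = StructureGeom("box", (67, 51, 36), (13, 23, 12))


@dataclass
class PhantomSpec:
    """Phantom geometry: per-structure shapes, mirrored left/right.

    The right-hemisphere geometry is painted explicitly and reflected through
    the midsagittal plane (the grid's central sagittal interface), so left
    and right structures have identical voxel counts by construction.
    """

    grid: VoxelGrid = field(default_factory=lambda: VoxelGrid.isotropic((96, 96, 96), 1.0))
    structure_geometry: dict[str, StructureGeom] = field(default_factory=_default_geometry)
    wm_envelope: StructureGeom | None = _WM_ENVELOPE
    seed: int = 0


@dataclass
class ResectionSpec:
    """Anterior temporal resection: lateral extent from the temporal tip plus
    optional en-bloc removal of the mesial structures.

    ``jitter_voxels`` flips a rind of that thickness at the outer brain
    surface of the post-surgical volume, emulating spurious pre/post
    difference from imperfect co-registration. ``seed`` is reserved for
    stochastic jitter variants; the default rind is deterministic.
    """

    side: Literal["left", "right"] = "left"
    posterior_extent_mm: float = 40.0
    include_mesial: bool = True
    jitter_voxels: int = 0
    seed: int = 0


@dataclass
class DeficitSpec:
    """Planted ipsilateral uptake deficit.

    In-brain uptake is ``baseline * (1 - depth_fraction)`` inside ``region``
    and ``baseline`` elsewhere, plus independent Gaussian noise; the deficit
    and the noise are the only sources of interhemispheric asymmetry. The
    default depth 0.20 against the classifier's 0.10 threshold makes
    noiseless recovery exact.
    """

    tracer: Tracer
    region: BinaryMask
    depth_fraction: float = 0.20
    baseline_uptake: float = 100.0
    noise_sd: float = 0.0
    seed: int = 0


@dataclass
class OutcomeModelSpec:
    """Logistic outcome model for simulated cohorts.

    ``p_engel1`` is the marginal probability of a satisfactory (Engel class I)
    outcome; ``effect_log_or`` maps covariate name to log odds per unit,
    applied to mean-centred covariates so the marginal rate stays at
    ``p_engel1``.
    """

    n_subjects: int = 32
    p_engel1: float = 25 / 32
    effect_log_or: dict[str, float] = field(default_factory=dict)
    seed: int = 0


def _paint(geom: StructureGeom, grid: VoxelGrid) -> np.ndarray:
    coords = np.meshgrid(*(np.arange(s, dtype=float) for s in grid.shape), indexing="ij")
    # default phantom grid is axis-aligned with unit origin offset zero:
    # world mm == voxel index * voxel size
    world = [c * v for c, v in zip(coords, grid.voxel_size_mm)]
    c, a = geom.center_mm, geom.semi_axes_mm
    if geom.shape == "box":
        m = np.ones(grid.shape, dtype=bool)
        for w, ci, ai in zip(world, c, a):
            m &= np.abs(w - ci) <= ai
        return m
    if geom.shape == "ellipsoid":
        q = sum(((w - ci) / ai) ** 2 for w, ci, ai in zip(world, c, a))
        return q <= 1.0
    raise ValueError(geom.shape)


def make_phantom_labels(spec: PhantomSpec) -> LabelVolume:
    """Paint the bilateral label volume from a phantom spec.

    Right-hemisphere structures are painted from the explicit geometry,
    white matter fills the unlabeled envelope, and the left hemisphere is
    the exact voxel reflection. Overlapping explicit structures are an
    error, as is any degenerate (empty) structure.
    """
    grid = spec.grid
    names = list(spec.structure_geometry)
    right = np.zeros(grid.shape, dtype=np.int32)
    label_map: dict[int, tuple[str, str]] = {}
    for k, name in enumerate(names):
        mask = _paint(spec.structure_geometry[name], grid)
        if not mask.any():
            raise ValueError(f"structure {name!r} paints no voxels (degenerate geometry)")
        if (right[mask] != 0).any():
            clash = {names[i - 1] for i in np.unique(right[mask]) if i != 0}
            raise ValueError(f"structure {name!r} overlaps {sorted(clash)}")
        right[mask] = k + 1
    if spec.wm_envelope is not None:
        env = _paint(spec.wm_envelope, grid) & (right == 0)
        names.append(WHITE_MATTER)
        right[env] = len(names)
    left = right[::-1, :, :]  # reflect through the midsagittal interface
    if ((left != 0) & (right != 0)).any():
        raise ValueError("hemisphere geometry crosses the midsagittal plane")
    data = np.where(right != 0, right + 100, 0) + np.where(left != 0, left + 200, 0)
    for k, name in enumerate(names):
        label_map[k + 101] = (name, "right")
        label_map[k + 201] = (name, "left")
    vol = LabelVolume(grid, data.astype(np.int32), label_map)  # type: ignore[arg-type]
    vol.validate()
    return vol


def _temporal_tip_mm(labels: LabelVolume, side: str) -> float:
    mask = labels.structure_mask(set(LATERAL_STRUCTURES), side).data
    ys = np.nonzero(mask)[1]
    return float(ys.max()) * labels.grid.voxel_size_mm[1]


def make_post_volume(
    pre: LabelVolume, spec: ResectionSpec
) -> tuple[LabelVolume, BinaryMask]:
    """Simulate the post-surgical label volume and return the truth cavity.

    The cavity is the lateral temporal structures (plus white matter) within
    ``posterior_extent_mm`` of the temporal tip, optionally united with the
    full mesial block; it is verified to be a single 26-connected component.
    A positive ``jitter_voxels`` additionally strips a rind of that thickness
    from the outer brain surface of the post volume.
    """
    grid = pre.grid
    lateral = pre.structure_mask(set(LATERAL_STRUCTURES) | {WHITE_MATTER}, spec.side).data
    tip = _temporal_tip_mm(pre, spec.side)
    ys = np.nonzero(lateral)[1] * grid.voxel_size_mm[1]
    if spec.posterior_extent_mm > tip - ys.min() + grid.voxel_size_mm[1]:
        raise ValueError("posterior_extent_mm exceeds the temporal lobe length")
    y_mm = np.arange(grid.shape[1]) * grid.voxel_size_mm[1]
    anterior = (y_mm > tip - spec.posterior_extent_mm)[None, :, None]
    cavity = lateral & anterior
    if spec.include_mesial:
        cavity |= pre.structure_mask(set(MESIAL_STRUCTURES), spec.side).data
    if cavity.any():
        _, n_cc = ndimage.label(cavity, structure=np.ones((3, 3, 3), dtype=int))
        if n_cc != 1:
            raise ValueError(f"resection cavity is not a single connected component ({n_cc})")
    post = pre.data.copy()
    post[cavity] = 0
    if spec.jitter_voxels > 0:
        brain = pre.data != 0
        interior = ndimage.binary_erosion(
            brain, structure=np.ones((3, 3, 3)), iterations=spec.jitter_voxels
        )
        post[brain & ~interior] = 0
    return (
        LabelVolume(grid, post, dict(pre.label_map)),
        BinaryMask(grid, cavity),
    )


def make_pet(
    labels: LabelVolume, deficit: DeficitSpec, n_frames: int = 1,
    scan_duration_s: float = 2400.0,
) -> PETVolume:
    """Simulate a static (``n_frames == 1``) or dynamic PET volume.

    Uptake is ``baseline`` over the whole brain, reduced by
    ``depth_fraction`` inside the planted region, with independent Gaussian
    noise per voxel (and per frame for dynamic scans); background is zero.
    Deterministic for a fixed ``deficit.seed``.
    """
    if deficit.noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if not labels.grid.same_geometry(deficit.region.grid):
        raise ValueError("deficit region must live on the label grid")
    rng = np.random.default_rng(deficit.seed)
    brain = labels.data != 0
    clean = np.where(
        brain,
        deficit.baseline_uptake * (1.0 - deficit.depth_fraction * deficit.region.data),
        0.0,
    )
    def one_frame() -> np.ndarray:
        f = clean.copy()
        if deficit.noise_sd > 0:
            f[brain] += rng.normal(0.0, deficit.noise_sd, size=int(brain.sum()))
        return f

    if n_frames == 1:
        return PETVolume(labels.grid, one_frame(), tracer=deficit.tracer)
    dt = scan_duration_s / n_frames
    frames = np.stack([one_frame() for _ in range(n_frames)])
    times = [(i * dt, (i + 1) * dt) for i in range(n_frames)]
    return PETVolume(labels.grid, frames, tracer=deficit.tracer, frame_times_s=times)


# fraction of unsatisfactory outcomes falling in Engel II / III / IV,
# matching the 1:2:4 split of the reference cohort
_UNSAT_SPLIT = {"II": 1 / 7, "III": 2 / 7, "IV": 4 / 7}


def make_cohort(
    model: OutcomeModelSpec, covariates: pd.DataFrame | dict[str, np.ndarray]
) -> pd.DataFrame:
    """Draw Engel outcomes from a logistic model over per-subject covariates.

    Returns a DataFrame with ``subject_id``, ``engel_class`` and the
    covariate columns. Covariates named in ``model.effect_log_or`` shift the
    log odds of a class I outcome; unnamed covariates are carried through
    untouched. Deterministic for a fixed ``model.seed``.
    """
    cov = pd.DataFrame(covariates).reset_index(drop=True)
    if len(cov) != model.n_subjects:
        raise ValueError(
            f"covariate rows ({len(cov)}) != n_subjects ({model.n_subjects})"
        )
    if not 0 < model.p_engel1 < 1:
        raise ValueError("p_engel1 must be in (0, 1)")
    rng = np.random.default_rng(model.seed)
    eta = np.full(model.n_subjects, logit(model.p_engel1))
    for name, beta in model.effect_log_or.items():
        x = np.asarray(cov[name], dtype=float)
        eta = eta + beta * (x - x.mean())
    satisfactory = rng.random(model.n_subjects) < expit(eta)
    classes = np.where(
        satisfactory,
        "I",
        rng.choice(list(_UNSAT_SPLIT), size=model.n_subjects, p=list(_UNSAT_SPLIT.values())),
    )
    out = cov.copy()
    out.insert(0, "subject_id", [f"S{i:03d}" for i in range(model.n_subjects)])
    out.insert(1, "engel_class", classes)
    return out
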