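"""Voxel-level digital phantoms with known ground truth.

Two generators: (a) DCE-MRI phantoms — tissue-parameter maps driven through
the 2CXM and the SPGR signal equation to a multi-flip-angle stack plus a 4-D
dynamic series, with seeded Gaussian noise; (b) PET phantoms — smooth
spherical lesions of configurable peak-to-background ratio over a uniform
cortex background.  Both record the truth needed for recovery testing.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .kinetics import (
    DEFAULT_HEMATOCRIT,
    ArterialInputFunction,
    Hematocrit,
    TissueParams,
    forward_2cxm,
)
from .relaxometry import VfaStack, spgr_signal


@dataclasses.dataclass
class PhantomTruth:
    """Ground-truth maps and lesion labels on one voxel grid."""

    f: np.ndarray
    bv: np.ndarray
    ki: np.ndarray
    ve: np.ndarray
    t1_ms: np.ndarray
    m0: np.ndarray
    voxel_size_mm: tuple = (2.0, 2.0, 2.0)
    lesion_masks: dict = dataclasses.field(default_factory=dict)
    lesion_labels: dict = dataclasses.field(default_factory=dict)
    enhancing: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {m.shape for m in (self.f, self.bv, self.ki, self.ve, self.t1_ms, self.m0)}
        if len(shapes) != 1:
            raise ValueError("all truth maps must share one grid")
        for name, mask in self.lesion_masks.items():
            if mask.shape != self.f.shape:
                raise ValueError("lesion masks must live on the truth grid")
            if name in self.lesion_labels and not mask.any():
                raise ValueError(f"labelled lesion '{name}' has an empty mask")

    @property
    def shape(self) -> tuple:
        return self.f.shape

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.voxel_size_mm)) / 1000.0

    def params_at(self, index) -> TissueParams:
        return TissueParams(
            F=float(self.f[index]), BV=float(self.bv[index]),
            Ki=float(self.ki[index]), Ve=float(self.ve[index]),
        )


def uniform_phantom(
    params: TissueParams,
    shape: Sequence[int] = (20, 20, 4),
    t1_ms: float = 1200.0,
    m0: float = 1000.0,
    voxel_size_mm: Sequence[float] = (2.0, 2.0, 2.0),
) -> PhantomTruth:
    """Homogeneous phantom — the recovery-test workhorse."""
    full = lambda v: np.full(tuple(shape), float(v))
    return PhantomTruth(
        f=full(params.F), bv=full(params.BV), ki=full(params.Ki), ve=full(params.Ve),
        t1_ms=full(t1_ms), m0=full(m0), voxel_size_mm=tuple(voxel_size_mm),
    )


def lesion_phantom(
    background: TissueParams,
    lesions: Sequence[tuple[Sequence[float], float, TissueParams]],
    shape: Sequence[int] = (32, 32, 16),
    t1_ms: float = 1200.0,
    m0: float = 1000.0,
    voxel_size_mm: Sequence[float] = (2.0, 2.0, 2.0),
    labels: Sequence[str] | None = None,
) -> PhantomTruth:
    """Background tissue with spherical lesions of distinct kinetics.

    ``lesions`` is a list of (centre voxel, radius mm, TissueParams).
    """
    truth = uniform_phantom(background, shape, t1_ms, m0, voxel_size_mm)
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    for i, (centre, radius_mm, params) in enumerate(lesions):
        r2 = sum(((g - c) * s) ** 2 for g, c, s in zip(grids, centre, voxel_size_mm))
        mask = r2 <= radius_mm**2
        for arr, val in (
            (truth.f, params.F), (truth.bv, params.BV),
            (truth.ki, params.Ki), (truth.ve, params.Ve),
        ):
            arr[mask] = val
        truth.lesion_masks[f"lesion{i}" if labels is None else labels[i]] = mask
    return truth


@dataclasses.dataclass(frozen=True)
class MrAcquisition:
    """SPGR acquisition constants for the phantom scanner."""

    flip_angles_deg: tuple = (2.0, 5.0, 10.0, 15.0)
    dynamic_flip_deg: float = 15.0
    tr_ms: float = 5.0
    r1: float = 3.6  # 1/s/mM at 3 T
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.flip_angles_deg)) < 4:
            raise ValueError("at least 4 distinct flip angles are required")
        if self.tr_ms <= 0:
            raise ValueError("TR must be positive")


@dataclasses.dataclass
class SyntheticMrData:
    vfa: VfaStack
    dynamic: np.ndarray  # (*grid, n_frames)
    concentration: np.ndarray  # noiseless truth, same layout
    acquisition: MrAcquisition


def _unique_param_curves(
    truth: PhantomTruth, aif: ArterialInputFunction, hematocrit: Hematocrit
) -> np.ndarray:
    """Concentration curves per voxel, computed once per unique parameter set."""
    stacked = np.stack(
        [truth.f.ravel(), truth.bv.ravel(), truth.ki.ravel(), truth.ve.ravel()], axis=1
    )
    uniq, inverse = np.unique(stacked, axis=0, return_inverse=True)
    curves = np.stack(
        [
            forward_2cxm(TissueParams(F=r[0], BV=r[1], Ki=r[2], Ve=r[3]), aif, hematocrit)
            for r in uniq
        ]
    )
    return curves[inverse].reshape(*truth.shape, aif.times.size)


def synthesize_mr_signals(
    truth: PhantomTruth,
    aif: ArterialInputFunction,
    acquisition: MrAcquisition = MrAcquisition(),
    hematocrit: Hematocrit = DEFAULT_HEMATOCRIT,
) -> SyntheticMrData:
    """VFA stack and dynamic SPGR series from ground truth.

    Pre-contrast volumes follow the SPGR equation at (T1, M0); dynamic frames
    use T1 shortened by the gadolinium concentration, 1/T1(t) = 1/T1 +
    r1 C(t).  Gaussian noise of the configured sd is added with the seed;
    identical seeds give bit-identical volumes.
    """
    conc = _unique_param_curves(truth, aif, hematocrit)
    rng = np.random.default_rng(acquisition.seed)

    vfa_signals = np.stack(
        [
            spgr_signal(truth.m0, truth.t1_ms, a, acquisition.tr_ms)
            for a in acquisition.flip_angles_deg
        ]
    )
    r1_t = 1000.0 / truth.t1_ms[..., None] + acquisition.r1 * conc  # 1/s
    t1_t = 1000.0 / r1_t
    dynamic = spgr_signal(
        truth.m0[..., None], t1_t, acquisition.dynamic_flip_deg, acquisition.tr_ms
    )
    if acquisition.noise_sd > 0:
        vfa_signals = vfa_signals + rng.normal(0, acquisition.noise_sd, vfa_signals.shape)
        dynamic = dynamic + rng.normal(0, acquisition.noise_sd, dynamic.shape)
    vfa = VfaStack(vfa_signals, np.asarray(acquisition.flip_angles_deg), acquisition.tr_ms)
    return SyntheticMrData(vfa=vfa, dynamic=dynamic, concentration=conc, acquisition=acquisition)


@dataclasses.dataclass(frozen=True)
class PetLesionSpec:
    """A spherical PET lesion: centre (voxel), radius (mm), peak/background ratio."""

    centre: tuple
    radius_mm: float
    ratio: float

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("lesion radius must be positive")
        if self.ratio < 0:
            raise ValueError("peak-to-background ratio must be >= 0")


def make_pet_phantom(
    background: float,
    lesions: Sequence[PetLesionSpec],
    shape: Sequence[int] = (32, 32, 16),
    voxel_size_mm: Sequence[float] = (2.0, 2.0, 2.0),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """PET activity volume with smooth spherical lesions over a background.

    Inside a lesion the profile is a raised cosine peaking at
    ratio x background at the centre and returning to the background at the
    lesion radius: act(r) = bg (1 + (ratio-1) cos^2(pi r / 2R)).  Overlapping
    lesion specs are rejected (the truth would be ambiguous).  Returns the
    volume and a dict of truth masks keyed 'lesion0', 'lesion1', ...
    """
    if background <= 0:
        raise ValueError("background activity must be positive")
    vs = np.asarray(voxel_size_mm, dtype=float)
    for i in range(len(lesions)):
        for j in range(i + 1, len(lesions)):
            d = np.linalg.norm((np.asarray(lesions[i].centre) - np.asarray(lesions[j].centre)) * vs)
            if d < lesions[i].radius_mm + lesions[j].radius_mm:
                raise ValueError(f"lesions {i} and {j} overlap; truth is ambiguous")

    vol = np.full(tuple(shape), float(background))
    masks = {}
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    for i, spec in enumerate(lesions):
        r = np.sqrt(
            sum(((g - c) * s) ** 2 for g, c, s in zip(grids, spec.centre, vs))
        )
        inside = r < spec.radius_mm
        profile = np.cos(np.pi * r / (2.0 * spec.radius_mm)) ** 2
        vol[inside] = background * (1.0 + (spec.ratio - 1.0) * profile[inside])
        masks[f"lesion{i}"] = inside
    if noise_sd > 0:
        vol = vol + np.random.default_rng(seed).normal(0, noise_sd, vol.shape)
    return vol, masks
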