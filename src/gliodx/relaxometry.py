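"""Variable-flip-angle (VFA) T1/M0 mapping and signal-to-concentration
conversion for spoiled gradient-echo (SPGR) DCE-MRI.

The SPGR steady-state signal with perfect spoiling is

    S = M0 sin(a) (1 - E1) / (1 - E1 cos(a)),   E1 = exp(-TR / T1),

which is linear in ``S/tan(a)`` vs ``S/sin(a)`` (DESPOT1).  T1 mapping uses
the linearised solution as initialiser followed by bounded nonlinear
refinement.  Gadolinium concentration follows from the longitudinal
relaxation-rate change, C(t) = (1/T1(t) - 1/T1(0)) / r1.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import least_squares

T1_BOUNDS_MS = (50.0, 8000.0)


def spgr_signal(m0, t1_ms, flip_deg, tr_ms):
    """SPGR signal equation; broadcasts over array inputs."""
    e1 = np.exp(-tr_ms / np.asarray(t1_ms, dtype=float))
    a = np.deg2rad(flip_deg)
    return m0 * np.sin(a) * (1.0 - e1) / (1.0 - e1 * np.cos(a))


@dataclasses.dataclass(frozen=True)
class VfaStack:
    """Pre-contrast multi-flip-angle SPGR volumes on a common grid.

    ``signals`` has the flip-angle axis first: shape (n_angles, *volume).
    At least four distinct flip angles in (0, 90] degrees are required;
    acquisitions with fewer do not support reliable T1 mapping and are
    rejected outright.
    """

    signals: np.ndarray
    flip_angles_deg: np.ndarray
    tr_ms: float

    def __post_init__(self) -> None:
        sig = np.asarray(self.signals, dtype=float)
        ang = np.asarray(self.flip_angles_deg, dtype=float)
        if ang.ndim != 1 or sig.shape[0] != ang.size:
            raise ValueError("one signal volume per flip angle is required")
        if np.unique(ang).size < 4:
            raise ValueError("T1 mapping requires at least 4 distinct flip angles")
        if np.any(ang <= 0) or np.any(ang > 90):
            raise ValueError("flip angles must lie in (0, 90] degrees")
        if self.tr_ms <= 0:
            raise ValueError("TR must be positive")
        object.__setattr__(self, "signals", sig)
        object.__setattr__(self, "flip_angles_deg", ang)


@dataclasses.dataclass
class RelaxometryMaps:
    """Voxel-wise T1 (ms), M0 (a.u.), validity mask and fit residual."""

    t1_ms: np.ndarray
    m0: np.ndarray
    valid: np.ndarray
    residual: np.ndarray


def _linearised_fit(stack: VfaStack) -> tuple[np.ndarray, np.ndarray]:
    """DESPOT1 regression of S/sin(a) on S/tan(a); returns (t1_ms, m0)."""
    a = np.deg2rad(stack.flip_angles_deg)
    sig = stack.signals.reshape(a.size, -1)
    y = sig / np.sin(a)[:, None]
    x = sig / np.tan(a)[:, None]
    xm = x.mean(axis=0)
    ym = y.mean(axis=0)
    sxx = ((x - xm) ** 2).sum(axis=0)
    sxy = ((x - xm) * (y - ym)).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = sxy / sxx
        intercept = ym - slope * xm
        t1 = np.where((slope > 0) & (slope < 1), -stack.tr_ms / np.log(slope), np.nan)
        m0 = np.where(np.isfinite(t1), intercept / (1.0 - slope), np.nan)
    shape = stack.signals.shape[1:]
    return t1.reshape(shape), m0.reshape(shape)


def fit_t1_vfa(stack: VfaStack, refine: bool = True) -> RelaxometryMaps:
    """Voxel-wise (T1, M0) estimation from a VFA stack.

    Linearised DESPOT1 initialises a bounded nonlinear least-squares
    refinement (T1 in [50, 8000] ms).  Degenerate voxels (all-zero signal,
    non-physical linearised slope, non-convergent refinement) are flagged
    invalid rather than raising.
    """
    t1, m0 = _linearised_fit(stack)
    shape = stack.signals.shape[1:]
    valid = np.isfinite(t1) & np.isfinite(m0) & (m0 > 0)
    t1 = np.where(valid, np.clip(t1, *T1_BOUNDS_MS), np.nan)
    residual = np.full(shape, np.nan)

    ang = stack.flip_angles_deg
    sig_flat = stack.signals.reshape(ang.size, -1)
    t1f, m0f = t1.reshape(-1), m0.reshape(-1)
    validf, resf = valid.reshape(-1), residual.reshape(-1)
    if refine:
        lo = np.array([T1_BOUNDS_MS[0], 0.0])
        for idx in np.nonzero(validf)[0]:
            s = sig_flat[:, idx]

            def model(p):
                return spgr_signal(p[1], p[0], ang, stack.tr_ms) - s

            try:
                sol = least_squares(
                    model,
                    x0=[t1f[idx], m0f[idx]],
                    bounds=(lo, [T1_BOUNDS_MS[1], np.inf]),
                    xtol=1e-12,
                    ftol=1e-12,
                )
                t1f[idx], m0f[idx] = sol.x
                resf[idx] = float(np.sqrt(np.mean(sol.fun**2)))
                if not np.isfinite(sol.x).all():
                    validf[idx] = False
            except Exception:
                validf[idx] = False
    else:
        for idx in np.nonzero(validf)[0]:
            pred = spgr_signal(m0f[idx], t1f[idx], ang, stack.tr_ms)
            resf[idx] = float(np.sqrt(np.mean((pred - sig_flat[:, idx]) ** 2)))

    return RelaxometryMaps(
        t1_ms=t1f.reshape(shape),
        m0=m0f.reshape(shape),
        valid=validf.reshape(shape),
        residual=resf.reshape(shape),
    )


def signal_to_concentration(
    dynamic: np.ndarray,
    maps: RelaxometryMaps,
    r1: float,
    tr_ms: float,
    flip_deg: float,
    n_baseline_frames: int,
    rescale_m0: bool = True,
    clamp_saturated: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Convert a dynamic SPGR series to gadolinium concentration (mM).

    ``dynamic`` has time as the last axis (NIfTI convention).  The effective
    M0 of the dynamic series is rescaled from the pre-contrast baseline
    frames (the dynamic sequence gain may differ from the VFA stack); set
    ``rescale_m0=False`` to trust ``maps.m0`` directly.  Returns
    ``(concentration, saturated)`` where ``saturated`` flags frames whose
    signal exceeds the theoretical SPGR saturation value; such frames are
    clamped (default) or set to NaN.

    C(t) = (1/T1(t) - 1/T1(0)) / r1 with T1 in seconds, r1 in 1/s/mM.
    """
    if n_baseline_frames < 1:
        raise ValueError("at least one baseline frame is required")
    if r1 <= 0:
        raise ValueError("relaxivity r1 must be positive")
    dyn = np.asarray(dynamic, dtype=float)
    a = np.deg2rad(flip_deg)
    t1_0 = maps.t1_ms[..., None]
    e1_0 = np.exp(-tr_ms / t1_0)
    f0 = np.sin(a) * (1.0 - e1_0) / (1.0 - e1_0 * np.cos(a))
    if rescale_m0:
        baseline = dyn[..., :n_baseline_frames].mean(axis=-1, keepdims=True)
        m0 = baseline / f0
    else:
        m0 = maps.m0[..., None]

    with np.errstate(divide="ignore", invalid="ignore"):
        s = dyn / (m0 * np.sin(a))
        e1 = (1.0 - s) / (1.0 - s * np.cos(a))
    saturated = ~((e1 > 0) & (e1 < 1))
    eps = 1e-6
    e1 = np.clip(e1, eps, 1.0 - 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        r1_t = -np.log(e1) / tr_ms * 1000.0  # 1/s
        r1_0 = 1000.0 / t1_0
        conc = (r1_t - r1_0) / r1
    if not clamp_saturated:
        conc = np.where(saturated, np.nan, conc)
    conc = np.where(maps.valid[..., None], conc, np.nan)
    return conc, saturated & maps.valid[..., None]
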