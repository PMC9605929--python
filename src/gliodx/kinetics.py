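"""Tracer-kinetic core: arterial input functions and the two-compartment
exchange model (2CXM).

The 2CXM describes gadolinium exchange between an intravascular compartment
and the extravascular-extracellular space (EES).  Parameters are carried in
the units radiologists report them in:

* ``F``  — blood flow, mL/100 g/min
* ``BV`` — blood volume, mL/100 g
* ``Ki`` — unidirectional clearance (Patlak slope), mL/100 g/min
* ``Ve`` — EES volume, mL/100 g

Internally the kinetics are written directly in these blood-equivalent units
(tissue density 1 g/mL, so mL/100 g and mL/100 mL coincide); hematocrit enters
only when converting a plasma arterial concentration to the whole-blood input
that drives the tissue (factor ``1 - Hct_large``), and in the optional mapping
to plasma-referenced parameters (``to_plasma_parameters``).  Under this
convention the tissue impulse response ``h`` satisfies exactly

* ``h(0) = F / 6000``      (fractional units per second),
* ``integral of h = (BV + Ve) / 100``  (the distribution volume),
* plateau tissue concentration under a constant blood concentration ``c`` with
  ``Ki = 0`` equals ``BV/100 * c``.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import signal as _signal

#: mL/100 g/min -> fractional volume per second (density 1 g/mL).
PER_100G_MIN = 1.0 / 6000.0


@dataclasses.dataclass(frozen=True)
class Hematocrit:
    """Large-vessel (arterial sampling) and small-vessel (tissue) hematocrit."""

    large: float = 0.45
    small: float = 0.25

    def __post_init__(self) -> None:
        for name in ("large", "small"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"hematocrit.{name} must be in [0, 1)")


DEFAULT_HEMATOCRIT = Hematocrit()


@dataclasses.dataclass(frozen=True)
class ArterialInputFunction:
    """Plasma gadolinium concentration (mM) sampled on a time grid (s)."""

    times: np.ndarray
    concentration: np.ndarray
    bolus_arrival: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentration, dtype=float)
        if t.ndim != 1 or c.shape != t.shape:
            raise ValueError("times and concentration must be 1-D and equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if np.any(c < 0):
            raise ValueError("AIF concentration must be non-negative")
        if np.any(c[t < self.bolus_arrival] != 0):
            raise ValueError("AIF must be zero before bolus arrival")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentration", c)

    @property
    def dt(self) -> float:
        """Frame spacing; raises if the grid is not uniform."""
        d = np.diff(self.times)
        if not np.allclose(d, d[0], rtol=1e-6):
            raise ValueError("AIF time grid is not uniform")
        return float(d[0])

    def blood_concentration(self, hematocrit: Hematocrit = DEFAULT_HEMATOCRIT) -> np.ndarray:
        """Whole-blood concentration driving the tissue (mM)."""
        return self.concentration * (1.0 - hematocrit.large)


@dataclasses.dataclass(frozen=True)
class AifParams:
    """Gamma-variate first pass plus slow exponential washout.

    ``amplitude`` is the peak plasma concentration (mM) and acts as the dose
    scale; ``shape``/``scale_s`` parameterise the gamma-variate so the peak
    occurs ``shape * scale_s`` seconds after bolus arrival.
    """

    amplitude: float = 5.0
    shape: float = 3.0
    scale_s: float = 4.0
    bolus_arrival_s: float = 30.0
    washout_fraction: float = 0.25
    washout_rise_s: float = 25.0
    washout_decay_s: float = 220.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("dose (amplitude) must be >= 0")
        if self.shape <= 0 or self.scale_s <= 0:
            raise ValueError("gamma-variate shape and scale must be positive")


def make_aif(params: AifParams, time_grid: Sequence[float]) -> ArterialInputFunction:
    """Population-style AIF: gamma-variate peak plus exponential washout."""
    t = np.asarray(time_grid, dtype=float)
    if t.ndim != 1 or np.any(np.diff(t) <= 0):
        raise ValueError("time grid must be 1-D and strictly increasing")
    tau = t - params.bolus_arrival_s
    c = np.zeros_like(t)
    pos = tau > 0
    a, th = params.shape, params.scale_s
    tp = tau[pos]
    peak = (tp / (a * th)) ** a * np.exp(a - tp / th)
    wash = (
        params.washout_fraction
        * (1.0 - np.exp(-tp / params.washout_rise_s))
        * np.exp(-tp / params.washout_decay_s)
    )
    c[pos] = params.amplitude * (peak + wash)
    return ArterialInputFunction(t, np.maximum(c, 0.0), params.bolus_arrival_s)


@dataclasses.dataclass(frozen=True)
class TissueParams:
    """2CXM tissue parameters in reported units (see module docstring)."""

    F: float
    BV: float
    Ki: float
    Ve: float

    def __post_init__(self) -> None:
        if min(self.F, self.BV, self.Ki, self.Ve) < 0:
            raise ValueError("all tissue parameters must be >= 0")
        if self.BV + self.Ve > 100.0:
            raise ValueError("BV + Ve cannot exceed 100 mL/100 g")
        if self.Ki > self.F:
            raise ValueError("Ki cannot exceed F (extraction cannot exceed delivery)")


def to_plasma_parameters(
    params: TissueParams, hematocrit: Hematocrit = DEFAULT_HEMATOCRIT
) -> dict:
    """Map reported (F, BV, Ki, Ve) to plasma-referenced (F_p, v_p, PS, v_e).

    F_p = F (1 - Hct_small), v_p = BV (1 - Hct_small) / 100, v_e = Ve / 100,
    and PS solves Ki = F_p PS / (F_p + PS) on the plasma scale.
    """
    fp = params.F * (1.0 - hematocrit.small)
    vp = params.BV * (1.0 - hematocrit.small) / 100.0
    ve = params.Ve / 100.0
    ki = params.Ki
    if ki <= 0:
        ps = 0.0
    elif ki >= fp:
        ps = np.inf
    else:
        ps = ki * fp / (fp - ki)
    return {"F_p": fp, "v_p": vp, "PS": ps, "v_e": ve}


def _modes(params: TissueParams) -> list[tuple[float, float]]:
    """Exponential modes (amplitude, rate) of the tissue impulse response.

    h(t) = sum_i a_i exp(lambda_i t), lambda_i <= 0, such that the tissue
    concentration is h convolved with the whole-blood input concentration.
    """
    f = params.F * PER_100G_MIN
    ki = params.Ki * PER_100G_MIN
    vb = params.BV / 100.0
    ve = params.Ve / 100.0
    if f == 0.0:
        return []
    if ki == 0.0 or ve == 0.0:
        if vb == 0.0:
            return []
        return [(f, -f / vb)]  # purely intravascular
    if vb == 0.0:
        return [(ki, -ki / ve)]  # permeability-limited, negligible vascular volume
    if ki >= f * (1.0 - 1e-12):
        # flow-limited: instantaneous equilibration, one well-mixed compartment
        return [(f, -f / (vb + ve))]
    ps = ki * f / (f - ki)
    m = np.array([[-(f + ps) / vb, ps / vb], [ps / ve, -ps / ve]])
    b = np.array([f / vb, 0.0])
    w = np.array([vb, ve])
    lam, vec = np.linalg.eig(m)
    coef = np.linalg.solve(vec, b)
    amps = (w @ vec) * coef
    return [(float(np.real(a)), float(np.real(l))) for a, l in zip(amps, lam)]


def impulse_response(params: TissueParams, times: Sequence[float]) -> np.ndarray:
    """Analytic tissue impulse response h(t) (fractional units per second)."""
    t = np.asarray(times, dtype=float)
    h = np.zeros_like(t)
    for a, lam in _modes(params):
        h += a * np.exp(lam * np.maximum(t, 0.0))
    h[t < 0] = 0.0
    return h


def _expconv(rate: float, dt: float, c: np.ndarray) -> np.ndarray:
    """Exact convolution of exp(rate * t) (rate <= 0) with piecewise-linear c.

    Returns y[k] = integral_0^{t_k} exp(rate (t_k - s)) c(s) ds evaluated with
    c linearly interpolated between samples; implemented as a linear
    recurrence via an IIR filter, so it is exact for piecewise-linear input.
    """
    u = rate * dt
    if abs(u) < 1e-8:
        phi1, phi2 = dt * (1.0 + u / 2.0), dt * (0.5 + u / 3.0)
    else:
        e = np.exp(u)
        phi1 = dt * (e - 1.0) / u
        phi2 = dt * (e - 1.0 - u) / u**2
    # increment over [t_k, t_{k+1}] given start value c[k], end value c[k+1]
    inc = c[:-1] * phi1 + (c[1:] - c[:-1]) * phi2
    decay = np.exp(u)
    y = np.empty_like(c)
    y[0] = 0.0
    y[1:] = _signal.lfilter([1.0], [1.0, -decay], inc)
    return y


def forward_2cxm(
    params: TissueParams,
    aif: ArterialInputFunction,
    hematocrit: Hematocrit = DEFAULT_HEMATOCRIT,
) -> np.ndarray:
    """Tissue concentration curve (mM) on the AIF time grid.

    C_t = h * C_blood with C_blood = (1 - Hct_large) x plasma AIF; the
    mode-wise convolution is exact for a piecewise-linear input, so no
    oversampling is needed.
    """
    dt = aif.dt
    c_in = aif.blood_concentration(hematocrit)
    ct = np.zeros_like(c_in)
    for a, lam in _modes(params):
        ct += a * _expconv(lam, dt, c_in)
    return np.maximum(ct, 0.0)


def forward_2cxm_batch(
    param_sets: Sequence[TissueParams],
    aif: ArterialInputFunction,
    hematocrit: Hematocrit = DEFAULT_HEMATOCRIT,
) -> np.ndarray:
    """Stack of tissue curves, one row per parameter set."""
    return np.stack([forward_2cxm(p, aif, hematocrit) for p in param_sets])
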