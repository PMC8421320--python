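"""Tracer-kinetic core: arterial input models, exponential convolution,
Renkin-Crone extraction maps, and single-tissue forward models.

Two forward models are provided.

**15O-water PET.** Water is freely diffusible, so its influx constant equals
flow and washout is flow over the tissue/blood partition coefficient p::

    C_PET(t) = PTF * F * [C_A (x) exp(-(F/p) t)] + Va * C_A(t)

with F the myocardial blood flow (mL/g/min), PTF the perfusable tissue
fraction (g/mL) and Va the arterial blood-volume (spillover) fraction.

**Gd DCE-MRI.** Gadolinium contrast is only partially extracted across the
capillary wall, so the influx constant K1 is below flow.  The extended
one-tissue model is::

    C_T(t) = K1 * [C_A (x) exp(-(K1/Ve) t)] + vb * C_A(t)

In ``plain`` mode K1 is a free parameter.  In ``ps_embedded`` mode the
Renkin-Crone relation K1 = F * (1 - exp(-PS/F)) ties K1 to flow F and the
permeability-surface area product PS, and the extraction site sees the
arterial bolus only after capillary transit: the tissue influx is driven by
the well-stirred capillary concentration::

    C_cap(t) = C_A (x) (F/vb) exp(-(F/vb) t)

(unit-area kernel; transit time vb/F, a few seconds at myocardial flows)
instead of C_A itself.  This matters: if tissue uptake were driven directly
by C_A the model would depend on (F, PS) only through K1 and the two could
never be separated from one curve; the flow-dependent delivery delay is
what makes direct estimation of F and PS possible.  Because the transit
kernel has unit area, the tracer mass entering tissue is unchanged, so a
plain-model fit to such data still recovers K1 ~ E*F (underestimating flow
wherever extraction is incomplete).  As F grows C_cap approaches C_A and
ps_embedded converges to the plain model with K1 = PS.

All flows and rate constants are carried in the conventional mL/g/min and
converted to 1/s at the model boundary; the time axis is seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .curves import SampledCurve

SEC_PER_MIN = 60.0
#: Water tissue/blood partition coefficient, mL/g (fixed, not fitted).
WATER_PARTITION_COEFF = 0.91


class KineticsError(ValueError):
    """Invalid kinetic-model input."""


class NoSolutionError(KineticsError):
    """Requested inversion has no finite solution (e.g. K1 >= PS)."""


# --------------------------------------------------------------------------
# parameter containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AifModelParams:
    """Gamma-variate bolus model for an arterial input function.

    The first-pass peak occurs at ``t0 + alpha*beta`` and equals ``amplitude``;
    ``recirc_fraction`` adds a recirculation tail (first pass convolved with a
    unit-area exponential of time constant ``recirc_tau``).
    """

    t0: float            # bolus arrival, s
    alpha: float         # gamma shape
    beta: float          # gamma scale, s
    amplitude: float     # peak value, curve units
    recirc_fraction: float = 0.0
    recirc_tau: float = 30.0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0 or self.amplitude <= 0:
            raise KineticsError("alpha, beta and amplitude must be positive")
        if self.t0 < 0:
            raise KineticsError("t0 must be non-negative")
        if not 0 <= self.recirc_fraction < 1:
            raise KineticsError("recirc_fraction must lie in [0, 1)")
        if self.recirc_tau <= 0:
            raise KineticsError("recirc_tau must be positive")


@dataclass(frozen=True)
class WaterKineticParams:
    """Parameters of the single-tissue 15O-water model."""

    F: float                     # MBF, mL/g/min
    PTF: float = 0.7             # perfusable tissue fraction, g/mL, (0, 1]
    Va: float = 0.25             # arterial blood-volume fraction, [0, 1)
    p: float = WATER_PARTITION_COEFF  # partition coefficient, mL/g

    def __post_init__(self) -> None:
        if self.F < 0:
            raise KineticsError("F must be non-negative")
        if not 0 < self.PTF <= 1:
            raise KineticsError("PTF must lie in (0, 1]")
        if not 0 <= self.Va < 1:
            raise KineticsError("Va must lie in [0, 1)")
        if self.p <= 0:
            raise KineticsError("partition coefficient must be positive")


@dataclass(frozen=True)
class GdKineticParams:
    """Parameters of the gadolinium one-tissue model.

    Either ``K1`` is given directly (plain model) or ``F`` and ``PS`` are
    given and K1 follows from the Renkin-Crone relation.  When F and PS are
    both set, a supplied K1 must be consistent with them.
    """

    F: float | None = None       # MBF, mL/g/min
    PS: float | None = None      # permeability-surface area product, mL/g/min
    K1: float | None = None      # influx constant, mL/g/min
    Ve: float = 0.35             # extravascular distribution volume, mL/g
    vb: float = 0.08             # blood-volume fraction, [0, 1)

    def __post_init__(self) -> None:
        if self.Ve <= 0:
            raise KineticsError("Ve must be positive")
        if not 0 <= self.vb < 1:
            raise KineticsError("vb must lie in [0, 1)")
        if self.F is not None and self.PS is not None:
            implied = renkin_crone_k1(self.F, self.PS)
            if self.K1 is None:
                object.__setattr__(self, "K1", implied)
            elif abs(self.K1 - implied) > 1e-9 + 1e-6 * implied:
                raise KineticsError(
                    f"K1={self.K1} inconsistent with Renkin-Crone value {implied:.6g} "
                    f"for F={self.F}, PS={self.PS}")
        if self.K1 is None:
            raise KineticsError("either K1 or both F and PS must be provided")
        if self.K1 < 0:
            raise KineticsError("K1 must be non-negative")


# --------------------------------------------------------------------------
# Renkin-Crone extraction
# --------------------------------------------------------------------------

def renkin_crone_k1(F: float, PS: float) -> float:
    """Influx constant K1 = F * (1 - exp(-PS/F)) (mL/g/min).

    The Renkin-Crone capillary model: the first-pass extraction fraction
    E = 1 - exp(-PS/F) falls with flow, so K1 = E*F saturates towards PS at
    high flow.  Returns 0 for F = 0.
    """
    if F < 0 or PS < 0:
        raise KineticsError("F and PS must be non-negative")
    if F == 0.0:
        return 0.0
    # -expm1 is accurate for small PS/F where 1-exp underflows
    return float(F * -math.expm1(-PS / F))


def renkin_crone_extraction(F: float, PS: float) -> float:
    """First-pass extraction fraction E = K1/F = 1 - exp(-PS/F)."""
    if F <= 0:
        raise KineticsError("extraction is defined for F > 0")
    return float(-math.expm1(-PS / F))


def renkin_crone_invert(K1: float, PS: float) -> float:
    """Flow F solving K1 = F * (1 - exp(-PS/F)) for given PS.

    The forward map is strictly increasing in F with range [0, PS), so the
    root is unique for 0 <= K1 < PS; K1 >= PS has no finite solution
    (extraction-corrected flow is unbounded there).
    """
    if K1 < 0:
        raise KineticsError("K1 must be non-negative")
    if PS <= 0:
        raise KineticsError("PS must be positive")
    if K1 >= PS:
        raise NoSolutionError(
            f"K1={K1:g} >= PS={PS:g}: extraction correction has no finite flow")
    if K1 == 0.0:
        return 0.0
    # K1 <= F always; large-F expansion K1 ~ PS - PS^2/(2F) gives an upper bound
    lo = K1
    hi = max(2.0 * K1, PS * PS / (2.0 * (PS - K1)) * 4.0)
    while renkin_crone_k1(hi, PS) < K1:
        hi *= 4.0
    return float(brentq(lambda F: renkin_crone_k1(F, PS) - K1, lo, hi,
                        xtol=1e-14, rtol=8.9e-16, maxiter=200))


def extraction_correction_amplification(F: float, PS: float) -> float:
    """First-order error amplification dF/dK1 of the extraction correction.

    dK1/dF = 1 - (1 + PS/F) exp(-PS/F); its reciprocal grows without bound
    as K1 approaches PS, which is why corrected flows are noisy at high flow.
    """
    if F <= 0 or PS <= 0:
        raise KineticsError("F and PS must be positive")
    x = PS / F
    dk1_df = 1.0 - (1.0 + x) * math.exp(-x)
    return float(1.0 / dk1_df)


# --------------------------------------------------------------------------
# convolution and input models
# --------------------------------------------------------------------------

def expconv(curve: SampledCurve, rate: float) -> SampledCurve:
    """Convolve a curve with exp(-rate*t) on its native (nonuniform) grid.

    Uses the recursion that is exact when the input is piecewise linear
    between samples, which is the right discretisation for short, unevenly
    sampled clinical curves.  ``rate`` is in 1/s.  With rate = 0 the result
    is the running time-integral of the curve.  The curve is taken as zero
    before its first sample.
    """
    if rate < 0:
        raise KineticsError("rate must be non-negative")
    t = curve.times
    f = curve.values
    out = np.zeros_like(f)
    if rate == 0.0:
        dt = np.diff(t)
        out[1:] = np.cumsum(0.5 * dt * (f[1:] + f[:-1]))
        return curve.with_values(out)
    dt = np.diff(t)
    e = np.exp(-rate * dt)
    # integral over [t_i, t_i+dt] of (f_i + m*u) e^{-k(dt-u)} du, m the slope
    one_me = -np.expm1(-rate * dt)           # 1 - e^{-k dt}, stable
    m = (f[1:] - f[:-1]) / dt
    seg = f[:-1] * one_me / rate + m * (dt - one_me / rate) / rate
    for i in range(1, len(f)):
        out[i] = out[i - 1] * e[i - 1] + seg[i - 1]
    return curve.with_values(out)


def gamma_variate_aif(params: AifModelParams, times: np.ndarray,
                      unit_tag: str = "kBq/mL") -> SampledCurve:
    """Evaluate a gamma-variate bolus AIF (plus optional recirculation).

    First pass: amplitude * ((t-t0)/(alpha*beta))^alpha * exp(alpha - (t-t0)/beta)
    (the peak-normalised gamma variate), zero before arrival t0, peaking at
    t0 + alpha*beta with value exactly amplitude.
    The recirculation term is recirc_fraction times the first pass convolved
    with a unit-area exponential kernel exp(-t/tau)/tau.
    """
    times = np.asarray(times, dtype=float)
    if np.any(times < 0) or not np.all(np.diff(times) > 0):
        raise KineticsError("times must be non-negative and strictly increasing")
    tau = np.maximum(times - params.t0, 0.0) / params.beta
    with np.errstate(divide="ignore", invalid="ignore"):
        first = params.amplitude * np.where(
            tau > 0,
            np.exp(params.alpha * np.log(np.where(tau > 0, tau, 1.0) / params.alpha)
                   + params.alpha - tau), 0.0)
    curve = SampledCurve(times, first, unit_tag)
    if params.recirc_fraction > 0:
        recirc = expconv(curve, 1.0 / params.recirc_tau).values / params.recirc_tau
        curve = curve.with_values(first + params.recirc_fraction * recirc)
    return curve


# --------------------------------------------------------------------------
# forward models
# --------------------------------------------------------------------------

def _resample_aif(aif: SampledCurve, times: np.ndarray) -> SampledCurve:
    times = np.asarray(times, dtype=float)
    if times.shape == aif.times.shape and np.allclose(times, aif.times):
        return aif
    return SampledCurve(times, aif.interp(times), aif.unit_tag)


def water_1tcm_forward(params: WaterKineticParams, aif: SampledCurve,
                       times: np.ndarray | None = None) -> SampledCurve:
    """Single-tissue 15O-water model prediction on ``times`` (default: AIF grid).

    C(t) = PTF * F * [C_A (x) exp(-(F/p) t)] + Va * C_A(t), F in mL/g/min
    converted internally to 1/s.  Output in AIF units.
    """
    ca = _resample_aif(aif, aif.times if times is None else times)
    k1_per_s = params.F / SEC_PER_MIN          # water: K1 = F
    k2_per_s = params.F / params.p / SEC_PER_MIN
    tissue = k1_per_s * expconv(ca, k2_per_s).values
    return ca.with_values(params.PTF * tissue + params.Va * ca.values)


def gd_1tcm_forward(params: GdKineticParams, aif: SampledCurve,
                    times: np.ndarray | None = None,
                    mode: str = "plain") -> SampledCurve:
    """Gadolinium one-tissue model prediction in tissue concentration units.

    ``plain`` uses params.K1 directly with a static vascular term:
    C_T(t) = K1 * [C_A (x) exp(-(K1/Ve) t)] + vb * C_A(t).

    ``ps_embedded`` requires F and PS, sets K1 = renkin_crone_k1(F, PS) and
    drives the tissue influx with the capillary-transit-dispersed input
    C_cap = C_A (x) (F/vb) exp(-(F/vb) t), which encodes flow in the
    delivery phase and makes (F, PS) jointly identifiable; the vascular
    term stays vb * C_A.  Zero rates reduce both modes to the blood-pool
    curve vb * C_A; F -> infinity recovers the plain model with K1 = PS.
    """
    if mode not in ("plain", "ps_embedded"):
        raise KineticsError(f"unknown mode {mode!r}")
    ca = _resample_aif(aif, aif.times if times is None else times)
    tissue_input = ca
    if mode == "ps_embedded":
        if params.F is None or params.PS is None:
            raise KineticsError("ps_embedded mode requires F and PS")
        k1 = renkin_crone_k1(params.F, params.PS)
        if params.vb > 0 and params.F > 0:
            kt_per_s = params.F / params.vb / SEC_PER_MIN
            tissue_input = ca.with_values(
                kt_per_s * expconv(ca, kt_per_s).values)
    else:
        if params.K1 is None:
            raise KineticsError("plain mode requires K1")
        k1 = params.K1
    if k1 > 0:
        k1_per_s = k1 / SEC_PER_MIN
        k2_per_s = k1 / params.Ve / SEC_PER_MIN
        tissue = k1_per_s * expconv(tissue_input, k2_per_s).values
    else:
        tissue = np.zeros_like(ca.values)
    return ca.with_values(tissue + params.vb * ca.values)
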