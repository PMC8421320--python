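"""Perfusion estimation from DCE-MRI curves via three analysis routes.

1. **plain_1tcm** — fit the one-tissue model with a free influx constant K1.
   Because gadolinium is incompletely extracted, K1 underestimates flow,
   increasingly so at high flow.
2. **ef_corrected** — invert the Renkin-Crone relation on a fitted K1 using a
   population permeability-surface area product, recovering flow at the cost
   of amplifying measurement noise near the K1 -> PS asymptote.
3. **1tcm_ps** — embed the Renkin-Crone relation in the model and fit flow F
   and PS directly (with distribution volume Ve and blood fraction vb),
   implicitly correcting for extraction.

Raw signal curves are first converted to gadolinium concentration by
inverting the saturation-recovery signal equation around a baseline estimate.
Unreliable fits (large relative standard error on the perfusion parameter or
a parameter pinned at a box bound) are flagged and excluded downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._fitting import multistart_least_squares
from .cohort import (BLOOD_SIGNAL, CONDITIONS, TISSUE_SIGNAL, Cohort,
                     SignalModelParams)
from .curves import CurveError, SampledCurve
from .kinetics import (GdKineticParams, KineticsError, NoSolutionError,
                       extraction_correction_amplification, gd_1tcm_forward,
                       renkin_crone_invert, renkin_crone_k1)
from .segments import TERRITORIES
from .pet import _region_curves

K1_BOUNDS = (0.01, 4.0)
F_BOUNDS = (0.05, 8.0)
PS_BOUNDS = (0.5, 6.0)
VE_BOUNDS = (0.05, 1.0)
VB_BOUNDS = (0.0, 0.3)
#: Fits with relative SE of the perfusion parameter above this, or with any
#: parameter pinned at a bound, are marked unreliable.
REL_SE_THRESHOLD = 0.5
DEFAULT_MAX_CONC = 20.0  # mmol/L saturation-clipping ceiling


@dataclass(frozen=True)
class MriFitResult:
    """One region's Gd-model fit under one analysis route."""

    model_tag: str                    # plain_1tcm | ef_corrected | 1tcm_ps
    params: GdKineticParams
    rss: float
    param_rel_se: dict[str, float]
    reliable: bool
    converged: bool = True
    amplification: float = 1.0        # dF/dK1 of the extraction correction

    @property
    def perfusion(self) -> float:
        """The route's perfusion-related parameter (K1 or F)."""
        if self.model_tag == "plain_1tcm":
            return float(self.params.K1)
        return float(self.params.F)


# --------------------------------------------------------------------------
# signal -> concentration
# --------------------------------------------------------------------------

def signal_to_concentration(signal: SampledCurve,
                            params: SignalModelParams,
                            baseline_frames: int = 5,
                            max_conc: float = DEFAULT_MAX_CONC) -> SampledCurve:
    """Invert the saturation-recovery signal equation to Gd concentration.

    The equilibrium signal S0 is inferred from the mean of the pre-contrast
    baseline frames; each sample is then passed through the strictly
    monotone inverse c = (-ln(1 - S/S0)/TD - 1/T10)/r1.  Samples at or above
    the model's asymptote S0 are clipped to ``max_conc`` with a warning.
    Baseline noise maps to small values scattered around zero (which may be
    slightly negative).
    """
    if baseline_frames < 3:
        raise CurveError("need at least 3 baseline frames to estimate S0")
    if len(signal) <= baseline_frames:
        raise CurveError("curve shorter than the requested baseline")
    sat_factor = -np.expm1(-params.TD / params.T10)   # 1 - exp(-TD/T10)
    s0 = float(np.mean(signal.values[:baseline_frames])) / sat_factor
    if s0 <= 0:
        raise CurveError("non-positive baseline signal; cannot estimate S0")
    frac = signal.values / s0
    clipped = frac >= 1.0 - 1e-12
    if np.any(clipped):
        warnings.warn(f"{int(clipped.sum())} sample(s) at/above the signal "
                      f"asymptote; clipped to {max_conc} mmol/L", stacklevel=2)
    safe = np.where(clipped, 0.5, frac)
    conc = (-np.log1p(-safe) / params.TD - 1.0 / params.T10) / params.r1
    conc = np.where(clipped, max_conc, conc)
    return SampledCurve(signal.times, conc, "mmol/L")


# --------------------------------------------------------------------------
# single-region fits
# --------------------------------------------------------------------------

def _finish(model_tag: str, fit, names: list[str], params: GdKineticParams,
            perfusion_name: str, amplification: float = 1.0) -> MriFitResult:
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = {n: float(abs(s / x)) if x != 0 else np.inf
               for n, s, x in zip(names, fit.se, fit.x)}
    unreliable = (not fit.converged
                  or not np.isfinite(rel.get(perfusion_name, np.inf))
                  or rel[perfusion_name] > REL_SE_THRESHOLD
                  or bool(fit.at_bound.any()))
    return MriFitResult(model_tag=model_tag, params=params, rss=float(fit.rss),
                        param_rel_se=rel, reliable=not unreliable,
                        converged=fit.converged, amplification=amplification)


def fit_gd_plain_1tcm(conc_tac: SampledCurve, conc_aif: SampledCurve
                      ) -> MriFitResult:
    """Fit the plain one-tissue model (free K1, Ve, vb) to a concentration TAC.

    K1 is returned as the perfusion-related parameter; no extraction
    correction is applied, so K1 underestimates flow wherever extraction is
    incomplete.
    """
    def residual(x: np.ndarray) -> np.ndarray:
        model = gd_1tcm_forward(
            GdKineticParams(K1=x[0], Ve=x[1], vb=x[2]), conc_aif,
            conc_tac.times, mode="plain")
        return conc_tac.values - model.values

    starts = [[k1, 0.35, 0.08] for k1 in (0.3, 1.0, 2.0)]
    fit = multistart_least_squares(
        residual, starts,
        lower=[K1_BOUNDS[0], VE_BOUNDS[0], VB_BOUNDS[0]],
        upper=[K1_BOUNDS[1], VE_BOUNDS[1], VB_BOUNDS[1]])
    x = np.where(np.isfinite(fit.x), fit.x, [K1_BOUNDS[0], 0.35, 0.0])
    params = GdKineticParams(K1=float(x[0]), Ve=float(x[1]), vb=float(x[2]))
    return _finish("plain_1tcm", fit, ["K1", "Ve", "vb"], params, "K1")


def apply_extraction_correction(K1: float, PS_population: float
                                ) -> tuple[float, float, bool]:
    """Extraction-correct a fitted K1 into flow via the Renkin-Crone inverse.

    Returns ``(F, amplification, recoverable)`` where amplification is the
    first-order error factor dF/dK1 = 1 / (1 - (1 + PS/F) exp(-PS/F)).  K1 at
    or above the population PS is unrecoverable (flow unbounded): F is NaN
    and ``recoverable`` is False — the regime where corrected values
    correlate poorly with reference flow.
    """
    if K1 < 0:
        raise KineticsError("K1 must be non-negative")
    try:
        F = renkin_crone_invert(K1, PS_population)
    except NoSolutionError:
        return np.nan, np.inf, False
    if F == 0.0:
        return 0.0, 1.0, True
    return F, extraction_correction_amplification(F, PS_population), True


def fit_gd_ef_corrected(conc_tac: SampledCurve, conc_aif: SampledCurve,
                        ps_population: float) -> MriFitResult:
    """Plain 1TCM fit followed by Renkin-Crone extraction correction of K1."""
    plain = fit_gd_plain_1tcm(conc_tac, conc_aif)
    F, amp, ok = apply_extraction_correction(float(plain.params.K1),
                                             ps_population)
    params = GdKineticParams(F=F if ok else None,
                             PS=ps_population if ok else None,
                             K1=float(plain.params.K1),
                             Ve=plain.params.Ve, vb=plain.params.vb)
    rel = dict(plain.param_rel_se)
    # error amplification propagates the K1 uncertainty onto F
    rel["F"] = rel["K1"] * amp if ok and np.isfinite(rel["K1"]) else np.inf
    reliable = plain.reliable and ok and rel["F"] <= REL_SE_THRESHOLD
    return MriFitResult(model_tag="ef_corrected", params=params,
                        rss=plain.rss, param_rel_se=rel, reliable=reliable,
                        converged=plain.converged, amplification=amp)


def fit_gd_1tcm_ps(conc_tac: SampledCurve, conc_aif: SampledCurve,
                   ps_fixed: float | None = None) -> MriFitResult:
    """Fit the PS-embedded one-tissue model: direct estimation of flow.

    Fits F in [0.05, 8] and PS in [0.5, 6] (mL/g/min) with K1 tied to
    F(1 - exp(-PS/F)), plus Ve and vb, from a grid of starts over F x PS.
    ``ps_fixed`` pins PS to a population value instead of fitting it.
    Reliability requires relative SE of F below 50% and no parameter at a
    bound.
    """
    fit_ps = ps_fixed is None

    def residual(x: np.ndarray) -> np.ndarray:
        ps = x[1] if fit_ps else ps_fixed
        model = gd_1tcm_forward(
            GdKineticParams(F=x[0], PS=ps, Ve=x[2], vb=x[3]), conc_aif,
            conc_tac.times, mode="ps_embedded")
        return conc_tac.values - model.values

    starts = [[f, ps, 0.35, 0.08]
              for f in (0.5, 1.5, 3.0) for ps in ((1.5, 3.0) if fit_ps
                                                  else (ps_fixed,))]
    lower = [F_BOUNDS[0], PS_BOUNDS[0] if fit_ps else ps_fixed - 1e-9,
             VE_BOUNDS[0], VB_BOUNDS[0]]
    upper = [F_BOUNDS[1], PS_BOUNDS[1] if fit_ps else ps_fixed + 1e-9,
             VE_BOUNDS[1], VB_BOUNDS[1]]
    fit = multistart_least_squares(residual, starts, lower, upper)
    if not fit_ps:
        fit.at_bound[1] = False       # pinned by design, not by the data
    x = np.where(np.isfinite(fit.x), fit.x, [F_BOUNDS[0], 2.0, 0.35, 0.0])
    params = GdKineticParams(F=float(x[0]),
                             PS=float(x[1]) if fit_ps else float(ps_fixed),
                             Ve=float(x[2]), vb=float(x[3]))
    return _finish("1tcm_ps", fit, ["F", "PS", "Ve", "vb"], params, "F")


# --------------------------------------------------------------------------
# population PS calibration
# --------------------------------------------------------------------------

def calibrate_population_ps(pairs: list[tuple[float, float]]) -> float:
    """Least-squares population PS from paired (MRI K1, reference flow F).

    Fits the single scalar PS in K1 = F(1 - exp(-PS/F)) across the pairs,
    which should span rest and stress flows for identifiability.  Warns when
    the flow range is too narrow (ill-conditioned) or when K1 ~ F everywhere
    (extraction ~ 1; PS unidentifiable, estimate driven to the upper bound).
    """
    if len(pairs) < 5:
        raise ValueError("need at least 5 (K1, F) pairs to calibrate PS")
    k1 = np.asarray([p[0] for p in pairs], dtype=float)
    f = np.asarray([p[1] for p in pairs], dtype=float)
    if np.any(k1 < 0) or np.any(f <= 0):
        raise ValueError("K1 must be non-negative and F positive")
    if np.ptp(f) < 0.05 * np.mean(f):
        warnings.warn("flow values nearly identical; PS calibration is "
                      "ill-conditioned", stacklevel=2)

    upper = 50.0

    def residual(x: np.ndarray) -> np.ndarray:
        return k1 - np.array([renkin_crone_k1(fi, x[0]) for fi in f])

    fit = multistart_least_squares(residual, [[1.5], [3.0], [6.0]],
                                   lower=[1e-6], upper=[upper])
    ps = float(fit.x[0])
    if ps > 0.95 * upper:
        warnings.warn("PS at calibration upper bound: extraction ~ 1, "
                      "PS unidentifiable from these pairs", stacklevel=2)
    return ps


# --------------------------------------------------------------------------
# cohort-level fitting
# --------------------------------------------------------------------------

def fit_cohort_mri(cohort: Cohort, model_tag: str = "1tcm_ps",
                   regions: str = "all", ps_population: float | None = None,
                   ps_fixed: float | None = None,
                   tissue_signal: SignalModelParams = TISSUE_SIGNAL,
                   blood_signal: SignalModelParams = BLOOD_SIGNAL,
                   baseline_frames: int = 5) -> pd.DataFrame:
    """Run one MRI analysis route over every subject/condition and region.

    Signals are converted to concentration per segment (blood pool with the
    blood relaxation parameters), then territory/global concentration curves
    are volume-weighted means of member segments.  ``ef_corrected`` requires
    ``ps_population``.  Unreliable fits keep their rows with
    ``reliable = False`` so downstream agreement analysis can count
    exclusions.
    """
    if model_tag not in ("plain_1tcm", "ef_corrected", "1tcm_ps"):
        raise ValueError(f"unknown model_tag {model_tag!r}")
    if model_tag == "ef_corrected" and ps_population is None:
        raise ValueError("ef_corrected route needs a population PS")
    seg_model = cohort.truth.segment_model
    rows = []
    for sub in cohort.truth.subjects:
        for cond in CONDITIONS:
            scan = cohort.mri.get((sub.subject_id, cond))
            if scan is None:
                rows.append({"subject": sub.subject_id, "condition": cond,
                             "region": "global", "mbf": np.nan, "ok": False,
                             "missing": True})
                continue
            aif = signal_to_concentration(scan.blood_signal, blood_signal,
                                          baseline_frames)
            concs = [signal_to_concentration(s, tissue_signal, baseline_frames)
                     for s in scan.segment_signals]
            curves = _region_curves(concs, seg_model)
            if regions == "global":
                names = ["global"]
            elif regions == "territories":
                names = ["global", *TERRITORIES]
            else:
                names = list(curves)
            for name in names:
                if model_tag == "plain_1tcm":
                    r = fit_gd_plain_1tcm(curves[name], aif)
                elif model_tag == "ef_corrected":
                    r = fit_gd_ef_corrected(curves[name], aif, ps_population)
                else:
                    r = fit_gd_1tcm_ps(curves[name], aif, ps_fixed=ps_fixed)
                rows.append({
                    "subject": sub.subject_id, "condition": cond,
                    "region": name, "model": model_tag,
                    "mbf": r.perfusion,
                    "K1": np.nan if r.params.K1 is None else float(r.params.K1),
                    "F": np.nan if r.params.F is None else float(r.params.F),
                    "PS": np.nan if r.params.PS is None else float(r.params.PS),
                    "Ve": r.params.Ve, "vb": r.params.vb, "rss": r.rss,
                    "rel_se": r.param_rel_se.get(
                        "K1" if model_tag == "plain_1tcm" else "F", np.nan),
                    "reliable": r.reliable, "converged": r.converged,
                    "ok": bool(r.reliable), "missing": False,
                })
    return pd.DataFrame(rows)
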