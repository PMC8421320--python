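"""Synthetic rest/stress cohort generator with known ground truth.

Emulates a simultaneous PET-MR perfusion study: each subject receives a
6-minute dynamic 15O-water PET scan and a 65-heartbeat saturation-recovery
DCE-MRI scan at rest and during hyperaemia.  Per-subject flows are drawn
from rest/stress population distributions, the Gd permeability-surface area
product PS is drawn once per subject (shared across conditions), and the 17
AHA segments scatter around the subject's global flow with a configurable
coefficient of variation while preserving the volume-weighted global mean
exactly.

PET noise is Gaussian per frame with variance proportional to activity over
frame duration (the usual count-statistics proxy); MRI noise is Gaussian at
a configured baseline signal-to-noise ratio.  Everything is reproducible
from the config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import stats

from .curves import SampledCurve
from .kinetics import (
    AifModelParams,
    GdKineticParams,
    KineticsError,
    WaterKineticParams,
    gamma_variate_aif,
    gd_1tcm_forward,
    water_1tcm_forward,
)
from .segments import N_SEGMENTS, SegmentModel

CONDITIONS = ("rest", "stress")


class CohortConfig(BaseModel):
    """Study-design and population parameters for the synthetic cohort.

    Flow distributions default to the population moments of the emulated
    cohort (rest/stress MBF in mL/g/min); scan-geometry defaults follow the
    emulated protocol (6-min PET, 65-heartbeat 3-slice MRI, heart rates
    66/82 bpm rest/stress).
    """

    model_config = ConfigDict(extra="forbid")

    n_subjects: int = Field(12, ge=2)
    seed: int = 0
    rest_mbf_mean: float = Field(1.02, gt=0)
    rest_mbf_sd: float = Field(0.28, ge=0)
    stress_mbf_mean: float = Field(3.13, gt=0)
    stress_mbf_sd: float = Field(1.16, ge=0)
    ps_mean: float = Field(2.91, gt=0)
    ps_sd: float = Field(0.37, ge=0)
    segment_heterogeneity_cv: float = Field(0.10, ge=0)
    pet_noise_scale: float = Field(1.5, ge=0)   # (kBq/mL)^0.5: SD = scale*sqrt(C/dt)
    mri_snr: float = Field(20.0, gt=0)          # baseline signal / noise SD
    pet_duration_s: float = Field(360.0, gt=0)
    mri_n_beats: int = Field(65, ge=10)
    heart_rate_rest: float = Field(66.0, gt=0)
    heart_rate_stress: float = Field(82.0, gt=0)
    # tissue/model constants (conventional 3 T values, explicit config)
    ve: float = Field(0.35, gt=0)
    vb: float = Field(0.08, ge=0, lt=1)
    ptf: float = Field(0.7, gt=0, le=1)
    va: float = Field(0.25, ge=0, lt=1)
    # truncation bounds for the population draws
    rest_mbf_lower: float = 0.3
    stress_mbf_lower: float = 1.0
    ps_lower: float = 0.5

    @model_validator(mode="after")
    def _check(self) -> "CohortConfig":
        if self.stress_mbf_lower <= 0 or self.rest_mbf_lower <= 0:
            raise ValueError("truncation bounds must be positive")
        return self


@dataclass(frozen=True)
class SignalModelParams:
    """Saturation-recovery MRI signal model parameters.

    S(c) = S0 * (1 - exp(-TD * R1(c))),  R1(c) = 1/T10 + r1 * c

    with TD the saturation-prep delay (s), T10 the pre-contrast T1 (s) and
    r1 the contrast-agent relaxivity (L/(mmol*s)).  flip/TR are carried for
    provenance; the simple exponential ignores the readout pulse train.
    """

    S0: float = 100.0       # equilibrium signal, a.u.
    T10: float = 1.2        # pre-contrast T1, s
    r1: float = 3.6         # relaxivity, L/(mmol*s)
    TD: float = 0.12        # saturation-prep delay, s
    flip_deg: float = 20.0
    TR: float = 0.0034      # s

    def __post_init__(self) -> None:
        if min(self.S0, self.T10, self.r1, self.TR, self.flip_deg) <= 0 or self.TD < 0:
            raise ValueError("signal-model parameters must be positive (TD >= 0)")


#: Default tissue and blood signal models (blood has longer pre-contrast T1).
TISSUE_SIGNAL = SignalModelParams(T10=1.2)
BLOOD_SIGNAL = SignalModelParams(T10=1.66)

#: PET AIF shape: bolus arriving ~10 s after injection, peak ~100 kBq/mL for
#: a 400 MBq injection (nominal dilution), mild recirculation tail.
PET_AIF_DEFAULT = AifModelParams(t0=10.0, alpha=4.0, beta=3.0, amplitude=100.0,
                                 recirc_fraction=0.15, recirc_tau=40.0)
#: Gd AIF: 0.05 mmol/kg at 5 mL/s for a nominal 75 kg subject -> 3.75 mmol
#: diluted in ~0.8 L first-pass blood -> ~4.7 mmol/L peak.
MRI_AIF_DEFAULT = AifModelParams(t0=8.0, alpha=4.0, beta=1.5,
                                 amplitude=0.05 * 75.0 / 0.8,
                                 recirc_fraction=0.15, recirc_tau=25.0)


@dataclass(frozen=True)
class SubjectTruth:
    """Generating parameters for one subject."""

    subject_id: str
    F_global: dict[str, float]            # condition -> global MBF
    PS: float                             # shared across conditions
    seg_F: dict[str, np.ndarray]          # condition -> 17 segmental MBFs
    Ve: float
    vb: float
    PTF: float
    Va: float
    noise_seed: int


@dataclass(frozen=True)
class GroundTruth:
    """Full generating truth for a cohort draw."""

    config: CohortConfig
    subjects: list[SubjectTruth]
    pet_aif_params: AifModelParams = PET_AIF_DEFAULT
    mri_aif_params: AifModelParams = MRI_AIF_DEFAULT
    segment_model: SegmentModel = field(default_factory=SegmentModel)

    def subject(self, subject_id: str) -> SubjectTruth:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)


# --------------------------------------------------------------------------
# sampling
# --------------------------------------------------------------------------

def truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                     lower: float, size: int | None = None) -> np.ndarray | float:
    """Draw from N(mean, sd) truncated below at ``lower`` (degenerate sd=0 ok)."""
    if sd == 0:
        val = np.full(size, mean) if size is not None else float(mean)
        return val
    a = (lower - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size,
                               random_state=rng)


def _segment_multipliers(rng: np.random.Generator, cv: float,
                         weights: np.ndarray) -> np.ndarray:
    """Lognormal segment multipliers renormalised to weighted mean 1."""
    if cv == 0:
        return np.ones(N_SEGMENTS)
    sigma = np.sqrt(np.log1p(cv * cv))
    m = rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=N_SEGMENTS)
    return m / np.sum(weights * m)  # weighted mean exactly 1


def sample_ground_truth(config: CohortConfig) -> GroundTruth:
    """Draw per-subject global and segmental generating parameters.

    Rest and stress global MBF come from truncated normals (lower bounds
    0.3 and 1.0 mL/g/min); PS is drawn once per subject and shared between
    conditions.  Segmental flows are the global flow times lognormal
    multipliers renormalised so the volume-weighted mean reproduces the
    global value exactly.  Fully determined by ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    seg_model = SegmentModel()
    subjects = []
    noise_seeds = np.random.SeedSequence(config.seed).spawn(config.n_subjects)
    for i in range(config.n_subjects):
        F_rest = float(truncated_normal(rng, config.rest_mbf_mean,
                                        config.rest_mbf_sd, config.rest_mbf_lower))
        F_stress = float(truncated_normal(rng, config.stress_mbf_mean,
                                          config.stress_mbf_sd, config.stress_mbf_lower))
        PS = float(truncated_normal(rng, config.ps_mean, config.ps_sd, config.ps_lower))
        seg_F = {}
        for cond, Fg in (("rest", F_rest), ("stress", F_stress)):
            mult = _segment_multipliers(rng, config.segment_heterogeneity_cv,
                                        seg_model.weights)
            seg_F[cond] = Fg * mult
        subjects.append(SubjectTruth(
            subject_id=f"sub-{i + 1:02d}",
            F_global={"rest": F_rest, "stress": F_stress},
            PS=PS, seg_F=seg_F,
            Ve=config.ve, vb=config.vb, PTF=config.ptf, Va=config.va,
            noise_seed=int(noise_seeds[i].generate_state(1)[0] % (2 ** 31)),
        ))
    return GroundTruth(config=config, subjects=subjects,
                       segment_model=seg_model)


# --------------------------------------------------------------------------
# PET simulation
# --------------------------------------------------------------------------

def pet_frame_schedule(duration_s: float = 360.0) -> tuple[np.ndarray, np.ndarray]:
    """Frame midpoints and durations: 24x5 s + 12x10 s + 6x20 s for 360 s.

    Other durations scale the three blocks proportionally.
    """
    scale = duration_s / 360.0
    durations = np.concatenate([np.full(24, 5.0), np.full(12, 10.0),
                                np.full(6, 20.0)]) * scale
    ends = np.cumsum(durations)
    mids = ends - durations / 2
    return mids, durations


def _pet_noise_sd(values: np.ndarray, durations: np.ndarray,
                  scale: float) -> np.ndarray:
    return scale * np.sqrt(np.maximum(values, 0.0) / durations)


@dataclass(frozen=True)
class PetScan:
    """One subject/condition PET acquisition: AIF and 17 segment TACs."""

    aif: SampledCurve               # noisy blood-pool input
    aif_true: SampledCurve          # noise-free input
    segment_tacs: list[SampledCurve]
    segment_tacs_true: list[SampledCurve]

    @property
    def global_tac(self) -> SampledCurve:
        vals = np.mean([c.values for c in self.segment_tacs], axis=0)
        return self.segment_tacs[0].with_values(vals)


def simulate_pet_scan(truth: GroundTruth, subject: SubjectTruth,
                      condition: str, rng: np.random.Generator | None = None
                      ) -> PetScan:
    """Simulate one dynamic water-PET scan for a subject/condition.

    Segment TACs follow the single-tissue water model with the subject's
    segmental flows; per-frame Gaussian noise has SD
    ``pet_noise_scale * sqrt(activity / frame_duration)``.  The blood-pool
    AIF gets the same noise model at a quarter of the scale (large VOI).
    """
    cfg = truth.config
    if rng is None:
        rng = np.random.default_rng((subject.noise_seed,
                                     CONDITIONS.index(condition), 0))
    mids, durs = pet_frame_schedule(cfg.pet_duration_s)
    grid = np.concatenate([[0.0], mids])  # include t=0 for convolution support
    aif_true_full = gamma_variate_aif(truth.pet_aif_params, grid)
    aif_true = SampledCurve(mids, aif_true_full.values[1:], "kBq/mL", durs)

    segs_true, segs = [], []
    for F in subject.seg_F[condition]:
        params = WaterKineticParams(F=float(F), PTF=subject.PTF, Va=subject.Va)
        clean_full = water_1tcm_forward(params, aif_true_full)
        clean = SampledCurve(mids, clean_full.values[1:], "kBq/mL", durs)
        segs_true.append(clean)
        noise = rng.normal(0.0, _pet_noise_sd(clean.values, durs,
                                              cfg.pet_noise_scale))
        segs.append(clean.with_values(clean.values + noise))
    aif_noise = rng.normal(0.0, _pet_noise_sd(aif_true.values, durs,
                                              0.25 * cfg.pet_noise_scale))
    aif = aif_true.with_values(aif_true.values + aif_noise)
    return PetScan(aif=aif, aif_true=aif_true,
                   segment_tacs=segs, segment_tacs_true=segs_true)


# --------------------------------------------------------------------------
# MRI simulation
# --------------------------------------------------------------------------

def mri_signal_model(conc: np.ndarray | float,
                     params: SignalModelParams) -> np.ndarray | float:
    """Saturation-recovery signal for a Gd concentration (mmol/L).

    Strictly increasing in concentration; S(0) = S0*(1 - exp(-TD/T10)).
    """
    conc_arr = np.asarray(conc, dtype=float)
    if np.any(conc_arr < 0):
        raise KineticsError("concentration must be non-negative")
    r1_total = 1.0 / params.T10 + params.r1 * conc_arr
    out = params.S0 * -np.expm1(-params.TD * r1_total)
    return float(out) if np.isscalar(conc) else out


@dataclass(frozen=True)
class MriScan:
    """One subject/condition DCE-MRI acquisition in signal units."""

    blood_signal: SampledCurve
    blood_signal_true: SampledCurve
    segment_signals: list[SampledCurve]
    segment_signals_true: list[SampledCurve]
    blood_conc_true: SampledCurve          # generating AIF, mmol/L
    segment_conc_true: list[SampledCurve]  # generating tissue conc, mmol/L

    @property
    def global_signal(self) -> SampledCurve:
        vals = np.mean([c.values for c in self.segment_signals], axis=0)
        return self.segment_signals[0].with_values(vals)


def simulate_mri_scan(truth: GroundTruth, subject: SubjectTruth,
                      condition: str,
                      tissue_signal: SignalModelParams = TISSUE_SIGNAL,
                      blood_signal: SignalModelParams = BLOOD_SIGNAL,
                      rng: np.random.Generator | None = None) -> MriScan:
    """Simulate one saturation-recovery DCE-MRI scan, one sample per beat.

    Tissue concentration follows the PS-embedded Gd one-tissue model with
    the subject's segmental flows and shared PS; concentrations pass through
    the saturation-recovery signal equation (blood and tissue with their own
    pre-contrast T1), then Gaussian noise with SD = baseline/SNR is added.
    ``mri_snr = inf`` gives noise-free signals.
    """
    cfg = truth.config
    if rng is None:
        rng = np.random.default_rng((subject.noise_seed,
                                     CONDITIONS.index(condition), 1))
    hr = cfg.heart_rate_rest if condition == "rest" else cfg.heart_rate_stress
    rr = 60.0 / hr
    times = np.arange(cfg.mri_n_beats) * rr
    grid = times if times[0] == 0 else np.concatenate([[0.0], times])
    aif_conc_full = gamma_variate_aif(truth.mri_aif_params, grid, "mmol/L")
    take = slice(len(grid) - len(times), None)
    aif_conc = SampledCurve(times, aif_conc_full.values[take], "mmol/L")

    blood_true = SampledCurve(times, mri_signal_model(aif_conc.values,
                                                      blood_signal), "a.u.")
    noise_sd_b = (0.0 if np.isinf(cfg.mri_snr)
                  else mri_signal_model(0.0, blood_signal) / cfg.mri_snr)
    blood = blood_true.with_values(
        blood_true.values + rng.normal(0.0, noise_sd_b, size=len(times)))

    base_t = mri_signal_model(0.0, tissue_signal)
    noise_sd_t = 0.0 if np.isinf(cfg.mri_snr) else base_t / cfg.mri_snr
    segs_true, segs, concs = [], [], []
    for F in subject.seg_F[condition]:
        params = GdKineticParams(F=float(F), PS=subject.PS,
                                 Ve=subject.Ve, vb=subject.vb)
        conc_full = gd_1tcm_forward(params, aif_conc_full, mode="ps_embedded")
        conc = SampledCurve(times, conc_full.values[take], "mmol/L")
        concs.append(conc)
        clean = SampledCurve(times, mri_signal_model(conc.values,
                                                     tissue_signal), "a.u.")
        segs_true.append(clean)
        segs.append(clean.with_values(
            clean.values + rng.normal(0.0, noise_sd_t, size=len(times))))
    return MriScan(blood_signal=blood, blood_signal_true=blood_true,
                   segment_signals=segs, segment_signals_true=segs_true,
                   blood_conc_true=aif_conc, segment_conc_true=concs)


# --------------------------------------------------------------------------
# cohort container and directory IO
# --------------------------------------------------------------------------

@dataclass
class Cohort:
    """In-memory synthetic cohort: truth plus per-subject/condition scans."""

    truth: GroundTruth
    pet: dict[tuple[str, str], PetScan]
    mri: dict[tuple[str, str], MriScan]

    @property
    def config(self) -> CohortConfig:
        return self.truth.config


def simulate_cohort(config: CohortConfig,
                    tissue_signal: SignalModelParams = TISSUE_SIGNAL,
                    blood_signal: SignalModelParams = BLOOD_SIGNAL) -> Cohort:
    """Sample ground truth and simulate every subject/condition scan pair."""
    truth = sample_ground_truth(config)
    pet, mri = {}, {}
    for sub in truth.subjects:
        for cond in CONDITIONS:
            pet[(sub.subject_id, cond)] = simulate_pet_scan(truth, sub, cond)
            mri[(sub.subject_id, cond)] = simulate_mri_scan(
                truth, sub, cond, tissue_signal, blood_signal)
    return Cohort(truth=truth, pet=pet, mri=mri)


def _truth_to_json(truth: GroundTruth) -> dict:
    return {
        "pet_aif_params": vars(truth.pet_aif_params),
        "mri_aif_params": vars(truth.mri_aif_params),
        "subjects": [
            {"subject_id": s.subject_id, "F_global": s.F_global, "PS": s.PS,
             "seg_F": {c: v.tolist() for c, v in s.seg_F.items()},
             "Ve": s.Ve, "vb": s.vb, "PTF": s.PTF, "Va": s.Va,
             "noise_seed": s.noise_seed}
            for s in truth.subjects
        ],
    }


def _truth_from_json(d: dict, config: CohortConfig) -> GroundTruth:
    subs = [SubjectTruth(
        subject_id=s["subject_id"], F_global=s["F_global"], PS=s["PS"],
        seg_F={c: np.asarray(v) for c, v in s["seg_F"].items()},
        Ve=s["Ve"], vb=s["vb"], PTF=s["PTF"], Va=s["Va"],
        noise_seed=s["noise_seed"]) for s in d["subjects"]]
    return GroundTruth(config=config, subjects=subs,
                       pet_aif_params=AifModelParams(**d["pet_aif_params"]),
                       mri_aif_params=AifModelParams(**d["mri_aif_params"]))


def save_cohort(cohort: Cohort, outdir: str | Path) -> Path:
    """Write the cohort directory tree (CSV curves + JSON sidecars + truth)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.yaml").write_text(
        yaml.safe_dump(cohort.config.model_dump(), sort_keys=False))
    (outdir / "ground_truth.json").write_text(
        json.dumps(_truth_to_json(cohort.truth), indent=1))
    for (sid, cond), scan in cohort.pet.items():
        d = outdir / sid / cond
        d.mkdir(parents=True, exist_ok=True)
        scan.aif.save(d / "pet_aif")
        scan.aif_true.save(d / "pet_aif_true")
        for i, tac in enumerate(scan.segment_tacs, start=1):
            tac.save(d / f"pet_seg{i:02d}")
    for (sid, cond), scan in cohort.mri.items():
        d = outdir / sid / cond
        scan.blood_signal.save(d / "mri_blood")
        scan.blood_signal_true.save(d / "mri_blood_true")
        for i, sig in enumerate(scan.segment_signals, start=1):
            sig.save(d / f"mri_seg{i:02d}")
    return outdir


def load_cohort(indir: str | Path) -> Cohort:
    """Read back a cohort directory written by :func:`save_cohort`.

    Noise-free tissue curves and true concentration curves are not stored on
    disk; loaded scans carry the noisy measurements (and the noise-free AIF),
    which is what the fitting stages consume.
    """
    indir = Path(indir)
    config = CohortConfig(**yaml.safe_load((indir / "config.yaml").read_text()))
    truth = _truth_from_json(
        json.loads((indir / "ground_truth.json").read_text()), config)
    pet, mri = {}, {}
    for sub in truth.subjects:
        for cond in CONDITIONS:
            d = indir / sub.subject_id / cond
            segs = [SampledCurve.load(d / f"pet_seg{i:02d}")
                    for i in range(1, N_SEGMENTS + 1)]
            pet[(sub.subject_id, cond)] = PetScan(
                aif=SampledCurve.load(d / "pet_aif"),
                aif_true=SampledCurve.load(d / "pet_aif_true"),
                segment_tacs=segs, segment_tacs_true=segs)
            msegs = [SampledCurve.load(d / f"mri_seg{i:02d}")
                     for i in range(1, N_SEGMENTS + 1)]
            blood = SampledCurve.load(d / "mri_blood")
            mri[(sub.subject_id, cond)] = MriScan(
                blood_signal=blood,
                blood_signal_true=SampledCurve.load(d / "mri_blood_true"),
                segment_signals=msegs, segment_signals_true=msegs,
                blood_conc_true=blood, segment_conc_true=msegs)
    return Cohort(truth=truth, pet=pet, mri=mri)
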