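# Methods

`dualflow` models and compares two routes to absolute myocardial blood flow
(MBF, mL/g/min): dynamic ¹⁵O-water PET and gadolinium first-pass DCE-MRI,
acquired simultaneously at rest and during hyperaemia. Because no raw scans
are available, the package pairs every estimator with a synthetic-cohort
generator whose ground truth is known exactly, so each analysis stage is
testable end to end.

## Kinetic models

### ¹⁵O-water PET

Water is freely diffusible, so influx equals flow and washout is flow over
the tissue/blood partition coefficient *p*:

    C_PET(t) = PTF · F · [C_A ⊗ e^(−(F/p)t)] + Va · C_A(t)

* `F` — MBF, fitted in [0.05, 8] mL/g/min.
* `PTF` — perfusable tissue fraction (g/mL), fitted in (0, 1]; scales the
  tissue term only (partial-volume and non-perfusable tissue).
* `Va` — arterial blood-volume (spillover) fraction, fitted in [0, 0.5].
* `p` — partition coefficient, fixed at 0.91 mL/g (standard cardiac value;
  fixing it removes a scale degeneracy with PTF).

Fitting is frame-duration-weighted nonlinear least squares (trust-region
reflective, multi-start over F ∈ {0.5, 1.5, 3.0}); standard errors come from
the Gauss–Newton covariance at the optimum. An optional ±10 s, 1-s grid
search over an input-curve delay is available (`fit_delay`), off by default
since the simulator introduces no delay; dispersion is not modelled.

### Gd-DOTA DCE-MRI

Gadolinium is only partially extracted across the capillary wall. The
Renkin–Crone capillary model gives the extraction fraction
E = 1 − e^(−PS/F) and the influx constant K1 = E·F, which saturates towards
the permeability–surface area product PS as flow rises. Three analysis
routes are implemented:

1. **plain_1tcm** — extended one-tissue model with free K1, distribution
   volume Ve and blood-volume fraction vb:
   `C_T = K1·[C_A ⊗ e^(−(K1/Ve)t)] + vb·C_A`. K1 underestimates flow above
   ~1 mL/g/min.
2. **ef_corrected** — the plain K1 pushed through the Renkin–Crone inverse
   at a population PS. The first-order error amplification
   dF/dK1 = 1/(1 − (1 + PS/F)e^(−PS/F)) is reported with each corrected
   value; K1 ≥ PS is flagged unrecoverable.
3. **1tcm_ps** — direct estimation: K1 is tied to F(1 − e^(−PS/F)) and
   (F, PS, Ve, vb) are fitted together, F ∈ [0.05, 8], PS ∈ [0.5, 6], from
   a 3×2 grid of (F, PS) starts. PS can instead be pinned to a population
   value (`ps_fixed`).

**Identifiability and the capillary-transit term.** If tissue uptake were
driven directly by C_A, the PS-embedded model would depend on (F, PS) only
through K1 and the pair could never be separated from a single curve. In
`ps_embedded` mode the tissue influx is therefore driven by the well-stirred
capillary concentration

    C_cap(t) = C_A ⊗ (F/vb)·e^(−(F/vb)t)

— a unit-area transit kernel with time constant vb/F (≈ 1.5 s at stress,
≈ 5 s at rest, resolvable at one sample per heartbeat). Flow then shapes the
delivery phase while PS acts through K1, and (F, PS) are jointly
identifiable; this is the same mechanism by which flow is identified in
quantitative first-pass perfusion generally. Because the kernel preserves
tracer mass, a plain-model fit to such data still recovers K1 ≈ E·F at
moderate-to-high flows (within ~1% at stress); at the lowest flows the
dispersion adds a further downward bias to plain K1, so the
plain-vs-Renkin-Crone correspondence is exact only on data generated from
the plain model itself. The two modes coincide in the F → ∞ limit
(C_cap → C_A, K1 → PS).

**Population PS calibration.** `calibrate_population_ps` least-squares fits
the single scalar PS in K1 = F(1 − e^(−PS/F)) over paired (MRI K1, PET MBF)
observations. Pairs must span rest and stress flows; a near-constant flow
set or K1 ≈ F everywhere (extraction ≈ 1) is flagged as unidentifiable.
On simulated cohorts the calibrated population PS comes out below the mean
of the direct per-subject PS fits, because plain K1 is biased low at rest
flows — the same ordering as between the two PS figures the emulated study
reports.

### Signal model and inversion

MRI signal is modelled with the simple saturation-recovery exponential

    S(c) = S0 · (1 − e^(−TD·R1(c))),   R1(c) = 1/T10 + r1·c

ignoring the readout pulse train and T2* effects. `signal_to_concentration`
estimates S0 from the mean of the pre-contrast baseline frames (default 5,
minimum 3) and applies the strictly monotone inverse; samples at or above
the asymptote are clipped to a ceiling (default 20 mmol/L) with a warning.
Blood and myocardium use separate pre-contrast T1 values.

### Numerics

* Convolutions use the exponential recursion that is exact for piecewise-
  linear inputs on the native non-uniform grid (no FFT): correct on short,
  unevenly sampled clinical curves, and verified against a dense-grid
  trapezoidal oracle to 1e−5 relative.
* The Renkin–Crone inverse uses bracketed Brent root-finding with the
  large-F expansion F ≈ PS²/(2(PS − K1)) as the upper bracket; round-trip
  error < 1e−10.
* Time is seconds internally; flows and rate constants are stored in
  mL/g/min and converted at the model boundary.
* Fits that fail to converge are flagged, not raised. A fit is "unreliable"
  when the relative standard error of its perfusion parameter exceeds 50%
  or any parameter sits within 1% of a box bound — an objective proxy for
  the visual rejection of bad fits; unreliable regions are excluded from
  agreement statistics and counted.

## Synthetic cohort

`CohortConfig` defaults define the emulated study conditions:

| parameter | default | note |
|---|---|---|
| rest MBF | 1.02 ± 0.28, truncated below 0.3 | per-subject truncated normal |
| stress MBF | 3.13 ± 1.16, truncated below 1.0 | drawn independently of rest |
| PS | 2.91 ± 0.37, truncated below 0.5 | one draw per subject, shared rest/stress |
| segment CV | 0.10 | 17 AHA segments, lognormal multipliers renormalised so the volume-weighted mean equals the global truth exactly |
| PET | 6-min scan, 24×5 s + 12×10 s + 6×20 s frames | frame schedule is a package choice |
| PET noise | Gaussian, SD = 1.5·√(C/Δt) | ≈ 10% of the early-frame tissue peak, count-statistics proxy |
| PET AIF | gamma-variate, arrival 10 s, peak 100 kBq/mL | nominal dilution of a 400 MBq bolus |
| MRI | 65 beats, one sample per beat; HR 66 (rest) / 82 (stress) bpm | |
| MRI AIF | gamma-variate, arrival 8 s, peak ≈ 4.7 mmol/L | 0.05 mmol/kg at 75 kg in ~0.8 L first-pass volume |
| MRI noise | Gaussian, SD = baseline/SNR, SNR 20 | |
| tissue constants | Ve 0.35 mL/g, vb 0.08, PTF 0.7, Va 0.25 | conventional values, not study-reported |
| relaxometry | tissue T1 1.2 s, blood T1 1.66 s, r1 3.6 L/(mmol·s), TD 120 ms | conventional 3 T values, explicit config |

Everything is reproducible from the config seed (per-subject noise streams
are spawned from it), and a noise-free configuration reproduces the forward
models exactly, which anchors the round-trip recovery tests.

What the generator does **not** emulate: image-domain effects (motion,
ECG-gating failures, partial volume beyond PTF/Va, B1 inhomogeneity), AIF
delay/dispersion between blood pool and myocardium, dual-bolus or
dual-sequence protocols, and T2* saturation of the AIF. Passing tests
therefore demonstrate correctness of the kinetic analysis chain under its
own model assumptions, not robustness to those real-world confounds.

## Aggregation and statistics

Segments follow the AHA 17-segment model with the standard coronary
assignment (LAD {1,2,7,8,13,14,17}, RCA {3,4,9,10,15}, LCx {5,6,11,12,16});
weights default to 1/17 and are configurable. Territory and global curves
are weighted means of member-segment curves formed before fitting (PET
activity averages linearly; MRI is averaged after conversion to
concentration, since signal is nonlinear in concentration).

Agreement between modalities uses: mean difference with 1.96·SD limits of
agreement (n−1 denominator; the multiplier is fixed at 1.96, matching
symmetric printed intervals rather than a small-sample t correction),
Spearman rank correlation (average ranks on ties, two-sided p from the
t-approximation with n−2 df), and the paired t-test (df = n−1; a
zero-variance nonzero difference yields an infinite statistic rather than
an exception). Myocardial flow reserve is stress/rest per subject/region
before any averaging. Pooled rest+stress comparisons treat each condition
as an independent pair, which overstates effective sample size — a caveat
inherited by any pooled scatter of this design. Excluded (unreliable or
missing) fits never enter n and are reported as `excluded_count`.

Because MFR divides two noisy estimates, its relative error exceeds that of
stress MBF alone at equal relative noise; at noise levels where the pooled
MBF correlation between modalities is still strong (r > 0.8), the MFR
correlation degrades markedly. The test suite reproduces this mechanism.

## Problem sizes

Default test and acceptance runs use desk-scale sizes chosen as the package's
own protocol: noiseless round trips on 2–3 subject cohorts; calibration
recovery over 100 random 24-pair draws; cohort-moment recovery with 50
subjects per condition (PET) and 12 subjects × 50 cohort draws for the
PS mean; Monte-Carlo property checks with 400 replicates. The acceptance
script completes in about a minute on one CPU.

## Known limitations

* The Gd model forms are the package's canonical substitutes for the
  emulated study's unpublished supplement equations; the capillary-transit
  delivery term is this package's explicit identifiability choice.
* PET AIF is an input (simulated or measured blood-pool curve); no
  image-based AIF extraction, no right-ventricular spillover term.
* No distributed-parameter (tissue-homogeneity) models, no hematocrit
  corrections, no dispersion modelling.
* The saturation-recovery signal equation ignores the readout train; with
  measured data the conversion should be calibrated per sequence.
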