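# Methods

## The question the pipeline answers

When a dynamic contrast-enhanced (DCE) MRI series is truncated to its
first *n* post-injection frames (ATC_n), how far do pharmacokinetic
parameter estimates drift from those obtained on the full time course
(FTC)? The FTC estimate — not the generating truth — is the gold
standard: the comparison mirrors what a clinic could measure, where truth
is unavailable. Agreement is scored voxelwise per patient with Lin's
concordance correlation coefficient (CCC), Pearson r and the ROI-mean
absolute percent error, and summarised cohort-wide by a census of
patients whose CCC meets a cut-off (0.80, 0.90) at each truncation
length.

## Acquisition presets

Two fixed presets drive everything downstream:

| | multi-site ("ACRIN") | single-site |
|---|---|---|
| field / flip / TR | 1.5 T, 90°, 100 ms | 3 T, 6°, 7.02 ms |
| frame spacing dt | 15 s | 7.27 s |
| frames | 14–37 (per patient) | 66 |
| baseline frames | 0 (injection at scan start) | 8 (1 min) |
| T1 mapping | multi-TR {110, 200, 300, 1200} ms | VFA 2°–20°, B1-corrected |
| input function | none → reference-region models | population AIF |

Each cohort is 15 patients with tabulated per-patient SNR (and, for the
multi-site set, series length). Contrast relaxivity defaults to
4.5 L mmol⁻¹ s⁻¹ at 1.5 T and 3.8 at 3 T (representative literature
values for Gd chelates; neither protocol publishes one — configurable).
TE is carried but T2* decay is neglected (TE ≪ T2*).

Units: time in minutes and Ktrans in min⁻¹ throughout the kinetic layer;
TR/TE in ms and relaxation rates in s⁻¹ in the relaxometry layer, with
explicit conversion at the boundary; concentrations in mM.

## Kinetic models

The Kety–Tofts convolution and its Patlak linearisation are standard.
Two choices deserve note:

- **Patlak vp.** The AIF-based Patlak fit carries the plasma fraction vp
  as a nuisance parameter (bounds [0, 0.5]) and reports only Ktrans;
  dropping vp entirely is a stronger assumption than the model makes.
- **Reference-region forms.** With no AIF, the tissue of interest (TOI)
  is linked to a chest-wall-muscle curve C_RR of assumed kinetics
  (defaults Ktrans_RR = 0.1 min⁻¹, ve_RR = 0.1, configurable; standard
  literature values for skeletal muscle). The implementation uses the
  exact closed-form solution of the usual integral relation,

      C_TOI = R [ C_RR + (kep_RR − kep) ∫ C_RR e^{−kep(t−u)} du ],
      R = Ktrans/Ktrans_RR,

  and its no-efflux limit for the reference-region Patlak variant, which
  is linear in Ktrans and solved in closed form.

Convolutions with the exponential kernel use a first-order recursion
that is **exact for piecewise-linear inputs** (a constant-coefficient IIR
filter on uniform grids), not FFT quadrature. Accuracy on coarse grids
is then limited only by how well the sampled input represents the
continuous curve; the population AIF is therefore tabulated on an
internal 0.25 s grid aligned to the bolus onset, and forward evaluations
interpolate to the acquisition grid. Halving the internal step moves
preset-grid tissue curves by < 0.1%.

## Relaxometry

SPGR signal S = S0 sin α (1−E)/(1−E cos α), E = exp(−TR·R1). T1 fits
(VFA with a per-voxel B1 scale; multi-TR at 90°) use bounded nonlinear
least squares on the full model — the classic linearised S/tan α
regression only seeds the start, because it is biased at low SNR. Bounds
T1 ∈ [50, 5000] ms span breast tissue at both field strengths.

Dynamic inversion to R1(t) references the pre-contrast baseline mean
(first frame when the acquisition has no baseline block); frames at or
above the SPGR saturation asymptote are not invertible and are clamped
to R1 = 100 s⁻¹ and counted. Signal values *below* the R1 = 0 level
(baseline noise) floor at R1 = 0. Fitting defaults to concentration
space after this inversion; the signal-space pathway exists but the
low-flip-angle preset saturates near its asymptote, which is the main
practical argument for concentration space.

The per-patient SNR is the temporal mean over temporal SD of the first
seven frames of a non-enhancing region, averaged over voxels, with the
exact chi-distribution correction for the small-sample bias of 1/s
(without it a 7-frame estimate runs ~15% high). The noise calibration in
the simulator (σ = pre-contrast signal / SNR) is exactly the inverse of
this estimator in expectation.

## Model fitting

Bounded nonlinear least squares (trust-region reflective), bounds
Ktrans ∈ [10⁻⁵, 10] min⁻¹, ve ∈ [10⁻⁵, 1], tolerances 10⁻¹². The first
start is data-driven — an influx-only linear pre-estimate of Ktrans with
ve = 0.3 — which in practice eliminates the catastrophic local minima a
fixed start produces on short, washout-heavy windows; a deterministic
3-point multi-start engages only if the first solution fails or lands on
a bound. Patlak-family fits are linear in their parameters and solved
directly. Fitted voxels outside the strict open box
0.001 < Ktrans < 5.0, 0.001 < ve < 1.0 are eliminated; the box applies
to ve only for models that estimate it. A voxel that fails the filter at
the FTC is dropped from every comparison (the gold standard is missing);
a failure at a single ATC drops the voxel from that ATC only.

## The synthetic cohort

The generator emulates the role of (unavailable) clinical voxel maps:

- Ktrans ~ LogNormal(median 0.2 min⁻¹, geometric SD 2), truncated to the
  physiological box — typical malignant breast lesions;
- ve ~ Beta(2,2) scaled to (0.05, 0.8);
- R10 ~ Normal(0.8 s⁻¹, 0.1 s⁻¹), truncated positive (T1 ≈ 1.25 s);
- 300 voxels per tumour ROI by default (desk-scale runtime while keeping
  CCC sampling error small; the bundled tests scale this down further).

Zero-noise concentration curves come from the Kety–Tofts model driven by
a population input function (bi-Gaussian bolus plus sigmoid-gated
washout, standard parameters) injected at the preset's injection frame;
they pass through relaxivity and the SPGR equation into signal, and
Gaussian noise is added at the patient's tabulated SNR (Rician available;
above SNR ≈ 5 the difference is negligible, and only one tabulated
patient sits at SNR 6). The muscle reference curve is generated
noiselessly from the same input function. All randomness flows through
one seeded generator per patient; a manifest of seeds reproduces every
byte.

**What the generator does not emulate:** bolus-arrival delay and
dispersion heterogeneity across voxels, spatial noise correlation,
motion, partial-volume and biopsy-clip artifacts, or model mismatch (the
data-generating model is the fitted model). A green cohort test
therefore establishes correctness of the pipeline and the *intrinsic*
truncation error, not scanner-level effects.

One structural consequence is worth stating plainly: because the curves
are exactly Kety–Tofts with a shared, delay-free input, the Patlak
window estimate decreases monotonically as the window grows (washout
contamination only accumulates), so its error against the own-model FTC
estimate also falls monotonically across the truncation schedule. The
interior error minimum reported for clinical data — error falling, then
rising once the window admits washout — does not reproduce in this
synthetic world; the corresponding acceptance check documents this
honestly rather than being tuned to pass. The SKT-side structure (CCC
rising with window length; ve error exceeding Ktrans error at the
shortest truncation) does reproduce, 15/15 and 15/15 patients on the
default seeded cohort.

## Statistics

CCC uses population (1/n) moments; it is undefined for two constant
vectors with equal means and recorded as missing (excluded from the
census with a count). Percent error excludes voxels with an exactly zero
gold standard, with a count. Confidence intervals are voxelwise
t-intervals (the CI construction is not otherwise specified); the
across-patient paired test defaults to the two-sided Wilcoxon
signed-rank (n = 15 per cohort, no normality claim), with a paired
t-test available. The census counts ccc ≥ cutoff.

## Known limitations

- The reference-region convolution on a 15 s grid leaves a residual
  window-dependence for fast-washout voxels (kep ≳ 4 min⁻¹) even
  noiselessly — inherent to coarse sampling, visible as a few-percent
  worst-voxel error in the noiseless round trip.
- Cohort-level agreement numbers depend strongly on the assumed
  parameter distributions; they are structural results, not predictions
  of any specific clinical cohort's values.
- The Patlak gold standard (own-model fit to the full course) is itself
  heavily washout-biased under these kinetics, which inflates Patlak
  percent errors relative to what a truth-referenced comparison would
  show.
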