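# dcetrunc

Quantitative error analysis for **abbreviated breast DCE-MRI**.

Dynamic contrast-enhanced MRI (DCE-MRI) time courses can be shortened to
cut scan time and cost, but pharmacokinetic parameters estimated from a
truncated series differ from those estimated from the full acquisition.
`dcetrunc` quantifies that truncation error: it simulates SNR-matched
dynamic acquisitions for two clinical presets (a multi-site trial at 15 s
temporal resolution with a 90° flip angle, and a single-site community
protocol at 7.27 s with a 6° flip angle), fits kinetic models to the full
time course (FTC) and to retrospectively abbreviated time courses
(ATC_n, the first *n* post-injection frames), and measures the voxelwise
agreement between the two.

It is aimed at quantitative-imaging researchers evaluating whether an
abbreviated protocol preserves pharmacokinetic information.

## Models

Tissue contrast concentration follows the **standard Kety–Tofts (SKT)**
two-compartment model,

    Ct(t) = Ktrans ∫₀ᵗ Cp(u) · exp(−(Ktrans/ve)(t−u)) du,

with volume transfer constant *K*<sup>trans</sup> (min⁻¹) and
extravascular-extracellular volume fraction *v*<sub>e</sub>, and its
early-phase **Patlak** linearisation

    Ct(t) = Ktrans ∫₀ᵗ Cp(u) du + vp · Cp(t),

which assumes no washout. When no arterial input function (AIF) is
available, the **reference-region** variants replace *C*<sub>p</sub> with
a measured chest-wall-muscle curve of assumed kinetics
(*K*<sup>trans</sup><sub>RR</sub>, *v*<sub>e,RR</sub>). Signal and
concentration are linked through the SPGR signal equation
S = S₀ sin α (1−E)/(1−E cos α), E = exp(−TR·R1), and the linear
relaxivity relation R1 = R10 + r₁·C. Agreement between ATC and FTC
estimates is summarised by Lin's concordance correlation coefficient
(CCC), Pearson *r*, and the ROI-averaged absolute percent error, plus a
census of patients meeting a CCC cut-off at each truncation length.

## Worked example

Simulate one patient on the single-site preset (66 frames at 7.27 s,
8 baseline frames, SNR 22), fit the SKT model to the full course and to
each scheduled abbreviation, and summarise agreement:

```python
from dcetrunc import (
    PatientSpec, single_site_preset, sample_parameter_map,
    simulate_patient, run_truncation_study, build_concordance_table,
    atc_duration_min,
)

spec = PatientSpec("demo", single_site_preset(), series_length=66, snr=22.0)
truth = sample_parameter_map(80, seed=7)
patient = simulate_patient(spec, truth, seed=8)

paired = run_truncation_study(patient, "SKT")
table = build_concordance_table([paired])
for _, row in table[table.param == "ktrans"].sort_values("atc_n").iterrows():
    mins = atc_duration_min(int(row.atc_n), spec.protocol.dt)
    print(f"ATC_{int(row.atc_n):>2} ({mins:>4.2f} min): "
          f"Ktrans CCC = {row.ccc:.3f}, mean |err| = {row.mean_abs_pct_err:5.2f}%")
```

prints

```
ATC_13 (1.58 min): Ktrans CCC = 0.977, mean |err| = 11.01%
ATC_21 (2.54 min): Ktrans CCC = 0.991, mean |err| =  7.99%
ATC_29 (3.51 min): Ktrans CCC = 0.996, mean |err| =  5.75%
ATC_37 (4.48 min): Ktrans CCC = 0.998, mean |err| =  3.58%
ATC_45 (5.45 min): Ktrans CCC = 0.999, mean |err| =  2.24%
ATC_53 (6.42 min): Ktrans CCC = 1.000, mean |err| =  1.48%
```

Truncating the 8-minute series to 1.6 min leaves ~11% error in
*K*<sup>trans</sup> relative to the full-course gold standard; by 3.5 min
the CCC exceeds 0.99 and the error is under 6%. Lengthening the window
monotonically improves agreement, the study's central observation.

The same pipeline runs from the shell:

```sh
dcetrunc truncation-study --dataset ACRIN --n-voxels 100 --seed 1 --outdir out/
```

which writes a seed manifest, tidy paired estimates, the concordance
table, the CCC cut-off census (0.80 and 0.90) and a markdown report.
`dcetrunc simulate-cohort`, `fit-t1`, `fit-pk` and `report` expose the
individual stages; 4-D NIfTI dynamics with an ROI mask are accepted in
place of simulated data via `dcetrunc.load_real_series`.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the full simulated study from scratch for both presets and both
models on the 15-patient cohorts (at a reduced per-patient voxel count
for runtime), prints the end-of-schedule error summary per model, and
writes the results JSON to `--out`.

## Layout

- `src/dcetrunc/protocols.py` — acquisition presets, cohort tables
- `src/dcetrunc/relaxometry.py` — SPGR model, VFA / multi-TR T1 fits, SNR
- `src/dcetrunc/pk_models.py` — kinetic forward models, AIF, fitting, filter
- `src/dcetrunc/synthetic_cohort.py` — SNR-matched simulation
- `src/dcetrunc/truncation_study.py` — ATC schedules, truncation, paired fits
- `src/dcetrunc/concordance_stats.py` — CCC, Pearson, percent error, census
- `src/dcetrunc/pipeline.py`, `cli.py` — orchestration, I/O, CLI

See `docs/methods.md` for the modelling assumptions, defaults and known
limitations.
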