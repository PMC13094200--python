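# neuromapopt

Noninvasive estimation of the optimal mean arterial pressure (MAPopt) in
neurocritical care, from intracranial-pressure (ICP) pulse morphology, with a
full statistical-agreement layer against the invasive reference method.

## The problem

After acute brain injury, cerebral autoregulation (CA) keeps cerebral blood
flow stable only inside a patient-specific arterial-pressure range.  The
established way to find that range is invasive: the pressure-reactivity index

```
PRx = corr( MAP̄₁…MAP̄₃₀ , ICP̄₁…ICP̄₃₀ )
```

— a moving Pearson correlation between 10-second block means of mean arterial
pressure (MAP) and ICP, computed over a 5-minute window sliding in 10-second
steps.  Near-zero or negative PRx means intact CA (ABP swings are buffered);
positive PRx means pressure-passive transmission.  Plotting PRx against MAP
(grouped into 1-mmHg bins) gives a U-shaped curve whose nadir is MAPopt.

A noninvasive surrogate uses ICP pulse morphology: each cardiac beat of the
ICP waveform has sub-peaks P1 (percussion), P2 (tidal) and P3 (dicrotic), and
the amplitude ratio **P2/P1** (measured above the pulse foot) rises as
intracranial compliance falls.  Binned against MAP, P2/P1 traces its own
U-curve.  This package implements both estimators end to end and quantifies
their agreement the way method-comparison studies do:

* **repeated-measures correlation (rmcorr)** — the common within-patient
  correlation from a shared-slope ANCOVA, `r = SSxy / √(SSxx·SSyy)` on
  within-patient-centred estimates, df = N − k − 1;
* **Bland–Altman** — bias = mean(MAPopt_PRx − MAPopt_P2P1), 95% limits of
  agreement = bias ± 1.96·SD;
* the fraction of sessions agreeing within a clinical threshold (6 mmHg) and
  an OLS line of one estimate on the other.

Because bedside waveform recordings cannot be redistributed, the package
ships a ground-truthed physiological simulator (`neuromapopt.simulate`) that
plants a U-shaped MAP→ICP transmission curve, a U-shaped P2/P1 compliance
curve with a configurable nadir offset, slow waves, drift and cardiac pulse
trains — so every stage of the pipeline is testable against known truth.

## Worked example

```
neuromapopt demo --seed 0 --n-patients 10 --out demo_out
```

simulates 10 patients × 2 twenty-minute sessions at 250 Hz, analyses every
session with both estimators, and prints the cohort agreement report:

```
{
 "n_sessions": 20,
 "n_patients": 10,
 "rmcorr_r": 0.9944451115049551,
 "rmcorr_ci95": [0.9779725662326004, 0.9986078358070386],
 "rmcorr_p": 4.1209351541375943e-10,
 "rmcorr_df": 9,
 "bias_mmhg": 2.1375174799424395,
 "sd_diff_mmhg": 0.6117491747237056,
 "loa_low_mmhg": 0.9384890974839766,
 "loa_high_mmhg": 3.3365458624009023,
 "fraction_within_threshold": 1.0,
 "threshold_mmhg": 6.0,
 "regression_slope": 1.0234528048871248,
 "regression_intercept": -4.251889387077441
}
```

Reading: the within-patient correlation between the two MAPopt estimates is
0.994; the PRx-derived estimate sits on average 2.14 mmHg above the
P2/P1-derived one — recovering the +2 mmHg nadir offset planted by the
simulator — and every session pair agrees within 6 mmHg.  `demo_out/`
contains the per-session U-curve pair (`ucurves.png`), the inter-method
scatter with its regression line (`scatter.png`), the Bland–Altman plot
(`bland_altman.png`) and the P2/P1 distribution inside the optimal band.

Other entry points: `neuromapopt simulate` writes cohorts as waveform CSVs
with ground-truth sidecars, `neuromapopt analyze` runs the pipeline on such
files (or any file in the documented `time_s,abp_mmhg,icp_mmhg` dialect),
`neuromapopt agreement` consumes a pairs CSV.  Everything is also available
as a library; see `neuromapopt.pipeline.analyze_session`.

## Layout

| module | role |
|---|---|
| `simulate` | ground-truthed ABP/ICP session and cohort generator |
| `signal_io` | waveform CSV dialect, artifact rules, 15-min session filter, CPP |
| `pulse` | beat segmentation, P1/P2/P3 landmarks, per-beat and block P2/P1 |
| `indices` | block averaging, moving-window PRx / P2P1 series, reactivity cutoffs |
| `mapopt` | 1-mmHg MAP binning, polynomial U-curve fit, nadir extraction, band stats |
| `agreement` | rmcorr, Bland–Altman, threshold fraction, OLS over session pairs |
| `pipeline` / `cli` | orchestration, deterministic outputs, `neuromapopt` command |

See `docs/methods.md` for the model, parameter defaults and limitations.
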