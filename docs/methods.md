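# Methods

## The estimation procedure

Both optimal-MAP estimators share one chain:

1. **Artifact masking.** Manual waveform review is replaced by automated
   rules: physiological range (ABP 20–250 mmHg, ICP −10–100 mmHg), a 2-s
   zero-variance flatline rule, a spike rule on first differences (|Δ| > 6
   SD of the channel's difference distribution; the plain SD is used
   deliberately, so that cardiac upstrokes — the dominant legitimate
   differences — set the scale and only gross excursions are flagged), and
   1-s mask dilation.  All thresholds are configurable
   (`signal_io.ArtifactRuleSet`).
2. **Session filter.** Sessions with less than 15 min (900 s) of *unmasked*
   data are skipped with a structured record.  Using unmasked rather than
   raw duration reflects the filter's purpose (enough usable windows).
3. **Beats and morphology.** Pulse feet are detected on ABP
   (steepest-upstroke-then-local-minimum; the foot is the *last* sample near
   the pre-upstroke minimum, which is robust when diastole is flat). Each
   ICP beat is low-passed at 15 Hz (zero-phase, so peak latencies do not
   shift); landmark candidates are prominence-filtered local maxima (≥10% of
   the beat's excursion), with curvature-sign-change shoulder recovery when
   fewer than two maxima exist.  P1 is searched in the first 40% of the
   beat, P2 in 20–70%.  Amplitudes are read off the raw waveform above the
   beat's foot-to-foot linear baseline: the detrending removes the tilt
   that slow pressure drift would otherwise impose on P2 relative to P1.
   Beats are flagged `ok` / `merged_peaks` / `low_amplitude` / `rejected`;
   a beat whose P1 carries less than 30% of the excursion is treated as a
   misdetection.  Block means (10 s) use `ok` beats and need ≥3 of them.
4. **Index series.** 10-s block means of MAP (true block mean of the ABP
   waveform) and ICP feed a moving Pearson correlation (PRx) on a 5-min
   window stepping every 10 s (30 blocks per window, ≥24 valid required, a
   10⁻⁶ mmHg² variance floor avoids 0/0).  The P2/P1 series supports two
   modes: *direct* (window value = mean of the window's P2/P1 blocks; the
   default, matching how the ratio is binned against MAP) and *correlation*
   (P2/P1 vs MAP, a PRx-like surrogate).  The sources describing this
   method are ambiguous about which variant produced the published curves;
   both are provided and the default is the direct reading.
5. **Binning and nadir.** Each valid window's value goes to the 1-mmHg bin
   `[floor(MAP), floor(MAP)+1)` of its window-mean MAP.  A least-squares
   polynomial (default degree 2; 2–4 supported, higher degrees use a
   0.01-mmHg grid minimum) is fitted to bin means weighted by bin counts
   (means/medians/raw selectable — the fitted statistic is not pinned down
   by the published description, so it is a config option).  Quality gates:
   ≥5 surviving bins, ≥8 mmHg span, ≥3 windows per bin.  A nadir is reported
   only for an interior strict minimum with positive curvature
   (`valid_u_shape`); boundary minima and concave fits withhold it.
6. **Agreement.** rmcorr is computed in-package from the shared-slope ANCOVA
   decomposition (within-patient centring; r = SSxy/√(SSxx·SSyy);
   df = N − k − 1; t-based p; Fisher-z CI with SE 1/√(df−1), the
   repeated-measures analogue of the 1/√(n−3) rule).  With a single patient
   it reduces exactly to that patient's Pearson correlation.  Bland–Altman
   is the classic unadjusted form on PRx-minus-P2/P1 differences — sessions
   repeat within patients, but the classic form is what method-comparison
   reports of this design use; a variance-components variant is out of
   scope.  Threshold comparisons use a closed boundary (|diff| ≤ 6 counts
   as agreeing).

## The simulator

The generator plants statistical structure, not mechanism (no
Windkessel/Monro–Kellie differential equations, no respiration, no sensor
transfer functions):

* **MAP(t)** = baseline + slow wave + trend + AR(1) drift, clipped to
  [40, 160] mmHg.  The slow wave (sinusoid, 12 mmHg amplitude, 60 s period)
  provides the within-window variation that correlation indices need.  The
  trend is a session-long linear ramp from −10 to +10 mmHg (random
  direction): a ramp, because the 5-min window mean of a linear trend equals
  the trend at the window centre, so MAP-bin coverage is obtained without
  distorting the binning.  (A session-scale sinusoid fails here: it sweeps
  several mmHg *within* each window, so windows never sit at a MAP level;
  this was the decisive argument for the ramp.)  The AR(1) drift (SD 2 mmHg,
  120 s time constant) roughens the coverage.
* **ICP slow component** = icp_baseline + τ(MAP)·(MAP − baseline) + AR(1),
  with the transmission coefficient
  `τ(m) = clip(floor + curvature·(m − MAPopt_PRx)², ceiling)`.
  Defaults: floor −0.2 (active counter-regulation at the nadir), curvature
  0.001 mmHg⁻² — giving a trough half-width √(0.2/0.001) ≈ 14 mmHg, wider
  than the slow-wave excursion, which is required for the windowed
  correlation to change sign across MAP; a narrower trough makes every
  window straddle the whole curve — and ceiling 0.8, because transmission
  coefficients above ~1 are unphysical and would push ICP outside its
  plausible range.
* **Pulse trains.** Both channels carry per-beat templates of three Gaussian
  bumps (P1/P2/P3 at 0.09/0.21/0.33 s, widths 30–35 ms, ≤¼ of the landmark
  spacing so template maxima equal the planted amplitudes within 1%).  The
  ICP P2 amplitude encodes the planted per-beat ratio
  `clip(p2p1_floor + p2p1_curvature·(MAP_beat − MAPopt_P2P1)², 0.05, ∞)`
  (floor 0.9, curvature 0.002 mmHg⁻² — the published literature gives no
  quantitative P2/P1-vs-MAP model; the parabola is this package's invention
  consistent with the U-shape premise, with levels chosen so the optimal
  band sits near ratio ~1 and the cohort mean near ~1.2).  Each bump's
  beat-mean is subtracted so block averages track the slow components.
  White measurement noise: 1.0 mmHg (ABP), 0.5 mmHg (ICP).  Beat-length
  jitter (±3%) exists for stress-testing and is off by default.
* **Nadir geometry.** `nadir_offset = MAPopt_PRx − MAPopt_P2P1` (default
  +2 mmHg), oriented so that the Bland–Altman difference (PRx-method minus
  P2/P1-method) recovers a positive bias.
* **Cohorts.** Per patient the PRx nadir is uniform over 75–105 mmHg
  (across-patient SD ≈ 8.7 mmHg); each session jitters it by N(0, 5 mmHg) —
  the autoregulatory set point moves between monitoring days, and without
  within-patient variance the repeated-measures correlation would be
  degenerate.  Each session's MAP baseline is pinned to its planted nadir
  so the recorded MAP excursion always covers it.  Session seeds derive
  from `SeedSequence([root_seed, patient_index, session_index])`.

### What the simulator does *not* emulate

Real waveforms carry respiration, posture and suction artifacts, sensor
drift, non-Gaussian beat-to-beat morphology variation, ICP plateau waves,
and MAP trajectories that need not cover the autoregulatory range at all.
Passing recovery tests therefore demonstrates that the *pipeline* is correct
and unbiased under the planted model — not that the indices are clinically
valid, nor that real sessions always yield a U-curve (on real data the
boundary/non-convex validity flags are expected to fire much more often).

## Problem sizes and numerical choices

Tests and the acceptance script use 20-minute sessions at 250 Hz (300 000
samples per channel), 50-session recovery cohorts and a 50-patient × 2
agreement cohort — large enough that every window/bin gate is exercised,
small enough that the whole suite runs in about a minute of simulation time.
Tolerances: moving-correlation oracle equivalence 10⁻¹⁰; rmcorr vs the
design-matrix ANCOVA oracle 10⁻⁸; exact-quadratic coefficient recovery
10⁻⁸; nadir recovery RMSE ≤ 2.5 mmHg; per-beat morphology ±0.02 on
noise-free sessions.  Degenerate inputs (flat windows, empty bands,
single-pair cohorts, all-masked beats) return flagged/missing results, never
exceptions, except where a statistic is mathematically undefined (zero
within-patient variance, zero regressor variance), which raises.

Known numerical quirk: the zero-phase low-pass (`sosfiltfilt`) is not
exactly time-symmetric at segment edges, so ratio identities that are exact
in infinite precision (equal-amplitude peaks → ratio 1) hold to ~10⁻³
through the smoothing path; scale and shift invariance of the ratio are
exact because smoothing is linear.
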