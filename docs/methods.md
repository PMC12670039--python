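# Methods

`alphasep` re-implements, as a tested reusable pipeline, an analysis that
separates oscillatory from aperiodic alpha-band EEG activity, quantifies how
each encodes the locus of covert visuospatial attention, and contrasts
rhythmic versus arrhythmic TMS conditions. Because the analysis is validated
on synthetic data with known ground truth, this note describes both the
analysis model and the generative model, and is explicit about what passing
tests do and do not establish about real EEG.

## Signal model

Posterior EEG during an attention delay period is modelled as the sum of

* **aperiodic activity** — a broadband, non-rhythmic component whose
  one-sided power spectral density follows a power law,
  `S(f) = 10^c · f^(−β)`, with exponent β (slope −β in log10–log10
  coordinates) and offset `c` (log10 power at 1 Hz);
* **oscillatory alpha** — a narrowband 8–13 Hz rhythm riding on that
  background;
* measurement noise (white).

Directing attention to one hemifield modulates posterior alpha amplitude:
a decrease contralateral and an increase ipsilateral to the attended side.
The same lateralisation pattern can, in principle, affect the aperiodic
offset, and the pipeline treats the two as separable questions.

## IRASA decomposition

Each trial × channel window is decomposed with irregular-resampling
auto-spectral analysis:

1. The **mixed spectrum** is a single Hann-tapered periodogram of the whole
   analysis window, zero-padded to at least 2 s equivalent so the 1 Hz
   output grid (1–35 Hz) remains meaningful for 600 ms windows, and
   linearly interpolated onto that grid. The 1–2 Hz and 31–35 Hz extremes
   are buffer zones: finite-window edge effects concentrate there, and the
   quantities of interest (alpha 8–13 Hz, broadband and fit range 3–30 Hz)
   deliberately avoid them.
2. For each resampling factor `h ∈ {1.10, 1.15, …, 1.90}` the signal is
   resampled by `h` and `1/h` (polyphase anti-aliased resampling; `h`
   approximated by a rational fraction with denominator ≤ 100). Evaluating
   both resampled signals at the nominal sampling rate rescales the
   frequency axis by `1/h` and `h`, so oscillatory peaks are displaced in
   opposite directions while a power law is an exact fixed point of the
   pair's geometric mean.
3. The **aperiodic spectrum** is the median across the 17 factors of the
   pairwise geometric means, multiplied by a small-sample debiasing factor
   `4/π` (below). The **oscillatory spectrum** is mixed − aperiodic, never
   floored: off-peak values are legitimately negative.

Six per-trial, per-channel features follow: oscillatory, aperiodic and
mixed alpha power (inclusive band means over 8–13 Hz, so
`mix = osc + ap` holds exactly), aperiodic broadband power (3–30 Hz), and
the slope and intercept of an ordinary least-squares line through the
aperiodic spectrum in log10–log10 coordinates. The fit range defaults to
3–30 Hz, matching the broadband definition; it is configurable because the
choice is not uniquely determined by the analysis being reproduced.
Decomposition is per trial (decoding needs per-trial features), not per
condition average.

### The 4/π debiasing factor

A single-taper periodogram ordinate is approximately `S(f)·χ²₂/2`
distributed. The geometric mean of an independent pair therefore
*underestimates* `√(S₁S₂)` by `E[√(X₁X₂)] = Γ(3/2)² = π/4 ≈ 0.785`. Without
correction this appears as a spurious positive "oscillatory" residual
proportional to `S(f)` at every frequency — large at low frequencies where
the power law is high. The aperiodic estimate is multiplied by `4/π`
to remove this bias. The median across factors is an order statistic of
partially correlated values and leaves a smaller (≈10% mid-band) residual
bias that no constant can remove; it cancels in paired or condition
contrasts and does not affect the fitted slope (it is multiplicative), but
it sets a floor on how exactly the oscillatory residual of a pure power law
vanishes in absolute terms.

A related inherent artefact: a strong narrowband peak at `f₀` leaks into
the aperiodic estimate at its resampled images (`f₀/h`, `f₀·h`) through the
square root of the pair product. In frequency-resolved condition contrasts
this shows up as negative side lobes flanking a genuine enhancement; the
enhancement itself stays localised at `f₀ ± 1` Hz.

## Preprocessing

* **ERP removal**: the across-trial mean time course is subtracted per
  condition and channel before spectral analysis, isolating induced
  activity. Subtracting a mean of `n` trials necessarily removes a `1/n`
  share of induced power as well — negligible at realistic trial counts.
* **Window selection**: half-open `[start, end)` with 0-based indexing.
* **Standardisation**: z-scoring uses the population denominator (`n`) and
  is computed once across *all* pseudo-trials before cross-validation —
  faithful to the procedure being reproduced, despite the mild train/test
  leakage it implies. A fold-wise alternative was considered and rejected
  as a deviation; null calibration (below) confirms the leakage does not
  move decoding off chance at these sample sizes.

## Decoding

Per condition, trials are randomly partitioned into groups of 4 and
averaged into pseudo-trials (leftovers dropped); the per-channel values of
one signal type form the feature vector (signals are never mixed in one
decoder). Classification is a linear SVM (one-vs-rest, C = 1; the
deterministic primal solver) under stratified fivefold cross-validation,
scored by balanced accuracy — macro-averaged per-class recall, which for
two classes is the mean of sensitivity and specificity. The whole procedure
is repeated 25 times with fresh groupings (repetition rng derived
deterministically from the seed and repetition index) and averaged. The
regularisation constant and multiclass scheme are declared defaults, not
reconstructions: only "linear SVM" is fixed by the source analysis.

## Lateralisation

For signal S averaged over trials of a cue condition and over a posterior
electrode group,

    MI_hemi = (S_hemi^attL − S_hemi^attR) / (½ (S_hemi^attL + S_hemi^attR))
    MI = MI_left − MI_right

Positive combined MI means contralateral decrease. S enters the formula
after trial averaging (subject-level MI); raw delay-period features are
used — baseline correction is applied only to topographic difference maps,
where it is a linear subtraction in power units. For eight-location
designs, MI uses only the 3 and 9 o'clock conditions. Default electrode
groups are O1/P3/P7/PO3/PO7 (left) and O2/P4/P8/PO4/PO8 (right); the TMS
contrast averages over a fixed 15-electrode right posterior stimulation
cluster and subtracts arrhythmic from rhythmic condition means.

## Statistics

One-sample t-tests (one-tailed for decoding against chance, two-tailed for
MI and TMS effects), Benjamini–Hochberg step-up FDR within each family,
Holm step-down adjustment for post hoc comparisons, one-way
repeated-measures ANOVA (`F = MS_cond / MS_cond×subj`; no sphericity
correction, as none is specified by the source analysis), and partial
Spearman correlation: rank-transform (average ranks), residualise on the
covariate — a categorical covariate such as dataset identity is one-hot
encoded with one level dropped — and correlate residuals, with p from the
t approximation on `n − 2 − c` degrees of freedom.

## Synthetic data generator

The generator is first-class, tested code: every downstream stage is
validated against its known ground truth.

* Aperiodic background by Fourier-amplitude shaping of complex Gaussian
  noise (`E|X_k|² = S(f_k)·f_s·n/2`, DC = 0), so the expected periodogram
  equals the analytic target exactly — testable without calibration runs.
* Alpha sinusoid with a uniformly random phase per trial (induced, not
  evoked, so ERP removal leaves it intact), coherent across channels
  within a trial.
* Cosine spatial tuning: a cue at clock angle θ (0° = 3 o'clock) carries
  horizontal coordinate `cos θ`; posterior channels with hemisphere sign
  `h = ∓1` scale alpha amplitude by `1 + d_osc·h·cos θ` and background
  power by `1 + d_ap·h·cos θ`. The 3 and 9 o'clock cues reproduce the pure
  left/right case; vertical cues are unlateralised; midline and
  non-posterior channels are unmodulated. This is the minimal model
  consistent with a horizontal modulation index.
* Optional common evoked component (a Gaussian-windowed 5 Hz wavelet at
  150 ms) to exercise ERP removal, and additive white noise.

Defaults (chosen once as realistic study conditions): β = 1.5 and offset
`c` = 1.0 — a typical posterior resting exponent with the alpha peak about
twice the background at 10 Hz given amplitude 2.0; noise sd 1.0 (noise
floor an order of magnitude below the background at 30 Hz); 8 conditions ×
40 trials; 30 channels comprising the full stimulation cluster, 13 left
mirrors and 2 midline electrodes; 600 ms windows at 250 Hz; oscillatory
modulation depth 0.3; aperiodic modulation depth 0.1 (a free synthetic
knob — the generative relationship between condition and aperiodic offset
in real data is unknown); evoked amplitude 0 unless a test enables it.

What the generator does **not** emulate: volume conduction and realistic
head geometry, TMS pulse artefacts, eye movements, non-stationary or
subject-specific alpha frequency, 1/f knees, or correlated sensor noise.
Passing tests therefore establish that the *pipeline* recovers what it is
supposed to recover under the assumed signal model — not that real EEG
satisfies that model.

## Calibration and problem sizes

The package's calibration checks run at desk scale, chosen once:

* Null decoding: 20 synthetic subjects per configuration (8-way: 40
  trials/location; 2-way: 80 trials/side; 30 channels, 600 ms @ 250 Hz);
  mean balanced accuracy must sit within ±0.01 of 1/8 or 1/2. The 2-way
  configuration has markedly higher per-subject dispersion than the 8-way
  one — two-class spurious separability of a few dozen pseudo-trials in 30
  dimensions does not benefit from multi-class recall averaging — so a
  20-subject mean in that configuration carries a standard error larger
  than the ±0.01 band it is checked against, and the check can fail by
  sampling alone for a perfectly calibrated decoder. Fold-wise
  standardisation (the leakage-free control) reproduces the full-set
  result on matched data, so the mandated pre-split z-scoring is not a
  bias source at these sizes.
* Exponent recovery: β ∈ {0.5, 1, 1.5, 2, 2.5}, 20 seeds each, 2 s
  windows; mean fitted slope within ±0.15 of −β (observed bias ≈ +0.04).
* Oscillation/aperiodic separation: 100 paired seeds, 40 trials of 2 s,
  unit 10 Hz sinusoid on a β = 1.5, offset 1.0 background; the
  trial-averaged oscillatory argmax (within 3–30 Hz) falls in 9–11 Hz and
  the aperiodic alpha band mean moves by < 10% on average.
* MI recovery and decoding sensitivity use a compact 12-channel posterior
  montage (both MI groups plus two midline channels) to keep runtimes in
  minutes; effect sizes are the generator defaults, not tuned values.

## Known limitations

* The aperiodic estimate from a single short window carries the ~10%
  order-statistic bias described above; absolute (unpaired) oscillatory
  residuals inherit it.
* Very short windows (600 ms) smear narrowband peaks over ±3 Hz, so the
  separation of a weak oscillation from the background is intrinsically
  noisy at the single-trial level; trial averaging is what makes the
  spectra interpretable.
* The full-set standardisation reproduces the source procedure's mild
  leakage by design; fold-wise standardisation is available
  (`zscore_features` applied per fold externally) but off by default.
* No vendor EEG readers: epochs enter via the documented HDF5 schema.
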