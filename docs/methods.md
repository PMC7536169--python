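# Methods

This note records the models, parameter choices and numerical decisions
behind `timbretest`, in the order of the pipeline.

## Stimulus model

A stimulus tone is the sum of eight equal-amplitude sine partials: the
fundamental f0 plus overtones at integer multiples 2–8. The partials with
base multiples 3, 4, 5 and 6 are the ones the flux dimension detunes.
Equal partial amplitudes are a deliberate simplification: the test's
dimensions are carried by timing (envelope), detuning (flux) and filtering
(centroid), so a flat source spectrum keeps the three manipulations
independent at the source.

### Link functions

All three dimensions are driven by a dimensionless slider s ∈ [0, 100].

- **Envelope.** Attack and decay each follow an exponential in the slider,
  `A·1.03^s + B`, with (A, B) calibrated so the curve passes exactly
  through the endpoints: attack 5 ms → 291 ms, decay 50 ms → 5 ms. A pure
  power law `c·1.03^s` cannot hit both printed endpoints (1.03¹⁰⁰ ≠ 291/5),
  so the affine-calibrated form keeps the stated growth base *and* the
  stated range; it gives attack(50) ≈ 58.1 ms. Attack and decay are
  inversely coupled so that overall tone duration varies little and
  listeners cannot judge purely by length.
- **Spectral flux.** Each detuned partial interpolates linearly between its
  harmonic ratio at s = 0 (3.0, 4.0, 5.0, 6.0) and its maximally detuned
  ratio at s = 100 (3.3, 3.7, 5.2, 5.8). Two ratios rise and two fall so
  the global pitch centre stays put. The scalar summary β — the mean
  absolute deviation of the four ratios from their integer bases — is then
  exactly 0.25·(s/100).
- **Spectral centroid.** The band-pass centre follows
  `600 + 400·(s/100)²` Hz. The square law is adopted because it places the
  700 Hz reference at slider 50 (a logarithmic map would put ≈775 Hz
  there); Q is fixed at 1.8.

### Rendering

- The band-pass stage is a second-order resonator (`scipy.signal.iirpeak`)
  with −3 dB bandwidth = centre/Q — the simplest filter realizing a
  constant-Q specification. It is applied before the amplitude envelope so
  the filter's own onset transient cannot lengthen very short attacks.
- The envelope is linear in amplitude: a 0→peak attack ramp, full-level
  sustain, and a peak→0 decay ramp. If attack + decay ever exceed the tone
  duration both ramps are compressed proportionally.
- Tone duration defaults to 700 ms (configurable); this comfortably holds
  the longest attack (291 ms) plus the longest decay (50 ms).
- Trial audio repeats the tone three times. The 800 ms repetition interval
  is implemented as a silent gap from tone offset to next onset, so long
  tones can never overlap; an onset-to-onset mode is available.
- The five test pitches are G3 and A#4 (the named range endpoints, 12-TET
  with A4 = 440 Hz) plus interior notes C4, E4, G4 — configurable.
- Output is peak-normalized mono at 44.1 kHz; WAV files are 16-bit PCM.

## Acoustic measurement

- **Macro envelope.** The magnitude of the analytic signal ripples at the
  waveform's crest rate, so it is passed through a *causal* (past-aligned)
  maximum filter before smoothing. A causal window does not delay a rising
  ramp, so threshold crossings are preserved; with the window at one
  fundamental period the sustain of a harmonic tone comes out flat. The
  last 5 ms of the signal are cosine-tapered before the Hilbert transform
  to suppress the Gibbs overshoot an abrupt truncation would cause.
- **Attack time** is read between the 1 % and 99 % crossings of the peak
  macro-envelope. Verified against constructed linear ramps (100 ms ramp
  measures within ±5 ms) and against the envelope link on rendered tones
  (within 10 % for attacks ≥ 20 ms). Below ~10 ms the filter's onset
  smearing dominates and only an upper bound is meaningful.
- **Spectral measurements** use the sustain segment (45–90 % of the tone,
  past the longest attack), a flat-top window, and an FFT zero-padded to
  at least 2¹⁵ points (< 1.4 Hz bin spacing at 44.1 kHz).
- **Envelope fluctuation** (std/mean of the sustain macro-envelope) is a
  qualitative roughness proxy only: it grows with the flux slider because
  detuned partials beat, but it is not a calibrated psychoacoustic
  roughness model.

## Protocol

Five **parameter sets** supply the trial targets. Slider targets
{10, 30, 50, 70, 90} are assigned to the three dimensions and the five
pitches by a cyclic Latin square, so each dimension (and the pitch) runs
through all five levels across the sets. The actual composition is fully
configurable. Each block presents all five sets once as match trials and
twice as memory trials, in a seed-permuted order; one training trial per
block is never scored. Full version: 45 scored items. Short version: match
trials only, minus the envelope and flux items whose target coincides with
the default slider position (50) — those items can be "answered" without
touching the slider — leaving 13 items (4 envelope, 4 flux, 5 centroid).
The centroid set whose target is 50 is retained to keep five centroid
items.

The default slider position is 50. An unmoved slider is a real,
scorable response (distance |target − 50|), never a missing value.

## Scoring

Per item, distances are cut at the type-1 (inverse empirical CDF)
quantiles j/6 into six equal-frequency bins; rank-based cuts avoid
interpolation artifacts. A distance equal to a boundary falls into the
better bin — deterministic and consistently favourable to the respondent.
When a heap of identical distances (typically responses clipped at a
slider rail, or unmoved sliders) pulls two quantiles onto the same value,
the later cut is shifted to the next distinct observed value: boundaries
stay strictly increasing, there are always exactly six bins, and
occupancies are equal up to the tie count. Items with more than 30 %
unmoved responses (strict inequality) are excluded before binning.
Boundaries are persisted as JSON, tagged with the session version, so
retest data is scored against the original sample's boundaries; a version
mismatch is an error.

## Psychometrics

- **α** is the standard covariance form; **ω-total** comes from a
  single-common-factor minres solution, `(Σλ)² / ((Σλ)² + Σψ)` — the
  instrument's final model is one factor, so no bifactor generalization is
  offered.
- **ICC** is ICC(A,1): single-measure, two-way random effects, absolute
  agreement, computed from the ANOVA mean squares and reported with
  between-subject df = n − 1; average-measures is available behind a flag.
- **Minres EFA** minimizes the off-diagonal squared residuals of
  R − ΛΛᵀ over the uniquenesses ψ (L-BFGS-B, bounds [10⁻³, 1], started at
  1 − SMC); given ψ, Λ is the scaled top eigenvectors of R − diag(ψ).
  Uniquenesses hitting the lower bound raise a Heywood warning. Fit
  indices use the normal-theory discrepancy
  F = ln|Σ̂| − ln|R| + tr(RΣ̂⁻¹) − p with
  χ² = (n − 1 − (2p+5)/6 − 2k/3)·F, df = ((p−k)² − (p+k))/2,
  RMSEA = √(max(χ²−df, 0)/(df·(n−1))), BIC = χ² − df·ln n.
- **Parallel analysis** resamples 100 uncorrelated standard-normal data
  sets of matching shape and uses the 95th-percentile eigenvalue bar
  (seeded).
- **BH correction** is applied once per correlation table (one family per
  report). Constant columns, whose rank correlation is undefined, are
  dropped from the family and flagged.

## Respondent simulator

The simulator exists so that scoring and psychometrics can be exercised
end-to-end; it is a deliberately simple latent-trait model, not a fitted
cognitive model. Each respondent draws ability a ~ N(0, 1); on a trial of
dimension d the final slider is target + N(0, σ_d·e^(−κa)), clipped to
[0, 100], with the sd multiplied by m on memory trials; with probability
p_stick the slider stays at the default. Defaults: n = 95 respondents,
σ_d = 15 slider points for all three dimensions, κ = 1,
m = 1.5, p_stick = 0.05. The multiplicative e^(−κa) keeps the sd positive
and makes score monotone in ability; σ = 15 and m = 1.5 put simulated mean
absolute distances in the 15–20 point range with a clear match/memory gap,
the magnitudes a realistic cohort of mixed musical background produces on
this kind of task.

What the simulator does **not** emulate: learning or fatigue across
trials, per-item difficulty beyond target placement, response rounding,
deliberate rail-seeking strategies, or any perceptual nonlinearity of the
slider-to-acoustics mapping (noise acts on the slider scale, where
responses and scores live). Passing pipeline tests therefore shows the
*machinery* is correct under a known generative process — not that human
data will show the same reliability or factor structure. One real
consequence of the model: the heavy low-ability tail (σ·e^(−κa) is
lognormal) clips many responses at the slider rails, producing the tied
distances the binning tie rule exists to handle.

## Problem sizes and determinism

The test suite uses: 95-respondent cohorts for end-to-end recovery and
factor structure; 25-respondent paired cohorts (50 replicates) plus one
3000-respondent oracle cohort for the test–retest variance-ratio check;
n = 5000 samples for factor-loading recovery; 200 replicates for the
closed-form ICC check; dense 401-point grids for link monotonicity. All
stochastic tests run under fixed seeds; audio rendering is fully
deterministic.

## Known limitations

- The five parameter sets and per-item bin boundaries of the published
  instrument are not distributed with it; defaults here are principled
  stand-ins and both are configurable/persistable.
- The attack measurement is tolerance-based by design; the band-pass stage
  reshapes onsets, so exact equality with the link value is not expected.
- Minres fit indices (RMSEA/BIC) follow the normal-theory approximations
  given above; other software may use slightly different variants.
- Loudness is not normalized across pitches, and no headphone/level
  calibration is modelled.
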