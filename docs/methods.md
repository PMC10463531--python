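# Methods

`pactacs` reimplements, as a tested pipeline, the computational content
of a cross-frequency tACS experiment: a tailored stimulation current in
which short gamma bursts ride on an alpha carrier, a
dynamic-visual-acuity (DVA) behavioral task, an occipital-EEG feature
pipeline (inter-trial phase coherence, spectral power, alpha-gamma
phase-amplitude coupling), and the nonparametric statistical plan that
ties them together. Because no subject-level data are publicly
deposited, every analysis stage is exercised on synthetic recordings
whose generator encodes the signal structure the analysis assumes.
This note documents the models, the defaults and why they were chosen,
the numerical decisions, and what the synthetic validation does and
does not show.

## Stimulation waveform

The verum current is, in closed form over time `t`,

    I(t) = s * env(t) * [ (A_a/2) sin(2*pi*f_a*t) + burst(phi_a(t)) ]

with `f_a = 10` Hz, alpha component peak-to-peak `A_a = 1.8` mA, and one
Hann-tapered gamma burst per alpha cycle: `n = 3` cycles of `f_g = 80`
Hz with untapered peak-to-peak `A_g = 1.2` mA (37.5 ms per burst). The
burst is centred on the midpoint of the entrainment interval — under
the sine phase convention, `[pi/16, 15*pi/16]` for the peak condition
(midpoint `pi/2`, the carrier maximum) and `[17*pi/16, 31*pi/16]` for
the trough condition (midpoint `3*pi/2`, the minimum). A narrower
alternative interval set (`interval_source="methods"`: `[pi/8, 3*pi/8]`
peak, `[5*pi/8, 7*pi/8]` trough) is selectable for sensitivity
analysis, but its pi/4 span (12.5 ms at 10 Hz) cannot contain the
default 37.5 ms burst, so constructing those parameters raises unless
explicitly overridden.

The stated component amplitudes (1.8 + 1.2 mA) do not add up to the
stated composite amplitude, so the composite session plateau is
rescaled by a single factor `s` to exactly 3.0 mA peak-to-peak,
preserving the 1.8:1.2 component ratio. The rescale factor is computed
on the session's own sampled plateau, making the plateau peak-to-peak
exact at any sampling rate. `env(t)` is a linear trapezoid: 30 s
ramp-up, 1200 s plateau, 30 s ramp-down. Sham is a pure 10 Hz carrier
under a triangular envelope (30 s up, 30 s down) that reaches 3.0 mA
peak-to-peak at its apex, then zero current for the remainder of the
session; the carrier is cosine-phased about the apex so the envelope
turns around exactly at a current peak.

Numerical choices worth noting:

* The session is evaluated from the continuous-time closed form rather
  than by tiling a sampled one-cycle template: one alpha period is
  204.8 samples at 2,048 Hz, so discrete tiling would accumulate phase
  error. `compose_cycle` still exposes a one-period sampled tile.
* The Hann taper was chosen because an untapered burst splice would put
  broadband splatter into the 70-90 Hz verification band and a
  discontinuity at the splice points; any similar taper would do.
* `verify_entrainment` is the independent check on the composition: it
  band-passes the plateau at 7-13 Hz (phase, sine convention) and 70-90
  Hz (analytic-signal envelope) and reports the envelope-weighted
  circular mean phase and mean resultant length. Construction is deemed
  correct when the preferred phase is within pi/8 of the interval
  midpoint; measured concentration is ~0.46 at default amplitudes.

## DVA task

One session is the full factorial of speed (200-700 deg/s, step 100),
movement direction (2), gap direction (4), and optotype size (3, 4, 5
MAR) — 144 trials, shuffled per session by seed; inter-stimulus
intervals are uniform on 1.5-2.5 s. The factorial is enumerated and
shuffled without replacement: the trial count equals the number of
factor combinations, which fixes that reading. Scoring produces overall
and per-size accuracies; chance level in the 4-AFC design is 25%. A
subject's size-specific analyses are excluded when that size's accuracy
is below chance in all three sessions of any single condition.
Rendering parameters (240 Hz display, 70 cm distance, +/-10 deg sweep)
are schedule metadata only; nothing is drawn.

## Synthetic data generator

The generator is the test bed for everything downstream, so its
defaults are the assumed study conditions, not free dials.

EEG (Oz, 2,048 Hz) is a sum of: 1/f-shaped background (white noise
shaped in the frequency domain, slope 1, 8 uV RMS), an alpha rhythm
`A sin(phi_a(t))` with `A = 10` uV and a Wiener-process phase
perturbation (5 rad^2/s) on top of the 10 Hz drift, a gamma sinusoid
whose envelope follows the alpha phase,
`g * (1 + kappa*cos(phi_a - phi_0)) / (1 + kappa)` with `g = 2` uV,
coupling depth `kappa = 0.6` and preferred phase `phi_0 = 3*pi/2`
(gamma strongest at alpha troughs, the coupling structure the analysis
is designed to detect), and 2 uV white noise. The amplitude-modulation
construction is the standard benchmark for Tort-style PAC estimators.
Because the alpha phase random-walks between trials, stimulus onsets
are not locked to any alpha phase — by construction, pre-stimulus ITPC
carries no alignment, which is what the ITPC analysis is meant to
verify. Amplitudes follow typical occipital resting EEG (alpha tens of
uV, high gamma a few uV); total background stays far below the 100 uV
rejection threshold so that clean trials are never rejected.

Artifacts are 50 ms Gaussian transients of 150 uV peak added inside the
pre-stimulus window of a seeded random trial subset; at that width they
pass the 1 Hz high-pass essentially unattenuated, so injected trials
always exceed the threshold and clean ones never do — giving exact
ground truth for the rejection stage. EOG is slow baseline wander plus
optional step-like saccades (10-50 ms sigmoid rise, 80-200 uV,
alternating sign, Poisson times) for detector recall/specificity
fixtures.

Behavior: `P(correct) = 0.25 + 0.75*logistic(a_size - b*(speed-200)/100
+ delta + u_subj)`, with size intercepts (0.8, 1.7, 2.5) and speed
slope 0.35 giving size-graded accuracies around 0.45/0.65/0.8 at
mid-range speeds, a per-subject shift `u_subj ~ N(0, 0.4)`, and a
per-(condition, session) log-odds shift `delta`. Wrong answers are
uniform over the remaining three gap directions. Effects enter only in
the trough condition's post sessions, in both behavior (`delta`) and
alpha amplitude (`alpha_boost`): presets `null` (0, x1.0), `moderate`
(0.8, x1.3), `strong` (1.5, x1.6). The paper-analogous effect sizes are
unknown (no effect sizes are reported), so `moderate` was calibrated to
the qualitative significance pattern only — trough-only improvements
detectable in a 16-17 subject cohort — and is not an estimate of the
real effect magnitude.

## EEG features

* Preprocessing: zero-phase (forward-backward) 4th-order Butterworth
  high-pass at 1 Hz, and a 60 Hz notch of quality factor 30. Epochs are
  [-1000, 0) ms before each onset (exactly `fs` samples); any epoch
  exceeding 100 uV absolute after filtering is rejected.
* ITPC: complex Morlet transform at 1-100 Hz (step 1), cycle count
  rising linearly from 3 at 1 Hz to 8 at 100 Hz; epochs carry +/-500 ms
  of trace context through the transform, discarded afterwards, to keep
  edge artifacts out of the window. ITPC(f,t) is the magnitude of the
  across-trial mean unit phasor. The transform parameters of the
  original toolbox call are not recoverable, so absolute ITPC values
  are implementation-specific; the statistics operate on within-subject
  contrasts, which do not depend on that calibration.
* Power: per-trial periodogram of the 1 s window (1 Hz bins; a sinusoid
  of amplitude A yields A^2/2 in its bin), averaged over trials;
  scalars at 10 and 80 Hz.
* PAC: Tort's modulation index, `MI = (log K - H(P)) / log K` with
  `K = 18` phase bins and `P` the normalized phase-binned mean
  amplitude (empty bins via the 0*log0 = 0 convention), over phase
  frequencies 4-20 Hz (step 1) x amplitude frequencies 30-100 Hz (step
  5). Phase bands are f +/- 1 Hz; amplitude bandwidth is f_phase + 2 Hz
  on each side so both modulation sidebands fall in the band — with a
  fixed narrow band, coupling at (10, 80) Hz would be invisible.
  Filtering happens per epoch with the padding context; phases and
  amplitudes are then concatenated across epochs before binning
  (per-trial 1 s segments are too short for a stable 18-bin estimate at
  4 Hz). Canolty's mean vector length is available as a secondary
  measure.
* Saccade detection: 30 Hz low-pass, first-difference velocity in uV
  per 10 ms, threshold 25 (default), 100 ms refractory merging.

## Statistics

Shapiro-Wilk (scipy's implementation of the standard approximation) is
the normality screen motivating the nonparametric plan. Friedman's
test uses mid-ranks with the standard tie correction. Its p-value
comes from the exact permutation distribution — a dynamic program over
the (k!)^n equally likely within-subject rank arrangements, feasible
because only the column rank-sum vector matters — for n <= 12 subjects,
and from the chi-square (k-1 df) reference beyond that. The switch
exists because the chi-square approximation deviates from the exact p
by up to ~0.12 at n = 6 while being adequate at cohort size (n = 16-17,
where exact enumeration is also what the approximation converges to).
The Wilcoxon signed-rank test is exact (convolution over doubled
mid-ranks, i.e. full 2^n sign enumeration) for n <= 25 and uses the
tie- and continuity-corrected normal approximation beyond; zeros are
dropped before ranking by default, with Pratt's method by flag. All
tests are two-sided.

The plan: per (measure, condition), Friedman over sessions; pairwise
Wilcoxon post-hocs (pre-post0, pre-post10, post0-post10) only when the
omnibus is significant at alpha = 0.05; Benjamini-Hochberg FDR within
each measure's three-contrast post-hoc family (the narrowest family
reading; a global family is selectable); plus, per measure, a Friedman
over conditions on the pre-session baselines. Boundary behavior: the
post-hoc gate is strictly `p < alpha`.

## Pipeline, determinism, and simulation sizes

`run_all` derives every stage's seed from the single config seed via a
master generator, so identical configs give byte-identical outputs.
Default cohort: 17 behavioral subjects, 16 with EEG, mirroring the
experiment's attrition so report shapes align (6 ITPC windows x 3
conditions; 3 conditions x 3 sessions x 4 accuracy measures).

Validation simulation sizes, chosen to bound the suite's runtime while
keeping estimates stable: type-I calibration uses 200 null-preset
behavioral cohorts of 17 subjects (observed omnibus rate ~=5.1%);
behavioral effect recovery uses 30 moderate-preset cohorts; alpha-power
recovery uses 8 EEG cohorts of 16 subjects (EEG synthesis at 2,048 Hz
dominates the cost, ~15 s per cohort). Oracle-equivalence checks run on
small fixtures (5-trial ITPC, n <= 6 Friedman enumeration, n <= 10 sign
enumeration, 1,000 random FDR vectors).

## Limitations

* The generator is phenomenological: sinusoidal oscillators plus shaped
  noise, single channel, no volume conduction, no non-stationarity in
  band power, no real artifact morphology. Passing tests show the
  *pipeline* recovers the structure it assumes; they say nothing about
  effect sizes or detectability in real recordings.
* Absolute ITPC and MI values depend on wavelet and filter-bandwidth
  choices that the original analysis did not specify; only relative
  (within-subject, between-session) comparisons are interpretable.
* The exact composition of the original FDR families is not
  recoverable; the per-measure reading is implemented, and switching to
  a global family can change borderline decisions.
* Whether PAC should be computed per trial and averaged, or on
  concatenated epochs, is not specified; concatenation was chosen for
  estimator stability and is the only mode implemented.
* EDF export quantizes to 16 bits over +/-1000 uV (~0.03 uV steps) —
  negligible against the signals simulated here, but a real-data user
  should widen the physical range for high-amplitude channels.
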