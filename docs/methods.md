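# Methods

This note documents the generative assumptions, analysis conventions and
numerical choices behind `thermocode`, and what the synthetic-data tests
do and do not establish about real recordings.

## Units and conventions

Seconds, °C, Hz, mm², fibers/mm² throughout; all timestamps are relative
to session (or trace) start. Temperature traces store the *command*
waveform of the thermal stimulator; the conductive lag between command
and skin temperature is not modeled, as no transfer function is
available. Response windows are half-open `(onset, onset + w]`: a lick or
spike exactly at onset cannot be a response to the stimulus. The default
sample rate is 1 kHz, matching typical behavioral acquisition.

## Behavioral scoring and d′

Hits and false alarms are licks inside the 3.5 s window of opportunity on
stimulus and catch trials respectively; catch windows are anchored at the
catch trial's virtual onset and have the same length. Licks during the
2 s pre-onset lockout are excluded from scoring and flagged. d′ uses a
full-precision inverse normal CDF (`scipy.stats.norm.ppf`), with extreme
rates replaced by `1/(2N)` and `1 − 1/(2N)`; the test suite cross-checks
the whole pipeline against an independently coded Acklam inverse-normal
evaluation (refined with one Halley step against `math.erfc`) to 1e-9.

Perceptual thresholds: the real experiments establish detection with
repeated-measures ANOVA on hit vs false-alarm rates across a cohort. At
single-session scale this package substitutes (a) d′ ≥ 1.0 and (b) a
trial-level percentile bootstrap (default 10,000 resamples of stimulus
and catch outcomes independently) whose 95% CI of h − fa must exclude 0.
The threshold is the smallest tested amplitude satisfying both. Both the
criterion and the resample count are exposed as arguments.

## The synthetic observer

The observer exists to give the scoring code data with the right
structure, not to model decision making:

- spontaneous licking: homogeneous Poisson, default 0.1 Hz (≈30%
  false-alarm probability per 3.5 s window, the upper range of a
  moderately impulsive animal);
- detection: Weibull psychometric
  `p(A) = guess + (1 − guess − lapse)(1 − exp(−ln4 (A/θ)^k))`, θ = 1 °C
  (the amplitude at 75% of asymptote, matching the ~1 °C perceptual
  threshold of trained mice), slope k = 3, lapse 0.02, guess 0;
- latency of the stimulus-locked lick: log-normal, median 0.8 s, log-SD
  0.4 (mean ≈ 0.87 s, in the range reported for warm-trained animals).

These forms are the simplest consistent with published lick PSTHs; they
carry no claim about mechanism. With the defaults, a 10 °C session
yields d′ ≈ 2.6–2.8, comparable to trained wild-type performance.

## Afferent rate models

**Warm-excited polymodal fibers** (C-MH and warm-responsive C-MHC):
rate 0 below an absolute recruitment threshold `t_on`; at `t_on` the
fiber produces a small onset discharge (default 2 Hz) and thereafter the
rate rises linearly with temperature (gain, Hz/°C), clipped at `r_max`
(50 Hz). The onset discharge is required by the threshold-measurement
convention itself — "the temperature that elicits the first action
potential" presupposes a detectable discharge at recruitment; with a
purely linear soft onset, first-spike thresholds would overshoot `t_on`
by `√(2 ln2 / gain)` (> 1 °C at low gains) and the generating threshold
would be unrecoverable at realistic repeat counts. Defaults: `t_on`
uniform on [33, 44] °C (only example low/high-threshold units are
published, so a maximally uninformative spread is used; exposed in
config), gain uniform on [0.5, 2] Hz/°C.

Noxious-range coding is piecewise: above 44 °C the wild-type slope
triples (`noxious_accel = 3`), reproducing the dramatic firing increase
of polymodal nociceptors in the noxious range; `trpv1_null` removes this
acceleration; the triple knockout (`tko`) scales the slope above 42 °C to
10%, leaving innocuous-range coding untouched. A minority
"warm-preferring" mode rolls rates off linearly above a `rolloff_temp`
instead.

**Cool-driven fibers**: ongoing rate drawn uniformly from the observed
0.2–6 Hz range at the adaptation temperature, incremented by
`cool_gain × cooling` (uniform [0.3, 1.5] Hz/°C) and multiplicatively
suppressed by warming at 0.15 of the ongoing rate per °C — complete
silencing at ~6.7 °C of warming, consistent with full silencing by a
10 °C step. Tonic rates re-reference to the session background
instantaneously (no adaptation time constant): ongoing discharge is the
same at 22 °C and 32 °C baselines, so these fibers encode magnitude of
change, not absolute temperature. Warm-excited thresholds, in contrast,
are absolute: a 22→32 °C step recruits essentially no warm-excited
fibers, which is what makes the low-baseline task suppression-dominated.

**Spiking**: inhomogeneous Poisson by thinning with a 5 ms absolute
refractory period (no interval statistics are published; this is the
simplest process matching mean-rate descriptions). Expected counts equal
the rate integral up to a relative deficit of order `rate × refractory`
(≈1.5% at 3 Hz, ≈10% at 20 Hz); convergence tests therefore run at
modest rates and the count-based decoder path (below) ignores the
refractory period.

## Population composition

`round(density × area)` fibers; default 176 fibers/mm² × 22 mm² = 3,872.
A fraction 0.36 is thermosensitive, with classes drawn from the
renormalized tally {C-MH 20/35, C-MHC 6/35, C-MC 7/35, C-C 2/35} (the
published tally names 35 of 37 units; the residual two are unclassified
and the mix is renormalized over named classes rather than guessed). A
fraction 0.19 of thermosensitive fibers is tonic, chosen among the
cool-capable classes with C-MC weighted 5:1 over C-MHC to match the
observed 5 + 1 composition; choosing tonic members *within* the
class-mix draw keeps overall class proportions equal to the mix.
Non-tonic C-MC and C-C fibers are cool-excited but silent at rest;
non-thermosensitive fibers are generated as silent mechanosensitive
units. Conduction velocities: uniform [0.3, 1.1] m/s for C-fibers.

Genotype presets: `trpm8_null` (and the pharmacological `pbmc_block`)
set the tonic fraction to 0 and remove the classes whose only thermal
drive is cooling (C-MC, C-C); C-MHC is retained as warm-excited-only, so
warm-responsive proportions are unchanged, as observed. `trpm2_null`
halves the cool-class mass. All generators are bit-reproducible given
(config, seed); one session seed expands into per-component streams via
`SeedSequence` spawn keys.

## The dual-channel decoder

Pooled spike counts of pool A (warm-excited) and pool B (tonic) are read
in a 1 s decision window after onset (behavioral latencies are ~0.3–0.9 s)
and a matched pre-stimulus window. Evidence: `e = A_stim − A_base`,
`s = B_base − B_stim`. The default *coincidence* rule `min(e, s)` (each
normalized by its null-epoch SD, estimated from the same run's null
trials) operationalizes the claim that neither channel alone suffices —
a deliberately interpretive choice, since how the two streams are
combined downstream is an open question; the *sum* rule `e + s` is kept
to represent the alternative in contrast experiments.

Degenerate channels: a channel that exists but is silent (zero null
variance, e.g. pool A during a 22→32 °C step) is normalized with a
unit-count floor instead, so the coincidence statistic reduces to
`min(0, s)` and suppression-only detection remains possible — the model
then predicts above-chance 22→32 °C detection for wild type and the
triple knockout alike. A channel with *no fibers at all* (trpm8 lesion)
makes the coincidence statistic identically 0 and detection collapses to
chance regardless of the other channel; results carry a `degenerate`
flag.

Because pooled counts of independent Poisson fibers are Poisson with the
summed intensity, `model_dprime` samples pooled counts directly
(superposition) rather than realizing thousands of trains per trial;
population identities are fixed per experiment and only spike noise is
resampled across trials. A dual-route test verifies the count sampler
against full train simulation on a small population (with the refractory
period disabled, since the count path deliberately neglects it). Both a
distribution-based d′, `(μ_stim − μ_null)/pooled σ`, and a
criterion-thresholded decision d′ are reported; zero-variance statistic
distributions yield d′ = 0 rather than an error.

Predicted ideal-observer d′ values are much larger than behavioral ones
(d′ ≈ 25 vs ≈ 2.5 at the 10 °C step) because the decoder pools ~1,400
fibers noiselessly and central noise is out of scope; only *contrasts*
across genotypes, amplitudes and areas are interpretable, and those are
what the test suite asserts.

## Problem sizes and tolerances

Simulation sizes used by the tests and the acceptance script: 20
simulated threshold series (5 amplitudes × 100 trials, 2,000 bootstrap
resamples each); 10 × 60 s trains for tonic-parameter recovery (expected
sampling error ≈ 3%, asserted within 10%); 50 ramp repeats per fiber for
recruitment-threshold recovery (median estimator; positive bias bound
+1 °C); 150–1,000 trials per encoding-model condition with 10–20
population seeds for monotonicity rank correlations. The trace sample
rate for decoder intensity integrals is 500 Hz; trapezoid integration of
piecewise-linear rates along piecewise-linear traces makes discretization
error negligible at these rates.

## What passing tests do not show

The synthetic generators reproduce the *statistical structure* the
analyses assume (trial schedules, psychometric detection, monotone warm
tuning, tonic suppression), not real data: no adaptation dynamics,
bursting or inter-fiber correlation; no skin thermal lag; no central
decision noise; mechanosensitivity reduced to boolean flags. Parameter
recovery therefore demonstrates the estimators are consistent with their
own generative assumptions — a necessary, not sufficient, condition for
validity on real recordings. Cohort-level statistics (repeated-measures
ANOVA and t-tests on real animals) are outside scope and replaced by the
trial-level bootstrap.
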