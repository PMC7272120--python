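# thermocode

Analysis and modeling tools for the psychophysics and peripheral neural
coding of innocuous skin **warming**. The package targets experiments in
which a head-restrained mouse reports forepaw warming in a go/no-go
licking task while thermosensitive C-fiber afferents are characterized in
ex vivo skin-nerve recordings, and it implements a population-coding model
in which warmth is signaled by **two concurrent channels**: excitation of
warm-sensitive polymodal C-fibers that are silent at rest, and suppression
of the ongoing discharge of cool-driven C-fibers that are active at rest.

It is intended for sensory-neuroscience researchers who want to score
thermal detection behavior, quantify thermosensitive afferents, or probe
ideal-observer predictions of the dual-channel code under in-silico
lesions (TRP-channel knockout presets) — all exercised end-to-end on
synthetic data generated with the statistical structure those experiments
assume.

## What it computes

**Behavior.** Sessions interleave warm-step stimulus trials and catch
trials (default 50 + 50, inter-trial intervals randomized over 3–30 s).
A *hit* is a lick within the 3.5 s window of opportunity after stimulus
onset; a *false alarm* is a lick in an equally long window on a catch
trial. Sensitivity is the signal-detection index

```
d' = z(h) − z(fa)
```

with `z` the inverse standard-normal CDF and extreme rates replaced by
`1 − 1/(2N)` or `1/(2N)` so d′ stays finite. Lick latencies, first-lick
PSTHs, learning curves, and perceptual thresholds (smallest amplitude
with d′ ≥ 1 whose bootstrap CI of h − fa excludes 0) build on this.

**Ephys.** Units are classified by conduction velocity (C < 1.2 m/s,
Aδ 1.2–10 m/s, Aβ > 10 m/s) and evoked modalities (C-MH, C-MHC, C-MC,
C-C, …); thermal thresholds are read off as the temperature at the first
evoked spike; ongoing activity, percent firing-rate change (−100% =
silencing), spike PSTHs and warm-preferring vs monotonic tuning are
quantified from spike trains plus temperature traces.

**Encoding model.** An ideal observer pools spike counts of the
warm-excited channel (A) and the tonic cool-driven channel (B) in a 1 s
decision window against matched pre-stimulus baselines. The default
*coincidence* rule `min(e, s)` (each channel normalized by its null-epoch
SD) requires simultaneous excitation (`e`) and suppression (`s`) to report
warm; a *sum* rule is available for contrast. Genotype presets implement
in-silico lesions — e.g. `trpm8_null` removes the tonic pool, which makes
coincidence detection degenerate and abolishes predicted warm detection
even though warm-excited firing is intact.

## Worked example

```bash
$ thermocode --seed 7 --out-dir demo simulate-session
hit rate 0.980  fa rate 0.220  d' 2.826
```

A default synthetic session (32→42 °C steps, 100 trials): the observer
hits 49/50 stimulus trials and licks spontaneously on 22% of catch
trials, giving d′ ≈ 2.8 — performance typical of a well-trained animal.

```bash
$ thermocode dprime --hits 0.94 --fas 0.30 --n-stim 50 --n-catch 50
2.0792
```

```bash
$ thermocode --out-dir demo encode --genotype wildtype   --amplitude 10 --trials 500 --seed 7
{"genotype": "wildtype", ... "predicted_dprime": 25.29, ... "degenerate": false}
$ thermocode --out-dir demo encode --genotype trpm8_null --amplitude 10 --trials 500 --seed 7
{"genotype": "trpm8_null", ... "predicted_dprime": 0.0, ... "degenerate": true}
```

The ideal observer pooling ~1,400 thermosensitive fibers under a 22 mm²
contact detects a 10 °C step with far higher sensitivity (d′ ≈ 25) than
the behaving animal — central noise is outside the model — but the
*contrast* is the point: removing the cool-driven tonic pool
(`trpm8_null`) leaves the coincidence decoder without its suppression
channel and predicted detection collapses to chance, while the
warm-excited channel alone is intact.

```bash
$ thermocode fiber-budget
63.36 informative fibers/mm^2, 1393.9 total
```

With 176 C-fibers/mm² and ~36% responsive to innocuous temperature
change, >60 fibers/mm² — over 1,300 fibers under the contact area — can
each contribute sparse warm-related information.

Other subcommands: `simulate-afferents`, `score-session`, `threshold`,
`classify-fibers`, `psth`, `lesion-grid`, `summation-curve` (see
`thermocode --help`).

## Layout

```
src/thermocode/
  stimuli.py        ramp-hold-ramp steps, linear ramps, temperature traces
  observer.py       trial schedules and the stochastic licking observer
  fibers.py         warm-excited / cool-tonic rate models, Poisson spiking
  population.py     population sampling, genotype lesion presets
  psychophysics.py  scoring, corrected d', latencies, PSTHs, thresholds
  ephys.py          classification, thermal thresholds, ongoing activity
  encoding.py       dual-channel ideal-observer model, lesions, summation
  io.py, config.py, cli.py
docs/methods.md     model assumptions, parameter choices, limitations
```
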