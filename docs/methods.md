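# Methods

This note documents the models, estimators and numerical choices behind
`reachmetrics`, and what the synthetic-data validation does and does
not establish about recorded human data.

## Movement model of the generator

Each movement segment is composed of strictly sequential minimum-jerk
submovements. A point-to-point minimum-jerk displacement over duration
`T` follows the quintic `s(τ) = 10τ³ − 15τ⁴ + 6τ⁵` (τ = t/T), the
unique rest-to-rest profile minimizing integrated squared jerk; its
speed is bell-shaped, symmetric, and peaks at `1.875·D/T` at `T/2`,
where `D` is the path length. A segment is:

1. a reaction hold (default 0.30 s) at the current hand position after
   target appearance;
2. a ballistic **primary** reach to the target center, duration set by
   the block's condition parameter (defaults 0.95–1.20 s) plus three
   additive Gaussian variance components — per-participant offset
   (sd 0.15 s, shared across conditions), per-(participant, mode, block)
   condition jitter (sd 0.12 s, the ANOVA's within-subject error term),
   and per-segment jitter (sd 0.08 s) — floored at 0.40 s;
3. `k ~ Poisson(mean)` **corrective** submovements oscillating about
   the target: an away-stroke of fixed 8 mm amplitude in a random
   direction, then a return stroke, each 0.40 s.

Because submovements are sequential with speed zero at their
boundaries, consecutive speed peaks are ≥ 0.40 s apart and every
corrective rises 37.5 mm/s above its preceding minimum — the
programmed count `k` is therefore resolvable by design under the
20 mm/s / 150 ms counting rule, and noise-free recovery of
`N_peak = k + 1` is a hard test of the counter. Under the default
0.2 mm position noise, recovery is approximate (±1 on a minority of
segments), which mirrors the noise sensitivity of the statistic itself.

Targets are the 8 vertices of a cube centered in the workspace, scaled
per ball mode so the mean pairwise distance equals the configured mean
inter-target movement distance (56 mm small-ball, 39 mm big-ball —
the big ball is contacted earlier, shortening the movement). The first
target of every block is fixed; the rest are drawn uniformly,
never repeating the current one. Between blocks the hand returns to a
standardized start position 1.2 mean-distances from the first target,
so every block's first segment — the comparison unit for EMG latency —
is the same controlled reach. Printed target radii (84/168 mm) are
carried in the configuration and event log for completeness, but event
timing is defined by movement completion: with inter-target distances
smaller than the ball radius, a pure within-radius contact detector
would fire at target appearance, so the generator instead sets the
disappearance time to the end of the constructed movement, i.e. the
instant the hand settles on the target.

## EMG model

Each muscle channel is the sum of

* band-limited carrier noise (white Gaussian → zero-phase 20–400 Hz
  band-pass, normalized to unit RMS) multiplied by an amplitude
  envelope equal to the session speed profile delayed by the muscle's
  latency offset (defaults 0.0–0.4 s in 0.1 s steps across the five
  muscles) and scaled by a per-muscle gain (7–10 mV per m/s);
* baseline Gaussian noise (0.01 mV sd);
* a 50 Hz mains sinusoid (0.05 mV, random phase).

This is an envelope-level surrogate: it reproduces exactly the timing
and bandwidth structure the peak-latency statistic measures, and
nothing about motor-unit physiology, amplitude normalization,
cross-talk, or electrode artifacts.

## Feature estimators

**Differentiation.** Speed is computed by central finite differences of
position (one-sided at segment boundaries). Positions are first passed
through a zero-phase 2nd-order Butterworth low-pass, default 10 Hz:
raw differentiation of quantization-scale noise produces spurious
velocity peaks, and 10 Hz sits an order of magnitude above the
< 1 Hz content of slow reaching. Both the cutoff and fully raw
differentiation are available.

**Peak counting.** The speed profile is reduced to an alternating
minimum/maximum sequence (plateaus collapse to their first sample; the
segment start acts as the initial minimum, so an initial monotone rise
counts as a peak; a final rising edge makes the last sample a maximum).
A maximum is a candidate if it rises strictly more than the 20 mm/s
cutoff above the preceding minimum; candidates are then accepted
greedily in time order, each ≥ 150 ms after the last *accepted* peak.
Greedy earliest-first acceptance is deterministic and independent of
peak amplitudes; the tests pin the whole contract against a
brute-force extremum-enumeration oracle.

**EMG latency.** Preprocessing is a 4th-order zero-phase Butterworth
band-pass (20–400 Hz) followed by a zero-phase IIR notch (50 Hz,
Q = 30); forward–backward application matters because any group delay
would bias the statistic, which *is* a latency. The envelope is a
centered 50 ms moving RMS followed by a zero-phase 2nd-order low-pass
at 1.5 Hz. The smoothing step exists because the argmax of the raw RMS
trace of a modulated-noise burst wanders over the burst's flat top
(point-wise RMS error ≈ 10–15 % moves the argmax of a ~1 s-wide
quintic speed bump by ~100 ms); averaging over the ~0.3 s smoothing
scale stabilizes it to ≲ 20 ms without biasing a symmetric burst.
1.5 Hz is appropriate for ~1 s reaching bursts; a raw absolute-value
mode and all cutoffs are exposed for other regimes. Latency is the
envelope argmax (earliest sample on plateaus) within the closed
[appear, disappear] interval of the selected block's first segment,
minus the appearance time.

## Statistics

The two-way within-subject ANOVA uses the classical decomposition: for
subjects × A (ball mode, 2) × B (cell, 4) with one value per cell,
each effect is tested against its own subject-interaction term
(`F_A = MS_A / MS_{A×S}`, etc.). Sums of squares are validated against
an independent loop-based decomposition to 1e-8 and against pingouin.
Mauchly's W per effect is computed on the covariance of orthonormal
(normalized Helmert) contrasts — collapsed over the other factor for
main effects, Kronecker-product contrasts for the interaction — with
the standard chi-square approximation; a 2-level effect is trivially
spherical. Under `auto` policy a Greenhouse–Geisser df correction
(ε from the contrast-covariance eigenvalues) is applied to an effect
when its Mauchly p < .05. Effects whose sum of squares is zero to
round-off report F = 0, p = 1. Post-hoc paired t-tests default to
baseline vs each retention cell within each ball mode with Bonferroni
family m = 3 (all-pairs, m = 6, is available); adjusted
p = min(1, m·p).

`power_check` runs the *full* simulate → segment → features → ANOVA
pipeline per Monte-Carlo replicate. Replicates offset the base seed by
100003·r; participants draw from independent substreams of
`SeedSequence(seed, participant)`, so enlarging a cohort never
reshuffles existing participants. Training blocks are skipped in these
replicates — they never enter inference, the analysis comparing
baseline with retention only — which keeps a 10-participant replicate
near one second. The shipped validation uses 200 null replicates for
type-I calibration and 100 replicates with a programmed 0.8 s
movement-time reduction for power; the latency-recovery study uses 100
participants on a baseline-only protocol (2 segments per mode), since
the statistic only consumes a block's first segment.

## What passing tests show — and what they do not

The synthetic cohort establishes that the estimators recover what they
claim to measure: programmed submovement counts, latency offsets and
condition effects come back at the stated tolerances, the type-I error
of the full pipeline is nominal, and every table is reproducible
byte-for-byte from (config, seed). They do not establish anything
about phenomena the generator omits: curved or via-point trajectories,
movement onset anticipation or reaction-time correlations, EMG
amplitude physiology, fatigue or learning drift within a block, or
missing/failed trials (the pipeline assumes a complete balanced
design and rejects incomplete cells rather than imputing them).

## Defaults at a glance

| parameter | default | unit | note |
|---|---|---|---|
| trajectory sample rate | 100 | Hz | robot telemetry scale |
| EMG sample rate | 1000 | Hz | |
| primary duration | 0.95–1.20 | s | per condition block |
| corrective count mean | 4.0–6.0 | – | per condition block |
| corrective amplitude / duration | 0.008 / 0.40 | m / s | |
| position noise | 0.0002 | m | encoder scale |
| peak cutoff / separation | 0.020 / 0.150 | m/s / s | counting rule |
| band-pass / notch | 20–400 / 50 | Hz | zero-phase |
| envelope window / smoothing | 0.050 s / 1.5 Hz | | |
| significance level | .05 | – | ANOVA and post-hocs |
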