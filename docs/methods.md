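# Methods

## Measurement model

A nanopore array reports, per detection channel, the ion current *i(t)*
in pA at 3 samples per millisecond ("tps" — time points). The open-pore
current *Io* drops to a residual level *Ir* while a molecule occupies the
lumen; a translocation event is a maximal run of consecutive samples with
*Ir/Io* below a ceiling. Osmium-tagged probes translocate slowly enough
to be sampled; intact RNA mostly is not, which is what makes the probe
countable against a biological background.

**Event acceptance.** An extracted run is kept iff its duration lies in
[4, 1200] tps (1.3–400 ms), its lowest *Ir/Io* is `< 0.55`, and every
sample satisfies `Ir/Io < 0.6` (automatic from the run definition). All
inequalities are strict. Coordinates are 0-based, half-open. Two design
choices were genuinely open and are fixed as follows: adjacent runs
separated by even one at-baseline sample are *not* merged (no merging
rule is defined by the platform's published thresholds, and the simpler
contract is exactly testable), and *Io* is estimated per channel as the
median of samples above 0.8× the trace's 95th percentile (robust while
dips occupy well under half the samples; the instrument itself treats
*Io* as known).

**Histograms and the R-factor.** Accepted events are binned on their
lowest *Ir/Io* into 0.05-wide, left-closed bins spanning [0.05, 0.55).
Runs typically show an early maximum near 0.15 (probe population) and a
late maximum near 0.30 (background); each is located as the
highest-count bin whose centre lies within ±0.05 of the nominal
position, since the maxima drift with flow-cell age. The R-factor is
`late_max_count / early_max_count`. Ties inside a search window resolve
to the lower-centre bin (deterministic; ties are measure-zero for real
counts).

**Calling a test.** One test is three 45-minute runs at −180 mV on one
flow cell: buffer control, then the probe/RNA mixture twice. Per run,
the direction of the R change versus control is judged significant by a
two-sided two-proportion z-test (α = 0.05) on the late-vs-early *window*
counts (all events under each search window, not just the maximum bin —
the windows are the natural sufficient statistic for the late-event
share, and using full windows roughly doubles the counts behind the
test). Detection requires ≥1 significant decrease and no increase;
silencing the reverse; mixed significant directions are inconclusive,
never majority-voted. Additionally, if both sample runs total fewer than
25% of the control's events the test is called silencing outright: fully
hybridized probe/target duplexes crowd the pore entrances without
translocating ("shielding") and suppress all traffic. The 25% fraction
is a package default — the phenomenon is reported qualitatively, with no
printed magnitude — and is configurable.

## Bracketing calculus

With probe copies `P = 600 · x(µL) · c(fM)` loaded against a `y` µL RNA
aliquot and 1:1 hybridization, a detection outcome bounds the target
above by `P/y` copies per µL of isolate and a silencing outcome bounds
it below. The estimate is the midpoint of the tightest consistent pair
(largest lower bound, smallest upper bound above it); any upper bound at
or below the chosen lower bound is physically inconsistent and raises an
error listing the offending experiments. For a bound ratio `r =
upper/lower` the relative accuracy is `(r − 1)/(r + 1)`; the protocol's
×1.5 spacing gives exactly 0.20, and pairs looser than 0.25 are flagged
as missing protocol accuracy.

The copies-per-(fM·µL) constant is fixed at 600 — the platform's
bookkeeping convention, which reproduces its published tables bit-for-bit
— with the exact Avogadro-derived 602.214 available behind `exact=True`.
Copies round half-up to integers and HL values half-up to two decimals;
the per-experiment pipeline normalizes the *unrounded* `P/y` before
rounding, because rounding the quotient twice can shift the last integer
digit.

**Normalization.** Copy numbers are proportional to the RNA content of
the isolate, so all values are scaled to the reference content
(16.0 ng/µL, a combined-healthy-serum reference isolate) and divided by
that reference's per-miRNA copy number (bundled panel: miR-16 210 250,
miR-15b 17 710, let-7b 12 150, miR-21 10 494, miR-375 9 240, miR-141
6 096 copies/µL RNA) to give HL units. One µL of reference RNA is
equivalent to 2 µL of serum.

**Known reporting discrepancies.** Three published per-sample bracket
cells do not equal the midpoint of their own starred bounds under any
rounding convention; the package reports the computed midpoint and the
bundled table marks those entries as not clean rather than reproducing
them. One published normalization note truncates where the quotient
rounds up (5503.78 printed as 5503); the package rounds half-up
consistently and the tests record the one-unit difference. In the
zero-overlap design table for underexpression, the published average and
fold columns derive from the rounded range endpoints; the library
computes the exact constructions `(1−a)/(1+a)` and `(1+a)/(1−a)` and the
tests accept either form at one unit in the last printed decimal.

## Validation statistics

The zero-overlap calculus links fractional accuracy `a` to the minimal
disease/control fold with disjoint data: control spans `[1−a, 1+a]`; an
overexpressed marker needs its lower limit at `1+a`, hence average
`(1+a)/(1−a)` and range `[(1+a), (1+a)²/(1−a)]`; underexpression
mirrors below 1 and yields the identical minimal fold. Group summaries
report mean and RSD with the n−1 sample standard deviation (the
denominator is otherwise unspecified). Screening classifies a marker as
elevated iff HL > 1.5 (strict), with a 2-of-3-biomarkers rule for the
multiplexed test; 2×2 ratios with empty denominators are reported as
not-applicable, never zero. Group comparison is the pooled
(equal-variance) two-sample t-test, two-sided, with no multiple-testing
correction — a single pooled comparison is reported. The threshold-test
planner inverts the normalization to find probe/RNA volumes in
[2, 15] µL putting `P/y` at `threshold × ref_copies × conc/16` within
1%, and suggests a dilution factor when a sample is too concentrated to
be reachable.

## Synthetic flow cell

The simulator generates what the platform assumes, not what any
instrument emitted:

* **Residual-ratio populations.** Min-ratio draws from truncated normals
  on (0, 0.55): probe 0.15 ± 0.03, background 0.30 ± 0.05 — matching the
  two histogram maxima and their ±0.05 wobble.
* **Counts.** Background events Poisson with mean 800 per 45-minute run
  at full channel activity, 35% of them in the early window (controls
  then sit at R ≈ 1.5–2, like published control runs). Expected probe
  events are `capture_efficiency × F` with free probe
  `F = max(0, P − T·y)` and capture efficiency 0.05 — chosen so that the
  ×1.5 titration rungs adjacent to the target produce decisive calls at
  realistic loadings (10³–10⁵ free copies map to tens–thousands of
  events).
* **Pore inactivation.** The active fraction decays by 0.15 per run, so
  totals shrink control → run 1 → run 2; reported only qualitatively by
  the platform, tunable here.
* **Shielding.** When `F = 0`, totals scale by 0.35 and the early window
  by a further 0.5, so R rises relative to control — the extra early
  suppression encodes that the slow, probe-like traffic is hit hardest
  by hybrid crowding at the pore mouths. Both factors are package
  defaults, not measured claims.
* **Durations** are log-uniform on [4, 1200] tps plus a 5% fraction of
  out-of-window decoys to exercise the duration filter. **Noise** in
  signal mode is additive Gaussian with sd 2% of *Io* (unspecified by
  the platform; 2% keeps baseline excursions far from the 0.6 ceiling).
* **Cohorts.** HL tables draw healthy markers at mean 1.0, RSD 0.17;
  validated cancer biomarkers at 1.83, RSD 0.09; miR-15b
  cancer-independently at 0.96, RSD 0.14 — the group structure the
  validation cohort exhibits. Truncated normals keep values positive.

All randomness flows from a single integer seed through
`numpy.random.default_rng` / `SeedSequence`; identical inputs reproduce
outputs bit-for-bit.

What the simulator does **not** emulate: per-channel heterogeneity,
baseline drift and re-estimation, correlated noise, partial
hybridization equilibria, probe cross-reactivity, or the instrument's
container internals. Passing tests therefore demonstrate that the
pipeline's logic and arithmetic are correct under the platform's own
model assumptions; they are not evidence about instrument physics or
about biological variation beyond the group structure injected above.

## Titration driver and problem sizes

The titration driver walks a geometric ladder of `P/y` values (×1.5
spacing) from a starting rung, moving up after silencing and down after
detection; inconclusive tests are retried up to two times, and a rung
between the bounds that stays inconclusive leaves a wider-than-protocol
bracket that is flagged, never silently tightened. Campaigns are capped
at 14 tests.

Test-suite problem sizes are chosen to exercise every code path while
keeping the default run interactive: detector-vs-oracle equivalence on
1000 seeded traces of 1500–4000 samples; caller accuracy on 200
simulated sessions per direction at ±1.5-fold loadings; end-to-end
recovery on 100 simulated samples log-uniform on 3 000–30 000 copies/µL
(event-table mode). The signal-level path is validated on short traces;
the CLI's default simulation container is likewise compact (16 channels,
20 s) while the simulator accepts instrument-scale parameters
(512 channels, 45 min).

## Limitations

* Detection power near the target is asymmetric: silencing (shielding)
  is decisive at any margin, while detection needs enough free probe for
  a significant early-window excess, so rungs a few percent above the
  target can stay inconclusive and widen the bracket — visible in the
  flagged, wider estimates rather than hidden.
* The inconclusive mixed-direction pattern may itself carry copy-number
  information; no rule is applied, the pattern is only surfaced in the
  call rationale.
* The probe design checker verifies structure (complementary core,
  4–5 T tail, A-flanks up to 6 per end as manufactured, core T
  substitution) and reports mismatch counts against paralogs; it does
  not predict hybridization thermodynamics or cross-detection within
  the miR-200 family.
* Multiplexed two-miRNA tests yield one shared copy number and are
  meaningful only for targets with similar abundance; the cohort table
  carries such combined measurements as their own marker label.
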