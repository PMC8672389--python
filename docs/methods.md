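# Methods

## Model

The package monitors the analytical process of a clinical chemistry
analyser through the patient results themselves. For each analyte a
*procedure* fixes: an inclusion rule, a calculation formula, its block
size or weighting factor, and control limits.

**Inclusion.** A result enters the calculation iff it is a patient sample
(QC material is identified by its sample ID and always excluded), its
patient is not in the exclusion registry for that analyte, and its value
lies inside the truncation limits. Truncation is strict-outside: a value
exactly on a limit is included. Haemolysis/icterus/lipemia flags are
carried with each result but do **not** exclude it — the analyser
transmits flagged results like any other, so interference-caused alarms
cannot be prevented upstream; they are identified downstream by the triage
algorithm.

**Simple MA.** The arithmetic mean of the last `n` included results,
recomputed at every included result (a rolling block, not a tumbling
one). Until the window first holds `n` values, the mean of the available
values is still emitted — one MA value per included result — but flagged
as warm-up and not alarm-eligible, which avoids spurious alarms from
means over a handful of results. Internally a running sum gives O(1)
updates; it is refreshed from the window every 256 updates, keeping the
drift against an exact mean far below 1e−12 relative.

**EWMA.** `z(t) = λ·x(t) + (1−λ)·z(t−1)` with `λ ∈ (0, 1]`. The seed
`z(0)` is a stored procedure parameter equal to the training-population
mean; it is not recomputed at runtime. EWMA points are alarm-eligible
from the first result (the seed is already a calibrated value). Engine
state persists across days within a monitoring session — the calculation
is continuous, with no daily reset.

**Alarms.** An alarm fires when an MA value falls strictly below the
lower or strictly above the upper control limit. Strictness matters
because the limits are the *attained* min/max of the MA over a stable
training period: the training extremes themselves are legal values, and
replaying the training stream must produce zero alarms.

## Control limits and procedure optimization

Control limits are derived as the min/max of the non-warm-up MA values
over a stable training stream, computed separately for every candidate
(formula, block size/weighting factor, truncation) combination, since
truncation changes which results feed the MA. For EWMA candidates the
seed is the mean of the training stream's included values.

Candidates are ranked by simulated bias detection at ±TEa (total
allowable error). A candidate *passes* when, in both directions, at
least half of the simulated episodes detect and the median number of
results to detection is within the analyte's average daily test volume —
i.e. a clinically significant shift is typically caught within one
working day. The ≥50 %-detection guard is needed because the median is
taken over detecting replicates only; without it a candidate detecting
in 3 of 100 episodes could "pass" on those 3. Among passing candidates
the selection minimizes the median results-to-detection summed over both
directions, with ties broken by the summed maximum, then by smaller
block size / larger weighting factor (faster-responding procedures), then
by declaration order. If nothing passes, the best non-passing candidate
is returned with a warning.

A `limits verify` operation replays a later stable period and reports
whether its MA range stays inside the configured limits (no correction
needed) — the check a laboratory should run when time has passed between
optimization and deployment.

## Bias-detection simulation

A step bias of `b` % multiplies every value from a random onset onward by
`(1 + b/100)`, *before* the truncation check — a real analytical shift
can push results out of the truncation range, and the simulation must
reproduce that interaction (a large bias on a truncated analyte can
become invisible to the MA; the AST configuration shows this).

For each replicate the engine is warm-started on the unbiased prefix, and
the count of included, biased results up to and including the first
alarming MA value is recorded; replicates whose stream ends first are
censored and excluded from the min/median/max but reported. Onsets are
drawn uniformly over the post-warm-up region; the original scheme behind
this kind of simulation (random vs. exhaustive sliding onset) is not
standardized, and random onsets with a configurable replicate count
(default 100) were chosen as the more general option. The median of an
even number of integer counts is the lower central value, keeping the
statistic an integer number of results. Detection curves evaluate the
bias grid −50…+50 % in steps of 5 plus ±TEa, using the *same* onset
positions for every bias size (common random numbers), so that points on
the curve differ only by the bias and the curve is monotone pathwise
where the mechanism is monotone.

## Alarm triage

Evidence is consumed in the work-up order: (1) review of patient results —
an extreme or consecutively abnormal contributor explained by patient
history/condition ⇒ *abnormal patient result* (release; exclude the
patient from future calculations only when the history marks the value as
chronic); (2) pre-analytical inspection — a found artifact ⇒
*pre-analytical sample problem* (repeat on the original sample for a
dilution, otherwise request a new sample; release); (3) retest of 3
samples from a stable period (the last working day without an alarm for
the analyte) — a difference > 2 analytical SD in ≥ 1 of the 3 ⇒ *small
analytical shift* (recalibrate and retest the day's samples); (4) 3-level
IQC under the 1:2s rule plus maintenance-log review. If step 4 is clear
and the review had flagged abnormal contributors that nothing else
explains, the cause is still the abnormal patient result; if the review
was unremarkable too, *no cause identified* (release). An out-of-limits
IQC at step 4 is treated as analytical. Reaching a step whose evidence
was not collected raises a "work-up incomplete" error naming the step.

The packaged 17-alarm example log encodes one six-month monitoring period
of the 10 packaged analytes; its documented causes partition 9/2/2/4
across the four categories. Cause percentages are rounded half-up to
integers (4/17 → 24 %), and the report flags when the rounded column does
not sum to 100 rather than forcing it. Alarm rates are rounded half-up to
3 decimals.

## Synthetic data

The generator emulates a small outpatient laboratory: per-analyte streams
of `tests_per_day` results spread over an 8-hour workday, values drawn
from a normal or lognormal distribution (skewed analytes — enzymes,
lipids, creatinine — are lognormal) truncated to a physiologic range by
rejection, pathological outliers injected at a configurable rate by a
multiplicative factor, and patients revisiting at 10 % by default so the
exclusion registry is exercised. The packaged specs centre each
distribution midway between the analyte's control limits with the CV set
so the stable MA range roughly spans those limits; sodium uses the ~1 %
spread typical of an outpatient population. The default study-scale
sizes used in tests and the acceptance script are 30 working days at the
analyte's daily volume (1,170 results for sodium), with 10,000-result
streams where a property concerns attained extremes.

Artifacts superimpose on a clean stream: a chronic pathological patient
(all of one patient's results scaled), a saline-diluted sample (one
sample's value scaled), lipemia/haemolysis (flag set, value perturbed),
and step shifts (the bias-injection primitive).

What the generator does **not** model: correlation between analytes,
within-day or seasonal case-mix structure, analyser drift other than step
shifts, and heavy-tailed pre-analytical error beyond the explicit
artifacts. Passing tests therefore demonstrate the correctness of the
machinery and its behaviour under the modelled conditions, not detection
performance on any particular real population — procedure parameters
optimized on these streams must be re-optimized on local patient data
before routine use.

## Numerical and design choices

- Alarm and truncation comparisons are strict inequalities (see above);
  degenerate constant training data would yield equal limits, which the
  procedure validator rejects rather than silently alarming never/always.
- EWMA seeds in the packaged configs are synthetic stand-ins (midpoint of
  the control limits); real deployments derive them from training data.
- All randomness flows through `numpy.random.default_rng` seeds;
  identical inputs and seeds reproduce outputs bit-for-bit, and CLI
  outputs embed the subcommand and seed in a comment header.
- Streams are processed in pure Python, single pass; 10⁵ results per
  second order of magnitude, which is far beyond a small laboratory's
  volume.
- Stream CSV is UTF-8, comma-separated, `.` decimal, ISO-8601 timestamps;
  values are written with full `repr` precision so write→read round-trips
  are lossless.

## Known limitations

- The triage engine decides from supplied evidence; it does not gather
  evidence (no patient-history lookup or maintenance-log parsing).
- Only the 1:2s IQC rule is implemented — the triage algorithm needs no
  other Westgard rule.
- Bull's algorithm (haematology) is out of scope.
- The optimizer's grid search is exhaustive, not adaptive; grids beyond a
  few dozen candidates on long streams cost minutes.
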