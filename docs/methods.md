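# Methods

## Costing model

Delivery costs are assembled bottom-up per intervention group and strategy
from a health-service perspective; only costs of delivering the intervention
are counted (no societal costs, no other service use).

Group-leader hours per leader per group:

| component | hours |
|---|---|
| child sessions | 8 (hybrid) or 16 (long) × (1 h session + 1 h preparation) |
| parent sessions | 0 (brochure) or 5 × (1.5 h session + 1 h preparation) |
| feedback-system review | 8 h total (1 h/week over the 8-week course), feedback arms only |
| supervision | 4 h |
| recruitment and screening | 2 h |

Labor cost = hours × loaded rate × 2 group leaders. The loaded rate defaults
to NOK 529/h, the average school-health-nurse wage multiplied by 1.4 for
social costs; the rate may alternatively be derived from a base wage and
multiplier. Flat per-group items: workbooks (NOK 1,345 brochure arms /
NOK 2,540 parent-session arms), the feedback app (NOK 225, feedback arms
only), and a NOK 1,000 supervisor fee. Supervision intentionally appears
twice — leader *time* (4 h in the labor term) and the supervisor's *fee*
(flat) are distinct resources. Cost per child divides by the average group
size of 5. No platform cost is attached to the web-based sessions of the
hybrid format (none was identified). Currency is NOK throughout; the 62-week
horizon is short enough that no discounting or inflation adjustment is
applied. Internally all arithmetic is full-precision; display rounding is
whole NOK per group and one decimal per child.

## Outcome accumulation

Measurements at weeks 0 (T1), 12 (T2) and 62 (T3) are summarised per arm as
available-case means (children missing at a timepoint are excluded from that
timepoint only) and accumulated by the trapezoid rule over the window,
expressed in score-years with a 52-week year:

    acc = (m1 + m2)/2 · 12/52 + (m2 + m3)/2 · 50/52

The two interval weights sum to 62/52, the window length in years, so a flat
trajectory at c accumulates to c·62/52 and the operation is affine in the
means. For the HRQoL utility the accumulated value is the QALY count.
Accumulation operates on *arm means*, not per-child trajectories, because the
per-timepoint Ns differ under available-case analysis; a completers-only
per-child mean AUC is available as a sensitivity option
(`accumulate_per_child`). Utilities are consumed directly — deriving a
utility from a quality-of-life questionnaire is upstream of this package.
The schedule (weeks and year length) is configurable for reuse.

The SD of a single observation is reported as missing, not zero.

### Reconstruction tolerances

The published accumulated values were computed from unrounded timepoint
means, while the published means are printed to two decimals. Re-accumulating
the printed means can therefore legitimately deviate by up to
0.005·62/52 ≈ 0.006 from the published accumulated value. Five of the 24
arm×measure cells exceed their printed half-unit (symptom scores) or the
0.002 QALY reconstruction tolerance; these are flagged
`rounding_exception: true` in `src/preventcea/data/trial_targets.yaml` and
tested against the analytic bound instead. One garbled source cell (the SLN
depressive-symptom mean at T3) was read as 9.11, the only reading that
reproduces the published accumulated 11.84.

## ICERs, dominance and the frontier

Effects are oriented so larger is healthier (symptom scores negated). With
strategies sorted by cost per child:

1. **Dominance.** A strategy is removed if any other strategy is at least as
   cheap and at least as effective, with one inequality strict. Weak
   dominance counts (ties never occur in the study data but are defined:
   equal cost is broken by better effect first; exact (cost, effect) ties
   collapse onto one representative).
2. **Extended dominance.** Among survivors, adjacent ICERs are computed;
   wherever the sequence fails to increase strictly, the middle strategy is
   removed and the sequence recomputed, until monotone. This is equivalent to
   keeping the lower convex hull in (effect, cost) space, which the test
   suite verifies against an independent brute-force hull oracle on random
   instances.
3. Survivors form the frontier; its consecutive ICERs strictly increase.

ICERs between adjacent rows are reported for *all* strategies in cost order
(the published table layout), including negative ICERs for dominated rows
(extra cost, worse health) and an explicit undefined/infinite result when
effects tie. Every CEA is run twice: at full input precision, and on
display-rounded inputs (integer NOK costs, accumulated scores at printed
precision — 2 decimals for symptom scores, 3 for QALYs), because the
published incremental columns and footnote ICERs are differences of rounded
table entries. Frontier membership agrees between the two on the study data.

QALY frontier ICERs are labelled against the Norwegian severity-dependent
threshold range, NOK 275,000–825,000 per QALY (below / within / above). No
threshold is defined for the symptom scores, so those analyses carry a note
instead of verdicts.

One published classification label is internally inconsistent with its own
table (a strategy labelled extended-dominated that is strictly dominated by a
cheaper, more effective alternative); the algorithm reports DOMINATED and the
golden tests assert frontier *membership* for that cell rather than the
label.

## Synthetic trial generator

The generator emulates the trial the analysis describes: 8 arms, 701 children
at baseline, 59.8% girls, mean age 10.5 (integer ages 8–12 drawn with weights
0.05/0.15/0.25/0.35/0.20, chosen once to match the mean within the range),
recruitment waves 2–5 assigned uniformly (wave carries no effect).

Per arm it draws a 9-dimensional latent normal (3 measures × 3 timepoints)
whose correlation is the Kronecker product of an AR(1) temporal structure
(lag-1 ρ = 0.6 — an assumption, flagged in the calibration report; the source
reports no longitudinal correlations) with the baseline cross-measure
correlation matrix (r = 0.438 anxiety–depression, −0.368 anxiety–utility,
−0.597 depression–utility), reused at every timepoint. A Kronecker product of
PSD matrices is PSD; user-supplied targets are projected onto the PSD cone by
eigenvalue clipping, the adjustment magnitude is logged, and generation
refuses if it exceeds 0.05.

Dropout is completely at random within arm and monotone at the record level:
records are retained through T2/T3 to match the per-arm maximum N across
measures exactly. The published per-measure Ns differ from the record-level
counts by 0–2 cells; those cells are masked per measure, with T2 masks placed
in records that drop before T3 so that "missing at T2 ⇒ missing at T3" holds
per measure (feasible for every default arm; infeasible configurations raise).

Margins are transformed latent-normal → target mean/SD → clipped to scale
bounds → rounded to integers (symptom scores). Two moment-matching modes:

- **exact** (default): after dropout, the latent values of the children
  observed at each (arm, measure, timepoint) are standardized to exactly the
  target mean/SD before clipping/rounding, and the centre is then iteratively
  adjusted so the post-clip/round mean matches the target (clipping at the
  symptom-score floor would otherwise bias means upward by ~0.2 points).
  Available-case summaries then reproduce the target grid up to residual
  rounding granularity (|mean shift| ≲ 0.04 points), which is what makes the
  full synthetic pipeline reproduce the published-means frontier sets almost
  surely — the frontier hinges on accumulated-score gaps as small as 0.09
  points, far below ordinary sampling noise.
- **stochastic**: free sampling; only the *analytic* clipping bias (censored
  normal closed form) is corrected, and only when it exceeds 0.5 score
  points, leaving sampling noise intact.

`validate_against_targets` reports, per margin, the observed vs. target N,
mean (as a z-score against the target SE) and SD, the pooled baseline
correlations vs. targets (tolerance ±0.08), the PSD adjustment and the
modelling assumptions, as JSON and text.

What passing tests do **not** show about real data: the generator reproduces
first and second moments and one correlation structure only. Real trial data
would carry skewness, floor effects beyond truncation, informative dropout,
school-level clustering and wave effects, none of which are modelled; the
exact mode additionally suppresses sampling variability of arm summaries by
construction, so synthetic-pipeline agreement with the published-means results is
a consistency check of the pipeline, not evidence about sampling behaviour.

## Problem sizes and numerical choices

The golden cost/accumulation/frontier reconstructions are closed-form and run
in milliseconds. Property suites run 500 seeded random frontier instances in
the unit tests and 1,000 more in the end-to-end suite against the brute-force
oracle, plus derandomised hypothesis checks of the algebraic invariants;
generator calibration uses one full-size trial per check, a 200-replicate
small-study (n = 20/arm) coverage check, and a 100-seed end-to-end frontier
concordance run (~6 s). Latent draws use a Cholesky factor with a 1e-12
diagonal jitter; all randomness flows through `numpy.random.default_rng`
seeded explicitly, so every artifact is bit-reproducible given a seed.

## Known limitations

- Uncertainty is deliberately out of scope: results are computed from mean
  values only (no probabilistic sensitivity analysis, acceptability curves or
  net monetary benefit), matching the deterministic design of the analysis.
- Costs do not vary between individuals; no societal or indirect costs.
- The utility mapping from the quality-of-life questionnaire is not
  implemented; utilities enter directly.
- Extended dominance assumes strategies are divisible/mixable in the usual
  frontier sense; with eight discrete programme variants this is a modelling
  convention, not an operational claim.
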