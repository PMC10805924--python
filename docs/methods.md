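# Methods notes

This note documents the modelling choices, numerical conventions and known
limitations of the `acvs` package in one place. It states no empirical
result beyond what the test suite and `scripts/acceptance.py` themselves
compute.

## Task structure and schedules

A *cycle* is plateau (3 trials, all 14 distractors one shape) → transition
(13 trials, one distractor flips per trial) → opposite plateau → transition
back; 32 trials in all. Blocks concatenate cycles and append a final
3-trial plateau (practice: 1 cycle, 35 trials; main: 3 cycles, 99 trials),
and the opening plateau alternates between consecutive blocks, continuing
across the practice/main boundary. Sessions of 2 practice + 4 main blocks
(466 trials) and 2 + 8 (862 trials) correspond to the online- and lab-scale
designs. For non-default phase lengths the transition counts are
`round(k·D/(L+1))`, k = 1..L, which reduces to the one-per-trial ramp for
the canonical D = 14, L = 13 and still yields a valid degenerate cycle for
the smallest configuration (L = 1, D = 2).

Displays place the 16 items on cells of an imaginary 5 × 7 grid chosen
uniformly at random (the design does not constrain placement, and no
constraint such as target adjacency is imposed). Pixel centers assume a
1920 × 1080 canvas with items at cell centers, origin top-left, 0-based
(row, col) — only *relative* positions matter for fixation assignment.
Shape variants are angle labels on a circular shape space, four per class,
drawn uniformly with no balancing. Target digits are distinct draws from
1–4; distractor digits are uniform on 5–8.

## Adaptation curve

Star-choice probability is `logistic(2·G·τ·(q(t−δ) − ½) − β)` with `q` the
pentagon-distractor proportion. Because `q` is piecewise linear in trial
position, the curve is a chain of connected sigmoids: flat on plateaus,
S-shaped through each transition.

* **Gain.** `G = 6` fixes the scale of τ: at τ = 1 the log-odds sweep from
  −6 to +6 over one full transition — i.e. the curve just about saturates
  ("fully reaches the plateaus") within a transition, and τ ≈ 10 behaves as
  a near-perfect discriminator. This single structural constant also places
  the plateau selection rates implied by the published group modes at the
  reported values (see the worked example), which serves as the conformance
  check of the functional form.
* **Shift.** δ is a continuous horizontal translation: `q` is evaluated at
  `t − δ` by linear interpolation between integer trial positions, clamped
  at block boundaries (blocks are separated by breaks, so the adaptation
  state does not carry across them). Negative δ (anticipation) is allowed.
* **Bias.** β acts additively on the log-odds scale toward pentagon
  choices. Applying it on the probability scale instead would break the
  symmetry between the two plateau types under relabelling; the log-odds
  convention keeps `τ = β = 0 → p = ½` exact and composes cleanly with the
  gain term.
* **Orientation.** All probabilities are expressed as "select star";
  unique-target probability is derived per trial from the schedule (the
  target whose shape matches the smaller distractor subset; undefined at
  the transition centre where subsets are equal).
* Probabilities are clipped to `(1e-9, 1 − 1e-9)` so extreme τ cannot
  produce log-likelihoods of −∞.

The reported "59%/66%-style" plateau quantities are the mean predicted
unique-target selection over plateau trials grouped by the plateau's shape
state (pentagon plateaus, where β works against the unique star target,
versus star plateaus), pooled over both block orientations. Grouping by
block orientation instead would mix both plateau types in every block and
collapse the two values to near-identical means.

## Hierarchical model and sampler

Participant level: `τ_i = exp(η_i)`, `η_i ~ N(μ_η, σ_η)`,
`δ_i ~ N(μ_δ, σ_δ)`, `β_i ~ N(μ_β, σ_β)`; choices Bernoulli from the curve.
Default hyperpriors are wide and weakly informative — `μ_η ~ N(−2, 1.5²)`,
`σ_η ~ HalfNormal(1)`, `μ_δ ~ N(0, 3²)`, `σ_δ ~ HalfNormal(2)`,
`μ_β ~ N(0, 1²)`, `σ_β ~ HalfNormal(1)` — and every constant is overridable
through `HierarchicalSpec.priors` (or the `sampler.priors` config key), so
alternative prior sets can be matched exactly. The reported group-level τ
is the natural-scale lognormal mean `exp(μ_η + σ_η²/2)`; group δ and β are
the normal means. Practice blocks are excluded from fits by default
(`include_practice` flips this).

Sampling is a seeded adaptive Metropolis-within-Gibbs scheme:

1. all participants' `(η, δ, β)` triples are updated in one vectorised
   block — a joint Gaussian proposal with *per-participant* accept/reject
   is valid because participants are conditionally independent given the
   hyperparameters;
2. group means by exact normal–normal Gibbs draws;
3. group scales by random-walk Metropolis on the log scale;
4. an interweaved *non-centered* move per parameter group: holding
   `z_i = (θ_i − μ)/σ` fixed, `(μ, log σ)` are proposed jointly and the
   participant values rescaled with them. This is the standard cure for
   the funnel geometry that otherwise freezes the scale parameters when
   participant-level information is weak.

Proposal scales adapt toward target acceptance rates during the tuning
phase only (Robbins–Monro-style multiplicative updates every 50
iterations), so retained draws come from a fixed kernel. Defaults are
desk-scale — 4 chains × 1000 draws after 1000 tuning iterations — with a
`full_scale` switch for the 20,000-draw convention. All randomness flows
from a single `SeedSequence`, so results are exactly reproducible given the
seed. Convergence is assessed with split-R̂ and bulk ESS (via `arviz`);
R̂ > 1.01 or a mode outside its HDI surfaces as a warning on the result
object, never silently. The scale hyperparameters (especially σ_δ) mix
slowest; the group-level location summaries are the robust quantities at
desk-scale settings.

Posterior summaries: the mode is the argmax of a Gaussian KDE (Silverman
bandwidth) on a 512-point grid — its precision is bandwidth-limited, about
±0.1 for 10⁵ standard-normal draws. The HDI is the exact sample HDI: the
narrowest window of `ceil(mass·n)` consecutive order statistics (first on
ties), so it contains the target mass to within 1/n by construction.
Contrasts between posteriors pair draws by index after truncation to the
common length and report mode, HDI and the mass fractions on either side
of zero.

## Preprocessing

Filter order follows the published sequencing: blocks with accuracy
strictly below 75% are removed first (block accuracy is computed on the
*raw* trials, before any trial-level removal), then incorrect-report
trials, then trials with RT strictly above 5000 ms; fixation analyses
additionally drop trials with RT strictly below 100 ms. "Incorrect" means
the reported digit matches neither target digit of that display — the
response pad only offers digits 1–4, and distractor digits (5–8) are not
reportable, so "a number not contained in the display" reduces to "not one
of the two target digits". Boundary semantics are literal readings of
"less than", "longer than" and "faster than". All filters are idempotent
and report counts that partition their input.

## Response times

Per-participant mean RTs are computed for plateau (P1–P3) and transition
(T1–T13) trials; participants lacking either phase are dropped with a
warning. The plateau-vs-transition comparison uses the BEST model —
Student-t likelihoods per group, `μ_k ~ N(pooled mean, 1000·pooled SD)`,
`σ_k ~ Uniform(SD/1000, SD·1000)`, `ν − 1 ~ Exponential(1/29)` — sampled
with a seeded adaptive random-walk chain. The two per-participant mean
vectors are treated as independent groups, mirroring the two-sample framing
customary for this analysis even though the samples are paired; a paired
variant (`paired=True`) is available but off by default, preferring
fidelity to the published framing over statistical optimality.

## Fixations

Each fixation is assigned to the display item with the smallest Euclidean
distance to its pixel center; exact ties break to the lowest item index and
are flagged. The central fixation mark is not an assignable item, and
positions outside the canvas still map to their nearest item. Normalized
shape proportions divide the share of (first | last | all) fixations on a
shape class by the number of displayed items of that class *including the
matching target* (15 vs 1 on a plateau), which puts chance at 1/16 for both
classes on every trial. The chosen/non-chosen plateau tables classify
fixations by whether they landed on the chosen target's shape class, split
trials by whether the unique target was chosen, and report first/last
proportions plus both a proportion and a mean per-trial count for all
fixations. Aggregation throughout is per-participant means first, then the
group mean; interval estimates on the differences come from a seeded
nonparametric bootstrap over participants (10,000 resamples by default),
since no parametric form is natural for these quantities.

## Synthetic-data generator

`simulate_study` emulates a complete experiment: counterbalanced starting
plateaus across participants; participant parameters drawn from exactly the
families the hierarchical model assumes (τ lognormal moment-matched to the
configured natural-scale mean and SD, so the configured mean is the
recoverable group quantity); Bernoulli choices from the curve; lognormal
RTs parameterised by arithmetic phase means (950 ms plateaus, +60 ms in
transitions, shape σ = 0.25) so the planted mean offset is directly
recoverable; contamination at configured rates — wrong-digit reports
(default 2.5%, drawn from the non-displayed response keys), timeouts
(default 0.1%, strictly above the 5000 ms threshold), and optional
chance-level participants who respond randomly and are caught by the block
accuracy filter. Defaults reflect the online-scale study: 30 participants,
2 practice + 4 main blocks, group τ = 0.1, δ = 1.2, β = 0.15 with
between-participant SDs (0.04, 0.6, 0.25) in the empirically plausible
range.

The fixation agent is deliberately a transparent test harness, not a
cognitive claim: the first fixation lands on a target with configurable
probability (optionally modulated by cycle position) and otherwise on a
uniform item; thereafter the agent stays within the currently inspected
shape subset with probability `p_stay` and terminates on the chosen target
(appending it if the cap of 12 fixations is reached), so the last fixation
always matches the choice. Two null variants exist for calibration tests:
item-uniform fixations (chance level for normalized proportions) and
shape-fair fixations (no chosen-shape excess). Positions get Gaussian
jitter (SD 8 px) around item centers; durations are lognormal around
200 ms. One root seed feeds named substreams (cohort, choices, RTs,
contamination, displays, fixations).

What the generator does *not* emulate — and hence what passing tests do not
establish about real data: sequential dependencies beyond the lagged
schedule (priming, fatigue, learning within a session), RT dependence on
the selected target or on eccentricity, saccade dynamics, blinks or
tracking loss, and any coupling of fixation paths to RT. Recovery results
show the pipeline is correct under its own assumptions, not that the model
is true of human observers.

## Problem sizes and test design

The suite runs recovery at 30 participants × 4 main blocks with 2 chains ×
800 draws per fit, 20 replicates — enough for HDI coverage counts with a
binomial tolerance (≥17/20) while keeping a full run in minutes on one
core. Null-calibration checks (BEST false-exclusion, shape-fair fixation
agent) use fixed seeds; their assertions are sized at 2–3 Monte-Carlo
standard errors, so they are deterministic reruns of a calibrated draw
rather than flaky re-samples. The acceptance script's quantities are fully
deterministic curve evaluations.

## Known limitations

* The sampler is a random-walk scheme, not gradient-based; it is well
  matched to this ~100-dimensional posterior but would scale poorly to far
  richer models. Scale-hyperparameter ESS is the binding diagnostic.
* The KDE mode is bandwidth-limited; for publication-grade point estimates
  at large draw counts, increase draws rather than trusting the third
  decimal.
* `ChoiceDataset` links trials to schedules by `(block, trial_in_block)`;
  datasets imported from other software must reconstruct the full design
  schedule (the lag term needs schedule positions even for excluded
  trials).
* The fixation import shim expects an already-parsed columnar fixation
  report; raw gaze streams and event parsing are out of scope.
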