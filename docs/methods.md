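# Methods

## The sequence-data representation

A course is a catalog of `T` tasks with nominal order 1..T (task ID =
nominal rank), partitioned into `S` contiguous sessions, each task one of
six types (coursework, quiz, multi-response poll, reading/video, G-chart,
discussion post).  A learner is an ordered set of *distinct* completed
task IDs; repetition is excluded at ingestion by keeping the earliest
completion event (completion means first submission/input).  Sequences
may omit tasks and end early, so lengths vary across the cohort.

Ingestion orders events by an explicit `order_index` when present,
otherwise by timestamp.  Tied timestamps for one learner with no order
column are refused rather than silently broken: every downstream quantity
is order-based, and an arbitrary tie-break would corrupt it.

Grade-quantile grouping ranks learners by grade with learner ID as a
lexicographic tie-break and takes the top and bottom `floor(N·f)`
learners (default f = 0.25, configurable; a median split is the f = 0.5
limit).  A single global ranking is used so the two groups are disjoint
even when all grades tie.

## Descriptive statistics

* **Position matrix** `P`: counts `n_ij` of task *i* at sequence position
  *j*, rows normalised.  Rows of never-completed tasks are kept at zero
  and flagged rather than dropped, so the matrix shape is stable.
* **Transitions**: counts `m_ij` of *j* immediately preceded by *i*;
  joint `p_{i→j} = m_ij/Σm`; conditional `π_ij` row-normalised.  Session
  resolution substitutes session IDs for task IDs before counting, so
  within-session moves appear as retained self-loops.  A virtual START
  state (0) makes the first completion a transition; it defaults off at
  task resolution and on at session resolution, where entry into the
  course is informative.  Rows with no outgoing transition are NaN and
  flagged — never silently uniform.
* **Group difference** `Δπ = π_A − π_B`, returned with its positive and
  negative parts separated (transitions more probable for each group);
  rows undefined in either input are NaN in both parts.
* **Jensen–Shannon profile**: distance = √(JS divergence), base-2
  logarithm, `0·log 0 = 0`, no smoothing — this makes the bounds exact:
  0 for identical distributions and 1 for disjoint support.  Outgoing
  profiles compare conditional rows.  Incoming profiles compare columns;
  since columns of a row-stochastic matrix have no canonical scale they
  are renormalised to sum to 1 by default (`column_mode="joint"` compares
  joint-probability columns instead).
* **Deviation matrix**: entry for the *j*-th completion of a learner with
  `n_k` completions is `j/n_k − rank(t_j)/T`.  Both terms are fractions
  of the learner's own progress and of the course, so a complete
  perfectly-nominal run is exactly zero, entries lie in (−1, 1), positive
  means completed later than nominal, and positions past the last
  completion are NaN (censored region).

## Task-centric statistics and confidence

Per group each task gets its completion frequency (fraction of members
completing it) and mean rank (mean 1-based position among completers, in
the learner's own sequence — not calendar time).  The contrast plane uses
`dfreq = freq(HP) − freq(LP)` and `drank = rank(LP) − rank(HP)`, so the
upper half means the high-performing group completed the task earlier on
average.  Tasks with no completers in either group have no mean rank and
are excluded from the per-type median/IQR summaries.

The confidence score `C = confident/(confident + revisit + support)` is
computed over a student's answered tasks only.  The group comparison
pairs by task (each task contributes one per-group confident proportion;
two-sided paired t-test), because tasks are the only index shared by both
groups; a per-student mode (Welch's two-sample test) is available since
the pairing unit is a genuine modelling choice.

## The reduced hypercubic model

The fully general Markov model of irreversible task acquisition lives on
the `2^T` subsets of tasks with `T·2^(T−1)` transition edges.  The
reduction keeps `T²` parameters: θ with basal log-propensities on the
diagonal and additive pairwise log-influences off it,

    P(next = j | acquired A) ∝ exp(θ_jj + Σ_{i∈A} θ_ij),  j ∉ A.

Additivity in log space (multiplicative propensities) is the convention
of the accumulation-model literature this follows; it is isolated in one
function so an additive-in-rate variant would be a local change.  Adding
a constant to every diagonal entry leaves all step distributions
unchanged — only contrasts are identifiable; the uniform prior bounds the
flat direction.

Completion order is fully observed here, so the likelihood of a sequence
is the exact product of its step probabilities.  Partial sequences
contribute only their observed steps: stopping is not modelled, which
keeps likelihoods comparable across prefix lengths in the classifier.
No path sampling over hidden orderings is needed — the defining
simplification fully-ordered data permit.

Inference is random-walk Metropolis over the full matrix: independent
uniform priors on [−10, 10] per entry, spherical Gaussian proposals
(initial scale 0.1), scale adapted every 100 iterations during burn-in
towards acceptance 0.234 with a damped multiplicative update capped at
the prior-box width (an uncapped update overshoots badly when the
likelihood is flat), frozen after burn-in so the post-burn-in chain is a
valid Metropolis sampler.  Defaults: 20,000 iterations, 10,000 burn-in,
thinning 10, seed mandatory.  Diagnostics kept per fit: acceptance rate
and log-likelihood trace; a chain that accepts nothing raises an error
suggesting a smaller proposal scale.  An exhaustive enumerator of all T!
ordering probabilities (refused above T = 8) serves as the model's
independent oracle.

## Posterior-odds classification

`P(s | group)` is the posterior-predictive likelihood: the average over
posterior draws of the exact sequence likelihood, computed with
log-sum-exp.  Averaging likelihoods (not log-likelihoods) is the default
because the quantity entering the odds ratio is a marginal probability;
log-averaging is available as a variant.  Membership trajectories
evaluate the odds at every prefix length in one pass per learner
(cumulative step log-probabilities per draw).  Two protocols: in-sample
(fit on all group members, evaluate the same members — a learnability
check) and held-out (stratified seeded 70/30 split per group — a
predictive check).  Exact symmetries hold by construction and are tested:
complementarity `P(g1)+P(g2)=1`, label-swap complementation, and exact
prior-odds linearity.

At large prefix length individual log-odds accumulate step-wise
log-Bayes-factors and saturate towards 0 or 1 even when both groups are
generated identically; calibration under a null is therefore assessed on
the ensemble mean over held-out learners and prefixes, which is stable,
rather than on per-prefix means over a handful of learners, which are
binomially noisy once trajectories saturate.

## Synthetic cohorts

The generator's default scenario is an 81-learner, 123-task, 10-session
course in three strata (20 top / 41 middle / 20 bottom): grade means
(std) 79.3 (3.3), 68.4 (5.0), 55.6 (4.6); per-response confident
probabilities 0.76 / 0.70 / 0.65; completion fractions 0.95 / 0.85 /
0.70.  Coursework tasks sit in sessions 3, 4 (twice) and 9.

Behaviour is encoded in θ: each task boosts its nominal successor
(within-session and between-session strengths separately per stratum),
task 1 carries a basal "start anchor" equal to the larger adherence (so
entering at the beginning is itself an adherence behaviour — without it
the first pick would be uniform), and coursework tasks get a basal pull
for strata that jump ahead to marked work.  Default log-boosts
(within/between): 7.5/9.0 top, 8.0/8.0 middle, 9.0/6.5 bottom — high
performers track the session progression more tightly, low performers
track the task order within sessions but stray across sessions.  These
values put the default cohort where realistic cohorts sit: ≈0.9
probability of completing task 1 first and roughly two-thirds of session
transitions on the diagonal/superdiagonal band.

Model draws are then post-processed, in order: a designated branch
subset (default tasks 78 and 81) is dropped entirely for a seeded 40% of
learners, producing bimodal downstream position histograms; a per-task
skip probability rising linearly from 0.02 to 0.25 along the course
drops further tasks (order preserved), producing declining completion
frequency and broadening; coursework is relocated earlier for strata
with a jump-ahead probability; finally the sequence is censored to the
learner's completion fraction.  Skips after generation preserve relative
order, matching how a skipped task shifts all later completion
positions.

What the generator does *not* emulate: calendar time and pacing,
re-attempts, non-stationary adherence within a learner, correlations
between grade and sequence beyond stratum membership, and any
higher-order (non-pairwise) interaction structure.  Tests passing on
synthetic cohorts therefore validate the machinery and its contracts,
not claims about any particular real cohort.

The *model-only* mode bypasses all post-processing and is used wherever
the data must match the model assumptions exactly (parameter recovery,
simulation-vs-enumeration consistency).

## Verification scale and numerical choices

Brute-force recount oracles (dictionary loops, written independently of
the array implementations) cover cohorts with N ≤ 5, T ≤ 6; exhaustive
enumeration covers T ≤ 6 at 1e-10; simulation consistency uses 10⁵ draws
at T = 3 (χ², α = 0.01).  Parameter recovery plants θ₁₂ = +3 and
θ₃₄ = −3 at T = 5 with 200 sequences and requires correct signs with 90%
credible intervals excluding zero.  Classification protocols run on
20 + 20 learners over 40 tasks with 20,000-iteration chains — sizes
chosen so the full verification cycle stays desk-scale while every
qualitative property (in-sample saturation, held-out separation, null
calibration) is exercised.  Tolerances: probability conservation at
1e-12; J–S endpoints exact by construction of the base-2 definition.

## Known limitations

* The MCMC sampler is a plain full-matrix random walk; at course scale
  (T² ≈ 15k parameters) it explores the posterior slowly, and fits there
  should be read as regularised point-cloud summaries rather than
  well-mixed posteriors.  Componentwise or gradient-based samplers would
  be the upgrade path.
* π at task resolution is sparse for small cohorts; J–S profiles skip
  undefined rows/columns and report them, but comparisons between very
  small groups are noisy.
* The confidence survey model treats responses as independent
  Bernoullis; real survey data cluster by session and by student.
* Only two-group classification is implemented; the odds-ratio extends
  to more groups but the trajectory containers assume a binary label.
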