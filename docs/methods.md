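# Methods

This note documents the models, numerical choices and open design decisions
behind the package, and what the built-in simulator does and does not show
about real data.

## Data model

A cohort is a demographics table (one row per individual) plus a single
chronological event stream per individual, obtained by merging the source
transactional tables on patient ID and relative date.  Same-day ties are
broken by a declared table-priority order and then by source row order, so
harmonization is deterministic.  Event timing is carried as **sojourn time**,
the number of days since the individual's previous event; the first event's
sojourn is defined as 0 so that all sojourns are computable without an
external per-individual study-start anchor.  Sojourn time is itself an event
attribute (every event type carries a timing attribute) and shares the core
`sojourn` column.

Per-individual event counts can be truncated at an empirical percentile of
the count distribution (with an additional hard cap), keeping the earliest
events.  Truncation deliberately removes the heaviest utilizers from the
modelled data; analyses of high-utilization individuals are out of scope for
cohorts prepared this way.

### Coding

The generative model is wholly categorical: both loss terms are
cross-entropies over a finite class set.  Categorical variables map to
1-based integer codes; originally-continuous variables (lab results,
resource intensity weights, age, sojourn) are **quantile-binned**
(default bin counts are declared per variable in the schema; 5–20 in the
bundled schemas).  Quantile binning preserves the marginal shape with equal
mass per bin.  Each bin decodes to the median training value inside it, so
decoded streams reproduce magnitudes up to bin resolution; duplicate
quantile edges (heavily tied data) are collapsed, so the effective bin count
can be smaller than requested.  Code 0 is reserved everywhere for
padding/missing.  Attributes outside the relevance set of a row's label are
forced to code 0 regardless of the source cell, which makes the
relevance map, not the raw table, the arbiter of missingness.

Sequences are chunked into fixed windows (default 120 events) padded with
zeros; chunk provenance (patient, ordinal) is kept so chunks re-assemble
losslessly.

## Generator

Architecture: independent embeddings per vocabulary (labels, each
attribute, each baseline variable); the embedded label and attributes are
concatenated and fed to an LSTM (1 layer by default, stackable); each
output head is a linear map over `[LSTM output ; embedded baseline]`.
Baseline variables therefore act as **main effects on the output logits** —
they shift the propensity of each next event type multiplicatively (in
probability space) from every state, the same structural form as covariate
effects in multinomial-logit or proportional-hazards models.  Interactions
between baseline and the current state are not representable at a single
step and can only be picked up through the hidden state's summary of
history.

Training uses teacher forcing (true previous events as inputs; next-step
prediction implies it) with the objective `loss_labels + λ·loss_attributes`
(λ default 1).  Padding positions are excluded from both averages: the
printed cross-entropy is averaged over real transitions only, so the model
is never rewarded for predicting padding.  A strict-formula switch
(`include_padding_targets`) restores averaging over all N·t positions.  The
attribute loss averages over the contributing (n, t, i) triples — the outer
mean is read as a mean over included terms — with a `sum` reduction
available that instead sums attribute terms per position.  Optional
per-label and per-attribute loss weights are exposed.  The hidden state is
reset between chunks of the same individual (windows are treated as
independent); carrying state across chunk boundaries is not implemented.

The network and its gradients are implemented directly in NumPy: standard
LSTM cell, backpropagation through time, per-head softmax cross-entropy
gradients, global gradient-norm clipping at 5, and Adam (default) or SGD.
Output heads initialize near zero so that the epoch-0 loss is close to
`ln C + λ·mean(ln C_i)` (the uniform-prediction value), a useful training
sanity check.  A non-finite loss aborts with diagnostics.  Training is
bit-reproducible given the seed and single-threaded BLAS.

Generation: the sequential tree synthesizer (below) provides baseline codes
and the first event; generation then iterates, sampling the next label from
the label head's softmax (temperature default 1.0; temperature ≤ 0 means
argmax), sampling each attribute relevant for the *sampled* label and
setting the rest to missing — so generated rows always have the same
missingness pattern as training rows — and feeding the sampled event back
with the carried state.  The padding class is excluded from sampling.
Sequences stop at the terminal label or the maximum length and are trimmed
at the first terminal event.  Dates are rebuilt by cumulating decoded
sojourn bin representatives, with the first event's sojourn forced to 0.

## Sequential tree seeding

Baseline variables and the first event's values are synthesized column by
column in a declared order (baseline variables, then the first-event label,
then its attributes): the first variable from its empirical marginal, each
later variable by routing the partial row down a decision tree fitted on
the earlier variables and sampling a real donor value from the reached
leaf.  Donor-pool sampling means no category is ever invented.  The minimum
leaf size defaults to 5 (variance control and privacy-adjacent smoothing);
a tree that cannot split degenerates to marginal sampling, which is logged.
Seeding runs on the integer-coded table, so drawn seeds are directly
consumable by the generator.

## Simulator (ground truth for testing)

The simulator emulates the *shape* of administrative health data — baseline
covariates, heterogeneous event types with per-type attribute sets,
variable-length sequences, an absorbing terminal event — with a first-order
Markov kernel per baseline stratum.  Specifics:

* Baseline: age ~ clipped normal, sex ~ Bernoulli, comorbidity ~ small
  ordinal; a single declared variable defines the stratum.
* Dynamics: per-stratum initial distribution and transition kernel (rows
  sum to 1 within 1e-9, terminal row absorbing); constant terminal hazard
  gives geometric sequence lengths, censored at `max_length`.
* Attributes: per-label categorical or location/scale conditionals; sojourn
  per label from non-negative integer families (geometric, Poisson).
* Bit-reproducible given the seed.

In the bundled two-stratum schema the strata differ by a **uniform
multiplicative shift of transition propensities** (less A, more B/C from
every state).  This is deliberate: main-effect shifts are the realistic
form of covariate effects on event dynamics, and they are exactly the
effect family the conditional architecture expresses through its
output-layer conditioning.  A pure label-by-stratum interaction (e.g.
permuted kernels between strata) is representable only through
history-based stratum inference and is not a regime the bundled tests
exercise.

What passing tests on simulated data do **not** show: robustness to
long-range (non-Markov) dependence, high-cardinality code vocabularies
(thousands of diagnosis codes), informative missingness beyond the
relevance map, calendar-time effects, or measurement error — all present in
real administrative data.

## Utility metrics

* Hellinger distance is computed as `(1/√2)·‖√p − √q‖₂` over the union of
  supports (algebraically `√(1 − Σ√(pᵢqᵢ))` for normalized inputs, but
  exactly 0 on identical arrays).  Attribute comparisons first filter to
  events whose label is relevant for the attribute; continuous attributes
  are discretized on quantile bins fitted to the real values (default 10).
  An attribute observed in neither cohort is reported undefined and
  excluded from summaries; observed in exactly one, it scores 1.
* Transition matrices of order k count length-(k+1) windows within
  individuals only; rows are renormalized before row-wise comparison (this
  also tolerates published matrices whose printed rows round to ≠ 1).
  Contexts present in only one matrix score distance 1 by default
  ("missing structure is maximal dissimilarity") or can be skipped.
* The multivariate Hellinger distance is `√(1 − exp(−BD))` with BD the
  Gaussian Bhattacharyya distance of the two tables' means/covariances;
  inputs are numeric-encoded (categoricals as integer codes, missing as 0)
  and covariances receive a `1e-6·trace/d` diagonal ridge.  The distance is
  affine-invariant, and on one column it reduces to the univariate normal
  closed form.
* The random-cohort assessment materializes both cohorts (events joined
  with baseline) in an embedded SQLite engine and fuzzes up to 3
  conjunctive predicates (categorical equality / numeric range, values
  drawn from the real data) plus either one scalar aggregate (COUNT or
  AVG) or one categorical GROUP BY.  Grouped results are compared by
  Hellinger distance on normalized group counts; scalar aggregates by the
  normalized Euclidean distance `|a−b|/√(a²+b²)` (0 when both are 0 —
  the exact normalization is a documented package choice).  Queries empty
  on both sides are skipped and counted; empty on one side scores 1.  The
  full query text is retained for audit.
* SMD: `|m₂−m₁|/√((s₁²+s₂²)/2)` for continuous variables and the pooled
  binomial-variance analogue for proportions; absolute (sign-free) values,
  symmetric and scale-invariant; both-degenerate cases return 0 on equal
  parameters and flag infinity otherwise.  CI overlap returns
  `100·½·(L/w₁ + L/w₂)` with L the intersection length; a zero-width
  interval contributes 1 if its point lies inside the other interval.
  Published CI-overlap percentages computed from unrounded interval bounds
  will differ slightly from values recomputed from rounded printed bounds.

## Privacy estimator

The attribution-disclosure assessment partitions each dataset into
equivalence classes on quasi-identifiers (default: age banded to 5-year
groups, sex, and death/hospitalization indicators derived from the presence
of the corresponding event labels; missing QI values form an explicit
band).  For each attacking record with a non-empty matching class in the
target dataset, the contribution is `1/(class size)` times an indicator
that the class-majority vote on a declared sensitive attribute equals the
attacker's true value ("learns something new"); the risk is the mean
contribution over all attacking records.  Both directions are computed
(population→sample: real attacks synthetic; sample→population: the
reverse) and the larger risk is compared to the 0.09 threshold (equivalent
to a minimal group size of 11 under maximum risk).  This estimator is an
interpretation of the matching + learn-something-new structure of the
published attack model — the underlying methodology has additional
refinements — and the learn indicator is pluggable.  Risk never exceeds the
reciprocal of the smallest matched class, and coarsening QI bands never
increases it.

## Problem sizes and tolerances

The test suite exercises the full pipeline at desk scale: the recovery
experiment trains on 2,000 simulated individuals (4 event labels, 2
attributes, 2 strata, sequences up to 60 events) for 40 epochs with hidden
size 32 — about a minute on one CPU — and requires the generated cohort's
per-stratum first-order transition matrix to be within sampling noise
+0.05 (Hellinger per row) of the generating kernels and the mean sequence
length within 5% of the real cohort's.  Deterministic chains must be
recovered exactly.  Loss and metric oracles are checked against direct
summation at 1e-12 relative tolerance; the multivariate/univariate
agreement at 1e-9.

## Known limitations

* The recurrent core is CPU-NumPy; it is appropriate for cohorts up to the
  tens of thousands of individuals, not for GPU-scale corpora.
* Continuous attributes are modelled only through bins; extreme tails
  beyond the outermost quantile edges are compressed to the edge bins, so
  outlier magnitudes are preserved only up to bin resolution.
* Cox model fitting is out of scope: the package provides the SMD and
  CI-overlap comparison operators around externally fitted estimates, not
  the survival models themselves.
* No differential-privacy accounting; the privacy guarantee is the
  empirical attribution-disclosure estimate only.
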