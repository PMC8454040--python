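# Methods

## The model

`latentpath` treats chemistry as geometry. A backend embeds every compound
structure into a fixed-dimension latent space as two vectors — a *tree* part
intended to capture the overall backbone and a *graph* part for the full
molecular graph — and can decode a latent point back to a structure. Under
this embedding:

- an enzymatic reaction is the difference vector of its main product and main
  substrate, `r = z_pro − z_sub`, tagged with its EC number and the exact
  molecular-weight change of the registered pair (cofactors and co-substrates
  are ignored; a reaction *is* its main pair);
- a desired transformation is the pathway vector `p = z_target − z_start`;
- a pathway is a set of registered reaction vectors whose sum approximates
  `p`; intermediates are the decoded cumulative sums
  `z_k = z_start + Σ_{j≤k} r_(j)`.

Latent dimensions are declared by the backend, never assumed: the toy
chemistry defaults to small equal tree/graph parts, while an adapter around a
pretrained generative encoder would declare that model's own bottleneck
dimensions (how a combined bottleneck splits between tree and graph parts is
an adapter decision, exposed as configuration).

The working assumption is that reactions catalysed by the same enzyme class
produce similar latent displacements wherever they apply. The `evaluation`
module tests that assumption directly: linear discriminant analysis classifies
reaction vectors into EC classes truncated to 1–3 dotted fields (classes with
fewer than two members excluded), under stratified cross-validation, and a
3-digit confusion matrix can be aggregated up to 2 digits by summing entries.
Comparisons between tree, graph and combined parts run on identical folds.

## Pathway design

Design repeats five steps: compute `p`; sample a uniform random subset of `M`
reaction features; select a subset of those by binary differential evolution;
order every selection and reconstruct intermediates; prune unrealistic
orderings. Selection minimises

    f(x) = |e|² + λ,   |e|² = ‖p − Σᵢ xᵢ rᵢ‖²,
    λ = 0 for x_len ≤ K,  λ = C · exp(x_len)² = C · e^(2·x_len) otherwise,

over binary x, with DE/rand/1: three mutually distinct parents (all distinct
from the current individual), mutant `v = x_a + F (x_b − x_c)` rounded to
binary at 0.5, uniform crossover at rate CR, greedy replacement on fitness.
The written exponent of the penalty is ambiguous between `(e^x_len)²` and
`e^(x_len²)`; the first reading is the default and the second is one
configuration flag away (`penalty_mode`). Two deliberate deviations from a
bare-bones DE, both documented and switchable:

- one crossover component is always taken from the mutant
  (`guaranteed_crossover`, default on) so a trial never duplicates its parent;
- the integer formulation (a reaction used up to K times) is *not*
  implemented; the printed binary algorithm is.

Early termination stops a run once the best `|e|` falls below the error
threshold Th. Selections with `|e| ≤ Th` are expanded into all `len!`
orderings; each ordering's strict intermediates and final point are decoded,
and the pathway is removed if any segment's decoded ΔMW deviates from the
registered ΔMW of that segment's reaction by more than the tolerance
(default ±3 u), or if a segment endpoint fails to decode (the rule cannot be
evaluated, and an undecodable intermediate is itself implausible). Candidates
are deduplicated by ordered EC list plus ordered substrate/product pairs.

Reference parameter values, used as defaults: F = 0.5, CR = 0.5, C = 1000.0,
Th = 50.0, population 2000, at most 50 generations, subset size 500, K = 3,
2000 repetitions, MW tolerance ±3. Desk-scale runs (tests, demos) override
population (≈50), generations (≈30), subset size (≈60) and repetitions (≈8),
which keeps a single exploration under ten seconds while preserving recovery
of 1- and 2-step planted pathways. `subset_coverage_probability` gives the
hypergeometric probability that all reactions of a planted solution land in a
subset of size M — increasing in M, which quantifies the trade-off between
subset size and per-repetition cost.

## Possibility scoring

A small binary classifier cannot say "plausible but unregistered"; a voting
ensemble can. Training data come in four recipes over a reaction DB and a
compound set: REAL (registered pair, its own substrate; label 1), VIRTUAL1
(registered pair, substrate swapped for another compound), VIRTUAL2 (random
non-registered pair, that pair's own substrate), VIRTUAL3 (random pair, an
unrelated third compound). Random pairs exclude registered pairs, which would
otherwise be mislabelled negatives. Each of Q combined datasets is the full
real data plus one virtual dataset; R-fold stratified cross-validation yields
R models per dataset, Q × R in total. Each model is a standardisation +
multilayer-perceptron pipeline with hidden layers (64, 32, 8), ReLU
activations and a thresholded binary output, trained with Adam on log-loss
(the binary-output contract fixes the interface; the training loss is an
implementation choice). Determinism comes from derived integer seeds for fold
shuffles and weight initialisation.

The vote fraction over all Q × R models is the reaction-possibility value
`v_r`; a pathway's feasibility is `v_p = Π v_r` over segments (never
increasing in pathway length), and the final score is `s = |e| / v_p`, lower
better, with `v_p = 0` scoring +∞ and ranking last. The typeset score formula
is ambiguous between a ratio and a product; the ratio is the default because
the intended behaviour is that among near-exact candidates the most feasible
pathway ranks first, and a product would instead reward low feasibility. The
product reading is available as `score_mode="product"`. Ties at equal score
are broken by higher feasibility, then lower `|e|`.

Whether summary statistics should be computed on held-out folds is not fixed
by the method; `summarize_possibilities` reports full-ensemble voting on the
given examples, `held_out_real_possibility` reports strictly out-of-fold votes
for the real training examples, and virtual-recipe summaries are computed on
freshly generated examples that never entered training.

## The synthetic world

`simulate` builds the study conditions for every test: a toy chemistry whose
compounds are non-negative integer fragment-count vectors, encoded by an exact
full-rank linear map (so reaction arithmetic is exact and planted pathways
satisfy `|e| = 0` identically), with exact molecular weights and
nearest-compound decoding (ties to the lowest compound id). Class structure:

- each synthetic EC class has a distinct integer fragment-change *motif*;
  class reactions apply the motif, optionally perturbed by ±1 on one fragment
  (`perturb_prob`, default 0.25), so reaction vectors cluster by class with
  tunable within-class noise; `separation` scales motifs (0 collapses
  classification to chance);
- each class has an *anchor fragment*: substrates carry 4–7 copies while
  unrelated compounds carry 0–2 of any fragment, and the class motif consumes
  2–3 copies of the anchor. Substrate specificity is therefore coupled to
  product validity — applying a reaction to a non-substrate implies a
  negative fragment count — which is the learnable cue that separates
  "substrate in" from "substrate out" examples;
- synthetic EC numbers are hierarchical (`a.b.c.serial`) with several 3-digit
  classes per 2-digit prefix, so confusion-matrix aggregation is exercised;
- planted queries are chains of unperturbed motifs registered like any other
  reaction; since unperturbed same-class reactions share an identical feature
  vector, planted-pathway recovery is identified at the 3-digit-class level.

The benchmark world for the four-recipe possibility experiment
(`scoring_benchmark_world`) uses 1,000 reactions over 12 classes with 12
fragments and a 12-dimensional latent per part. Two properties of the
reference setting motivated those sizes: the combined training dataset there
is nearly class-balanced (≈10⁴ real vs 10⁴ virtual records), so one real
dataset of 1,000 balances one 1,000-record virtual dataset; and real reaction
space is far too diverse for the reaction vector alone to give away pair
realness, so the class count is large enough that models must also use the
substrate. Under these conditions the recipe means reproduce the qualitative
2×2 structure — Real/in ≈ 0.99, Virtual/out ≤ 0.09, with the strict ordering
Real/in > Real/out > Virtual/in > Virtual/out — on all five master seeds
exercised by the acceptance suite.

What the toy world does *not* emulate: continuous, noisy latent geometry
(every toy latent is exact, real encoders are not), decode failures (toy
decoding always returns the nearest compound; the pipeline nevertheless
treats decode failure as a represented outcome), isomerism, cofactor
chemistry, and any relation between fragment masses and plausibility beyond
the ΔMW bookkeeping. Passing tests therefore demonstrate the correctness and
internal consistency of the machinery — vector arithmetic, search, pruning,
voting — not chemical accuracy of a particular embedding.

## Numerical and degenerate-case choices

- Nearest-reaction search and DE residuals use Euclidean distance, consistent
  with the squared-error objective; nearest-neighbour ties keep DB order.
- Latent equality tests in the suite use exact comparison where construction
  is exact and `atol ≤ 1e-9` where float summation is involved.
- Decode ties resolve to the lowest compound id; universes are stored in
  sorted-id order so `argmin` realises the tie-break.
- Stratified folds shrink to the smallest class count when a class is rarer
  than the requested fold count; a degenerate single-class training fold is
  re-stratified with a fresh shuffle before erroring.
- The empty selection is part of the DE search space (no penalty) and of the
  exhaustive oracle; the design loop discards it.
- All randomness flows from integer master seeds through
  `numpy.random.SeedSequence` spawning; per-repetition, per-dataset and
  per-model seeds are derived, never shared.

## Known limitations

- With three or more reaction steps, the probability that every needed
  reaction lands in one random subset falls quickly, and recovery degrades —
  the acceptance suite asserts only non-zero 3-step recovery.
- The real/virtual boundary in the toy world is sharper than real chemistry;
  absolute possibility values (as opposed to their ordering) should not be
  read as calibrated probabilities.
- `ToyChemistry.decode` never fails; backends wrapping generative decoders
  should return `None` on failure, which the pipeline already handles
  (segment flagged, pathway removed at pruning).
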