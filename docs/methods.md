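# Methods

## Model

The interactome is a signed, (optionally) directed graph over proteins keyed
by UniProtKB-style accessions. A *stimulus* clamps each drug-target node to
its action sign (+1 activation, −1 inhibition). All other node activities
follow the damped saturating update

    a_i ← (1 − λ)·a_i + λ·tanh( Σ_j w_ji · sign_ji · a_j )

iterated synchronously from zero until `max|Δa| < tol` or an iteration cap.
Undirected edges transmit in both directions; directed edges only
source → target. The form is the minimal bounded, sign-preserving
propagation rule: activities stay in [−1, 1] (tanh plus a convex update),
clamped nodes hold their stimulus exactly, and negating the stimulus negates
the fixed point (odd symmetry — there are no bias terms).

Trainable parameters are the edge-weight *magnitudes* in [0, 1]; edge signs
are fixed by the interactome. This keeps every trained solution readable as a
signed mechanism: an edge either transmits its catalogued activating or
inhibiting influence with some strength, or is silent.

Defaults: λ = 0.5; for reporting-grade propagation tol = 1e-6, max_iter = 100.
During training the budget is tol = 1e-4, max_iter = 60: on hub-heavy
networks the linearized convergence rate approaches 1 and machine-precision
fixed points are unnecessary — satisfaction decisions depend on activity
floors of 0.05–0.1, three orders of magnitude above the resolved error.

## Constraint satisfaction

A truth-table restriction relates a drug (stimulus) to a condition
characterized by signed effectors. The positive criterion: a strict majority
of the mapped effectors must respond in the expected direction
(pathological direction for "induces", its opposite for "treats") with
|activity| ≥ τ_act (default 0.1). Exact ties are unsatisfied. A label-false
restriction is satisfied exactly when the positive criterion fails.
Restrictions whose effectors are entirely absent from the network are
indeterminate and excluded from accuracy. The majority aggregation is a
design choice — multi-effector conditions need some aggregation rule, and
majority is the weakest one that still forces a condition-level response
rather than a single-protein response.

## Training

Each solution is found by simulated annealing over the weight vector
(geometric cooling, T₀ = 1.0, ratio 0.95, 200 steps), starting from all-zero
weights, with an objective of mean restriction satisfaction minus a small
parsimony penalty (0.01 × mean weight). Three proposal moves:

* **mechanism-guided** (p = 0.5): pick a violated restriction; for a positive,
  strengthen one shortest stimulus→effector path per non-responding effector
  until a strict majority could respond, preferring paths whose sign parity
  already yields the expected direction (sampling among tied shortest paths);
  for a violated negative, weaken the inputs of the effectors responding
  pathologically.
* **Gaussian** (residual probability): perturb a random 5% of weights by
  N(0, 0.2), clipped to [0, 1].
* **sparsify** (p = 0.25): zero a random tenth of the active weights.

After annealing, a minimality pass removes every weight whose deletion does
not reduce training accuracy (bulk sweeps at increasing floors, then
edge-by-edge in random order). Solutions are therefore sparse mechanistic
hypotheses: the edges that remain are those needed to satisfy the
constraints. The zero start plus minimality is what makes ensemble
interaction frequencies informative — an edge is frequent across solutions
because it is repeatedly *needed*, not because it was never cleaned up.

Ensembles derive per-solution seeds from the master seed by a counter-based
splitmix64 stream, so they are reproducible and order-independent. Solutions
below the accuracy floor (default 0.9) are retrained once from a fresh
derived seed, then kept flagged. The best-so-far accuracy trace is recorded
and is non-decreasing by construction.

## Relationship scoring

A (stimulus set, response set) pair is described by eight permutation-
invariant features: mean |activity| over response proteins, the fraction
responding in the expected direction, the sign-parity agreement of the
shortest mechanism path per effector, mean and minimum shortest-path
distance between the sets (unreachable pairs use the sentinel
diameter + 1), both set sizes, and the overlap count. Activities come from a
trained ensemble's mean prediction when available, otherwise from unit-weight
propagation.

The classifier is a single-hidden-layer (16 unit) MLP. With desk-scale truth
tables (a few dozen examples) a held-out early-stopping fold is noise-
dominated, so capacity is controlled by an L2 penalty (α = 1.0) and the fit
uses lbfgs. Scores are 100 × predicted probability of a true relationship.
Categories use the fixed bins high [77, 100], medium [38, 77), low [0, 38) —
the operational definition of the reporting scale — with boundary values 77
and 38 belonging to the upper bin of their interval notation. An empirical
add-one permutation p-value, p = (1 + #{null ≥ score}) / (1 + N) against
≥ 99 random same-cardinality protein-set pairs, is reported alongside; the
fixed bins are authoritative for categorization.

## Comparison analyses

An edge is *active* in a solution when its weight magnitude exceeds ε_w and
signal reaches it: the upstream endpoint's converged |activity| exceeds ε_a
(for undirected edges the more active endpoint counts as upstream); both
default 0.05. The interaction-frequency map divides active counts by the
ensemble size. The representation threshold is the smallest candidate
frequency whose retained subgraph has at most `max_nodes` (default 30)
nodes — maximal retained frequency mass subject to readability, ties toward
the smaller threshold.

The perturbed protein set of an MoA model is the set with mean predicted
|activity| above τ_pert (default 0.05), excluding clamped stimulus nodes
(the analysis concerns *indirectly* driven changes). When two combinations
are compared, the exclusion is the union of both stimuli: a protein clamped
by one combination cannot be meaningfully compared as an indirect effect of
the other, and under this definition the nested-stimulus full-overlap
property is exact for nonnegative weights (the fixed point is monotone in
the stimulus support). Differential activity is the per-protein difference
of mean predicted activities, significant when |Δ| strictly exceeds 0.5;
proteins absent from one model's network default to activity 0 ("not
detected").

## Synthetic scenarios

Generators emulate the shape of the curated inputs with known ground truth:

* interactomes are Barabási–Albert preferential-attachment graphs (heavy-
  tailed degrees, as in protein interaction networks), each edge
  independently inhibitory with probability `p_negative_sign` (default 0.2),
  connected by construction;
* drugs and conditions are disjoint random target/effector sets (drug
  actions default to activating, mirroring the coagulation agents; effector
  directions are random signs);
* mechanisms are planted as signed paths (length ≤ `path_len`, default 2)
  from every drug target to every effector of the paired condition, reusing
  an existing shortest path when its sign parity already matches and adding
  edges otherwise, so the planted pair is genuinely satisfiable under the
  strict-majority criterion;
* truth tables label planted pairs positive and sampled unplanted pairs
  negative, with independent label noise (default 5%);
* adverse-event counts are binomial draws at specified per-trial frequencies.

The default scale — 300 nodes at mean degree 4, 8 drugs × 2 targets,
4 conditions × 3 effectors, 2 planted conditions per drug, 16 + 16 labeled
pairs — gives non-trivial multi-hop mechanisms while keeping a 100-solution
ensemble run in the low minutes on one core. All generators are pure
functions of (parameters, seed).

The `hemophilia_toy_scenario` wires the three printed drug characterizations
(emicizumab→FX↑; rFVIIa→FVII↑; aPCC→FII, FVII, FIX, FX, KNG1, KLK1, all ↑)
into a small all-activating generated interactome, preserving the
combination-stimulus nesting that drives the full-overlap analysis.

The `recovery_scenario` is the parameter-recovery instance: default scale,
a single drug planted into a single condition at path length 1 (direct
signed edges), noise-free labels. Direct planted edges are uniquely
shortest, making the mechanism identifiable; on multi-mechanism scenarios
with tied shortest paths, edge-level recovery would measure tie-breaking
rather than inference.

What the synthetic data does *not* emulate: literature-curation ambiguity,
interactome false positives/negatives, correlated label errors, dosing and
quantitative pharmacology (the model is qualitative throughout), and the
composition of real pharmacovigilance extracts. Passing tests therefore
demonstrate internal correctness and recoverability under the generative
assumptions, not clinical validity on real inputs.

## Numerical and degenerate-input choices

* Undirected edges are stored once under lexicographic endpoint order.
* Seeds missing from the interactome yield a coverage report, not a failure;
  an entirely unmapped seed set is an error.
* Duplicate truth-table entries deduplicate with a warning; conflicting
  labels for the same (drug, condition, relation) raise.
* Event names compare case-insensitively after whitespace normalization.
* Non-convergence of propagation is flagged on the returned state, never
  raised; non-finite weights are rejected at construction.
* Frequency-threshold optimization returns the largest candidate when no
  threshold meets the node budget.
* In `compare_combinations` the ensemble seed is derived from the stimulus
  content, so identical stimuli always produce identical MoA models under a
  fixed master seed.

## Problem sizes used in validation

The packaged validation suite trains classifiers on ten 32-restriction truth
tables (seconds) and one 100-solution ensemble on the 300-node default
scenario plus one on the recovery instance (a few minutes together on one
core). These sizes were chosen so the whole suite runs on a laptop while
leaving the planted-mechanism structure non-trivial.

## Known limitations

* The propagation rule and training objective are this package's own
  formulation of constraint-trained signal propagation; published ensemble-
  modeling platforms in this space are proprietary and may differ in
  functional form, objective, and solution-diversity mechanism.
* Accuracy on noisy truth tables is bounded by flipped labels that become
  (un)satisfiable; the accuracy floor (0.9) absorbs a small number of flips
  at the default scale.
* The relationship classifier is only as good as its features; on real
  interactomes with dense shortcuts, distance-based features lose contrast.
* Edge-level mechanism recovery is only meaningful for identifiable planted
  mechanisms (see above).

One consistency rule matters in the pipeline: relationship scores are always
computed with the same featurization mode the classifier was trained on
(untrained unit-weight propagation). Mixing modes — training on untrained
features and scoring on ensemble-derived ones — shifts the feature
distribution and collapses the scores; the trained ensembles instead feed
the frequency, overlap and differential analyses.
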