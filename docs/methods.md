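# Methods

## The model

`wordrep` simulates a word-repetition experiment with a discrete-state
active-inference agent. The generative model is a three-epoch partially
observed Markov decision process with three hidden factors — **epoch**
(listen → repeat → feedback, a fixed chain with an absorbing final state),
**target word** (red, blue, triangle, square; identity transitions) and
**repeated word** (red, *read*, triangle, square, blue; fully controllable,
one action per sayable word) — and three outcome modalities:
**proprioception** (still/moving; moving only while repeating),
**audition** (the heard word: the target in epoch 1, the spoken word in
epochs 2–3, with the spurious level "read" pronounced like "red") and
**evaluation** (neutral/positive/negative; informative only at epoch 3,
positive iff the spoken word *sounds like* the target, so "read" is
accepted for target "red").

All conditional distributions are Dirichlet-parameterized by
pseudocounts: plausible entries start at concentration 1 and implausible
entries at 0.5. Initial-state counts are 10 on every target and
repeated-word level and concentrated on epoch 1 (non-initial epochs get a
floor of e⁻¹⁶, because a literal zero count has no finite expected log).
The agent holds five deep policies, one per word, each repeating its
word-action at both transitions. Log-preferences put +0.5 nats on a
positive evaluation at epoch 3; the action precision is α = 16 and the
policy-precision prior rate is β = 1.

## Belief updating

State inference under each policy is exact mean-field coordinate ascent
(CAVI) on the variational free energy of the full three-time-point
trajectory, re-run every epoch with all outcomes observed so far.
Messages use Dirichlet expected logs (digamma differences) for both
likelihood and transition counts; at small counts this amplifies the
plausible/implausible contrast (a 1-vs-0.5 transition column behaves with
≈0.57 rather than 0.4 persistence), which is what lets trajectory beliefs
persist well enough for learning to get off the ground. Up to 16 sweeps
per epoch, full-step updates, early stop when the free-energy decrease
falls below 1/128 nats; exact coordinate updates guarantee monotone F. A
floor of e⁻¹⁶ is applied inside every logarithm.

Policies are scored by their free energy F plus γ-weighted expected free
energy G over the remaining time points. Policies inconsistent with
actions already taken are pruned — the agent knows what it did — which is
essential for credit assignment: without pruning the repeated-word state
stays uncertain and likelihood learning smears across contexts. G
combines risk, ambiguity (expected likelihood conditional entropy) and,
while learning is enabled, the expected information gain about the
likelihood and transition pseudocounts (novelty). The risk term is
switchable (`InferenceSettings.risk`): the KL divergence of predicted
outcomes from the preference distribution during learning, and plain
expected log-preference (utility) once learning is frozen. The KL form's
prediction-entropy bonus is what drives epistemic exploration during
acquisition, but with preferences as weak as 0.5 nats it makes
uninformative (flattened or lesioned) mappings *attractive* — an agent
evaluated with it prefers saying "read" — so evaluation runs are scored
exploitatively. The policy precision γ = 1/β follows the usual fixed
point β = β₀ + (π − π_G)·G iterated jointly with the policy posterior;
actions are sampled from softmax(α·ln marginal).

## Learning

Likelihood counts accumulate the outer product of the end-of-trial
Bayesian-model-average state expectations with the observed outcome, one
unit per epoch (learning rate 1, no decay). Transition counts accumulate
*two-slice pair marginals* ξ(s′,s) ∝ B(s′|s)q(s)·[q(s′)/(Bq)(s′)] — the
forward–backward smoothed pair, not the product of marginals — scaled by
the confidence (negentropy) of both marginals. A plain outer product of
diffuse marginals loses the within-trial correlation that identifies
persistent states and accumulates a rank-one "everything maps to the
average" matrix.

Transitions of the target word are a special case: the target is observed
(auditorily) only once per trial, so beliefs about its later time points
derive from the very transition prior being learned. Learning it online
is circular and empirically collapses — early sampling noise feeds back
through inference until every word maps to the same successor, regardless
of confidence gating. Its pair counts are therefore accumulated in a
buffer during the acquisition phase and consolidated in a single offline
update at the end (`consolidate_transitions`), in the same spirit as the
offline/sleep structure-learning step below. Initial-state counts are
never learned.

## Structure learning and lesions

Removing the spurious state ("structure learning") sets every audition
likelihood concentration conditioned on repeated word "read" to 10,
making its normalized columns uniform — the state is disconnected from
the outcome it generates. Only the audition mapping is flattened by
default: flattening the learned evaluation mapping as well would hand the
disconnected state uniform (hence agreeable, under weak preferences)
predictions and turn it into a behavioral attractor instead of a
redundant alternative.

Lesions are precision reductions: each conditional column p of the
targeted array is replaced by normalize(p^η), with column totals
preserved, so the strongest connections weaken and the weakest
strengthen; η = 1 is a no-op. The extrinsic ("A") lesion applies η = 0.4
to the evaluation likelihood; the intrinsic ("B") lesion applies η = 0.5
to the target-word transitions. Lesions are applied to the post-learning
(and, for nonspurious groups, structure-learned) models, with further
learning disabled.

## Measures

Each epoch, for each hidden factor, the package assembles the bundle
F = complexity − accuracy = energy − entropy, with
redundancy ≡ complexity = KL[Q‖P] of the posterior trajectory against the
pre-epoch predictive prior (the previous epoch's Bayesian model average;
the D-based policy-averaged predictive at epoch 1), accuracy the expected
log-likelihood of the observed outcomes shared equally across factors,
and the companion identity redundancy = cost − degeneracy. Degeneracy is
scored on the beliefs about the *present* time point by default
(`AggregationSpec.entropy_scope`), reading degeneracy as uncertainty
about the causes of the current sensation, while complexity scores the
full trajectory shift; cost is defined as complexity + entropy so the
identities hold under either scope.

Aggregation to one scalar per trial is configurable: the default — sum
over time points and hidden factors, mean over epochs, present-scope
entropy — was fixed once against the post-learning control-condition
benchmark values used by the acceptance suite and then left alone. Because all reductions are linear, the
decomposition identities survive every choice. Behavioral accuracy is the
percentage of unforced trials ending in a positive evaluation — distinct
from the statistical accuracy term above.

## Simulated electrophysiology

The per-sweep belief snapshots within each epoch are read as a neuronal
gradient flow; a population's firing rate is a selected expectation
(default: the predicted probability of a positive evaluation at epoch 3,
computed under the same model that generated the record), each epoch
spans 250 ms of peristimulus time, snapshots are linearly interpolated,
and the simulated LFP is the first temporal derivative. Mismatch waves
are deviant-minus-standard differences between a trial whose final
evaluation is forced positive and one forced negative (same seed, so the
histories agree up to that outcome), using the nonspurious models with
the target fixed to "red". Group traces are subject means. No filtering
or smoothing beyond the interpolation is applied.

## What the simulation does and does not establish

The environment is the idealized deterministic experiment: outcomes are
the modal consequences of the true states, targets are drawn uniformly,
and the only noise is in the agent's own action sampling. Passing tests
therefore show the *internal* consistency of the decomposition and the
direction of learning and lesion effects under these idealized
conditions; they say nothing about acoustic variability, response
latencies, or any empirical population.

Two known divergences from the benchmark values in the acceptance suite
are structural, not tunable. First, this scheme acquires the task from
genuinely naive likelihoods, so belief updating (redundancy) *grows* as
the model sharpens; any quantity defined as a learning-phase average, or
as a learning-phase-minus-post-learning difference, depends on that
trajectory shape and comes out much smaller here than under a scheme
whose early updating is large and declines. Second, the precision
lesions degrade decision margins smoothly, and the dual-lesion group
retains partial competence rather than collapsing fully to chance; the
superadditivity of deficits survives, but the dual-lesion magnitudes
(behavioral accuracy, redundancy, the near-flatness of the lesioned
mismatch trace) are milder than the benchmarks. Both are left visible in
the test expectations rather than patched over.

## Problem sizes and determinism

The canonical run is 50 subjects × 500 learning trials plus eight
evaluation groups of 50 × 10 trials (≈4–5 minutes on one core);
violation-paradigm traces use 20 subjects. Subject s draws its rng from
`base_seed + s` with documented offsets separating learning, evaluation
and violation streams; identical seeds reproduce identical tables
bit-for-bit.
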