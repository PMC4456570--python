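# Methods

## Model

The package simulates discrete-time networks of McCulloch–Pitts binary
threshold cells connected by binary synapses. Every plastic projection is
a Willshaw associative memory: storage is clipped Hebbian
(`w_ij(t+1) = w_ij(t) ∨ (x_i ∧ y_j)`, weights start at 0 and only ever
grow), and recall is a single synchronous pass with the classical
Willshaw threshold θ = number of active input cells; a cell exactly at
threshold fires. Recall quality is always measured as the Hamming
distance between the retrieved and the target pattern.

The proposed hippocampal model composes three plastic projections —

* `W_e` (n × n): exteroceptive autoassociation (pattern completion),
* `W_i` (m × m): interoceptive autoassociation over the one-hot valence
  codes,
* `W_ev` (n × p·m): heteroassociative links from the exteroceptive cells
  onto p ordered groups of m intermediate valence cells —

plus two *prewired, non-plastic* structures in the valence layer: an
inhibition matrix `I` (cell i inhibits cell j iff group(i) > group(j);
none within a group) and a one-to-one projection from each valence cell
to the interoceptive cell of the same within-group position.

A trial has three phases. (1) Recall cascade: the exteroceptive cue is
completed by `W_e`; the completed pattern drives the valence layer
through `W_ev` (threshold = number of completed-pattern active cells);
inhibition leaves at most the highest-indexed excited group active; the
surviving activity projects into the interoceptive network, whose recall
is the valence prediction. (2) Evaluation: completion mismatch
HD(â⁽ᵉ⁾, a⁽ᵉ⁾) is compared against the exteroceptive novelty threshold e
and prediction mismatch HD(â⁽ⁱ⁾, a⁽ⁱ⁾) against the valence threshold v
(strict inequalities); in parallel, each valence group's post-inhibition
activity is compared with the afferent valence — an active group whose
activity mismatches beyond v raises the interference flag Ξ for that
group. (3) Learning: if either novelty signal fired, activity is driven
purely by the afferent patterns and the clipped updates are applied.
The afferent valence is placed onto the primary group and onto any group
whose gate was opened by Ξ at its predecessor; inhibition resolution
keeps the highest-indexed of these, which receives the `W_ev` update.

### Adopted readings and numerical choices

Several points of the recall/learning rules admit more than one reading;
the package fixes them as follows.

* **Threshold at exactly 0 input.** An all-zero cue would make θ = 0 and
  fire every output cell under the printed rule; the package returns an
  all-zero output instead ("no input, no recall"), which is the only
  behaviour consistent with how recalled activity is used downstream.
* **Self-connections** are learned in the autoassociative stores (the
  literal update rule does not exclude i = j). This is what makes
  full-cue recall of a stored pattern exact; a switch can exclude the
  diagonal for study.
* **One-pass inhibition.** Only later→earlier inhibitory wiring exists,
  so the shunting dynamics have a unique fixed point — the
  highest-indexed excited group survives — and the closed form is used
  instead of iterating the settling process.
* **Interference is computed on post-inhibition activity**, hence at most
  one group can flag interference per trial and escalation to group k+2
  requires a later trial. This is what makes several training blocks
  necessary to clear all conflicts in a large stimulus set.
* **Gating is per-trial**: interference flags and gates are recomputed
  from each trial's recall and never persisted; the only persistent state
  is the weights.
* **Capacity exhaustion.** If interference is flagged at the *last*
  group, no further group can be recruited; the heteroassociative update
  is skipped (writing into an already-conflicted group cannot resolve the
  conflict) and the trial is flagged, while the autoassociative stores
  still proceed. With p = 1 there is no associated-group machinery at
  all: conflicts are re-written directly into the primary group, which is
  precisely the simple heteroassociative baseline (and why its errors
  persist).
* **Recall is feedforward and single-pass**; the autoassociative networks
  are not iterated to an attractor fixed point.

### Baselines

The *standard autoassociative* model stores each stimulus as the
concatenation `[a⁽ᵉ⁾ | a⁽ⁱ⁾]` in one (n+m)² Willshaw network. Recall
cues carry zeros in the interoceptive segment and θ counts only the
exteroceptive cue cells — the only convention under which full-cue recall
of a stored pair is exact. Completion and prediction errors are the
Hamming mismatches of the two segments. The *simple heteroassociative*
model is the proposed model with p = 1.

## Synthetic data

The generator reproduces the study's stimulus statistics: exteroceptive
patterns over n = 300 cells with exactly k = 8 active cells drawn
uniformly without replacement (k ≈ log₂ 300, a density at which Willshaw
recall of ~100 stored patterns is essentially error-free), and valences
drawn uniformly from {positive, negative, neutral} one-hot codes. Partial
cues silence d ∈ 1..7 uniformly chosen active cells. The reversal task
allocates 8 cue cells and 8 disjoint 7-cell context blocks (64 cells
total) and composes three groups of four stimuli with the prescribed
valence signs; group 2 pairs new cues with old contexts, group 3 old cues
with new contexts, both with reversed valence.

What the generator does *not* emulate: correlated or hierarchically
structured feature statistics, graded activity, multiple simultaneous
interoceptive dimensions (arousal, somatic states), and pattern overlap
beyond chance. Passing tests therefore speak to the interference
mechanism under decorrelated sparse input, not to performance on
naturalistic stimuli, where upstream pattern separation would have to
supply the decorrelation.

Randomness is controlled by one master seed per experiment; each
replicate derives named substreams (stimuli, valence assignment, block
shuffling, cue degradation) from `SeedSequence([seed, run])`, so every
output is reproducible piecewise and byte-for-byte. The model core is
pure integer arithmetic, so results are platform-independent.

## Experiments and problem sizes

All experiments follow the block/trial protocol: a block is one pass
through the stimulus set in fresh random order; training trials learn
when a novelty signal fires; test blocks run with learning disabled.
Means over 20 independent replicates are reported with symmetric 95%
t-based confidence intervals (a single replicate degenerates to a point
interval).

* **Capacity**: N ∈ {10..100} stimuli, 1–5 training blocks, full-cue test
  block after each; also records per-block interference detections and
  the number of associated groups structurally in use (nonzero `W_ev`
  columns).
* **Partial cue**: N = 100, every stored pattern cued with d ∈ 1..7 of
  its 8 cells silenced; completion reported both as % of trials with
  HD ≥ 1 and as mean HD, prediction as % of trials with any valence
  mismatch.
* **Thresholds**: 10 initially neutral stimuli, valences re-drawn
  uniformly (so ~2/3 change), one retraining block under
  (e, v) ∈ {(0,0), (2,2), (2,0)}; with v = 2 a changed one-hot valence
  (HD = 2) is tolerated and never relearned, producing errors on the
  changed two-thirds, while v = 0 detects every change.
* **Reversal**: 4 acquisition blocks over the original 4 stimuli, then 4
  blocks over all 12; errors are scored on the training trials (the task
  is continual) and split into old/new subsets.

These sizes match the study conditions; the test suite runs the full
20-replicate versions in seconds because each trial is a handful of
dense 300-cell integer matrix-vector products.

## Known limitations

* A faithful implementation of the stated parameters yields ~3 full-cue
  prediction errors per 100 stored patterns for the baseline models at
  N = 100 — qualitatively the published overload effect (errors appear
  from N ≈ 50 and grow with N, both baselines identical, the gated model
  clears them), but an order of magnitude below the published ~25. The
  closed-form rate, P(wrong valence fires) ≈ [1 − (1 − k/n)^(N/3)]^k,
  confirms the simulated value, and the acceptance script reports the
  honestly computed number.
* Valence-overload capacity is bounded by the number of associated
  groups; once interference reaches the last group the conflicted
  association is simply flagged, a regime the experiments here never
  enter (≤ 2 groups are ever recruited at these loads).
* Pattern-overload interference between exteroceptive patterns is out of
  scope: loads are kept where autoassociative completion is essentially
  perfect, standing in for upstream dentate pattern separation.
* The storage/recall mode switch is abstract; no neuromodulatory
  dynamics, oscillations, or downstream consumers of the valence
  prediction are modelled.
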