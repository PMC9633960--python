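# Methods

This note documents the model implemented in `spikeintent`: its equations
and assumptions, the parameter choices that matter, the numerical decisions
taken where the design was open, and what the synthetic experiments do and
do not establish.

## Neuron model and integration

All regions use the two-variable Izhikevich neuron

    v' = 0.04 v² + 5 v + 140 − u + I
    u' = a (b v − u)          if v ≥ 30 mV: v ← c, u ← u + d

with shared reset constants `c = −65 mV`, `d = 8`, and per-region
`(a, b)`: striatal D1 `(0.01, 0.01)`, striatal D2 `(0.1, 0.5)`, every other
region `(0.02, 0.6)`. Integration is synchronous forward Euler with
`dt = 0.5 ms` (both derivatives evaluated on the pre-step state; resets
applied at step end, simultaneously for all neurons that crossed
threshold). Initial conditions are `v = −65`, `u = b·v`.

Two consequences of these parameter values shape the implementation:

* With `b = 0.6` (and `b = 0.5`) the nullclines `0.04v² + (5−b)v + 140 = 0`
  have no real root, so those neurons have no resting fixed point — they are
  tonically active even at `I = 0`. We therefore gate DLPFC activation at
  the population level: only the category row receiving visual drive is
  integrated during a trial; undriven rows are held quiescent. This realises
  "all neurons representing this category are activated" while keeping the
  state code well defined.
* The basal-ganglia output neurons do integrate freely. Their common
  intrinsic drift cancels in the winner-take-all comparison: every BG neuron
  follows the same trajectory plus the input kicks `dt·W[s, j]` delivered at
  DLPFC volley times, so the first neuron to reach threshold — ties resolved
  by crossing voltage, then by lowest index — is exactly the argmax of the
  weight row. This reduction (selection ≡ row-wise argmax with deterministic
  tie-break) is asserted as a property test over random weight matrices.

One trial simulates up to 100 ms; the volley normally completes within
~3 ms, after which the winning channel is relayed (fixed weight 50,
suprathreshold) through thalamus to PMC and the trial ends early. Striatal
populations appear in the topology and carry the reward-phase timing roles;
the forward volley delivers the plastic current directly to the BG output
layer, which is the granularity of the weight matrix itself (one entry per
state–intention pathway; a row's neurons fire in lockstep).

## Plasticity and reward routing

The pair-based STDP rule, with constants fitted to biological pairing data
(`A₊ = 0.777`, `A₋ = −0.237`, `τ₊ = 16.8 ms`, `τ₋ = −33.7 ms`), produces a
ratio `Δw`; weights update multiplicatively, `W ← W(1 + Δw)`, and are
floor-clamped at `10⁻³ ×` the initial weight because a multiplicative rule
cannot regrow an exact zero.

Feedback routing assigns each plastic synapse at most one spike pair per
trial, at a nominal lag of 10 ms: the MOFC pathway fires DLPFC before
striatum (`Δt = −10 ms`, multiplier ≈ ×1.4284), the LOFC pathway fires
striatum before DLPFC (`Δt = +10 ms`, multiplier ≈ ×0.8239). Positive
feedback yields one LTP event on the rewarded synapse `(s, a)` and LTD
events on `(s′, a)` for every `s′ ≠ s` — the MOFC-inhibition-of-LOFC gate is
modelled as removal of the `(s, a)` entry from the LTD set. Negative
feedback yields a single LTD event on `(s, a)`. Column-wise LTD (reserving
the learned intention against *future* states) is what produces the
cross-state elimination behaviour and the published count distribution; the
row-wise phrasing that also appears in the source description is
inconsistent with that distribution and was not used.

The exact lag value is a free parameter (only the pathway order is
specified); any lag whose single LTD event pushes a weight strictly below
its untouched competitors yields identical interaction counts. With the
default lags, a previously learned synapse (≈14.28 from 10) needs **three**
wrong predictions to fall below the depressed background (≈8.24), so a
changed rule is abandoned after three interactions; the abandonment count is
logged per state rather than hard-coded.

## The interaction protocol and its counting model

One interaction = one (prediction, feedback) pair. Training presents states
in a fixed order (default: state by state to criterion; a seeded shuffled
order is available), and is complete when every state was predicted
correctly at its most recent presentation. Under truthful feedback the
circuit's behaviour reduces exactly to an elimination process: the cost of a
state is the rank of its correct intention among the intentions not yet
claimed, because claimed intentions' entries have been depressed for every
other state and untouched candidates are tried in index order. Summed over
states this equals `N + inversions(π)` (Lehmer code), giving bounds
`[N, N(N+1)/2]` and the symmetric Mahonian distribution over all `N!` rules,
with mode = mean = `(N + N(N+1)/2)/2` (tied modes averaged). The spiking
loop and the abstract counter are verified to agree rule-for-rule,
exhaustively for all 153 rules with `N ≤ 5`.

The per-rule count depends on the presentation order (relabelling), but the
count *distribution* over all rules does not; statistics are therefore
order-free.

The Q-learning baseline is a reconstruction: tabular Q, zero-initialised,
greedy with lowest-index tie-break, reward ±1, learning rate 1, no
exploration, states independent. It needs `1 + π(s)` interactions per state
— `N(N+1)/2` for every rule — which matches the published fixed counts; the
original agent's exact hyperparameters are not available, and any variant
reproducing those counts is equivalent for this comparison. The advantage of
the circuit, `(N² − N)/4`, follows from the distribution symmetry.

Exhaustive enumeration is used through `N = 9` (362,880 rules, vectorised
via the inversion identity and cross-checked against the sequential
elimination oracle and the Mahonian generating function); beyond that the
closed forms plus seeded sampling are authoritative. The guard against
non-termination trips at `N(N+1)` trials for fresh training (the worst case
is `N(N+1)/2`) and `3N(N+1)` for relearning runs, which also spend trials
abandoning old rules.

## Gesture front-end

Twenty binary feature neurons summarise a gesture from 3-D joint streams:
per hand, six movement directions (net displacement beyond 15 % of shoulder
width) and four shoulder-relative positions (within a 10 %-width radius of a
shoulder; higher than a shoulder by 10 % width *and* laterally over it).
The twelve gesture prototypes encode the definitions as performed from a
neutral stance with the hands slightly in front of the body plane, so
motions ending on the body also fire that hand's toward-body neuron. Where a
definition leaves the hand or path open, conventions were chosen to keep the
twelve binary codes well separated (the leftward sweep uses the left hand;
a hand is placed above the opposite shoulder by crossing over; "both hands
above both shoulders" is the crossed-arms-overhead pose). Even so the code
is not error-correcting: at 5 % independent feature-flip noise the Bayes
accuracy of nearest-prototype classification is about 93 %, because a
single flip can make two gestures' noisy patterns exactly equidistant.

The classifier is online and unsupervised. Each learned gesture owns a
target neuron with a synaptic weight vector over the feature neurons; an
incoming pattern is matched by Pearson correlation, and a pattern below the
novelty threshold `θ = 0.5` recruits a new target neuron. Matched synapses
update by the STDP factors — potentiation for co-active features,
depression for silent ones — applied once per pairing, with eight pairings
per presentation (feature neurons fire on every frame of a performed
gesture), bounded in `[0.01, 50]`; this drives each weight vector to the
features its gesture presents in the majority of samples.

The training protocol presents one sample of each of the twelve gestures
per batch. Because the batch composition is known, target neurons compete
across the whole batch: samples and neurons are paired one-to-one by
descending correlation (winner-take-all with lateral inhibition), and
leftover samples recruit. This is what lets a gesture whose feature set
contains another's (both-hands-drop vs single-hand-drop) keep its own
neuron — a single sample cannot distinguish a superset prototype from a
noisy variant, but the protocol can. Samples silenced entirely by noise are
invisible to a detector: skipped in training, scored as errors in test.
For scoring, each target neuron is labelled by the majority gesture among
its matched training samples (the standard evaluation of an unsupervised
classifier), and neurons matched only once never consolidated and sit out
of test-time competition.

On 360 held-out noisy samples, accuracy after six batches is 0.908–0.931
across seeds 1–5 (e.g. 0.931 at seed 1), against the ≈0.93 Bayes ceiling of
the code itself. Accuracy as a function of batch number rises to a plateau
but fluctuates within ±1–2 % there — the sampling noise of a 360-sample
test set — so the learning-curve property is asserted as final-batch
accuracy exceeding first-batch accuracy unless the first batch already
scored ≥ 0.9.

**What the synthetic experiments show.** The generator emulates detector
errors as independent per-feature flips on fixed prototypes. Real recordings
have correlated errors, per-user geometry, and continuous-valued streams;
the synthetic ≥ 90 % result demonstrates that the online mechanism
recruits, consolidates, and separates the twelve classes under calibrated
noise — it is a stand-in property and does not claim any real-data accuracy
figure. The trajectory stage likewise begins at the abstract six-view code;
the image-processing chain that produces those views (binarisation, edge
detection, Hough transform) is stock computer vision and out of scope.

## Configuration

Every free parameter — intention count, integration step, trial window,
drive current (20, comfortably suprathreshold for all three parameter
sets), fixed relay weight (50), initial plastic weight (10, uniform, so the
first choice is the deterministic tie-break), weight floor ratio, the two
nominal lags, STDP constants, presentation order, seed — lives in
`RunConfiguration`, round-trips through YAML, and is echoed into each CLI
run's JSON-lines log. Indices are 0-based internally and 1-based in all
user-facing output.

## Known limitations

* The spiking trial is a single feed-forward volley; there are no
  conductance synapses, delays, or noise currents, and no learning outside
  the DLPFC→BG matrix.
* Spike-time bookkeeping drives the record, but plasticity uses the nominal
  pathway lags; measured lags would require the unpublished drive and
  routing magnitudes.
* The interaction counts assume truthful, immediate feedback; noisy or
  delayed feedback is not modelled.
* The gesture code's Bayes accuracy caps near 93 % at the calibrated noise;
  richer (non-binary) features would be needed to exceed it.
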