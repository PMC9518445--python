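# Methods

## Model

The classifier performs distributed, feature-level fusion of `n` EEG
channels. Each selected channel is processed by its own recurrent branch: a
sequence of `T` one-second epochs (100 samples each at 100 Hz) runs through
one or two LSTM layers with `H` hidden units per direction. Cells follow the
standard gated form — forget, input and output gates as sigmoids of affine
maps of the current input and previous hidden state, internal state
`s_t = F⊙s_{t−1} + I⊙tanh(Ux_t + Wh_{t−1} + b)`, output `h_t = tanh(s_t)⊙O`.
A bidirectional branch runs the sequence both ways and concatenates the two
final outputs (width `2H`); with two stacked layers, the first returns its
full output sequence to the second. The branch feature (the last cell's
output) is optionally passed through a dense layer of size `S`; the fusion
node concatenates all branch features into `f = [f_1 … f_n]`; if the
per-branch dense layer exists, a second dense layer with the same size and
activation transforms `f`; a 2-unit softmax layer yields the class
probabilities. The binary decision applies a threshold chosen on the
*training* ROC curve by maximizing Youden's J = Sen + Spe − 1 (the standard
reading of an "optimal cut-off"; it is invariant to class prevalence and to
the order of operating points).

"`H` units" always means per direction. This interpretation is forced by
the published parameter totals of the two reference architectures: with
`n = 3`, bidirectional `H = 100`, `I = 100` and `S = 300` (resp. 200) the
closed form

    n·dir·4(H(I+H)+H) + n·(dir·H+1)·S + (n·S+1)·S + (S+1)·2

gives exactly 934,202 (resp. 723,602), which the package reproduces both by
formula and by counting allocated arrays.

Training minimizes class-weighted cross-entropy with Adam (learning rate
0.001, batch size 1024). Weights are the inverse-frequency form
`w_c = N/(2·N_c)`, under which the all-majority and all-minority trivial
predictors incur equal loss; balanced data gives `w = (1, 1)`. Dropout is
applied to recurrent-branch outputs and dense outputs (output dropout, not
recurrent-connection dropout) at the decoded rate; it does not change the
parameter count. There is no early stopping; the epoch budget is a plain
configuration value because its useful range depends entirely on the data
size at hand.

The network is implemented directly over numpy with a small reverse-mode
autodiff core (`capfusion._nn`) providing exactly the operations the
architecture needs; gradients are validated against central finite
differences in the test suite, and training is bit-deterministic given the
seed.

## Architecture encoding

A 15-bit genome encodes: bits 0–2 the channel mask over (Fp2–F4, F4–C4,
C4–A1) with 000 invalid; bits 3–4 `T ∈ {5,10,15,25}`; bit 5 depth `{1,2}`;
bit 6 direction; bits 7–8 `H ∈ {50,100,150,200}`; bits 9–10 dropout
`{5,10,15,20}%`; bits 11–12 `S ∈ {0,100,200,300}` (0 = no dense layers);
bits 13–14 activation `{tanh, sigmoid, ReLU, SELU}`. This table is shipped
as YAML (`capfusion/data/decoding_table.yaml`) so it can be audited or
swapped. The exact option values for fields not pinned by the two reference
optima are a reconstruction, chosen so that (a) every published option value
appears and (b) the valid-pattern count is exactly 7·2^12 = 28,672, matching
the published grid size. Genomes with `S = 0` but different activation bits
decode to functionally identical networks; counting is by bit pattern, which
is how the 28,672 figure is defined. Invalid genomes (mask 000) are
*repaired* by setting one uniformly chosen channel bit, rather than
discarded, so optimizer evaluation budgets stay fixed.

## Optimizers

**GA.** Population z = 15 genomes, G = 20 generations, patience 15. The
initial population's evaluation counts as generation 1; each later round
builds z − 2 varied offspring — with probability 0.9 a two-point crossover
(cuts 0 < i < j < 15, one offspring) of two distinct tournament winners,
otherwise a clone of a tournament-of-two winner — mutates them bitwise at
rate m(g) = max(0.01, 0.2·0.7^⌊(g−1)/5⌋), repairs, and carries the two
elites over unmutated. Pool-and-truncate survival keeps the best z − 2 of
(P minus elites) ∪ Q, then reinserts the elites. The expected number of bit
flips per round is therefore m(g)·(z−2)·15, and a full run evaluates
exactly 20·15 = 300 candidates. Ties in sorting break by insertion order
for determinism. Patience counts consecutive generations without strict
improvement of the incumbent best.

**Binary PSO.** Swarm of 15 particles on a ring (each sees itself and its
two adjacent neighbors); velocity per bit
`v' = ω v + c1 r1 (p − x) + c2 r2 (l − x)` with c1 = 0.6, c2 = 0.3,
r1, r2 ~ U[0,1] drawn per dimension, clamped to ±v_max; position resampled
per bit as Bernoulli(σ(v')). The inertia decays multiplicatively
(ω = max(0.4, 0.9·0.91^⌊(i−1)/5⌋)) — the multiplicative reading parallels
the GA's mutation decay. v_max = 6 keeps σ(v) off hard saturation; initial
velocities are U[−1, 1]; both are conventional choices where no value is
prescribed. Personal bests update on strict improvement; the local best of
a particle is the best personal best in its ring neighborhood.

A practical note on these dynamics: because the global best can only
improve when a complete improving bit string is *sampled*, and because
velocity decays whenever a bit already matches its attractors, the sampling
probability of any specific full pattern stays bounded well away from 1.
With the small cognitive/social weights above, the swarm reliably climbs to
13–14 ones on a 15-bit OneMax within 20 iterations but rarely samples the
exact optimum; the GA, whose elitist crossover assembles building blocks,
solves the same benchmark in every seed. This is an inherent property of
sigmoid-sampling binary PSO at these weights, not an implementation
artifact; the corresponding benchmark expectation is asserted as stated and
its failure for PSO is a finding, reported by the test suite.

## Evaluation protocols

Accuracy, sensitivity and specificity use the standard denominators
(Sen = TP/(TP+FN), Spe = TN/(TN+FP)); AUC is the trapezoidal area under the
ROC curve, with "A" the positive class. The mean metric (arithmetic mean of
the three) summarizes balance under heavy imbalance. Post-processing flips
isolated interior labels (010→000, 101→111) in one simultaneous pass
decided on the input sequence — iterating to a fixed point would collapse
genuine alternations. Population diversity is the normalized mean pairwise
Hamming distance, 2/(zL(z−1))·ΣHam, in [0,1].

TFCV splits subjects into two group-stratified, subject-independent folds,
trains a cold-started model on each and scores the other; the mean of the
two test AUCs is the optimizers' fitness. LOO holds out each subject in
turn, re-initializes weights, selects the threshold on the training ROC,
post-processes the held-out predictions, and reports per-subject and
aggregate Acc/Sen/Spe/AUC. Both protocols guard against subject leakage by
construction (pools are keyed by subject id).

## Preprocessing

Signals above 100 Hz are decimated after zero-phase (forward–backward)
filtering with a Chebyshev type I filter (order 8, 0.05 dB passband ripple,
cutoff 0.8× the post-decimation Nyquist); zero-phase filtering avoids group
delay that would shift events relative to the second-aligned labels.
Non-integer ratios (512 → 100 Hz) use rational polyphase resampling with the
equivalent anti-aliasing cutoff, since plain decimation is undefined there.
Standardization (zero mean, unit variance) is per recording and per channel.
Windows of `T` epochs slide over each recording; the first `T − 1` epochs
yield no window (no zero-padding — fabricating signal content would bias
the earliest labels), and each window carries the label of its last epoch.

## Synthetic cohort generator

The generator emulates the statistical skeleton of CAP-scored sleep EEG:
per-channel 1/f^β background (β = 1) built from a shared latent source
(inter-channel correlation ρ, default 0.5) plus independent channel noise;
activation events as amplitude bursts (gain 3) with duration uniform in
[2, 60] s, placed by rejection sampling with ≥2 s guard bands, drawing each
duration near the remaining need so the per-second label prevalence lands
close to its target (15% by default, split 0.81×/1.19× between FND-like and
SDP-like halves of a cohort to mirror the lower/higher A-phase time of the
two strata). A second is labeled 1 when an event overlaps at least half of
it — a deterministic rounding rule. Determinism is per (seed,
subject index).

What this does *not* model: CAP grammar (B phases bounded by A phases,
sequences and cycles), REM/NREM macrostructure, subtype-specific A-phase
morphology, artifacts, or any quantitative spectral signature of real A
phases. Passing tests therefore demonstrate that the pipeline's mechanics
(fusion, search, validation, robustness) behave correctly on data with the
right coarse structure — not that the classifier reaches clinical
performance on real polysomnography.

## Robustness protocols

Both protocols perturb only test-time inputs of clean-trained models.
Channel loss substitutes each lost channel's signal verbatim with an
assigned working channel (10 scenarios over 3 channels: 1 clean, 6
one-lost, 3 two-lost). AWGN is added per channel at a requested SNR
computed against the standardized signal the model actually consumes
(hence signal power ≈ 1); the default grid is {−20, −10, −5, 0, 5, 10, 20}
dB. Sweeps reuse the LOO-trained models and report per-scenario,
per-subject AUC for quartile summaries.

## Scaled-down study conditions

The end-to-end checks run on 6-subject synthetic cohorts, 10 minutes per
subject, with a deliberately small fused architecture (T = 5, one
bidirectional layer, H = 16, no dense layer) trained for 8 epochs — sizes
chosen so a full leave-one-subject-out pass takes well under a minute of
CPU while leaving the fusion advantage measurable. Under these conditions,
averaged over five seeds, the fused 3-channel model's mean LOO AUC (~0.82)
exceeds both the label-shuffled null (~0.50) and the best single-channel
model (~0.78). Full-scale optimization (300 TFCV-evaluated architectures on
16 whole-night recordings) is days of GPU time and is exercised here only
through its operators and accounting.

## Numerical choices and degenerate inputs

Float64 throughout; Glorot-uniform weight init (zeros for biases) from a
seeded generator; softmax and cross-entropy computed via log-sum-exp;
standardization rejects zero-variance input; metrics raise on empty
denominators rather than returning NaN; AUC and threshold selection require
both classes; ROC thresholds use the `score ≥ threshold` convention, and
sklearn's +inf sentinel threshold is mapped above the top score. Sorting
ties in the GA break by insertion order; tournament ties resolve by fair
coin. All randomness flows through `numpy.random.Generator` objects seeded
explicitly; no global state.
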