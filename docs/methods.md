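# Methods

## The model

The package models the acquisition of number representations by a robot that
counts on its fingers while hearing the number words. All embodiment enters
through two fixed tables:

* **Finger joints** — 11 configurations (rest plus one..ten) × 14 joint
  angles in degrees. Each hand contributes 7 degrees of freedom (2 each for
  thumb, index and middle; 1 for the glued ring+pinky pair). Numbers 1–5 are
  counted on the right hand; from 6 on the right hand is fully open and the
  left hand adds fingers. Angles deviate slightly from the ideal
  0/90/180/220 because of element collision and tendon limits in the
  simulated hand.
* **Word MFCCs** — 10 words × 13 mel-frequency cepstral coefficients taken
  from recordings of a child's voice. The first coefficient is the
  energy-like term and dominates every word (−29…−36); the remaining twelve
  are O(1) or smaller. No audio I/O or MFCC extraction is performed: the
  coefficients are the data.

Before training, every matrix is normalized into [−1, 1]. The default mode
divides each feature (a joint, or a cepstral coefficient, observed across
configurations/words) by its own maximum absolute value, so each feature
spans the full range; a `global` mode (single divisor for the whole matrix)
is available via `normalization_mode`. Per-feature is the default because
the energy coefficient would otherwise compress the remaining twelve
coefficients to ±0.06 and dominate every distance; the choice is exposed
precisely because the compressed variant is a plausible account of how such
data may have been handled historically.

### Sequence memories

Counting is memorised by linear, bias-free recurrent nets with output
feedback:

    h_t = W_in y_{t-1} + W_rec h_{t-1},   y_t = W_out h_t.

During training the feedback input is the target at the previous step
(teacher forcing); in operation the net's own output is fed back. Three
consequences of linearity + no bias are load-bearing and tested:

* all-ones hidden state is the canonical start of a count;
* an all-zero hidden state (and zero feedback) is silent forever;
* incepting the stored hidden state of number *n* resumes the count at
  *n*+1.

The feedback fed at the *first* step of a rollout is resolved as: zeros for
a silent (all-zero) start; the stored step-0 context for the all-ones start
(the normalized rest configuration for motor nets — the proprioceptive state
of a hand at rest — and silence for the auditory net); and `W_out h` for any
other incepted state, so that resuming from number *n* sees the output it
was emitting at *n*.

Architecture: right-hand and left-hand motor nets with 5 hidden units and 7
joint outputs each (the two-net split models lateralization: the left net is
hard-clamped to zero while numbers 1–5 are processed), and an auditory net
with 10 hidden units and 13 MFCC outputs. The right net learns the
right-hand columns of the normalized joint table over steps one..ten (a
sequence that saturates at five); the left net learns the left-hand columns
over six..ten; the auditory net learns the word rows one..ten. When counting
past five the right net's state is frozen at its number-five value rather
than left free-running, which makes the "right hand stays open" regularity
exact rather than approximate.

Weights are initialized from a seeded uniform(−0.5, 0.5). A net counts as
trained when its teacher-forced mean squared error is below 10⁻⁶; on failure
the fit retries with the next seed (up to 10 attempts). In practice the fits
reach 10⁻¹⁰–10⁻¹⁹ in ≤ 15 accepted epochs on the first attempt.

### The optimizer

All training uses a from-scratch Levenberg–Marquardt implementation.
Performance is the mean of squared output errors. Each accepted iteration
solves (JᵀJ + μI)Δx = Jᵀe, with μ₀ = 10⁻³, ×0.1 after an accepted step and
×10 after each rejected trial, capped at 10¹⁰; performance therefore
decreases at every accepted epoch by construction, and epochs count accepted
steps only. Stopping: performance gradient (2/N)·Jᵀe below 10⁻⁷ in infinity
norm (the norm is configurable; the infinity norm is this package's choice,
not an assertion about any other implementation), the epoch cap, μ overflow,
or an optional explicit performance goal. The damped system is solved by
Cholesky with a pseudo-inverse (rcond = 10⁻¹²) fallback for numerically
non-positive-definite cases.

Recurrent Jacobians are obtained by unfolding through time and accumulating
sensitivities in forward mode (the hidden-state sensitivity recursion
mirrors the unrolled network); rows are time-step-major, columns follow the
canonical flattening (W_in, W_rec, W_out). Correctness is pinned to central
finite differences at < 10⁻⁵ relative error.

### Classification protocol

Five per-number feature datasets are assembled: (1) the 10-d concatenated
motor hidden states, (2) the 13-d normalized MFCC rows (no sequence
learning), (3) the 10-d auditory hidden states, (4) = (1)⊕(2) (23-d),
(5) = (1)⊕(3) (20-d). A single softmax layer p = softmax(Wᵀx + b) (with
bias, seeded uniform(−0.5, 0.5) init) is trained on squared error against
one-hot targets over the ten exemplars — one per class; the experiment
measures fit quality under a tight epoch budget, not held-out
generalization. The Jacobian folds in the full softmax derivative
diag(p) − ppᵀ. The repeated-runs protocol retrains the classifier 100 times
(run r seeds with base+r, the sequence memories are trained once and
shared), records the likelihood assigned to the true class of every
exemplar, and reports per-class medians and sample standard deviations,
their average, and per-epoch curves (mean true-class likelihood;
median count of argmax misclassifications, ties broken toward the lower
class). Paired two-sided t-tests (paired by seed index, no
multiple-testing correction) compare datasets per class.

**A known, deliberate discrepancy.** With one exemplar per class the
squared-error/softmax landscape has a monotone valley to an interpolating
solution, so damped Gauss–Newton steps of any useful size are accepted and
the true-class likelihood saturates near 1.0 within one or two accepted
epochs for *every* dataset. Consequently this implementation does not
reproduce the absolute mid-range likelihood plateaus (≈0.26–0.94 after ten
epochs, ordered by dataset quality) that have been reported historically
for this protocol; those levels require an optimizer that is throttled in
some way the available method descriptions do not specify (we verified that
diagonal softmax-derivative approximations, global instead of per-feature
normalization, and init scales from 0.5 to 20 all fail to produce them —
large inits also destroy the quality ordering). The package keeps the
protocol faithful and reports what it computes; the dataset-quality
*mechanisms* (lateralized motor structure, sequence-ordered
representations, the near-redundancy of raw word MFCCs) are preserved and
tested through the representation-geometry properties instead.

### Associative maps and addition

The cross-modal maps w₁ (motor→auditory) and w₂ (auditory→motor) are 10×10
linear maps fitted by the same optimizer on the ten per-number hidden pairs,
from seeded uniform(−0.5, 0.5) inits. The fit stops on an explicit error
floor (mean squared mapping error < 10⁻¹⁵) with the gradient tolerance
disabled: near the least-squares solution of a linear system the
performance gradient drops below any useful tolerance while the error is
still orders of magnitude above the floor, and stopping there leaves maps
bad enough to break additions. The number of accepted iterations needed is
μ-schedule-bound — μ must decay below the smallest Gram eigenvalue, so it
grows with log₁₀ cond(XᵀX): in practice ~4 for the well-conditioned
auditory→motor direction and 4–13 for motor→auditory,
whose design matrix is poorly conditioned because representation rows 5–10
share an identical right-hand half (the frozen open hand). Rank-deficient
representation matrices fall back to the pseudo-inverse solution with a
warning and a flag.

The switch layer is a small state machine (idle, start-all, counting, two
resets, two transfer directions, output) whose transition table is
reconstructed from the narrated five-step addition plus the layer's four
capabilities; illegal events raise. Addition of a + b ≤ 10: both memories
count to the first heard operand (operands are MFCC rows matched by a
nearest-neighbour matcher in normalized coefficient space — the minimum
inter-word distance comfortably exceeds small perturbations); the plus word
resets the auditory memory while the motor memory holds; both count the
second operand, leaving the motor memory at a+b; the motor state is mapped
through w₁ into auditory form; and the concatenated (motor, transferred)
20-d vector is classified by a fingers+words classifier. Sums beyond ten
raise an overflow error — no representation exists past the tenth — and the
buffer roles (motor accumulates, auditory counts operands) are fixed as in
the worked example.

### Clustering view

`cluster_representations` builds a complete-linkage hierarchy on Euclidean
distances between the ten representation rows and orders the leaves
optimally (scipy's optimal leaf ordering, which minimises the sum of
consecutive-leaf distances exactly). The adjacency score — mean absolute
numeric difference between consecutive leaves, 1.0 for a perfectly
sequence-ordered tree — quantifies how much a representation respects the
counting order. Finger-sequence representations score lower (more
sequence-like) than raw word MFCCs for the large majority of training
seeds; because single draws are noisy, the property is asserted across
seeds, not per draw. Average linkage gives qualitatively similar orderings
but is not asserted.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| μ₀, μ×, μ÷, μ_max | 10⁻³, 10, 0.1, 10¹⁰ | damping schedule of the optimizer |
| grad_tol | 10⁻⁷ | stop when ‖(2/N)Jᵀe‖∞ falls below |
| max_epochs | 1000 | accepted-iteration cap for sequence memories |
| classifier epochs | 10 | accepted iterations per classification run |
| runs | 100 | classifier retrainings per dataset |
| init range | ±0.5 | uniform weight init, all trainables |
| trained threshold | 10⁻⁶ | teacher-forced MSE defining "trained" |
| mapping error goal | 10⁻¹⁵ | stop floor for the associative maps |
| hidden sizes | 5+5 motor, 10 auditory | per-hand and word memory capacity |

Seeds: an experiment's `base_seed` derives the three RNN seeds (+101, +202,
+303), the classifier run seeds (+1000+r), the associative seeds (+5000+s)
and the map-fit seed (+7); identical configurations are bit-reproducible.

## What the fixtures do and do not emulate

The two tables are the study conditions themselves, not synthetic
stand-ins; the perturbation generator (`perturb`, seeded i.i.d. Gaussian
noise in table units) exists only to probe robustness, e.g. of the word
matcher. Nothing here models real articulatory or acoustic variability,
speaker differences, sensor noise on joints, or physics — joint angles are
vectors, never commands to a simulator. Passing tests therefore show that
the architecture acquires and manipulates these specific sequences, not
that it would survive raw audio or a physical hand.

## Problem sizes

Every experiment is small by construction — 10-step sequences, ≤ 23-d
features, ≤ 360 parameters per net — so the full suite (including the
100-run × 5-dataset protocol, the 100 associative fits, and a 20-seed ×
45-pair addition sweep) completes in well under a minute on one CPU. The
acceptance script uses the printed protocol sizes (100 runs, 10 epochs, 100
trials) directly.

## Known limitations

* The absolute classification-likelihood levels differ from historically
  reported mid-range plateaus, as analysed above; comparisons of datasets by
  those saturated values are uninformative in this implementation.
* The associative iteration count depends on the conditioning of the motor
  representations, hence on the training seed (≈4–8.5 on seeds examined).
* The state-machine transition table is a documented reconstruction; other
  wirings consistent with the same narrative are possible.
* Whether each motor net should have 5 or 10 hidden units is ambiguous in
  the source material; the 5+5 reading is implemented (the concatenated
  10-d motor representation then matches the stated dataset widths).
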