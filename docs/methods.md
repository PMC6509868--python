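# Methods

## Model

A probe of length *l* is a bag `B_I` with label `Y_I ∈ {−1, +1}`; its
instances are the `⌊(l − c)/s⌋ + 1` sliding windows of width *c* at step
*s* (0-based, half-open coordinates; trailing bases not covered by a full
window are dropped). Windows are one-hot encoded with the fixed alphabet
order A, T, C, G — A→(1,0,0,0), T→(0,1,0,0), C→(0,0,1,0), G→(0,0,0,1) —
giving feature vectors of length 4*c* with exactly *c* ones. The MIL
semantics are the standard ones: a negative bag's instances are all
negative; a positive bag contains at least one positive instance.

The decision function is a kernel expansion
`f(x) = Σ_k α_k K(sv_k, x) + b` with a gaussian
(`K(u,v) = exp(−γ‖u−v‖²)`) or linear kernel. A bag's score is
`max_i f(x_i)`; its predicted label is the sign of that score. Training
solves, heuristically, the witness-based soft-margin program

    min_s min_{w,b,ε} ½‖w‖² + C Σ_I ε_I
    s.t.  Y_I = −1:  −f(x_i) ≥ 1 − ε_I  for every instance i of B_I
          Y_I = +1:   f(x_{s(I)}) ≥ 1 − ε_I

where `s(I)` picks each positive bag's witness. For a fixed witness
assignment this is a standard soft-margin SVM whose training set is the
witnesses (+1) plus every instance of every negative bag (−1, never
subsampled); the dual coefficients obey the box constraint `|α| ≤ C`. The
MIL objective reported and compared throughout evaluates one shared slack
per negative bag (the hinge loss of its worst-violating instance) so it
matches the program above rather than the per-instance-slack SVM
surrogate used inside the inner fit.

## Witness iteration and stopping

Both trainers alternate (i) fitting the inner SVM at the current witness
assignment and (ii) re-selecting each positive bag's witness as its
argmax-decision-value instance (lowest index on ties).

* **MI-SVM** stops only when the re-selected assignment equals the one
  just trained on (an exact fixed point), or at `max_iter` (default 50),
  in which case `converged` is False.
* **MD-SVM** uses a relaxed, stabilised criterion: stop when the fraction
  of changed witnesses is ≤ `witness_change_tol` (default 0.01), when the
  relative objective change is ≤ `objective_rel_tol` (default 1e-4), or
  when the assignment revisits a previously evaluated state — a cycle, in
  which case the best-objective state seen is returned. With both
  tolerances at zero and no cycle this is exactly the MI-SVM criterion,
  but it terminates in a stable state even when the fixed-point iteration
  oscillates. The exact form of this criterion was an open design choice;
  the implemented rule was picked because it guarantees termination,
  degrades gracefully to the classical loop, and exposes its two
  tolerances as ordinary parameters.

The recorded `objective_value` is the MIL objective at the assignment the
returned model was trained on; the recorded witness map is the argmax
re-selection under that model, so it is self-consistent in every stopping
mode (the two coincide at an exact fixed point).

### Initialisation and restarts

The witness local search is greedy and its fixed points depend strongly
on the start. Two failure modes shaped the design:

1. *Self-confirmation*: starting from an arbitrary per-bag instance, the
   first SVM fit tends to score exactly that instance highest, producing
   a spurious fixed point at iteration 1. The primary start therefore
   trains the first SVM on each positive bag's **centroid** (the mean of
   its encoded instances) so that structure shared across bags steers the
   first selection; the initial witnesses are the argmax instances under
   that model. A secondary start uses each bag's instance closest to its
   own mean. Both searches run; the lower final objective wins.
2. *Register lock-in*: single-witness moves cannot slide the entire
   assignment one position along the probes, so a converged solution can
   sit one base off the optimal motif register while classifying almost
   as well. After the initial starts, the best assignment shifted by ±1
   instance (clamped per bag) seeds further searches, repeated while a
   restart improves the objective (at most 4 rounds). In the benchmark
   this reliably moves a shifted register (objective ≈ 128) onto the
   planted one (≈ 87).

Everything is deterministic: identical inputs and configuration produce
byte-identical model files. For all-singleton bags every start collapses
to the same assignment and both trainers perform a single standard SVM
fit, so MIL training reduces exactly to a supervised SVM.

### Defaults

| parameter | default | rationale |
| --- | --- | --- |
| window *c* | 10 bp | typical TF site length (5–15 bp); sets feature dim 4c = 40 |
| step *s* | 1 bp | every candidate site considered |
| kernel | gaussian | nonlinear boundary on one-hot windows |
| γ | 1/(4c) | inverse feature dimension; scale-aware |
| C | 1.0 | standard soft-margin weight |
| max_iter | 50 | witness maps stabilise in far fewer rounds |
| witness_change_tol | 0.01 | "stable" = <1% of positive bags still moving |
| objective_rel_tol | 1e-4 | objective plateau |
| pseudocount | 0.5 per letter | avoids −∞ log-odds from finite witness sets |
| background | uniform 0.25 | overridable; synthetic probes are uniform |

## Motif model

`build_pwm` estimates `p_j(x) = (count_j(x) + a) / (N + 4a)` with
pseudocount *a*; columns always sum to 1. Log-odds scoring is the
additive `S(x) = Σ_j log2(p_j(x_j)/p_bg(x_j))` in bits; the consensus
attains the maximal score of its PWM. Information content per column is
`2 + Σ_x p log2 p` bits (0 for uniform, 2 for conserved; `0·log 0 := 0`),
and logo letter heights are `p · IC`. `extract_motif` pools the witness
window of every bag the model predicts positive — by default on held-out
probes — and builds the PWM from them. Export formats: JASPAR PFM
(counts, rows A/C/G/T), MEME minimal, tab-delimited logo heights, and an
optional rendered PNG.

## Evaluation

Bags are scored by `max_i f(x_i)` and compared by ROC AUC — the
Mann–Whitney probability that a random positive bag outscores a random
negative one, ties counted ½ — computed from the trapezoidal ROC curve
(the two agree to machine precision; the test suite cross-checks against
`scipy.stats.mannwhitneyu`). Probe labels come from intensity ranking: a
stable descending sort takes the top `n_top` probes as positive bags and
the bottom `n_bottom` as negative bags (defaults 200/200), discarding the
ambiguous middle; original row order breaks ties. `compare_models` trains
MI-SVM and MD-SVM on one probe table and evaluates both on a second,
refusing overlapping bag ids.

## Synthetic data

The generator emulates the variable region of a PBM probe set at the
package's default study conditions: 200 positive + 200 negative probes of
35 bp, a 10 bp motif sampled at 1.5 bits per column, uniform background,
uniform-random plant position, and an intensity gap of 0.5. Motif
sampling draws Dirichlet columns whose concentration is matched to the
target entropy via the digamma closed form and accepts columns within
±0.2 bits of the target. Positive probes carry exactly one planted site
(rejection-resampled if the consensus string appears elsewhere); negative
probes are pure background with no consensus occurrence. Intensities are
two non-overlapping uniform bands — negatives in [0, 1], positives in
[1 + gap, 2 + gap] — so ranking recovers the planted labels exactly; the
pipeline only consumes ranks, so the band shape is immaterial.

What the generator does **not** emulate: array optics and replicate
noise, position-specific probe effects, flanking-sequence context,
multiple or overlapping sites per probe, palindromic/reverse-complement
binding, and motif-free intensity gradients. Passing the synthetic
benchmarks therefore demonstrates that the estimator recovers a signal it
can represent, not that it is robust to every artefact of real arrays.

## Numerical choices and degenerate inputs

* Argmax and sort ties resolve to the lowest index; a bag score of
  exactly 0 predicts +1; duplicate intensities at a labeling cut keep the
  earlier row. All tie-breaks are documented so runs are reproducible.
* Sequences are uppercased; IUPAC ambiguity codes (including N) are
  rejected with the offending character and position, never imputed.
* Probes shorter than the window, empty bags, single-class training
  inputs, ragged PWM instances, zero-probability log-odds and witness
  indices out of range all raise explicit errors.
* The inner SVM is solved by scikit-learn's `SVC` at tolerance 1e-6; the
  kernel-space regulariser `½‖w‖²` is computed from the dual as
  `½ αᵀKα`.
* The exhaustive oracle enumerates witness assignments only up to a
  product guard of 10⁴ combinations.
* Model files are versioned JSON; loading validates every required field
  and the window dimension, so a model trained at one window width cannot
  silently score bags of another.

## Problem sizes

The shipped benchmark trains on 400 bags (10,400 instances of dimension
40) and evaluates on 400 held-out bags; one full MD-SVM + MI-SVM
comparison completes in tens of seconds on a single CPU. The oracle
comparison uses 20 problems of at most 3 positive bags × 3 instances so
exhaustive enumeration stays below 27 SVM fits per problem. These sizes
were chosen so the complete pipeline, including both trainers and the
oracle, runs comfortably on a laptop while keeping every estimate
well-resolved (AUC standard error < 0.01 at 200 + 200 test bags).

## Known limitations

* The witness heuristic is a local search; the restarts above remove the
  two failure modes we observed, but global optimality is not guaranteed
  (the exhaustive oracle exists precisely to measure this on small
  problems).
* At small sample sizes (tens of positive bags) register lock-in can
  survive the restarts when the shifted and true registers score almost
  identically; recovery assertions hold at the default 200-bag scale.
* One motif per run: multiple distinct motifs in one probe set will be
  merged into a single PWM.
* Forward-strand scanning by default; `with-reverse-complement` appends
  reverse-complement windows but the PWM itself is not strand-symmetrised.
* The relaxed stopping rule is a design choice of this package; other
  stabilisations (e.g. annealed tolerances) were not explored.
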