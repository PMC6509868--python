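# mdsvm

Discovery of transcription-factor binding-site motifs from protein-binding
microarray (PBM) probes with a multiple-instance support vector machine.

## The problem

A PBM measures, in vitro, how strongly a transcription factor (TF) binds
each of tens of thousands of short DNA probes. The probes that bind most
strongly must contain the TF's binding site somewhere in their sequence,
but the assay does not say *where*. `mdsvm` treats each probe as a **bag**
of candidate sites in the multiple-instance-learning (MIL) sense: every
window of width *c* bp (default 10, step 1) obtained by sliding along the
probe is an **instance**, one-hot encoded into a binary vector of length
4*c*. A probe of length *l* yields ⌊(*l* − *c*)/*s*⌋ + 1 instances — 26
for a standard 35 bp variable region. A bag is positive iff at least one
of its windows is a true site.

Bags are scored by the maximum kernelised decision value over their
instances, `f(x) = Σ_k α_k K(sv_k, x) + b`, and labeled by its sign.
Training minimises the witness-based soft-margin program

    min_s min_{w,b,ε}  ½‖w‖² + C Σ_I ε_I

where each positive bag is represented by a single chosen instance — its
*witness* `s(I)` — and every instance of every negative bag is a negative
example. Two iterative trainers alternate fitting a standard soft-margin
SVM on the current witnesses and re-selecting each positive bag's witness
as its highest-scoring instance:

* `fit_mi_svm` — the classical MI-SVM loop, stopping only at an exact
  witness fixed point;
* `fit_md_svm` — the same inner loop under a relaxed, stabilised
  criterion (changed-witness fraction, relative objective change, and
  cycle detection with best-objective memory) that always terminates in a
  stable state, and reduces exactly to MI-SVM when its tolerances are 0.

The witness windows of bags predicted positive are pooled into a position
weight matrix (PWM) `p_j(x)`, scored against sequences by the log-odds sum
`S(x) = Σ_j log2(p_j(x_j) / p_bg(x_j))`, and exported as JASPAR PFM / MEME
minimal files and sequence-logo heights (letter height = `p · IC`, column
information content `IC = 2 + Σ p log2 p` bits).

Because real PBM arrays are large external downloads, the package ships a
planted-motif generator that emulates the assay: positive probes carry
exactly one site sampled from a known PWM on i.i.d. background, negative
probes are background only, and binding intensities rank positives above
negatives. Every generated dataset carries its ground truth, so
classification and motif recovery are measurable end to end.

## Worked example

```
mdsvm simulate --seed 3 --with-test --outdir demo
mdsvm train demo/probes.tsv --outdir run
mdsvm evaluate demo/probes.tsv demo/probes_test.tsv --outdir run
mdsvm logo run/model.json demo/probes_test.tsv --outdir run
mdsvm predict run/model.json demo/probes_test.tsv --out run/scores.tsv
```

This simulates a 400-probe training table (200 positive + 200 negative,
35 bp probes, a sampled 10 bp motif at 1.5 bits per column) plus a
held-out table with the same planted motif, trains MD-SVM on the
intensity-ranked bags, and evaluates both algorithms on the held-out
probes. Output from the run above:

```
wrote 400 probes to demo/probes.tsv (planted consensus GGTACACATT)
training md-svm on 400 bags (200 positive, 200 negative)
converged=True after 2 iterations (stop: witness-change); objective 86.9713
 model  n_pos  n_neg   auc
mi-svm    200    200 0.997
md-svm    200    200 0.997
motif consensus GGTACACATT from 196 witnesses -> run
```

Held-out AUC 0.997 means a random positive probe outscores a random
negative probe 99.7% of the time, and the motif rebuilt from the 196
witness windows reproduces the planted consensus `GGTACACATT` exactly.
`run/scores.tsv` reports, per probe, the bag score, predicted label and
the witness window (offset + sequence) — the model's best guess at the
binding site location:

```
probe	score	predicted_label	witness_offset	witness_sequence
probe0	1.667157	+1	7	GGTACACATT
probe1	0.693409	+1	4	AATACACATT
```

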