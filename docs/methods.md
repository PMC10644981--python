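# Methods

## Problem setting

`connectomlp` asks a feasibility question: can a small feed-forward network
separate two groups of participants from their weighted-undirected
structural connectomes alone, and — more usefully — which regions and
connections carry that separation?  Connectomes are square, symmetric,
non-negative matrices over a brain parcellation; the package defaults to the
84-region Desikan–Killiany (DK) parcellation (68 cortical, 14 subcortical
and 2 cerebellar regions, 42 per hemisphere), under which each participant
reduces to the 84·83/2 = 3486 unique edge weights of the strict upper
triangle.

## Input representation

Matrices are read from plain text, symmetrized by averaging when asymmetry
is within 1e−6 relative (tractography builders emit symmetric matrices;
anything worse is treated as a corrupt file), and self-connections on the
diagonal are zeroed with a warning.  Edges are flattened row-major over
pairs (i, j), i < j — the ordering is fixed so gradient scores are
comparable across runs — and each participant's edge vector is min–max
scaled to [0, 1].  Normalization is **per participant** by default: it
removes the arbitrary inter-subject streamline-count scale and, because it
uses no statistics from other subjects, cannot leak test-set information
into training.  A cohort-wide mode (`normalize_mode="cohort"`) is available
for sensitivity analyses.

## Classifier

A four-layer multi-layer perceptron with widths 1024, 256, 64 and 2 (one
output per class), ReLU after each hidden layer, softmax on the output.
Where the underlying design left choices open, the package uses standard
contemporary defaults and treats them as fixed conventions:

| parameter | default | rationale |
|---|---|---|
| activation | ReLU | contemporaneous default for MLPs |
| optimizer | full-batch Adam | cohorts are ≤ a few hundred subjects; full batch removes batch-order nondeterminism |
| learning rate | 1e−3 | Adam's conventional default |
| epochs | 100 | fixed training length of the protocol |
| initialization | He-scaled Gaussian, zero biases | preserves activation variance under ReLU |
| regularization | none | interpretability study, not a benchmark |

All forward/backward/update arithmetic is explicit numpy (float32 for
training speed; float64 available via `TrainConfig(dtype=...)`).  When
numba is importable the Adam update runs through a fused kernel;
mathematically the numpy fallback is identical.  Training is bitwise
deterministic given (data, seed, config) on a fixed platform.

## Experimental protocol

Participants are split once into k = 5 **stratified** folds (plain random
splitting can produce single-class test folds at clinical cohort sizes,
e.g. 17/11).  The experiment is repeated over many network-initialization
seeds with the fold assignment held fixed — only the initial weights vary;
an optional `refold_per_seed` flag re-draws folds per repeat.  Within a
repeat, the fold-f model trains from seed `init_seed·k + f` on the other
folds and predicts fold f, so every participant is held out exactly once;
**pooled accuracy** is the exact fraction m/N of correct held-out
predictions.  The **best model** is the repeat with maximal pooled
accuracy, ties broken toward the lowest seed.

## Gradient saliency

For every repeat and every participant *correctly* predicted as a held-out
case, the package computes the gradient of the network output for the
participant's true class with respect to the 3486 inputs, under the fold
model that made the prediction (a model trained on all data is never
evaluated, so saliency is only ever read from models whose prediction was
validated out-of-sample).  Samples are averaged jointly over (seed ×
participant) per class; the per-edge mean is the **gradient score**, and a
node's score is the sum over its incident edges (hence the exact handshake
identity Σ_v s(v) = 2 Σ_e g(e)).

The differentiated quantity defaults to the softmax **probability** of the
target class.  With two classes this forces ∂p₀/∂x = −∂p₁/∂x exactly, which
is the mechanical basis of the observed duality where an edge scoring
positive for one group scores negative for the other; `logit` and `margin`
targets are provided as alternatives.  Two sample-set conventions exist:
`per-class` (each class averages its own correct participants; the default)
and `shared` (both classes' gradients on the union of correct participants,
under which the sign duality is exact by construction).  Rankings are
sorted by descending score with ties broken by ascending edge/node index
for determinism; a cross-hemisphere edge is one whose endpoints carry
different L/R codes (midline `M` never counts).

## Synthetic cohorts

No clinical data ships with the package; the generator emulates the data
model instead.  The backbone places an edge with probability 0.6 within a
hemisphere and 0.3 across (dense, lateralised networks resembling DK-scale
tractography connectomes), with log-normal(0, 1) weights — positive and
right-skewed like streamline weights.  Subjects multiply every present
backbone edge by exp(ε), ε ~ N(0, 0.3²) per edge (multiplicative noise
keeps matrices non-negative by construction).  Group 1 additionally
multiplies a planted edge set by (1 + effect_size); planting
cross-hemisphere edges emulates interhemispheric group differences.  The
default cohort is 20 + 28 subjects, matching a typical clinical
feasibility cohort.  One config seed drives documented derived streams
(backbone, planted-edge choice, and `seed + 1 + s` per subject), so any
subject is reproducible independent of cohort size.

The generator deliberately omits: distance-dependent connection
probability, tractography artefacts (gyral bias, false-positive bundles),
site/scanner effects, and correlated edge noise.  Passing recovery tests
therefore demonstrates that the pipeline's bookkeeping and attribution
machinery are sound — not that comparable accuracy is attainable on real
clinical connectomes.

## Verification problem sizes

The test suite checks behaviour at these scales (chosen to keep a full run
in the tens of minutes on one CPU; each 100-epoch training of the
3486-input network costs roughly 3 s):

* **Gradient correctness** — central finite differences (h = 1e−5, float64)
  on 20 random small networks, all three modes; antisymmetry on 1000 cases.
* **Null calibration** — 100/100 subjects, no effect, 10 init seeds: mean
  pooled accuracy within 3 binomial SE of 50%.
* **Separable cohort** — 20/20 subjects, effect ×6, noise sd 0.01, 5 seeds:
  best pooled accuracy 100%.
* **Planted-edge recovery** — five replicate cohorts, 30/30 subjects, 20
  cross-hemisphere planted edges at effect ×3, 5 init seeds per replicate:
  ≥ 80% of planted edges in the top-40 group-1 edges and Mann–Whitney rank
  enrichment p < 0.01, in ≥ 4 of 5 replicates; ≥ 1 cross-hemisphere edge in
  the top-10 in ≥ 4 of 5, against an intra-hemisphere contrast arm (3
  replicates) with a lower expected count.

Five init seeds per replicate (rather than tens or hundreds) keep the
recovery experiments tractable; with ~250 gradient samples per class they
are already stable, and more repeats only tighten the averages.

## Numerical notes and edge cases

* Constant edge vectors (max = min) are rejected as degenerate rather than
  silently normalized.
* Softmax is computed with max-subtraction; probabilities are accumulated
  in float64 even when parameters are float32.
* The probability-mode gradient seeds backprop with ±p₀p₁ directly, which
  is what makes the two-class antisymmetry exact in floating point rather
  than approximate.
* Ranking ties (exactly equal scores) are resolved by ascending index, so
  regression tests are stable across platforms.
* `mannwhitneyu` p-values below ~1e−300 are clamped before log-transforming
  in reports.

## Known limitations

Accuracies obtained on synthetic cohorts say nothing quantitative about
clinical cohorts; the null-calibration test bounds optimism but cannot rule
out real-data confounds (age, scanner, motion).  Saliency is first-order:
gradient scores measure local sensitivity of the trained network, not
causal contribution of an edge.  With ≤ 60 subjects the network memorises
the training folds (training accuracy reaches 100% well before epoch 100);
held-out pooled accuracy is the only meaningful performance number the
package reports.
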