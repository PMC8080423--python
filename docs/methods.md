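# Methods

## Problem setting

Grading a single cervical cell from a Pap smear is an ordinal problem: the
seven WHO classes run from three types of normal cells through mild, moderate
and severe dysplasia to carcinoma in situ, and an error between distant grades
is clinically worse than one between neighbours. A plain softmax classifier
trained with cross-entropy (CE) ignores this order entirely: it maximizes the
probability of the true class and is indifferent to how the remaining mass is
arranged, so it happily produces multimodal probability vectors in which grade
1 and grade 3 both outrank grade 2.

`ordicell` implements a family of non-parametric losses that push the
predicted distribution toward unimodality around the true class, together
with the baselines they are measured against, the ordinal metrics used to
compare them, synthetic data that reproduces the structure of the problem,
and the cross-validation protocol that ties it all together.

## Losses

For a K-class problem with true class k* and predicted probabilities
p&#8321;..p&#8342;, define the margin penalty

    P(k*, p) = sum over rising pairs  ReLU(delta + p_k - p_{k+1})
             + sum over falling pairs ReLU(delta + p_{k+1} - p_k)

where the rising pairs sit before the peak and the falling pairs after it.
The three penalized losses are:

* **CO** — CE + lambda * P with delta = 0: deviations from unimodality are
  penalized proportionally to the offending probability gap, but flat
  plateaus cost nothing.
* **CO2** — CE + lambda * P with delta > 0 (default 0.05): consecutive
  probabilities must differ by at least the margin, excluding
  near-flat distributions from the zero-penalty set.
* **HO2** — H(p) + lambda * P, where H is the Shannon entropy. The hard
  one-hot target of CE is replaced by the softer requirement of a
  low-entropy, delta-strictly unimodal distribution peaked at k*.

Baselines: plain **CE**; **OE** (ordinal encoding: K-1 sigmoid outputs
trained with mean binary cross-entropy against the cumulative code
1(m < k*), decoded by counting outputs above 0.5); **BU** (a single sigmoid
output q mapped through the binomial(K-1, q) PMF); **PU** (a single positive
rate mapped through the Poisson log-PMF and a temperature-1 softmax).

### Boundary convention

Writing the penalty sums with indicator functions 1(k <= k*) and 1(k >= k*)
makes both sums include the pair at k = k*, which forces a penalty floor of
2*delta at the peak transition (for k* < K) even for ideal predictions, and
charges a one-hot at the true class more than a slightly softened version of
it. The package therefore defaults to the `non_overlapping` convention
(rising pairs k < k*, falling pairs k >= k*), whose zero set is exactly the
delta-strictly unimodal distributions peaked at k*; the overlapping variant
is retained as `boundary_mode="as_printed"` and both are tested. Under
`non_overlapping`, a one-hot at k* costs lambda * delta *
(max(k*-2, 0) + max(K-1-k*, 0)): each flat-zero pair pays the margin and the
pairs adjacent to the peak are satisfied by the full 1-to-0 gap.

### Numerical choices

* Natural logarithm throughout.
* Probabilities are clamped at 1e-12 before any logarithm, so degenerate
  outputs give large but finite losses and gradients.
* Batch reduction is the mean.
* ReLU subgradient 0 at kinks.
* `delta` interacts with feasibility: a delta-strict unimodal distribution
  needs roughly (K-1)*delta of probability range, so (K-1)*delta > 1 makes
  the zero-penalty set empty. With K = 7 and delta = 0.05 the constraint is
  comfortably feasible; the package does not guard against infeasible
  combinations beyond documenting this.

## Heads and inference rules

`binomial_probabilities` and `poisson_probabilities` are unimodal for every
parameter value (verified over dense grids in the tests). The Poisson rate is
linked to an unconstrained network output by softplus + 1e-6. Two inference
rules convert probabilities to a class: `mode` (argmax, ties to the lowest
class — the conservative choice for a screening context) and `mean` (the
expectation trick: round sum_k k*p_k half-up, clamped to 1..K; rounding is
explicit because numpy's bankers' rounding would bias half-way cases toward
even classes). OE models are decoded natively by the count rule
(1 + #outputs above threshold), which is robust to non-monotone raw outputs;
their probability vector, needed for AUROC and Gini, is reconstructed by a
running-minimum projection followed by successive differences — the
projection is idempotent and inverts exact codes to one-hots.

## Metrics

Accuracy, MAE (class units), Kendall's tau-b (tie-corrected, since class
data is heavily tied), macro one-vs-rest AUROC (classes absent from the
truths are excluded; a single-class truth set is an explicit error), and the
mean Gini coefficient of the prediction vectors (0 = uniform, (K-1)/K =
one-hot) as a sparsity measure.

The UOC index (lower is better, 0-100) is shipped as a contract-tested
implementation behind a pluggable `formula` argument: rows of the confusion
matrix are normalized to class-conditional frequencies (making the index
invariant to class prevalence), and each cell pays the average of a
misclassification indicator and its normalized rank distance from the
diagonal. A diagonal matrix scores 0; moving mass farther from the diagonal
strictly increases the score. Any drop-in confusion-matrix functional can
replace it.

## Synthetic data

`sample_ordinal_features` draws class-conditional isotropic Gaussians whose
means lie on a line (the latent severity axis), at spacing
`class_separation` in units of the within-class spread. The default
conditions are K = 7 classes with the 8/7/11/19/16/22/17 % imbalance profile
of the real seven-class benchmark, separation 1.0 — adjacent classes overlap
substantially (about 31 % adjacent-pair Bayes overlap), which is the regime
where ordinal structure matters — and 350 samples, a deliberately scarce
desk-scale analogue of the 917-cell dataset.

`render_toy_cells` draws one cell per image: an elliptical cytoplasm with
random orientation, a central nuclear disc whose radius is non-decreasing in
the abnormality grade (the key morphological cue: abnormal cells have larger
nuclei), plus additive stain noise; ground-truth masks are emitted. The
nucleus is rasterized from an explicit distance grid with a quarter-pixel
centre offset so the mask area tracks pi*r^2 within a few pixels.

What the generators do **not** emulate: real chromatin texture, staining
variability, out-of-focus blur, overlapping cells and clumps, or the fact
that real class boundaries are defined by expert judgement rather than a
latent 1-D axis. Passing tests on this data show that the losses, metrics
and protocol behave as designed under controlled ordinal structure — not
that any loss ranking transfers to real cytology images.

Preprocessing follows the standard pretrained-backbone pipeline:
zero-padding to square (centred, so cell shape is preserved), bilinear
resize to 224 x 224, ImageNet channel normalization, and label-preserving
augmentation (shifts up to 10 %, zoom 0.9-1.1, rotation within +-15 degrees,
flips, saturation factor 0.8-1.2; rotation and saturation magnitudes are the
package's own mild defaults, configurable).

## Reference networks and training

The reference models are implemented in NumPy: dense/ReLU/inverted-dropout
layers, a 3-block 3x3-conv + max-pool backbone for small images, a two-layer
(64-unit) perceptron backbone for feature vectors, and an identity backbone.
The classification head is dropout 20 % / 512-dense / ReLU / dropout 20 % /
256-dense / ReLU / linear output, with output width K (softmax losses), K-1
(OE), or 1 (BU, PU); widths are configurable. Every loss exposes an analytic
gradient with respect to the raw outputs (the penalty is chained through the
softmax Jacobian), verified against central differences in the tests.

Optimization is Adam, defaults lr 1e-4, 100 epochs, batch 32, with the lr
multiplied by 0.9 whenever the epoch-mean training loss fails to improve by
more than 1e-4 for 10 consecutive epochs ("stagnant" is operationalized on
the training loss; patience resets after each drop).

## Protocol

`run_experiment` splits the data into stratified outer folds (default 10;
fold assignment deals each class's shuffled indices cyclically, so per-fold
class counts differ by at most one and leave-one-out works). On each outer
training split the penalty weight lambda of CO/CO2/HO2 is tuned by nested
stratified CV (default k = 5) over a grid (default {0.01, 0.1, 1, 10}),
selecting by inner-validation MAE with ties to the smallest lambda; the
selection metric is configurable. `compare_models` builds a league table per
metric: the best configuration is marked, and others are marked statistically
similar when a two-sided paired t-test over per-fold values has p > 0.1.
When all paired differences are identical the t statistic is undefined; the
p-value is then defined as 1 for a zero difference and 0 otherwise.

## Desk-scale study conditions

The acceptance script and the end-to-end test run a reduced protocol sized
for a single CPU: 3 outer folds, the feature-vector generator above, head
widths (64, 32), Adam at 1e-3 for 100 epochs (a from-scratch MLP on 2-D
features needs a larger step than fine-tuning a pretrained backbone), and
lambda grid {1, 10} for the penalized losses — the active upper half of the
default grid: with small lambda the HO2 entropy term can collapse the model
onto a single constant one-hot output before the penalty shapes it, and
nested tuning from the full grid selects lambda = 10 there. Results are
averaged over three dataset seeds. Under these conditions the
unimodality-aware losses (CO2, HO2, OE) achieve a lower mean MAE than CE,
and the Gini sparsity of their prediction vectors is markedly lower (the
probability mass is more spread across neighbouring classes), the expected
qualitative signature of unimodal regularization.

## Known limitations

* HO2 depends on the true class only through the penalty, so with small
  lambda it can converge to an input-independent one-hot; lambda tuning is
  not optional for HO2.
* The NumPy CNN backbone is sized for toy images (tens of pixels); it is a
  reference implementation, not an efficient trainer for 224 x 224 inputs.
* The exact published formula of the UOC index is not reproduced; the
  implementation satisfies its documented contract and is pluggable.
* Mode/mean inference can legitimately disagree on weakly peaked
  distributions; both rules are exposed and the choice is part of the
  configuration.
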