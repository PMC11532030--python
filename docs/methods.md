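# Methods

## The modelling problem

Enzyme turnover numbers span roughly eight orders of magnitude and are
measured with substantial inter-laboratory noise. All modelling in this
package therefore happens on y = log10(k_cat): the noise model is closer
to additive there, squared-error losses are meaningful, and reported MSE
values are in squared decades. The inverse transform (10^y) is provided
for reporting on the natural scale.

## Reaction fingerprints

A reaction is two multisets of molecules (agents, when present in
`a>x>b` notation, are ignored — they do not change chemistry on either
side). For every molecule we enumerate atom-centred circular
environments at radii 0..2: the radius-0 identifier is the single-atom
fragment SMILES; for radius ≥ 1 the identifier is the canonical fragment
SMILES over the bond environment returned by the cheminformatics
backend. Environments that do not grow at a given radius (e.g. radius 2
around a terminal atom of a two-bond chain) are skipped, following the
usual circular-fingerprint convention. Identifiers are prefixed with the
radius so a whole small molecule seen at two radii yields two distinct
identifiers.

Identifiers map to bit positions via a 64-bit FNV-1a hash of the UTF-8
string, reduced modulo the (power-of-two) bit size. FNV-1a was chosen
over the process-randomised builtin hash and over backend-internal
hashing because it is trivially re-implementable: the test suite carries
an independent copy and recomputes every fingerprint from a brute-force
environment enumeration.

The three schemes differ only in how the two sides are combined:

| scheme       | bits | combination                                              |
|--------------|------|----------------------------------------------------------|
| structural   | 4096 | per-side membership bits, substrate half ∥ product half  |
| differential | 2048 | counts accumulated per hashed bin; bit = 1 iff the signed product−substrate bin difference is nonzero |
| difference   | 2048 | set symmetric difference of identifiers, one bit each    |

Consequences asserted as properties: identity reactions give all-zero
difference-type fingerprints and mirrored structural halves; reversing a
reaction swaps the structural halves; all three schemes are invariant to
molecule order within a side and to SMILES rewriting (canonical
identifiers); the differential scheme is multiplicity-sensitive
(`CCO.CCO>>CCO` is nonzero) while the difference scheme is not.

Membership (set) semantics, rather than counts, are used on each side of
the structural scheme; counts enter only the differential scheme, where
they are the point.

## Sequence embeddings

Embedding providers are pluggable objects with a fixed output dimension
of 1280 per sequence. Real pretrained protein-language-model adapters
(a base and a task-fine-tuned variant) satisfy the same interface but
require multi-gigabyte weights, so the package's default provider is a
deterministic surrogate: overlapping 3-mers are counted, each distinct
3-mer contributes its count times a fixed Gaussian direction seeded from
(salt, 3-mer), and the sum is L2-normalised. Distinct salts stand in for
distinct pretrained models. The surrogate preserves the properties
downstream code relies on — fixed dimensionality, determinism,
locality (point mutations move the vector) — but carries no evolutionary
information; results obtained with it validate the machinery, not the
biology. A third block is the elementwise product of the two embedding
blocks, used by default only in the CNN's channel stack.

## Preprocessing

Cleaning removes records missing sequence, reaction or label; merges
records with identical (sequence, reaction) into one with the geometric
mean k_cat (the natural average for a multiplicative quantity); and then
removes records whose log10-k_cat z-score, computed on the post-merge
set, exceeds 3 in magnitude. The cleaning report's counts reconcile by
construction and this is asserted.

Z-score normalization uses population (divisor-n) standard deviations
fitted on training rows only; constant columns map to zero everywhere
rather than dividing by zero. Binary fingerprint blocks pass through
unnormalised by default (a 0/1 indicator is already scale-bounded and
tree models are scale-free); a switch normalises them too for
experiments. Splitting honours explicit train/test labels verbatim when
a dataset carries them; otherwise a seeded uniform split of the stated
fraction is drawn.

## Regressors

**Boosted trees.** XGBoost with squared-error objective, single thread
and fixed seed, which makes fits bit-reproducible. Hyperparameters are
sampled uniformly from: learning rate [0.01, 1], max depth {4..12},
reg_lambda [0, 5], max delta step [0, 5], min child weight [0.1, 15],
rounds {20..200}. Search scores each configuration by mean validation
MSE over k seeded folds; the partition is fixed across trials so
configurations compete on identical data. Defaults n_trials=50,
k_folds=5; the examples, tests and acceptance script use smaller budgets
(5–10 trials, 3 folds) because the search spaces are benign at those
problem sizes.

**1-D CNN.** Implemented natively in NumPy. Architecture: three
(conv1d → ReLU → max-pool 2) stages, flatten, one fully connected ReLU
layer with inverted dropout, linear scalar output. Valid (no-padding)
convolutions; a kernel longer than the current feature length is a
build-time error. Input tensors are (samples × channels × length):
selected feature blocks zero-padded on the right to the longest block's
length, one channel per block.

Training: MSE loss on minibatches; a seeded 10% row slice is held out
for validation; early stopping (default patience 10) restores the best
weights; the learning rate halves after 5 stale epochs. Optimizers:
Adam, Nadam and RMSprop with the usual β₁=0.9, β₂=0.999, ε=1e-8
(decay 0.9 for RMSprop). The output layer is initialised to the mean
predictor — zero weights, bias equal to the mean training target — so
training starts from the natural baseline and the constant-target
optimum is reachable immediately. All randomness (init, shuffling,
dropout) flows from one seeded generator, so training is exactly
reproducible; there is no separate "deterministic mode".

The randomized search draws filters {2,4..} within 2–15 / 4–25 / 8–35,
odd kernels within 3–19 / 5–17 / 7–15, fully connected width from
{16, 32, 64, 128, 256}, optimizer from the three above, batch size
8–128 and dropout 0–0.5. The fully-connected-width set and the dropout
range are this package's choices; the learning rate is fixed at 1e-3 in
sampled configs (the plateau schedule adapts it downward). Configurations
that cannot be built on the given tensor (kernel too long after pooling)
are recorded as failed trials with infinite loss rather than aborting
the search.

## Ensembling

Given an n × m panel of member predictions with truth, weights minimise
mean squared error of P·w over the probability simplex. The objective is
a convex quadratic, so the optimum is global; the solver runs SLSQP from
the uniform point and from every vertex, projects each solution exactly
onto the simplex, and finally compares against the raw feasible starts —
guaranteeing the fitted ensemble never loses to the uniform mean or to
any single member on the fitting panel, even if the numerical solver
stalls. Weights are fitted on a validation slice of the training data,
never on test. Member selection takes the k (default 3) configurations
with the smallest validation losses, ties to the lower index. The test
suite cross-checks the solver against an exhaustive simplex grid search
at step 0.001 for m ≤ 3, and verifies inverse-variance weight recovery
on synthetic panels.

## Synthetic data

The generator emulates the study conditions rather than real enzyme
biology: uniform-random sequences of 30–80 residues over the 20-letter
alphabet; reactions with 1–2 substrates and 1–2 products drawn from a
20-metabolite SMILES vocabulary (water, ethanol, sugars, small acids…)
— not required to be stoichiometrically balanced, since hash-based
fingerprints only need parseable molecules; features computed through
the real featurization path; and log10-k_cat equal to a sparse linear
signal over designated feature columns plus Gaussian noise. The default
signal places coefficients on three embedding columns scaled to give
roughly 1.2 decades of signal spread, and the default noise is 0.7
decades — comparable to the irreducible disagreement reported between
curated turnover-number measurements. What the generator deliberately
lacks: enzyme-family structure, sequence conservation, realistic kcat
marginals beyond log-normality, and any sequence–reaction dependence
beyond the planted signal. Tests passing on it therefore demonstrate the
correctness of the machinery (featurization, training, ensembling,
bookkeeping), not predictive performance on real kinetics data.

Prediction panels for ensemble tests use an equicorrelated error model:
member j's prediction is truth + bias_j + σ_j(√ρ·g + √(1−ρ)·u_j) with a
shared factor g, giving exact control of per-model error variance and
pairwise correlation.

## Pipeline and problem sizes

The orchestrator runs clean → log transform → split → featurize →
normalize → search/train both families → select top-k → fit weights on
validation → evaluate single-best and ensemble on test, emitting
R²/MSE/Pearson reports and per-point scatter data (CSV, not rendered
figures). Every stage failure is rewrapped with the stage name.

Tests and the acceptance script run the pipeline at deliberately small
sizes — 60–150 synthetic records, 2–10 search trials, 2–3 folds, a few
CNN epochs — chosen so the full suite completes in about a minute while
still exercising every code path; the regressor-recovery checks use
n = 2000 with noise sd 0.1, where the boosted trees reach held-out
R² ≥ 0.99 and the CNN's held-out MSE is about one fifth of the
mean-predictor baseline.

## Known limitations

* The surrogate embedder validates plumbing, not biology; swapping in
  real pretrained providers changes accuracy, not interfaces.
* The CNN is CPU-only NumPy; it is exact and reproducible but not fast
  enough for very large inputs (the full 4096-length stacks train at
  hundreds of samples per second per epoch, not thousands).
* Position-sparse signals are intrinsically hard for weight-shared
  convolutions with pooling; the CNN needs materially more epochs than
  the boosted trees on such synthetic benchmarks.
* Outlier removal (|z| > 3 on log10-k_cat) and duplicate merging by
  geometric mean are fixed policies; datasets with heavy-tailed but
  genuine variation may prefer a larger threshold.
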