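# Methods

## The model

`adscca` integrates two paired gene-level omics matrices — mRNA
expression X ∈ ℝⁿˣᵖ (RSEM-like counts) and DNA methylation Y ∈ ℝⁿˣᑫ
(beta values) — by a multi-task, adaptively weighted deep sparse
canonical correlation model, and feeds the stably selected genes into a
genomically ordered bidirectional-LSTM Cox survival head.

### Sparse deep CCA

Each modality passes through an encoder that preserves the gene
interface (one encoded coordinate per gene). Sparse canonical weight
vectors u ∈ ℝᵖ, v ∈ ℝᑫ gate the encoded features elementwise, and the
canonical variates are the gated sums

    t_x = ⟨h_x, u⟩,   t_y = ⟨h_y, v⟩,

which reduce to the linear CCA projections Xu, Yv when the encoders are
the identity. Training minimizes

    L = λ₁·(−corr(t_x, t_y)) + λ₂·(‖u‖₁ + ‖v‖₁)
      + λ₃·(‖X − X̂‖² + ‖Y − Ŷ‖²)/entries + λ₄·((Var t_x − 1)² + (Var t_y − 1)²)

with λᵢ = 1/(2σᵢ²), σᵢ = softplus(raw σᵢ) + 10⁻³, the σᵢ trained jointly
with the network (homoscedastic-uncertainty weighting). The weighted sum
alone is minimized by σ → ∞, so a + Σ log σᵢ stabilizer is added to the
optimized objective; it is reported separately in `LossBreakdown` so the
printed `total` remains Σ λᵢ·lᵢ. Decoders X̂, Ŷ are single linear layers
reading the pre-gating encoded features h — reconstructing from h rather
than from the gated features keeps the reconstruction task from fighting
the sparsity task.

Optimization is Adam at 1e-3 halved every 100 epochs, batches of 32,
weight decay 1e-4 on encoder/decoder weights (u, v and the σ's are
exempt: u, v already carry the L1 penalty), gradient clipping at global
norm 5. Everything is float64 on a hand-rolled reverse-mode autodiff
engine (`adscca.nn`), single-threaded, so runs are bit-reproducible
from the seed.

### Why the encoders are gene-local

Three encoder families are implemented (`TrainConfig.encoder`):

* **gene-local** (default): h = x + φ(x) with φ a shared scalar MLP
  (1 → 8 → 1, tanh) applied entrywise per modality. It can learn a
  per-modality monotone rescaling — e.g. undo the logistic squash that
  maps latent signal to beta values — but cannot mix genes.
* **dense**: the residual bottleneck p → min(256, 4p) → p with batch
  normalization and ReLU, zero-initialized so h = x at the start.
* **linear**: a single near-identity linear layer (the linear limit used
  to check equivalence with closed-form CCA).

The dense variant is the obvious architecture, but it quietly destroys
the gene-level meaning of u and v: any trainable cross-gene map can
synthesize the shared factor internally and route it through one or two
encoded coordinates, after which the L1 penalty prunes every other
weight. On synthetic data with 20 truly coupled genes per modality, the
dense (and even the trainable linear) encoder collapses the support to
~2 genes at every threshold, while the gene-local encoder recovers
18–20/20 per fold. Since the sparse gate is the part of the model that
claims biological interpretability, the default keeps it honest; the
dense encoder remains available for problems where gene-level weights
are not the goal.

### Support extraction and stability selection

Continuous L1 optimization under Adam never yields exact zeros — unused
weights oscillate at the optimizer's step scale. "Gene j selected"
is therefore operationalized as |w_j| / max|w| > ε with ε = 0.01 by
default. At ε = 10⁻³ the oscillation floor (~140 of 180 noise genes per
fold) passes the gate; at 0.01 per-fold false positives are rare and,
crucially, not reproducible across folds, so the cross-fold stability
rule — keep genes selected (in either modality) in ≥ 9 of 10 folds —
removes them while retaining ~95% of truly coupled genes.

## The survival head

Selected genes are ordered by chromosome (natural order 1..22, X, Y,
then others) and start coordinate. Each patient is a sequence of
2-channel tokens (expression z-score, methylation z-score; 0 fills a
modality a gene lacks — the neutral value on the z scale). A single
bidirectional LSTM (8 units per direction) reads the sequence; the risk
is a per-position linear Cox readout over the concatenated hidden
states and tokens ("skip-linear" pooling), with dropout 0.1 before the
readout. Training maximizes the Breslow partial log-likelihood
(mean-per-event for scale stability) by full-batch Adam — risk sets
couple all samples, so batching is not meaningful — at lr 5e-3 for 200
epochs, halving at epoch 200 by default, weight decay 1e-3.

Mean pooling into a single embedding (`pooling="mean"`) is also
implemented. It systematically underperforms on additive hazards:
a linear readout of the mean token cannot express position-specific
coefficients, so the LSTM must encode position internally, and at a few
hundred samples it memorizes instead (train C ≈ 0.97, test ≈ 0.59 on
the additive benchmark, against 0.72–0.78 for skip-linear with oracle
0.75). The skip-linear readout is still a pooling operator — a learned
position-weighted sum — and keeps the LSTM responsible for what it is
actually needed for: interactions between genomic neighbours.

### The shuffle test

To test whether genomic ordering carries information, the head is
trained once on the genomic order and n_perm = 20 times on random
permutations of the gene order with identical hyperparameters, all
evaluated on the same event-stratified held-out split. On hazards built
from products of adjacent gene pairs the ordered model wins (the LSTM
learns local products; permutation scatters the pairs); on purely
additive hazards the gap sits inside the permutation spread, because a
retrained per-position readout is indifferent to order.

## Cross-validation protocol

`run_nested_cv` is event-stratified at both levels: samples are split
by the event indicator (shuffled, dealt round-robin, so per-fold event
counts differ by ≤ 1). Per outer fold: preprocessing (log2(x+1) for
expression, variance filter below the 10th train percentile, per-gene
z-score) is fitted on outer-train only; the sparse-CCA model is
refitted on each inner fold (preprocessing refitted per inner fold
too); stability selection over the inner folds produces the gene panel;
the survival head trains on outer-train and is evaluated on outer-test
(C-index, median-dichotomized Kaplan–Meier, log-rank, hazard ratio with
95% CI from a univariate Cox fit on the group indicator). The result
object carries an audit trail of every inner-fold training set, and a
test asserts no outer-test sample ever enters one. An empty stable
panel falls back to the top-frequency genes, flagged with a warning.

The inner loop can also select the encoder width from a grid by mean
inner validation canonical correlation (`hidden_width_grid`); the
default is a single width, since the gene-local encoder has no width
hyperparameter worth tuning at desk scale.

## The synthetic generator

One standard-normal latent factor drives both modalities: s coupled
genes per modality load on g(latent) with constant magnitude and random
sign (g ∈ {linear, tanh, quadratic}); all other genes are independent
noise. Expression is emitted as 2^(value+8) — RSEM-scale counts, so the
log2(x+1) path is genuinely exercised — and methylation as
logistic(value), beta values in (0,1) whose monotone distortion gives
nonlinear encoders something real to undo. Survival times are
exponential proportional-hazards draws from a chosen linear predictor;
censoring times are exponential with the rate calibrated by bisection
so the expected censored fraction matches the request. Coordinates are
assigned in blocks dealt round-robin across chromosomes, with strictly
increasing jittered ~10 kb starts, so block members are genomic
neighbours. `generate_blocked_risk` adds products of adjacent
non-overlapping gene windows to the log hazard, creating the
order-sensitive signal the shuffle test needs.

What the generator does **not** emulate: probe-level methylation
structure, count overdispersion, batch effects, tumor subtypes,
gene–gene correlation beyond the single shared factor, or informative
censoring. Passing the bundled studies therefore shows the machinery is
correct and the model behaves as designed under its own assumptions —
not that it will match any particular real-cohort performance.

## Reference study designs (scripts/acceptance.py)

* **Linear limit**: n=500, p=q=20 Gaussian shared-factor data; the
  linear/unpenalized model's trained correlation vs the generalized
  eigenproblem solution (gap ~5e-3, band 0.05).
* **Support recovery**: n=300, p=q=200, s=20, signal/noise 2; 10-fold
  stability selection at ≥9/10, three seeds; recall and FDP vs the
  planted support. 80 epochs per fold keeps the three-seed study around
  three minutes.
* **Survival benchmark**: n=400, 20 genes, ±0.25 additive hazard, 30%
  censoring (true-predictor oracle C ≈ 0.75); 300/100 stratified split;
  permuted-label control averaged over 5 permutations.
* **Shuffle study**: n=400, 24 genes; blocked arm with window-2
  interactions at strength 0.6 (order-information oracle C ≈ 0.84),
  additive arm with ±0.25 coefficients; 20 permutations each.
* **Training dynamics**: n=200, p=q=40 run for 300 epochs; λ
  trajectories must stay in (0, 1/(2·10⁻⁶)), every component finite,
  and the moving-average (window 31) total non-increasing after
  epoch 50.

## Numerical choices

* σ floor 10⁻³ under softplus bounds λᵢ < 5·10⁵; ε = 10⁻⁸ guards the
  Pearson denominator (a zero-variance variate yields correlation 0,
  never NaN).
* Zero-variance genes at z-score fit: sd floored at 10⁻⁸ and flagged;
  any positive variance-filter percentile removes them.
* Variance-filter percentile: linear interpolation between order
  statistics; removal is strict `<` the cutoff.
* Ties: Breslow approximation in every Cox computation; C-index pairs
  tied in time are incomparable, tied risks credit 0.5; a risk equal to
  the median goes to the low group.
* Wilcoxon signed-rank: exact enumeration up to 25 nonzero differences,
  normal approximation with continuity correction beyond.
* Monotone Cox likelihoods (separation) are flagged with a ±inf CI
  after scale-normalizing the covariate, never silently returned.
* Days→months conversions use 30.44 when needed; the generator emits
  months directly.

## Limitations

Two views only; a single canonical pair (no deflation); the recurrent
head sees at most a few thousand genes comfortably; the hand-rolled
autodiff engine is CPU/float64 only and unbatched over LSTM time steps,
so paper-scale cohorts (10⁴ genes, 1000 epochs) are hours, not minutes;
stability selection frequencies are interpreted by a fixed threshold
rather than an error-controlled bound.
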