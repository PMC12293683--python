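# Methods

## Problem

Brain age — the age a model attributes to a brain from structural imaging
features — is used as a compact biomarker of neurodegeneration: a positive
brain-age gap (predicted minus chronological age) in a patient group is read
as accelerated structural ageing. `brainsage` implements the tabular half of
such a pipeline: it starts from per-subject, per-ROI grey-matter (GM) and
white-matter (WM) volumes (N = 56 atlas regions by default), learns an
anatomical graph over the ROIs, and regresses age with a graph neural
network designed to stay informative at depth. Image processing
(segmentation, parcellation) is out of scope; the package consumes the
resulting volume tables.

## Preprocessing

Volumes are divided by the subject's total intracranial volume (TIV) to
remove head-size effects, then each ROI column is standardized to zero mean
and unit variance (sample SD, ddof = 1 — the choice only rescales features
uniformly). Standardization statistics are fitted on the training split by
default and applied to held-out data; fitting on all subjects is available
(`--standardize-on=all`) because the original protocol computed statistics
"across subjects" without specifying the split, but the train-only default
avoids leakage. Order is enforced by state flags: normalise, then
standardise; repeating either step raises.

## Anatomical graph learning

For node i with standardized GM column y_i and remaining columns Y_i, edge
weights solve the neighbourhood-selection LASSO

    J_i(w) = (1/2M) ||y_i − Y_i w||² + λ ||w||₁ ,

by cyclic coordinate descent with soft-thresholding (tol 1e-8 on the
largest coefficient update, iteration cap 1e5). The 1/(2M) quadratic
scaling is the mainstream LASSO convention and makes λ interpretable on a
partial-correlation scale, so the default λ = 0.06 prunes meaningfully
regardless of cohort size; the literal unscaled sum-of-squares objective is
available as `objective_scaling="sum"`. Tests pin both conventions against
an independent convex solver.

The N per-node coefficient vectors (zero-padded at their own index) are
stacked into W and symmetrized either as

* `matrix_product` (default): A = √|W Wᵀ| entrywise, diagonal forced to
  zero. The "multiply by the transpose, then take the square root"
  construction; the absolute value guards against negative inner products
  and the diagonal (‖w_i‖², a self-loop) is discarded. Note the entries of
  W Wᵀ are inner products of coefficient rows, so two nodes can be joined
  through shared neighbours even when neither selects the other — this mode
  tends to produce denser graphs.
* `hadamard`: A_ij = √|w_ij · w_ji|, the geometric mean of the two directed
  coefficients — the standard reciprocal-support symmetrization in sparse
  graph learning; typically much sparser.

The 2×2 swap matrix W = [[0,1],[1,0]] separates the modes: the matrix
product is the identity (edge annihilated), the Hadamard form keeps the
edge. Entries above a numerical threshold (1e-8) become the edges of an
unweighted graph. By default the graph is learned from the training split
only; `--graph-on=all` uses every subject. Graph construction is fully
deterministic.

## Model

Node features are the standardized (GM, WM) pair, so X ∈ R^{N×2} per
subject, on a topology shared by all subjects. The network cascades r = 4
GraphSAGE layers with a mean aggregator,

    x_v' = LeakyReLU( [ x_v ; mean_{u∈N(v)} x_u ] · W ),

with a separate learnable root path for the node's own vector (the form
mainstream graph libraries implement for the mean aggregator). A config
switch (`sage_self="include"`) instead folds the node into the mean,
x_v' = σ(mean over {v}∪N(v) · W), the inductive-GCN reading. The default
matters for the oversmoothing analysis below: with the self vector inside
the mean every layer is a contraction toward neighbourhood averages,
whereas the root path preserves node-distinct information at depth, and
only the latter reproduces the energy-retention behaviour the architecture
is designed for. Isolated nodes aggregate only themselves.

After every layer an ROI-aware pooling block produces a graph-level
embedding: each of H = 4 heads owns a learnable logit per ROI, softmaxed
over the N nodes into an attention distribution (each head is a
distribution over ROIs — the axis choice that makes the pooled vector a
weighted average); head h pools z_h = Σ_i a_{ih} x_i and heads are
concatenated into Z^(l) ∈ R^{H·F}. Each Z^(l) feeds an independent
two-layer auxiliary regression head (deep supervision). The per-layer
embeddings are fused — concatenation by default; mean, max, sum, a
softmax-weighted sum with learnable layer logits, and a data-dependent
attention over layers (a learnable scorer maps each Z^(l) to a scalar,
softmaxed across layers; the construction is our interpretation, since
only the method name is canonical) — and a final two-layer perceptron
outputs age. With r = 1 every fusion method degenerates to Z^(1), a tested
invariant.

Unstated widths default to hidden_dim = 64, H = 4, LeakyReLU slope 0.01;
none is claimed to be canonical. Dropout (ρ = 0.15) is applied after each
activation, before pooling, only in training mode. Weights are initialised
fan-in-uniform from a seeded generator; a fit is a pure function of
(data, graph, configs, seed).

Baselines with the same predict-age contract are provided for comparison:
an FCNN on flattened N·F features, and GCN / classic GraphSAGE / GAT
(single-head, dense masked attention — exact at N = 56) / GIN stacks plus a
`plain_mean` mean-aggregation stack, each with a single global mean pool
and the same regressor head. All networks, including backpropagation, run
on a small reverse-mode autodiff core written for this package
(`brainsage.autodiff`); gradients are finite-difference-checked in the test
suite.

## Training

The hybrid loss is

    L = MSE(ŷ, y) + α · (1/r) Σ_l MSE(ŷ_aux^(l), y),   α = 0.30,

optimised with Adam (lr 0.01, batch size 16) over shuffled mini-batches.
At α = 0 the auxiliary heads receive exactly zero gradient (tested). The
adaptive learning-rate policy is reduce-on-plateau of the monitored MAE
(factor 0.5, patience 10, floor 1e-5) with early stopping (patience 30)
and an epoch cap of 300; all are engineering choices, exposed in
`TrainConfig`. Evaluation uses an 80:20 holdout (test count floored) and
5-fold cross-validation with plain shuffled folds (no age stratification),
reporting MAE and RMSE in years and Pearson correlation (sample
covariance); RMSE ≥ MAE is asserted on every report. The acceptance script
and the heavier tests shorten the schedule (epochs 40–100 with
proportionally tighter patience), which is ample for the synthetic cohorts
used there.

## Oversmoothing diagnostics

The degree-normalised Dirichlet energy of node features x at a layer is

    E(x) = Σ_i Σ_{j∈N(i)} ‖ x_i/√(1+d_i) − x_j/√(1+d_j) ‖²

(each edge counted in both directions). Low energy means neighbouring
embeddings have collapsed toward each other. Two subtleties the test suite
makes explicit: identical features do *not* give zero energy when degrees
differ (a 3-node path of identical scalars has E ≈ 0.0673), and E is
homogeneous of degree 2 in the feature scale, so raw energies of different
networks are only comparable when their embedding scales are — comparisons
across trained models should be read with that in mind. Energy profiles
are computed in inference mode after training, averaged over subjects.
The reference null is an unparameterised include-self mean-aggregation
stack (identity weights), whose per-layer energy decreases monotonically
on a connected graph; the trained default network retains strictly higher
final-layer energy than that stack at equal depth, and ablating the
auxiliary loss (α = 0) collapses deep-layer energy by more than an order
of magnitude — the mechanism the architecture exists to counter.

## Synthetic cohorts

The generator emulates a volumetric ageing cohort at the table level: ages
uniform on 51–95 years; TIV normal (1.5e6 ± 1.2e5 mm³, truncated
positive); per-ROI baseline volume fractions uniform on 0.8–2% of TIV; GM
declining linearly by 0.3–0.7% of baseline per year (WM 0.2–0.6%,
independent slopes); a per-(cluster, subject) standard-normal community
factor entering with loading 6e-4 so ROIs in the same latent cluster (4
clusters over 56 ROIs) co-vary beyond the shared age trend; additive
Gaussian noise with SD 4e-4 on the volume-fraction scale. At these
defaults the per-ROI age correlation is ≈ 0.7–0.8 — a strong but not
degenerate signal chosen so that age recovery succeeds with a clear margin
over the ≈ 11-year MAE of a null predictor, which is the regime the
pipeline's contracts are tested in. Setting slopes and loading to zero
yields a pure-noise null cohort (negative control: cross-validated |PCC|
stays below 0.2). What the generator does not emulate — real
neuroanatomy, hemispheric symmetry, scanner/site effects, non-linear
trajectories, disease heterogeneity — bounds what passing tests show: they
validate the machinery and its contracts, not clinical performance, and
the original study's real-data accuracy figures are not reproducible from
synthetic tables.

## Numerical and degenerate-input choices

Softmax is computed with max-subtraction; ties in max-fusion split the
gradient equally (measure-zero for continuous inputs). Zero-variance ROI
columns, non-positive TIV, non-finite cells, asymmetric adjacency input,
k > M folds and empty batches all raise informative errors rather than
propagating NaNs; a non-finite training loss aborts naming the epoch.
Checkpoints carry the model/train configs and a fingerprint (hash) of the
graph edge list; prediction on a graph whose fingerprint differs from the
checkpoint's is refused, since predictions would not be comparable.

## Known limitations

The LASSO solver is plain cyclic coordinate descent — adequate at N = 56
but not tuned for large N. The GAT baseline materialises a dense N×N
attention matrix. No bias-correction of brain-age estimates
(regression-to-the-mean) and no significance testing of gap differences
are performed, mirroring the scope of the protocol the package implements.
Training is single-threaded NumPy; cohort sizes in the hundreds are
comfortable, but this is a desk-scale research implementation, not a
production trainer.
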