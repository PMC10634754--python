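# Methods

This note documents the models implemented in `hypconn`, the numerical
choices behind them, what the synthetic generators emulate, and the known
limitations. Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`.

## Poincaré-ball geometry

All embeddings live on the Poincaré ball of curvature `K < 0`, the open
set `{x : |K|·||x||² < 1}` of Euclidean radius `1/√|K|`. The geodesic
distance is

    d_K(u, v) = arccosh(1 + 2|K|·||u−v||² / ((1−|K|·||u||²)(1−|K|·||v||²))) / √|K|,

which for points measured from the center reduces to
`d_K(0, x) = (2/√|K|)·artanh(√|K|·||x||)`. As `|K| → 0` the distance
approaches `2·||u−v||`; this flat limit is what makes the Euclidean GCN a
degenerate case of the hyperbolic one.

Euclidean operations are transported through the tangent space at the
origin: `f(x) ↦ exp₀(f(log₀(x)))`. Möbius matrix–vector multiplication
uses the norm-rescaled closed form; Möbius addition is the gyrovector
sum. Only origin-based exponential/logarithmic maps are exposed;
base-point maps exist privately inside the Fréchet-mean solver.

Numerical safeguards, applied uniformly:

* points are clamped to radius `(1−ε)/√|K|` with `ε = 1e−5`;
* `artanh` / `arccosh` arguments are clamped into their open domains by
  `1e−15`;
* norms are computed as `√(Σx² + 1e−30)` so that all operations remain
  differentiable at the origin.

### Fréchet (Karcher) mean

Neighborhood aggregation uses the weighted Fréchet mean — the minimizer
of the weighted sum of **squared** geodesic distances (the differentiable
Karcher formulation; the equally common "sum of distances" phrasing
describes the same construction loosely). The solver is a damped
fixed-point iteration: map the point set into the tangent space at the
current iterate, take the weighted Euclidean mean scaled by a step size,
and map back.

Two choices matter for robustness:

* **Warm start.** The default initialization is the weighted Lorentzian
  centroid (lift to the hyperboloid, Minkowski-average, renormalize,
  project back), computed detached from the autodiff tape. Initializing
  at the largest-weight input point is available as an option, but for
  near-boundary point sets — which arise mid-training — that start plus a
  unit step oscillates and can take hundreds of iterations.
* **Step size.** The eigenvalues of the Hessian of `d²/2` lie in
  `[1, z·coth z]` with `z = √|K|·d`, so the per-row step
  `1/E_w[z·coth z]` is safe; a detached backtracking line search guards
  the remainder. The objective is therefore non-increasing across
  iterations by construction.

The public `frechet_mean` converges to tolerance `1e−8` on the objective
(up to 1000 iterations) and raises on non-convergence. Inside network
layers the solve is truncated (tolerance `1e−4`, at most 30 damped
iterations) and returns the last — still monotone-improved — iterate;
gradients are obtained by differentiating through the unrolled
iterations, which agrees with the implicit derivative to about `1e−4`
(checked against central finite differences).

Aggregation weights are uniform over the closed neighborhood
`{N(i), i}`; isolated nodes aggregate over themselves alone.

## The hyperbolic graph convolutional network

Input features are one-hot node identities, lifted into the ball by
`exp₀` at the hidden curvature. Each of the two layers applies

1. feature transform: `h_i = (W ⊗_K x_i) ⊕_K exp₀(b)`;
2. Fréchet-mean aggregation over `{N(i), i}`;
3. tangent-space ReLU (hidden layer only), which also carries the state
   from the hidden curvature `K₁` to the output curvature `K₂`.

The final layer applies no activation, so the output coordinates live on
the ball of curvature `K₂`. Defaults: hidden dimension 6, output
dimension `D` (2–8), 100 epochs, learning rate 0.02, batch size one
graph, Adam with betas (0.9, 0.999) — a configuration sized for dense
90-ROI graphs. Curvatures are either
fixed at −1 or learned through `K = −softplus(c)` (initialized at −1), so
negativity is guaranteed and all trainable parameters are unconstrained —
ordinary Adam updates are then exactly the Riemannian Adam updates for
this parameterization. Biases are Euclidean parameters lifted by `exp₀`
before Möbius addition, for the same reason.

The decoder is Fermi–Dirac: `p_ij = 1/(exp((d²(x_i,x_j) − r)/t) + 1)`
with `r = 2`, `t = 1`. Rather than cross-entropy on binary edges, the
loss is the mean squared error between decoded probabilities and min–max
scaled PLV values over all off-diagonal upper-triangle pairs — the
continuous connectivity carries information the 0/1 adjacency has lost.
Scaling is per graph, so each network's targets span [0, 1].

The training loop and all generators consume explicit integer seeds and
are fully deterministic: two runs with equal seeds produce bitwise-equal
loss traces and embeddings.

### Autodiff

No GPU tensor framework is used; gradients come from a small
reverse-mode engine (`hypconn._ad`) over numpy arrays with the usual
broadcasting semantics. Geometry code is written once against dispatching
helpers and serves both the training path (taped) and inference (plain
numpy).

### Baselines

* **Euclidean GCN** — identical architecture with linear layers,
  arithmetic-mean aggregation over the closed neighborhood, ReLU, and a
  Euclidean-distance Fermi–Dirac decoder. At `|K| → 0` the hyperbolic
  layer reproduces it (asserted at `|K| = 1e−6`).
* **Shallow Poincaré embedding** — per-node free coordinates on the unit
  ball fit to a single graph by Riemannian SGD (gradient rescaled by
  `(1−||θ||²)²/4`) with negative-sampling softmax over distances, 10
  negatives per edge, a 10-epoch burn-in at a tenth of the learning
  rate. It is transductive: it cannot embed unseen graphs.

## Link-prediction evaluation

Cross-validation is grouped by participant: both sessions of a subject
share a fold, so held-out subjects never contribute gradients. The HGCN
and GCN are evaluated inductively — the trained model embeds an unseen
test graph and MAP is computed over all its node pairs. The shallow model
is fit per test graph on 80% of its edges and scored on the held-out 20%,
with training edges excluded from the candidate ranking; the report
records the protocol per row so the asymmetry is explicit.

MAP is per-node average precision: for each node with degree ≥ 1, rank
all other candidates by score (descending, ties broken by node index) and
average the precision at each true-neighbor hit, then average over nodes.
Note a property relevant to null baselines: for a node with `k` neighbors
among `n` candidates, the expected AP of a random ranking exceeds the
prevalence `k/n` by a term of order `(1−k/n)/(k+1)`; the suite therefore
checks the random-score null against an exact permutation oracle rather
than against the raw density.

## Radius hierarchy and group statistics

The hierarchy proxy of a node is its geodesic distance from the ball
center at the learned output curvature; hubs embed near the center, so a
*lower* radius means a *higher* hierarchical position. Subnetwork
hierarchy is the unweighted mean radius of member nodes under the eight
canonical resting-state subnetworks (pDMN, aDMN, DAN, FPN, VN, VAN, SN,
SMN). The shipped AAL-90 → subnetwork table is an approximate
literature-based assignment by spatial proximity and is explicitly a
replaceable configuration file (`load_subnetwork_map`).

Group inference is a covariate-adjusted linear contrast: radii are
session-averaged per subject, then each subnetwork's mean radius is
regressed on the group indicator plus covariates (age by default) by
ordinary least squares; the contrast's t-test p-value (or a subject-level
permutation p, two-sided, label permutations shared across subnetworks)
is corrected across the eight subnetworks by Benjamini–Hochberg FDR. This
is deliberately a simpler, transparent approximation of a two-way
repeated-measures ANCOVA (time × diagnosis with an age covariate): with
session-averaged radii, the between-subject diagnosis effect tested here
is the same contrast; within-subject time effects and interactions are
out of scope.

Radius-based analyses presuppose hub-centric embeddings. Link-probability
training occasionally settles into an optimum that fits edge
probabilities without placing hubs centrally; `fit_radius_embedder`
screens for this with a training-set diagnostic (mean Spearman
correlation between node degree and radius; runs above −0.55 are refit
with a shifted seed, at most twice, keeping the most hub-centric fit).
The diagnostic never sees held-out data.

For classification, features are (a) the vectorized upper-triangle PLV
values (4005 for 90 ROIs), (b) the 90 node radii, or (c) their
concatenation, restricted to pre-intervention sessions. The classifier is
an SVM (RBF kernel, `C = 1`; linear kernel by flag) with per-training-fold
standardization inside a stratified five-fold CV, reporting Macro F1 and
AUC-ROC. Kernel and `C` are common defaults, not tuned.

## Synthetic data

The generators give every analysis a no-download test surface with known
ground truth. They emulate the statistical shape of alpha-band PLV brain
networks, not their biophysics.

* **Hierarchical graphs** come from a popularity×similarity (S¹
  geometric) rule: deterministic heavy-tailed hidden degrees `κ_i`
  (Pareto-like with exponent `γ = 2.5`, largest at low node index),
  uniform angles, connection probability
  `1/(1 + (d_ij/(μ·κ_i·κ_j))^{1/T})` with temperature `T = 0.3`, and `μ`
  calibrated by bisection to the target mean degree (density 0.20 by
  default, matching a thresholded PLV network that retains roughly 20% of
  edges). Connection propensities plus Gaussian noise (SD 0.02), min–max
  scaled, double as continuous PLV-like edge weights. At `T → 0` the rule
  degenerates to a deterministic threshold graph.
* **Cohorts** share a latent angular layout across subjects (participant
  brain networks share most of their topology); each subject jitters the
  angles (SD 0.1 rad) and redraws edges. Without this sharing, nothing
  about edge placement transfers across subjects and inductive link
  prediction collapses to degree information only.
* **Two-group cohorts** implant a hierarchy difference by multiplying the
  hidden degrees of designated-subnetwork nodes (DAN, FPN, VAN by
  default) in group 2 by `1 + δ`, then recalibrating `μ` so both groups
  share the same expected density. The implant therefore shifts
  *relative* hubness: an uncompensated boost would raise group-2 density
  by ~20% and confound every radius comparison. The compensation is
  zero-sum — non-designated nodes carry an opposite shift of roughly
  `κ-share/(1 − κ-share) ≈ 27/73` of the implanted signal — so perfect
  set-specificity of recovery is structurally limited; the validation
  suite measures sensitivity, exact-set rate and null calibration
  separately. The default `δ = 0.5` produces designated-subnetwork radius
  effects of roughly 3–6 subject-level standard deviations, clearly
  detectable at n = 20/group; a paper-realistic implant matching reported
  effect magnitudes (differences ≈ 0.09–0.16 against subject SD
  ≈ 0.1–0.19, d ≈ 1–1.6) corresponds to δ ≈ 0.3 and sits near the
  detection boundary, as such effects do in real cohorts. Each subject
  optionally gets a second session by rewiring 5% of edges, and a normal
  age covariate (71 ± 4.5 years).
* **Oscillator cohorts** validate the PLV estimator: a symmetric coupling
  matrix is reduced to its best rank-one factorization `w·wᵀ` (top
  eigenpair); region `r` mixes a shared oscillator with weight `w_r`
  against independent phase noise per source and epoch. Expected PLV is
  then monotone in coupling, exactly rank-one couplings being the
  calibrated case.
* **Radius tables** (`make_radius_table`) generate subject×session
  subnetwork radii with implanted shifts directly, bypassing graphs, to
  calibrate the statistics in isolation.

PLV itself is computed per epoch (the magnitude of the time-averaged unit
phasor of the phase difference, averaged over all source pairs) and then
averaged across epochs; a flag pools epochs into one window instead. The
binarization threshold (0.329 by default) is exposed alongside a
target-density mode that keeps exactly `round(density·n_pairs)` edges.

## Problem sizes of the shipped experiments

The validation suite and acceptance script run every experiment at desk
scale, chosen to complete on one CPU core in minutes: the model
comparison uses a 20-graph cohort of 90-node networks, 4 training graphs,
70 epochs, five seeds; hierarchy recovery uses 5–6 replicates (plus 3
null replicates) of n = 20/group cohorts with a 4-graph, 30-epoch
screened embedder; the Fréchet oracle comparison uses 60–100 random
point sets.
The defaults on the model classes themselves (100 epochs, full training
sets) are unchanged by this scaling.

## Known limitations

* MEG preprocessing, beamforming and source reconstruction are out of
  scope; the pipeline starts from phases or PLV matrices.
* The shipped subnetwork table is approximate; analyses intended for real
  AAL data should supply a study-specific mapping.
* The generators do not model volume conduction or source leakage, so
  passing tests demonstrate correct behavior on networks with known
  ground truth, not performance on real MEG cohorts.
* The repeated-measures ANCOVA is approximated by the adjusted contrast
  described above; time-by-diagnosis interactions are not tested.
* Per-node average precision carries the finite-candidate bias noted
  above; compare MAP values only across models evaluated on the same
  graphs.
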