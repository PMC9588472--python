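# Methods

## The model

`ntfa` implements a topographic factor model for labelled 4-D fMRI
segments. A *segment* is the data of one participant-trial combination,
a T×V matrix Y of T time points (TRs) over V in-mask voxels. The model
assumes Y ≈ W F: a K×V matrix F of spatial factors — radial basis
"blobs" in brain space — weighted over time by a T×K matrix W, with
K ≪ V.

Everything above the factorization is driven by low-dimensional
embeddings passed through three shared one-hidden-layer tanh networks
(16 hidden units — the smallest genuinely nonlinear choice that did not
leave spare capacity for encoding participant identity the data never
ask for; standard-deviation heads pass through softplus with a 10^-3
floor):

* each participant p has a **spatial embedding** z^PF_p and a **weight
  embedding** z^P_p, each D-dimensional with a standard-normal prior;
* each trial s has a **trial embedding** z^S_s, same prior;
* θ_C maps (z^P_p, z^S_s) to the **activation embedding** z^C of the
  combination (a deterministic node);
* θ_F maps z^PF_p to Gaussian parameters (μ^x, σ^x, μ^ρ, σ^ρ) from
  which the K factor centers x^F (mm) and log-widths ρ^F are drawn;
* θ_W maps z^C to Gaussian parameters (μ^W, σ^W) from which the factor
  weights are drawn independently at every TR.

The factor kernel is F[k, v] = exp(−‖coords[v] − x_k‖² / exp(ρ_k)), so
exp(ρ) is a squared-width scale: a blob of Gaussian shape with spatial
sd w corresponds to ρ = log(2w²). Data are generated as
Y_t ~ N(W_t F, σ_Y² I).

Because the networks are shared across all participants and trials, the
embeddings are commensurable: two combinations whose brains respond
alike end up with nearby activation embeddings, and the *cluster
structure* of those embeddings reveals degeneracy — whether distinct
trials (or participants) engage distinct neural patterns while carrying
the same task labels.

D = 2 by default so embeddings are directly plottable. σ_Y is fixed at
1.0 after the data are standardized to unit global variance (an
optional flag learns log σ_Y as a point parameter); this removes the
scale ambiguity between W and σ_Y.

## Inference

The posterior over all latents is approximated with a fully factorized
Gaussian family: per-TR weight blocks q(W_{n,t}), per-trial q(z^S_s),
and per-participant q(x^F_p), q(ρ^F_p), q(z^P_p), q(z^PF_p), each
parameterized by a mean and a log-std. The evidence lower bound

    L = E_q[log p(Y | W, x^F, ρ^F)] − KL(q ‖ p)

is maximized over the variational parameters and the network weights
with reparameterized gradients. Embedding KL terms are closed-form
against the standard normal; the factor and weight KL terms are
closed-form Gaussian KLs evaluated at a reparameterized draw of the
conditioning embedding (their prior parameters are network outputs, so
no unconditional closed form exists). The estimator is therefore
unbiased for L and the reported KL part is non-negative by
construction, with total = reconstruction − KL as an arithmetic
identity.

Gradients are computed by a small reverse-mode automatic
differentiation engine written on numpy (`ntfa.autodiff`); its
vector-Jacobian products are verified against central finite
differences in the test suite. The optimizer is Adam (learning rate
10⁻², the adaptive-step default; a vanilla-SGD flag exists), full batch,
one Monte-Carlo sample per step by default.

### Initialization

* Embedding blocks start at mean 0, std 1.
* Factor centers/log-widths: either k-means on the voxel coordinates
  (centers = centroids, widths from cluster variances) or, by default,
  **hotspot** initialization — greedily place each center at the peak
  of the mean image, fit the best isotropic width by golden-section
  search for a factor scaled to the residual peak value, subtract, and
  repeat. Peaks are picked on *each participant's own* mean image
  (factors are per-participant variables), order-aligned to a
  dataset-level reference by optimal assignment, and snapped onto the
  reference wherever they agree within 1.5 voxels. The snap keeps the
  factor basis identical across participants wherever their functional
  anatomy agrees, which is what makes factor weights — and hence
  activation embeddings — comparable across participants; the
  participant-specific peaks that survive the snap are exactly the ones
  that carry participant-level degeneracy.
* Weight means: ordinary least squares fit of the initial factors to
  the dataset-wide average image (ridge fallback if the factor matrix
  is rank-deficient); stds start at 1.
* The output biases of θ_F and θ_W are set so the conditional priors
  start centered on the same initialization.

### Regularization

An L2 penalty (weight 1.0) on the three networks' weight matrices (not
their biases, which anchor the initialization) is added to the loss.
Its purpose is identifiability rather than generalization: a
participant offset inside an activation-embedding cluster that the data
do not require changes the ELBO by well under a nat against a
reconstruction term of order 10⁵, so wherever early training leaves
such an offset it would otherwise persist and masquerade as cluster
structure. Occam pressure on the shared maps removes embedding
directions the data do not use, while genuine participant splits (which
buy reconstruction) survive it.

### Convergence

Training stops when the relative change between successive 50-epoch
moving averages of the ELBO falls below 10⁻⁴, or at 2000 epochs. A
shorter window is unreliable at one Monte-Carlo sample per step: the
window means are then noise-dominated and the rule can fire mid-climb.

## Synthetic data

The simulator emulates a two-condition experiment: per participant, 2
baseline trials and 6 experimental trials (2 each of types A, B, C), 20
TRs per trial, on an ellipsoidal MNI-proportioned grid with 8 mm
isotropic voxels. Activation templates are sums of three spherical
Gaussian areas (sd 12 mm, amplitude 1) with centers sampled uniformly
over in-mask voxels under a minimum pairwise separation of 4 widths —
at 3 widths the summed tails of two areas stay above half-maximum
between them and the areas cease to be distinct at the conventional
0.5-max threshold. Scenarios differ only in template sharing:

* **non-degenerate** — A, B, C share one template;
* **by condition** — three distinct templates, shared by participants;
* **by condition and participant** — additionally, participants past
  the first get their own A and C variants (one group area replaced by
  a new one), while B stays shared.

Noise is i.i.d. Gaussian, sd = sd(rendered template over in-mask
voxels)/SNR, with SNR 8 by default. Baseline trials have a zero
template; their noise sd is the scenario's floor, set to the mean
experimental noise sd so all trials are equally noisy. All randomness
derives from one top-level seed with one child stream per segment,
keyed by (participant, trial).

What the simulator does *not* emulate: hemodynamic response, drift,
physiological or motion artifacts, spatially correlated noise,
multi-session designs. Passing tests therefore demonstrate that the
method recovers degeneracy structure from idealized, denoised
BOLD-like data — not that it is robust to real-scanner nuisance
structure.

## Reading degeneracy off the embeddings

After fitting, each combination's activation embedding is
θ_C(E[z^P], E[z^S]), with uncertainty from 100 pushforward draws. The
means are clustered with seeded k-means (20 restarts) for k ∈ 2..6; k
is chosen by mean silhouette with a parsimony rule: the smallest k
within 0.02 of the best silhouette. (With 16 near-duplicate points,
0.01-level silhouette differences routinely favour spurious finer
clusterings that no visual reading of the embedding plot would
distinguish.) The verdict rule:

* experimental combinations in one cluster, disjoint from baseline →
  non-degenerate;
* clusters align with trial types, none split by participant →
  degeneracy by condition;
* any trial type whose combinations occupy ≥ 2 clusters with membership
  perfectly predicted by participant → degeneracy by condition and
  participant (those types are listed).

Posterior uncertainty is reported in the tables and plots but does not
enter the verdict.

## The GLM baseline

Per participant, segments are stacked in trial order and each trial
gets one boxcar regressor (no hemodynamic convolution or nuisance
columns — the simulation contains neither). For disjoint boxcars the
per-voxel OLS betas equal each trial's temporal mean exactly (tested as
an identity). The contrast is mean(experimental betas) −
mean(baseline betas) per participant, averaged across participants, so
the 2-vs-6 trial imbalance cancels. Region counting binarizes at
0.5 × map maximum and counts 6-connected components inside the mask —
deterministic and scale-free on synthetic data, in place of the
statistical thresholds used on real designs.

## Problem sizes and stochasticity

Analyses, tests and the acceptance script run on a 12×14×12 grid
(~600 in-mask voxels at 8 mm), 2 participants, 16 segments — the
package's desk-scale configuration; `make_brain_grid()` defaults to the
full 23×27×23 MNI-at-8mm box for larger runs, and a 20-participant
configuration is supported. K = 5 factors for the one- and
three-template scenarios; K = 8 for the participant-degeneracy
scenario, where each participant expresses nine distinct areas and
five factors would occupy only the shared peaks, leaving no capacity
for the participant-specific areas that carry the split signal.

Single-sample stochastic variational fits on these small datasets are
genuinely run-to-run variable: across many seeds, roughly five of six
runs per scenario land in the expected structure, and the failure
modes are instructive (a residual participant offset read as extra
clusters, or a weak mode swallowed by the weight prior's variance).
Cluster-structure checks are therefore taken as the majority outcome
of three seeded runs, both in the acceptance tests and in
`scripts/acceptance.py`; single-fit behaviour is what the per-seed
sweeps in the development history show, not something the package
guarantees.

## Known limitations

* The activation-embedding geometry is identified only up to the
  data's demands; the L2 pressure resolves the remaining freedom in
  favour of fewer clusters, which is a modelling choice, not a fact
  about brains.
* The silhouette rule is a deterministic surrogate for visual cluster
  reading; its 0.02 parsimony margin and the 2..6 scan range are
  conventions.
* The KL terms conditioned on network outputs are estimated at one
  embedding draw per step; their gradients are unbiased but noisy, and
  nothing here addresses amortization or importance weighting.
* No hemodynamics anywhere: applying the package to real fMRI would
  require convolution-aware preprocessing upstream.
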