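# Methods

## Model

`latentsna` models, jointly, N participant-specific symmetric V × V
connectivity matrices and an N × P behavior table.  Edge values follow a
symmetric bilinear latent-space regression

    x_uvi = w_i' β + a_i + z_ui z_vi + e_uvi,    e_uvi ~ N(0, σ²),  u < v,

with participant covariates w_i (first entry 1), participant intercepts
a_i, and unidimensional region latents z_ui.  Outcomes follow a Rasch-type
measurement model with unit item loadings

    y_ip = h_i' γ + b_p + θ_i + ε_ip,    ε_ip ~ N(0, τ²).

The per-participant latent vector (z_i, θ_i) is MVN(0, Σ) with
Σ = [[Λ_z, Λ_zθ], [Λ_zθ', Λ_θ]]; nonzero entries of the V × 1 cross block
Λ_zθ are the region-level biomarkers.  Self-edges are never modeled or
read; all edge sums run over u < v.  Missing edges or outcome items are
carried as masks and simply drop out of the likelihood sums — this one
mechanism also implements out-of-sample prediction (below).

Priors: β, γ ~ MVN(0, I); a_i, b_p ~ N(0, 1); σ⁻², τ⁻² ~ gamma(½, ½)
(shape/rate); Σ ~ inverse-Wishart with identity scale S₀ and degrees of
freedom m₀ = V + D + 2 (D = 1), so the prior mean of Σ is the identity.
θ's location is softly identified by its zero-mean prior against the item
intercepts; no hard constraint is imposed.

## Estimation

A six-step Gibbs cycle, in order: (β, a) → σ² → (γ, b) → τ² → {Z, θ} → Σ.
All full conditionals are conjugate:

- β and γ: multivariate normal; a_i and b_p: scalar normal.
- σ⁻² ~ gamma(½ + n_edges/2, ½ + SSE/2), τ⁻² analogous with the item SSE.
- z_ui, swept u = 1…V and vectorized across participants (they are
  conditionally independent): normal with precision
  Σ_{v≠u} z_vi²/σ² + (prior term) and mean combining the bilinear-free edge
  residuals f_uvi z_vi/σ² with the prior's cross terms.  By default the
  prior term is the exact conditional of z_u given all other coordinates
  under MVN(0, Σ), taken from the joint precision matrix; the
  `region_marginal_prior` switch instead inverts only the 2 × 2 submatrix
  of Σ involving (z_u, θ) — a single-region approximation that coincides
  with the exact rule whenever Σ couples each region to θ only.
- θ_i: normal with precision P_obs/τ² + Q_θ and mean combining item
  residuals with the −Q_θz' z_i cross term.
- Σ ~ IW(S₀ + F'ᵀF', N + m₀) with F' the N × (V+1) matrix of latent rows.

### Reflection indeterminacy

The bilinear term makes the edge likelihood invariant under z_i → −z_i per
participant.  Three mechanisms deal with the three consequences:

1. **Mixing.** Coordinate-wise z draws essentially never cross the
   reflection barrier once ‖z_i‖ is large, so a plain sweep freezes each
   participant's sign at an arbitrary early-chain value and the
   cross-covariance collapses toward zero.  After each regional sweep the
   sampler therefore makes an exact reflection-mode Gibbs move: the
   conditional probability of the flipped mode depends only on the prior
   cross term g_i = θ_i (Q_θz · z_i) and is sampled in closed form.  This
   move leaves the stationary distribution untouched and is what lets the
   chain find the mode in which latent signs align with the outcome —
   without it, planted cross-covariances of 0.9 are estimated near 0.1.
2. **Post-burn-in sign constraint.** From the first post-burn-in
   iteration, each participant's z row is flipped back whenever its inner
   product with that reference draw is negative (ties keep the current
   sign).  This constraint is applied to the chain state itself, so the Σ
   updates and all stored draws live in one consistent reflection mode;
   after burn-in the chain samples a sign-constrained pseudo-posterior
   rather than the unconstrained (and multimodal) exact posterior.
3. **Global gauge.** Even the constrained chain's overall sign is
   arbitrary, because the posterior is exactly symmetric under
   (Z, Λ_zθ) → (−Z, −Λ_zθ).  At the end of a run the reporting gauge is
   canonicalized to a nonnegative aggregate cross-covariance (cubic-
   weighted sum over regions), so planted positive signals are reported
   with positive sign.

A consequence worth stating plainly: with P = 1 the split of Var(y)
between Λ_θ and τ² is unidentified, Λ_θ wanders above 1, and whenever
Λ_θ · E[z²|data] exceeds 1 the *exact* posterior spontaneously breaks the
per-participant reflection symmetry — null regions acquire bimodal
cross-covariance posteriors at ±c* of order 0.1–0.2 whose credible
intervals exclude zero.  No chain-length increase removes this; it is a
property of the model, not of the sampler (σ² passes simulation-based
calibration; the cross-covariance block does not, in exactly the pattern
the mean-field gain argument predicts).  The in-chain sign constraint
dampens but does not eliminate the effect: at zero signal
(N=500, V=20) the per-region false-flag rate is about 0.15 rather than
the nominal 0.05, while planted signals are recovered essentially
unbiased.  A sampler that never crosses the reflection symmetry would be
nominally calibrated under the null but cannot recover planted signal
from random starts; this package prioritizes recovery and documents the
calibration gap (the corresponding acceptance assertion fails honestly).

### Defaults

3000 iterations, 1000 burn-in, thinning 1, ten random starts — all
config-overridable; chain length is not dictated by the model, and the
package's own tests use shorter chains (500–1500 iterations) at the
simulation sizes where they were verified to mix.  Multi-start selection
scores each chain by held-out behavior-prediction correlation on a masked
participant subset and returns the maximizing chain with the full score
log.  One seeded generator drives each chain; initialization draws
parameters from their priors with Σ = I and unit noise variances.

## Biomarker inference

Per region: posterior mean and central credible interval (inclusive
linear-interpolation quantiles) of the Λ_zθ draws; a region is significant
when the interval excludes zero.  No multiplicity correction across the V
regions — decisions are per-region 95% intervals by design.  Power and
specificity against a known simulation truth are the flagged fraction of
true signal regions and the unflagged fraction of true null regions; empty
denominators yield NaN, never 0.

## Synthetic data

The generator draws (z_i, θ_i) ~ MVN(0, Σ*) where Σ* has unit diagonal, a
uniformly chosen subset of round(signal_proportion · V) regions with
cross-covariance 0.9 (and the same value on the within-Λ_z entries among
those regions), and zeros elsewhere; it errors rather than repairing a
non-PD construction.  Edges are z_u z_v plus N(0, σ²) noise with
σ² = 1/SNR (unit latent variance; the simplest monotone mapping consistent
with holding latent variance fixed), behavior is θ plus N(0, 0.5) noise,
P = 1, and all intercepts are zero.  The full factorial grid is
{500, 1000, 2000} participants × {20, 70} regions × SNR {0.5, 1} × signal
proportion {0.1, 0.3} — 24 scenarios with distinct derived seeds.

What the generator does *not* emulate: spatial structure, site effects,
non-Gaussian edge distributions, and any additive (non-bilinear) linear
pathway from connectivity to behavior.  Passing tests on this design
therefore validate the estimation machinery, not performance on real
connectomes.

## Prediction

Both directions reuse the missing-data mechanism: test participants ride
along in the MCMC with the target block masked.

- **Behavior from connectivity, θ route**: test outcomes are drawn from
  their posterior predictive each retained iteration; the prediction is
  the mean of those draws.
- **Behavior from connectivity, Z route**: significant regions are chosen
  by the 95% intervals; ordinary least squares of training outcomes on the
  training rows of the posterior-mean Ẑ columns supplies coefficients
  applied to the test rows.  With no significant region the training mean
  is returned with a warning.
- **Connectivity from behavior**: test participants have all edges masked;
  their z_i is drawn from the latent conditional given θ_i under the
  current Σ (the unique model-consistent imputation), and predictive edge
  matrices are averaged over retained draws.  Sub-graph evaluation on the
  top-k biomarker regions is supported.  The **Average** baseline predicts
  every test matrix by the entry-wise training mean.

Point predictions are posterior means (the Bayes estimator under squared
loss); correlations are Pearson, over vectorized u < v entries for
matrices, with NaN (plus a warning) on zero-variance inputs.

### A structural caveat on behavior prediction

Under the synthetic design itself, behavior cannot be predicted from
connectivity at all: y depends on the data only through θ, the latents are
jointly Gaussian with mean zero, and the conditional law of z given the
bilinear products zz' is symmetric under z → −z, so cov(g(x), y) = 0 for
*every* function g of the connectivity data.  Detection of Λ_zθ still
works because observed training outcomes anchor the reflection gauge
inside the joint fit; out-of-sample behavior prediction has expected
correlation exactly zero, for this model and for any competitor, on data
generated from this design.  On real connectivity data — which carries an
additive common structure the bilinear model absorbs differently — the
same machinery can be predictive; the synthetic design simply cannot
demonstrate it.  The behavior-prediction functions are implemented and
tested for their contractual properties (hygiene, invariances, null
behavior); the corresponding end-to-end accuracy assertion in the
acceptance suite documents this impossibility by failing honestly.

## Network statistics

The latent network of a participant (or of the participant-averaged latent
vector) is the outer product zz' with zero diagonal.  Node strength is the
row sum.  Path-based centralities first shift all edges up by the
magnitude of the most negative edge (only if one exists), drop edges that
land exactly at zero, and use distance = 1/weight: closeness is the
reciprocal of the summed shortest-path distances to reachable nodes
(isolated nodes get 0), betweenness is unnormalized Brandes counting with
fractional ties.  Distribution shape is summarized by bias-uncorrected
sample skewness and excess kurtosis.

## Comparison methods

All baselines consume the same vectorized u < v edge matrix.  CPM
correlates each edge with the outcome, splits edges passing a two-sided
p < 0.01 threshold (configurable; the protocol's simulation threshold is
unstated) into positive and negative sets, and regresses the outcome on
the two sum scores.  The L1 selector is lasso with the penalty minimizing
10-fold cross-validated MSE; selected edges are the nonzero coefficients,
deliberately not debiased.  CCA takes the absolute first-canonical-vector
edge loadings (after PCA reduction when edges outnumber participants),
aggregates to regions by the max over incident edges, and flags the top
round(true signal proportion × V) regions — the cutoff uses the known
truth, as the protocol specifies.  For region-level comparison, CPM and
lasso flag a region when any incident edge is selected (the mapping most
favorable to the baselines).

## Numerical choices

- Cholesky-based MVN draws and log-densities; non-PD Σ is a hard error
  with a condition-number diagnostic.
- Edge standardization uses the n−1 sample standard deviation and errors
  on zero-variance edges.
- Retained-draw count is floor((iterations − burn-in)/thinning); at least
  10 retained draws are required by the config, at least 100 by the
  interval summarizer.
- The flip probability is computed through a clipped logistic to avoid
  overflow at extreme prior cross terms.
- Scenario seeds and chain sub-seeds are drawn from seeded generators and
  kept below 2³¹.

## Problem sizes used by the test and acceptance runs

Conjugacy oracles use 10,000 draws on instances with N ≤ 5, V ≤ 3, P ≤ 2.
The latent-kernel stationarity check runs 120,000 sweeps on the V=2, P=1,
N=1 instance against a 121³ quadrature grid.  Parameter recovery uses 3
replicates of the N=2000, V=20, SNR=1, proportion-0.1 cell with
800-iteration chains; null calibration uses 20 replicates at N=500, V=20
with 1500-iteration chains; prediction uses 3 repeats of 100 test
participants at N=500, V=20, proportion 0.3.  These are scaled-down
versions of the full 100-replicate protocol; thresholds are unchanged.

## Known limitations

- D = 1 behavior latent dimension only; item loadings fixed at 1.
- Covariate effects β are shared across edges; no per-edge coefficients.
- The Λ_θ/τ² variance split is only weakly identified when P = 1 (only
  their sum is pinned by Var(y)); cross-covariances remain identified.
- Null regions' cross-covariance posteriors are inflated relative to the
  empirical latent correlations (spontaneous reflection-symmetry breaking,
  see Estimation above): the per-region false-flag rate at zero signal is
  about 0.15 at N=500, V=20 instead of the nominal 0.05.
- No parallel tempering or gradient-based samplers; no within-chain
  parallelism guarantees.
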