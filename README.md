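# latentsna

Joint Bayesian latent-space modeling of brain connectivity and behavior.

Neuroimaging studies routinely ask which brain regions' connectivity
patterns carry information about a behavioral or clinical outcome.  Edge-
wise approaches (mass-univariate correlation, penalized regression) treat
the V(V−1)/2 connectivity values as independent predictors and pay a heavy
price in power when signals are sparse and edges are noisy.  `latentsna`
implements a generative alternative: each participant's symmetric
connectivity matrix is driven by bilinear products of region-level latent
variables, the behavioral outcome by a Rasch-type latent trait, and the two
latent blocks are coupled through a joint covariance whose cross block is
the object of inference.

## Model

For participant *i*, regions *u* < *v*, and outcome items *p*:

    x_uvi = w_i' β + a_i + z_ui · z_vi + e_uvi,   e ~ N(0, σ²)
    y_ip  = h_i' γ + b_p + θ_i + ε_ip,            ε ~ N(0, τ²)
    (z_1i, …, z_Vi, θ_i)' ~ MVN(0, Σ),   Σ = [[Λ_z, Λ_zθ], [Λ_zθ', Λ_θ]]

The bilinear term z_u z_v preserves third-order network structure
(transitivity, balance, clusterability); the cross-covariance block Λ_zθ
(V × 1) quantifies, region by region, how connectivity co-varies with the
behavioral trait across participants.  A region is reported as a biomarker
when the central 95% credible interval of its Λ_zθ entry excludes zero.

Estimation is a six-step conjugate Gibbs cycle (normal regressions, gamma
noise precisions, region-wise latent draws, inverse-Wishart Σ), with an
exact reflection-mode move that lets the chain cross the z_i → −z_i
likelihood symmetry, plus the post-burn-in sign alignment and a canonical
reporting gauge that make cross-covariance draws comparable across
iterations.

The package also provides the simulation-study machinery (a 24-cell
factorial design over sample size, network size, signal-to-noise ratio and
signal proportion), dual out-of-sample prediction (behavior from
connectivity and connectivity from behavior, plus an entry-wise Average
baseline), weighted-graph topology statistics (strength, shifted closeness,
betweenness), and three edge-based comparison methods (CPM, L1-penalized
selection, CCA loadings).

## Worked example

```python
import numpy as np
from latentsna import (SimulationConfig, SamplerConfig, simulate_dataset,
                       run_chain, summarize_covariances, power_specificity)

cfg = SimulationConfig(n_participants=1000, n_regions=20, snr=1.0,
                       signal_proportion=0.1, seed=1)
conn, behav, truth = simulate_dataset(cfg)

samples = run_chain(conn, behav,
                    config=SamplerConfig(n_iterations=800, burn_in=400,
                                         seed=1))
report = summarize_covariances(samples)
power, spec = power_specificity(report, truth)
sig = sorted(truth.signal_regions)
print("signal regions:", sig)
print("their posterior-mean cross-covariances:",
      np.round(report.posterior_mean[sig], 3))
print("power:", power, " specificity:", round(spec, 3))
```

Output:

```
signal regions: [8, 10]
their posterior-mean cross-covariances: [0.831 0.841]
power: 1.0  specificity: 0.944
```

The two planted regions (true cross-covariance 0.9) are recovered with
posterior means near 0.9 and both flagged significant; one of the eighteen
null regions is falsely flagged at this seed, close to the nominal 5% rate.

A command-line interface wraps the same pipeline:

```bash
latentsna simulate --config run.yaml --out data/
latentsna fit --connectivity data/connectivity.csv \
              --behavior data/behavior.csv --iterations 800 \
              --burn-in 400 --seed 1 --out fit/
latentsna report --fit fit/ --out biomarkers.csv
latentsna netstats --fit fit/ --out centralities.csv
```

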