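# geme

Complexity of weighted networks via graph embedding and spatial
point-pattern analysis.

## The problem

Weighted networks — functional brain connectivity matrices, co-varying
asset returns, gene co-expression — carry their organization in a dense
real-valued adjacency matrix `W (n x n)`. Entropy-style complexity measures
exist for binary graphs, but for weighted networks the edge-weight
distribution is unknown and heavily correlated, and thresholding the
weights throws information away. This package implements **Geme**
(**g**raph-**em**bedding point-process cross **e**ntropy), a scalar
complexity / non-randomness score for a weighted network:

1. **Embed.** Double-center the adjacency matrix, `B = ½ J W J` with
   `J = I − (1/n)𝟙𝟙ᵀ`, and factor it spectrally. The top-k eigenpairs give
   node coordinates `X̃ (k x n)` minimizing `‖X̃ᵀX̃ − B‖_F` — classical
   multidimensional scaling of the network. The configuration is invariant
   to node permutation, so isomorphic networks score identically.
2. **Measure the point pattern.** A random weighted graph embeds to a
   pattern close to complete spatial randomness (CSR); organized networks
   embed to clustered patterns. The deviation is quantified with the
   edge-corrected Ripley K estimator on a radius grid,

       K̂(r) = λ̂⁻¹ (1/n) Σᵢ Σ_{j≠i} η_ij 1(d_ij < r),

   with `λ̂ = n/|window|` and translation (any k) or isotropic (k = 2)
   boundary corrections `η_ij ≥ 1`.
3. **Integrate.** `L̂(r) = K̂(r)/c` (default `c = 1`) and
   `Geme = ∫ L̂(r) dr` by the trapezoid rule over the grid.

The package also ships the block-covariance simulation harness used to
validate the metric (groups of subjects, each an `n x T` Gaussian time
series with compound-symmetry community blocks, turned into correlation
networks), Monte-Carlo power analysis for two-group comparisons, and a
covariate regression with a group-by-sex interaction for cohort analyses.

## Worked example

```python
import numpy as np
from geme import (SimulationSpec, sample_timeseries, correlation_network,
                  geme, two_group_test, geme_batch, simulate_group_study)

# one simulated subject: 100 nodes, two communities (20 and 30 nodes with
# within-community correlations 0.5 and 0.6), 150 time points
spec = SimulationSpec(n=100, block_sizes=(20, 30),
                      block_correlations=(0.5, 0.6), T=150,
                      n_subjects=20, seed=7)
net = correlation_network(sample_timeseries(spec, subject_index=0))
result = geme(net)
print(f"Geme = {result.geme:.4f} over {result.curve.radii.size} radii")

# two-group comparison: same communities vs a (20, 20) design
other = SimulationSpec(n=100, block_sizes=(20, 20),
                       block_correlations=(0.6, 0.5), T=150,
                       n_subjects=20, seed=8)
g1, g2 = simulate_group_study(spec, other)
res = two_group_test(geme_batch(g1), geme_batch(g2))
print(f"group means {res.group_means[0]:.4f} vs {res.group_means[1]:.4f}, "
      f"Welch p = {res.p_value:.3f}")
```

prints

```
Geme = 0.0198 over 100 radii
group means 0.0195 vs 0.0171, Welch p = 0.018
```

The first number is the area under the corrected K curve for one subject's
network — larger values mean a more clustered embedding, i.e. a more
organized network. The group comparison
detects the design difference even at 20 subjects per arm here; at the
study size of 100 subjects per arm it is detected in the vast majority of
replicate studies (see below).

There is also a command line:

```sh
geme geme --input network.csv --k 2          # score one or many networks
geme embed --input network.csv -o coords.csv # dump embedding coordinates
geme simulate --config run.yaml --outdir sim # write simulated cohorts
geme power --spec1 a.yaml --spec2 b.yaml --replicates 100 --seed 1
```

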