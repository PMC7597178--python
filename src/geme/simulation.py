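"""Synthetic groups of weighted networks from block covariance matrices.

Each simulated subject is a zero-mean Gaussian multivariate time series
``Z (n x T)`` with a block-diagonal covariance: communities are
compound-symmetry blocks ``I_a (1 - rho) + J_a rho`` (unit variance, constant
within-block correlation rho) and nodes outside every block are mutually
independent.  The subject's weighted network is the correlation matrix of Z
computed about the known zero mean, ``U = Z Z^T / (T - 1)`` normalized to unit
diagonal.  This emulates a resting-state functional-connectivity cohort:
T plays the role of the number of fMRI volumes (default 150, a typical
resting-state scan length), communities play the role of coupled brain
subnetworks.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np

from .exceptions import DegenerateNodeError, ValidationError
from .network import WeightedNetwork

#: default number of time points per subject
DEFAULT_T = 150


@dataclass(frozen=True)
class SimulationSpec:
    """Design of one simulated group of subjects.

    ``block_sizes`` and ``block_correlations`` define the community blocks of
    the covariance matrix; the remaining ``n - sum(sizes)`` nodes are
    independent standard normals.  ``seed`` anchors per-subject substreams so
    any subject is reproducible in isolation.
    """

    n: int
    block_sizes: tuple[int, ...]
    block_correlations: tuple[float, ...]
    T: int = DEFAULT_T
    n_subjects: int = 100
    mean: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "block_sizes", tuple(int(a) for a in self.block_sizes))
        object.__setattr__(
            self, "block_correlations", tuple(float(r) for r in self.block_correlations)
        )
        if len(self.block_sizes) != len(self.block_correlations):
            raise ValidationError(
                f"{len(self.block_sizes)} block sizes but "
                f"{len(self.block_correlations)} correlations"
            )
        if any(a < 1 for a in self.block_sizes):
            raise ValidationError("block sizes must be positive")
        if sum(self.block_sizes) > self.n:
            raise ValidationError(
                f"block sizes sum to {sum(self.block_sizes)} > n = {self.n}"
            )
        if any(not 0.0 <= r < 1.0 for r in self.block_correlations):
            raise ValidationError("block correlations must lie in [0, 1)")
        if self.T < 3:
            raise ValidationError("need T >= 3 time points for correlations")
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be positive")


def block_covariance(spec: SimulationSpec) -> np.ndarray:
    """Block-diagonal covariance with compound-symmetry community blocks.

    A block of size a with correlation rho is ``I_a (1 - rho) + J_a rho``;
    its spectrum is ``1 + (a - 1) rho`` (once) and ``1 - rho`` (a - 1 times),
    so the matrix is symmetric positive definite for rho in [0, 1).
    """
    sigma = np.eye(spec.n)
    start = 0
    for a, rho in zip(spec.block_sizes, spec.block_correlations):
        sigma[start : start + a, start : start + a] = (1 - rho) * np.eye(a) + rho
        start += a
    return sigma


@lru_cache(maxsize=64)
def _cholesky_factor(
    n: int, sizes: tuple[int, ...], corrs: tuple[float, ...]
) -> np.ndarray:
    spec = SimulationSpec(n=n, block_sizes=sizes, block_correlations=corrs)
    return np.linalg.cholesky(block_covariance(spec))


def _subject_rng(seed: int, subject_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), int(subject_index))))


def sample_timeseries(spec: SimulationSpec, subject_index: int) -> np.ndarray:
    """Draw the ``n x T`` Gaussian time series of one subject.

    Columns are independent N(mean, Sigma) draws.  The stream is derived from
    ``(spec.seed, subject_index)``, so repeated calls are bit-identical and
    subjects are independent of one another.
    """
    rng = _subject_rng(spec.seed, subject_index)
    L = _cholesky_factor(spec.n, spec.block_sizes, spec.block_correlations)
    return spec.mean + L @ rng.standard_normal((spec.n, spec.T))


def correlation_network(Z: np.ndarray, center: bool = False) -> WeightedNetwork:
    """Correlation network of a node-by-time matrix.

    With ``center=False`` (the default, matching the known-zero-mean
    simulation design) the second-moment matrix ``U = Z Z^T / (T - 1)`` is
    normalized to unit diagonal; ``center=True`` subtracts row means first,
    giving ordinary Pearson correlations for real data.
    """
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2 or Z.shape[1] < 3:
        raise ValidationError(f"need an n x T matrix with T >= 3, got {Z.shape}")
    if center:
        Z = Z - Z.mean(axis=1, keepdims=True)
    T = Z.shape[1]
    U = Z @ Z.T / (T - 1)
    var = np.diag(U)
    if np.any(var <= 0):
        bad = np.flatnonzero(var <= 0).tolist()
        raise DegenerateNodeError(
            f"nodes {bad} have zero variance; correlations undefined"
        )
    inv_sd = 1.0 / np.sqrt(var)
    W = np.clip(U * np.outer(inv_sd, inv_sd), -1.0, 1.0)
    np.fill_diagonal(W, 1.0)
    return WeightedNetwork(W)


def fisher_z_transform(net: WeightedNetwork, clip: float = 0.999) -> WeightedNetwork:
    """Variance-stabilizing arctanh of the edge weights.

    Magnitudes are clipped at ``clip`` before the transform so perfect
    correlations stay finite; the diagonal is set uniformly to
    ``arctanh(clip)``.
    """
    if not 0.0 < clip < 1.0:
        raise ValidationError("clip must lie strictly between 0 and 1")
    W = np.arctanh(np.clip(net.weights, -clip, clip))
    np.fill_diagonal(W, np.arctanh(clip))
    return WeightedNetwork(W, net.node_labels)


def simulate_group_study(
    spec_group1: SimulationSpec, spec_group2: SimulationSpec
) -> tuple[list[WeightedNetwork], list[WeightedNetwork]]:
    """Simulate the two groups of subject networks of a two-sample study.

    Each subject's stream depends only on its spec's seed and subject index;
    give the two specs different seeds so the groups are independent.
    """
    if spec_group1.n != spec_group2.n:
        raise ValidationError("both groups must share the node count n")
    groups: list[list[WeightedNetwork]] = []
    for spec in (spec_group1, spec_group2):
        groups.append(
            [
                correlation_network(sample_timeseries(spec, s))
                for s in range(spec.n_subjects)
            ]
        )
    return groups[0], groups[1]


def shuffle_edge_weights(
    net: WeightedNetwork, rng: np.random.Generator
) -> WeightedNetwork:
    """Random weighted graph with the same marginal edge-weight distribution.

    Uniformly permutes the upper-triangle weights and resymmetrizes, keeping
    the diagonal.  This destroys all topological organization while matching
    the edge-weight marginals exactly — the i.i.d.-weight null that an
    organized network's complexity is compared against.
    """
    n = net.n_nodes
    iu = np.triu_indices(n, k=1)
    vals = net.weights[iu].copy()
    rng.shuffle(vals)
    W = np.zeros_like(net.weights)
    W[iu] = vals
    W = W + W.T
    np.fill_diagonal(W, np.diag(net.weights))
    return WeightedNetwork(W, net.node_labels)


def with_seed(spec: SimulationSpec, seed: int) -> SimulationSpec:
    """Copy of ``spec`` with a different random seed."""
    return replace(spec, seed=int(seed))
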