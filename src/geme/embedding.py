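"""Graph embedding of a weighted network into R^k.

The embedding is the classical spectral factorization of the double-centered
adjacency matrix: with ``J = I - (1/n) 1 1^T`` the target Gram matrix is

    B = (1/2) J W J,

and the coordinates ``X (k x n)`` solve ``argmin_X || X^T X - B ||_F`` over
rank-k nonnegative factorizations, i.e. they are the top-k eigenvectors of B
scaled by the square roots of the (nonnegative-clipped) eigenvalues.  Because
J commutes with any permutation matrix, the point configuration — and hence
every distance-based statistic computed from it — is invariant to node
relabeling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .exceptions import DegenerateEmbeddingError, ValidationError
from .network import WeightedNetwork

logger = logging.getLogger(__name__)

#: fraction of total absolute spectral mass above which truncated negative
#: eigenvalues trigger a warning
NEGATIVE_MASS_WARN = 0.05

_ZERO_TOL = 1e-12


@dataclass
class GramMatrix:
    """Double-centered Gram matrix ``B = (scale) J W J``."""

    values: np.ndarray
    centering_applied: bool = True


@dataclass
class PointSet:
    """Embedded node coordinates.

    Attributes
    ----------
    coordinates:
        ``k x n`` matrix; column ``i`` is the position of node ``i``.
    eigenvalues_kept:
        The k retained spectral values, nonnegative, sorted descending.
    discarded_negative_mass:
        Sum of magnitudes of truncated negative eigenvalues (0 for a PSD
        Gram matrix).
    """

    coordinates: np.ndarray
    eigenvalues_kept: np.ndarray
    discarded_negative_mass: float = 0.0

    @property
    def k(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_points(self) -> int:
        return self.coordinates.shape[1]


def double_center_gram(net: WeightedNetwork, scale: float = 0.5) -> GramMatrix:
    """Return ``B = scale * J W J`` with ``J = I - (1/n) 1 1^T``.

    Double centering removes row and column means (J annihilates constant
    vectors), so B is symmetric with every row and column summing to zero.
    """
    W = net.weights
    row = W.mean(axis=1, keepdims=True)
    col = W.mean(axis=0, keepdims=True)
    B = scale * (W - row - col + W.mean())
    B = (B + B.T) / 2.0  # remove float round-off asymmetry
    return GramMatrix(values=B)


def embed(net: WeightedNetwork, k: int = 2, gram_scale: float = 0.5) -> PointSet:
    """Project a weighted network to a k-dimensional point configuration.

    The top-k eigenvalues of the centered Gram matrix are clipped below at
    zero; the coordinates are ``diag(sqrt(lambda)) V^T`` for the matching
    orthonormal eigenvectors.  Eigenvector signs are fixed so the
    largest-magnitude entry of each is positive, which makes the output
    deterministic (distances are unaffected either way).

    Raises
    ------
    ValidationError
        If ``k`` is outside ``[1, n-1]``.
    DegenerateEmbeddingError
        If the spectrum has no positive part while the Gram matrix is not
        itself (numerically) zero.  A zero Gram matrix — e.g. a constant
        weight matrix — embeds legitimately to n coincident points at the
        origin.
    """
    n = net.n_nodes
    if not 1 <= k <= n - 1:
        raise ValidationError(f"embedding dimension k={k} must be in [1, {n - 1}]")
    B = double_center_gram(net, scale=gram_scale).values
    lam, V = np.linalg.eigh(B)  # ascending
    lam = lam[::-1]
    V = V[:, ::-1]

    neg = lam[lam < 0.0]
    neg_mass = float(-neg.sum())
    total_mass = float(np.abs(lam).sum())
    if total_mass > 0 and neg_mass > NEGATIVE_MASS_WARN * total_mass:
        logger.warning(
            "embedding discarded %.1f%% of absolute spectral mass as negative "
            "eigenvalues; the adjacency matrix is far from positive semidefinite",
            100.0 * neg_mass / total_mass,
        )

    scale_ref = max(total_mass / n, 1.0)
    if lam[0] <= _ZERO_TOL * scale_ref:
        if total_mass <= n * _ZERO_TOL * scale_ref:
            # B == 0: all nodes indistinguishable after centering
            return PointSet(
                coordinates=np.zeros((k, n)),
                eigenvalues_kept=np.zeros(k),
                discarded_negative_mass=neg_mass,
            )
        raise DegenerateEmbeddingError(
            "centered Gram matrix has no positive eigenvalues; "
            "the network has no embeddable structure"
        )

    kept = np.clip(lam[:k], 0.0, None)
    vecs = V[:, :k].copy()
    # deterministic sign: largest-magnitude entry of each eigenvector positive
    idx = np.argmax(np.abs(vecs), axis=0)
    signs = np.sign(vecs[idx, np.arange(k)])
    signs[signs == 0] = 1.0
    vecs *= signs
    coords = np.sqrt(kept)[:, None] * vecs.T
    # eigenvectors of B with nonzero eigenvalue are orthogonal to 1 exactly;
    # re-center to scrub float residue so the zero-mean invariant is hard
    coords -= coords.mean(axis=1, keepdims=True)
    return PointSet(
        coordinates=coords,
        eigenvalues_kept=kept,
        discarded_negative_mass=neg_mass,
    )


def pairwise_distances(points: PointSet) -> np.ndarray:
    """Euclidean distance matrix between embedded nodes (n x n, zero diagonal)."""
    return squareform(pdist(points.coordinates.T))
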