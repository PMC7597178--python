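"""Weighted-network container and validation.

A weighted network is a dense symmetric real matrix of edge weights over a
fixed node set.  For functional-connectivity applications the weights are
(Fisher-z transformed) correlation coefficients, but any symmetric real
matrix is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ValidationError

#: tolerance below which an asymmetric matrix is silently symmetrized
SYMMETRY_TOL = 1e-8


@dataclass
class WeightedNetwork:
    """Dense weighted network ``G = (V, E, W)``.

    Parameters
    ----------
    weights:
        Square symmetric matrix of edge weights ``w_ij`` (``n x n``, real,
        finite).  Asymmetry up to ``SYMMETRY_TOL`` is averaged away; anything
        larger is rejected.
    node_labels:
        Ordered node identifiers, length ``n``.  Defaults to ``v1 .. vn``.
    """

    weights: np.ndarray
    node_labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValidationError(
                f"adjacency matrix must be square, got shape {W.shape}"
            )
        n = W.shape[0]
        if n < 3:
            raise ValidationError(
                f"need at least 3 nodes for a nondegenerate point pattern, got {n}"
            )
        if not np.all(np.isfinite(W)):
            bad = np.argwhere(~np.isfinite(W))
            raise ValidationError(
                f"non-finite entries at positions {bad[:5].tolist()}"
                + ("..." if len(bad) > 5 else "")
            )
        asym = np.abs(W - W.T)
        if asym.max() > SYMMETRY_TOL:
            i, j = np.unravel_index(np.argmax(asym), asym.shape)
            raise ValidationError(
                f"matrix is asymmetric beyond tolerance {SYMMETRY_TOL:g}: "
                f"w[{i},{j}]={W[i, j]!r} vs w[{j},{i}]={W[j, i]!r}"
            )
        self.weights = (W + W.T) / 2.0
        if not self.node_labels:
            self.node_labels = tuple(f"v{i + 1}" for i in range(n))
        elif len(self.node_labels) != n:
            raise ValidationError(
                f"{len(self.node_labels)} node labels for {n} nodes"
            )
        else:
            self.node_labels = tuple(str(x) for x in self.node_labels)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def permuted(self, perm: np.ndarray) -> "WeightedNetwork":
        """Return the isomorphic network with nodes reordered by ``perm``."""
        perm = np.asarray(perm)
        if sorted(perm.tolist()) != list(range(self.n_nodes)):
            raise ValidationError("perm must be a permutation of 0..n-1")
        return WeightedNetwork(
            self.weights[np.ix_(perm, perm)],
            tuple(self.node_labels[i] for i in perm),
        )
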