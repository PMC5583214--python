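"""Degree statistics, the s-metric, degree cCDFs and edge-count matching.

The s-metric S(W) = Σ_{(i,j)∈E, i<j} d_i·d_j (binary degrees on the network's
support, each unordered edge counted once) quantifies how strongly edges
concentrate on high-degree nodes: among graphs with the same number of edges,
hub-and-spoke wiring scores higher than homogeneous wiring.  The degree cCDF
P(D ≥ d), plotted in log-log coordinates, is the usual visual check for a
heavy (power-law-like) degree tail.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np

from ._utils import ZERO_TOL, as_matrix
from .errors import ParameterError
from .estimators import ConnectivityMatrix, soft_threshold

__all__ = [
    "DegreeVector",
    "DegreeDistribution",
    "node_degrees",
    "s_metric",
    "degree_ccdf",
    "match_edge_count",
    "edge_count",
    "MatchResult",
]


@dataclass
class DegreeVector:
    degrees: np.ndarray
    mode: str  # "binary" or "weighted"


@dataclass
class DegreeDistribution:
    """Empirical degree distribution pooled over one or more networks."""

    support: np.ndarray  # sorted unique degree values
    counts: np.ndarray
    ccdf: np.ndarray  # P(D >= support[k])

    def to_table(self, exclude_zero: bool = True) -> np.ndarray:
        """(degree, ccdf) rows for log-log plotting.

        Zero degrees are retained in the counts/ccdf but excluded from the
        exported table by default, since log(0) is undefined.
        """
        keep = self.support > 0 if exclude_zero else np.ones_like(self.support, bool)
        return np.column_stack([self.support[keep], self.ccdf[keep]])


def node_degrees(W, mode: str = "binary", zero_tol: float = ZERO_TOL) -> DegreeVector:
    """Per-node degree, diagonal ignored.

    binary: count of off-diagonal entries with |W_ij| > zero_tol;
    weighted: Σ_{z≠i} |W_iz|.
    """
    if mode not in ("binary", "weighted"):
        raise ParameterError(f"unknown degree mode {mode!r}")
    arr = as_matrix(W)
    A = np.abs(arr).astype(float)
    np.fill_diagonal(A, 0.0)
    if mode == "binary":
        deg = np.sum(A > zero_tol, axis=1).astype(float)
    else:
        deg = A.sum(axis=1)
    return DegreeVector(degrees=deg, mode=mode)


def edge_count(W, zero_tol: float = ZERO_TOL) -> int:
    """Number of unordered off-diagonal pairs with |W_ij| > zero_tol."""
    arr = as_matrix(W)
    iu, ju = np.triu_indices(arr.shape[0], k=1)
    return int(np.sum(np.abs(arr[iu, ju]) > zero_tol))


def s_metric(W, zero_tol: float = ZERO_TOL) -> float:
    """S(W) = Σ over edges of the product of endpoint binary degrees."""
    arr = as_matrix(W)
    A = np.abs(arr) > zero_tol
    np.fill_diagonal(A, False)
    A = A | A.T  # support of the undirected graph
    deg = A.sum(axis=1).astype(float)
    iu, ju = np.triu_indices(arr.shape[0], k=1)
    edges = A[iu, ju]
    return float(np.sum(deg[iu[edges]] * deg[ju[edges]]))


def degree_ccdf(degree_vectors: Iterable[DegreeVector | np.ndarray]) -> DegreeDistribution:
    """Pool node degrees over subjects and return the empirical cCDF P(D ≥ d)."""
    pooled: list[np.ndarray] = []
    for dv in degree_vectors:
        arr = np.asarray(getattr(dv, "degrees", dv), dtype=float)
        pooled.append(arr.ravel())
    if not pooled or sum(a.size for a in pooled) == 0:
        raise ParameterError("empty degree pool")
    d = np.concatenate(pooled)
    support, counts = np.unique(d, return_counts=True)
    # P(D >= support[k]) = (# of nodes with degree >= support[k]) / N
    tail = np.cumsum(counts[::-1])[::-1]
    ccdf = tail / d.size
    return DegreeDistribution(support=support, counts=counts, ccdf=ccdf)


class MatchResult(NamedTuple):
    lam: float
    network: ConnectivityMatrix
    achieved_count: int


def match_edge_count(
    Xs,
    reference_count: int,
    cfg=None,
    zero_tol: float = ZERO_TOL,
    max_bisect: int = 200,
) -> MatchResult:
    """Find λ so the L1-shrunk correlation network has ≈ reference_count edges.

    The edge count of soft(XᵀX, λ/2) is a non-increasing, piecewise-constant
    function of λ, so bisection returns (up to float resolution) the largest
    λ whose edge count is ≥ reference_count; ties among |S_ij| values can
    make an exact match unattainable, so the achieved count is returned
    alongside.
    """
    from .estimators import _standardized_values  # local to avoid cycle

    values, labels = _standardized_values(Xs)
    S = values.T @ values
    S = (S + S.T) / 2.0
    n = S.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    absvals = np.abs(S[iu, ju])
    if not (0 <= reference_count <= absvals.size):
        raise ParameterError(
            f"reference_count {reference_count} outside [0, {absvals.size}]"
        )

    def count(lam: float) -> int:
        return int(np.sum(absvals - lam / 2.0 > zero_tol))

    attainable = count(0.0)
    if reference_count > attainable:
        raise ParameterError(
            f"reference_count {reference_count} exceeds the attainable "
            f"maximum {attainable} (ties/zeros in the correlation matrix)"
        )
    lo, hi = 0.0, 2.0 * float(absvals.max(initial=0.0)) + 1.0
    # invariant: count(lo) >= reference_count > count(hi)
    for _ in range(max_bisect):
        mid = 0.5 * (lo + hi)
        if count(mid) >= reference_count:
            lo = mid
        else:
            hi = mid
    lam = lo
    W = soft_threshold(S, lam / 2.0)
    net = ConnectivityMatrix(
        W=W, estimator="pc_sparsity", lam=lam, roi_labels=labels
    )
    return MatchResult(lam=lam, network=net, achieved_count=edge_count(W, zero_tol))
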