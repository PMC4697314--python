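"""Weighted graph measures of a connectivity matrix.

All measures operate on a symmetric, zero-diagonal weight matrix W with
entries in [0, 1] (a dense PLI matrix in practice; no thresholding is
applied, so no node is ever artificially disconnected):

* degree_i       — mean weight of node i's links;
* C_i, Cw        — weighted clustering coefficient (triangle-intensity
                   ratio) and its network mean;
* L = 1/W        — edge length; shortest paths give the distance matrix,
                   the harmonic-mean path length Lw, per-node eccentricity,
                   radius and diameter;
* Kw             — degree diversity <degree^2>/<degree>, high for
                   hub-dominated networks;
* Rw             — degree correlation (Pearson over endpoint degrees of
                   present edges);
* gamma, lambda  — Cw and Lw normalized by their averages over
                   edge-weight-reshuffled surrogate networks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import dijkstra

__all__ = [
    "GraphMetrics",
    "node_degree",
    "clustering",
    "path_length",
    "degree_diversity",
    "degree_correlation",
    "normalize",
    "graph_metrics",
]


@dataclass
class GraphMetrics:
    """Scalar summary of one weight matrix."""

    degree: np.ndarray
    C: np.ndarray
    Cw: float
    Lw: float
    Ec: np.ndarray
    radius: float
    diameter: float
    Kw: float
    Rw: float  # NaN when undefined (zero degree variance)
    gamma: float | None = None
    lambda_: float | None = None
    n_surrogates: int | None = None
    n_iterations: int | None = None

    def to_dict(self) -> dict:
        return {
            "degree": self.degree.tolist(),
            "C": self.C.tolist(),
            "Cw": self.Cw,
            "Lw": self.Lw,
            "Ec": [float(e) for e in self.Ec],
            "radius": self.radius,
            "diameter": self.diameter,
            "Kw": self.Kw,
            "Rw": None if np.isnan(self.Rw) else self.Rw,
            "gamma": self.gamma,
            "lambda": self.lambda_,
            "n_surrogates": self.n_surrogates,
            "n_iterations": self.n_iterations,
        }


def _check(W: np.ndarray) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("W must be square")
    if W.shape[0] < 2:
        raise ValueError("need at least 2 nodes")
    if not np.allclose(W, W.T, atol=1e-12):
        raise ValueError("W must be symmetric")
    return W


def node_degree(W: np.ndarray) -> np.ndarray:
    """degree_i = mean weight over node i's n-1 links."""
    W = _check(W)
    n = W.shape[0]
    return (W.sum(axis=1) - np.diag(W)) / (n - 1)


def clustering(W: np.ndarray) -> tuple[np.ndarray, float]:
    """Weighted clustering coefficient per node and its mean Cw.

    C_i = sum_{k!=i, l!=i, l!=k} W_ik W_il W_kl / sum_{k!=i, l!=i, l!=k} W_ik W_il.
    Isolated nodes (zero denominator) get C_i = 0 with a warning.
    """
    W = _check(W)
    W = W - np.diag(np.diag(W))
    numer = np.diag(W @ W @ W)  # 2 x sum of triangle intensities at i
    s = W.sum(axis=1)
    denom = s ** 2 - (W ** 2).sum(axis=1)
    C = np.zeros_like(s)
    ok = denom > 0
    if not ok.all():
        warnings.warn("isolated node(s): clustering coefficient set to 0", stacklevel=2)
    C[ok] = numer[ok] / denom[ok]
    return C, float(C.mean())


def path_length(W: np.ndarray) -> tuple[np.ndarray, float, np.ndarray, float, float]:
    """Shortest paths on edge lengths 1/W (infinite where W = 0).

    Returns (distance matrix, Lw, eccentricity, radius, diameter) with the
    harmonic-mean path length Lw = 1 / mean(1/L_ij) over ordered pairs.
    """
    W = _check(W)
    n = W.shape[0]
    with np.errstate(divide="ignore"):
        lengths = np.where(W > 0, 1.0 / np.where(W > 0, W, 1.0), 0.0)
    # dense csgraph input: zero entries mean "no edge"
    D = dijkstra(lengths, directed=False)
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isinf(D[off]), 0.0, 1.0 / D[off])
    mean_inv = inv.mean()
    Lw = float(np.inf) if mean_inv == 0 else float(1.0 / mean_inv)
    Ec = np.where(off, D, -np.inf).max(axis=1)
    return D, Lw, Ec, float(Ec.min()), float(Ec.max())


def degree_diversity(W: np.ndarray) -> float:
    """Kw = <degree^2> / <degree>."""
    deg = node_degree(W)
    mean_deg = deg.mean()
    if mean_deg == 0:
        raise ValueError("all-zero weight matrix: Kw undefined")
    return float(np.mean(deg ** 2) / mean_deg)


def degree_correlation(W: np.ndarray) -> float:
    """Rw: Pearson correlation of the degrees at the two ends of each edge.

    Each present edge contributes both orientations, making the statistic
    symmetric in node order.  Returns NaN when endpoint degrees have zero
    variance (e.g. regular graphs).
    """
    W = _check(W)
    deg = node_degree(W)
    iu, ju = np.triu_indices_from(W, k=1)
    present = W[iu, ju] > 0
    if present.sum() < 3:
        raise ValueError("need at least 3 edges with nonzero weight")
    x = np.concatenate([deg[iu[present]], deg[ju[present]]])
    y = np.concatenate([deg[ju[present]], deg[iu[present]]])
    tol = 1e-12 * (np.abs(x).mean() + 1.0)
    if np.std(x) <= tol or np.std(y) <= tol:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def _surrogate(W: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Reshuffle upper-triangle weights; preserves the weight multiset,
    symmetry and the zero diagonal while destroying structure."""
    n = W.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    vals = rng.permutation(W[iu, ju])
    S = np.zeros_like(W)
    S[iu, ju] = vals
    return S + S.T


def normalize(
    W: np.ndarray, n_surr: int = 50, n_iter: int = 5, seed: int = 0
) -> tuple[float, float]:
    """gamma = Cw/Cr and lambda = Lw/Lr against reshuffled surrogates.

    Cr and Lr are means over ``n_surr`` surrogate networks; the whole
    average is repeated ``n_iter`` times and the repetitions averaged.
    """
    W = _check(W)
    _, Cw = clustering(W)
    _, Lw, _, _, _ = path_length(W)
    rng = np.random.default_rng(seed)
    cr_runs, lr_runs = [], []
    for _ in range(n_iter):
        cs, ls = [], []
        for _ in range(n_surr):
            S = _surrogate(W, rng)
            _, c = clustering(S)
            _, l, _, _, _ = path_length(S)
            cs.append(c)
            ls.append(l)
        cr_runs.append(np.mean(cs))
        lr_runs.append(np.mean(ls))
    Cr, Lr = float(np.mean(cr_runs)), float(np.mean(lr_runs))
    if Cr == 0 or Lr == 0:
        raise ValueError("surrogate Cr or Lr is zero; normalization undefined")
    return Cw / Cr, Lw / Lr


def graph_metrics(
    W: np.ndarray,
    n_surr: int = 50,
    n_iter: int = 5,
    seed: int = 0,
    normalized: bool = True,
) -> GraphMetrics:
    """All measures of one weight matrix (surrogate normalization optional)."""
    W = _check(W)
    deg = node_degree(W)
    C, Cw = clustering(W)
    _, Lw, Ec, radius, diameter = path_length(W)
    Kw = degree_diversity(W)
    try:
        Rw = degree_correlation(W)
    except ValueError:
        Rw = float("nan")
    gamma = lam = None
    if normalized:
        gamma, lam = normalize(W, n_surr=n_surr, n_iter=n_iter, seed=seed)
    return GraphMetrics(degree=deg, C=C, Cw=Cw, Lw=Lw, Ec=Ec, radius=radius,
                        diameter=diameter, Kw=Kw, Rw=Rw, gamma=gamma, lambda_=lam,
                        n_surrogates=n_surr if normalized else None,
                        n_iterations=n_iter if normalized else None)
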