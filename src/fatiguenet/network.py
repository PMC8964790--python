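"""Functional-connectivity networks and weighted graph-theoretic metrics.

The regional time series of one (species, band) pair yield an 8x8 Pearson
correlation matrix r. Graph analysis runs on w = |r| with zero diagonal:

* node clustering coefficient (weighted, max-normalised):
      C_u = 1 / (deg(u)(deg(u)-1)) * sum_{v,w} (w'_uv w'_uw w'_vw)^(1/3)
  with w' = w / max(w), the sum over ordered neighbour pairs;
* network clustering coefficient C = mean of C_u over nodes;
* characteristic path length L = mean over ordered node pairs of the
  shortest-path distance with edge length 1 / w_uv;
* small-worldness sigma = gamma / lambda with gamma = C_real / C_random and
  lambda = L_real / L_random against matched random networks (degree
  sequence preserved by double-edge swaps; in weighted mode the weight
  multiset is additionally permuted over the rewired edges).

Binarization at a fixed sparsity keeps the k = round(s * n(n-1)/2)
strongest edges so every binarized network in a study has the same edge
count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import shortest_path as _sp_shortest_path

from .data_model import BandSpec, Montage
from .preprocess import BandRoiSeries

__all__ = [
    "ConnectivityNetwork",
    "NetworkMetrics",
    "fc_matrix",
    "node_clustering",
    "clustering_coefficient",
    "characteristic_path_length",
    "binarize_by_sparsity",
    "matched_random_networks",
    "small_worldness",
    "hemisphere_means",
]

DEFAULT_SPARSITY = 0.45
DEFAULT_N_RANDOM = 100
SWAP_MULTIPLIER = 10  # attempted double-edge swaps per edge


@dataclass
class ConnectivityNetwork:
    """Inter-ROI Pearson correlations and the derived nonnegative weights."""

    r: np.ndarray  # (n, n) signed correlations, diagonal 1
    w: np.ndarray  # (n, n) |r| off-diagonal, diagonal 0
    roi_order: tuple[str, ...]
    species: str | None = None
    band: BandSpec | None = None


@dataclass
class NetworkMetrics:
    """Clustering, path length and small-world statistics for one network."""

    C: float
    L: float
    gamma: float
    lam: float
    sigma: float
    C_random: float
    L_random: float
    mode: str  # "weighted" | "unweighted"
    n_random: int
    seed: int
    disconnected: bool = False


def fc_matrix(series: BandRoiSeries) -> ConnectivityNetwork:
    """Pearson correlation network of the ROI time series."""
    y = np.asarray(series.y, dtype=float)
    if y.shape[0] < 3:
        raise ValueError("need at least 3 time points for a correlation network")
    sd = y.std(axis=0)
    if np.any(sd == 0.0):
        roi = series.roi_order[int(np.argmin(sd))]
        raise ValueError(f"zero-variance ROI series: {roi!r}")
    r = np.corrcoef(y, rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    w = np.abs(r)
    np.fill_diagonal(w, 0.0)
    return ConnectivityNetwork(
        r=r, w=w, roi_order=series.roi_order, species=series.species, band=series.band
    )


def _check_weights(w: np.ndarray) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weight matrix must be square")
    if not np.allclose(w, w.T):
        raise ValueError("weight matrix must be symmetric")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    if np.any(np.diag(w) != 0):
        raise ValueError("weight matrix diagonal must be zero")
    return w


def _node_clustering_all(w: np.ndarray) -> np.ndarray:
    """Per-node weighted clustering; assumes w already validated, max > 0.

    The ordered-neighbour-pair sum equals the diagonal of K^3 with
    K = cbrt(w / max(w)), since any term with a missing incident edge
    vanishes.
    """
    cbrt = np.cbrt(w / w.max())
    numer = np.einsum("uv,vt,tu->u", cbrt, cbrt, cbrt)
    deg = (w > 0).sum(axis=1)
    out = np.zeros(w.shape[0])
    ok = deg >= 2
    out[ok] = numer[ok] / (deg[ok] * (deg[ok] - 1))
    return out


def node_clustering(w: np.ndarray, u: int) -> float:
    """Weighted clustering coefficient of node ``u`` (geometric triangle mean)."""
    w = _check_weights(w)
    if w.max() == 0.0:
        raise ValueError("all-zero weight matrix: maximum weight undefined")
    return float(_node_clustering_all(w)[u])


def clustering_coefficient(w: np.ndarray) -> float:
    """Mean node clustering coefficient over all nodes."""
    w = _check_weights(w)
    if w.max() == 0.0:
        return 0.0  # edgeless network: every node has C_u = 0
    return float(_node_clustering_all(w).mean())


def characteristic_path_length(w: np.ndarray) -> tuple[float, bool]:
    """Mean shortest-path length over ordered node pairs (edge length 1/w).

    Returns ``(L, disconnected)``. On a disconnected graph the mean runs
    over reachable pairs only and the flag is set.
    """
    w = _check_weights(w)
    n = w.shape[0]
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    d = _sp_shortest_path(lengths, method="D", directed=False)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    if not finite.any():
        raise ValueError("no reachable node pairs: graph has no edges")
    disconnected = bool(finite.sum() < off.sum())
    return float(d[finite].mean()), disconnected


def binarize_by_sparsity(w: np.ndarray, sparsity: float = DEFAULT_SPARSITY) -> np.ndarray:
    """Keep the k strongest edges, k = round(sparsity * n(n-1)/2), half up.

    Ties at the cutoff are broken by lexicographic (u, v) order so repeated
    calls give identical adjacency.
    """
    w = _check_weights(w)
    if not (0.0 < sparsity <= 1.0):
        raise ValueError(f"sparsity must lie in (0, 1], got {sparsity}")
    n = w.shape[0]
    n_possible = n * (n - 1) // 2
    k = int(math.floor(sparsity * n_possible + 0.5))
    if k == 0:
        raise ValueError(f"sparsity {sparsity} keeps zero edges on {n} nodes")
    iu, ju = np.triu_indices(n, k=1)
    # sort by weight descending, then (u, v) ascending for deterministic ties
    order = sorted(range(n_possible), key=lambda e: (-w[iu[e], ju[e]], iu[e], ju[e]))
    adj = np.zeros((n, n), dtype=int)
    for e in order[:k]:
        adj[iu[e], ju[e]] = adj[ju[e], iu[e]] = 1
    return adj


def _edge_list(w: np.ndarray) -> list[tuple[int, int]]:
    iu, ju = np.triu_indices(w.shape[0], k=1)
    mask = w[iu, ju] > 0
    return list(zip(iu[mask].tolist(), ju[mask].tolist()))


def _double_edge_swaps(
    edges: list[tuple[int, int]], rng: np.random.Generator, n_attempts: int
) -> tuple[list[tuple[int, int]], bool]:
    """Degree-preserving rewiring: repeatedly swap endpoints of edge pairs.

    Returns the rewired edge list and whether at least one swap succeeded.
    """
    edge_set = {frozenset(e) for e in edges}
    edges = list(edges)
    m = len(edges)
    swapped = False
    if m < 2:
        return edges, False
    for _ in range(n_attempts):
        e1, e2 = rng.integers(0, m, size=2)
        if e1 == e2:
            continue
        (a, b), (c, d) = edges[e1], edges[e2]
        if rng.random() < 0.5:
            c, d = d, c
        # propose (a, d) and (c, b)
        if a == d or c == b:
            continue
        new1, new2 = frozenset((a, d)), frozenset((c, b))
        if new1 in edge_set or new2 in edge_set:
            continue
        edge_set.discard(frozenset((a, b)))
        edge_set.discard(frozenset((c, d)))
        edge_set.add(new1)
        edge_set.add(new2)
        edges[e1] = (min(a, d), max(a, d))
        edges[e2] = (min(c, b), max(c, b))
        swapped = True
    return edges, swapped


def matched_random_networks(
    w: np.ndarray,
    n_random: int = DEFAULT_N_RANDOM,
    seed: int = 0,
    mode: str = "weighted",
) -> list[np.ndarray]:
    """Null networks matched on degree sequence (and weight multiset).

    Each replicate rewires the positive-weight support with double-edge
    swaps (``SWAP_MULTIPLIER`` * E attempts) and, in weighted mode, then
    permutes the original weight multiset over the rewired edges. On
    graphs too small or dense to swap (e.g. complete graphs) the topology
    is left unchanged and only the weights are permuted.
    """
    w = _check_weights(w)
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    if mode not in ("weighted", "unweighted"):
        raise ValueError(f"mode must be 'weighted' or 'unweighted', got {mode!r}")
    edges = _edge_list(w)
    if not edges:
        raise ValueError("cannot randomize an edgeless network")
    weights = np.array([w[u, v] for u, v in edges])
    n = w.shape[0]
    rng = np.random.default_rng(seed)
    out: list[np.ndarray] = []
    for _ in range(n_random):
        new_edges, _ok = _double_edge_swaps(edges, rng, SWAP_MULTIPLIER * len(edges))
        null = np.zeros_like(w, dtype=float)
        if mode == "weighted":
            perm = rng.permutation(len(new_edges))
            vals = weights[perm]
        else:
            vals = np.ones(len(new_edges))
        for (u, v), val in zip(new_edges, vals):
            null[u, v] = null[v, u] = val
        out.append(null)
    return out


def small_worldness(
    w: np.ndarray,
    n_random: int = DEFAULT_N_RANDOM,
    seed: int = 0,
    mode: str = "weighted",
    sparsity: float = DEFAULT_SPARSITY,
) -> NetworkMetrics:
    """Small-world statistics against matched random nulls.

    The network support is first thresholded at ``sparsity`` (the strongest
    k = round(sparsity * n(n-1)/2) edges): in unweighted mode surviving
    edges get weight 1, in weighted mode they keep their weights. On a
    dense correlation network this is what makes the degree-preserving
    null informative — rewiring a complete graph is a no-op. Pass
    ``sparsity=1.0`` to analyse the full weighted matrix.
    """
    w = _check_weights(w)
    adj = binarize_by_sparsity(w, sparsity)
    if mode == "unweighted":
        w = adj.astype(float)
    elif mode == "weighted":
        w = w * adj
    else:
        raise ValueError(f"mode must be 'weighted' or 'unweighted', got {mode!r}")
    C_real = clustering_coefficient(w)
    L_real, disconnected = characteristic_path_length(w)
    nulls = matched_random_networks(w, n_random=n_random, seed=seed, mode=mode)
    C_random = float(np.mean([clustering_coefficient(m) for m in nulls]))
    L_random = float(np.mean([characteristic_path_length(m)[0] for m in nulls]))
    if C_random == 0.0:
        raise ValueError("degenerate null model: mean random clustering is zero")
    gamma = C_real / C_random
    lam = L_real / L_random
    return NetworkMetrics(
        C=C_real,
        L=L_real,
        gamma=gamma,
        lam=lam,
        sigma=gamma / lam,
        C_random=C_random,
        L_random=L_random,
        mode=mode,
        n_random=n_random,
        seed=seed,
        disconnected=disconnected,
    )


def hemisphere_means(net: ConnectivityNetwork, montage: Montage) -> tuple[float, float]:
    """Mean connectivity weight within the left and right hemispheres.

    Averages w over unordered ROI pairs that lie entirely within one
    hemisphere; medial ROIs are excluded.
    """
    means = []
    idx = {roi: i for i, roi in enumerate(net.roi_order)}
    for side in ("left", "right"):
        rois = montage.rois_in_hemisphere(side)
        if len(rois) < 2:
            raise ValueError(f"fewer than 2 ROIs in the {side} hemisphere")
        vals = [
            net.w[idx[a], idx[b]]
            for i, a in enumerate(rois)
            for b in rois[i + 1 :]
        ]
        means.append(float(np.mean(vals)))
    return means[0], means[1]
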