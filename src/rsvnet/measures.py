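"""Comparison graph measures for weighted networks.

Five global measures commonly applied to weighted structural connectomes:

* node strength variance ``V`` — spread of the strength distribution;
* assortativity — strength correlation between connected endpoints;
* normalised clustering coefficient ``gamma = C / P`` — Onnela weighted
  clustering over graph density;
* routing efficiency ``E_rout`` — mean inverse weighted shortest-path
  length (edge length = 1 / weight);
* diffusion efficiency ``E_diff`` — mean inverse mean-first-passage time
  of the weight-proportional random walk.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse import csr_array
from scipy.sparse.csgraph import connected_components, shortest_path

from .network import WeightedNetwork


class DisconnectedNetworkError(ValueError):
    """Raised where a measure requires a single connected component."""


class MeasureComputationError(RuntimeError):
    """One or more measures failed; carries the per-measure errors."""

    def __init__(self, errors: dict[str, Exception]):
        self.errors = errors
        detail = "; ".join(f"{k}: {v}" for k, v in errors.items())
        super().__init__(f"measure computation failed — {detail}")


@dataclass(frozen=True)
class GraphMeasureSet:
    """Bundle of the five comparison measures with parameter provenance."""

    strength_variance: float
    assortativity: float
    clustering_norm: float
    routing_efficiency: float
    diffusion_efficiency: float
    params: dict = field(default_factory=dict)


def strength_variance(net: WeightedNetwork) -> float:
    """Sample variance (``n - 1`` denominator) of the node strengths."""
    if net.n_nodes < 2:
        raise ValueError("strength variance needs at least 2 nodes")
    return float(net.weights.sum(axis=1).var(ddof=1))


def assortativity(net: WeightedNetwork) -> float:
    """Strength assortativity: Pearson correlation of endpoint strengths.

    Sums run over all ordered pairs ``(i, j)`` with ``w_ij > 0`` (each
    undirected edge counted in both directions), which makes the printed
    moment-ratio form identical to the Pearson correlation between the
    strengths at the two ends of an edge.  When every endpoint strength
    is equal the ratio is 0/0; NaN is returned with a warning rather
    than a misleading 0.
    """
    s = net.weights.sum(axis=1)
    ii, jj = np.nonzero(net.weights)
    if ii.size < 4:  # fewer than 2 undirected edges
        raise ValueError("assortativity needs at least 2 edges")
    si, sj = s[ii], s[jj]
    m_prod = np.mean(si * sj)
    m_sum = np.mean((si + sj) / 2.0)
    m_sq = np.mean((si**2 + sj**2) / 2.0)
    denom = m_sq - m_sum**2
    if denom <= 0:
        warnings.warn(
            "assortativity undefined: all edge-endpoint strengths equal (0/0)",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("nan")
    return float((m_prod - m_sum**2) / denom)


def _to_graph(net: WeightedNetwork) -> nx.Graph:
    g = nx.from_numpy_array(net.weights)
    return g


def onnela_clustering(net: WeightedNetwork) -> float:
    """Mean Onnela weighted clustering coefficient.

    Weights are normalised by the network maximum; nodes with degree < 2
    contribute 0.
    """
    if net.n_nodes < 3:
        raise ValueError("clustering needs at least 3 nodes")
    if net.n_edges == 0:
        raise ValueError("clustering undefined on an edgeless network")
    return float(nx.average_clustering(_to_graph(net), weight="weight", count_zeros=True))


def density(net: WeightedNetwork) -> float:
    """Graph density ``P = 2M / (n (n - 1))``."""
    n = net.n_nodes
    return 2.0 * net.n_edges / (n * (n - 1))


def clustering_norm(net: WeightedNetwork) -> float:
    """Density-normalised Onnela clustering, ``gamma = C / P``."""
    return onnela_clustering(net) / density(net)


def routing_efficiency(net: WeightedNetwork, length_transform: str = "inverse") -> float:
    """Mean inverse weighted shortest-path length over ordered node pairs.

    Edge lengths are ``1 / w`` (strong connections are short); unreachable
    pairs contribute 0, so disconnected networks are handled gracefully.
    """
    if length_transform != "inverse":
        raise ValueError(f"unknown length transform {length_transform!r}")
    n = net.n_nodes
    if n < 2:
        raise ValueError("routing efficiency needs at least 2 nodes")
    with np.errstate(divide="ignore"):
        lengths = np.where(net.weights > 0, 1.0 / net.weights, 0.0)
    d = shortest_path(csr_array(lengths), method="D", directed=False)
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / np.where(d > 0, d, 1.0), 0.0)
    return float(inv[off].sum() / (n * (n - 1)))


def is_connected(net: WeightedNetwork) -> bool:
    n_comp, _ = connected_components(csr_array(net.weights), directed=False)
    return n_comp == 1


def mean_first_passage_times(net: WeightedNetwork) -> np.ndarray:
    """Mean first-passage time matrix of the weight-proportional walk.

    The walker at node *i* moves to neighbour *j* with probability
    ``W_ij / s_i``.  MFPTs come in closed form from the chain's
    fundamental matrix ``Z = (I - P + 1 pi^T)^{-1}`` with stationary
    distribution ``pi_j = s_j / sum_k s_k``:

    ``t_ij = (Z_jj - Z_ij) / pi_j``,  ``t_ii = 0``.

    Requires a connected network (MFPTs are infinite otherwise).
    """
    if not is_connected(net):
        raise DisconnectedNetworkError(
            "mean first-passage times are infinite on a disconnected network; "
            "restrict to the largest connected component first"
        )
    W = net.weights
    n = net.n_nodes
    if n < 2:
        raise ValueError("MFPT needs at least 2 nodes")
    s = W.sum(axis=1)
    P = W / s[:, None]
    pi = s / s.sum()
    Z = np.linalg.inv(np.eye(n) - P + np.outer(np.ones(n), pi))
    T = (np.diag(Z)[None, :] - Z) / pi[None, :]
    np.fill_diagonal(T, 0.0)
    return T


def diffusion_efficiency(net: WeightedNetwork) -> float:
    """Mean inverse mean-first-passage time over ordered node pairs."""
    T = mean_first_passage_times(net)
    n = net.n_nodes
    off = ~np.eye(n, dtype=bool)
    return float((1.0 / T[off]).sum() / (n * (n - 1)))


_MEASURES = {
    "strength_variance": strength_variance,
    "assortativity": assortativity,
    "clustering_norm": clustering_norm,
    "routing_efficiency": routing_efficiency,
    "diffusion_efficiency": diffusion_efficiency,
}


def all_measures(net: WeightedNetwork, strict: bool = True) -> GraphMeasureSet:
    """Compute all five comparison measures.

    With ``strict=True`` any per-measure failure raises a
    :class:`MeasureComputationError` naming every measure that failed;
    with ``strict=False`` failed measures are reported as NaN and the
    errors recorded in ``params["errors"]``.
    """
    values: dict[str, float] = {}
    errors: dict[str, Exception] = {}
    for name, fn in _MEASURES.items():
        try:
            values[name] = fn(net)
        except Exception as exc:  # noqa: BLE001 — collected and re-raised
            errors[name] = exc
            values[name] = float("nan")
    if errors and strict:
        raise MeasureComputationError(errors)
    params = {
        "length_transform": "inverse",
        "clustering_normalisation": "max_weight",
        "variance_estimator": "sample (n-1)",
    }
    if errors:
        params["errors"] = {k: str(v) for k, v in errors.items()}
    return GraphMeasureSet(params=params, **values)


def mean_edge_weight(net: WeightedNetwork) -> float:
    """Mean weight over present (nonzero) edges."""
    upper = np.triu(net.weights, k=1)
    vals = upper[upper > 0]
    if vals.size == 0:
        raise ValueError("no edges present")
    return float(vals.mean())
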