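"""Relative node strength, RSV and its sliding-window (hierarchical) variant.

The relative strength of node *i* compares its strength to the strengths of
its immediate neighbours.  Two formulations are provided:

* uncorrected: ``r_i = s_i / mean_{j in N(i)} s_j`` — strength over mean
  neighbour strength;
* edge-corrected: the weight of the connecting edge is subtracted from both
  strengths before forming each neighbour ratio, and ``r_i`` is the
  reciprocal of the mean of those corrected neighbour-to-self ratios,

  ``r_i = [ (1/|N(i)|) * sum_{j in N(i)} (s_j - W_ij) / (s_i - W_ij) ]^{-1}``.

  This removes the contribution of the edge (i, j) itself, which otherwise
  inflates relative strength for strong reciprocal connections.  With the
  subtraction disabled the corrected form reduces exactly to the
  uncorrected one.

RSV (relative strength variability) is the sample standard deviation of the
``r_i`` over all nodes: high where strong and weak nodes interconnect
(core-periphery mixing), low where connectivity stays local on the strength
hierarchy.  hRSV slides a window of ``w`` consecutive strength-ranked nodes
across the hierarchy, takes the sample SD of ``r`` within each of the
``n - w + 1`` windows, and averages: with a small window it behaves as a
weighted statistical-complexity measure (low for both regular and random
networks, high for structurally diverse ones).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .network import WeightedNetwork

#: Default sliding-window sizes: a small window (4) for the complexity
#: regime and a quarter-of-85-nodes window (21) for the broad regime.
DEFAULT_WINDOWS = (4, 21)


class DegenerateTermError(ValueError):
    """Corrected-form term with non-positive self strength after edge removal."""


class IsolatedNodeError(ValueError):
    """A node with no neighbours has no defined relative strength."""


@dataclass(frozen=True)
class RelativeStrengthProfile:
    """Per-node relative strengths ``r`` and strengths ``s``."""

    r: np.ndarray
    s: np.ndarray
    corrected: bool
    n_degenerate_terms: int = 0


@dataclass(frozen=True)
class RSVResult:
    """Network-wide relative strength variability.

    ``value`` is the sample standard deviation of the relative strengths
    (``n - 1`` denominator); ``variance`` is its square, the variance form.
    """

    value: float
    variance: float
    mu_r: float
    n_nodes: int


@dataclass(frozen=True)
class HRSVResult:
    """Sliding-window (hierarchical) RSV.

    ``per_window[k]`` is the sample SD of ``r`` over the ``w`` consecutive
    nodes at strength ranks ``k .. k+w-1`` (ascending); ``value`` is the
    mean over all ``n - w + 1`` windows.
    """

    value: float
    window_size: int
    per_window: np.ndarray
    ordering: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "per_window", np.asarray(self.per_window, dtype=float))


@dataclass(frozen=True)
class TierAssignment:
    """Partition of nodes into strength tiers (tier 1 = highest strength)."""

    tier_of_node: np.ndarray
    ordering: str
    n_tiers: int

    def nodes_in_tier(self, tier: int) -> np.ndarray:
        return np.flatnonzero(self.tier_of_node == tier)


def node_strengths(net: WeightedNetwork) -> np.ndarray:
    """Node strengths ``s_i = sum_j W_ij`` (weighted degree)."""
    return net.weights.sum(axis=1)


def relative_strengths(
    net: WeightedNetwork,
    corrected: bool = True,
    degenerate: str = "skip",
) -> RelativeStrengthProfile:
    """Relative node strengths, uncorrected or edge-corrected.

    Parameters
    ----------
    net
        Weighted network; every node must have at least one neighbour.
    corrected
        If True, subtract the connecting edge's weight from both node
        strengths before forming each neighbour ratio (the edge-corrected
        form); if False, use plain strength over mean neighbour strength.
    degenerate
        Policy for corrected-form terms with ``s_i - W_ij <= 0`` (e.g.
        leaf nodes whose only weight is the connecting edge):
        ``"skip"`` drops those terms from the mean with a warning,
        ``"strict"`` raises :class:`DegenerateTermError`.

    Raises
    ------
    IsolatedNodeError
        If any node has no neighbours.
    """
    if degenerate not in ("skip", "strict"):
        raise ValueError(f"degenerate policy must be 'skip' or 'strict', got {degenerate!r}")
    W = net.weights
    n = net.n_nodes
    s = W.sum(axis=1)
    adj = W > 0
    deg = adj.sum(axis=1)
    if np.any(deg == 0):
        i = int(np.argmin(deg))
        raise IsolatedNodeError(
            f"node {net.node_labels[i]!r} is isolated; relative strength undefined"
        )
    if not corrected:
        neigh_mean = (adj * s).sum(axis=1) / deg
        r = s / neigh_mean
        return RelativeStrengthProfile(r, s, corrected=False)

    # corrected form: per-edge ratios (s_j - W_ij) / (s_i - W_ij)
    self_minus = s[:, None] - W          # (s_i - W_ij) along rows
    neigh_minus = s[None, :] - W         # (s_j - W_ij) along columns
    degenerate_mask = adj & (self_minus <= 0)
    n_degen = int(degenerate_mask.sum())
    if n_degen and degenerate == "strict":
        i, j = np.argwhere(degenerate_mask)[0]
        raise DegenerateTermError(
            f"s_i - W_ij <= 0 for node {net.node_labels[i]!r} via neighbour "
            f"{net.node_labels[j]!r}; strict degenerate-term policy"
        )
    valid = adj & ~degenerate_mask
    if n_degen:
        warnings.warn(
            f"dropped {n_degen} degenerate corrected-form terms (s_i - W_ij <= 0)",
            RuntimeWarning,
            stacklevel=2,
        )
    n_valid = valid.sum(axis=1)
    if np.any(n_valid == 0):
        i = int(np.argmin(n_valid))
        raise DegenerateTermError(
            f"all corrected-form terms degenerate for node {net.node_labels[i]!r}"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(valid, neigh_minus / np.where(valid, self_minus, 1.0), 0.0)
    mean_ratio = ratios.sum(axis=1) / n_valid
    if np.any(mean_ratio <= 0):
        i = int(np.argmin(mean_ratio))
        raise DegenerateTermError(
            f"non-positive mean corrected ratio for node {net.node_labels[i]!r}"
        )
    r = 1.0 / mean_ratio
    return RelativeStrengthProfile(r, s, corrected=True, n_degenerate_terms=n_degen)


def rsv(
    net: WeightedNetwork,
    corrected: bool = True,
    degenerate: str = "skip",
) -> RSVResult:
    """Relative strength variability: sample SD of ``r`` over all nodes."""
    n = net.n_nodes
    if n < 2:
        raise ValueError("RSV needs at least 2 nodes")
    prof = relative_strengths(net, corrected=corrected, degenerate=degenerate)
    mu = float(prof.r.mean())
    var = float(np.sum((prof.r - mu) ** 2) / (n - 1))
    return RSVResult(value=float(np.sqrt(var)), variance=var, mu_r=mu, n_nodes=n)


def _ranked_order(basis: np.ndarray) -> np.ndarray:
    """Ascending stable argsort (ties broken by node index/label order)."""
    return np.argsort(np.asarray(basis, dtype=float), kind="stable")


def hrsv(
    net: WeightedNetwork,
    window_size: int,
    corrected: bool = True,
    ordering: str = "own_strength",
    population_strengths: np.ndarray | None = None,
    degenerate: str = "skip",
) -> HRSVResult:
    """Sliding-window hierarchical RSV.

    Nodes are sorted ascending by the ordering basis (their own strengths,
    or a cohort-mean strength vector when ``ordering`` is
    ``"population_mean_strength"``); window ``k`` covers the ``w``
    consecutive nodes at ranks ``k .. k+w-1``, and the result averages the
    ``n - w + 1`` within-window sample SDs of ``r``.

    With ``window_size == n`` there is a single window covering all nodes,
    so the value equals :func:`rsv` exactly.
    """
    n = net.n_nodes
    if not (2 <= window_size <= n):
        raise ValueError(f"window_size must lie in [2, n={n}], got {window_size}")
    prof = relative_strengths(net, corrected=corrected, degenerate=degenerate)
    basis = _ordering_basis(prof.s, ordering, population_strengths)
    if window_size == n:
        # single window over all nodes: identical to RSV by construction,
        # computed through the same estimator so the equality is exact
        mu = float(prof.r.mean())
        sd = float(np.sqrt(np.sum((prof.r - mu) ** 2) / (n - 1)))
        per_window = np.array([sd])
    else:
        order = _ranked_order(basis)
        r_sorted = prof.r[order]
        per_window = _sliding_sd(r_sorted, window_size)
    return HRSVResult(
        value=float(per_window.mean()),
        window_size=window_size,
        per_window=per_window,
        ordering=ordering,
    )


def _ordering_basis(
    own_strengths: np.ndarray,
    ordering: str,
    population_strengths: np.ndarray | None,
) -> np.ndarray:
    if ordering == "own_strength":
        return own_strengths
    if ordering == "population_mean_strength":
        if population_strengths is None:
            raise ValueError("population ordering requires population_strengths")
        pop = np.asarray(population_strengths, dtype=float)
        if pop.shape != own_strengths.shape:
            raise ValueError("population_strengths length must equal n_nodes")
        return pop
    raise ValueError(f"unknown ordering {ordering!r}")


def _sliding_sd(values: np.ndarray, w: int) -> np.ndarray:
    """Sample SDs of all length-``w`` contiguous windows of ``values``."""
    windows = np.lib.stride_tricks.sliding_window_view(values, w)
    return windows.std(axis=1, ddof=1)


def assign_tiers(
    strength_basis: np.ndarray,
    n_tiers: int = 4,
    ordering: str = "own_strength",
) -> TierAssignment:
    """Partition nodes into contiguous strength tiers.

    Nodes are ranked descending by ``strength_basis``; tier sizes differ
    by at most one, with the larger blocks assigned to the lower-numbered
    (higher-strength) tiers.  Tier 1 holds the top-strength nodes.
    """
    basis = np.asarray(strength_basis, dtype=float)
    n = basis.size
    if n_tiers < 1:
        raise ValueError("n_tiers must be >= 1")
    if n < n_tiers:
        raise ValueError(f"cannot split {n} nodes into {n_tiers} tiers")
    # descending rank with stable label-order tie-break
    order_desc = np.argsort(-basis, kind="stable")
    base, rem = divmod(n, n_tiers)
    sizes = [base + 1 if t < rem else base for t in range(n_tiers)]
    tier_of_node = np.empty(n, dtype=int)
    start = 0
    for t, size in enumerate(sizes, start=1):
        tier_of_node[order_desc[start : start + size]] = t
        start += size
    return TierAssignment(tier_of_node=tier_of_node, ordering=ordering, n_tiers=n_tiers)


def tier_hrsv(
    net: WeightedNetwork,
    tiers: TierAssignment,
    window_size: int,
    corrected: bool = True,
    ordering: str = "own_strength",
    population_strengths: np.ndarray | None = None,
    degenerate: str = "skip",
) -> dict[int, HRSVResult]:
    """Sliding-window RSV restricted to each strength tier.

    Relative strengths are computed on the full network; windows then
    slide over each tier's nodes in ascending rank order.  Every tier
    must hold at least ``window_size`` nodes.
    """
    prof = relative_strengths(net, corrected=corrected, degenerate=degenerate)
    basis = _ordering_basis(prof.s, ordering, population_strengths)
    results: dict[int, HRSVResult] = {}
    for t in range(1, tiers.n_tiers + 1):
        nodes = tiers.nodes_in_tier(t)
        if nodes.size < window_size:
            raise ValueError(
                f"tier {t} has {nodes.size} nodes, fewer than window_size={window_size}"
            )
        order = nodes[_ranked_order(basis[nodes])]
        per_window = _sliding_sd(prof.r[order], window_size)
        results[t] = HRSVResult(
            value=float(per_window.mean()),
            window_size=window_size,
            per_window=per_window,
            ordering=ordering,
        )
    return results
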