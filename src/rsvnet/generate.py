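"""Synthetic weighted-network families and cohorts.

Generators for the archetype families used to characterise the variability
measures:

* ``er`` — Erdős–Rényi G(n, M): M edges drawn uniformly (low RSV, low hRSV);
* ``geometric`` — random geometric graph on the unit square (low hRSV);
* ``hetero_geometric`` — geometric graph with heavy-tailed per-node radii,
  giving a heterogeneous degree distribution (high hRSV: the statistical-
  complexity regime);
* ``star_like`` / ``core_periphery`` — dense hub set tied to a sparse
  periphery (high RSV: core-periphery mixing);
* ``lattice`` — ring lattice; ``regular`` — random k-regular graph
  (uniform weights give RSV = hRSV = 0 exactly).

Edge counts are hit exactly for er/geometric/hetero_geometric/star-like
families (edges are the M best-scoring pairs), and to the nearest feasible
even degree for lattice/regular.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .network import Cohort, WeightedNetwork

FAMILIES = (
    "er",
    "geometric",
    "hetero_geometric",
    "star_like",
    "core_periphery",
    "lattice",
    "regular",
)
WEIGHT_MODELS = ("uniform", "lognormal", "distance_decay")


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of one synthetic network family.

    Defaults match the connectome setting the measures target: 85 nodes
    (Desikan-Killiany parcellation plus subcortical regions) at density
    0.6 (typical for a group-thresholded structural connectome), with
    lognormal edge weights of sigma 0.5.
    """

    family: str = "er"
    n: int = 85
    density: float = 0.6
    weight_model: str = "lognormal"
    sigma: float = 0.5
    hub_fraction: float = 0.15
    pareto_alpha: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if self.weight_model not in WEIGHT_MODELS:
            raise ValueError(f"unknown weight model {self.weight_model!r}")
        if not (0.0 < self.density <= 1.0):
            raise ValueError("density must lie in (0, 1]")
        if self.n < 4:
            raise ValueError("n must be >= 4")


def _target_edges(n: int, density: float) -> int:
    m_max = n * (n - 1) // 2
    m = int(round(density * m_max))
    if m < 1:
        raise ValueError(f"density {density} yields no edges at n={n}")
    return m


def _adjacency_from_pairs(n: int, ii: np.ndarray, jj: np.ndarray) -> np.ndarray:
    adj = np.zeros((n, n), dtype=bool)
    adj[ii, jj] = True
    adj |= adj.T
    return adj


def _upper_pairs(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n, k=1)


def _structure(spec: GeneratorSpec, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray | None]:
    """Return (boolean adjacency, optional node coordinates)."""
    n = spec.n
    ii, jj = _upper_pairs(n)
    if spec.family == "er":
        m = _target_edges(n, spec.density)
        pick = rng.choice(ii.size, size=m, replace=False)
        return _adjacency_from_pairs(n, ii[pick], jj[pick]), None

    if spec.family in ("geometric", "hetero_geometric"):
        pts = rng.random((n, 2))
        d = np.hypot(pts[ii, 0] - pts[jj, 0], pts[ii, 1] - pts[jj, 1])
        if spec.family == "geometric":
            score = d
        else:
            # heavy-tailed per-node reach: a few far-reaching hubs
            radii = rng.pareto(spec.pareto_alpha, size=n) + 1.0
            score = d / (radii[ii] + radii[jj])
        m = _target_edges(n, spec.density)
        pick = np.argsort(score, kind="stable")[:m]
        return _adjacency_from_pairs(n, ii[pick], jj[pick]), pts

    if spec.family in ("star_like", "core_periphery"):
        m = _target_edges(n, spec.density)
        n_hub = max(1, int(round(spec.hub_fraction * n)))
        hubs = np.arange(n_hub)
        is_hub = np.isin(ii, hubs) | np.isin(jj, hubs)
        hub_pairs = np.flatnonzero(is_hub)
        peri_pairs = np.flatnonzero(~is_hub)
        if m <= hub_pairs.size:
            pick = rng.choice(hub_pairs, size=m, replace=False)
        else:
            extra = rng.choice(peri_pairs, size=m - hub_pairs.size, replace=False)
            pick = np.concatenate([hub_pairs, extra])
        return _adjacency_from_pairs(n, ii[pick], jj[pick]), None

    if spec.family == "lattice":
        k = max(2, 2 * int(round(spec.density * (n - 1) / 2.0)))
        if k >= n or abs(k / (n - 1) - spec.density) > 0.1 * spec.density:
            raise ValueError(
                f"density {spec.density} infeasible for ring lattice at n={n}: "
                f"nearest even degree {k} realises {k / (n - 1):.3f}"
            )
        g = nx.watts_strogatz_graph(n, k, p=0.0)
        return nx.to_numpy_array(g).astype(bool), None

    if spec.family == "regular":
        k = max(2, int(round(spec.density * (n - 1))))
        if (k * n) % 2:
            k += 1
        if k >= n or abs(k / (n - 1) - spec.density) > 0.1 * spec.density:
            raise ValueError(
                f"density {spec.density} infeasible for {k}-regular graph at n={n}"
            )
        g = nx.random_regular_graph(k, n, seed=int(rng.integers(2**31)))
        return nx.to_numpy_array(g).astype(bool), None

    raise AssertionError(spec.family)


def _weights(
    adj: np.ndarray,
    spec: GeneratorSpec,
    rng: np.random.Generator,
    coords: np.ndarray | None,
) -> np.ndarray:
    n = adj.shape[0]
    W = np.zeros((n, n))
    ii, jj = np.nonzero(np.triu(adj, k=1))
    if spec.weight_model == "uniform":
        w = np.ones(ii.size)
    elif spec.weight_model == "lognormal":
        w = rng.lognormal(mean=0.0, sigma=spec.sigma, size=ii.size)
    else:  # distance_decay
        if coords is None:
            coords = rng.random((n, 2))
        d = np.hypot(coords[ii, 0] - coords[jj, 0], coords[ii, 1] - coords[jj, 1])
        w = 1.0 / (0.1 + d)
    W[ii, jj] = w
    W += W.T
    return W


def generate(spec: GeneratorSpec) -> WeightedNetwork:
    """Generate one weighted network; deterministic for a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    adj, coords = _structure(spec, rng)
    W = _weights(adj, spec, rng, coords)
    return WeightedNetwork.from_matrix(W, weight_kind="other")


def generate_cohort(
    spec: GeneratorSpec,
    n_subjects: int,
    subject_noise: float = 0.2,
    edge_dropout: float = 0.1,
    seed: int | None = None,
) -> Cohort:
    """A cohort of noisy realisations of one base network.

    Each subject's network is the base network with independent
    multiplicative lognormal weight noise (``sigma = subject_noise``)
    and independent Bernoulli edge dropout (``edge_dropout`` per edge),
    mimicking between-subject variability around a shared topology.
    Metadata columns ``age`` (years, truncated normal around 64),
    ``sex`` and ``site`` are drawn reproducibly from the same seed.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if subject_noise < 0 or not (0.0 <= edge_dropout < 1.0):
        raise ValueError("subject_noise must be >= 0 and edge_dropout in [0, 1)")
    if seed is None:
        seed = spec.seed + 1
    base = generate(spec)
    n = base.n_nodes
    rng = np.random.default_rng(seed)
    ii, jj = np.nonzero(np.triu(base.weights, k=1))
    nets = []
    for _ in range(n_subjects):
        w = base.weights[ii, jj].copy()
        if subject_noise > 0:
            w *= rng.lognormal(0.0, subject_noise, size=w.size)
        if edge_dropout > 0:
            w[rng.random(w.size) < edge_dropout] = 0.0
        W = np.zeros((n, n))
        W[ii, jj] = w
        W += W.T
        nets.append(base.with_weights(W))
    ids = [f"S{k + 1:04d}" for k in range(n_subjects)]
    age = np.clip(rng.normal(64.0, 7.65, size=n_subjects), 45.0, 82.0)
    sex = rng.choice(["F", "M"], size=n_subjects, p=[0.53, 0.47])
    site = rng.choice(
        ["site1", "site2", "site3", "site4"],
        size=n_subjects,
        p=[0.58, 0.16, 0.2587, 0.0013],
    )
    meta = pd.DataFrame({"age": age, "sex": sex, "site": site}, index=ids)
    return Cohort(nets, ids, meta)


#: Default signed loadings of the 10-task synthetic battery, spanning
#: absolute values 0.42-0.75; negative loadings mark lower-is-better
#: tasks (reaction-time- and error-count-like scores).
DEFAULT_LOADINGS = (-0.45, 0.53, 0.71, -0.75, 0.67, 0.61, 0.65, 0.46, -0.42, 0.55)


def generate_battery(
    n_subjects: int,
    loadings: tuple[float, ...] = DEFAULT_LOADINGS,
    missing_rate: float = 0.1,
    seed: int = 0,
    g: np.ndarray | None = None,
):
    """One-factor synthetic cognitive battery with missingness.

    Task ``j`` scores are ``lambda_j * g + sqrt(1 - lambda_j^2) * eps``
    with iid standard-normal noise, so each task has unit variance and
    population loading ``lambda_j`` on the factor.  A ``missing_rate``
    fraction of entries is masked completely at random.  Pass ``g`` to
    couple the battery to an externally constructed factor (e.g. one
    carrying network-measure signal); otherwise g is drawn standard
    normal.  Returns ``(CognitiveMatrix, true_g)``.
    """
    from .cognition import CognitiveMatrix

    lam = np.asarray(loadings, dtype=float)
    if np.any(np.abs(lam) >= 1.0):
        raise ValueError("loadings must have absolute value < 1")
    if not (0.0 <= missing_rate < 1.0):
        raise ValueError("missing_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    if g is None:
        g = rng.standard_normal(n_subjects)
    else:
        g = np.asarray(g, dtype=float)
        if g.shape != (n_subjects,):
            raise ValueError("g must have length n_subjects")
    eps = rng.standard_normal((n_subjects, lam.size))
    scores = g[:, None] * lam[None, :] + eps * np.sqrt(1.0 - lam**2)[None, :]
    if missing_rate > 0:
        scores = np.where(rng.random(scores.shape) < missing_rate, np.nan, scores)
    task_names = [f"task{j + 1:02d}" for j in range(lam.size)]
    df = pd.DataFrame(scores, columns=task_names,
                      index=[f"S{k + 1:04d}" for k in range(n_subjects)])
    convention = {
        name: ("lower_better" if l < 0 else "higher_better")
        for name, l in zip(task_names, lam)
    }
    return CognitiveMatrix(df, sign_convention=convention), g


def archetype_suite(n: int = 85, density: float = 0.6, seed: int = 0) -> dict[str, GeneratorSpec]:
    """Specs for the four archetype quadrants at matched n and density."""
    return {
        family: GeneratorSpec(family=family, n=n, density=density, seed=seed)
        for family in ("er", "geometric", "hetero_geometric", "star_like", "lattice")
    }
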