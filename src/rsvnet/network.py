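"""Core containers for weighted, undirected networks and subject cohorts.

A :class:`WeightedNetwork` is one subject's symmetric, non-negative,
zero-diagonal adjacency matrix together with node labels and a tag naming
the edge-weighting scheme (streamline count, fractional anisotropy, ...).
A :class:`Cohort` stacks networks that share a parcellation, aligned with
per-subject metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: Recognised edge-weighting schemes for diffusion-MRI connectomes.
WEIGHT_KINDS = ("FA", "MD", "SC", "OD", "ISOVF", "ICVF", "other")

#: Absolute tolerance within which an adjacency matrix counts as symmetric.
SYMMETRY_ATOL = 1e-10


class NetworkValidationError(ValueError):
    """Raised when an adjacency matrix violates the network invariants."""


@dataclass(frozen=True)
class WeightedNetwork:
    """A single subject's weighted, undirected network.

    Parameters
    ----------
    weights
        ``(n, n)`` symmetric matrix of non-negative edge weights; zero
        means "no edge".  The diagonal is zero (no self-loops).
    node_labels
        Ordered region identifiers, length ``n``.
    weight_kind
        One of :data:`WEIGHT_KINDS`.
    """

    weights: np.ndarray
    node_labels: tuple[str, ...]
    weight_kind: str = "other"

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise NetworkValidationError(
                f"adjacency matrix must be square, got shape {w.shape}"
            )
        if not np.all(np.isfinite(w)):
            raise NetworkValidationError("adjacency matrix contains non-finite entries")
        if np.any(w < 0):
            bad = np.argwhere(w < 0)[0]
            raise NetworkValidationError(
                f"negative weight {w[tuple(bad)]:g} at {tuple(bad)}; weights must be >= 0"
            )
        asym = np.max(np.abs(w - w.T)) if w.size else 0.0
        if asym > SYMMETRY_ATOL:
            raise NetworkValidationError(
                f"matrix asymmetric beyond tolerance: max |W - W.T| = {asym:g}"
            )
        # Exact symmetrisation removes sub-tolerance float noise.
        w = (w + w.T) / 2.0
        np.fill_diagonal(w, 0.0)
        w.flags.writeable = False
        object.__setattr__(self, "weights", w)
        labels = tuple(str(x) for x in self.node_labels)
        if len(labels) != w.shape[0]:
            raise NetworkValidationError(
                f"{len(labels)} labels for {w.shape[0]} nodes"
            )
        if len(set(labels)) != len(labels):
            raise NetworkValidationError("node labels must be unique")
        object.__setattr__(self, "node_labels", labels)
        if self.weight_kind not in WEIGHT_KINDS:
            raise NetworkValidationError(
                f"unknown weight_kind {self.weight_kind!r}; expected one of {WEIGHT_KINDS}"
            )

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        """Number of undirected edges (nonzero weight pairs)."""
        return int(np.count_nonzero(np.triu(self.weights, k=1)))

    def with_weights(self, weights: np.ndarray) -> "WeightedNetwork":
        """Return a copy carrying new weights but the same labels and kind."""
        return WeightedNetwork(np.array(weights, dtype=float), self.node_labels, self.weight_kind)

    @classmethod
    def from_matrix(
        cls,
        weights: np.ndarray,
        node_labels: Sequence[str] | None = None,
        weight_kind: str = "other",
    ) -> "WeightedNetwork":
        """Build a network, defaulting labels to ``R1..Rn``."""
        w = np.asarray(weights, dtype=float)
        if node_labels is None:
            node_labels = [f"R{i + 1}" for i in range(w.shape[0])]
        return cls(w, tuple(node_labels), weight_kind)


@dataclass(frozen=True)
class EdgeMask:
    """Boolean edge-retention mask from cohort prevalence thresholding."""

    keep: np.ndarray
    prevalence_threshold: float

    def __post_init__(self) -> None:
        k = np.asarray(self.keep, dtype=bool)
        if k.ndim != 2 or k.shape[0] != k.shape[1]:
            raise NetworkValidationError("mask must be square")
        if not np.array_equal(k, k.T):
            raise NetworkValidationError("mask must be symmetric")
        k = k.copy()
        np.fill_diagonal(k, False)
        k.flags.writeable = False
        object.__setattr__(self, "keep", k)
        if not (0.0 < self.prevalence_threshold <= 1.0):
            raise NetworkValidationError("prevalence_threshold must lie in (0, 1]")

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.keep, k=1)))


@dataclass
class Cohort:
    """Aligned stack of :class:`WeightedNetwork` sharing one parcellation.

    ``metadata`` is a subjects-by-columns table (age, sex, site, global
    volumes, ...) indexed like ``subject_ids``.
    """

    networks: list[WeightedNetwork]
    subject_ids: list[str]
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if not self.networks:
            raise NetworkValidationError("cohort must contain at least one network")
        labels = self.networks[0].node_labels
        for net in self.networks[1:]:
            if net.node_labels != labels:
                raise NetworkValidationError(
                    "all cohort networks must share node labels and order"
                )
        self.subject_ids = [str(s) for s in self.subject_ids]
        if len(self.subject_ids) != len(self.networks):
            raise NetworkValidationError(
                f"{len(self.subject_ids)} subject ids for {len(self.networks)} networks"
            )
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise NetworkValidationError("subject ids must be unique")
        if self.metadata.empty:
            self.metadata = pd.DataFrame(index=pd.Index(self.subject_ids, name="subject_id"))
        else:
            self.metadata = self.metadata.copy()
            self.metadata.index = pd.Index(self.subject_ids, name="subject_id")

    @property
    def n_subjects(self) -> int:
        return len(self.networks)

    @property
    def n_nodes(self) -> int:
        return self.networks[0].n_nodes

    @property
    def node_labels(self) -> tuple[str, ...]:
        return self.networks[0].node_labels

    def stacked_weights(self) -> np.ndarray:
        """Return a ``(n_subjects, n, n)`` array of all adjacency matrices."""
        return np.stack([net.weights for net in self.networks])

    def mean_strengths(self) -> np.ndarray:
        """Cohort-mean node strength vector (the population ranking basis)."""
        return self.stacked_weights().sum(axis=2).mean(axis=0)
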