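"""Reading, validating, thresholding and writing connectome data.

Dense adjacency files are ``n x n`` CSV/TSV grids, optionally carrying
node labels in a header row plus first column.  Edge lists are 3-column
files of ``(label_i, label_j, weight)``.  Cohort-level prevalence
thresholding retains edges present (weight > 0) in at least a given
fraction of subjects.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .network import Cohort, EdgeMask, NetworkValidationError, WeightedNetwork


class FormatError(ValueError):
    """Raised when an input file does not match the declared format."""


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def _sniff_delimiter(path: Path) -> str:
    with open(path, newline="") as fh:
        sample = fh.read(4096)
    return "\t" if sample.count("\t") >= sample.count(",") else ","


def read_network(
    path: str | Path,
    format: str = "dense",
    weight_kind: str = "other",
) -> WeightedNetwork:
    """Read one weighted network from a dense-matrix or edge-list file.

    Parameters
    ----------
    path
        CSV/TSV file.  Dense form: ``n x n`` numeric grid, optionally
        with a label header row and first-column labels.  Edge-list
        form: rows of ``label_i, label_j, weight``.
    format
        ``"dense"`` or ``"edgelist"``.
    weight_kind
        Weighting-scheme tag stored on the returned network.

    Returns
    -------
    WeightedNetwork
        Validated (symmetrised, zero diagonal, non-negative).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    delim = _sniff_delimiter(path)
    with open(path, newline="") as fh:
        rows = [row for row in csv.reader(fh, delimiter=delim) if row and any(c.strip() for c in row)]
    if not rows:
        raise FormatError(f"{path}: empty file")
    if format == "dense":
        return _parse_dense(rows, path, weight_kind)
    if format == "edgelist":
        return _parse_edgelist(rows, path, weight_kind)
    raise ValueError(f"unknown format {format!r}; expected 'dense' or 'edgelist'")


def _parse_dense(rows: list[list[str]], path: Path, weight_kind: str) -> WeightedNetwork:
    has_header = not _is_number(rows[0][-1])
    labels: list[str] | None = None
    if has_header:
        header = [c.strip() for c in rows[0]]
        body = rows[1:]
        # header may or may not carry a stub cell over the label column
        first_col_labels = body and not _is_number(body[0][0])
        if first_col_labels:
            labels = [r[0].strip() for r in body]
            body = [r[1:] for r in body]
            if len(header) == len(body[0]) + 1:
                header = header[1:]
        else:
            labels = header
        if labels != header and header != labels:
            raise FormatError(f"{path}: header row and label column disagree")
    else:
        body = rows
    try:
        mat = np.array([[float(c) for c in r] for r in body], dtype=float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric entry in dense matrix: {exc}") from exc
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise FormatError(f"{path}: dense matrix must be square, got {mat.shape}")
    return WeightedNetwork.from_matrix(mat, labels, weight_kind)


def _parse_edgelist(rows: list[list[str]], path: Path, weight_kind: str) -> WeightedNetwork:
    if rows and not _is_number(rows[0][-1]):
        rows = rows[1:]  # header row
    edges: dict[tuple[str, str], float] = {}
    labels: list[str] = []
    seen: set[str] = set()
    for r in rows:
        if len(r) != 3:
            raise FormatError(f"{path}: edge-list rows need 3 columns, got {len(r)}")
        a, b, wtok = (c.strip() for c in r)
        try:
            w = float(wtok)
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric weight {wtok!r}") from exc
        for lab in (a, b):
            if lab not in seen:
                seen.add(lab)
                labels.append(lab)
        key = (a, b) if a <= b else (b, a)
        if key in edges and edges[key] != w:
            raise FormatError(
                f"{path}: conflicting weights for edge {key}: {edges[key]:g} vs {w:g}"
            )
        edges[key] = w
    n = len(labels)
    idx = {lab: i for i, lab in enumerate(labels)}
    mat = np.zeros((n, n))
    for (a, b), w in edges.items():
        i, j = idx[a], idx[b]
        mat[i, j] = mat[j, i] = w
    return WeightedNetwork.from_matrix(mat, labels, weight_kind)


def write_network(net: WeightedNetwork, path: str | Path) -> None:
    """Write a network as a dense CSV with a label header and label column."""
    df = pd.DataFrame(net.weights, index=net.node_labels, columns=net.node_labels)
    df.to_csv(path, float_format="%.12g")


def group_threshold(
    cohort: Cohort,
    prevalence_threshold: float = 0.5,
    presence_rule: str = "nonzero",
) -> tuple[EdgeMask, Cohort]:
    """Cohort prevalence thresholding.

    An edge is retained iff its weight is nonzero in at least
    ``prevalence_threshold`` (inclusive) of the cohort's subjects.
    Returns the mask and a new cohort with masked-out entries zeroed.
    """
    if presence_rule != "nonzero":
        raise ValueError(f"unknown presence rule {presence_rule!r}")
    if not (0.0 < prevalence_threshold <= 1.0):
        raise ValueError("prevalence_threshold must lie in (0, 1]")
    stack = cohort.stacked_weights()
    prevalence = (stack > 0).mean(axis=0)
    keep = prevalence >= prevalence_threshold
    keep &= keep.T
    mask = EdgeMask(keep, prevalence_threshold)
    return mask, apply_mask(cohort, mask)


def apply_mask(cohort: Cohort, mask: EdgeMask) -> Cohort:
    """Zero out all edges outside ``mask`` in every subject's network.

    The same mask may be applied across weighting schemes of the same
    subjects (e.g. a streamline-count-derived mask applied to FA/MD
    variants sharing the streamline edge support).
    """
    if mask.keep.shape[0] != cohort.n_nodes:
        raise ValueError(
            f"mask is {mask.keep.shape[0]}-node but cohort has {cohort.n_nodes} nodes"
        )
    nets = [net.with_weights(net.weights * mask.keep) for net in cohort.networks]
    return Cohort(nets, list(cohort.subject_ids), cohort.metadata)


@dataclass
class MeasureTable:
    """Subjects-by-measures numeric table with parameter provenance.

    Column names encode the measure, weighting and parameterisation,
    e.g. ``hRSV_w4_FA``.  ``params`` records every analysis decision
    (length transform, SD estimator, degenerate-term policy, ...).
    """

    data: pd.DataFrame
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = self.data.copy()
        self.data.index.name = "subject_id"


def write_measure_table(table: MeasureTable, path: str | Path) -> None:
    """Write a measure table as tidy CSV (12 significant digits)."""
    if table.data.empty:
        raise ValueError("refusing to write an empty measure table")
    table.data.to_csv(path, float_format="%.12g")


def read_measure_table(path: str | Path) -> MeasureTable:
    """Read back a measure table written by :func:`write_measure_table`."""
    df = pd.read_csv(path, index_col="subject_id")
    return MeasureTable(df)


def load_cohort(
    paths: Sequence[str | Path],
    format: str = "dense",
    weight_kind: str = "other",
    subject_ids: Iterable[str] | None = None,
    metadata: pd.DataFrame | None = None,
) -> Cohort:
    """Load a cohort of same-parcellation networks from files.

    Subject ids default to file stems.
    """
    paths = [Path(p) for p in paths]
    nets = [read_network(p, format=format, weight_kind=weight_kind) for p in paths]
    ids = list(subject_ids) if subject_ids is not None else [p.stem for p in paths]
    return Cohort(nets, ids, metadata if metadata is not None else pd.DataFrame())
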