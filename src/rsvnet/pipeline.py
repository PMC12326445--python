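"""End-to-end cohort pipeline: load, threshold, measure, write.

``compute_measures`` is the library entry point: it takes one cohort per
weighting scheme, derives a single prevalence mask (from the designated
reference weighting, by default streamline count when present, since all
weightings of a subject share the streamline-defined edge support),
applies it to every weighting, and computes RSV, windowed hRSV and the
comparison graph measures per subject.  ``run_compute`` wraps this with
file I/O and a JSON sidecar recording every parameter decision, so a run
is reconstructible without the shell history.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import measures as gm
from .rsv import DEFAULT_WINDOWS, hrsv as _hrsv, rsv as _rsv
from .io import MeasureTable, group_threshold, apply_mask, read_network, write_measure_table
from .network import Cohort


@dataclass
class RunConfig:
    """Parameters of one compute run.

    ``inputs`` maps each weighting-scheme tag to the list of per-subject
    adjacency files (aligned across weightings by position).
    ``mask_scope`` is ``"reference"`` (one mask from ``reference_kind``,
    applied to all weightings) or ``"per_weighting"`` (each weighting
    thresholded on its own support).
    """

    inputs: dict[str, list[str | Path]] = field(default_factory=dict)
    format: str = "dense"
    threshold: float = 0.5
    windows: tuple[int, ...] = DEFAULT_WINDOWS
    corrected: bool = True
    ordering: str = "population_mean_strength"
    degenerate: str = "skip"
    mask_scope: str = "reference"
    reference_kind: str | None = None
    seed: int = 0
    out_dir: str | Path = "."

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold <= 1.0):
            raise ValueError("threshold must lie in (0, 1]")
        if any(w < 2 for w in self.windows):
            raise ValueError("all window sizes must be >= 2")
        if self.mask_scope not in ("reference", "per_weighting"):
            raise ValueError(f"unknown mask scope {self.mask_scope!r}")


def _pick_reference(kinds: list[str], reference_kind: str | None) -> str:
    if reference_kind is not None:
        if reference_kind not in kinds:
            raise ValueError(f"reference weighting {reference_kind!r} not among {kinds}")
        return reference_kind
    return "SC" if "SC" in kinds else kinds[0]


def compute_measures(
    cohorts: dict[str, Cohort],
    threshold: float = 0.5,
    windows: tuple[int, ...] = DEFAULT_WINDOWS,
    corrected: bool = True,
    ordering: str = "population_mean_strength",
    degenerate: str = "skip",
    mask_scope: str = "reference",
    reference_kind: str | None = None,
) -> tuple[MeasureTable, dict[str, list[str]]]:
    """Threshold each weighting's cohort and compute all measures.

    Returns the measure table and a per-weighting record of subjects for
    which one or more measures failed (reported as NaN in the table).
    Raises if every subject of a weighting fails.
    """
    if not cohorts:
        raise ValueError("no cohorts supplied")
    kinds = list(cohorts)
    subject_ids = cohorts[kinds[0]].subject_ids
    for kind, cohort in cohorts.items():
        if cohort.subject_ids != subject_ids:
            raise ValueError(f"weighting {kind!r} has misaligned subject ids")

    masked: dict[str, Cohort] = {}
    if mask_scope == "reference":
        ref = _pick_reference(kinds, reference_kind)
        mask, _ = group_threshold(cohorts[ref], threshold)
        for kind in kinds:
            masked[kind] = apply_mask(cohorts[kind], mask)
    else:
        for kind in kinds:
            _, masked[kind] = group_threshold(cohorts[kind], threshold)

    columns: dict[str, np.ndarray] = {}
    failures: dict[str, list[str]] = {}
    for kind in kinds:
        cohort = masked[kind]
        pop = cohort.mean_strengths() if ordering == "population_mean_strength" else None
        names = (
            [f"RSV_{kind}"]
            + [f"hRSV_w{w}_{kind}" for w in windows]
            + [f"V_{kind}", f"assort_{kind}", f"gamma_{kind}", f"Erout_{kind}",
               f"Ediff_{kind}", f"meanw_{kind}"]
        )
        values = np.full((cohort.n_subjects, len(names)), np.nan)
        failed: list[str] = []
        for s, net in enumerate(cohort.networks):
            try:
                row = [_rsv(net, corrected=corrected, degenerate=degenerate).value]
                for w in windows:
                    row.append(
                        _hrsv(
                            net, w, corrected=corrected, ordering=ordering,
                            population_strengths=pop, degenerate=degenerate,
                        ).value
                    )
                ms = gm.all_measures(net, strict=False)
                row += [
                    ms.strength_variance, ms.assortativity, ms.clustering_norm,
                    ms.routing_efficiency, ms.diffusion_efficiency,
                    gm.mean_edge_weight(net),
                ]
                values[s] = row
                if "errors" in ms.params:
                    failed.append(cohort.subject_ids[s])
            except Exception:  # noqa: BLE001 — per-subject robustness contract
                failed.append(cohort.subject_ids[s])
        if len(failed) == cohort.n_subjects and np.isnan(values).all():
            raise RuntimeError(f"all subjects failed for weighting {kind!r}")
        if failed:
            failures[kind] = failed
        for name, col in zip(names, values.T):
            columns[name] = col

    params = {
        "threshold": threshold,
        "windows": list(windows),
        "corrected": corrected,
        "ordering": ordering,
        "degenerate_policy": degenerate,
        "mask_scope": mask_scope,
        "reference_kind": _pick_reference(kinds, reference_kind) if mask_scope == "reference" else None,
        "length_transform": "inverse",
        "sd_estimator": "sample (n-1)",
        "clustering_normalisation": "max_weight",
    }
    table = MeasureTable(
        pd.DataFrame(columns, index=pd.Index(subject_ids, name="subject_id")),
        params=params,
    )
    return table, failures


def run_compute(config: RunConfig) -> MeasureTable:
    """Load cohorts from files per ``config``, compute, and write outputs.

    Writes ``measures.csv`` and a ``measures_params.json`` sidecar (all
    parameter decisions plus any per-subject failures) into
    ``config.out_dir``.
    """
    # read per file so one corrupt input fails that subject, not the run;
    # a failed subject is dropped from every weighting (positional alignment)
    load_failures: dict[str, str] = {}
    raw: dict[str, list] = {}
    kinds = list(config.inputs)
    n_files = {len(v) for v in config.inputs.values()}
    if len(n_files) > 1:
        raise ValueError("all weightings must list the same number of subject files")
    for kind, paths in config.inputs.items():
        wk = kind if kind in ("FA", "MD", "SC", "OD", "ISOVF", "ICVF") else "other"
        nets = []
        for pos, p in enumerate(paths):
            try:
                nets.append(read_network(p, format=config.format, weight_kind=wk))
            except Exception as exc:  # noqa: BLE001 — robustness contract
                nets.append(None)
                load_failures[str(p)] = str(exc)
        raw[kind] = nets
    n_subj = n_files.pop()
    good = [i for i in range(n_subj)
            if all(raw[kind][i] is not None for kind in kinds)]
    if not good:
        raise RuntimeError("no subject could be loaded for every weighting")
    cohorts = {}
    for kind in kinds:
        ids = [Path(config.inputs[kind][i]).stem for i in good]
        cohorts[kind] = Cohort([raw[kind][i] for i in good], ids)
    table, failures = compute_measures(
        cohorts,
        threshold=config.threshold,
        windows=config.windows,
        corrected=config.corrected,
        ordering=config.ordering,
        degenerate=config.degenerate,
        mask_scope=config.mask_scope,
        reference_kind=config.reference_kind,
    )
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_measure_table(table, out_dir / "measures.csv")
    sidecar = dict(table.params)
    sidecar["seed"] = config.seed
    sidecar["failures"] = failures
    sidecar["load_failures"] = load_failures
    (out_dir / "measures_params.json").write_text(json.dumps(sidecar, indent=2) + "\n")
    return table
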