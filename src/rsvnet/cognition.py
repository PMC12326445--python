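"""Cognitive battery handling: missingness exclusion, low-rank imputation
and extraction of the general factor (g).

A battery is a subjects-by-tasks score matrix with missing entries.
Subjects missing more than a cutoff number of tasks are excluded;
remaining gaps are filled by low-rank matrix completion (alternating
truncated-SVD projection with observed entries restored each sweep).
g is the first unrotated principal component of the z-scored,
completed battery, z-normalised, with standardised loadings reported
per task.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd


@dataclass
class CognitiveMatrix:
    """Subjects-by-tasks scores with NaN marking missing entries.

    ``sign_convention`` optionally tags each task ``"higher_better"`` or
    ``"lower_better"`` (reaction times, error counts); it is used only to
    anchor the sign of the extracted component.
    """

    scores: pd.DataFrame
    sign_convention: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scores = self.scores.astype(float).copy()
        for task, tag in self.sign_convention.items():
            if task not in self.scores.columns:
                raise ValueError(f"sign convention names unknown task {task!r}")
            if tag not in ("higher_better", "lower_better"):
                raise ValueError(f"bad sign tag {tag!r} for task {task!r}")

    @property
    def observed(self) -> np.ndarray:
        return ~self.scores.isna().to_numpy()

    @property
    def task_names(self) -> list[str]:
        return list(self.scores.columns)

    @property
    def n_subjects(self) -> int:
        return self.scores.shape[0]


def exclude_by_missingness(
    matrix: CognitiveMatrix, max_missing: int = 7
) -> tuple[CognitiveMatrix, list]:
    """Drop subjects missing strictly more than ``max_missing`` tasks.

    With the default cutoff of 7 on a 10-task battery, a subject missing
    exactly 7 tasks is retained and one missing 8 is dropped.
    Returns the filtered matrix and the dropped subject ids.
    """
    n_tasks = matrix.scores.shape[1]
    if max_missing >= n_tasks:
        raise ValueError("max_missing must be smaller than the number of tasks")
    n_missing = matrix.scores.isna().sum(axis=1)
    keep = n_missing <= max_missing
    if not keep.any():
        raise ValueError("all subjects exceed the missingness cutoff")
    dropped = list(matrix.scores.index[~keep])
    return replace(matrix, scores=matrix.scores.loc[keep]), dropped


@dataclass(frozen=True)
class ImputationResult:
    matrix: CognitiveMatrix
    rank: int
    n_iter: int
    converged: bool


def _truncated_svd(X: np.ndarray, rank: int) -> np.ndarray:
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    return U[:, :rank] @ (s[:rank, None] * Vt[:rank])


def lowrank_impute(
    matrix: CognitiveMatrix,
    rank: int = 1,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> ImputationResult:
    """Impute missing entries by alternating truncated-SVD projection.

    Missing cells are initialised at column means, then the matrix is
    repeatedly projected onto the best rank-``rank`` approximation with
    observed entries restored after each projection, until the RMS change
    of the imputed entries drops below ``tol`` (relative to the RMS of
    the observed scores) or ``max_iter`` sweeps elapse.  Observed entries
    are preserved exactly in the output.
    """
    X = matrix.scores.to_numpy(dtype=float)
    obs = ~np.isnan(X)
    n, p = X.shape
    if rank < 1 or rank > min(n, p):
        raise ValueError(f"rank must lie in [1, {min(n, p)}]")
    if not obs.any(axis=0).all():
        raise ValueError("every task needs at least one observed score")
    if not obs.any(axis=1).all():
        raise ValueError("every subject needs at least one observed score")
    if obs.all():
        return ImputationResult(matrix, rank, 0, True)
    col_means = np.nanmean(X, axis=0)
    filled = np.where(obs, X, col_means[None, :])
    scale = float(np.sqrt(np.mean(X[obs] ** 2))) or 1.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        approx = _truncated_svd(filled, rank)
        new = np.where(obs, X, approx)
        delta = np.sqrt(np.mean((new[~obs] - filled[~obs]) ** 2))
        filled = new
        if delta < tol * scale:
            converged = True
            break
    out = matrix.scores.copy()
    out.iloc[:, :] = filled
    return ImputationResult(replace(matrix, scores=out), rank, it, converged)


def choose_rank(
    matrix: CognitiveMatrix,
    ranks: range | list[int] = range(1, 6),
    holdout_fraction: float = 0.1,
    seed: int = 0,
    max_iter: int = 200,
) -> int:
    """Pick the completion rank by cross-validated masked RMSE.

    A random ``holdout_fraction`` of the observed entries is hidden, each
    candidate rank imputes them, and the rank with the lowest RMSE on the
    held-out cells wins (ties to the smaller rank).
    """
    X = matrix.scores.to_numpy(dtype=float)
    obs = ~np.isnan(X)
    rng = np.random.default_rng(seed)
    cand = np.argwhere(obs)
    n_hold = max(1, int(round(holdout_fraction * cand.shape[0])))
    hold = cand[rng.choice(cand.shape[0], size=n_hold, replace=False)]
    masked = X.copy()
    masked[hold[:, 0], hold[:, 1]] = np.nan
    masked_cm = replace(matrix, scores=pd.DataFrame(masked, index=matrix.scores.index, columns=matrix.scores.columns))
    best_rank, best_rmse = None, np.inf
    for r in ranks:
        if r > min(X.shape):
            continue
        res = lowrank_impute(masked_cm, rank=r, max_iter=max_iter)
        pred = res.matrix.scores.to_numpy()[hold[:, 0], hold[:, 1]]
        truth = X[hold[:, 0], hold[:, 1]]
        rmse = float(np.sqrt(np.mean((pred - truth) ** 2)))
        if rmse < best_rmse - 1e-12:
            best_rank, best_rmse = r, rmse
    return best_rank


@dataclass(frozen=True)
class GFactorResult:
    """First unrotated principal component of the battery.

    ``g`` is z-normalised (mean 0, SD 1); ``loadings`` are the
    correlations of each z-scored task with g; ``prop_var`` is the
    fraction of total variance carried by the first component.
    """

    g: pd.Series
    loadings: pd.Series
    prop_var: float


def extract_g(matrix: CognitiveMatrix, anchor_task: str | None = None) -> GFactorResult:
    """Extract g as the first unrotated principal component.

    Task columns are z-scored (correlation-matrix PCA, since tasks sit on
    incommensurate scales) and the first right singular vector defines
    the component.  The component sign is anchored so that
    ``anchor_task`` loads positively; by default the anchor is the
    ``higher_better``-tagged task with the largest absolute loading, or
    simply the largest-|loading| task when no sign conventions are given.
    """
    X = matrix.scores.to_numpy(dtype=float)
    n, p = X.shape
    if p < 2 or n < 3:
        raise ValueError("g extraction needs at least 2 tasks and 3 subjects")
    if np.isnan(X).any():
        raise ValueError("matrix contains missing values; impute first")
    sd = X.std(axis=0, ddof=1)
    dead = sd <= 1e-12 * np.maximum(1.0, np.abs(X).max(axis=0))
    if np.any(dead):
        task = matrix.task_names[int(np.argmax(dead))]
        raise ValueError(f"task {task!r} has zero variance")
    Z = (X - X.mean(axis=0)) / sd
    _, s, Vt = np.linalg.svd(Z, full_matrices=False)
    score = Z @ Vt[0]
    g = (score - score.mean()) / score.std(ddof=1)
    loadings = Z.T @ g / (n - 1)  # correlation of each z-scored task with g
    prop_var = float(s[0] ** 2 / np.sum(s**2))
    sign = _anchor_sign(matrix, loadings, anchor_task)
    g, loadings = sign * g, sign * loadings
    return GFactorResult(
        g=pd.Series(g, index=matrix.scores.index, name="g"),
        loadings=pd.Series(loadings, index=matrix.task_names, name="loading"),
        prop_var=prop_var,
    )


def _anchor_sign(
    matrix: CognitiveMatrix, loadings: np.ndarray, anchor_task: str | None
) -> float:
    names = matrix.task_names
    if anchor_task is None:
        positive = [
            t for t in names if matrix.sign_convention.get(t) == "higher_better"
        ]
        pool = positive if positive else names
        idx = max(pool, key=lambda t: abs(loadings[names.index(t)]))
        anchor_task = idx
    elif anchor_task not in names:
        raise ValueError(f"anchor task {anchor_task!r} not in battery")
    val = loadings[names.index(anchor_task)]
    return -1.0 if val < 0 else 1.0
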