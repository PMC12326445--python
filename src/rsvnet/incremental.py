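"""Sequential residualisation and incremental-variance decomposition.

To quantify the unique variance a network measure explains in an outcome
(g) beyond more conventional predictors, the predictor matrix is ordered
by convention priority (covariates, then mean edge weight, then common
graph measures, then the focal measure) and passed through classical
Gram-Schmidt orthogonalisation: each column is residualised on all
preceding columns, unit-normalised, then every column is z-normalised.
Regressing g on the orthogonalised design decomposes the joint R² into
per-predictor increments — the focal measure's increment is the headline
"incremental validity" statistic.  Order matters by construction: each
predictor is credited only with variance unexplained by its predecessors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests


class CollinearityError(ValueError):
    """A predictor column is (numerically) in the span of its predecessors."""


#: Residual-norm fraction below which a column counts as collinear.
COLLINEARITY_RTOL = 1e-12


def gram_schmidt(X: np.ndarray, column_names: list[str] | None = None) -> np.ndarray:
    """Classical Gram-Schmidt on a centred data matrix.

    Columns are processed left to right: column k is stripped of its
    projections on columns 1..k-1, unit-normalised, and finally all
    columns are z-normalised (mean 0, SD 1).  Column k of the output
    therefore spans exactly the information in column k of ``X`` that is
    orthogonal to everything before it.

    Raises
    ------
    CollinearityError
        If a column's residual norm falls below ``COLLINEARITY_RTOL``
        times its original norm.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D matrix")
    n, p = X.shape
    if p > n:
        raise ValueError(f"more predictors ({p}) than observations ({n})")
    names = column_names if column_names is not None else [f"x{k + 1}" for k in range(p)]
    col_means = X.mean(axis=0)
    if np.any(np.abs(col_means) > 1e-8 * (1.0 + np.abs(X).max(axis=0))):
        raise ValueError("columns must be centred before orthogonalisation")
    U = np.empty_like(X)
    for i in range(p):
        u = X[:, i].copy()
        orig_norm = np.linalg.norm(u)
        if orig_norm == 0:
            raise CollinearityError(f"column {names[i]!r} is identically zero")
        for j in range(i):
            u -= (u @ U[:, j]) * U[:, j]
        norm = np.linalg.norm(u)
        if norm < COLLINEARITY_RTOL * orig_norm:
            raise CollinearityError(
                f"column {names[i]!r} is collinear with preceding columns "
                f"(residual norm ratio {norm / orig_norm:.2e})"
            )
        U[:, i] = u / norm
    # z-normalisation: columns are centred already, rescale to unit SD
    U = U / U.std(axis=0, ddof=1)
    return U


@dataclass
class PredictorBlock:
    """Ordered predictor matrix with per-column model-stage labels.

    ``order_spec`` maps each column to the progressive model it enters
    (e.g. ``"covariates"``, ``"mean_edge_weight"``, ``"graph_measures"``,
    ``"focal"``); columns must already be sorted by convention priority.
    """

    X: pd.DataFrame
    order_spec: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = self.X.astype(float).copy()
        sd = self.X.std(ddof=1)
        dead = list(sd.index[sd == 0])
        if dead:
            raise ValueError(f"zero-variance predictor columns: {dead}")
        for col in self.order_spec:
            if col not in self.X.columns:
                raise ValueError(f"order_spec names unknown column {col!r}")


@dataclass(frozen=True)
class IncrementalFit:
    """Per-predictor incremental contributions to g."""

    U: pd.DataFrame
    betas: pd.Series
    incremental_r2: pd.Series
    p_values: pd.Series
    p_fdr: pd.Series
    model_labels: pd.Series
    r2_total: float
    focal: str | None

    @property
    def focal_increment(self) -> float:
        if self.focal is None:
            raise ValueError("no focal predictor was declared")
        return float(self.incremental_r2[self.focal])


def progressive_models(
    g: pd.Series | np.ndarray,
    block: PredictorBlock,
    focal: str | None = None,
) -> IncrementalFit:
    """Fit g on sequentially residualised predictors.

    The outcome and the orthogonalised columns are z-scored, so each
    coefficient is a standardised beta, each squared beta is that
    predictor's incremental R², and the increments sum to the joint
    OLS R² on the original block.  p-values come from the t-statistics
    of the joint fit (equivalent, under orthogonality, to the
    1-df sequential F-tests).
    """
    gv = np.asarray(g, dtype=float)
    X = block.X
    if gv.shape[0] != X.shape[0]:
        raise ValueError(
            f"outcome has {gv.shape[0]} rows but predictors have {X.shape[0]}"
        )
    if focal is not None and focal not in X.columns:
        raise ValueError(f"focal column {focal!r} not in predictor block")
    names = list(X.columns)
    Xc = X.to_numpy() - X.to_numpy().mean(axis=0)
    U = gram_schmidt(Xc, names)
    gz = (gv - gv.mean()) / gv.std(ddof=1)
    fit = sm.OLS(gz, sm.add_constant(U)).fit()
    betas = pd.Series(fit.params[1:], index=names)
    pvals = pd.Series(fit.pvalues[1:], index=names)
    incr = betas**2
    idx = pd.Index(names)
    return IncrementalFit(
        U=pd.DataFrame(U, index=X.index, columns=names),
        betas=betas,
        incremental_r2=pd.Series(incr, index=idx, name="incremental_r2"),
        p_values=pvals,
        p_fdr=pd.Series(fdr_adjust(pvals.to_numpy()), index=idx),
        model_labels=pd.Series(
            [block.order_spec.get(c, "") for c in names], index=idx
        ),
        r2_total=float(fit.rsquared),
        focal=focal,
    )


def fdr_adjust(p: np.ndarray, method: str = "benjamini_hochberg") -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    if method != "benjamini_hochberg":
        raise ValueError(f"unknown FDR method {method!r}")
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def covariate_design(covariates: pd.DataFrame) -> pd.DataFrame:
    """Dummy-code categoricals and centre every column.

    Column order is preserved from the input frame; categorical columns
    expand into reference-coded dummies in category order.  Because
    Gram-Schmidt is order-dependent, callers should pass covariates in
    their conventional priority order (age, sex, site, ...).
    """
    out = {}
    for col in covariates.columns:
        series = covariates[col]
        if series.dtype.kind in "biufc":
            out[col] = series.astype(float)
        else:
            dummies = pd.get_dummies(series, prefix=col, drop_first=True, dtype=float)
            for dcol in dummies.columns:
                out[dcol] = dummies[dcol]
    design = pd.DataFrame(out, index=covariates.index)
    return design - design.mean()


def association_scan(
    measures: pd.DataFrame,
    g: pd.Series | np.ndarray,
    covariates: pd.DataFrame,
    fdr_q: float = 0.05,
) -> pd.DataFrame:
    """Covariate-adjusted association of each measure with g.

    Each measure column and g are residualised on the (dummy-coded,
    centred) covariates; the standardised beta is the correlation of the
    two residual vectors, with its OLS p-value, and BH-adjusted p-values
    across the scanned family.  Measures with zero residual variance are
    skipped with a warning.
    """
    gv = np.asarray(g, dtype=float)
    if gv.shape[0] != measures.shape[0] or covariates.shape[0] != measures.shape[0]:
        raise ValueError("measures, g and covariates must be row-aligned")
    C = sm.add_constant(covariate_design(covariates).to_numpy())
    resid_g = sm.OLS(gv, C).fit().resid
    rows = {}
    for col in measures.columns:
        m = measures[col].to_numpy(dtype=float)
        resid_m = sm.OLS(m, C).fit().resid
        if resid_m.std(ddof=1) == 0:
            warnings.warn(
                f"measure {col!r} has zero residual variance after covariate "
                "removal; skipped",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        z_m = (resid_m - resid_m.mean()) / resid_m.std(ddof=1)
        z_g = (resid_g - resid_g.mean()) / resid_g.std(ddof=1)
        fit = sm.OLS(z_g, sm.add_constant(z_m)).fit()
        rows[col] = {
            "beta_standardised": float(fit.params[1]),
            "p": float(fit.pvalues[1]),
        }
    table = pd.DataFrame(rows).T
    if table.empty:
        raise ValueError("no measures survived the scan")
    table["p_fdr"] = fdr_adjust(table["p"].to_numpy())
    table["significant"] = table["p_fdr"] < fdr_q
    return table
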