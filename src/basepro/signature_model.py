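"""Weighted gene-signature definition from aberration-status regressions.

For every gene i, expression (log2 scale) is regressed on the binary event
indicators, either jointly (multivariate model: one OLS fit per gene on all
events, capturing co-occurrence and mutual exclusivity between events) or
one event at a time (univariate model).  The per-(gene, event) coefficient
beta and two-sided p-value are then turned into nonnegative weights:

    raw_i = -log10(p_i),  capped at 10
    beta_i > 0  ->  w+_i = raw_i, w-_i = 0
    beta_i < 0  ->  w-_i = raw_i, w+_i = 0

and both vectors are divided by the range (max - min) over their union, so
weights lie in [0, 1] with the most significant gene at 1.  The cap of 10
with base-10 logs means every p <= 1e-10 saturates at the maximum weight.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("basepro.signatures")

P_FLOOR = 1e-300  # avoid log(0) for p-values below machine tiny


class CollinearityError(ValueError):
    """The event design matrix is rank deficient."""


@dataclass
class RegressionFitTable:
    """Per-(gene, event) OLS coefficients and p-values, plus intercepts."""

    beta: pd.DataFrame  # genes x events
    pvalue: pd.DataFrame  # genes x events
    intercept: pd.Series  # per gene
    dof: int
    n_samples: int


@dataclass
class SignatureWeightSet:
    """Sign-split, range-normalised weights for one event's signature."""

    name: str
    w_plus: pd.Series  # gene-indexed, in [0, 1]
    w_minus: pd.Series

    def __post_init__(self) -> None:
        if ((self.w_plus != 0) & (self.w_minus != 0)).any():
            raise ValueError(f"{self.name}: a gene has both w+ and w- nonzero")

    @property
    def genes(self) -> pd.Index:
        return self.w_plus.index


def _ols_by_gene(Y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Vectorised OLS of every row of Y (genes x samples) on X (samples x k).

    Returns (coefficients k x genes, p-values, intercept handling is the
    caller's concern via X's first column).
    """
    n, k = X.shape
    dof = n - k
    if dof < 2:
        raise ValueError(f"need at least {k + 2} samples for {k - 1} events, got {n}")
    xtx = X.T @ X
    xtx_inv = np.linalg.inv(xtx)
    B = xtx_inv @ (X.T @ Y.T)  # k x genes
    resid = Y.T - X @ B
    sigma2 = np.einsum("ij,ij->j", resid, resid) / dof
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))  # k x genes
    with np.errstate(divide="ignore", invalid="ignore"):
        t = B / se
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    return B, p, se, dof


def _check_design(X: pd.DataFrame, drop_collinear: bool) -> pd.DataFrame:
    """Validate the event design: no zero-variance columns, full rank."""
    const = X.columns[X.nunique() <= 1]
    if len(const):
        raise ValueError(f"zero-variance event column(s): {list(const)}")
    design = np.column_stack([np.ones(len(X)), X.to_numpy(float)])
    rank = np.linalg.matrix_rank(design)
    if rank == design.shape[1]:
        return X
    # identify a collinear set from the QR factor's collapsed pivots
    _, r = np.linalg.qr(design)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(design.shape) * np.finfo(float).eps
    # columns whose pivot magnitude collapses are dependent on earlier ones
    dependent = [X.columns[j - 1] for j in range(1, design.shape[1]) if diag[j] <= tol]
    if not dependent:  # fallback: report all columns
        dependent = list(X.columns)
    if drop_collinear:
        logger.warning("dropping collinear event column(s): %s", dependent)
        return _check_design(X.drop(columns=dependent), drop_collinear=False)
    raise CollinearityError(
        f"event design is rank deficient; collinear column(s): {dependent} "
        "(pass drop_collinear=True to drop automatically)"
    )


def fit_multivariate(
    expr: pd.DataFrame, aberration_matrix: pd.DataFrame, drop_collinear: bool = False
) -> RegressionFitTable:
    """Joint OLS of each gene's expression on all event indicators.

    ``expr`` is genes x samples on the log2 scale; ``aberration_matrix`` is
    samples x events (0/1).  Genes with zero expression variance get beta=0,
    p=1 for every event.  A rank-deficient design raises
    :class:`CollinearityError` naming the collinear columns unless
    ``drop_collinear`` is set.
    """
    ab = aberration_matrix.loc[expr.columns]
    ab = _check_design(ab, drop_collinear)
    X = np.column_stack([np.ones(ab.shape[0]), ab.to_numpy(float)])
    Y = expr.to_numpy(float)
    B, p, _, dof = _ols_by_gene(Y, X)

    beta = pd.DataFrame(B[1:].T, index=expr.index, columns=ab.columns)
    pval = pd.DataFrame(p[1:].T, index=expr.index, columns=ab.columns)
    flat = np.ptp(Y, axis=1) == 0
    if flat.any():
        beta.loc[flat] = 0.0
        pval.loc[flat] = 1.0
        logger.info("%d constant gene(s): beta=0, p=1", int(flat.sum()))
    pval = pval.fillna(1.0)
    return RegressionFitTable(
        beta=beta,
        pvalue=pval,
        intercept=pd.Series(B[0], index=expr.index),
        dof=dof,
        n_samples=expr.shape[1],
    )


def fit_univariate(expr: pd.DataFrame, event_indicator: pd.Series) -> RegressionFitTable:
    """OLS of each gene on a single event indicator.

    Equivalent to a two-sample pooled-variance t-test of carriers vs
    non-carriers for each gene.
    """
    name = event_indicator.name or "event"
    return fit_multivariate(expr, event_indicator.to_frame(name))


def derive_weights(
    fit_table: RegressionFitTable,
    cap: float = 10.0,
    log_base: float = 10.0,
) -> dict[str, SignatureWeightSet]:
    """Turn a regression fit into one sign-split weight set per event.

    Raw weights are -log_b(p), capped at ``cap``, assigned to w+ or w- by
    the coefficient sign, then divided by the range over the union of both
    capped vectors.  If every p-value is 1 the weights are all zero (logged).
    """
    if cap <= 0 or log_base <= 1:
        raise ValueError("cap must be positive and log_base > 1")
    out: dict[str, SignatureWeightSet] = {}
    for event in fit_table.beta.columns:
        beta = fit_table.beta[event].to_numpy()
        p = np.clip(fit_table.pvalue[event].to_numpy(), P_FLOOR, 1.0)
        raw = np.minimum(-np.log(p) / np.log(log_base), cap)
        w_plus = np.where(beta > 0, raw, 0.0)
        w_minus = np.where(beta < 0, raw, 0.0)
        rng_union = max(w_plus.max(initial=0.0), w_minus.max(initial=0.0)) - min(
            w_plus.min(initial=0.0), w_minus.min(initial=0.0)
        )
        if rng_union == 0:
            logger.warning("%s: all p-values are 1; weights all zero", event)
        else:
            w_plus = w_plus / rng_union
            w_minus = w_minus / rng_union
        out[event] = SignatureWeightSet(
            name=event,
            w_plus=pd.Series(w_plus, index=fit_table.beta.index),
            w_minus=pd.Series(w_minus, index=fit_table.beta.index),
        )
    return out
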