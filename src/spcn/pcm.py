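"""Rank transform, (partial) correlation matrices, and their significance.

The partial correlation matrix is obtained by inverting the correlation
matrix, normalizing it row- and column-wise so the diagonal is one, and
negating the off-diagonal: ``P_ij = -W_ij / sqrt(W_ii * W_jj)`` with
``W = C^-1``. Each entry is tested with a Fisher z statistic whose degrees
of freedom are reduced by the number of control variables, and p-values are
corrected by Benjamini-Hochberg.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from spcn.data_io import SignalMatrix

logger = logging.getLogger(__name__)

#: Default constant subtracted (together with the control count) from the
#: sample size in the Fisher-z variance: z = atanh(r) * sqrt(n - k - offset).
DEFAULT_DF_OFFSET = 3

_SYMMETRY_TOL = 1e-12


@dataclass
class SymmetricAssociationMatrix:
    """A p x p symmetric association matrix with unit diagonal.

    ``kind`` is ``"correlation"`` or ``"partial_correlation"``; ``n_controls``
    is 0 for a correlation matrix and p - 2 for a full partial correlation
    matrix (every remaining variable is controlled for).
    """

    values: np.ndarray
    kind: str
    n_samples: int
    n_controls: int
    variable_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        p = self.values.shape[0]
        if self.values.shape != (p, p):
            raise ValueError("association matrix must be square")
        if self.kind not in ("correlation", "partial_correlation"):
            raise ValueError(f"unknown kind '{self.kind}'")
        if np.max(np.abs(self.values - self.values.T)) > _SYMMETRY_TOL:
            raise ValueError("matrix is not symmetric")
        if np.max(np.abs(np.diag(self.values) - 1.0)) > _SYMMETRY_TOL:
            raise ValueError("diagonal must be 1")
        if np.any(np.abs(self.values) > 1 + 1e-9):
            raise ValueError("entries must lie in [-1, 1]")

    @property
    def p(self) -> int:
        return self.values.shape[0]


@dataclass
class SignificanceMatrices:
    """Paired p-value and q-value matrices for one association matrix."""

    pvalues: np.ndarray
    qvalues: np.ndarray
    n_tests: int

    def __post_init__(self) -> None:
        self.pvalues = np.asarray(self.pvalues, dtype=float)
        self.qvalues = np.asarray(self.qvalues, dtype=float)
        if self.pvalues.shape != self.qvalues.shape:
            raise ValueError("p and q matrices must have the same shape")


def rank_transform(X: SignalMatrix) -> SignalMatrix:
    """Replace each column independently by its ranks 1..n (midranks for ties).

    Strictly monotone transforms of a column leave its ranks unchanged, which
    makes every downstream computation invariant to them.
    """
    if X.scale_tag == "rank":
        raise ValueError("matrix is already rank-scale")
    spans = np.ptp(X.values, axis=0)
    if np.any(spans == 0):
        const = [X.variable_names[j] for j in np.flatnonzero(spans == 0)]
        raise ValueError(f"constant columns cannot be ranked: {const}")
    ranked = stats.rankdata(X.values, axis=0, method="average")
    return SignalMatrix(ranked, X.sample_ids, X.variable_names, scale_tag="rank")


def correlation_matrix(X: SignalMatrix) -> SymmetricAssociationMatrix:
    """Pearson correlation matrix of the columns of ``X``.

    Applied to rank-scale data this is the Spearman correlation of the
    original values.
    """
    if X.n_samples < 3:
        raise ValueError("need at least 3 samples for a correlation matrix")
    if np.any(np.ptp(X.values, axis=0) == 0):
        raise ValueError("constant columns have undefined correlation")
    C = np.corrcoef(X.values, rowvar=False)
    if not np.all(np.isfinite(C)):
        raise ValueError("non-finite correlation entries")
    C = np.clip((C + C.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    return SymmetricAssociationMatrix(
        C, kind="correlation", n_samples=X.n_samples, n_controls=0,
        variable_names=list(X.variable_names),
    )


def partial_correlation_matrix(
    C: SymmetricAssociationMatrix, max_condition: float = 1e12
) -> SymmetricAssociationMatrix:
    """Full-control partial correlations from the inverse correlation matrix."""
    if C.kind != "correlation":
        raise ValueError("input must be a correlation matrix")
    cond = np.linalg.cond(C.values)
    logger.debug("correlation matrix condition number: %.3g", cond)
    if not np.isfinite(cond) or cond > max_condition:
        raise np.linalg.LinAlgError(
            f"correlation matrix is singular or near-singular (cond={cond:.3g}); "
            "remove collinear variables"
        )
    omega = np.linalg.inv(C.values)
    d = np.sqrt(np.diag(omega))
    P = -omega / np.outer(d, d)
    P = (P + P.T) / 2.0
    np.fill_diagonal(P, 1.0)
    P = np.clip(P, -1.0, 1.0)
    return SymmetricAssociationMatrix(
        P,
        kind="partial_correlation",
        n_samples=C.n_samples,
        n_controls=max(C.p - 2, 0),
        variable_names=C.variable_names,
    )


def bh_adjust(pvals: np.ndarray, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    ``q_(i) = min_{j >= i} m * p_(j) / j`` over the ascending order statistics,
    clipped at 1 and returned in the original order.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be 1-D")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("m must be at least the number of p-values")
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, p.size + 1)
    scaled = p[order] * m / ranks
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def fisher_z_significance(
    P: SymmetricAssociationMatrix, df_offset: int = DEFAULT_DF_OFFSET
) -> SignificanceMatrices:
    """Fisher-z p-values and BH q-values for every off-diagonal entry.

    ``z = atanh(r) * sqrt(n - k - df_offset)`` with ``k`` control variables;
    z is referred to the standard normal (two-sided). All p(p-1)/2
    upper-triangle tests enter the BH correction.
    """
    n, k, p = P.n_samples, P.n_controls, P.p
    df = n - k - df_offset
    if df < 1:
        raise ValueError(f"non-positive degrees of freedom: n={n}, controls={k}")
    iu = np.triu_indices(p, k=1)
    r = P.values[iu]
    degenerate = np.abs(r) >= 1.0
    if np.any(degenerate):
        warnings.warn("|partial correlation| = 1 encountered; p-value set to 0")
    with np.errstate(divide="ignore"):
        z = np.arctanh(np.clip(r, -1.0, 1.0)) * np.sqrt(df)
    pv = np.where(degenerate, 0.0, 2.0 * stats.norm.sf(np.abs(z)))
    qv = bh_adjust(pv)
    pmat = np.zeros((p, p))
    qmat = np.zeros((p, p))
    pmat[iu], qmat[iu] = pv, qv
    pmat += pmat.T
    qmat += qmat.T
    np.fill_diagonal(pmat, 0.0)
    np.fill_diagonal(qmat, 0.0)
    return SignificanceMatrices(pmat, qmat, n_tests=p * (p - 1) // 2)
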