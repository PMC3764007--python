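"""Cross-validated sparsification of partial correlation matrices.

A sparse network cannot be obtained by a significance cutoff alone: with
very large sample sizes essentially every entry of the partial correlation
matrix is significant. Instead, for each cross-validation fold a q-value
threshold sweep is performed on the training portion; at each threshold each
variable is predicted by ordinary least squares from its co-variables only,
and the mean squared test error is recorded. The selected threshold is the
lowest (sparsest) one whose error stays within ``tolerance`` (default 10%)
of the min-max error range. Edges kept in at least ``min_support`` of the
``n_folds`` per-fold sparse matrices form the mask applied to the full-data
partial correlation matrix. Optionally the degree of one special node
(e.g. "mRNA") is completed up to a target using lower-significance edges.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from spcn.data_io import Network, SignalMatrix
from spcn.pcm import (
    DEFAULT_DF_OFFSET,
    SignificanceMatrices,
    SymmetricAssociationMatrix,
    correlation_matrix,
    fisher_z_significance,
    partial_correlation_matrix,
    rank_transform,
)

logger = logging.getLogger(__name__)

PROV_NONE = ""
PROV_MASKED = "masked"
PROV_COMPLETED = "mrna_completed"


@dataclass
class CvErrorCurve:
    """Mean test prediction error along a decreasing q-threshold grid."""

    thresholds: np.ndarray
    errors: np.ndarray

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.errors = np.asarray(self.errors, dtype=float)
        if self.thresholds.size == 0:
            raise ValueError("empty threshold grid")
        if self.thresholds.size != self.errors.size:
            raise ValueError("thresholds and errors must align")
        if np.any(np.diff(self.thresholds) > 0):
            raise ValueError("thresholds must be decreasing")
        if not np.all(np.isfinite(self.errors)):
            raise ValueError("non-finite prediction errors")

    @property
    def e_min(self) -> float:
        return float(np.min(self.errors))

    @property
    def e_max(self) -> float:
        return float(np.max(self.errors))


@dataclass
class EdgeMask:
    """Per-edge cross-validation support and the resulting boolean mask."""

    keep: np.ndarray
    support: np.ndarray
    provenance: np.ndarray
    n_folds: int
    min_support: int

    def __post_init__(self) -> None:
        self.keep = np.asarray(self.keep, dtype=bool)
        self.support = np.asarray(self.support, dtype=int)
        p = self.keep.shape[0]
        if self.keep.shape != (p, p) or self.support.shape != (p, p):
            raise ValueError("mask matrices must be square and aligned")
        if np.any(self.keep != self.keep.T) or np.any(self.support != self.support.T):
            raise ValueError("mask must be symmetric")
        if np.any(np.diag(self.keep)):
            raise ValueError("mask diagonal must be false")

    def degree(self, i: int) -> int:
        return int(self.keep[i].sum())


@dataclass
class SPCN:
    """A sparse partial correlation network.

    ``weights`` is the full-data partial correlation matrix with masked-out
    entries set to zero; ``qvalues`` the full-data q-values; provenance
    distinguishes mask-voted edges from special-node completions.
    """

    weights: np.ndarray
    qvalues: np.ndarray
    mask: EdgeMask
    variable_names: list[str]
    fold_thresholds: list[float]
    curves: list[CvErrorCurve]
    seed: int
    config: dict = field(default_factory=dict)

    @property
    def p(self) -> int:
        return self.weights.shape[0]

    def edge_indices(self) -> list[tuple[int, int]]:
        iu = np.triu_indices(self.p, k=1)
        return [(int(i), int(j)) for i, j in zip(*iu) if self.mask.keep[i, j]]

    def to_network(self) -> Network:
        net = Network(variables=list(self.variable_names), edges={})
        for i, j in self.edge_indices():
            net.add_edge(
                self.variable_names[i],
                self.variable_names[j],
                weight=float(self.weights[i, j]),
                q_value=float(self.qvalues[i, j]),
                support_count=int(self.mask.support[i, j]),
                provenance=str(self.mask.provenance[i, j]),
            )
        return net


def fold_split(n_samples: int, n_folds: int, seed: int) -> np.ndarray:
    """Assign each sample a fold label 0..n_folds-1 (near-equal, disjoint)."""
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    if n_samples < n_folds:
        raise ValueError("more folds than samples")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_samples)
    labels = np.empty(n_samples, dtype=int)
    for f, chunk in enumerate(np.array_split(perm, n_folds)):
        labels[chunk] = f
    return labels


def _augmented_gram(X: np.ndarray) -> np.ndarray:
    """Gram matrix of [X | 1]; sufficient statistics for every OLS subproblem."""
    n = X.shape[0]
    Xa = np.hstack([X, np.ones((n, 1))])
    return Xa.T @ Xa


def _ols_test_error(
    A_train: np.ndarray, A_test: np.ndarray, n_test: int, target: int, predictors: np.ndarray
) -> float:
    """Mean squared test error of OLS(target ~ predictors + intercept).

    Solved from the augmented Gram matrices only; rank-deficient designs fall
    back to the minimum-norm least-squares solution (equivalent to dropping
    redundant columns).
    """
    p = A_train.shape[0] - 1
    cols = np.append(predictors, p)  # intercept column is last
    G = A_train[np.ix_(cols, cols)]
    g = A_train[cols, target]
    try:
        beta = np.linalg.solve(G, g)
        if not np.all(np.isfinite(beta)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        warnings.warn("singular co-variable design; dropping redundant directions")
        beta = np.linalg.lstsq(G, g, rcond=None)[0]
    Gt = A_test[np.ix_(cols, cols)]
    gt = A_test[cols, target]
    sse = A_test[target, target] - 2.0 * beta @ gt + beta @ Gt @ beta
    return float(max(sse, 0.0) / n_test)


def cv_prediction_error(
    train: SignalMatrix | np.ndarray,
    test: SignalMatrix | np.ndarray,
    sparse_P: SymmetricAssociationMatrix | np.ndarray,
) -> float:
    """Mean over variables of the OLS test error using co-variables only.

    For each variable the predictors are the variables with a nonzero entry
    in its row of ``sparse_P``; a variable with no co-variables gets an
    intercept-only model.
    """
    Xtr = train.values if isinstance(train, SignalMatrix) else np.asarray(train, dtype=float)
    Xte = test.values if isinstance(test, SignalMatrix) else np.asarray(test, dtype=float)
    S = sparse_P.values if isinstance(sparse_P, SymmetricAssociationMatrix) else np.asarray(sparse_P)
    p = Xtr.shape[1]
    if Xte.shape[1] != p or S.shape != (p, p):
        raise ValueError("train/test/sparse matrix shapes do not align")
    keep = S != 0
    np.fill_diagonal(keep, False)
    A_tr = _augmented_gram(Xtr)
    A_te = _augmented_gram(Xte)
    errs = [
        _ols_test_error(A_tr, A_te, Xte.shape[0], i, np.flatnonzero(keep[i])) for i in range(p)
    ]
    return float(np.mean(errs))


def select_threshold(curve: CvErrorCurve, tolerance: float = 0.10) -> float:
    """Lowest threshold whose error is within ``tolerance`` of the error range.

    Returns the smallest t in the grid with
    ``E(t) <= e_min + tolerance * (e_max - e_min)``.
    """
    if not 0 <= tolerance <= 1:
        raise ValueError("tolerance must lie in [0, 1]")
    cutoff = curve.e_min + tolerance * (curve.e_max - curve.e_min)
    ok = np.flatnonzero(curve.errors <= cutoff + 1e-15)
    # thresholds are decreasing, so the last qualifying index is the lowest t
    return float(curve.thresholds[ok[-1]])


def threshold_grid(qvalues_upper: np.ndarray, cap: int = 200) -> np.ndarray:
    """Decreasing grid of candidate q-thresholds.

    Uses the sorted unique observed q-values (every attainable sparsity
    level); above ``cap`` values, a log-spaced subset is snapped to the
    nearest attained values. A sentinel below the minimum is appended so the
    empty network is part of the sweep.
    """
    u = np.unique(np.asarray(qvalues_upper, dtype=float))
    if u.size > cap:
        pos = u[u > 0]
        lo = max(pos.min(), np.finfo(float).tiny)
        grid = np.geomspace(lo, pos.max(), cap)
        idx = np.clip(np.searchsorted(u, grid), 0, u.size - 1)
        u = np.unique(np.concatenate([u[idx], [u[0], u[-1]]]))
    thresholds = u[::-1]
    if thresholds[-1] > 0:
        thresholds = np.append(thresholds, thresholds[-1] / 2.0)
    return thresholds


def _fold_sparse_pattern(
    ranked: np.ndarray,
    train_rows: np.ndarray,
    test_rows: np.ndarray,
    tolerance: float,
    df_offset: int,
    threshold_cap: int,
    names: list[str],
) -> tuple[np.ndarray, float, CvErrorCurve]:
    """One CV fold: train-side PCM + q-sweep; returns (keep, threshold, curve)."""
    Xtr = ranked[train_rows]
    Xte = ranked[test_rows]
    sm_tr = SignalMatrix(Xtr, [str(i) for i in range(Xtr.shape[0])], names, scale_tag="rank")
    C = correlation_matrix(sm_tr)
    P = partial_correlation_matrix(C)
    sig = fisher_z_significance(P, df_offset=df_offset)
    p = P.p
    iu = np.triu_indices(p, k=1)
    thresholds = threshold_grid(sig.qvalues[iu], cap=threshold_cap)

    A_tr = _augmented_gram(Xtr)
    A_te = _augmented_gram(Xte)
    n_test = Xte.shape[0]
    offdiag = ~np.eye(p, dtype=bool)
    cache: dict[tuple[int, tuple[int, ...]], float] = {}
    errors = np.empty(thresholds.size)
    for t_idx, t in enumerate(thresholds):
        keep = (sig.qvalues <= t) & offdiag
        total = 0.0
        for i in range(p):
            preds = tuple(np.flatnonzero(keep[i]))
            key = (i, preds)
            if key not in cache:
                cache[key] = _ols_test_error(A_tr, A_te, n_test, i, np.array(preds, dtype=int))
            total += cache[key]
        errors[t_idx] = total / p
    curve = CvErrorCurve(thresholds, errors)
    t_sel = select_threshold(curve, tolerance)
    keep_sel = (sig.qvalues <= t_sel) & offdiag
    return keep_sel, t_sel, curve


def build_mask(fold_sparse_matrices: list[np.ndarray], min_support: int = 7) -> EdgeMask:
    """Vote per-fold sparse patterns into a mask: keep iff support >= min_support."""
    n_folds = len(fold_sparse_matrices)
    if n_folds == 0:
        raise ValueError("no fold matrices")
    if not 1 <= min_support <= n_folds:
        raise ValueError("min_support must lie in [1, n_folds]")
    stack = np.array([np.asarray(m, dtype=bool) for m in fold_sparse_matrices])
    if any(m.shape != stack[0].shape for m in stack):
        raise ValueError("fold matrices must share a shape")
    support = stack.sum(axis=0).astype(int)
    np.fill_diagonal(support, 0)
    keep = support >= min_support
    provenance = np.where(keep, PROV_MASKED, PROV_NONE).astype("<U14")
    return EdgeMask(keep, support, provenance, n_folds=n_folds, min_support=min_support)


def complete_special_node(
    mask: EdgeMask,
    Q: SignificanceMatrices,
    variable_names: list[str],
    node: str = "mRNA",
    target_degree: int = 4,
) -> EdgeMask:
    """Complete one node's degree up to ``target_degree`` by smallest q-value.

    Added edges are tagged ``mrna_completed`` so mask-voted and completed
    edges stay distinguishable.
    """
    if node not in variable_names:
        raise ValueError(f"special node '{node}' not among variables")
    i = variable_names.index(node)
    keep = mask.keep.copy()
    provenance = mask.provenance.copy()
    deficit = target_degree - int(keep[i].sum())
    if deficit <= 0:
        return EdgeMask(keep, mask.support.copy(), provenance, mask.n_folds, mask.min_support)
    candidates = [j for j in range(len(variable_names)) if j != i and not keep[i, j]]
    candidates.sort(key=lambda j: (Q.qvalues[i, j], variable_names[j]))
    if len(candidates) < deficit:
        warnings.warn(
            f"only {len(candidates)} candidates to complete '{node}' "
            f"(needed {deficit}); completing as far as possible"
        )
    for j in candidates[:deficit]:
        keep[i, j] = keep[j, i] = True
        provenance[i, j] = provenance[j, i] = PROV_COMPLETED
    return EdgeMask(keep, mask.support.copy(), provenance, mask.n_folds, mask.min_support)


def build_spcn(
    X: SignalMatrix,
    n_folds: int = 10,
    min_support: int = 7,
    tolerance: float = 0.10,
    special_node: str | None = None,
    special_degree: int = 4,
    df_offset: int = DEFAULT_DF_OFFSET,
    threshold_cap: int = 200,
    seed: int = 0,
    rank: bool = True,
) -> SPCN:
    """Full pipeline: rank, per-fold sparsification, support vote, completion.

    The rank transform is applied once to the full matrix before fold
    splitting (the transform precedes cross-validation in the pipeline; the
    mild train/test leakage through shared ranks is accepted by design).
    """
    ranked = rank_transform(X) if (rank and X.scale_tag != "rank") else X
    n = ranked.n_samples
    labels = fold_split(n, n_folds, seed)
    keeps: list[np.ndarray] = []
    thresholds: list[float] = []
    curves: list[CvErrorCurve] = []
    for f in range(n_folds):
        test_rows = np.flatnonzero(labels == f)
        train_rows = np.flatnonzero(labels != f)
        keep_f, t_f, curve_f = _fold_sparse_pattern(
            ranked.values, train_rows, test_rows, tolerance, df_offset,
            threshold_cap, list(ranked.variable_names),
        )
        keeps.append(keep_f)
        thresholds.append(t_f)
        curves.append(curve_f)
        logger.debug("fold %d: threshold %.3g, %d edges", f, t_f, keep_f.sum() // 2)
    mask = build_mask(keeps, min_support=min_support)

    C_full = correlation_matrix(ranked)
    P_full = partial_correlation_matrix(C_full)
    sig_full = fisher_z_significance(P_full, df_offset=df_offset)
    if special_node is not None:
        mask = complete_special_node(
            mask, sig_full, list(ranked.variable_names), special_node, special_degree
        )
    weights = np.where(mask.keep, P_full.values, 0.0)
    config = {
        "n_folds": n_folds,
        "min_support": min_support,
        "tolerance": tolerance,
        "special_node": special_node,
        "special_degree": special_degree,
        "df_offset": df_offset,
        "threshold_cap": threshold_cap,
        "rank": rank,
    }
    return SPCN(
        weights=weights,
        qvalues=sig_full.qvalues,
        mask=mask,
        variable_names=list(ranked.variable_names),
        fold_thresholds=thresholds,
        curves=curves,
        seed=seed,
        config=config,
    )
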