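"""Explaining-away effect matrices.

For every pair of variables the difference between the full-control partial
correlation and the marginal correlation is recorded, together with the one
control variable that, on its own, changes the marginal correlation the most
(exhaustive search over single controls only — combinations of controls are
deliberately not explored).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from spcn.data_io import SignalMatrix
from spcn.pcm import correlation_matrix, partial_correlation_matrix, rank_transform


@dataclass
class EffectMatrix:
    """Per-pair marginal vs partial correlations and the top single explainer.

    ``diff = p_full - r`` (signed); ``top_explainer[i, j]`` names the control
    k maximizing ``|r_ij.k - r_ij|`` and ``top_effect`` stores that maximum.
    """

    r: np.ndarray
    p_full: np.ndarray
    diff: np.ndarray
    top_explainer: np.ndarray
    top_effect: np.ndarray
    variable_names: list[str]

    def pair(self, a: str, b: str) -> dict:
        i = self.variable_names.index(a)
        j = self.variable_names.index(b)
        return {
            "r": float(self.r[i, j]),
            "p_full": float(self.p_full[i, j]),
            "diff": float(self.diff[i, j]),
            "top_explainer": str(self.top_explainer[i, j]),
            "top_effect": float(self.top_effect[i, j]),
        }


def single_control_partial(r_xy: float, r_xz: float, r_yz: float) -> float:
    """First-order partial correlation of x and y given a single control z:
    ``(r_xy - r_xz * r_yz) / sqrt((1 - r_xz^2) (1 - r_yz^2))``.
    """
    for v in (r_xy, r_xz, r_yz):
        if not -1.0 <= v <= 1.0:
            raise ValueError(f"correlation {v} outside [-1, 1]")
    if abs(r_xz) >= 1.0 or abs(r_yz) >= 1.0:
        raise ValueError("control is perfectly correlated with a target variable")
    return (r_xy - r_xz * r_yz) / np.sqrt((1.0 - r_xz**2) * (1.0 - r_yz**2))


def effect_matrix(X: SignalMatrix, rank: bool = True) -> EffectMatrix:
    """Compute the explaining-away effect matrix of ``X``.

    Ties in the argmax over controls are broken by variable order (first
    index wins).
    """
    if X.n_variables < 3:
        raise ValueError("need at least 3 variables")
    ranked = rank_transform(X) if (rank and X.scale_tag != "rank") else X
    C = correlation_matrix(ranked)
    P = partial_correlation_matrix(C)
    r = C.values
    p = r.shape[0]

    # r_cond[k, i, j] = partial correlation of (i, j) given the single control k
    rk = r  # rows: correlation of each variable with control k is r[:, k]
    impact = np.full((p, p, p), -np.inf)
    for k in range(p):
        a = rk[:, k]
        denom = np.sqrt(np.outer(1.0 - a**2, 1.0 - a**2))
        with np.errstate(divide="ignore", invalid="ignore"):
            r_cond = (r - np.outer(a, a)) / denom
        delta = np.abs(r_cond - r)
        delta[k, :] = -np.inf
        delta[:, k] = -np.inf
        impact[k] = delta
    top_k = np.argmax(impact, axis=0)  # first maximizer = variable-order tie-break
    top_effect = np.max(impact, axis=0)
    np.fill_diagonal(top_effect, 0.0)
    names = np.array(X.variable_names, dtype=object)
    top_explainer = names[top_k].astype(object)
    for i in range(p):
        top_explainer[i, i] = ""
    return EffectMatrix(
        r=r,
        p_full=P.values,
        diff=P.values - r,
        top_explainer=top_explainer,
        top_effect=top_effect,
        variable_names=list(X.variable_names),
    )


def consensus_effects(matrices: list[EffectMatrix]) -> dict[tuple[str, str], dict]:
    """Merge per-condition effect matrices over the shared variable set.

    For every pair the modal top explainer and its support count across
    conditions are reported, together with the mean signed difference.
    """
    if len(matrices) < 2:
        raise ValueError("need at least 2 effect matrices")
    shared = set(matrices[0].variable_names)
    for em in matrices[1:]:
        shared &= set(em.variable_names)
    shared_sorted = sorted(shared)
    out: dict[tuple[str, str], dict] = {}
    for ai, a in enumerate(shared_sorted):
        for b in shared_sorted[ai + 1:]:
            explainers = []
            diffs = []
            for em in matrices:
                rec = em.pair(a, b)
                explainers.append(rec["top_explainer"])
                diffs.append(rec["diff"])
            (modal, count), = Counter(explainers).most_common(1)
            out[(a, b)] = {
                "modal_explainer": modal,
                "support": count,
                "n_conditions": len(matrices),
                "mean_diff": float(np.mean(diffs)),
            }
    return out
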