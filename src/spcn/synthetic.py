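"""Synthetic data: sparse Gaussian graphical models with known edge sets.

The generator draws a random edge set, places equal-magnitude random-sign
entries on it, and makes the precision matrix strictly diagonally dominant,
which guarantees positive definiteness. Samples may then be pushed through
strictly monotone marginal transforms to obtain non-Gaussian (including
bimodal) marginals with unchanged column ranks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from spcn.data_io import SignalMatrix


@dataclass
class GgmTruth:
    """A known sparse Gaussian graphical model.

    ``edge_set`` lists the index pairs with nonzero off-diagonal precision;
    ``partial_corr_true[i, j] = -precision[i, j] / sqrt(prec_ii * prec_jj)``.
    """

    precision: np.ndarray
    edge_set: list[tuple[int, int]]
    partial_corr_true: np.ndarray

    def __post_init__(self) -> None:
        w = np.linalg.eigvalsh(self.precision)
        if np.min(w) <= 0:
            raise ValueError("precision matrix is not positive definite")
        p = self.precision.shape[0]
        iu = np.triu_indices(p, k=1)
        nz = {(int(i), int(j)) for i, j in zip(*iu) if self.precision[i, j] != 0}
        if nz != {tuple(sorted(e)) for e in self.edge_set}:
            raise ValueError("edge_set does not match the precision support")

    @property
    def p(self) -> int:
        return self.precision.shape[0]

    @property
    def covariance(self) -> np.ndarray:
        cov = np.linalg.inv(self.precision)
        return (cov + cov.T) / 2.0


def _partials_from_precision(omega: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(omega))
    P = -omega / np.outer(d, d)
    np.fill_diagonal(P, 1.0)
    return P


def _sample_edges(
    p: int, n_edges: int, max_degree: int | None, rng: np.random.Generator
) -> list[tuple[int, int]] | None:
    pairs = [(i, j) for i in range(p) for j in range(i + 1, p)]
    if max_degree is None:
        chosen = rng.choice(len(pairs), size=n_edges, replace=False)
        return [pairs[c] for c in chosen]
    order = rng.permutation(len(pairs))
    degree = np.zeros(p, dtype=int)
    edges: list[tuple[int, int]] = []
    for c in order:
        i, j = pairs[c]
        if degree[i] < max_degree and degree[j] < max_degree:
            edges.append((i, j))
            degree[i] += 1
            degree[j] += 1
            if len(edges) == n_edges:
                return edges
    return None  # greedy fill got stuck; caller retries


def random_sparse_precision(
    p: int,
    n_edges: int,
    min_abs_partial: float = 0.1,
    seed: int = 0,
    margin: float = 0.25,
    max_degree: int | None = None,
    max_retries: int = 200,
) -> GgmTruth:
    """Random sparse precision matrix with all edge partials >= a floor.

    Equal magnitudes with random signs on a uniformly sampled edge set;
    the diagonal is the absolute row sum plus ``margin`` (strict diagonal
    dominance => positive definite), which makes every edge's partial
    correlation roughly ``1 / sqrt(deg_i * deg_j)``. Edge sets whose induced
    partial correlations fall below ``min_abs_partial`` (high-degree
    collisions) are resampled up to ``max_retries`` times; passing
    ``max_degree`` bounds node degrees during sampling, which keeps edge
    strengths comparable and well above the floor.
    """
    n_pairs = p * (p - 1) // 2
    if n_edges > n_pairs:
        raise ValueError(f"cannot place {n_edges} edges among {n_pairs} pairs")
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        edges = _sample_edges(p, n_edges, max_degree, rng)
        if edges is None:
            continue
        omega = np.zeros((p, p))
        signs = rng.choice([-1.0, 1.0], size=n_edges)
        for (i, j), s in zip(edges, signs):
            omega[i, j] = omega[j, i] = s
        np.fill_diagonal(omega, np.abs(omega).sum(axis=1) + margin)
        partials = _partials_from_precision(omega)
        if n_edges == 0 or min(abs(partials[i, j]) for i, j in edges) >= min_abs_partial:
            return GgmTruth(omega, sorted(edges), partials)
    raise RuntimeError(
        f"could not achieve |partial| >= {min_abs_partial} with {n_edges} edges "
        f"on {p} variables after {max_retries} attempts"
    )


def sample_ggm(truth: GgmTruth, n: int, seed: int = 0) -> SignalMatrix:
    """Draw n samples from the zero-mean MVN with covariance precision^-1."""
    if n < truth.p + 4:
        raise ValueError(f"need at least p + 4 = {truth.p + 4} samples")
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(truth.covariance)
    X = rng.standard_normal((n, truth.p)) @ L.T
    return SignalMatrix(
        X,
        sample_ids=[f"s{i:06d}" for i in range(n)],
        variable_names=[f"V{j:02d}" for j in range(truth.p)],
        scale_tag="raw",
    )


def _bimodal_quantile(u: np.ndarray, loc: float, scale: float) -> np.ndarray:
    """Quantile function of 0.5 N(-loc, scale) + 0.5 N(loc, scale) via a
    dense strictly-increasing grid (monotone interpolation)."""
    grid = np.linspace(-loc - 8 * scale, loc + 8 * scale, 20001)
    cdf = 0.5 * (stats.norm.cdf(grid, -loc, scale) + stats.norm.cdf(grid, loc, scale))
    return np.interp(u, cdf, grid)


def monotone_distort(X: SignalMatrix, mode: str = "lognormal", seed: int = 0) -> SignalMatrix:
    """Pass every column through a strictly increasing transform.

    ``lognormal`` exponentiates the standardized column; ``bimodal`` maps the
    standardized column through the normal CDF and then through the quantile
    function of a two-component Gaussian mixture (dip-separated modes). Ranks
    are preserved exactly, so the whole rank-based pipeline is unaffected.
    """
    rng = np.random.default_rng(seed)
    out = np.empty_like(X.values)
    for j in range(X.n_variables):
        col = X.values[:, j]
        sd = col.std()
        z = (col - col.mean()) / (sd if sd > 0 else 1.0)
        if mode == "lognormal":
            out[:, j] = np.exp(z)
        elif mode == "bimodal":
            # per-column separation jitter keeps marginals visibly distinct
            loc = 2.0 + 0.5 * rng.random()
            u = stats.norm.cdf(np.clip(z, -8.0, 8.0))
            out[:, j] = _bimodal_quantile(u, loc=loc, scale=0.55)
        else:
            raise ValueError(f"unknown distortion mode '{mode}'")
    return SignalMatrix(out, X.sample_ids, X.variable_names, scale_tag=X.scale_tag)
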