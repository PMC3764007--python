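import numpy as np
import pytest

from spcn.data_io import SignalMatrix
from spcn.synthetic import sample_ggm


@pytest.fixture
def small_matrix() -> SignalMatrix:
    rng = np.random.default_rng(42)
    values = rng.random((30, 4))
    return SignalMatrix(
        values,
        sample_ids=[f"g{i}" for i in range(30)],
        variable_names=["A", "B", "C", "D"],
        scale_tag="raw",
    )


@pytest.fixture
def chain_sample() -> tuple[SignalMatrix, object]:
    """n=4000 draws from a 3-variable chain GGM (edges 0-1 and 1-2)."""
    omega = np.array(
        [
            [1.5, 0.8, 0.0],
            [0.8, 2.0, 0.8],
            [0.0, 0.8, 1.5],
        ]
    )
    from spcn.synthetic import GgmTruth, _partials_from_precision

    truth = GgmTruth(omega, [(0, 1), (1, 2)], _partials_from_precision(omega))
    X = sample_ggm(truth, 4000, seed=7)
    return X, truth


# ---------------------------------------------------------------------------
# independent oracles (deliberately naive implementations)


def bh_brute_force(pvals: np.ndarray, m: int | None = None) -> np.ndarray:
    """Step-up BH by direct evaluation of q_i = min_{j: p_(j) >= p_i} m p_(j)/rank_j."""
    p = np.asarray(pvals, dtype=float)
    if m is None:
        m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q = np.empty_like(p)
    for i in range(p.size):
        cands = [m * ranked[j] / (j + 1) for j in range(p.size) if ranked[j] >= p[i]]
        q[i] = min(1.0, min(cands))
    return q


def residual_partial_correlation(X: np.ndarray, i: int, j: int) -> float:
    """Partial correlation of columns i, j controlling for all others, via
    explicit regression residuals ("keep the residuals")."""
    n, p = X.shape
    others = [k for k in range(p) if k not in (i, j)]
    A = np.column_stack([X[:, others], np.ones(n)])
    ri = X[:, i] - A @ np.linalg.lstsq(A, X[:, i], rcond=None)[0]
    rj = X[:, j] - A @ np.linalg.lstsq(A, X[:, j], rcond=None)[0]
    return float(np.corrcoef(ri, rj)[0, 1])


def first_order_partial(r_xy: float, r_xz: float, r_yz: float) -> float:
    return (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
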