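"""Overlap statistics between ranked lists of variable pairs.

Pairs are ranked by increasing q-value; for every prefix length n the
proportion of pairs common to all lists is compared with its null
expectation: n/N for two lists (hypergeometric null with equal numbers of
white balls and draws) and (n/N)^(L-1) for L lists, with Monte-Carlo
p-values for three or more lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from spcn.pcm import SignificanceMatrices, SymmetricAssociationMatrix

DEFAULT_N_SIMS = 100_000


@dataclass
class RankedPairList:
    """Variable pairs ordered by ascending q-value.

    Ties are broken by descending |partial correlation|, then by the
    lexicographic pair name, so the ordering is deterministic.
    """

    pairs: list[tuple[str, str]]
    N_total: int
    universe: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("pairs must be distinct")
        if len(self.pairs) > self.N_total:
            raise ValueError("more pairs than the pair universe size")

    def top(self, n: int) -> set[tuple[str, str]]:
        return set(self.pairs[:n])


@dataclass
class OverlapResult:
    n_values: np.ndarray
    observed_proportion: np.ndarray
    expected_proportion: np.ndarray
    p_values: np.ndarray
    is_bound: np.ndarray
    method: str
    n_lists: int


def rank_pairs(
    Q: SignificanceMatrices, P: SymmetricAssociationMatrix
) -> RankedPairList:
    """Rank all upper-triangle pairs by (q asc, |partial| desc, name)."""
    names = P.variable_names
    if names is None:
        raise ValueError("association matrix must carry variable names")
    p = P.p
    if Q.qvalues.shape != (p, p):
        raise ValueError("q-value matrix does not align with the association matrix")
    records = []
    for i in range(p):
        for j in range(i + 1, p):
            pair = tuple(sorted((names[i], names[j])))
            records.append((Q.qvalues[i, j], -abs(P.values[i, j]), pair))
    records.sort()
    return RankedPairList(
        pairs=[rec[2] for rec in records],
        N_total=p * (p - 1) // 2,
        universe=frozenset(names),
    )


def expected_two_list(n: int, N: int) -> float:
    """Expected overlap proportion of two random top-n lists: n/N."""
    if not 1 <= n <= N:
        raise ValueError("need 1 <= n <= N")
    return n / N


def hypergeom_pvalue(x: int, n: int, N: int) -> float:
    """P(X >= x) with X ~ Hypergeometric(N, n, n): overlap of two random
    n-subsets of an N-element pair universe."""
    if not 0 <= x <= n <= N:
        raise ValueError("need 0 <= x <= n <= N")
    return float(stats.hypergeom.sf(x - 1, N, n, n))


def _simulate_intersections(
    N: int, n: int, L: int, n_sims: int, rng: np.random.Generator, with_replacement: bool
) -> np.ndarray:
    """Sizes of the intersection of L random n-element lists from N pairs."""
    counts = np.empty(n_sims, dtype=int)
    chunk = max(1, min(n_sims, int(2e7) // max(N * L, 1)))
    done = 0
    while done < n_sims:
        m = min(chunk, n_sims - done)
        member = np.ones((m, N), dtype=bool)
        for _ in range(L):
            if with_replacement:
                draws = rng.integers(0, N, size=(m, n))
                mem = np.zeros((m, N), dtype=bool)
                np.put_along_axis(mem, draws, True, axis=1)
            else:
                u = rng.random((m, N))
                idx = np.argpartition(u, n - 1, axis=1)[:, :n]
                mem = np.zeros((m, N), dtype=bool)
                np.put_along_axis(mem, idx, True, axis=1)
            member &= mem
        counts[done:done + m] = member.sum(axis=1)
        done += m
    return counts


def multi_list_null(
    x: int,
    n: int,
    N: int,
    L: int = 3,
    n_sims: int = DEFAULT_N_SIMS,
    seed: int = 0,
    with_replacement: bool = False,
) -> tuple[float, float, bool]:
    """Null expectation and Monte-Carlo p-value for an L-list overlap of x.

    Returns ``(expected_proportion, p_value, is_bound)``; when no simulated
    intersection reaches x the value 1/n_sims is returned flagged as an
    upper bound. ``with_replacement=True`` draws each list's n pairs i.i.d.
    (duplicates allowed) instead of as a distinct-pair subset.
    """
    if L < 3:
        raise ValueError("use hypergeom_pvalue for two lists")
    if n_sims < 1:
        raise ValueError("n_sims must be positive")
    if not 0 <= x <= n <= N:
        raise ValueError("need 0 <= x <= n <= N")
    expected = (n / N) ** (L - 1)
    if x == 0:
        return expected, 1.0, False
    rng = np.random.default_rng(seed)
    counts = _simulate_intersections(N, n, L, n_sims, rng, with_replacement)
    hits = int(np.sum(counts >= x))
    if hits == 0:
        return expected, 1.0 / n_sims, True
    return expected, hits / n_sims, False


def overlap_curve(
    lists: list[RankedPairList],
    n_sims: int = 10_000,
    seed: int = 0,
    with_replacement: bool = False,
) -> OverlapResult:
    """Observed / expected overlap proportions and p-values for all prefix
    lengths n = 1..len(shortest list).

    For three or more lists the whole curve shares one set of simulated list
    L-tuples (each simulation draws one random ranking per list, so prefixes
    are consistent across n).
    """
    L = len(lists)
    if L < 2:
        raise ValueError("need at least 2 lists")
    N = lists[0].N_total
    universe = lists[0].universe
    for rl in lists[1:]:
        if rl.N_total != N or rl.universe != universe:
            raise ValueError("lists must share the same pair universe")
    n_max = min(len(rl.pairs) for rl in lists)
    n_values = np.arange(1, n_max + 1)

    # incremental intersection of prefixes
    seen: dict[tuple[str, str], int] = {}
    full = (1 << L) - 1
    inter = 0
    observed_counts = np.empty(n_max, dtype=int)
    for n in range(1, n_max + 1):
        for li, rl in enumerate(lists):
            pair = rl.pairs[n - 1]
            prev = seen.get(pair, 0)
            new = prev | (1 << li)
            seen[pair] = new
            if new == full and prev != full:
                inter += 1
        observed_counts[n - 1] = inter
    observed = observed_counts / n_values

    if L == 2:
        expected = n_values / N
        pvals = np.array(
            [hypergeom_pvalue(int(x), int(n), N) for x, n in zip(observed_counts, n_values)]
        )
        bound = np.zeros(n_max, dtype=bool)
        method = "hypergeometric"
    else:
        expected = (n_values / N) ** (L - 1)
        rng = np.random.default_rng(seed)
        if with_replacement:
            pvals = np.empty(n_max)
            bound = np.zeros(n_max, dtype=bool)
            for k, (x, n) in enumerate(zip(observed_counts, n_values)):
                _, pv, b = multi_list_null(
                    int(x), int(n), N, L, n_sims,
                    seed=int(rng.integers(2**31)), with_replacement=True,
                )
                pvals[k] = pv
                bound[k] = b
        else:
            pvals, bound = _prefix_null_pvalues(observed_counts, n_max, N, L, n_sims, rng)
        method = "simulation"
    return OverlapResult(n_values, observed, expected, pvals, bound, method, L)


def _prefix_null_pvalues(
    observed_counts: np.ndarray,
    n_max: int,
    N: int,
    L: int,
    n_sims: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate random rankings once; a pair is in list l's top n iff its
    position there is < n, so the intersection size at n is the cumulative
    count of per-pair maximum positions below n."""
    ge_counts = np.zeros(n_max, dtype=np.int64)
    chunk = max(1, min(n_sims, int(2e7) // max(N * L, 1)))
    done = 0
    while done < n_sims:
        m = min(chunk, n_sims - done)
        maxpos = np.zeros((m, N), dtype=np.int32)
        for _ in range(L):
            pos = np.argsort(rng.random((m, N)), axis=1).argsort(axis=1)
            np.maximum(maxpos, pos, out=maxpos)
        for s in range(m):
            hist = np.bincount(maxpos[s], minlength=N)
            inter_at_n = np.cumsum(hist)[:n_max]
            ge_counts += inter_at_n >= observed_counts
        done += m
    pvals = ge_counts / n_sims
    bound = ge_counts == 0
    pvals[bound] = 1.0 / n_sims
    return pvals, bound
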