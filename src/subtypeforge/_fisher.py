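"""Exact Fisher-Freeman-Halton tests for r x c contingency tables.

The two-sided p-value uses the probability-mass criterion: p is the total
multivariate-hypergeometric probability of all tables sharing the observed
margins whose probability does not exceed that of the observed table
(ties included within a relative tolerance).

Three computational routes are provided:

* ``fisher_exact_2xc`` -- exact big-integer/rational arithmetic for 2 x c
  tables (a 2 x c table is determined by its first row, and each table's
  probability is proportional to a product of binomial coefficients, so the
  whole computation stays in integers).
* ``fisher_exact_rxc`` -- a pruned network dynamic program over column
  compositions in log space, in the spirit of the Mehta-Patel network
  algorithm.  Small state spaces use a memoized dict implementation; large
  ones a vectorized layer-by-layer DP with numpy arrays.
* Monte-Carlo sampling of tables with fixed margins (``mode="monte-carlo"``)
  for tables whose exact network exceeds the state budget.

The total probability over all same-margin tables is re-accumulated during
every exact run and checked against 1 to 1e-9; a failure raises rather than
returning a silently wrong p-value.
"""

from __future__ import annotations

import math
from fractions import Fraction
from math import comb, inf

import numpy as np
import scipy.stats

__all__ = ["fisher_exact_2xc", "fisher_exact_rxc"]

#: relative tolerance for counting a table as tied with the observed one
TIE_TOL = 1e-7

# rounding grid (decimal places) for merging forward path log-probabilities
_ROUND = 9

# slack (nats) covering float32 round-off in the stored path-length bounds
_F32_SLACK = 1e-3

_LOGFACT = np.concatenate([[0.0], np.cumsum(np.log(np.arange(1, 2049)))])


def _logfact(n: int) -> float:
    if n < len(_LOGFACT):
        return float(_LOGFACT[n])
    return math.lgamma(n + 1.0)


class _Kahan:
    """Compensated accumulator for sums of many small positive terms."""

    __slots__ = ("total", "_c")

    def __init__(self) -> None:
        self.total = 0.0
        self._c = 0.0

    def add(self, x: float) -> None:
        y = x - self._c
        t = self.total + y
        self._c = (t - self.total) - y
        self.total = t


def _validate_counts(counts) -> np.ndarray:
    a = np.asarray(counts)
    if a.ndim != 2:
        raise ValueError("contingency table must be two-dimensional")
    if not np.issubdtype(a.dtype, np.integer):
        f = np.asarray(counts, dtype=float)
        if not np.all(np.isfinite(f)) or np.any(f != np.round(f)):
            raise ValueError("contingency table entries must be non-negative integers")
        a = f.astype(np.int64)
    if np.any(a < 0):
        raise ValueError("contingency table entries must be non-negative")
    if a.sum() == 0:
        raise ValueError("contingency table total must be positive")
    return a.astype(np.int64)


# ---------------------------------------------------------------------------
# 2 x c: exact integer arithmetic
# ---------------------------------------------------------------------------

def fisher_exact_2xc(counts) -> float:
    """Exact two-sided Fisher test for a 2 x c table.

    The table probability is ``prod_j C(c_j, x_j) / C(n, r_1)`` where ``x``
    is the first row; all comparisons and sums are carried out with exact
    integer arithmetic, so ties are handled exactly.  Columns are processed
    in order of decreasing total, which lets the min/max path bounds prune
    the bulk of the network early.
    """
    a = _validate_counts(counts)
    if a.shape[0] != 2:
        raise ValueError(f"expected 2 rows, got {a.shape[0]}")
    a = a[:, a.sum(axis=0) > 0]
    if a.shape[1] < 2 or a[0].sum() == 0 or a[1].sum() == 0:
        return 1.0
    a = a[:, np.argsort(a.sum(axis=0))[::-1]]
    c = a.sum(axis=0).tolist()
    n = int(sum(c))
    r1 = int(a[0].sum())
    m = len(c)
    w_obs = 1
    for j in range(m):
        w_obs *= comb(c[j], int(a[0, j]))

    suffix = [0] * (m + 1)
    for j in reversed(range(m)):
        suffix[j] = suffix[j + 1] + c[j]

    def bounds(j: int, s: int) -> tuple[int, int]:
        hi = min(c[j], r1 - s)
        lo = max(0, c[j] - (suffix[j] - (r1 - s)))
        return lo, hi

    # backward DP: per (stage, row-1 units placed) the min/max/sum of
    # completion weights, in exact integers
    max_w: list[dict[int, int]] = [dict() for _ in range(m + 1)]
    min_w: list[dict[int, int]] = [dict() for _ in range(m + 1)]
    sum_w: list[dict[int, int]] = [dict() for _ in range(m + 1)]
    max_w[m][r1] = min_w[m][r1] = sum_w[m][r1] = 1
    for j in reversed(range(m)):
        for s in range(0, r1 + 1):
            lo, hi = bounds(j, s)
            if lo > hi:
                continue
            mx = mn = None
            tot = 0
            for x in range(lo, hi + 1):
                nxt = s + x
                if nxt not in sum_w[j + 1]:
                    continue
                w = comb(c[j], x)
                cand_mx = w * max_w[j + 1][nxt]
                cand_mn = w * min_w[j + 1][nxt]
                tot += w * sum_w[j + 1][nxt]
                if mx is None or cand_mx > mx:
                    mx = cand_mx
                if mn is None or cand_mn < mn:
                    mn = cand_mn
            if mx is not None:
                max_w[j][s], min_w[j][s], sum_w[j][s] = mx, mn, tot

    # forward pass with pruning; entries: (placed, past weight) -> mass
    p_num = 0
    frontier: dict[tuple[int, int], int] = {(0, 1): 1}
    for j in range(m):
        nxt_frontier: dict[tuple[int, int], int] = {}
        for (s, wp), mass in frontier.items():
            if wp * max_w[j][s] <= w_obs:
                p_num += mass * sum_w[j][s]
                continue
            if wp * min_w[j][s] > w_obs:
                continue
            lo, hi = bounds(j, s)
            for x in range(lo, hi + 1):
                if (s + x) not in sum_w[j + 1]:
                    continue
                w = comb(c[j], x)
                key = (s + x, wp * w)
                nxt_frontier[key] = nxt_frontier.get(key, 0) + mass * w
        frontier = nxt_frontier
    for (s, wp), mass in frontier.items():
        if wp <= w_obs:
            p_num += mass
    return float(Fraction(p_num, comb(n, r1)))


# ---------------------------------------------------------------------------
# r x c: log-space network DP
# ---------------------------------------------------------------------------

def _log_p_table(a: np.ndarray) -> float:
    r = a.sum(axis=1)
    c = a.sum(axis=0)
    n = int(a.sum())
    k = (
        sum(_logfact(int(v)) for v in r)
        + sum(_logfact(int(v)) for v in c)
        - _logfact(n)
    )
    return k - sum(_logfact(int(v)) for v in a.ravel())


def _compositions(total: int, caps: tuple[int, ...]):
    """All ways to split `total` over len(caps) cells with per-cell caps."""
    k = len(caps)

    def rec(i: int, rem: int, prefix: tuple[int, ...]):
        if i == k - 1:
            if rem <= caps[i]:
                yield prefix + (rem,)
            return
        tail_cap = sum(caps[i + 1:])
        lo = max(0, rem - tail_cap)
        for x in range(lo, min(caps[i], rem) + 1):
            yield from rec(i + 1, rem - x, prefix + (x,))

    yield from rec(0, total, ())


def _exact_small(r: tuple[int, ...], c: tuple[int, ...], log_w_obs: float,
                 tie_tol: float, k_const: float) -> tuple[float, float]:
    """Dict-based pruned network DP.

    Returns the probability mass (linear scale, compensated summation) of
    same-margin tables at or below the observed probability, and above it.
    """
    C = len(c)
    thr = log_w_obs + tie_tol

    # memoized backward pass: node (stage j, remaining row sums) ->
    # (min completion length, max completion length, completion mass (log),
    #  arcs: list of (weight, child rem))
    memo: dict[tuple[int, tuple[int, ...]], tuple] = {}

    def node(j: int, rem: tuple[int, ...]):
        key = (j, rem)
        got = memo.get(key)
        if got is not None:
            return got
        if j == C:
            out = (0.0, 0.0, 0.0, None)
            memo[key] = out
            return out
        mn, mx = inf, -inf
        terms: list[float] = []
        arcs: list[tuple[float, tuple[int, ...]]] = []
        for x in _compositions(c[j], rem):
            w = -sum(_LOGFACT[v] for v in x)
            child_rem = tuple(a - b for a, b in zip(rem, x))
            child = node(j + 1, child_rem)
            if child[0] == inf:
                continue
            mn = min(mn, w + child[0])
            mx = max(mx, w + child[1])
            terms.append(w + child[2])
            arcs.append((w, child_rem))
        if not arcs:
            out = (inf, -inf, -inf, [])
        else:
            peak = max(terms)
            mass = peak + math.log(math.fsum(math.exp(t - peak) for t in terms))
            out = (mn, mx, mass, arcs)
        memo[key] = out
        return out

    full = tuple(r)
    if node(0, full)[0] == inf:
        raise RuntimeError("empty network for given margins")

    below, above = _Kahan(), _Kahan()
    frontier: dict[tuple[tuple[int, ...], float], float] = {(full, 0.0): 0.0}
    for j in range(C):
        nxt: dict[tuple[tuple[int, ...], float], float] = {}
        for (rem, rp), lm in frontier.items():
            mn, mx, mass, arcs = node(j, rem)
            if rp + mx <= thr:
                below.add(math.exp(k_const + lm + mass))
                continue
            if rp + mn > thr:
                above.add(math.exp(k_const + lm + mass))
                continue
            for w, child_rem in arcs:
                key = (child_rem, round(rp + w, _ROUND))
                lm_new = lm + w
                old = nxt.get(key)
                if old is None:
                    nxt[key] = lm_new
                elif old >= lm_new:
                    nxt[key] = old + math.log1p(math.exp(lm_new - old))
                else:
                    nxt[key] = lm_new + math.log1p(math.exp(old - lm_new))
        frontier = nxt
    for (rem, rp), lm in frontier.items():
        if rp <= thr:
            below.add(math.exp(k_const + lm))
        else:
            above.add(math.exp(k_const + lm))
    return below.total, above.total


def _exact_large(r: np.ndarray, c: np.ndarray, log_w_obs: float,
                 tie_tol: float, k_const: float,
                 max_expansions: int) -> tuple[float, float]:
    """Vectorized pruned network DP for large tables.

    Rows are sorted descending; the largest row is implied (its cell in each
    column is forced once the other rows are fixed).  Backward arrays per
    layer hold, for every reachable state, the min/max completion path
    length (float32) and the total completion mass (exponentially tilted
    linear scale with a per-layer log offset).
    """
    r = np.sort(r)[::-1]
    c = np.sort(c)[::-1]
    R, C = len(r), len(c)
    n = int(r.sum())
    r0 = int(r[0])
    free = [int(v) for v in r[1:]]            # caps of free rows 1..R-1
    S = tuple(v + 1 for v in free)            # boundary state shape
    cum = np.concatenate([[0], np.cumsum(c)])
    tilt = math.log(max(1.0, n / (R * C)))
    thr = log_w_obs + tie_tol

    sum_grid = np.indices(S).sum(axis=0)

    bound_min: list = [None] * (C + 1)
    bound_max: list = [None] * (C + 1)
    bound_mass: list = [None] * (C + 1)
    bound_off: list[float] = [0.0] * (C + 1)
    mid_min: list[list] = [[None] * R for _ in range(C)]
    mid_max: list[list] = [[None] * R for _ in range(C)]
    mid_mass: list[list] = [[None] * R for _ in range(C)]
    mid_off: list[list] = [[0.0] * R for _ in range(C)]

    fin_min = np.full(S, np.float32(inf), dtype=np.float32)
    fin_max = np.full(S, -np.float32(inf), dtype=np.float32)
    fin_mass = np.zeros(S)
    idx_full = tuple(v for v in free)
    fin_min[idx_full] = 0.0
    fin_max[idx_full] = 0.0
    fin_mass[idx_full] = 1.0
    bound_min[C], bound_max[C], bound_mass[C] = fin_min, fin_max, fin_mass

    lf = _LOGFACT

    for j in reversed(range(C)):
        cj = int(c[j])
        # forced cell of the implied row: layer after all free rows of col j
        p_ax = np.arange(cj + 1)
        x0 = cj - p_ax
        consumed0 = cum[j] + p_ax[:, None] - sum_grid.reshape(1, -1)
        valid = ((consumed0 >= 0) & (consumed0 + x0[:, None] <= r0)).reshape((cj + 1,) + S)
        w_col = (-lf[x0]).reshape((-1,) + (1,) * (R - 1))
        m_min = np.where(valid, bound_min[j + 1][None] + w_col.astype(np.float32), np.float32(inf))
        m_max = np.where(valid, bound_max[j + 1][None] + w_col.astype(np.float32), -np.float32(inf))
        m_mass = np.where(valid, bound_mass[j + 1][None] * np.exp(tilt * x0 - lf[x0]).reshape((-1,) + (1,) * (R - 1)), 0.0)
        off = bound_off[j + 1]
        peak = m_mass.max()
        if peak > 0:
            m_mass /= peak
            off += math.log(peak)
        shape_mid = (cj + 1,) + S
        mid_min[j][R - 1], mid_max[j][R - 1], mid_mass[j][R - 1] = m_min, m_max, m_mass
        mid_off[j][R - 1] = off

        for i in range(R - 1, 0, -1):
            nxt_min, nxt_max, nxt_mass = mid_min[j][i], mid_max[j][i], mid_mass[j][i]
            prv_min = np.full(shape_mid, np.float32(inf), dtype=np.float32)
            prv_max = np.full(shape_mid, -np.float32(inf), dtype=np.float32)
            prv_mass = np.zeros(shape_mid)
            ax = i
            cap = min(free[i - 1], cj)
            for x in range(cap + 1):
                w = float(-lf[x])
                wt = math.exp(tilt * x - lf[x])
                src = [slice(None)] * len(shape_mid)
                dst = [slice(None)] * len(shape_mid)
                src[0] = slice(x, cj + 1)
                dst[0] = slice(0, cj + 1 - x)
                src[ax] = slice(x, free[i - 1] + 1)
                dst[ax] = slice(0, free[i - 1] + 1 - x)
                src_t, dst_t = tuple(src), tuple(dst)
                np.minimum(prv_min[dst_t], nxt_min[src_t] + np.float32(w), out=prv_min[dst_t])
                np.maximum(prv_max[dst_t], nxt_max[src_t] + np.float32(w), out=prv_max[dst_t])
                prv_mass[dst_t] += wt * nxt_mass[src_t]
            peak = prv_mass.max()
            off2 = mid_off[j][i]
            if peak > 0:
                prv_mass /= peak
                off2 += math.log(peak)
            if i == 1:
                bound_min[j] = prv_min[0].copy()
                bound_max[j] = prv_max[0].copy()
                bound_mass[j] = prv_mass[0].copy()
                bound_off[j] = off2
            else:
                mid_min[j][i - 1], mid_max[j][i - 1], mid_mass[j][i - 1] = prv_min, prv_max, prv_mass
                mid_off[j][i - 1] = off2

    below, above = _Kahan(), _Kahan()
    expansions = 0

    def mass_log(lin: float, off: float, consumed: int) -> float:
        if lin <= 0.0:
            return -inf
        return math.log(lin) + off - tilt * (n - consumed)

    def lae(a: float, b: float) -> float:
        if a >= b:
            return a + math.log1p(math.exp(b - a))
        return b + math.log1p(math.exp(a - b))

    start = (0,) * (R - 1)
    frontier: dict[tuple, float] = {(start, 0.0): 0.0}
    for j in range(C):
        cj = int(c[j])
        mids: dict[tuple, float] = {}
        for (s, rp), lm in frontier.items():
            mn = float(bound_min[j][s])
            mx = float(bound_max[j][s])
            if rp + mx <= thr - _F32_SLACK:
                below.add(math.exp(k_const + lm + mass_log(float(bound_mass[j][s]), bound_off[j], int(cum[j]))))
                continue
            if rp + mn > thr + _F32_SLACK:
                above.add(math.exp(k_const + lm + mass_log(float(bound_mass[j][s]), bound_off[j], int(cum[j]))))
                continue
            for x in range(min(free[0] - s[0], cj) + 1):
                w = float(-lf[x])
                key = ((x, s[0] + x) + s[1:], round(rp + w, _ROUND))
                lm_new = lm + w
                old = mids.get(key)
                mids[key] = lm_new if old is None else lae(old, lm_new)
                expansions += 1
        for i in range(2, R):
            nxt: dict[tuple, float] = {}
            for (ps, rp), lm in mids.items():
                p, s = ps[0], ps[1:]
                idx = (p,) + s
                mn = float(mid_min[j][i - 1][idx])
                mx = float(mid_max[j][i - 1][idx])
                if rp + mx <= thr - _F32_SLACK:
                    below.add(math.exp(k_const + lm + mass_log(float(mid_mass[j][i - 1][idx]), mid_off[j][i - 1], int(cum[j]) + p)))
                    continue
                if rp + mn > thr + _F32_SLACK:
                    above.add(math.exp(k_const + lm + mass_log(float(mid_mass[j][i - 1][idx]), mid_off[j][i - 1], int(cum[j]) + p)))
                    continue
                for x in range(min(free[i - 1] - s[i - 1], cj - p) + 1):
                    w = float(-lf[x])
                    s_new = s[:i - 1] + (s[i - 1] + x,) + s[i:]
                    key = ((p + x,) + s_new, round(rp + w, _ROUND))
                    lm_new = lm + w
                    old = nxt.get(key)
                    nxt[key] = lm_new if old is None else lae(old, lm_new)
                    expansions += 1
            mids = nxt
        frontier = {}
        for (ps, rp), lm in mids.items():
            p, s = ps[0], ps[1:]
            idx = (p,) + s
            mn = float(mid_min[j][R - 1][idx])
            mx = float(mid_max[j][R - 1][idx])
            if rp + mx <= thr - _F32_SLACK:
                below.add(math.exp(k_const + lm + mass_log(float(mid_mass[j][R - 1][idx]), mid_off[j][R - 1], int(cum[j]) + p)))
                continue
            if rp + mn > thr + _F32_SLACK:
                above.add(math.exp(k_const + lm + mass_log(float(mid_mass[j][R - 1][idx]), mid_off[j][R - 1], int(cum[j]) + p)))
                continue
            x0 = cj - p
            consumed0 = int(cum[j]) + p - sum(s)
            if x0 < 0 or consumed0 < 0 or consumed0 + x0 > r0:
                continue
            w = float(-lf[x0])
            key = (s, round(rp + w, _ROUND))
            lm_new = lm + w
            old = frontier.get(key)
            frontier[key] = lm_new if old is None else lae(old, lm_new)
            expansions += 1
        if expansions > max_expansions:
            raise RuntimeError(
                f"exact network exceeded the expansion budget ({max_expansions}); "
                "use mode='monte-carlo'"
            )
    for (s, rp), lm in frontier.items():
        if rp <= thr:
            below.add(math.exp(k_const + lm))
        else:
            above.add(math.exp(k_const + lm))
    return below.total, above.total


def fisher_exact_rxc(counts, *, mode: str = "exact", B: int = 100_000,
                     seed: int | None = None, tie_tol: float = TIE_TOL,
                     state_budget: int = 500_000_000,
                     max_expansions: int = 50_000_000) -> float:
    """Two-sided exact (or Monte-Carlo) Fisher test for an r x c table.

    Parameters
    ----------
    counts : array-like of shape (r, c)
        Non-negative integer contingency table.
    mode : {"exact", "monte-carlo"}
        Exact network DP, or Monte-Carlo over tables with fixed margins
        (Patefield sampling via :func:`scipy.stats.random_table`).
    B : int
        Number of Monte-Carlo tables when ``mode="monte-carlo"``.
    seed : int, optional
        Seed for Monte-Carlo mode.
    tie_tol : float
        Relative tolerance within which a table counts as tied with the
        observed one.
    state_budget : int
        Upper bound on the vectorized DP state-space size (states x layers);
        tables beyond it raise an error advising Monte-Carlo mode.
    max_expansions : int
        Safety cap on forward path expansions in exact mode.
    """
    a = _validate_counts(counts)
    a = a[a.sum(axis=1) > 0][:, a.sum(axis=0) > 0]
    if a.shape[0] < 2 or a.shape[1] < 2:
        return 1.0
    log_p_obs = _log_p_table(a)
    r = a.sum(axis=1)
    c = a.sum(axis=0)
    n = int(a.sum())
    k_const = (
        sum(_logfact(int(v)) for v in r)
        + sum(_logfact(int(v)) for v in c)
        - _logfact(n)
    )
    log_w_obs = log_p_obs - k_const  # observed path length

    if mode == "monte-carlo":
        if B < 1:
            raise ValueError("B must be >= 1")
        rng = np.random.default_rng(seed)
        dist = scipy.stats.random_table(r, c)
        hits = 0
        chunk = 20_000
        done = 0
        while done < B:
            b = min(chunk, B - done)
            tabs = dist.rvs(b, random_state=rng)
            lp = k_const - _LOGFACT[tabs.reshape(b, -1).astype(np.int64)].sum(axis=1)
            hits += int(np.sum(lp <= log_p_obs + tie_tol))
            done += b
        return (1 + hits) / (B + 1)
    if mode != "exact":
        raise ValueError(f"unknown mode {mode!r}")

    # orientation: keep the per-layer state space (product over non-implied
    # margin sums times the largest stage total) as small as possible
    def footprint(rows, cols):
        rs = np.sort(rows)[::-1]
        return (int(cols.max()) + 1) * int(np.prod([int(v) + 1 for v in rs[1:]]))

    if footprint(r, c) <= footprint(c, r):
        rows, cols = r, c
    else:
        rows, cols = c, r

    small = int(np.prod([min(int(v), n) + 1 for v in rows])) <= 60_000
    if small:
        below, above = _exact_small(
            tuple(int(v) for v in np.sort(rows)[::-1]),
            tuple(int(v) for v in np.sort(cols)[::-1]),
            log_w_obs, tie_tol, k_const,
        )
    else:
        layers = len(rows) * len(cols)
        if footprint(rows, cols) * layers > state_budget:
            raise RuntimeError(
                "table state space exceeds the exact-mode budget; "
                "use mode='monte-carlo'"
            )
        below, above = _exact_large(rows, cols, log_w_obs, tie_tol, k_const,
                                    max_expansions)

    total = below + above
    if abs(total - 1.0) > 1e-9:
        raise RuntimeError(
            f"internal mass check failed: same-margin probabilities sum to {total!r}"
        )
    return min(1.0, below)
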