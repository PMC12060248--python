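"""Independent brute-force oracles used by the tests.

These deliberately re-derive expected values by exhaustive enumeration or
textbook formulas, sharing no code with the implementation paths they
check.
"""
from __future__ import annotations

import math
from functools import lru_cache


def chain_cover_oracle(targets, max_target_gap: int = 5,
                       max_query_gap: int = 5) -> int:
    """Maximum number of gene pairs coverable by disjoint monotone chains
    (size >= 2) after first reserving a maximum-cardinality ascending chain
    as the neighborhood backbone.

    ``targets`` is the permutation of target ranks in query order (query
    ranks are the positions 1..n).  Chains are subsequences whose
    consecutive members differ by at most the gap limits on both axes and
    whose target ranks are strictly monotone.
    """
    t = tuple(targets)
    n = len(t)
    chains_by_low: list[list[int]] = [[] for _ in range(n)]
    ascending: list[tuple[int, int]] = []  # (mask, length)

    def extend(start: int, last: int, direction: int, mask: int,
               length: int) -> None:
        for j in range(last + 1, n):
            if j - last > max_query_gap:
                break
            step = t[j] - t[last]
            if step == 0 or abs(step) > max_target_gap:
                continue
            sign = 1 if step > 0 else -1
            if direction and sign != direction:
                continue
            m2 = mask | (1 << j)
            chains_by_low[start].append(m2)
            if sign > 0:
                ascending.append((m2, length + 1))
            extend(start, j, sign, m2, length + 1)

    for i in range(n):
        ascending.append((1 << i, 1))
        extend(i, i, 0, 1 << i, 1)

    @lru_cache(maxsize=None)
    def cover(mask: int) -> int:
        if not mask:
            return 0
        i = (mask & -mask).bit_length() - 1
        best = cover(mask ^ (1 << i))
        for cm in chains_by_low[i]:
            if cm & mask == cm:
                v = cover(mask ^ cm) + bin(cm).count("1")
                if v > best:
                    best = v
        return best

    full = (1 << n) - 1
    best_len = max(length for _, length in ascending)
    if best_len < 2:
        result = cover(full)
    else:
        result = max(length + cover(full ^ mask)
                     for mask, length in ascending if length == best_len)
    cover.cache_clear()
    return result


def welch_oracle(a, b) -> tuple[float, float, float]:
    """Textbook Welch statistic, Satterthwaite df, and two-sided p-value
    (normal-free: uses the regularized incomplete beta for the t CDF)."""
    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    # two-sided p from the t distribution via the incomplete beta function
    x = df / (df + t * t)
    p = _betainc_reg(df / 2.0, 0.5, x)
    return t, df, p


def _betainc_reg(a: float, b: float, x: float) -> float:
    # continued-fraction evaluation (Lentz), adequate for test accuracy
    if x <= 0:
        return 0.0
    if x >= 1:
        return 1.0
    ln_front = (math.lgamma(a + b) - math.lgamma(a) - math.lgamma(b)
                + a * math.log(x) + b * math.log(1 - x))
    front = math.exp(ln_front) / a
    f, c, d = 1.0, 1.0, 0.0
    for i in range(200):
        m = i // 2
        if i == 0:
            num = 1.0
        elif i % 2 == 0:
            num = m * (b - m) * x / ((a + 2 * m - 1) * (a + 2 * m))
        else:
            num = -(a + m) * (a + b + m) * x / ((a + 2 * m) * (a + 2 * m + 1))
        d = 1.0 + num * d
        d = 1.0 / (d if abs(d) > 1e-30 else 1e-30)
        c = 1.0 + num / (c if abs(c) > 1e-30 else 1e-30)
        f *= c * d
        if abs(1.0 - c * d) < 1e-12:
            break
    val = front * (f - 1.0)
    if x < (a + 1) / (a + b + 2):
        return val
    return 1.0 - _betainc_reg(b, a, 1.0 - x)


def permutation_p_two_sided(a, b, rng, n_perm: int = 4000) -> float:
    """Permutation p-value for the difference of means (two-sided)."""
    import numpy as np
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    pooled = np.concatenate([a, b])
    obs = abs(a.mean() - b.mean())
    count = 0
    for _ in range(n_perm):
        rng.shuffle(pooled)
        d = abs(pooled[:a.size].mean() - pooled[a.size:].mean())
        if d >= obs - 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1)
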