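"""Independent brute-force / closed-form oracles used to cross-check the package.

These deliberately avoid networkx, scipy.stats.pearsonr and statsmodels so the
implementation and its check never share a code path.
"""

from __future__ import annotations

import math


def union_find_components(nodes, edges):
    """Connected components by plain union-find; returns a set of frozensets."""
    parent = {n: n for n in nodes}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    groups: dict = {}
    for n in nodes:
        groups.setdefault(find(n), set()).add(n)
    return {frozenset(members) for members in groups.values()}


def _student_t_sf(t: float, df: int) -> float:
    """Upper tail of Student's t via the regularized incomplete beta function."""
    x = df / (df + t * t)
    p = 0.5 * _betainc_reg(df / 2.0, 0.5, x)
    return p if t >= 0 else 1.0 - p


def _betainc_reg(a: float, b: float, x: float) -> float:
    """Regularized incomplete beta I_x(a, b) by continued fraction (Lentz)."""
    if x <= 0.0:
        return 0.0
    if x >= 1.0:
        return 1.0
    ln_front = (
        math.lgamma(a + b) - math.lgamma(a) - math.lgamma(b)
        + a * math.log(x) + b * math.log1p(-x)
    )
    if x > (a + 1.0) / (a + b + 2.0):
        return 1.0 - _betainc_reg(b, a, 1.0 - x)
    # continued fraction for I_x(a,b)
    tiny = 1e-300
    qab, qap, qam = a + b, a + 1.0, a - 1.0
    c = 1.0
    d = 1.0 - qab * x / qap
    if abs(d) < tiny:
        d = tiny
    d = 1.0 / d
    h = d
    for m in range(1, 300):
        m2 = 2 * m
        aa = m * (b - m) * x / ((qam + m2) * (a + m2))
        d = 1.0 + aa * d
        if abs(d) < tiny:
            d = tiny
        c = 1.0 + aa / c
        if abs(c) < tiny:
            c = tiny
        d = 1.0 / d
        h *= d * c
        aa = -(a + m) * (qab + m) * x / ((a + m2) * (qap + m2))
        d = 1.0 + aa * d
        if abs(d) < tiny:
            d = tiny
        c = 1.0 + aa / c
        if abs(c) < tiny:
            c = tiny
        d = 1.0 / d
        delta = d * c
        h *= delta
        if abs(delta - 1.0) < 1e-15:
            break
    return math.exp(ln_front) * h / a


def pearson_direct(x, y):
    """Textbook Pearson r and its two-sided t-transform p-value (n-2 df)."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    r = sxy / math.sqrt(sxx * syy)
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * _student_t_sf(abs(t), n - 2)
    return r, p


def ols_direct(x, y):
    """Closed-form simple OLS: slope, intercept, two-sided slope p (n-2 df)."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxx = sum((a - mx) ** 2 for a in x)
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    slope = sxy / sxx
    intercept = my - slope * mx
    rss = sum((b - intercept - slope * a) ** 2 for a, b in zip(x, y))
    sigma2 = rss / (n - 2)
    se = math.sqrt(sigma2 / sxx)
    if se == 0.0:
        return slope, intercept, 0.0
    t = slope / se
    p = 2.0 * _student_t_sf(abs(t), n - 2)
    return slope, intercept, p
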