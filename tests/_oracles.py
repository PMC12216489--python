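"""Independent brute-force oracle implementations used to cross-check the
package. These are deliberately written in plain loops/dicts, without reusing
any package code path, so that agreement is a meaningful check."""

from __future__ import annotations

import math


def oracle_rpm(counts: dict[tuple[int, str], float]) -> dict[tuple[int, str], float]:
    total = sum(counts.values())
    assert total > 0
    return {k: v * 1e6 / total for k, v in counts.items()}


def oracle_enrichment(sel: dict, unsel: dict, p: float) -> dict:
    keys = set(sel) | set(unsel)
    return {k: (sel.get(k, 0.0) + p) / (unsel.get(k, 0.0) + p) for k in keys}


def oracle_preferences(enrich: dict[tuple[int, str], float]) -> dict:
    sites = {site for site, _ in enrich}
    out = {}
    for site in sites:
        row = {aa: v for (s, aa), v in enrich.items() if s == site}
        total = sum(row.values())
        for aa, v in row.items():
            out[(site, aa)] = v / total
    return out


def oracle_diffsel(
    sel: dict, unsel: dict, wt_aa: dict[int, str], p: float
) -> dict[tuple[int, str], float]:
    out = {}
    keys = set(sel) | set(unsel)
    for site, aa in keys:
        s_mut = sel.get((site, aa), 0.0) + p
        u_mut = unsel.get((site, aa), 0.0) + p
        s_wt = sel.get((site, wt_aa[site]), 0.0) + p
        u_wt = unsel.get((site, wt_aa[site]), 0.0) + p
        if aa == wt_aa[site]:
            out[(site, aa)] = 0.0
        else:
            out[(site, aa)] = math.log2((s_mut / s_wt) / (u_mut / u_wt))
    return out


def oracle_entropy(probs: list[float]) -> float:
    return -sum(p * math.log2(p) for p in probs if p > 0)


def oracle_pearson(xs: list[float], ys: list[float]) -> float:
    n = len(xs)
    mx = sum(xs) / n
    my = sum(ys) / n
    cov = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    vx = sum((x - mx) ** 2 for x in xs)
    vy = sum((y - my) ** 2 for y in ys)
    return cov / math.sqrt(vx * vy)


def oracle_welch(a: list[float], b: list[float]) -> tuple[float, float]:
    """(t, df) by the textbook Welch formulas; p left to scipy in the tests."""
    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return t, df
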