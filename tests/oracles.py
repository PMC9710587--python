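"""Independent brute-force oracles used to check the GSEA engine.

Deliberately written as explicit pure-Python loops, sharing no code with the
package implementation.
"""

from __future__ import annotations


def brute_force_enrichment(
    item_ids: list[str],
    stats: list[float],
    members: set[str],
    weight_exponent: float = 1.0,
) -> tuple[float, list[float]]:
    """Weighted KS enrichment score by explicit walk over the sorted list.

    Returns (es, running_sum) with the same conventions as the engine:
    descending sort with ties broken by item id, ES = running-sum value of
    largest magnitude with magnitude ties resolved toward the positive
    extremum.
    """
    order = sorted(range(len(item_ids)), key=lambda i: (-stats[i], item_ids[i]))
    hits = [i for i in order if item_ids[i] in members]
    n, n_hits = len(item_ids), len(hits)
    if n_hits == 0 or n_hits >= n:
        raise ValueError("set empty on the list or covering it entirely")
    total = sum(abs(stats[i]) ** weight_exponent for i in hits)
    running: list[float] = []
    cur = 0.0
    for i in order:
        if item_ids[i] in members:
            if total == 0:
                cur += 1.0 / n_hits
            else:
                cur += abs(stats[i]) ** weight_exponent / total
        else:
            cur -= 1.0 / (n - n_hits)
        running.append(cur)
    hi, lo = max(running), min(running)
    es = hi if hi >= -lo else lo
    return es, running


def brute_force_bh(pvals: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up by the textbook definition."""
    n = len(pvals)
    order = sorted(range(n), key=lambda i: pvals[i])
    q = [0.0] * n
    prev = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, pvals[i] * n / rank_from_top)
        q[i] = val
        prev = val
    return q


def brute_force_spearman(x: list[float], y: list[float]) -> float:
    """Spearman rho via explicit average ranks and the Pearson formula."""

    def ranks(v: list[float]) -> list[float]:
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rx, ry = ranks(x), ranks(y)
    n = len(x)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    dx = sum((a - mx) ** 2 for a in rx) ** 0.5
    dy = sum((b - my) ** 2 for b in ry) ** 0.5
    return num / (dx * dy)
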