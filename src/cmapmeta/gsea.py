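"""Self-contained preranked GSEA engine.

Implements the weighted Kolmogorov-Smirnov enrichment statistic on a ranked
list, a random-set permutation null, normalized enrichment scores (NES),
one-sided permutation p-values and Benjamini-Hochberg q-values. The same
engine drives both meta-analysis stages of the stratified connectivity
pipeline: experiments -> compound scores and compounds -> MoA / target
scores.

Walking the list sorted by decreasing statistic, the running sum gains
``|s|^w / sum_hits |s|^w`` at each set member ("hit") and loses
``1 / (N - n_hits)`` at each non-member ("miss"); the enrichment score (ES)
is the running-sum value of largest magnitude. The NES divides the ES by the
mean magnitude of same-sign null scores from random sets of the same size,
making scores comparable across set sizes; p-values are one-sided within the
ES sign, with add-one smoothing so that 1/(B+1) is the smallest attainable
value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RankedList",
    "ItemSet",
    "EnrichmentResult",
    "enrichment_score",
    "permutation_null",
    "normalize_and_test",
    "gsea_preranked",
    "adjust_bh",
]


@dataclass
class RankedList:
    """Items with a real ranking statistic, held sorted by decreasing stat.

    Ties in the statistic are broken by item id ascending so the order (and
    every downstream score) is deterministic.
    """

    item_ids: list[str]
    stat: np.ndarray

    def __post_init__(self) -> None:
        ids = np.asarray([str(i) for i in self.item_ids], dtype=object)
        stat = np.asarray(self.stat, dtype=float)
        if ids.size != stat.size:
            raise ValueError("item_ids and stat differ in length")
        if ids.size < 2:
            raise ValueError("a ranked list needs at least 2 items")
        if np.isnan(stat).any():
            raise ValueError("ranking statistics must not be missing")
        if len(set(ids)) != ids.size:
            raise ValueError("duplicate item ids in ranked list")
        order = np.lexsort((ids, -stat))  # stat desc, id asc within ties
        self.item_ids = [str(i) for i in ids[order]]
        self.stat = stat[order]
        self._pos = {item: k for k, item in enumerate(self.item_ids)}

    def __len__(self) -> int:
        return len(self.item_ids)

    def positions_of(self, members: set[str] | frozenset[str]) -> np.ndarray:
        """Sorted 0-based positions of the members present in the list."""
        return np.asarray(
            sorted(self._pos[m] for m in members if m in self._pos), dtype=np.intp
        )


@dataclass(frozen=True)
class ItemSet:
    """A named set of item ids (a perturbagen's experiments, an MoA's drugs...)."""

    name: str
    members: frozenset[str]

    def __init__(self, name: str, members) -> None:
        object.__setattr__(self, "name", str(name))
        object.__setattr__(self, "members", frozenset(str(m) for m in members))


@dataclass
class EnrichmentResult:
    """One scored set: ES, NES, p, q, membership size and leading edge."""

    name: str
    es: float
    nes: float
    pval: float
    qval: float
    set_size: int
    leading_edge: list[str] = field(default_factory=list)
    running_sum: np.ndarray | None = None


def _es_core(
    stat: np.ndarray, positions: np.ndarray, weight_exponent: float
) -> tuple[float, np.ndarray, int]:
    """ES, running sum and extremum index for hit `positions` in a sorted list."""
    n = stat.size
    n_hits = positions.size
    if n_hits == 0:
        raise ValueError("set has no members in the ranked list")
    if n_hits >= n:
        raise ValueError("set covers the whole ranked list (miss normalizer is zero)")
    steps = np.full(n, -1.0 / (n - n_hits))
    w = np.abs(stat[positions]) ** weight_exponent
    total = w.sum()
    if total == 0:
        # all hit statistics are exactly zero: fall back to equal hit weights
        w = np.ones(n_hits)
        total = float(n_hits)
    steps[positions] = w / total
    running = np.cumsum(steps)
    hi = int(np.argmax(running))
    lo = int(np.argmin(running))
    # magnitude tie broken toward the positive extremum (deterministic)
    if running[hi] >= -running[lo]:
        idx = hi
    else:
        idx = lo
    return float(running[idx]), running, idx


def enrichment_score(
    ranked: RankedList,
    item_set: ItemSet,
    weight_exponent: float = 1.0,
) -> tuple[float, np.ndarray, list[str]]:
    """Weighted KS enrichment score of a set along a ranked list.

    Returns ``(es, running_sum, leading_edge)``. The leading edge contains
    the hit members at or before the extremum for a positive ES, and at or
    after it for a negative ES.
    """
    positions = ranked.positions_of(item_set.members)
    es, running, idx = _es_core(ranked.stat, positions, weight_exponent)
    if es > 0:
        lead = positions[positions <= idx]
    elif es < 0:
        lead = positions[positions >= idx]
    else:
        lead = positions[:0]
    leading_edge = [ranked.item_ids[p] for p in lead]
    return es, running, leading_edge


def permutation_null(
    ranked: RankedList,
    set_size: int,
    permutations: int = 1000,
    weight_exponent: float = 1.0,
    random_state: int | np.random.Generator = 0,
) -> np.ndarray:
    """Null ES distribution from uniformly random sets of ``set_size`` items.

    Deterministic given (seed, permutations, set_size, statistics); all
    draws come from one seeded stream.
    """
    n = len(ranked)
    if not (1 <= set_size < n):
        raise ValueError(f"set_size {set_size} out of range [1, {n})")
    if permutations < 100:
        warnings.warn(
            f"permutations={permutations} < 100 gives very coarse p-values",
            stacklevel=2,
        )
    rng = (random_state if isinstance(random_state, np.random.Generator)
           else np.random.default_rng(random_state))
    null = np.empty(permutations)
    for b in range(permutations):
        pos = np.sort(rng.choice(n, size=set_size, replace=False))
        null[b], _, _ = _es_core(ranked.stat, pos, weight_exponent)
    return null


def normalize_and_test(es: float, null: np.ndarray) -> tuple[float, float]:
    """NES and permutation p-value of an observed ES against a null sample.

    NES = es / mean(|null values of the same sign as es|); the p-value is
    one-sided within that sign with add-one smoothing. With no same-sign
    null values the NES is undefined (NaN, with a warning) and the p-value
    falls back to a two-sided comparison on |es|.
    """
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValueError("empty null distribution")
    if es == 0:
        return 0.0, 1.0
    same = null[null > 0] if es > 0 else null[null < 0]
    if same.size == 0:
        warnings.warn(
            "no null scores share the observed ES sign; NES undefined",
            stacklevel=2,
        )
        pval = (1 + int((np.abs(null) >= abs(es)).sum())) / (1 + null.size)
        return float("nan"), pval
    nes = es / np.abs(same).mean()
    pval = (1 + int((np.abs(same) >= abs(es)).sum())) / (1 + same.size)
    return float(nes), float(pval)


def adjust_bh(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, order-preserving)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def gsea_preranked(
    ranked: RankedList,
    sets: list[ItemSet],
    weight_exponent: float = 1.0,
    permutations: int = 1000,
    random_state: int = 0,
    min_size: int = 1,
    max_size: int | None = None,
    keep_running_sum: bool = True,
) -> list[EnrichmentResult]:
    """Score every set against one ranked list; BH-adjust across the call.

    Sets are filtered to ``min_size <= present members <= max_size``. All
    sets of equal (present) size share one permutation null — random sets
    depend only on their size, so this changes nothing but the Monte-Carlo
    noise. Results are sorted by descending NES, ties by name.
    """
    if not sets:
        raise ValueError("no sets supplied")
    retained: list[tuple[ItemSet, np.ndarray]] = []
    for s in sets:
        k = ranked.positions_of(s.members).size
        if k < max(1, min_size):
            continue
        if max_size is not None and k > max_size:
            continue
        if k >= len(ranked):
            continue
        retained.append((s, ranked.positions_of(s.members)))
    if not retained:
        warnings.warn("all sets were filtered out", stacklevel=2)
        return []

    rng = np.random.default_rng(random_state)
    sizes = sorted({pos.size for _, pos in retained})
    nulls = {
        k: permutation_null(ranked, k, permutations, weight_exponent, rng)
        for k in sizes
    }

    results: list[EnrichmentResult] = []
    for s, _pos in retained:
        es, running, lead = enrichment_score(ranked, s, weight_exponent)
        nes, pval = normalize_and_test(es, nulls[_pos.size])
        results.append(
            EnrichmentResult(
                name=s.name, es=es, nes=nes, pval=pval, qval=float("nan"),
                set_size=_pos.size, leading_edge=lead,
                running_sum=running if keep_running_sum else None,
            )
        )
    qvals = adjust_bh(np.array([r.pval for r in results]))
    for r, q in zip(results, qvals):
        r.qval = float(q)
    results.sort(key=lambda r: (-(r.nes if np.isfinite(r.nes) else -np.inf), r.name))
    return results
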