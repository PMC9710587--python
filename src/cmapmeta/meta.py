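"""The stratified meta-analysis: experiments -> compounds -> MoA / targets.

Stage 1 groups the experiment-level connectivities by perturbagen: for each
drug d_j the set D_j of its experiment ids is scored by preranked GSEA on the
list of experiments ranked by connectivity rho, yielding the compound score
x_j = NES(D_j, rho). Perturbagens with fewer than ``min_experiments``
experiments (default 20) are excluded for statistical robustness.

Stage 2 repeats the same enrichment one level up: drugs are ranked by their
compound NES, and MoA classes (sets M_j of drugs sharing a mechanism label)
and target genes (sets T_j of drugs annotated to a target) are scored as
q_j = NES(M_j, x) and r_j = NES(T_j, x). The stage-2 universe is the set of
drugs actually scored at stage 1, so the second enrichment is relative to
what was measured, not to the whole annotation.

For multiple query contrasts an activation matrix summarizes, per contrast,
the most positively and negatively connected drugs as max-normalized NES
values in [-1, 1].
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix, compute_connectivity
from .gsea import EnrichmentResult, ItemSet, RankedList, gsea_preranked
from .io import AnnotationTable, QueryMatrix, ReferenceDatabase

__all__ = [
    "PerturbagenSet",
    "ActivationMatrix",
    "StratifiedResult",
    "build_perturbagen_sets",
    "compound_enrichment",
    "moa_enrichment",
    "target_enrichment",
    "compound_scores_from_results",
    "build_activation_matrix",
    "results_to_table",
    "run_stratified_analysis",
]

log = logging.getLogger(__name__)

DEFAULT_MIN_EXPERIMENTS = 20
DEFAULT_MIN_SET_SIZE = 3


@dataclass
class PerturbagenSet:
    """A drug d_j and the set D_j of its experiment ids in the reference."""

    drug: str
    experiment_ids: frozenset[str]

    def __post_init__(self) -> None:
        self.experiment_ids = frozenset(self.experiment_ids)
        if not self.experiment_ids:
            raise ValueError(f"perturbagen set for {self.drug!r} is empty")

    def as_item_set(self) -> ItemSet:
        return ItemSet(self.drug, self.experiment_ids)


@dataclass
class ActivationMatrix:
    """Drugs x contrasts matrix of max-normalized compound NES in [-1, 1]."""

    drugs: list[str]
    contrast_names: list[str]
    values: np.ndarray
    top_n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.drugs, columns=self.contrast_names)


def build_perturbagen_sets(
    ref: ReferenceDatabase,
    min_experiments: int = DEFAULT_MIN_EXPERIMENTS,
) -> list[PerturbagenSet]:
    """One set per drug with at least ``min_experiments`` experiments.

    Excluded drugs are logged with their experiment counts; an empty result
    only warns (nothing passed the filter).
    """
    by_drug: dict[str, set[str]] = {}
    for e in ref.experiment_ids:
        by_drug.setdefault(ref.drug_of[e], set()).add(e)
    sets, excluded = [], {}
    for drug, exps in by_drug.items():
        if len(exps) >= min_experiments:
            sets.append(PerturbagenSet(drug, frozenset(exps)))
        else:
            excluded[drug] = len(exps)
    if excluded:
        log.info("excluded %d perturbagens with < %d experiments: %s",
                 len(excluded), min_experiments,
                 dict(sorted(excluded.items())[:10]))
    if not sets:
        warnings.warn(
            f"no perturbagen has >= {min_experiments} experiments", stacklevel=2
        )
    return sets


def compound_enrichment(
    conn: ConnectivityMatrix,
    sets: list[PerturbagenSet],
    weight_exponent: float = 1.0,
    permutations: int = 1000,
    random_state: int = 0,
    min_size: int | None = None,
    max_size: int | None = None,
) -> dict[str, list[EnrichmentResult]]:
    """Stage 1: per contrast, GSEA of each perturbagen's experiments on rho.

    Experiments with missing connectivity are dropped from the ranking (with
    a logged count); a contrast with fewer than two scored experiments is
    skipped with a warning.
    """
    out: dict[str, list[EnrichmentResult]] = {}
    item_sets = [s.as_item_set() for s in sets]
    for c, contrast in enumerate(conn.contrast_names):
        rho = conn.rho[:, c]
        ok = np.isfinite(rho)
        n_drop = int((~ok).sum())
        if n_drop:
            log.info("contrast %s: dropping %d experiments with missing rho",
                     contrast, n_drop)
        if ok.sum() < 2:
            warnings.warn(
                f"contrast {contrast!r}: fewer than 2 scored experiments; skipped",
                stacklevel=2,
            )
            continue
        ranked = RankedList(
            [e for e, keep in zip(conn.experiment_ids, ok) if keep], rho[ok]
        )
        out[contrast] = gsea_preranked(
            ranked, item_sets,
            weight_exponent=weight_exponent, permutations=permutations,
            random_state=random_state,
            min_size=min_size if min_size is not None else 1,
            max_size=max_size,
        )
    return out


def compound_scores_from_results(
    compound_results: dict[str, list[EnrichmentResult]],
) -> dict[str, dict[str, float]]:
    """Per contrast: drug -> compound NES, excluding undefined (NaN) scores."""
    scores: dict[str, dict[str, float]] = {}
    for contrast, results in compound_results.items():
        scores[contrast] = {
            r.name: r.nes for r in results if np.isfinite(r.nes)
        }
    return scores


def _annotation_enrichment(
    compound_scores: dict[str, dict[str, float]],
    groups: dict[str, set[str]],
    what: str,
    weight_exponent: float,
    permutations: int,
    random_state: int,
    min_size: int,
    max_size: int | None,
) -> dict[str, list[EnrichmentResult]]:
    out: dict[str, list[EnrichmentResult]] = {}
    for contrast, scores in compound_scores.items():
        if len(scores) < 2:
            warnings.warn(
                f"contrast {contrast!r}: fewer than 2 scored drugs; "
                f"{what} level skipped", stacklevel=2,
            )
            continue
        scored = set(scores)
        sets = [
            ItemSet(label, members & scored)
            for label, members in groups.items()
            if members & scored
        ]
        if not sets:
            raise ValueError(
                f"no overlap between scored drugs and the {what} annotation "
                f"for contrast {contrast!r}"
            )
        ranked = RankedList(list(scores), np.array([scores[d] for d in scores]))
        out[contrast] = gsea_preranked(
            ranked, sets,
            weight_exponent=weight_exponent, permutations=permutations,
            random_state=random_state, min_size=min_size, max_size=max_size,
        )
    return out


def moa_enrichment(
    compound_scores: dict[str, dict[str, float]],
    ann: AnnotationTable,
    weight_exponent: float = 1.0,
    permutations: int = 1000,
    random_state: int = 0,
    min_size: int = DEFAULT_MIN_SET_SIZE,
    max_size: int | None = None,
) -> dict[str, list[EnrichmentResult]]:
    """Stage 2a: MoA-class enrichment on the drug ranking by compound NES.

    A drug with k mechanism labels belongs to k sets; a drug without labels
    contributes to no set but still occupies its rank position.
    """
    return _annotation_enrichment(
        compound_scores, ann.moa_sets(), "moa",
        weight_exponent, permutations, random_state, min_size, max_size,
    )


def target_enrichment(
    compound_scores: dict[str, dict[str, float]],
    ann: AnnotationTable,
    weight_exponent: float = 1.0,
    permutations: int = 1000,
    random_state: int = 0,
    min_size: int = DEFAULT_MIN_SET_SIZE,
    max_size: int | None = None,
) -> dict[str, list[EnrichmentResult]]:
    """Stage 2b: target-gene enrichment on the drug ranking by compound NES."""
    return _annotation_enrichment(
        compound_scores, ann.target_sets(), "target",
        weight_exponent, permutations, random_state, min_size, max_size,
    )


def build_activation_matrix(
    compound_results: dict[str, list[EnrichmentResult]],
    top_n: int = 15,
    q_cap: float = 1.0,
) -> ActivationMatrix:
    """Drugs x contrasts summary of the strongest signed compound scores.

    Per contrast the ``top_n`` drugs by |NES| with q-value <= ``q_cap`` are
    selected; rows are the union of the selections, cells hold
    NES / max|NES| over the whole matrix, and rows are ordered by
    descending row mean.
    """
    if not compound_results:
        raise ValueError("no compound results to summarize")
    contrasts = list(compound_results)
    nes_of: dict[str, dict[str, float]] = {
        c: {r.name: r.nes for r in res if np.isfinite(r.nes)}
        for c, res in compound_results.items()
    }
    selected: set[str] = set()
    for c, res in compound_results.items():
        eligible = [r for r in res if np.isfinite(r.nes) and r.qval <= q_cap]
        eligible.sort(key=lambda r: (-abs(r.nes), r.name))
        selected.update(r.name for r in eligible[:top_n])
    drugs = sorted(selected)
    mat = np.zeros((len(drugs), len(contrasts)))
    for j, c in enumerate(contrasts):
        for i, d in enumerate(drugs):
            mat[i, j] = nes_of[c].get(d, 0.0)
    peak = np.abs(mat).max()
    if peak > 0:
        mat = mat / peak
    order = np.argsort(-mat.mean(axis=1), kind="mergesort")
    return ActivationMatrix(
        [drugs[i] for i in order], contrasts, mat[order], top_n
    )


def results_to_table(
    levels: dict[str, dict[str, list[EnrichmentResult]]],
) -> pd.DataFrame:
    """Concatenate {level: {contrast: results}} into one flat result table."""
    rows = []
    for level, per_contrast in levels.items():
        for contrast, results in per_contrast.items():
            for r in results:
                rows.append({
                    "level": level, "contrast": contrast, "name": r.name,
                    "set_size": r.set_size, "es": r.es, "nes": r.nes,
                    "pval": r.pval, "qval": r.qval,
                    "leading_edge": list(r.leading_edge),
                })
    return pd.DataFrame(rows, columns=[
        "level", "contrast", "name", "set_size", "es", "nes",
        "pval", "qval", "leading_edge",
    ])


@dataclass
class StratifiedResult:
    """Everything one stratified analysis produced."""

    connectivity: ConnectivityMatrix
    compound: dict[str, list[EnrichmentResult]]
    moa: dict[str, list[EnrichmentResult]]
    target: dict[str, list[EnrichmentResult]]
    compound_scores: dict[str, dict[str, float]]
    activation: ActivationMatrix | None
    table: pd.DataFrame
    manifest: dict[str, object] = field(default_factory=dict)

    # convenience for the plotting layer
    def ranked_list(self, contrast: str) -> RankedList:
        rho = self.connectivity.to_frame()[contrast]
        ok = np.isfinite(rho.to_numpy())
        return RankedList(list(rho.index[ok]), rho.to_numpy()[ok])


def _checksum(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def run_stratified_analysis(
    query: QueryMatrix,
    ref: ReferenceDatabase,
    ann: AnnotationTable | None = None,
    min_overlap: int = 15,
    min_experiments: int = DEFAULT_MIN_EXPERIMENTS,
    min_set_size: int = DEFAULT_MIN_SET_SIZE,
    weight_exponent: float = 1.0,
    permutations: int = 1000,
    random_state: int = 0,
    top_n: int = 15,
    q_cap: float = 1.0,
) -> StratifiedResult:
    """Run connectivity -> compound -> MoA/target in order.

    Thin functional wrapper over :class:`cmapmeta.mapper.ConnectivityMapper`;
    see that class for the estimator interface.
    """
    from .mapper import ConnectivityMapper

    mapper = ConnectivityMapper(
        min_overlap=min_overlap, min_experiments=min_experiments,
        min_set_size=min_set_size, weight_exponent=weight_exponent,
        permutations=permutations, random_state=random_state,
        top_n=top_n, q_cap=q_cap,
    )
    return mapper.fit(ref, ann).analyze(query)
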