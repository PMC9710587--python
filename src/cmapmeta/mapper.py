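"""scikit-learn style estimator wrapping the full stratified analysis.

``ConnectivityMapper`` is fitted on a perturbation reference (and optional
drug annotation) and then transforms query signatures into enrichment
tables: Spearman connectivities per experiment, GSEA-pooled compound scores,
and second-level MoA / target scores. It composes with sklearn tooling
(``get_params`` / ``set_params``, ``clone``) like any transformer whose
output is a DataFrame.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from . import __version__
from .connectivity import compute_connectivity
from .io import AnnotationTable, QueryMatrix, ReferenceDatabase
from .meta import (
    StratifiedResult,
    _checksum,
    build_activation_matrix,
    build_perturbagen_sets,
    compound_enrichment,
    compound_scores_from_results,
    moa_enrichment,
    results_to_table,
    target_enrichment,
)

__all__ = ["ConnectivityMapper"]


class ConnectivityMapper(BaseEstimator):
    """Map query expression signatures onto a drug-perturbation reference.

    Parameters
    ----------
    min_overlap : int, default=15
        Minimum gene intersection between query and reference.
    min_experiments : int, default=20
        Perturbagens with fewer experiments are excluded from stage 1;
        20 is the recommended floor for a stable pooled score.
    min_set_size : int, default=3
        Minimum number of scored drugs an MoA class or target gene needs
        at stage 2.
    weight_exponent : float, default=1.0
        Exponent of the weighted KS statistic (0 = classic unweighted KS).
    permutations : int, default=1000
        Random-set permutations per null distribution.
    random_state : int, default=0
        Seed for every permutation stream.
    top_n : int, default=15
        Drugs per contrast entering the activation matrix.
    q_cap : float, default=1.0
        q-value ceiling for activation-matrix eligibility (1.0 = no cap).

    Attributes
    ----------
    reference_ : ReferenceDatabase
        The fitted perturbation reference.
    annotation_ : AnnotationTable or None
        Drug annotation, when provided.
    perturbagen_sets_ : list of PerturbagenSet
        Drugs retained after the min-experiments filter, with their
        experiment sets.

    Examples
    --------
    >>> from cmapmeta.synthdata import generate_scenario
    >>> query, ref, ann, truth = generate_scenario(seed=0)
    >>> table = ConnectivityMapper(random_state=0).fit(ref, ann).transform(query)
    >>> set(table["level"]) == {"compound", "moa", "target"}
    True
    """

    def __init__(
        self,
        min_overlap: int = 15,
        min_experiments: int = 20,
        min_set_size: int = 3,
        weight_exponent: float = 1.0,
        permutations: int = 1000,
        random_state: int = 0,
        top_n: int = 15,
        q_cap: float = 1.0,
    ) -> None:
        self.min_overlap = min_overlap
        self.min_experiments = min_experiments
        self.min_set_size = min_set_size
        self.weight_exponent = weight_exponent
        self.permutations = permutations
        self.random_state = random_state
        self.top_n = top_n
        self.q_cap = q_cap

    def fit(
        self,
        reference: ReferenceDatabase,
        annotation: AnnotationTable | None = None,
    ) -> "ConnectivityMapper":
        """Bind a perturbation reference (X) and optional drug annotation (y)."""
        if not isinstance(reference, ReferenceDatabase):
            raise TypeError("reference must be a ReferenceDatabase")
        if reference.n_experiments == 0:
            raise ValueError("reference contains no experiments")
        self.reference_ = reference
        self.annotation_ = annotation
        self.perturbagen_sets_ = build_perturbagen_sets(
            reference, self.min_experiments
        )
        return self

    def analyze(self, query: QueryMatrix) -> StratifiedResult:
        """Full stratified analysis of one query matrix.

        Runs, in order: connectivity (Spearman rho per experiment and
        contrast), compound enrichment (NES per retained drug), and — when
        an annotation is fitted — MoA and target enrichment on the drug
        ranking. Aborts with a stage-labeled error on the first failure.
        """
        check_is_fitted(self, "reference_")
        try:
            conn = compute_connectivity(query, self.reference_, self.min_overlap)
        except Exception as exc:
            raise RuntimeError(f"[connectivity] {exc}") from exc
        try:
            compound = compound_enrichment(
                conn, self.perturbagen_sets_,
                weight_exponent=self.weight_exponent,
                permutations=self.permutations,
                random_state=self.random_state,
            )
        except Exception as exc:
            raise RuntimeError(f"[compound] {exc}") from exc
        scores = compound_scores_from_results(compound)

        moa: dict = {}
        target: dict = {}
        if self.annotation_ is not None:
            try:
                moa = moa_enrichment(
                    scores, self.annotation_,
                    weight_exponent=self.weight_exponent,
                    permutations=self.permutations,
                    random_state=self.random_state,
                    min_size=self.min_set_size,
                )
                target = target_enrichment(
                    scores, self.annotation_,
                    weight_exponent=self.weight_exponent,
                    permutations=self.permutations,
                    random_state=self.random_state,
                    min_size=self.min_set_size,
                )
            except Exception as exc:
                raise RuntimeError(f"[moa/target] {exc}") from exc

        activation = build_activation_matrix(
            compound, self.top_n, self.q_cap
        ) if compound else None

        table = results_to_table(
            {"compound": compound, "moa": moa, "target": target}
        )
        manifest = {
            "package_version": __version__,
            "n_genes_query": query.n_genes,
            "n_contrasts": query.n_contrasts,
            "n_genes_reference": self.reference_.n_genes,
            "n_experiments": self.reference_.n_experiments,
            "n_drugs_retained": len(self.perturbagen_sets_),
            "n_genes_used": conn.n_genes_used,
            "query_checksum": _checksum(query.values),
            "reference_checksum": _checksum(self.reference_.values),
            **{k: v for k, v in self.get_params().items()},
        }
        return StratifiedResult(
            connectivity=conn, compound=compound, moa=moa, target=target,
            compound_scores=scores, activation=activation, table=table,
            manifest=manifest,
        )

    def transform(self, query: QueryMatrix) -> pd.DataFrame:
        """Return the flat enrichment result table for a query matrix."""
        return self.analyze(query).table

    def fit_transform(
        self,
        reference: ReferenceDatabase,
        annotation: AnnotationTable | None = None,
        *,
        query: QueryMatrix,
    ) -> pd.DataFrame:
        return self.fit(reference, annotation).transform(query)
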