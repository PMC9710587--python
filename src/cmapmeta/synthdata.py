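"""Synthetic perturbation scenarios with planted ground truth.

Emulates the structure of a landmark-gene perturbation catalogue (about a
thousand genes, tens of drugs, tens of experiments per drug, MoA classes and
target annotations) so that every stage of the stratified analysis is
testable without any external download.

Signal model
------------
The query signature is i.i.d. standard normal per gene (and contrast).
Experiments of an *inactive* drug are i.i.d. Normal(0, noise_sd).
Experiments of an *active* drug with signed strength s mix the first query
contrast into fresh noise::

    x = s * query + sqrt(1 - s^2) * Normal(0, noise_sd)

With noise_sd = 1 this gives a bivariate-normal Pearson correlation of
exactly s between an active experiment and the query, hence an expected
Spearman of (6/pi) * asin(s/2) — slightly attenuated below s (about 0.48
for s = 0.5). Tests against planted signal use this corrected expectation.

Active drugs share one MoA label and one target gene; the remaining drugs
draw their labels round-robin from small pools, so every decoy MoA/target
class has enough members to be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import (
    AnnotationTable,
    QueryMatrix,
    ReferenceDatabase,
    write_query,
    write_reference,
)

__all__ = [
    "ScenarioTruth",
    "generate_scenario",
    "generate_null_scenario",
    "expected_spearman",
    "write_scenario",
]

ACTIVE_MOA = "planted-moa"
ACTIVE_TARGET = "PLANTED1"


@dataclass
class ScenarioTruth:
    """Planted ground truth of a generated scenario."""

    active_drugs: dict[str, float]  # drug -> signed strength in [-1, 1]
    active_moa: str | None
    active_target: str | None
    seed: int
    params: dict[str, float | int] = field(default_factory=dict)


def expected_spearman(pearson: float) -> float:
    """Population Spearman of a bivariate normal with Pearson correlation r."""
    return float(6.0 / np.pi * np.arcsin(pearson / 2.0))


def generate_scenario(
    n_genes: int = 1000,
    n_drugs: int = 50,
    experiments_per_drug: int = 25,
    n_active: int = 3,
    strength: float = 0.5,
    noise_sd: float = 1.0,
    n_contrasts: int = 1,
    n_moa_pool: int = 8,
    n_target_pool: int = 8,
    seed: int = 0,
) -> tuple[QueryMatrix, ReferenceDatabase, AnnotationTable, ScenarioTruth]:
    """Generate (query, reference, annotation, truth) with planted signal.

    The first ``n_active`` drugs are active with the given signed
    ``strength`` against the first query contrast; they share the MoA label
    ``planted-moa`` and the target gene ``PLANTED1``. Deterministic given
    the seed.
    """
    if not 0 <= n_active < n_drugs:
        raise ValueError("need 0 <= n_active < n_drugs")
    if abs(strength) > 1:
        raise ValueError("|strength| must be <= 1")
    if n_genes < 2 or experiments_per_drug < 1 or n_contrasts < 1:
        raise ValueError("invalid scenario sizes")
    rng = np.random.default_rng(seed)

    gene_ids = [f"G{i:04d}" for i in range(1, n_genes + 1)]
    contrast_names = [f"contrast{c + 1}" for c in range(n_contrasts)]
    query_values = rng.standard_normal((n_genes, n_contrasts))

    drugs = [f"drug{j:02d}" for j in range(1, n_drugs + 1)]
    active = drugs[:n_active]

    n_exp = n_drugs * experiments_per_drug
    values = rng.normal(0.0, noise_sd, size=(n_genes, n_exp))
    experiment_ids: list[str] = []
    col = 0
    planted = query_values[:, 0]
    mix = np.sqrt(1.0 - strength**2)
    for drug in drugs:
        for k in range(experiments_per_drug):
            experiment_ids.append(f"{drug}@exp{k + 1:03d}")
            if drug in active and strength != 0.0:
                values[:, col] = strength * planted + mix * values[:, col]
            col += 1
    ref = ReferenceDatabase(gene_ids, values, experiment_ids)

    moa_pool = [f"moa-class-{m + 1:02d}" for m in range(n_moa_pool)]
    target_pool = [f"TGT{t + 1:02d}" for t in range(n_target_pool)]
    moa_labels: dict[str, set[str]] = {}
    target_genes: dict[str, set[str]] = {}
    for j, drug in enumerate(drugs):
        if drug in active:
            moa_labels[drug] = {ACTIVE_MOA}
            target_genes[drug] = {ACTIVE_TARGET}
        else:
            # offset decorrelates the two round-robin assignments
            moa_labels[drug] = {moa_pool[j % n_moa_pool]}
            target_genes[drug] = {target_pool[(j + 3) % n_target_pool]}
    ann = AnnotationTable(drugs, moa_labels, target_genes)

    truth = ScenarioTruth(
        active_drugs={d: strength for d in active},
        active_moa=ACTIVE_MOA if active else None,
        active_target=ACTIVE_TARGET if active else None,
        seed=seed,
        params={
            "n_genes": n_genes, "n_drugs": n_drugs,
            "experiments_per_drug": experiments_per_drug,
            "n_active": n_active, "strength": strength,
            "noise_sd": noise_sd, "n_contrasts": n_contrasts,
        },
    )
    query = QueryMatrix(gene_ids, query_values, contrast_names)
    return query, ref, ann, truth


def generate_null_scenario(
    n_genes: int = 1000,
    n_drugs: int = 50,
    experiments_per_drug: int = 25,
    noise_sd: float = 1.0,
    n_contrasts: int = 1,
    seed: int = 0,
    **kwargs,
) -> tuple[QueryMatrix, ReferenceDatabase, AnnotationTable, ScenarioTruth]:
    """A scenario without any planted signal (n_active = 0)."""
    return generate_scenario(
        n_genes=n_genes, n_drugs=n_drugs,
        experiments_per_drug=experiments_per_drug,
        n_active=0, strength=0.0, noise_sd=noise_sd,
        n_contrasts=n_contrasts, seed=seed, **kwargs,
    )


def write_scenario(
    query: QueryMatrix,
    ref: ReferenceDatabase,
    ann: AnnotationTable,
    truth: ScenarioTruth,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write the three standard input files plus a truth manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "query": outdir / "query.tsv",
        "reference": outdir / "reference.tsv",
        "annotation": outdir / "annotation.tsv",
        "truth": outdir / "truth.txt",
    }
    write_query(query, paths["query"])
    write_reference(ref, paths["reference"])
    with open(paths["annotation"], "w", encoding="utf-8") as fh:
        fh.write("drug\tmoa\ttarget\n")
        for d in ann.drugs:
            fh.write(
                f"{d}\t{'|'.join(sorted(ann.moa_labels[d]))}\t"
                f"{'|'.join(sorted(ann.target_genes[d]))}\n"
            )
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        fh.write(f"seed={truth.seed}\n")
        fh.write(f"active_moa={truth.active_moa or ''}\n")
        fh.write(f"active_target={truth.active_target or ''}\n")
        for d, s in truth.active_drugs.items():
            fh.write(f"active_drug={d}:{s}\n")
        for k, v in truth.params.items():
            fh.write(f"{k}={v}\n")
    return paths
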