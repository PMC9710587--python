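"""Two-stage meta-analysis: perturbagen sets, compound/MoA/target scores."""

import numpy as np
import pandas as pd
import pytest

from cmapmeta import ConnectivityMapper
from cmapmeta.connectivity import ConnectivityMatrix, compute_connectivity
from cmapmeta.io import AnnotationTable, QueryMatrix, ReferenceDatabase
from cmapmeta.meta import (
    build_activation_matrix,
    build_perturbagen_sets,
    compound_enrichment,
    compound_scores_from_results,
    moa_enrichment,
    run_stratified_analysis,
    target_enrichment,
)
from cmapmeta.synthdata import generate_scenario


def _toy_ref(counts: dict[str, int], n_genes: int = 25, seed: int = 0):
    rng = np.random.default_rng(seed)
    headers = [f"{d}@e{k}" for d, n in counts.items() for k in range(n)]
    return ReferenceDatabase(
        [f"G{i}" for i in range(n_genes)],
        rng.standard_normal((n_genes, len(headers))),
        headers,
    )


class TestBuildPerturbagenSets:
    def test_min_experiments_boundary(self):
        ref = _toy_ref({"a": 19, "b": 20, "c": 21})
        names = {s.drug for s in build_perturbagen_sets(ref, 20)}
        assert names == {"b", "c"}  # 19 excluded, exactly 20 retained

    def test_min_one_keeps_everything(self):
        ref = _toy_ref({"a": 1, "b": 2, "c": 3})
        assert len(build_perturbagen_sets(ref, 1)) == 3

    def test_nothing_retained_warns(self):
        ref = _toy_ref({"a": 2})
        with pytest.warns(UserWarning, match=">= 20"):
            assert build_perturbagen_sets(ref, 20) == []


class TestCompoundEnrichment:
    def _planted_conn(self, n_exp=500, n_top=25, seed=0):
        """Connectivities where one drug's experiments hold the top ranks."""
        rng = np.random.default_rng(seed)
        rho = rng.uniform(-0.5, 0.5, n_exp)
        rho[:n_top] = rng.uniform(0.8, 0.99, n_top)
        headers = [f"hit@e{k}" for k in range(n_top)]
        headers += [f"d{k % 19}@e{k}" for k in range(n_top, n_exp)]
        conn = ConnectivityMatrix(rho[:, None], headers, ["c1"], 900)
        ref = ReferenceDatabase(
            ["G1", "G2"], np.zeros((2, n_exp)), headers
        )
        return conn, build_perturbagen_sets(ref, 20)

    def test_drug_occupying_top_ranks_wins(self):
        conn, sets = self._planted_conn()
        res = compound_enrichment(conn, sets, permutations=1000,
                                  random_state=0)["c1"]
        assert res[0].name == "hit"
        assert res[0].qval < 0.05

    def test_negated_connectivities_flip_the_winner_to_last(self):
        conn, sets = self._planted_conn()
        neg = ConnectivityMatrix(-conn.rho, conn.experiment_ids,
                                 conn.contrast_names, conn.n_genes_used)
        res = compound_enrichment(neg, sets, permutations=1000,
                                  random_state=0)["c1"]
        assert res[-1].name == "hit" and res[-1].nes < 0

    def test_random_subset_drug_is_null(self, rng):
        hits = 0
        for rep in range(20):
            r = np.random.default_rng(rep)
            rho = r.uniform(-1, 1, 400)
            headers = [f"d{k % 16}@e{k}" for k in range(400)]
            conn = ConnectivityMatrix(rho[:, None], headers, ["c1"], 500)
            ref = ReferenceDatabase(["G1"], np.zeros((1, 400)), headers)
            res = compound_enrichment(conn, build_perturbagen_sets(ref, 20),
                                      permutations=500, random_state=rep)["c1"]
            hits += any(x.qval < 0.05 for x in res)
        assert hits <= 2  # significant in at most 10% of null replicates

    def test_missing_rho_dropped_and_empty_contrast_skipped(self):
        rho = np.array([[0.5, np.nan], [0.2, np.nan], [np.nan, np.nan],
                        [-0.1, np.nan]] * 10)
        headers = [f"d{k % 2}@e{k}" for k in range(40)]
        conn = ConnectivityMatrix(rho, headers, ["c1", "c2"], 100)
        ref = ReferenceDatabase(["G1"], np.zeros((1, 40)), headers)
        sets = build_perturbagen_sets(ref, 10)
        with pytest.warns(UserWarning, match="c2"):
            res = compound_enrichment(conn, sets, permutations=200,
                                      random_state=0)
        assert "c2" not in res and "c1" in res


class TestStageTwo:
    def _scores(self, ordering: list[str]) -> dict[str, dict[str, float]]:
        n = len(ordering)
        return {"c1": {d: float(n - i) for i, d in enumerate(ordering)}}

    def test_moa_shared_by_top_drugs_ranks_first(self):
        drugs = [f"d{k}" for k in range(50)]
        ann = AnnotationTable(
            drugs,
            {d: ({"top-moa"} if k < 5 else {f"m{k % 5}"})
             for k, d in enumerate(drugs)},
            {d: set() for d in drugs},
        )
        res = moa_enrichment(self._scores(drugs), ann, permutations=500,
                             random_state=0)["c1"]
        assert res[0].name == "top-moa" and res[0].nes > 0

    def test_target_planted_at_bottom_is_most_negative(self):
        drugs = [f"d{k}" for k in range(40)]
        targets = {d: ({"BOT"} if k >= 36 else {f"T{k % 4}"})
                   for k, d in enumerate(drugs)}
        ann = AnnotationTable(drugs, {d: set() for d in drugs}, targets)
        res = target_enrichment(self._scores(drugs), ann, permutations=500,
                                random_state=0)["c1"]
        assert res[-1].name == "BOT" and res[-1].nes < 0

    def test_min_size_excludes_small_classes(self):
        drugs = [f"d{k}" for k in range(12)]
        ann = AnnotationTable(
            drugs,
            {d: ({"pair"} if k < 2 else {"bulk"}) for k, d in enumerate(drugs)},
            {d: set() for d in drugs},
        )
        res = moa_enrichment(self._scores(drugs), ann, permutations=200,
                             random_state=0, min_size=3)["c1"]
        assert {r.name for r in res} == {"bulk"}

    def test_unannotated_drug_still_occupies_a_rank(self):
        drugs = [f"d{k}" for k in range(10)]
        moa = {d: ({"m"} if k < 9 else set()) for k, d in enumerate(drugs)}
        ann = AnnotationTable(drugs, moa, {d: set() for d in drugs})
        res = moa_enrichment(self._scores(drugs), ann, permutations=200,
                             random_state=0)["c1"]
        # set 'm' has 9 members on a 10-item universe (not 9 of 9, which
        # would be rejected as covering the list)
        assert res[0].set_size == 9

    def test_disjoint_annotation_raises(self):
        ann = AnnotationTable(["other"], {"other": {"m"}}, {"other": set()})
        with pytest.raises(ValueError, match="no overlap"):
            moa_enrichment(self._scores([f"d{k}" for k in range(5)]), ann,
                           permutations=200)

    def test_shuffled_annotation_destroys_enrichment(self):
        """Negative control: permuting drug labels breaks the planted MoA."""
        hits = 0
        for rep in range(20):
            rng = np.random.default_rng(rep)
            drugs = [f"d{k}" for k in range(50)]
            scores = {"c1": {d: float(v) for d, v in
                             zip(drugs, rng.standard_normal(50))}}
            shuffled = list(drugs)
            rng.shuffle(shuffled)
            ann = AnnotationTable(
                shuffled,
                {d: ({"planted"} if k < 5 else {f"m{k % 5}"})
                 for k, d in enumerate(shuffled)},
                {d: set() for d in drugs},
            )
            res = moa_enrichment(scores, ann, permutations=500,
                                 random_state=rep)["c1"]
            planted = next(r for r in res if r.name == "planted")
            hits += planted.qval < 0.05
        assert hits <= 2


class TestActivationMatrix:
    def _results(self, nes_by_drug, contrast="c1"):
        from cmapmeta.gsea import EnrichmentResult

        return {contrast: [
            EnrichmentResult(d, np.sign(v) * 0.5, v, 0.05, 0.1, 20)
            for d, v in nes_by_drug.items()
        ]}

    def test_single_contrast_top_n(self):
        res = self._results({f"d{k}": float(k - 10) for k in range(20)})
        am = build_activation_matrix(res, top_n=10)
        assert am.values.shape == (10, 1)

    def test_values_scaled_to_unit_interval_and_signs_kept(self):
        res = self._results({"a": 2.0, "b": -4.0, "c": 1.0})
        am = build_activation_matrix(res, top_n=3)
        assert np.abs(am.values).max() == pytest.approx(1.0)
        frame = am.to_frame()
        assert frame.loc["b", "c1"] == pytest.approx(-1.0)
        assert frame.loc["a", "c1"] == pytest.approx(0.5)

    def test_identical_contrasts_give_identical_columns(self):
        base = {f"d{k}": float(k - 3) for k in range(8)}
        res = {**self._results(base, "c1"), **self._results(base, "c2")}
        am = build_activation_matrix(res, top_n=5)
        np.testing.assert_allclose(am.values[:, 0], am.values[:, 1])

    def test_rows_ordered_by_descending_mean(self):
        res = self._results({"a": 1.0, "b": 3.0, "c": -2.0})
        am = build_activation_matrix(res, top_n=3)
        assert am.drugs == ["b", "a", "c"]


class TestRunStratifiedAnalysis:
    def test_recovers_planted_truth_end_to_end(self, small_result):
        res, truth = small_result
        comp = res.compound["contrast1"]
        assert comp[0].name in truth.active_drugs
        assert res.moa["contrast1"][0].name == truth.active_moa
        assert res.target["contrast1"][0].name == truth.active_target

    def test_rerun_with_same_seed_is_identical(self, small_scenario):
        query, ref, ann, _ = small_scenario
        kw = dict(min_experiments=20, permutations=300, random_state=5)
        t1 = run_stratified_analysis(query, ref, ann, **kw).table
        t2 = run_stratified_analysis(query, ref, ann, **kw).table
        pd.testing.assert_frame_equal(t1, t2)

    def test_stage_separability(self, small_result):
        """Stage-2 input scores equal the compound-level table entries."""
        res, _ = small_result
        table = res.table
        comp = table[(table["level"] == "compound")
                     & (table["contrast"] == "contrast1")]
        for _, row in comp.iterrows():
            if np.isfinite(row["nes"]):
                assert res.compound_scores["contrast1"][row["name"]] == row["nes"]

    def test_result_table_invariants(self, small_result):
        res, _ = small_result
        t = res.table
        ok = np.isfinite(t["nes"])
        assert (np.sign(t.loc[ok, "nes"]) == np.sign(t.loc[ok, "es"])).all()
        assert ((t["qval"] >= t["pval"] - 1e-12) | ~np.isfinite(t["qval"])).all()
        assert t["pval"].between(0, 1).all()
        assert set(t["level"]) == {"compound", "moa", "target"}

    def test_without_annotation_compound_only(self, small_scenario):
        query, ref, _, _ = small_scenario
        res = run_stratified_analysis(query, ref, None, permutations=200,
                                      random_state=0)
        assert res.moa == {} and res.target == {}
        assert set(res.table["level"]) == {"compound"}

    def test_monotone_response_to_signal_strength(self):
        """A stronger planted correlation never worsens the planted rank."""
        mean_rank = []
        for strength in (0.0, 0.35, 0.7):
            ranks = []
            for seed in range(5):
                q, ref, ann, tr = generate_scenario(
                    n_genes=200, n_drugs=10, experiments_per_drug=20,
                    n_active=1, strength=strength, seed=seed,
                )
                res = run_stratified_analysis(
                    q, ref, None, permutations=300, random_state=seed,
                )
                comp = res.compound["contrast1"]
                names = [r.name for r in comp]
                active = next(iter(tr.active_drugs)) if tr.active_drugs \
                    else "drug01"
                ranks.append(names.index(active) + 1)
            mean_rank.append(np.mean(ranks))
        assert mean_rank[2] <= mean_rank[1] <= mean_rank[0] + 1e-9

    def test_reversal_symmetry(self, small_scenario):
        query, ref, ann, truth = small_scenario
        kw = dict(min_experiments=20, permutations=300, random_state=3)
        fwd = run_stratified_analysis(query, ref, None, **kw)
        rev = run_stratified_analysis(query.negated(), ref, None, **kw)
        top_fwd = fwd.compound["contrast1"][0].name
        bottom_rev = rev.compound["contrast1"][-1].name
        assert top_fwd in truth.active_drugs
        assert bottom_rev in truth.active_drugs

    def test_estimator_contract(self, small_scenario):
        from sklearn.base import clone

        query, ref, ann, _ = small_scenario
        mapper = ConnectivityMapper(permutations=200, random_state=1)
        cloned = clone(mapper)
        assert cloned.get_params() == mapper.get_params()
        table = mapper.fit(ref, ann).transform(query)
        assert isinstance(table, pd.DataFrame) and len(table) > 0
        assert hasattr(mapper, "perturbagen_sets_")

    def test_unfitted_estimator_refuses_transform(self, small_scenario):
        from sklearn.exceptions import NotFittedError

        query = small_scenario[0]
        with pytest.raises(NotFittedError):
            ConnectivityMapper().transform(query)

    def test_stage_labelled_error_on_bad_overlap(self, small_scenario):
        _, ref, ann, _ = small_scenario
        bad_query = QueryMatrix(["X1", "X2"], np.array([[1.0], [2.0]]), ["c"])
        mapper = ConnectivityMapper().fit(ref, ann)
        with pytest.raises(RuntimeError, match=r"\[connectivity\]"):
            mapper.analyze(bad_query)
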