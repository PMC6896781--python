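"""GO DAG handling, evidence filtering, distinct-function counting,
gained-term detection, category totals and enrichment statistics."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tseen.function_gain import (ASPECTS, EvidenceFilter, GoAnnotation,
                                 GoDag, GoError, categorize_counts,
                                 count_distinct_functions, detect_gains,
                                 enrich, filter_evidence, parse_obo)


def make_dag(parents, aspect="biological_process", obsolete=()):
    terms = {t: {"name": t, "aspect": aspect, "obsolete": t in obsolete}
             for t in set(parents) | {p for ps in parents.values() for p in ps}}
    return GoDag(terms=terms, parents={t: parents.get(t, []) for t in terms})


class TestDag:
    def test_chain_ancestors(self):
        dag = make_dag({"A": ["B"], "B": ["C"], "C": []})
        assert dag.ancestors("A") == {"B", "C"}

    def test_cycle_rejected(self):
        with pytest.raises(GoError, match="cycle"):
            make_dag({"A": ["B"], "B": ["A"]})

    def test_dangling_parent_rejected(self):
        with pytest.raises(GoError, match="dangling"):
            GoDag(terms={"A": {"name": "A", "aspect": "biological_process",
                               "obsolete": False}},
                  parents={"A": ["GHOST"]})

    def test_obsolete_terms_excluded_from_closure(self):
        dag = make_dag({"A": ["B"], "B": ["C"], "C": []}, obsolete={"B"})
        assert dag.ancestors("A") == {"C"}

    def test_obo_round_trip(self, tmp_path):
        from tseen.simulate import toy_ontology, write_obo

        onto = toy_ontology()
        path = tmp_path / "toy.obo"
        write_obo(onto, str(path))
        dag = parse_obo(str(path))
        assert set(dag.terms) == set(onto["terms"])
        for tid, (name, aspect) in onto["terms"].items():
            assert dag.terms[tid]["name"] == name
            assert dag.terms[tid]["aspect"] == aspect
            assert dag.parents[tid] == sorted(onto["parents"][tid])

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_ancestors_agree_with_brute_force_reachability(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 100))
        names = [f"T{i}" for i in range(n)]
        parents = {names[i]: sorted({names[int(j)] for j in
                                     rng.integers(i + 1, n,
                                                  size=rng.integers(0, 3))})
                   if i < n - 1 else [] for i in range(n)}
        dag = make_dag(parents)

        def reach(t):
            seen = set()
            stack = list(parents[t])
            while stack:
                u = stack.pop()
                if u not in seen:
                    seen.add(u)
                    stack.extend(parents[u])
            return seen

        for t in names:
            assert dag.ancestors(t) == reach(t)


ANNS = [
    GoAnnotation("g1", "GO:1", "IDA", "molecular_function"),
    GoAnnotation("g1", "GO:1", "IMP", "molecular_function"),
    GoAnnotation("g1", "GO:2", "IEA", "molecular_function"),
    GoAnnotation("g2", "GO:3", "TAS", "biological_process"),
]


class TestEvidence:
    def test_experimental_keeps_ida(self):
        kept = filter_evidence(ANNS, EvidenceFilter("experimental"))
        assert all(a.evidence_code in ("IDA", "IMP") for a in kept)

    def test_experimental_drops_iea(self):
        kept = filter_evidence(ANNS, EvidenceFilter("experimental"))
        assert not any(a.evidence_code == "IEA" for a in kept)

    def test_all_mode_is_identity(self):
        assert filter_evidence(ANNS, EvidenceFilter("all")) == ANNS

    def test_unknown_code_dropped_not_fatal(self, caplog):
        import logging

        anns = [GoAnnotation("g", "GO:1", "WTF", "molecular_function")]
        with caplog.at_level(logging.WARNING):
            assert filter_evidence(anns, EvidenceFilter("experimental")) == []
        assert any("WTF" in r.message for r in caplog.records)


class TestDistinctCounting:
    def test_repeated_evidence_counts_once(self):
        assert count_distinct_functions("g1", ANNS, "molecular_function") == 2

    def test_two_terms_count_two(self):
        anns = [GoAnnotation("g", "GO:1", "IDA", "biological_process"),
                GoAnnotation("g", "GO:2", "IMP", "biological_process")]
        assert count_distinct_functions("g", anns, "biological_process") == 2

    def test_unannotated_gene_counts_zero(self):
        assert count_distinct_functions("nobody", ANNS,
                                        "biological_process") == 0


class TestDetectGains:
    def dag(self):
        return make_dag({"GO:1": [], "GO:2": [], "GO:3": []})

    def test_reference_only_term_is_gained(self):
        anns = [GoAnnotation("f", "GO:1", "IDA", "biological_process"),
                GoAnnotation("r", "GO:1", "IDA", "biological_process"),
                GoAnnotation("r", "GO:2", "IMP", "biological_process")]
        rec = detect_gains("f", "r", anns, self.dag())
        assert rec.gained_terms["biological_process"] == {"GO:2"}
        assert rec.counts["biological_process"] == (1, 2)

    def test_identical_sets_gain_nothing(self):
        anns = [GoAnnotation("f", "GO:1", "IDA", "biological_process"),
                GoAnnotation("r", "GO:1", "IEA", "biological_process")]
        rec = detect_gains("f", "r", anns, self.dag())
        assert not rec.all_gained()

    def test_unknown_term_is_error(self):
        anns = [GoAnnotation("f", "GO:99", "IDA", "biological_process")]
        with pytest.raises(GoError):
            detect_gains("f", "r", anns, self.dag())

    def test_gain_asymmetry_partitions_symmetric_difference(self):
        anns = [GoAnnotation("f", "GO:1", "IDA", "biological_process"),
                GoAnnotation("f", "GO:3", "IDA", "biological_process"),
                GoAnnotation("r", "GO:2", "IMP", "biological_process"),
                GoAnnotation("r", "GO:3", "IMP", "biological_process")]
        fwd = detect_gains("f", "r", anns, self.dag()).all_gained()
        rev = detect_gains("r", "f", anns, self.dag()).all_gained()
        assert fwd == {"GO:2"}
        assert rev == {"GO:1"}
        assert not fwd & rev

    def test_detected_gains_equal_simulated_truth(self, dataset):
        from tseen.pipeline import _dag_from_toy

        dag = _dag_from_toy(dataset.ontology)
        anns = [GoAnnotation(*row) for row in dataset.annotations]
        assert dataset.history.truth_gained_terms
        for (f, r), truth in dataset.history.truth_gained_terms.items():
            rec = detect_gains(f, r, anns, dag)
            assert rec.all_gained() == truth


class TestCategorize:
    def dag(self):
        return make_dag({"dev_root": [], "sig_root": [],
                         "leaf_dev": ["mid"], "mid": ["dev_root"],
                         "leaf_both": ["mid", "sig_root"],
                         "leaf_other": []})

    def test_descendant_counts_under_category(self):
        totals = categorize_counts({"g": {"leaf_dev"}},
                                   {"development": ["dev_root"]}, self.dag())
        assert totals == {"development": 1}

    def test_multi_parent_term_counts_in_both(self):
        cats = {"development": ["dev_root"], "signaling": ["sig_root"]}
        totals = categorize_counts({"g": {"leaf_both"}}, cats, self.dag())
        assert totals == {"development": 1, "signaling": 1}

    def test_empty_sample_zero_totals(self):
        totals = categorize_counts({}, {"development": ["dev_root"]},
                                   self.dag())
        assert totals == {"development": 0}

    def test_unknown_root_is_error(self):
        with pytest.raises(GoError):
            categorize_counts({}, {"x": ["GHOST"]}, self.dag())

    def test_totals_sum_over_genes(self):
        totals = categorize_counts({"g1": {"leaf_dev"}, "g2": {"leaf_dev"}},
                                   {"development": ["dev_root"]}, self.dag())
        assert totals == {"development": 2}


def brute_force_overrep_p(N, K, n, k):
    """P(X >= k) by exhaustive enumeration of all size-n study subsets."""
    hits = 0
    total = 0
    items = list(range(N))
    annotated = set(items[:K])
    for subset in itertools.combinations(items, n):
        total += 1
        if len(annotated & set(subset)) >= k:
            hits += 1
    return hits / total


class TestEnrich:
    def flat_dag(self, n_terms=6):
        return make_dag({f"GO:{i}": [] for i in range(n_terms)})

    def run(self, study, background, gene_terms):
        anns = [GoAnnotation(g, t, "IEA", "biological_process")
                for g, ts in gene_terms.items() for t in ts]
        return enrich(study, background, anns, self.flat_dag())

    def test_fully_enriched_term_closed_form(self):
        background = {f"g{i}" for i in range(20)}
        study = {f"g{i}" for i in range(5)}
        gene_terms = {f"g{i}": ["GO:1"] for i in range(5)}
        res = self.run(study, background, gene_terms)[0]
        assert res.fold_enrichment == pytest.approx(4.0)
        assert res.p_raw == pytest.approx(1 / math.comb(20, 5))

    def test_null_term_fold_one_p_large(self):
        background = {f"g{i}" for i in range(8)}
        study = {"g0", "g1", "g2", "g3"}
        gene_terms = {g: ["GO:1"] for g in ("g0", "g1", "g4", "g5")}
        res = self.run(study, background, gene_terms)[0]
        assert res.fold_enrichment == pytest.approx(1.0)
        assert res.p_raw >= 0.5

    @pytest.mark.parametrize("N,K,n,k_genes", [
        (10, 4, 5, 3), (12, 6, 4, 4), (9, 3, 3, 1), (11, 5, 6, 2)])
    def test_p_matches_exhaustive_enumeration(self, N, K, n, k_genes):
        background = {f"g{i}" for i in range(N)}
        study = {f"g{i}" for i in range(n)}
        # annotate k_genes of the study and K - k_genes outside it
        annotated = [f"g{i}" for i in range(k_genes)] + \
            [f"g{i}" for i in range(n, n + K - k_genes)]
        gene_terms = {g: ["GO:1"] for g in annotated}
        res = self.run(study, background, gene_terms)[0]
        assert res.k == k_genes and res.K == K
        expected = brute_force_overrep_p(N, K, n, k_genes)
        assert res.p_raw == pytest.approx(expected, rel=1e-9)

    def test_study_outside_background_is_error(self):
        with pytest.raises(GoError):
            self.run({"alien"}, {"g0"}, {"g0": ["GO:1"]})

    def test_bh_q_values_monotone_in_sorted_p(self):
        rng = np.random.default_rng(0)
        background = {f"g{i}" for i in range(30)}
        study = {f"g{i}" for i in range(10)}
        gene_terms = {f"g{i}": [f"GO:{j}" for j in
                                rng.integers(0, 6, size=rng.integers(1, 4))]
                      for i in range(30)}
        res = self.run(study, background, gene_terms)
        ps = [r.p_raw for r in res]
        qs = [r.q_bh for r in res]
        assert ps == sorted(ps)
        assert all(q2 >= q1 - 1e-12 for q1, q2 in zip(qs, qs[1:]))
        assert all(q >= p for p, q in zip(ps, qs))

    def test_propagated_annotations_reach_ancestors(self):
        dag = make_dag({"leaf": ["root"], "root": []})
        anns = [GoAnnotation("g0", "leaf", "IDA", "biological_process")]
        res = enrich({"g0"}, {"g0", "g1"}, anns, dag)
        assert {r.term_id for r in res} == {"leaf", "root"}
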