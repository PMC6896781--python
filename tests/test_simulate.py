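"""Generator behavior: event-free limits, truth-table consistency,
divergence monotonicity, determinism, and the statistical contracts of the
GO-gain and expression emitters."""

import json
from pathlib import Path

import numpy as np
import pytest
from scipy.stats import chisquare

from tseen import expression as expr
from tseen.homology import read_fasta
from tseen.simulate import (CATEGORY_ROOTS, DEFAULT_TREE, SimConfig,
                            SimulationError, SpeciesTreeSpec,
                            _category_leaf_sets, emit_expression, emit_go,
                            emit_proteomes, nb_draws, ontology_leaves,
                            simulate_dataset, simulate_families, toy_ontology)

QUIET = SimConfig(n_root_families=1, birth_rate=0.0, dup_rate=0.0,
                  loss_rate=0.0)


def scaled_tree(factor):
    import re

    nwk = re.sub(r":(\d+\.\d+)",
                 lambda m: f":{float(m.group(1)) * factor:.6f}",
                 DEFAULT_TREE.newick_text)
    return SpeciesTreeSpec(nwk, "outgroup", "focal", "reference", ("witness",))


class TestFamilies:
    def test_no_event_limit_one_gene_per_species(self):
        hist = simulate_families(DEFAULT_TREE, QUIET, seed=0)
        species = {g.species for g in hist.genes}
        assert species == {"outgroup", "focal", "reference", "witness"}
        assert len(hist.genes) == 4
        # all cross-species pairs are orthologs
        assert len(hist.truth_ortholog_pairs) == 6

    def test_post_outgroup_birth_absent_from_outgroup(self):
        cfg = SimConfig(n_root_families=5, dup_rate=0.0, loss_rate=0.0)
        hist = simulate_families(DEFAULT_TREE, cfg, seed=3)
        outgroup_fams = {g.family_id for g in hist.genes
                         if g.species == "outgroup"}
        post = [g for g in hist.genes if g.species == "focal"
                and hist.truth_age[g.gene_id] == "post_outgroup_split"]
        assert post, "expected at least one post-split focal gene"
        for g in post:
            assert g.family_id not in outgroup_fams
            assert g.birth_branch != "root"

    def test_truth_age_consistent_with_outgroup_orthologs(self):
        """A focal gene is post-split exactly when it has no truth ortholog
        in the outgroup (no-loss regime)."""
        cfg = SimConfig(n_root_families=20, dup_rate=0.05, loss_rate=0.0)
        hist = simulate_families(DEFAULT_TREE, cfg, seed=5)
        outgroup = set(hist.genes_of("outgroup"))
        for g in hist.genes_of("focal"):
            has_og = any(hist.are_orthologs(g, o) for o in outgroup)
            expected = "pre_outgroup_split" if has_og else "post_outgroup_split"
            assert hist.truth_age[g] == expected

    def test_tseen_subset_of_post_split_focal_genes(self, dataset):
        hist = dataset.history
        for g in hist.truth_tseen:
            assert hist.truth_age[g] == "post_outgroup_split"

    def test_determinism_byte_identical(self):
        cfg = SimConfig(n_root_families=10)
        h1 = simulate_families(DEFAULT_TREE, cfg, seed=7)
        h2 = simulate_families(DEFAULT_TREE, cfg, seed=7)
        assert h1.to_json() == h2.to_json()

    def test_missing_tip_is_structured_error(self):
        with pytest.raises(SimulationError, match="nosuch"):
            SpeciesTreeSpec(DEFAULT_TREE.newick_text, "nosuch", "focal",
                            "reference", ("witness",))


class TestProteomes:
    def test_zero_divergence_identical_orthologs(self):
        tree = scaled_tree(0.0)
        hist = simulate_families(tree, QUIET, seed=0)
        prot = emit_proteomes(hist, tree, QUIET, seed=0)
        seqs = {sp: list(d.values())[0] for sp, d in prot.items()}
        assert len(set(seqs.values())) == 1

    def test_identity_decreases_with_divergence(self):
        cfg = SimConfig(n_root_families=100, birth_rate=0.0, dup_rate=0.0,
                        loss_rate=0.0)
        means = []
        for factor in (0.1, 0.6, 1.5):
            tree = scaled_tree(factor)
            hist = simulate_families(tree, cfg, seed=11)
            prot = emit_proteomes(hist, tree, cfg, seed=11)
            idents = []
            for fid in {g.family_id for g in hist.genes}:
                a = prot["focal"][f"focal|{fid}|1"]
                b = prot["reference"][f"reference|{fid}|1"]
                idents.append(np.mean([x == y for x, y in zip(a, b)]))
            means.append(np.mean(idents))
        assert means[0] > means[1] > means[2]

    def test_fasta_round_trip(self, tmp_path):
        cfg = SimConfig(n_root_families=5)
        hist = simulate_families(DEFAULT_TREE, cfg, seed=2)
        prot = emit_proteomes(hist, DEFAULT_TREE, cfg, seed=2,
                              outdir=str(tmp_path))
        for sp, seqs in prot.items():
            assert read_fasta(str(tmp_path / f"{sp}.faa")) == seqs

    def test_truncated_duplicates_are_shorter(self):
        cfg = SimConfig(n_root_families=30, dup_rate=0.6,
                        frac_truncated_duplicates=1.0)
        hist = simulate_families(DEFAULT_TREE, cfg, seed=1)
        prot = emit_proteomes(hist, DEFAULT_TREE, cfg, seed=1)
        trunc = [g for g in hist.genes if g.truncated]
        assert trunc, "expected truncated duplicate copies"
        for g in trunc:
            full = [len(prot[r.species][r.gene_id]) for r in hist.genes
                    if r.family_id == g.family_id and not r.truncated]
            if full:
                assert len(prot[g.species][g.gene_id]) < min(full)


class TestGo:
    def test_zero_gain_rate_empty_truth(self):
        cfg = SimConfig(n_root_families=10, gain_rate_reference_lineage=0.0)
        hist = simulate_families(DEFAULT_TREE, cfg, seed=4)
        emit_go(hist, cfg, seed=4)
        assert hist.truth_gained_terms
        assert all(not v for v in hist.truth_gained_terms.values())

    def test_unbiased_gains_match_base_category_frequencies(self):
        """With category_gain_bias = 1 the gained-term category split must
        match the leaf-pool frequencies (chi-square goodness of fit)."""
        cfg = SimConfig(n_root_families=300, birth_rate=0.0, dup_rate=0.0,
                        loss_rate=0.0, category_gain_bias=1.0,
                        gain_rate_reference_lineage=3.0, frac_tseen=1.0)
        hist = simulate_families(DEFAULT_TREE, cfg, seed=9)
        emit_go(hist, cfg, seed=9)
        onto = toy_ontology()
        dev = _category_leaf_sets(onto)["development"] & set(ontology_leaves(onto))
        n_leaves = len(ontology_leaves(onto))
        gained = [t for terms in hist.truth_gained_terms.values() for t in terms]
        assert len(gained) > 500
        n_dev = sum(t in dev for t in gained)
        expected = np.array([len(dev), n_leaves - len(dev)]) / n_leaves * len(gained)
        _stat, p = chisquare([n_dev, len(gained) - n_dev], expected)
        assert p > 1e-3

    def test_biased_gains_enrich_development(self, dataset):
        onto = dataset.ontology
        dev = _category_leaf_sets(onto)["development"]
        tseen = dataset.history.truth_tseen
        gained_tseen = [t for (f, _r), ts in
                        dataset.history.truth_gained_terms.items()
                        if f in tseen for t in ts]
        frac_dev_pool = len(dev & set(ontology_leaves(onto))) / len(
            ontology_leaves(onto))
        if gained_tseen:
            frac = np.mean([t in dev for t in gained_tseen])
            assert frac > frac_dev_pool

    def test_annotation_terms_exist_in_obo(self, dataset, tmp_path):
        from tseen.function_gain import parse_obo
        from tseen.simulate import write_obo

        write_obo(dataset.ontology, str(tmp_path / "toy.obo"))
        dag = parse_obo(str(tmp_path / "toy.obo"))
        for gene, term, _code, aspect in dataset.annotations:
            assert term in dag.terms
            assert dag.aspect(term) == aspect


class TestExpression:
    def test_tseen_genes_have_zero_normal_counts(self, dataset):
        assert dataset.truth_tseen
        for g in dataset.truth_tseen:
            assert dataset.counts.loc[g, "normal"] == 0

    def test_nb_moments_match_closed_form(self):
        rng = np.random.default_rng(0)
        draws = nb_draws(rng, mean=50.0, dispersion=5.0, size=10_000)
        assert abs(draws.mean() - 50.0) / 50.0 < 0.1
        var_expected = 50.0 + 50.0**2 / 5.0
        assert abs(draws.var() - var_expected) / var_expected < 0.1

    def test_no_planted_tseen_yields_no_candidates(self):
        cfg = SimConfig(n_root_families=15, frac_tseen=0.0)
        ds = simulate_dataset(config=cfg, seed=6)
        tpm = expr.normalize_tpm(ds.counts)
        states = expr.call_presence(tpm, ds.counts)
        assert expr.select_candidates(states) == set()


def test_dataset_outputs_byte_identical_across_reruns(tmp_path):
    """Identical seeds must give byte-identical FASTA/OBO/TSV/JSON files."""
    cfg = SimConfig(n_root_families=12)
    out = {}
    for name in ("a", "b"):
        d = tmp_path / name
        simulate_dataset(config=cfg, seed=13, outdir=str(d))
        out[name] = {p.name: p.read_bytes() for p in sorted(d.iterdir())}
    assert out["a"].keys() == out["b"].keys()
    for name in out["a"]:
        assert out["a"][name] == out["b"][name], f"{name} differs"
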