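"""End-to-end orchestration on synthetic (or pre-loaded) data.

Runs the full chain: simulate -> TPM/presence selection -> all-vs-all
protein search -> ortholog calls by both methods -> novelty and
TT_Rgr_EEN classification -> reference-ortholog mapping -> GO gain
detection -> flow summary and conservation test, and scores every stage
against the simulator's truth tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import expression as expr
from . import function_gain as fg
from . import homology, orthology, phylostrat, report
from .simulate import (CATEGORY_ROOTS, DEFAULT_TREE, SimConfig,
                       SpeciesTreeSpec, SyntheticDataset, simulate_dataset)

METHODS = ("rbh", "oma_like")


@dataclass
class PipelineResult:
    dataset: SyntheticDataset
    selected: set
    records: dict
    calls: dict                        # (species, method) -> ortholog calls
    novelty: dict                      # method -> gene -> bool
    ref_summary: dict                  # method -> fan-out summary
    gains: dict                        # method -> list[GainRecord]
    flow: report.FlowSummary
    conservation: dict                 # method -> ContingencyResult
    metrics: dict = field(default_factory=dict)


def _dag_from_toy(onto) -> fg.GoDag:
    terms = {tid: {"name": n, "aspect": a, "obsolete": False}
             for tid, (n, a) in onto["terms"].items()}
    return fg.GoDag(terms=terms, parents=dict(onto["parents"]))


def run_pipeline(tree: SpeciesTreeSpec = None, config: SimConfig = None,
                 seed: int = 0,
                 thresholds: expr.PresenceThresholds = None,
                 search_thresholds: homology.SearchThresholds = None,
                 tolerance_k: float = 1.5) -> PipelineResult:
    tree = tree or DEFAULT_TREE
    config = config or SimConfig()
    thresholds = thresholds or expr.PresenceThresholds()
    search_thresholds = search_thresholds or homology.SearchThresholds()
    ds = simulate_dataset(tree, config, seed)

    # --- expression selection -------------------------------------------
    tpm = expr.normalize_tpm(ds.counts)
    states = expr.call_presence(tpm, ds.counts, thresholds)
    selected = expr.select_candidates(states)

    # --- homology searches ----------------------------------------------
    F, O, R = tree.focal_tip, tree.outgroup_tip, tree.reference_tip
    W = tree.witness_tips[0] if tree.witness_tips else None
    prot = ds.proteomes
    scoring = homology.ScoringScheme()
    params = homology.KarlinAltschulParams()

    def search(sp_a, sp_b):
        return homology.all_vs_all_search(prot[sp_a], prot[sp_b], scoring,
                                          params, search_thresholds)

    hits = {(F, O): search(F, O), (O, F): search(O, F),
            (F, R): search(F, R), (R, F): search(R, F)}
    wit_hits = {}
    if W is not None:
        wit_hits = {(F, W): search(F, W), (O, W): search(O, W),
                    (R, W): search(R, W)}

    # --- ortholog calls --------------------------------------------------
    calls = {}
    for other in (O, R):
        calls[(other, "rbh")] = orthology.reciprocal_best_hits(
            orthology.best_hit_map(hits[(F, other)]),
            orthology.best_hit_map(hits[(other, F)]),
            F, other, hits_ab=hits[(F, other)])
        witness = None
        if W is not None:
            witness = {W: (orthology.distances_from_hits(wit_hits[(F, W)]),
                           orthology.distances_from_hits(wit_hits[(other, W)]))}
        calls[(other, "oma_like")] = orthology.oma_like_pairs(
            orthology.distances_from_hits(hits[(F, other)]), F, other,
            witness=witness, tolerance_k=tolerance_k)

    # --- novelty + TT_Rgr_EEN -------------------------------------------
    focal_genes = ds.history.genes_of(F)
    matrix = phylostrat.build_presence_matrix(focal_genes, calls)
    novelty = {m: phylostrat.classify_novelty(matrix, O, m) for m in METHODS}
    records = phylostrat.call_ttrgr_een(selected, novelty)
    ref_summary = {m: phylostrat.map_reference_orthologs(
        records, calls[(R, m)], m) for m in METHODS}

    # --- GO gains on called focal/reference pairs ------------------------
    dag = _dag_from_toy(ds.ontology)
    anns = [fg.GoAnnotation(*row) for row in ds.annotations]
    gains = {}
    for m in METHODS:
        pairs = sorted({(c.gene_a, c.gene_b) for c in calls[(R, m)]
                        if records.get(c.gene_a) is not None
                        and records[c.gene_a].is_ttrgr_een(m)})
        gains[m] = [fg.detect_gains(f, r, anns, dag) for f, r in pairs]

    # --- flow + conservation ---------------------------------------------
    stage_counts = {}
    conservation = {}
    for m in METHODS:
        een = sorted(g for g, r in records.items() if r.is_ttrgr_een(m))
        novel_all = sorted(g for g, v in novelty[m].items() if v)
        ref_of = {c.gene_a for c in calls[(R, m)]}
        een_with_ref = [g for g in een if g in ref_of]
        novel_with_ref = [g for g in novel_all if g in ref_of]
        stage_counts[m] = {
            "selected": len(selected),
            "stable_id": len(selected),      # identity filter in synthetic mode
            "novel": len(een),
            "novel_with_reference_orthologs": len(een_with_ref),
            "reference_ortholog_total": ref_summary[m]["n_reference_orthologs"],
        }
        a = len(een_with_ref)
        b = len(een) - a
        c = len(novel_with_ref)
        d = len(novel_all) - c
        if a + b > 0 and c + d > 0:
            conservation[m] = report.chisq_2x2(a, b, c, d)
    flow = report.flow_summary(stage_counts)

    result = PipelineResult(ds, selected, records, calls, novelty,
                            ref_summary, gains, flow, conservation)
    result.metrics = score_against_truth(result, tree)
    return result


def ortholog_metrics(calls, truth_pairs, species_pair) -> dict:
    """Precision/recall of called pairs against truth pairs for one
    unordered species pair."""
    predicted = {tuple(sorted((c.gene_a, c.gene_b))) for c in calls}
    truth = set(truth_pairs)
    tp = len(predicted & truth)
    return {
        "species_pair": tuple(sorted(species_pair)),
        "n_predicted": len(predicted), "n_truth": len(truth),
        "precision": tp / len(predicted) if predicted else 1.0,
        "recall": tp / len(truth) if truth else 1.0,
    }


def _truth_pairs_between(history, sp_a, sp_b):
    sp_of = {g.gene_id: g.species for g in history.genes}
    return {p for p in history.truth_ortholog_pairs
            if {sp_of[p[0]], sp_of[p[1]]} == {sp_a, sp_b}}


def score_against_truth(result: PipelineResult,
                        tree: SpeciesTreeSpec) -> dict:
    """Score ortholog calls, novelty and TSEEN recovery against the
    simulator's truth tables."""
    hist = result.dataset.history
    F, O, R = tree.focal_tip, tree.outgroup_tip, tree.reference_tip
    metrics: dict = {"orthology": {}, "novelty_accuracy": {}, "tseen": {}}

    for m in METHODS:
        all_calls = result.calls[(O, m)] + result.calls[(R, m)]
        truth = (_truth_pairs_between(hist, F, O)
                 | _truth_pairs_between(hist, F, R))
        metrics["orthology"][m] = ortholog_metrics(
            all_calls, truth, (F, "other"))

        truth_novel = {g: age == "post_outgroup_split"
                       for g, age in hist.truth_age.items()}
        agree = sum(1 for g, v in result.novelty[m].items()
                    if truth_novel.get(g) == v)
        metrics["novelty_accuracy"][m] = agree / len(result.novelty[m])

        recovered = {g for g, r in result.records.items()
                     if r.is_ttrgr_een(m)}
        truth_tseen = hist.truth_tseen
        tp = len(recovered & truth_tseen)
        metrics["tseen"][m] = {
            "n_recovered": len(recovered), "n_truth": len(truth_tseen),
            "recall": tp / len(truth_tseen) if truth_tseen else 1.0,
            "fdr": (len(recovered) - tp) / len(recovered) if recovered else 0.0,
        }

    sel = result.selected
    truth_tseen = hist.truth_tseen
    metrics["selection"] = {
        "recall": (len(sel & truth_tseen) / len(truth_tseen)
                   if truth_tseen else 1.0),
        "n_selected": len(sel),
    }
    return metrics


def category_totals_for_sample(result: PipelineResult, method: str = "rbh"
                               ) -> dict:
    """Development/transcription/signaling/immune totals for the focal
    TT_Rgr_EEN genes versus their reference orthologs (Table-2 analog)."""
    dag = _dag_from_toy(result.dataset.ontology)
    anns = [fg.GoAnnotation(*row) for row in result.dataset.annotations]
    categories = {name: [root] for name, root in CATEGORY_ROOTS.items()}
    focal_sets = {}
    ref_sets = {}
    for rec in result.gains[method]:
        focal_sets.setdefault(rec.focal_gene, set()).update(
            fg.terms_of(rec.focal_gene, anns))
        ref_sets.setdefault(rec.reference_gene, set()).update(
            fg.terms_of(rec.reference_gene, anns))
    return {
        "focal": fg.categorize_counts(focal_sets, categories, dag),
        "reference": fg.categorize_counts(ref_sets, categories, dag),
    }
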