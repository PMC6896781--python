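"""GO annotation comparison between focal genes and reference orthologs.

Covers: OBO parsing into a DAG, evidence-code filtering, distinct-function
counting (one count per term id, however many evidence codes annotate it),
gained-term detection (terms annotated to the reference ortholog but absent
from the focal gene — the "progressive functions" pattern), category
grouping by ancestor closure, and term enrichment (one-sided
hypergeometric with fold enrichment and Benjamini-Hochberg correction).

Distinct-function counts use direct annotations only; ancestor propagation
is applied solely inside enrichment, where it is standard practice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import obonet
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

ASPECTS = ("biological_process", "molecular_function", "cellular_component")
EXPERIMENTAL_CODES = frozenset({"EXP", "IDA", "IPI", "IMP", "IGI", "IEP"})
GO_EVIDENCE_CODES = EXPERIMENTAL_CODES | {
    "HTP", "HDA", "HMP", "HGI", "HEP", "IBA", "IBD", "IKR", "IRD", "ISS",
    "ISO", "ISA", "ISM", "IGC", "RCA", "TAS", "NAS", "IC", "ND", "IEA"}


class GoError(ValueError):
    pass


@dataclass
class GoDag:
    """Directed acyclic graph of GO terms with is_a edges child -> parent."""
    terms: dict[str, dict]            # id -> {name, aspect, obsolete}
    parents: dict[str, list[str]]
    _anc_cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for child, ps in self.parents.items():
            for p in ps:
                if p not in self.terms:
                    raise GoError(f"dangling is_a parent {p!r} of {child!r}")
                g.add_edge(child, p)
        if not nx.is_directed_acyclic_graph(g):
            edge = next(iter(nx.find_cycle(g)))
            raise GoError(f"ontology contains a cycle through edge {edge}")
        self._graph = g

    def ancestors(self, term: str) -> set[str]:
        """All is_a ancestors of a term (excluding the term itself);
        obsolete terms take no part in closures."""
        if term not in self.terms:
            raise GoError(f"unknown term {term!r}")
        if term not in self._anc_cache:
            anc = nx.descendants(self._graph, term)  # edges point rootward
            self._anc_cache[term] = {
                a for a in anc if not self.terms[a].get("obsolete")}
        return self._anc_cache[term]

    def aspect(self, term: str) -> str:
        return self.terms[term]["aspect"]


def parse_obo(path: str) -> GoDag:
    """Read an OBO 1.2-subset ontology (id, name, namespace, is_a)."""
    graph = obonet.read_obo(path, ignore_obsolete=False)
    terms: dict[str, dict] = {}
    parents: dict[str, list[str]] = {}
    for node, data in graph.nodes(data=True):
        terms[node] = {
            "name": data.get("name", node),
            "aspect": data.get("namespace", "biological_process"),
            "obsolete": data.get("is_obsolete", "false") in ("true", True),
        }
        parents[node] = sorted(
            v for _u, v, k in graph.out_edges(node, keys=True) if k == "is_a")
    return GoDag(terms=terms, parents=parents)


@dataclass(frozen=True)
class GoAnnotation:
    gene_id: str
    term_id: str
    evidence_code: str
    aspect: str


def read_annotations_tsv(path: str) -> list[GoAnnotation]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("gene_id"):
            raise GoError(f"{path}: expected header starting with 'gene_id'")
        for line in fh:
            gene, term, code, aspect = line.rstrip("\n").split("\t")
            out.append(GoAnnotation(gene, term, code, aspect))
    return out


@dataclass(frozen=True)
class EvidenceFilter:
    """mode='all' keeps everything; mode='experimental' keeps only the six
    experimental codes EXP, IDA, IPI, IMP, IGI, IEP."""
    mode: str = "all"

    def __post_init__(self):
        if self.mode not in ("all", "experimental"):
            raise GoError("mode must be 'all' or 'experimental'")


def filter_evidence(annotations: list[GoAnnotation],
                    evidence_filter: EvidenceFilter) -> list[GoAnnotation]:
    if evidence_filter.mode == "all":
        return list(annotations)
    kept = []
    for ann in annotations:
        if ann.evidence_code in EXPERIMENTAL_CODES:
            kept.append(ann)
        elif ann.evidence_code not in GO_EVIDENCE_CODES:
            log.warning("unknown evidence code %r on %s; dropped",
                        ann.evidence_code, ann.gene_id)
    return kept


def terms_of(gene: str, annotations: list[GoAnnotation],
             aspect: str | None = None) -> set[str]:
    return {a.term_id for a in annotations
            if a.gene_id == gene and (aspect is None or a.aspect == aspect)}


def count_distinct_functions(gene: str, annotations: list[GoAnnotation],
                             aspect: str) -> int:
    """Distinct term ids annotated to the gene in an aspect — repeated
    annotation of one term under several evidence codes counts once.
    Direct annotations only, no ancestor propagation."""
    return len(terms_of(gene, annotations, aspect))


@dataclass
class GainRecord:
    """Per-aspect annotation comparison for one focal/reference ortholog
    pair; gained terms are those present for the reference gene and absent
    from the focal gene."""
    focal_gene: str
    reference_gene: str
    counts: dict[str, tuple[int, int]]        # aspect -> (focal_n, reference_n)
    gained_terms: dict[str, frozenset]        # aspect -> term ids

    def all_gained(self) -> frozenset:
        return frozenset(t for s in self.gained_terms.values() for t in s)


def detect_gains(focal_gene: str, reference_gene: str,
                 annotations: list[GoAnnotation], dag: GoDag) -> GainRecord:
    counts = {}
    gained = {}
    for aspect in ASPECTS:
        f_terms = terms_of(focal_gene, annotations, aspect)
        r_terms = terms_of(reference_gene, annotations, aspect)
        for t in f_terms | r_terms:
            if t not in dag.terms:
                raise GoError(f"annotated term {t!r} not in the ontology")
        counts[aspect] = (len(f_terms), len(r_terms))
        gained[aspect] = frozenset(r_terms - f_terms)
    return GainRecord(focal_gene, reference_gene, counts, gained)


def categorize_counts(gene_term_sets: dict[str, set[str]],
                      categories: dict[str, list[str]],
                      dag: GoDag) -> dict[str, int]:
    """Table-2-style category totals for a gene sample.

    A term belongs to a category when one of the category's root terms is
    the term itself or lies in its ancestor closure; terms may fall in
    several categories.  The sample total per category is the sum over
    genes of their distinct in-category terms.
    """
    for cat, roots in categories.items():
        for r in roots:
            if r not in dag.terms:
                raise GoError(f"unknown category root {r!r} in {cat!r}")
    totals = {cat: 0 for cat in categories}
    for _gene, terms in sorted(gene_term_sets.items()):
        for cat, roots in categories.items():
            rootset = set(roots)
            n = sum(1 for t in terms
                    if t in rootset or (rootset & dag.ancestors(t)))
            totals[cat] += n
    return totals


@dataclass
class EnrichmentResult:
    term_id: str
    k: int                # study genes annotated (after propagation)
    n: int                # study size
    K: int                # background genes annotated
    N: int                # background size
    fold_enrichment: float
    p_raw: float
    q_bh: float = float("nan")


def enrich(study_genes: set[str], background_genes: set[str],
           annotations: list[GoAnnotation], dag: GoDag
           ) -> list[EnrichmentResult]:
    """Per-term over-representation of the study set against the
    background: one-sided hypergeometric p (Fisher exact), fold
    enrichment (k/n)/(K/N), Benjamini-Hochberg q over the tested terms.
    Annotations are propagated to ancestors for this test only; terms with
    no background hits are skipped.
    """
    if not background_genes:
        raise GoError("background gene set is empty")
    if not study_genes <= background_genes:
        raise GoError("study genes must be a subset of the background")
    gene_terms: dict[str, set[str]] = {}
    for ann in annotations:
        if ann.gene_id not in background_genes:
            continue
        closure = {ann.term_id} | dag.ancestors(ann.term_id)
        gene_terms.setdefault(ann.gene_id, set()).update(closure)

    term_bg: dict[str, int] = {}
    term_study: dict[str, int] = {}
    for gene, terms in gene_terms.items():
        for t in terms:
            term_bg[t] = term_bg.get(t, 0) + 1
            if gene in study_genes:
                term_study[t] = term_study.get(t, 0) + 1

    N, n = len(background_genes), len(study_genes)
    results = []
    for term in sorted(term_bg):
        K = term_bg[term]
        k = term_study.get(term, 0)
        p = float(hypergeom.sf(k - 1, N, K, n))
        fold = (k / n) / (K / N) if n else float("nan")
        results.append(EnrichmentResult(term, k, n, K, N, fold, p))
    if results:
        qs = multipletests([r.p_raw for r in results], method="fdr_bh")[1]
        for r, q in zip(results, qs):
            r.q_bh = float(q)
    results.sort(key=lambda r: (r.p_raw, r.term_id))
    return results


def enrichment_to_tsv(results: list[EnrichmentResult], path: str):
    with open(path, "w") as fh:
        fh.write("term_id\tk\tn\tK\tN\tfold_enrichment\tp_raw\tq_bh\n")
        for r in results:
            fh.write(f"{r.term_id}\t{r.k}\t{r.n}\t{r.K}\t{r.N}\t"
                     f"{r.fold_enrichment:.4f}\t{r.p_raw:.4g}\t{r.q_bh:.4g}\n")


def gains_to_tsv(records: list[GainRecord], path: str):
    with open(path, "w") as fh:
        fh.write("focal_gene\treference_gene\taspect\tfocal_n\treference_n\t"
                 "gained_term_ids\n")
        for rec in records:
            for aspect in ASPECTS:
                fn, rn = rec.counts[aspect]
                fh.write(f"{rec.focal_gene}\t{rec.reference_gene}\t{aspect}\t"
                         f"{fn}\t{rn}\t"
                         + ";".join(sorted(rec.gained_terms[aspect])) + "\n")
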