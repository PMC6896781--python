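"""Gene-age classification and the tumor-and-regression-expressed,
evolutionarily novel (TT_Rgr_EEN) call.

A focal gene is *evolutionarily novel* when it has no ortholog call in the
designated outgroup genome (the lamprey role); intersecting novelty with
the expression-selected candidate set yields the TT_Rgr_EEN class.  Calls
are tracked per orthology method so that methods can be compared and a
consensus (novel by all methods) extracted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .orthology import OrthologCall


class PhylostratError(ValueError):
    pass


def build_presence_matrix(gene_universe: list[str],
                          calls: dict[tuple[str, str], list[OrthologCall]]
                          ) -> pd.DataFrame:
    """Boolean matrix: focal gene x (species, method) -> has >= 1 ortholog.

    ``calls`` maps (species, method) -> ortholog calls whose ``gene_a`` is
    the focal gene.  Every configured (species, method) must be present
    (an empty list is a valid entry; a missing one is a configuration gap).
    """
    if not calls:
        raise PhylostratError("no (species, method) call sets configured")
    cols = pd.MultiIndex.from_tuples(sorted(calls), names=["species", "method"])
    mat = pd.DataFrame(False, index=pd.Index(sorted(gene_universe),
                                             name="gene_id"), columns=cols)
    for (sp, method), call_list in calls.items():
        for c in call_list:
            if c.gene_a in mat.index:
                mat.loc[c.gene_a, (sp, method)] = True
    return mat


def classify_novelty(matrix: pd.DataFrame, outgroup: str,
                     method: str) -> dict[str, bool]:
    """novel iff the gene has no ortholog call in the outgroup genome."""
    if (outgroup, method) not in matrix.columns:
        raise PhylostratError(
            f"no calls for outgroup {outgroup!r} with method {method!r}")
    col = matrix[(outgroup, method)]
    return {g: not bool(v) for g, v in col.items()}


@dataclass
class TseenRecord:
    gene_id: str
    expression_selected: bool
    novel_by_method: dict[str, bool] = field(default_factory=dict)
    reference_orthologs: list[str] = field(default_factory=list)

    def is_ttrgr_een(self, method: str) -> bool:
        return self.expression_selected and self.novel_by_method.get(method, False)


def call_ttrgr_een(expression_selected: set[str],
                   novelty: dict[str, dict[str, bool]]) -> dict[str, TseenRecord]:
    """Intersect expression selection with per-method novelty.

    ``novelty`` maps method -> (gene -> novel flag); all methods must share
    the same gene universe.
    """
    universes = {frozenset(n) for n in novelty.values()}
    if len(universes) > 1:
        raise PhylostratError("novelty maps disagree on the gene universe")
    records = {}
    for gene in sorted(next(iter(universes), frozenset())):
        records[gene] = TseenRecord(
            gene_id=gene,
            expression_selected=gene in expression_selected,
            novel_by_method={m: novelty[m][gene] for m in sorted(novelty)})
    return records


def map_reference_orthologs(records: dict[str, TseenRecord],
                            reference_calls: list[OrthologCall],
                            method: str) -> dict:
    """Attach reference-genome ortholog lists to the TT_Rgr_EEN genes of
    one method and summarize the fan-out.

    Returns {"n_focal_with_ref", "n_reference_orthologs"}: distinct focal
    genes with >= 1 reference ortholog, and distinct reference genes
    reached (a reference gene hit from two focal genes counts once).
    """
    by_gene: dict[str, list[str]] = {}
    for c in reference_calls:
        if c.method == method:
            by_gene.setdefault(c.gene_a, []).append(c.gene_b)
    een = [r for r in records.values() if r.is_ttrgr_een(method)]
    ref_reached = set()
    n_with = 0
    for rec in een:
        refs = sorted(set(by_gene.get(rec.gene_id, [])))
        rec.reference_orthologs = refs
        if refs:
            n_with += 1
            ref_reached.update(refs)
    return {"n_focal_with_ref": n_with,
            "n_reference_orthologs": len(ref_reached)}


def method_consensus(records: dict[str, TseenRecord]) -> dict:
    """Per-method TT_Rgr_EEN counts, the confirmed set (novel by every
    method), and per-gene disagreements attributed to the dissenting
    method."""
    methods = sorted({m for r in records.values() for m in r.novel_by_method})
    if len(methods) < 2:
        raise PhylostratError("consensus needs >= 2 methods")
    per_method = {m: sorted(g for g, r in records.items() if r.is_ttrgr_een(m))
                  for m in methods}
    confirmed = sorted(set.intersection(*(set(v) for v in per_method.values())))
    disagreements = []
    for g, r in sorted(records.items()):
        if not r.expression_selected:
            continue
        flags = {m: r.novel_by_method[m] for m in methods}
        if len(set(flags.values())) > 1:
            # the dissenting method is the one declining the novelty call
            dissent = sorted(m for m, v in flags.items() if not v)
            disagreements.append({"gene_id": g, "novel_by": flags,
                                  "dissenting": dissent})
    return {"methods": methods,
            "per_method_counts": {m: len(v) for m, v in per_method.items()},
            "per_method_genes": per_method,
            "confirmed": confirmed,
            "n_confirmed": len(confirmed),
            "disagreements": disagreements}


def records_to_tsv(records: dict[str, TseenRecord], path: str):
    methods = sorted({m for r in records.values() for m in r.novel_by_method})
    with open(path, "w") as fh:
        fh.write("gene_id\texpression_selected\t"
                 + "\t".join(f"novel_{m}" for m in methods)
                 + "\treference_orthologs\n")
        for g in sorted(records):
            r = records[g]
            fh.write(f"{g}\t{int(r.expression_selected)}\t"
                     + "\t".join(str(int(r.novel_by_method.get(m, False)))
                                 for m in methods)
                     + "\t" + ";".join(r.reference_orthologs) + "\n")
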