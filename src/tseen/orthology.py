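"""Ortholog inference from filtered alignment hits.

Two methods mirror the two routes of the study design:

* ``rbh`` — reciprocal best hits on E-value/score, the BLAST/Ensembl-style
  heuristic; calls are strictly one-to-one.
* ``oma_like`` — evolutionary distances (Kimura-corrected) with explicit
  inference uncertainty: per gene, every partner within ``tolerance_k``
  standard deviations of the minimum distance is a candidate, mutual
  candidates form one-to-many / many-to-many groups, and a third "witness"
  genome can veto pairs whose closeness is better explained by an old
  duplication followed by differential gene loss.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import networkx as nx

from .homology import AlignmentHit

log = logging.getLogger(__name__)


class OrthologyError(ValueError):
    pass


class DistanceSaturationError(OrthologyError):
    """The Kimura correction is undefined (p too large); treat the distance
    as effectively infinite."""


@dataclass(frozen=True)
class DistanceEstimate:
    d: float          # substitutions per site, Kimura-corrected
    variance: float
    aligned_len: int

    @property
    def sd(self) -> float:
        return math.sqrt(self.variance)


def estimate_distance(p: float, aligned_len: int) -> DistanceEstimate:
    """Kimura's empirical correction for protein distances,
    d = -ln(1 - p - p^2/5), with variance propagated from binomial sampling
    of the mismatch fraction p over ``aligned_len`` ungapped columns:
    var(d) = p(1-p)/L * (dd/dp)^2.

    Raises :class:`DistanceSaturationError` for p >= 0.85, where the
    correction leaves its domain.
    """
    if aligned_len < 1:
        raise OrthologyError("aligned_len must be >= 1")
    if not (0.0 <= p <= 1.0):
        raise OrthologyError("mismatch fraction p must be in [0, 1]")
    if p >= 0.85:
        raise DistanceSaturationError(
            f"p={p:.3f} saturates the Kimura correction; treat d as +inf")
    arg = 1.0 - p - p * p / 5.0
    d = -math.log(arg)
    slope = (1.0 + 0.4 * p) / arg  # dd/dp
    variance = p * (1.0 - p) / aligned_len * slope * slope
    return DistanceEstimate(d=d, variance=variance, aligned_len=aligned_len)


def distance_from_hit(hit: AlignmentHit) -> DistanceEstimate | None:
    """Distance over the hit's local-alignment columns; None on saturation."""
    if hit.n_columns < 1:
        return None
    p = 1.0 - hit.n_identical / hit.n_columns
    try:
        return estimate_distance(p, hit.n_columns)
    except DistanceSaturationError:
        return None


@dataclass(frozen=True)
class OrthologCall:
    gene_a: str
    species_a: str
    gene_b: str
    species_b: str
    relation: str          # one2one | one2many | many2many
    method: str            # rbh | oma_like
    score_or_distance: float
    group_id: str = ""


# ---------------------------------------------------------------------------
# reciprocal best hits
# ---------------------------------------------------------------------------

def best_hit_map(hits: list[AlignmentHit]) -> dict[str, str]:
    """Per query, the target with lowest E-value (ties: highest score, then
    lexicographically smallest subject id).  Input hits must already have
    passed the hit filter."""
    best: dict[str, AlignmentHit] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None or (h.evalue, -h.score, h.subject_id) < (
                cur.evalue, -cur.score, cur.subject_id):
            best[h.query_id] = h
    return {q: h.subject_id for q, h in best.items()}


def reciprocal_best_hits(map_ab: dict[str, str], map_ba: dict[str, str],
                         species_a: str, species_b: str,
                         hits_ab: list[AlignmentHit] | None = None
                         ) -> list[OrthologCall]:
    """Pairs (x, y) with map_ab[x] == y and map_ba[y] == x; one2one."""
    ev = {}
    if hits_ab:
        for h in hits_ab:
            ev[(h.query_id, h.subject_id)] = h.evalue
    calls = []
    for x in sorted(map_ab):
        y = map_ab[x]
        if map_ba.get(y) == x:
            calls.append(OrthologCall(
                gene_a=x, species_a=species_a, gene_b=y, species_b=species_b,
                relation="one2one", method="rbh",
                score_or_distance=ev.get((x, y), float("nan")),
                group_id=f"rbh:{x}"))
    return calls


# ---------------------------------------------------------------------------
# distance-based stable pairs with witness of non-orthology
# ---------------------------------------------------------------------------

DistanceTable = dict[tuple[str, str], DistanceEstimate]


def distances_from_hits(hits: list[AlignmentHit]) -> DistanceTable:
    """Keep, per (query, subject) pair, the distance from the best hit."""
    table: DistanceTable = {}
    for h in hits:
        est = distance_from_hit(h)
        if est is None:
            continue
        key = (h.query_id, h.subject_id)
        if key not in table or est.d < table[key].d:
            table[key] = est
    return table


def _candidates_within_tolerance(dist: DistanceTable, tolerance_k: float
                                 ) -> dict[str, set[str]]:
    """For each gene x, partners y with d(x,y) within tolerance_k pooled
    standard deviations of x's minimum distance."""
    by_query: dict[str, list[tuple[str, DistanceEstimate]]] = {}
    for (x, y), est in dist.items():
        by_query.setdefault(x, []).append((y, est))
    out: dict[str, set[str]] = {}
    for x, partners in by_query.items():
        dmin, vmin = min((e.d, e.variance) for _, e in partners)
        keep = set()
        for y, e in partners:
            tol = tolerance_k * math.sqrt(e.variance + vmin)
            if e.d <= dmin + tol:
                keep.add(y)
        out[x] = keep
    return out


def _symmetrize(dist_ab: DistanceTable, dist_ba: DistanceTable | None
                ) -> tuple[DistanceTable, DistanceTable]:
    if dist_ba is None:
        dist_ba = {(y, x): e for (x, y), e in dist_ab.items()}
    return dist_ab, dist_ba


def oma_like_pairs(dist_ab: DistanceTable,
                   species_a: str, species_b: str,
                   witness: dict[str, tuple[DistanceTable, DistanceTable]] | None = None,
                   tolerance_k: float = 1.5) -> list[OrthologCall]:
    """Distance-based ortholog calls between species A and B.

    ``dist_ab`` maps (gene_in_A, gene_in_B) -> DistanceEstimate (treated as
    symmetric).  ``witness`` maps a witness species name C to a pair of
    tables (distances A->C, distances B->C); any single witness genome
    rejecting a pair suffices.  Without witness tables the stable-pair step
    runs alone and a warning is logged.

    Steps: (i) stable pairs — (x, y) is kept when each lies within
    ``tolerance_k`` pooled standard deviations of the other's minimum
    distance; mutually kept genes form groups whose relation is read off
    the per-species multiplicity.  (ii) witness rejection — (x, y) is
    dropped when genome C holds genes z_x, z_y with
    d(x, z_x) < d(x, y) - tol and d(y, z_y) < d(x, y) - tol (z_x = z_y
    allowed unless that gene is itself called orthologous to both), the
    signature of an ancestral duplication resolved by differential loss.
    """
    dist_ab, dist_ba = _symmetrize(dist_ab, None)
    cand_ab = _candidates_within_tolerance(dist_ab, tolerance_k)
    cand_ba = _candidates_within_tolerance(dist_ba, tolerance_k)

    mutual = sorted(
        (x, y) for x, ys in cand_ab.items() for y in ys
        if x in cand_ba.get(y, ()))

    if witness:
        mutual = [
            (x, y) for x, y in mutual
            if not _witness_rejects(x, y, dist_ab[(x, y)], witness, tolerance_k)]
    else:
        log.warning("no witness genome configured; skipping witness-of-"
                    "non-orthology step for %s-%s", species_a, species_b)

    # group mutually kept pairs into connected components
    graph = nx.Graph()
    graph.add_edges_from(mutual)
    calls: list[OrthologCall] = []
    comps = sorted(nx.connected_components(graph), key=lambda c: min(c))
    for gi, comp in enumerate(comps):
        comp_pairs = sorted(p for p in mutual if p[0] in comp)
        a_genes = {x for x, _ in comp_pairs}
        b_genes = {y for _, y in comp_pairs}
        if len(a_genes) == 1 and len(b_genes) == 1:
            relation = "one2one"
        elif min(len(a_genes), len(b_genes)) == 1:
            relation = "one2many"
        else:
            relation = "many2many"
        for x, y in comp_pairs:
            calls.append(OrthologCall(
                gene_a=x, species_a=species_a, gene_b=y, species_b=species_b,
                relation=relation, method="oma_like",
                score_or_distance=dist_ab[(x, y)].d,
                group_id=f"oma:{gi:04d}"))
    return calls


def _witness_rejects(x: str, y: str, est_xy: DistanceEstimate,
                     witness: dict, tolerance_k: float) -> bool:
    """True when some witness genome C holds genes significantly closer to
    x and to y than x and y are to each other.

    A single shared witness gene close to both sides is treated as a
    legitimate outgroup ortholog of the pair and does not reject; rejection
    requires two distinct witness genes (the paralogous copies retained in
    C after the duplication that x and y descend from).
    """
    cutoff = est_xy.d - tolerance_k * est_xy.sd
    for wname in sorted(witness):
        dist_aw, dist_bw = witness[wname]
        zx = {z for (g, z), e in dist_aw.items() if g == x and e.d < cutoff}
        zy = {z for (g, z), e in dist_bw.items() if g == y and e.d < cutoff}
        if zx and zy and len(zx | zy) >= 2:
            log.info("pair (%s, %s) rejected by witness genome %s", x, y, wname)
            return True
    return False


def calls_to_tsv(calls: list[OrthologCall], path: str):
    with open(path, "w") as fh:
        fh.write("gene_a\tspecies_a\tgene_b\tspecies_b\trelation\tmethod\t"
                 "distance_or_evalue\tgroup_id\n")
        for c in calls:
            fh.write(f"{c.gene_a}\t{c.species_a}\t{c.gene_b}\t{c.species_b}\t"
                     f"{c.relation}\t{c.method}\t{c.score_or_distance:.6g}\t"
                     f"{c.group_id}\n")
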