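"""Synthetic evolution + expression data generator.

Produces a fully specified dataset for the downstream pipeline: a rooted
species tree with an outgroup, gene family histories under a
birth/duplication/loss process, diverged protein sequences, a toy GO
ontology with per-gene annotations that gain terms on the focal→reference
lineage, and negative-binomial tag counts over three conditions
(normal, tumor, regressed).  Every stochastic choice is recorded in truth
tables so each downstream stage can be scored exactly.

All randomness flows through :func:`numpy.random.default_rng` seeded from
the caller-supplied integer; identical seeds give byte-identical outputs.
"""

from __future__ import annotations

import io
import json
import os
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
from Bio import Phylo, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
EVIDENCE_CODES = ["IDA", "IMP", "IEP", "ISS", "IEA", "IC"]
CONDITIONS = ["normal", "tumor", "regressed"]

# stage constants mixed into the seed so the emitters draw independent streams
_STAGE_FAMILIES = 11
_STAGE_PROTEOMES = 23
_STAGE_GO = 37
_STAGE_EXPRESSION = 53


class SimulationError(ValueError):
    """Raised for invalid tree or configuration inputs."""


# ---------------------------------------------------------------------------
# species tree
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpeciesTreeSpec:
    """A rooted species tree plus the roles its tips play.

    ``outgroup_tip`` is the lineage against which gene novelty is judged
    (the lamprey role), ``focal_tip`` the tumor-bearing species (zebrafish
    role), ``reference_tip`` the annotation-rich species (human role), and
    ``witness_tips`` third genomes used by the distance-based orthology
    method to expose paralogy through differential gene loss.
    """

    newick_text: str
    outgroup_tip: str
    focal_tip: str
    reference_tip: str
    witness_tips: tuple[str, ...]

    def __post_init__(self):
        roles = [self.outgroup_tip, self.focal_tip, self.reference_tip]
        if len(set(roles)) != 3:
            raise SimulationError("outgroup, focal and reference tips must be distinct")
        tips = {n.name for n in self._phylo().get_terminals()}
        for tip in roles + list(self.witness_tips):
            if tip not in tips:
                raise SimulationError(f"tip {tip!r} is not a leaf of the tree")
        if len(tips) < 4:
            raise SimulationError("tree needs >= 4 tips (outgroup, focal, reference, witness)")
        for clade in self._phylo().find_clades():
            if clade.branch_length is not None and clade.branch_length < 0:
                raise SimulationError("negative branch length in species tree")

    def _phylo(self):
        return Phylo.read(io.StringIO(self.newick_text), "newick")


@dataclass
class _Node:
    name: str
    length: float
    children: list
    is_tip: bool


def _build_nodes(spec: SpeciesTreeSpec) -> _Node:
    """Convert the Biopython tree into a lightweight node structure with
    stable names for unnamed internal nodes."""
    tree = spec._phylo()

    def convert(clade, is_root=False):
        if clade.is_terminal():
            return _Node(clade.name, float(clade.branch_length or 0.0), [], True)
        kids = [convert(c) for c in clade.clades]
        if is_root:
            name = "root"
        else:
            name = clade.name or "anc(" + "+".join(
                sorted(t for k in kids for t in _tipset(k))) + ")"
        return _Node(name, float(clade.branch_length or 0.0), kids, False)

    return convert(tree.root, is_root=True)


def _tipset(node: _Node) -> list[str]:
    if node.is_tip:
        return [node.name]
    return [t for c in node.children for t in _tipset(c)]


def _branches_preorder(root: _Node) -> list[_Node]:
    """All non-root nodes, preorder; the branch above each node carries
    its name."""
    out = []

    def walk(n):
        for c in n.children:
            out.append(c)
            walk(c)

    walk(root)
    return out


#: Default four-species panel: an early-diverging outgroup, a witness genome,
#: and the focal/reference sister pair.  Branch lengths are expected amino
#: acid substitutions per site.
DEFAULT_TREE = SpeciesTreeSpec(
    newick_text="(outgroup:0.50,(witness:0.20,(focal:0.10,reference:0.15):0.15):0.15);",
    outgroup_tip="outgroup",
    focal_tip="focal",
    reference_tip="reference",
    witness_tips=("witness",),
)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimConfig:
    """Generator parameters.

    Rates are events per unit branch length (substitutions/site).  The
    defaults aim for a desk-scale genome: ~60 ancestral families plus
    ~20 lineage-specific births on the focal path, mild duplication and
    loss, and SAGE-like library depth where an expressed gene draws
    negative-binomial counts with mean ``nb_mean``.
    """

    n_root_families: int = 60
    birth_rate: float = 50.0
    dup_rate: float = 0.08
    loss_rate: float = 0.03
    protein_len_range: tuple[int, int] = (80, 200)
    go_terms_per_gene_range: tuple[int, int] = (2, 6)
    gain_rate_reference_lineage: float = 3.0
    category_gain_bias: float = 4.0
    nb_mean: float = 50.0
    nb_dispersion: float = 5.0
    frac_tseen: float = 0.4
    frac_silent: float = 0.1
    frac_truncated_duplicates: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if min(self.birth_rate, self.dup_rate, self.loss_rate,
               self.gain_rate_reference_lineage) < 0:
            raise SimulationError("rates must be >= 0")
        if not (0.0 <= self.frac_tseen <= 1.0):
            raise SimulationError("frac_tseen must be in [0, 1]")
        if not (0.0 <= self.frac_silent <= 1.0):
            raise SimulationError("frac_silent must be in [0, 1]")
        if self.nb_dispersion <= 0:
            raise SimulationError("nb_dispersion must be > 0")
        if self.protein_len_range[0] < 30:
            raise SimulationError("minimum protein length is 30 residues")
        if self.protein_len_range[0] > self.protein_len_range[1]:
            raise SimulationError("protein_len_range must be (min, max) with min <= max")


# ---------------------------------------------------------------------------
# gene family histories
# ---------------------------------------------------------------------------

@dataclass
class GeneRecord:
    gene_id: str
    species: str
    family_id: str
    birth_branch: str
    truncated: bool = False


@dataclass
class FamilyHistory:
    """Complete record of simulated gene families and their truth tables.

    ``truth_ortholog_pairs`` holds lexicographically sorted gene-id tuples;
    use :meth:`are_orthologs` for symmetric lookup.  ``truth_gained_terms``
    is filled by :func:`emit_go`.
    """

    genes: list[GeneRecord]
    truth_ortholog_pairs: set[tuple[str, str]]
    truth_age: dict[str, str]            # focal gene -> pre/post_outgroup_split
    truth_tseen: set[str]
    truth_gained_terms: dict[tuple[str, str], frozenset] = field(default_factory=dict)
    gene_trees: list[tuple[str, str, dict]] = field(default_factory=list)

    def are_orthologs(self, a: str, b: str) -> bool:
        return tuple(sorted((a, b))) in self.truth_ortholog_pairs

    def genes_of(self, species: str) -> list[str]:
        return sorted(g.gene_id for g in self.genes if g.species == species)

    def to_json(self) -> str:
        payload = {
            "genes": [asdict(g) for g in self.genes],
            "truth_ortholog_pairs": sorted(map(list, self.truth_ortholog_pairs)),
            "truth_age": dict(sorted(self.truth_age.items())),
            "truth_tseen": sorted(self.truth_tseen),
            "truth_gained_terms": {
                f"{f}\t{r}": sorted(terms)
                for (f, r), terms in sorted(self.truth_gained_terms.items())
            },
            "gene_trees": self.gene_trees,
        }
        return json.dumps(payload, sort_keys=True, indent=1)


def _sim_lineage(node: _Node, pos: float, elen: float, trunc: bool,
                 rng: np.random.Generator, cfg: SimConfig) -> Optional[dict]:
    """Evolve a single gene lineage starting ``pos`` into the branch above
    ``node``; returns a gene-tree node dict or None if the lineage dies.

    ``elen`` is evolutionary length accumulated since the last divergence
    event (birth, duplication or speciation).
    """
    rate = cfg.dup_rate + cfg.loss_rate
    t = pos
    while True:
        dt = rng.exponential(1.0 / rate) if rate > 0 else np.inf
        if t + dt >= node.length:
            break
        t += dt
        if rng.random() < (cfg.loss_rate / rate if rate > 0 else 0.0):
            return None
        # duplication: the second copy may be domain-truncated
        e_here = elen + (t - pos)
        new_trunc = trunc or (rng.random() < cfg.frac_truncated_duplicates)
        c1 = _sim_lineage(node, t, 0.0, trunc, rng, cfg)
        c2 = _sim_lineage(node, t, 0.0, new_trunc, rng, cfg)
        kids = [c for c in (c1, c2) if c is not None]
        if not kids:
            return None
        if len(kids) == 1:
            kids[0]["elen"] += e_here
            return kids[0]
        return {"kind": "dup", "elen": e_here, "children": kids}
    e_end = elen + (node.length - pos)
    if node.is_tip:
        return {"kind": "leaf", "species": node.name, "elen": e_end,
                "truncated": trunc}
    kids = [_sim_lineage(c, 0.0, 0.0, trunc, rng, cfg) for c in node.children]
    kids = [k for k in kids if k is not None]
    if not kids:
        return None
    if len(kids) == 1:
        kids[0]["elen"] += e_end
        return kids[0]
    return {"kind": "spec", "elen": e_end, "children": kids}


def _sim_family_from_root(root: _Node, rng, cfg) -> Optional[dict]:
    kids = [_sim_lineage(c, 0.0, 0.0, False, rng, cfg) for c in root.children]
    kids = [k for k in kids if k is not None]
    if not kids:
        return None
    if len(kids) == 1:
        return kids[0]
    return {"kind": "spec", "elen": 0.0, "children": kids}


def _leaves(tree: dict) -> list[dict]:
    if tree["kind"] == "leaf":
        return [tree]
    return [l for c in tree["children"] for l in _leaves(c)]


def _collect_ortholog_pairs(tree: dict, pairs: set):
    if tree["kind"] == "leaf":
        return
    for c in tree["children"]:
        _collect_ortholog_pairs(c, pairs)
    if tree["kind"] != "spec":
        return
    kids = tree["children"]
    for i in range(len(kids)):
        for j in range(i + 1, len(kids)):
            for a in _leaves(kids[i]):
                for b in _leaves(kids[j]):
                    if a["species"] != b["species"]:
                        pairs.add(tuple(sorted((a["gene_id"], b["gene_id"]))))


def simulate_families(tree: SpeciesTreeSpec, config: SimConfig,
                      seed: int) -> FamilyHistory:
    """Run the birth/duplication/loss process over the species tree.

    ``n_root_families`` families exist at the root; additional families are
    born along each branch as a Poisson process at ``birth_rate`` events per
    unit branch length.  A gene born on a branch exists only in species
    descending from it.  Genes whose family coalesces at a speciation node
    are orthologs; at a duplication node, paralogs.
    """
    root = _build_nodes(tree)
    rng = np.random.default_rng([_STAGE_FAMILIES, seed])

    family_trees: list[tuple[str, str, dict]] = []
    fam_counter = 0
    for _ in range(config.n_root_families):
        fid = f"F{fam_counter:04d}"
        fam_counter += 1
        gtree = _sim_family_from_root(root, rng, config)
        if gtree is not None:
            family_trees.append((fid, "root", gtree))
    for branch in _branches_preorder(root):
        n_births = rng.poisson(config.birth_rate * branch.length)
        positions = np.sort(rng.uniform(0.0, branch.length, size=n_births))
        for pos in positions:
            fid = f"F{fam_counter:04d}"
            fam_counter += 1
            gtree = _sim_lineage(branch, float(pos), 0.0, False, rng, config)
            if gtree is not None:
                family_trees.append((fid, branch.name, gtree))

    genes: list[GeneRecord] = []
    pairs: set[tuple[str, str]] = set()
    truth_age: dict[str, str] = {}
    for fid, birth_branch, gtree in family_trees:
        counters: dict[str, int] = {}
        for leaf in _leaves(gtree):
            sp = leaf["species"]
            counters[sp] = counters.get(sp, 0) + 1
            leaf["gene_id"] = f"{sp}|{fid}|{counters[sp]}"
            genes.append(GeneRecord(leaf["gene_id"], sp, fid, birth_branch,
                                    bool(leaf["truncated"])))
            if sp == tree.focal_tip:
                age = ("pre_outgroup_split" if birth_branch == "root"
                       else "post_outgroup_split")
                truth_age[leaf["gene_id"]] = age
        _collect_ortholog_pairs(gtree, pairs)

    post = sorted(g for g, a in truth_age.items() if a == "post_outgroup_split")
    n_tseen = int(round(config.frac_tseen * len(post)))
    tseen = set(rng.choice(post, size=n_tseen, replace=False)) if n_tseen else set()

    return FamilyHistory(genes=genes, truth_ortholog_pairs=pairs,
                         truth_age=truth_age, truth_tseen=tseen,
                         gene_trees=family_trees)


# ---------------------------------------------------------------------------
# proteomes
# ---------------------------------------------------------------------------

def _mutate(codes: np.ndarray, elen: float, rng) -> np.ndarray:
    """Apply Poisson(elen) substitutions per site; each substitution replaces
    the residue with a uniform choice among the 19 alternatives."""
    if elen <= 0:
        return codes.copy()
    out = codes.copy()
    n_events = rng.poisson(elen, size=out.shape[0])
    for i in np.nonzero(n_events)[0]:
        for _ in range(n_events[i]):
            out[i] = (out[i] + 1 + rng.integers(0, 19)) % 20
    return out


def emit_proteomes(history: FamilyHistory, tree: SpeciesTreeSpec,
                   config: SimConfig, seed: int,
                   outdir: Optional[str] = None) -> dict[str, dict[str, str]]:
    """Evolve protein sequences down each family's gene tree.

    The root sequence is uniform over the 20 amino acids with length drawn
    from ``protein_len_range``; each gene-tree edge applies substitutions at
    its evolutionary length under uniform replacement.  Domain-truncated
    duplicate copies keep only the first 40% of the sequence.  Returns
    species -> gene_id -> sequence and, when ``outdir`` is given, writes one
    FASTA per species.
    """
    rng = np.random.default_rng([_STAGE_PROTEOMES, seed])
    proteomes: dict[str, dict[str, str]] = {
        n.name: {} for n in _branches_preorder(_build_nodes(tree)) if n.is_tip}

    for fid, _branch, gtree in history.gene_trees:
        length = int(rng.integers(config.protein_len_range[0],
                                  config.protein_len_range[1] + 1))
        root_seq = rng.integers(0, 20, size=length)

        def walk(node, parent_seq):
            seq = _mutate(parent_seq, node["elen"], rng)
            if node["kind"] == "leaf":
                if node["truncated"]:
                    seq = seq[: max(30, int(0.4 * seq.shape[0]))]
                proteomes[node["species"]][node["gene_id"]] = "".join(
                    AMINO_ACIDS[c] for c in seq)
            else:
                for c in node["children"]:
                    walk(c, seq)

        walk(gtree, root_seq)

    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        for sp in sorted(proteomes):
            records = [SeqRecord(Seq(proteomes[sp][g]), id=g, description="")
                       for g in sorted(proteomes[sp])]
            SeqIO.write(records, os.path.join(outdir, f"{sp}.faa"), "fasta")
    return proteomes


# ---------------------------------------------------------------------------
# toy GO ontology + annotations
# ---------------------------------------------------------------------------

CATEGORY_ROOTS = {
    "development": "GO:7000001",
    "transcription_regulation": "GO:7000002",
    "signaling": "GO:7000003",
    "immune": "GO:7000004",
}

_DEV_LEAF_NAMES = [
    "placenta development", "lung development", "mammary gland development",
    "ventricular septum development", "cerebral cortex development",
    "cochlea development", "in utero embryonic development",
    "fin regeneration", "liver development", "heart tube formation",
    "neural crest migration", "somite boundary formation",
    "epithelial tube branching", "gill arch morphogenesis",
]


def toy_ontology() -> dict:
    """A fixed toy DAG: four category roots mirroring the developmental /
    transcription / signaling / immune groupings, plus molecular-function
    and cellular-component branches, >= 50 leaf terms, and one multi-parent
    term to exercise multi-category membership.

    Returns ``{"terms": id -> (name, aspect), "parents": id -> [ids]}``.
    """
    terms: dict[str, tuple[str, str]] = {}
    parents: dict[str, list[str]] = {}

    def add(tid, name, aspect, *par):
        terms[tid] = (name, aspect)
        parents[tid] = sorted(par)

    add("GO:7000001", "developmental process", "biological_process")
    add("GO:7000002", "regulation of transcription", "biological_process")
    add("GO:7000003", "signal transduction", "biological_process")
    add("GO:7000004", "immune system process", "biological_process")
    add("GO:7000005", "binding", "molecular_function")
    add("GO:7000006", "cellular anatomical entity", "cellular_component")
    # mid-level development terms (Table-2-like split)
    add("GO:7000011", "anatomical structure development", "biological_process",
        "GO:7000001")
    add("GO:7000012", "developmental growth", "biological_process", "GO:7000001")

    nid = 100
    for i, name in enumerate(_DEV_LEAF_NAMES):
        mid = "GO:7000011" if i % 2 == 0 else "GO:7000012"
        add(f"GO:70001{nid:02d}", name, "biological_process", mid)
        nid += 1
    for i in range(8):
        add(f"GO:70002{i:02d}", f"transcription regulation process {i+1}",
            "biological_process", "GO:7000002")
    for i in range(10):
        add(f"GO:70003{i:02d}", f"signaling pathway {i+1}",
            "biological_process", "GO:7000003")
    for i in range(8):
        add(f"GO:70004{i:02d}", f"immune response process {i+1}",
            "biological_process", "GO:7000004")
    for i in range(8):
        add(f"GO:70005{i:02d}", f"molecular binding activity {i+1}",
            "molecular_function", "GO:7000005")
    for i in range(6):
        add(f"GO:70006{i:02d}", f"cell compartment {i+1}",
            "cellular_component", "GO:7000006")
    # multi-parent: developmental signaling sits under both roots
    add("GO:7000999", "signaling involved in development",
        "biological_process", "GO:7000011", "GO:7000003")
    return {"terms": terms, "parents": parents}


def ontology_leaves(onto: dict) -> list[str]:
    has_child = {p for ps in onto["parents"].values() for p in ps}
    return sorted(t for t in onto["terms"] if t not in has_child)


def _category_leaf_sets(onto: dict) -> dict[str, set[str]]:
    """Leaf membership of each named category via ancestor closure."""
    memo: dict[str, set] = {}

    def ancestors(t):
        if t not in memo:
            acc = set()
            for p in onto["parents"][t]:
                acc.add(p)
                acc |= ancestors(p)
            memo[t] = acc
        return memo[t]

    out = {}
    for cat, root in CATEGORY_ROOTS.items():
        out[cat] = {t for t in onto["terms"]
                    if root == t or root in ancestors(t)}
    return out


def write_obo(onto: dict, path: str):
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: tseen-toy\n")
        for tid in sorted(onto["terms"]):
            name, aspect = onto["terms"][tid]
            fh.write(f"\n[Term]\nid: {tid}\nname: {name}\nnamespace: {aspect}\n")
            for p in onto["parents"][tid]:
                fh.write(f"is_a: {p} ! {onto['terms'][p][0]}\n")


def emit_go(history: FamilyHistory, config: SimConfig, seed: int,
            outdir: Optional[str] = None,
            tree: SpeciesTreeSpec = None) -> dict:
    """Annotate genes with toy GO terms and plant function gains on the
    focal→reference lineage.

    Every gene inherits its family's base term set (drawn at family birth).
    For each truth ortholog pair (focal gene f, reference gene r) the
    reference copy gains ``Poisson(gain_rate_reference_lineage)`` extra
    terms; development-category terms are upweighted by
    ``category_gain_bias`` when f is a planted TSEEN gene.  Gains are
    recorded exactly in ``history.truth_gained_terms``.

    Returns ``{"ontology", "annotations"}`` where annotations is a list of
    (gene_id, term_id, evidence_code, aspect) rows sorted deterministically.
    """
    tree = tree or DEFAULT_TREE
    rng = np.random.default_rng([_STAGE_GO, seed])
    onto = toy_ontology()
    leaves = ontology_leaves(onto)
    dev_leaves = _category_leaf_sets(onto)["development"]

    lo, hi = config.go_terms_per_gene_range
    fam_terms: dict[str, list[str]] = {}
    gene_terms: dict[str, set[str]] = {}
    for g in history.genes:
        if g.family_id not in fam_terms:
            k = int(rng.integers(lo, hi + 1))
            fam_terms[g.family_id] = sorted(
                rng.choice(leaves, size=min(k, len(leaves)), replace=False))
        gene_terms[g.gene_id] = set(fam_terms[g.family_id])

    # plant gains once per reference-lineage gene; every focal ortholog of
    # that gene shares the same gained set (the gain event happened in the
    # reference lineage, not in the pair)
    history.truth_gained_terms = {}
    focal, ref = tree.focal_tip, tree.reference_tip
    sp_of = {g.gene_id: g.species for g in history.genes}
    focal_partners: dict[str, list[str]] = {}
    for a, b in history.truth_ortholog_pairs:
        if {sp_of[a], sp_of[b]} == {focal, ref}:
            f, r = (a, b) if sp_of[a] == focal else (b, a)
            focal_partners.setdefault(r, []).append(f)
    for r in sorted(focal_partners):
        fs = sorted(focal_partners[r])
        n_gain = int(rng.poisson(config.gain_rate_reference_lineage))
        pool = sorted(set(leaves) - gene_terms[r])
        n_gain = min(n_gain, len(pool))
        gained: frozenset = frozenset()
        if n_gain:
            biased = any(f in history.truth_tseen for f in fs)
            w = np.array([config.category_gain_bias
                          if (t in dev_leaves and biased) else 1.0
                          for t in pool])
            picks = rng.choice(pool, size=n_gain, replace=False, p=w / w.sum())
            gained = frozenset(str(t) for t in picks)
            gene_terms[r] |= gained
        for f in fs:
            history.truth_gained_terms[(f, r)] = gained

    rows = []
    for gid in sorted(gene_terms):
        for term in sorted(gene_terms[gid]):
            n_codes = 2 if rng.random() < 0.3 else 1
            codes = rng.choice(EVIDENCE_CODES, size=n_codes, replace=False)
            for code in sorted(str(c) for c in codes):
                rows.append((gid, term, code, onto["terms"][term][1]))

    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        write_obo(onto, os.path.join(outdir, "ontology.obo"))
        by_sp: dict[str, list] = {}
        for row in rows:
            by_sp.setdefault(sp_of[row[0]], []).append(row)
        for sp in sorted(by_sp):
            with open(os.path.join(outdir, f"go_{sp}.tsv"), "w") as fh:
                fh.write("gene_id\tterm_id\tevidence_code\taspect\n")
                for row in by_sp[sp]:
                    fh.write("\t".join(row) + "\n")

    return {"ontology": onto, "annotations": rows}


# ---------------------------------------------------------------------------
# expression counts
# ---------------------------------------------------------------------------

def nb_draws(rng: np.random.Generator, mean: float, dispersion: float,
             size) -> np.ndarray:
    """Negative-binomial draws parameterized by mean and dispersion r, with
    variance mean + mean^2 / r."""
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def emit_expression(history: FamilyHistory, config: SimConfig, seed: int,
                    outdir: Optional[str] = None,
                    tree: SpeciesTreeSpec = None):
    """Draw three-condition tag counts for every focal-species gene.

    Planted TSEEN genes draw exactly 0 tags in normal liver and NB counts in
    tumor and regressed libraries; other expressed genes draw NB counts in
    all three; a ``frac_silent`` fraction is silent everywhere.  Returns
    (counts DataFrame indexed by gene_id, truth_tseen set).
    """
    import pandas as pd

    tree = tree or DEFAULT_TREE
    rng = np.random.default_rng([_STAGE_EXPRESSION, seed])
    genes = history.genes_of(tree.focal_tip)
    tseen = history.truth_tseen
    non_tseen = [g for g in genes if g not in tseen]
    n_silent = int(round(config.frac_silent * len(non_tseen)))
    silent = set(rng.choice(non_tseen, size=n_silent, replace=False)) if n_silent else set()

    data = np.zeros((len(genes), 3), dtype=np.int64)
    for i, g in enumerate(genes):
        if g in silent:
            continue
        if g in tseen:
            data[i, 1] = nb_draws(rng, config.nb_mean, config.nb_dispersion, None)
            data[i, 2] = nb_draws(rng, config.nb_mean, config.nb_dispersion, None)
        else:
            data[i, :] = nb_draws(rng, config.nb_mean, config.nb_dispersion, 3)
    counts = pd.DataFrame(data, index=pd.Index(genes, name="gene_id"),
                          columns=CONDITIONS)
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        counts.to_csv(os.path.join(outdir, "counts.tsv"), sep="\t")
    return counts, set(tseen)


# ---------------------------------------------------------------------------
# one-call bundle
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    tree: SpeciesTreeSpec
    config: SimConfig
    history: FamilyHistory
    proteomes: dict
    ontology: dict
    annotations: list
    counts: "object"
    truth_tseen: set


def simulate_dataset(tree: SpeciesTreeSpec = None, config: SimConfig = None,
                     seed: int = 0, outdir: Optional[str] = None) -> SyntheticDataset:
    """Generate the full synthetic study: families, proteomes, GO, counts."""
    tree = tree or DEFAULT_TREE
    config = config or SimConfig()
    history = simulate_families(tree, config, seed)
    proteomes = emit_proteomes(history, tree, config, seed, outdir=outdir)
    go = emit_go(history, config, seed, outdir=outdir, tree=tree)
    counts, tseen = emit_expression(history, config, seed, outdir=outdir, tree=tree)
    if outdir is not None:
        with open(os.path.join(outdir, "truth.json"), "w") as fh:
            fh.write(history.to_json())
    return SyntheticDataset(tree, config, history, proteomes,
                            go["ontology"], go["annotations"], counts, tseen)
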