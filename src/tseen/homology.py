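"""Pairwise protein search: Smith-Waterman local alignment with affine
gaps, Karlin-Altschul E-values, and the published hit filters (E < 1e-3,
coverage >= 25% of either protein).

This is a desk-scale, exact search engine: every query/target pair is
aligned by full dynamic programming (no heuristic seeding), which is
feasible for proteomes of up to a few thousand sequences.  A gap of
length k costs ``gap_open + k * gap_extend`` (NCBI convention).  The
traceback reports one optimal alignment with ties broken
diagonal > up > left.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

ALPHABET = "ARNDCQEGHILKMFPSTWYVX"  # X = unknown, scores 0 vs anything
_CODE = {aa: i for i, aa in enumerate(ALPHABET)}
_X = _CODE["X"]


class SearchError(ValueError):
    pass


def encode(seq: str) -> np.ndarray:
    return np.array([_CODE.get(aa, _X) for aa in seq.upper()], dtype=np.int8)


def _blosum62_matrix() -> np.ndarray:
    from Bio.Align import substitution_matrices

    bl = substitution_matrices.load("BLOSUM62")
    mat = np.zeros((21, 21), dtype=np.int32)
    for i, a in enumerate(ALPHABET[:20]):
        for j, b in enumerate(ALPHABET[:20]):
            mat[i, j] = int(bl[a, b])
    # unknown residues are neutral
    mat[_X, :] = 0
    mat[:, _X] = 0
    return mat


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix (21x21 over ARNDCQEGHILKMFPSTWYVX) plus affine
    gap penalties.  A gap of length k costs ``gap_open + k * gap_extend``;
    the defaults (BLOSUM62, existence 11, extension 1) match the standard
    gapped setting the Gumbel parameters in
    :class:`KarlinAltschulParams` are fitted to."""
    substitution_matrix: np.ndarray = field(default_factory=_blosum62_matrix)
    gap_open: int = 11
    gap_extend: int = 1

    def __post_init__(self):
        m = self.substitution_matrix
        if m.shape != (21, 21):
            raise SearchError("substitution matrix must be 21x21 (20 aa + X)")
        if not np.array_equal(m, m.T):
            raise SearchError("substitution matrix must be symmetric")
        if float(m[:20, :20].mean()) >= 0:
            raise SearchError("expected score under uniform background must be < 0")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise SearchError("gap penalties must be >= 0")
        if self.gap_extend > self.gap_open:
            raise SearchError("gap_extend must be <= gap_open")


@dataclass(frozen=True)
class KarlinAltschulParams:
    """Gumbel parameters of the local-score distribution; defaults are the
    standard values for gapped BLOSUM62 (open 11 total, extend 1)."""
    lambda_: float = 0.267
    k_const: float = 0.041

    def __post_init__(self):
        if self.lambda_ <= 0 or self.k_const <= 0:
            raise SearchError("Karlin-Altschul parameters must be > 0")


@dataclass(frozen=True)
class SearchThresholds:
    """Published hit filter: E-value strictly below 1e-3 and alignment
    covering at least 25% of either protein."""
    max_evalue: float = 1e-3
    min_coverage: float = 0.25
    both_sequences: bool = False  # require min_coverage of both proteins

    def __post_init__(self):
        if self.max_evalue <= 0:
            raise SearchError("max_evalue must be > 0")
        if not (0 < self.min_coverage <= 1):
            raise SearchError("min_coverage must be in (0, 1]")


@njit(cache=True)
def _sw_fill(a, b, sub, gap_open, gap_ext):  # pragma: no cover - jit
    m = a.shape[0]
    n = b.shape[0]
    H = np.zeros((m + 1, n + 1), np.int32)
    E = np.zeros((m + 1, n + 1), np.int32)
    F = np.zeros((m + 1, n + 1), np.int32)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            e = H[i, j - 1] - gap_open - gap_ext
            if E[i, j - 1] - gap_ext > e:
                e = E[i, j - 1] - gap_ext
            E[i, j] = e
            f = H[i - 1, j] - gap_open - gap_ext
            if F[i - 1, j] - gap_ext > f:
                f = F[i - 1, j] - gap_ext
            F[i, j] = f
            h = H[i - 1, j - 1] + sub[a[i - 1], b[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    return H, E, F, best, bi, bj


@dataclass
class LocalAlignment:
    score: int
    query_span: tuple[int, int]    # 1-based inclusive
    subject_span: tuple[int, int]
    n_columns: int                 # aligned (non-gap) columns
    n_identical: int
    mismatches: int
    gap_opens: int
    alignment_length: int          # columns including gaps

    @property
    def identity(self) -> float:
        return self.n_identical / self.n_columns if self.n_columns else 0.0


def align_local(seq_a: str, seq_b: str,
                scoring: ScoringScheme = None) -> LocalAlignment:
    """Optimal local alignment of two protein sequences.

    Returns the best Smith-Waterman score under affine-gap dynamic
    programming and one optimal traceback (ties: diagonal > up > left).
    """
    if not seq_a or not seq_b:
        raise SearchError("sequences must be non-empty")
    scoring = scoring or ScoringScheme()
    a = encode(seq_a)
    b = encode(seq_b)
    sub = scoring.substitution_matrix
    H, E, F, best, bi, bj = _sw_fill(a, b, sub,
                                     scoring.gap_open, scoring.gap_extend)
    if best == 0:
        return LocalAlignment(0, (0, 0), (0, 0), 0, 0, 0, 0, 0)

    go, ge = scoring.gap_open, scoring.gap_extend
    i, j = bi, bj
    state = "H"
    n_cols = n_ident = mismatches = gap_opens = aln_len = 0
    while True:
        if state == "H":
            if H[i, j] == 0:
                break
            diag = H[i - 1, j - 1] + sub[a[i - 1], b[j - 1]]
            if H[i, j] == diag:
                n_cols += 1
                aln_len += 1
                if a[i - 1] == b[j - 1]:
                    n_ident += 1
                else:
                    mismatches += 1
                i -= 1
                j -= 1
            elif H[i, j] == F[i, j]:
                state = "F"
            else:
                state = "E"
        elif state == "F":  # vertical: consume query residue (gap in subject)
            aln_len += 1
            if F[i, j] == H[i - 1, j] - go - ge:
                gap_opens += 1
                state = "H"
            i -= 1
        else:  # E, horizontal: consume subject residue
            aln_len += 1
            if E[i, j] == H[i, j - 1] - go - ge:
                gap_opens += 1
                state = "H"
            j -= 1
    return LocalAlignment(int(best), (i + 1, bi), (j + 1, bj),
                          n_cols, n_ident, mismatches, gap_opens, aln_len)


def compute_evalue(score: float, m: int, n: int,
                   params: KarlinAltschulParams = KarlinAltschulParams()) -> float:
    """Karlin-Altschul expectation E = K * m * n * exp(-lambda * score) for
    a query of length m against a database of total length n."""
    if m <= 0 or n <= 0:
        raise SearchError("sequence/database lengths must be > 0")
    if score < 0:
        raise SearchError("score must be >= 0")
    return float(params.k_const * m * n * np.exp(-params.lambda_ * score))


@dataclass
class AlignmentHit:
    """A filtered local alignment between two proteins."""
    query_id: str
    subject_id: str
    score: int
    evalue: float
    identity: float
    query_cov: float
    subject_cov: float
    query_span: tuple[int, int]
    subject_span: tuple[int, int]
    n_columns: int = 0
    n_identical: int = 0
    mismatches: int = 0
    gap_opens: int = 0
    alignment_length: int = 0


def hit_filter(hit: AlignmentHit,
               thresholds: SearchThresholds = SearchThresholds()) -> bool:
    """Pass iff E-value is strictly below the cutoff and the alignment
    covers at least ``min_coverage`` of either protein (of both when
    ``both_sequences`` is set)."""
    if hit.evalue >= thresholds.max_evalue:
        return False
    if thresholds.both_sequences:
        return min(hit.query_cov, hit.subject_cov) >= thresholds.min_coverage
    return max(hit.query_cov, hit.subject_cov) >= thresholds.min_coverage


def _as_dict(seqs, label) -> dict[str, str]:
    if isinstance(seqs, dict):
        return seqs
    out = {}
    for sid, seq in seqs:
        if sid in out:
            raise SearchError(f"duplicate sequence id {sid!r} in {label}")
        out[sid] = seq
    return out


def all_vs_all_search(queries, targets,
                      scoring: ScoringScheme = None,
                      params: KarlinAltschulParams = KarlinAltschulParams(),
                      thresholds: SearchThresholds = SearchThresholds()
                      ) -> list[AlignmentHit]:
    """Align every query against every target and keep hits passing the
    filter; per query, hits are sorted by ascending E-value, then
    descending score, then subject id.

    E-values use the summed target length as the database size n, matching
    a one-round search of a full proteome.
    """
    queries = _as_dict(queries, "queries")
    targets = _as_dict(targets, "targets")
    if not queries or not targets:
        raise SearchError("query and target proteomes must be non-empty")
    scoring = scoring or ScoringScheme()
    db_len = sum(len(s) for s in targets.values())
    sub = scoring.substitution_matrix
    enc_t = {tid: encode(ts) for tid, ts in targets.items()}

    hits: list[AlignmentHit] = []
    for qid in sorted(queries):
        qseq = queries[qid]
        qenc = encode(qseq)
        qhits = []
        for tid in sorted(targets):
            tseq = targets[tid]
            _H, _E, _F, best, _bi, _bj = _sw_fill(
                qenc, enc_t[tid], sub, scoring.gap_open, scoring.gap_extend)
            if best <= 0:
                continue
            ev = compute_evalue(best, len(qseq), db_len, params)
            if ev >= thresholds.max_evalue:
                continue
            aln = align_local(qseq, tseq, scoring)
            hit = AlignmentHit(
                query_id=qid, subject_id=tid, score=aln.score, evalue=ev,
                identity=aln.identity,
                query_cov=(aln.query_span[1] - aln.query_span[0] + 1) / len(qseq),
                subject_cov=(aln.subject_span[1] - aln.subject_span[0] + 1) / len(tseq),
                query_span=aln.query_span, subject_span=aln.subject_span,
                n_columns=aln.n_columns, n_identical=aln.n_identical,
                mismatches=aln.mismatches, gap_opens=aln.gap_opens,
                alignment_length=aln.alignment_length)
            if hit_filter(hit, thresholds):
                qhits.append(hit)
        qhits.sort(key=lambda h: (h.evalue, -h.score, h.subject_id))
        hits.extend(qhits)
    return hits


def write_hits_tsv(hits: list[AlignmentHit], path):
    """12-column tab-separated records modeled on tabular BLAST output;
    ``path`` may be a filename or an open text stream."""
    fh = open(path, "w") if isinstance(path, str) else path
    try:
        for h in hits:
            fh.write("\t".join(map(str, [
                h.query_id, h.subject_id, round(h.identity * 100, 2),
                h.alignment_length, h.mismatches, h.gap_opens,
                h.query_span[0], h.query_span[1],
                h.subject_span[0], h.subject_span[1],
                f"{h.evalue:.3g}", h.score])) + "\n")
    finally:
        if isinstance(path, str):
            fh.close()


def read_fasta(path: str) -> dict[str, str]:
    from Bio import SeqIO

    out: dict[str, str] = {}
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in out:
            raise SearchError(f"duplicate sequence id {rec.id!r} in {path}")
        out[rec.id] = str(rec.seq)
    return out


def translate_six_frames(nucleotide: str) -> list[str]:
    """Six-frame translation front-end for nucleotide queries (the blastx
    use case); stops are emitted as X so downstream scoring stays defined."""
    from Bio.Seq import Seq

    seq = Seq(nucleotide.upper())
    frames = []
    for s in (seq, seq.reverse_complement()):
        for off in range(3):
            sub = s[off: len(s) - (len(s) - off) % 3]
            frames.append(str(sub.translate()).replace("*", "X"))
    return frames
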