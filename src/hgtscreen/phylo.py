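"""Phylogenetic validation of candidate donor origin.

For each candidate, the top hits from the six taxon databases (archaea,
bacteria, fungi, plants, metazoa, other eukaryotes) are gathered, aligned with
the candidate peptide, trimmed of gap-rich columns, and summarised as a
neighbor-joining tree on Kimura-corrected protein distances.  A candidate is
validated when it is monophyletic with the donor kingdom on the full-data
tree; column-bootstrap support for that grouping is reported alongside.

The tree stage deliberately trades the maximum-likelihood machinery typically
used for this task for a deterministic distance method: NJ on the same trimmed
alignment, with seeded bootstrap resampling.  ``nj_tree`` is an injection
point — any callable mapping a distance matrix to an skbio ``TreeNode`` can be
substituted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as _skbio_nj

from .homology import ProteinRecord, ScoringScheme, TaxonDb, search_db, TAXA

__all__ = [
    "ValidateConfig",
    "Msa",
    "ValidationResult",
    "collect_taxon_hits",
    "progressive_align",
    "trim_gap_columns",
    "pairwise_distance",
    "nj_tree",
    "monophyly_test",
    "bootstrap_support",
    "validate_candidate",
]

_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"
_AA_INDEX = {c: i for i, c in enumerate(_ALPHABET)}


@dataclass(frozen=True)
class ValidateConfig:
    hits_per_taxon: int = 5
    gap_trim_fraction: float = 0.20
    bootstrap_reps: int = 100
    support_min: float = 0.5  # reported, not gating
    min_bits: float = 30.0    # hit-inclusion floor, like a search E-value cut

    def __post_init__(self) -> None:
        if self.hits_per_taxon < 1 or self.bootstrap_reps < 1:
            raise ValueError("hits_per_taxon and bootstrap_reps must be >= 1")
        if not 0.0 < self.gap_trim_fraction < 1.0:
            raise ValueError("gap_trim_fraction must lie in (0,1)")


@dataclass(frozen=True)
class Msa:
    ids: tuple[str, ...]
    taxa: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("MSA rows differ in width")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate MSA row ids")

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def degapped(self, i: int) -> str:
        return self.rows[i].replace("-", "")


@dataclass(frozen=True)
class ValidationResult:
    candidate_id: str
    donor_taxon: str
    msa: Msa | None
    tree: TreeNode | None
    monophyletic: bool | None
    support: int | None
    bootstrap_reps: int
    verdict: str  # "validated" | "rejected" | "not_assessable"
    reason: str = ""


class TrimError(ValueError):
    """Gap trimming removed every column; relax gap_trim_fraction."""


# ---------------------------------------------------------------------------
# profile-profile progressive alignment

@njit
def _gotoh_profile(S, gap_open_total, gap_extend):  # pragma: no cover - numba
    """Global affine DP over a precomputed column-score matrix.

    Returns a traceback path of moves (1 diag, 2 up/gap-in-B, 3 left/gap-in-A)
    ordered from the start of the alignment.
    """
    n, m = S.shape
    NEG = -1e30
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in B (consume A row)
    Y = np.full((n + 1, m + 1), NEG)  # gap in A (consume B col)
    ptrM = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptrX = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptrY = np.zeros((n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -gap_open_total - (i - 1) * gap_extend
        ptrX[i, 0] = 2
    for j in range(1, m + 1):
        Y[0, j] = -gap_open_total - (j - 1) * gap_extend
        ptrY[0, j] = 3
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = S[i - 1, j - 1]
            # M: diag from best of M/X/Y
            best = M[i - 1, j - 1]
            p = 1
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                p = 2
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                p = 3
            M[i, j] = best + s
            ptrM[i, j] = p
            # X: gap in B, consume row i
            op = M[i - 1, j] - gap_open_total
            ext = X[i - 1, j] - gap_extend
            alt = Y[i - 1, j] - gap_open_total
            if op >= ext and op >= alt:
                X[i, j] = op
                ptrX[i, j] = 1
            elif ext >= alt:
                X[i, j] = ext
                ptrX[i, j] = 2
            else:
                X[i, j] = alt
                ptrX[i, j] = 3
            # Y: gap in A, consume col j
            op = M[i, j - 1] - gap_open_total
            ext = Y[i, j - 1] - gap_extend
            alt = X[i, j - 1] - gap_open_total
            if op >= ext and op >= alt:
                Y[i, j] = op
                ptrY[i, j] = 1
            elif ext >= alt:
                Y[i, j] = ext
                ptrY[i, j] = 2
            else:
                Y[i, j] = alt
                ptrY[i, j] = 3
    # traceback from best terminal state (prefer M, then X, then Y)
    state = 1
    best = M[n, m]
    if X[n, m] > best:
        best = X[n, m]
        state = 2
    if Y[n, m] > best:
        state = 3
    path = np.empty(n + m, dtype=np.int8)
    k = 0
    i, j = n, m
    while i > 0 or j > 0:
        if state == 1:
            prev = ptrM[i, j]
            path[k] = 1
            i -= 1
            j -= 1
        elif state == 2:
            prev = ptrX[i, j]
            path[k] = 2
            i -= 1
        else:
            prev = ptrY[i, j]
            path[k] = 3
            j -= 1
        k += 1
        state = prev
    return path[:k][::-1].copy()


def _profile(rows: list[str], matrix: np.ndarray) -> np.ndarray:
    """Column frequency matrix (width x alphabet); gaps carry zero weight."""
    w = len(rows[0])
    freq = np.zeros((w, len(_ALPHABET)))
    for r in rows:
        for j, c in enumerate(r):
            if c != "-":
                freq[j, _AA_INDEX[c]] += 1.0
    return freq / len(rows)


def _merge(rows_a: list[str], rows_b: list[str], M: np.ndarray,
           gap_open_total: float, gap_extend: float) -> list[str]:
    fa = _profile(rows_a, M)
    fb = _profile(rows_b, M)
    S = fa @ M @ fb.T
    path = _gotoh_profile(S, gap_open_total, gap_extend)
    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    i = j = 0
    for move in path:
        if move == 1:
            for k, r in enumerate(rows_a):
                out_a[k].append(r[i])
            for k, r in enumerate(rows_b):
                out_b[k].append(r[j])
            i += 1
            j += 1
        elif move == 2:
            for k, r in enumerate(rows_a):
                out_a[k].append(r[i])
            for k in range(len(rows_b)):
                out_b[k].append("-")
            i += 1
        else:
            for k in range(len(rows_a)):
                out_a[k].append("-")
            for k, r in enumerate(rows_b):
                out_b[k].append(r[j])
            j += 1
    return ["".join(r) for r in out_a] + ["".join(r) for r in out_b]


def _guide_order(seqs: list[str], scheme: ScoringScheme) -> list[list[int]]:
    """UPGMA merge schedule from normalised local-alignment similarities."""
    n = len(seqs)
    aligner = scheme.make_aligner("local")
    selfsc = [max(aligner.score(s, s), 1.0) for s in seqs]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            sim = aligner.score(seqs[i], seqs[j]) / min(selfsc[i], selfsc[j])
            d[i, j] = d[j, i] = 1.0 - min(max(sim, 0.0), 1.0)
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    dist = {frozenset((i, j)): d[i, j] for i in range(n) for j in range(i + 1, n)}
    schedule = []
    next_id = n
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for ai, a in enumerate(keys):
            for b in keys[ai + 1:]:
                dd = dist[frozenset((a, b))]
                if best is None or dd < best[0]:
                    best = (dd, a, b)
        _, a, b = best
        schedule.append((clusters[a], clusters[b]))
        merged = clusters[a] + clusters[b]
        na, nb = len(clusters[a]), len(clusters[b])
        del clusters[a], clusters[b]
        for c in clusters:
            dist[frozenset((next_id, c))] = (
                na * dist[frozenset((a, c))] + nb * dist[frozenset((b, c))]
            ) / (na + nb)
        clusters[next_id] = merged
        next_id += 1
    return schedule


def progressive_align(records: list[ProteinRecord],
                      scheme: ScoringScheme | None = None,
                      gap_open: float = 10.0, gap_extend: float = 1.0) -> Msa:
    """Progressive sum-of-pairs alignment (guide tree + profile merges).

    BLOSUM62 column scores; a gap of length L in a merge costs
    gap_open + L*gap_extend.  Degapping any output row reproduces its input.
    """
    if len(records) < 2:
        raise ValueError("progressive alignment needs at least 2 sequences")
    scheme = scheme or ScoringScheme()
    M = np.array(scheme.matrix, dtype=float)
    seqs = [r.sequence for r in records]
    schedule = _guide_order(seqs, scheme)
    aligned: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [s]) for i, s in enumerate(seqs)
    }
    # replay the schedule on live cluster states
    live: list[tuple[list[int], list[str]]] = []
    state = {frozenset([i]): ([i], [seqs[i]]) for i in range(len(seqs))}
    for mem_a, mem_b in schedule:
        ka, kb = frozenset(mem_a), frozenset(mem_b)
        ida, rows_a = state.pop(ka)
        idb, rows_b = state.pop(kb)
        merged_rows = _merge(rows_a, rows_b, M, gap_open + gap_extend, gap_extend)
        state[ka | kb] = (ida + idb, merged_rows)
    (order, rows), = state.values()
    # restore input order
    by_idx = {idx: row for idx, row in zip(order, rows)}
    rows = [by_idx[i] for i in range(len(records))]
    return Msa(tuple(r.id for r in records), tuple(r.taxon for r in records),
               tuple(rows))


def trim_gap_columns(m: Msa, cfg: ValidateConfig = ValidateConfig()) -> Msa:
    """Drop columns whose gap fraction strictly exceeds the threshold."""
    n = len(m.rows)
    keep = [j for j in range(m.width)
            if sum(r[j] == "-" for r in m.rows) / n <= cfg.gap_trim_fraction]
    if not keep:
        raise TrimError(
            "every column exceeded the gap fraction threshold "
            f"{cfg.gap_trim_fraction}; relax gap_trim_fraction")
    rows = tuple("".join(r[j] for j in keep) for r in m.rows)
    return Msa(m.ids, m.taxa, rows)


_P_CLAMP = 0.85
_D_MAX = 5.0


def _kimura(p: float) -> float:
    if p >= _P_CLAMP:
        return _D_MAX
    arg = 1.0 - p - 0.2 * p * p
    if arg <= 0.0:
        return _D_MAX
    return -math.log(arg)


def pairwise_distance(m: Msa, on_empty: str = "error") -> DistanceMatrix:
    """Kimura-corrected protein distances over mutually ungapped columns.

    ``on_empty`` controls pairs with no comparable column: "error" raises,
    "max" assigns the saturation distance (used during bootstrap resampling).
    """
    n = len(m.rows)
    if n < 2:
        raise ValueError("need at least 2 rows")
    arrs = [np.frombuffer(r.encode(), dtype=np.uint8) for r in m.rows]
    gap = ord("-")
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (arrs[i] != gap) & (arrs[j] != gap)
            ncomp = int(ok.sum())
            if ncomp == 0:
                if on_empty == "max":
                    dij = _D_MAX
                else:
                    raise ValueError(
                        f"no comparable columns between {m.ids[i]} and {m.ids[j]}")
            else:
                p = float((arrs[i][ok] != arrs[j][ok]).mean())
                dij = _kimura(p)
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(d, list(m.ids))


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbor joining (scikit-bio) with negative branch lengths clamped to 0."""
    if len(dm.ids) < 3:
        raise ValueError("NJ needs at least 3 labels")
    tree = _skbio_nj(dm)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


_ZERO_EDGE = 1e-8


def _bipartition_sides(tree: TreeNode, collapse_zero: bool = False) -> list[frozenset]:
    """Leaf sets under each non-root node (one side of each edge).

    With ``collapse_zero``, internal edges of (numerically) zero length are
    ignored, as if collapsed into a polytomy: a zero-length edge is an
    arbitrary resolution of a tie, not a supported grouping.
    """
    sides = []
    for node in tree.traverse(include_self=False):
        if node.is_tip():
            sides.append(frozenset([node.name]))
        elif not (collapse_zero and node.length is not None
                  and node.length <= _ZERO_EDGE):
            sides.append(frozenset(t.name for t in node.tips()))
    return sides


def monophyly_test(tree: TreeNode, query_leaf: str, donor_taxon: str,
                   taxon_of: dict[str, str]) -> bool:
    """Does the query nest exclusively with donor-taxon leaves?

    Among all bipartition sides that contain the query and at least one other
    leaf, the minimal-size side(s) must contain only donor-taxon leaves besides
    the query.  Zero-length internal edges (arbitrary resolutions of distance
    ties) are collapsed first.  A tree holding only the query and donor leaves
    passes.
    """
    leaves = frozenset(t.name for t in tree.tips())
    if query_leaf not in leaves:
        raise ValueError(f"query leaf {query_leaf!r} not in tree")
    candidates = []
    for side in _bipartition_sides(tree, collapse_zero=True):
        qside = side if query_leaf in side else leaves - side
        if len(qside) >= 2:
            candidates.append(qside)
    candidates.append(leaves)  # the trivial side: whole leaf set
    msize = min(len(s) for s in candidates)
    for side in candidates:
        if len(side) != msize:
            continue
        if not all(taxon_of[x] == donor_taxon for x in side if x != query_leaf):
            return False
    return True


def bootstrap_support(m: Msa, query_leaf: str, donor_taxon: str,
                      taxon_of: dict[str, str],
                      cfg: ValidateConfig = ValidateConfig(),
                      seed: int = 0) -> int:
    """Column-bootstrap replicates supporting the query-donor grouping."""
    rng = np.random.default_rng(seed)
    support = 0
    cols = m.width
    for _ in range(cfg.bootstrap_reps):
        idx = rng.integers(0, cols, size=cols)
        rows = tuple("".join(r[j] for j in idx) for r in m.rows)
        bm = Msa(m.ids, m.taxa, rows)
        try:
            dm = pairwise_distance(bm, on_empty="max")
            t = nj_tree(dm)
        except ValueError:
            continue
        if monophyly_test(t, query_leaf, donor_taxon, taxon_of):
            support += 1
    return support


def collect_taxon_hits(candidate_pep: str, dbs: dict[str, TaxonDb],
                       scheme: ScoringScheme = ScoringScheme(),
                       cfg: ValidateConfig = ValidateConfig()) -> list[ProteinRecord]:
    """Top hits_per_taxon records per taxon database, by bit score.

    Hits below ``cfg.min_bits`` are not collected: a conventional search
    engine would not report them at all, and admitting noise-level local
    alignments of unrelated proteins degrades the alignment and the tree.
    """
    seq_of = {}
    for db in dbs.values():
        for r in db.records:
            seq_of[r.id] = r
    kept: list[ProteinRecord] = []
    for taxon in TAXA:
        db = dbs.get(taxon)
        if db is None or not db.records:
            continue
        res = search_db("cand", candidate_pep, db, scheme,
                        top_n=cfg.hits_per_taxon)
        for h in res.hits[:cfg.hits_per_taxon]:
            if h.bit_score >= cfg.min_bits:
                kept.append(seq_of[h.subject_id])
    return kept


def validate_candidate(candidate_id: str, candidate_pep: str, donor_taxon: str,
                       dbs: dict[str, TaxonDb],
                       scheme: ScoringScheme = ScoringScheme(),
                       cfg: ValidateConfig = ValidateConfig(),
                       seed: int = 0) -> ValidationResult:
    """Full validation pipeline: collect, align, trim, tree, monophyly.

    The verdict comes from the full-data tree; bootstrap support is reported
    alongside.  Fewer than 3 usable sequences (query included) or a degenerate
    alignment yields "not_assessable".
    """
    if donor_taxon not in ("bacteria", "fungi"):
        raise ValueError("donor_taxon must be 'bacteria' or 'fungi'")
    hits = collect_taxon_hits(candidate_pep, dbs, scheme, cfg)
    records = [ProteinRecord(candidate_id, "query", candidate_pep)] + hits
    if len(records) < 3:
        return ValidationResult(candidate_id, donor_taxon, None, None, None,
                                None, cfg.bootstrap_reps, "not_assessable",
                                "fewer than 3 usable sequences")
    taxon_of = {r.id: r.taxon for r in records}
    non_query = {r.taxon for r in hits}
    if non_query <= {donor_taxon}:
        # only donor-taxon homologs exist: trivially monophyletic
        return ValidationResult(candidate_id, donor_taxon, None, None, True,
                                cfg.bootstrap_reps, cfg.bootstrap_reps,
                                "validated", "only donor-taxon homologs")
    try:
        msa = trim_gap_columns(progressive_align(records, scheme), cfg)
        dm = pairwise_distance(msa)
        tree = nj_tree(dm)
    except (TrimError, ValueError) as e:
        return ValidationResult(candidate_id, donor_taxon, None, None, None,
                                None, cfg.bootstrap_reps, "not_assessable",
                                str(e))
    mono = monophyly_test(tree, candidate_id, donor_taxon, taxon_of)
    support = bootstrap_support(msa, candidate_id, donor_taxon, taxon_of, cfg,
                                seed)
    verdict = "validated" if mono else "rejected"
    return ValidationResult(candidate_id, donor_taxon, msa, tree, mono,
                            support, cfg.bootstrap_reps, verdict)
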