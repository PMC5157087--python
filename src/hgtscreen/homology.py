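"""Local protein alignment, bit-score conversion, and taxon-database search.

Raw Smith–Waterman–Gotoh scores are normalised onto the bit scale with the
Karlin–Altschul transform  S' = (lambda * S - ln K) / ln 2, using the standard
gapped BLOSUM62 constants (lambda = 0.267, K = 0.041) by default.  The gap cost
convention is the NCBI one: a gap of length L costs gap_open + L * gap_extend,
so the defaults 11/1 charge 12 for a single-residue gap.

All hits carry 0-based half-open residue intervals.  Externally computed hits
in the conventional 12-column tabular format (1-based inclusive coordinates)
can be loaded as a drop-in substitute for the built-in aligner.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from Bio.Align import PairwiseAligner, substitution_matrices

__all__ = [
    "TAXA",
    "ScoringScheme",
    "ProteinRecord",
    "TaxonDb",
    "Hit",
    "SearchResult",
    "sw_align",
    "bit_score",
    "search_db",
    "load_tabular_hits",
    "write_tabular_hits",
]

TAXA = ("archaea", "bacteria", "fungi", "plants", "metazoa", "other_eukaryotes")


class AlphabetError(ValueError):
    """Residue outside the scoring matrix alphabet."""


@dataclass(frozen=True)
class ScoringScheme:
    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = 0.267
    K: float = 0.041

    def __post_init__(self) -> None:
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must not exceed gap_open")
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")

    @property
    def matrix(self):
        return substitution_matrices.load(self.matrix_name)

    def make_aligner(self, mode: str = "local",
                     gap_open: int | None = None,
                     gap_extend: int | None = None) -> PairwiseAligner:
        go = self.gap_open if gap_open is None else gap_open
        ge = self.gap_extend if gap_extend is None else gap_extend
        al = PairwiseAligner()
        al.mode = mode
        al.substitution_matrix = self.matrix
        # biopython charges open on the first gap residue: open+(L-1)*extend;
        # shift by extend to realise cost(L) = open + L*extend
        al.open_gap_score = -(go + ge)
        al.extend_gap_score = -ge
        return al


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    taxon: str
    sequence: str
    lineage: str = ""

    def __post_init__(self) -> None:
        if self.taxon not in TAXA + ("query",):
            raise ValueError(f"unknown taxon {self.taxon!r} for {self.id}")


@dataclass(frozen=True)
class TaxonDb:
    """A searchable protein partition with clade exclusions applied up front."""

    role: str  # "donor" | "eukaryote_background" | free-form
    records: tuple[ProteinRecord, ...]
    excluded_clades: tuple[str, ...] = ()

    @staticmethod
    def build(role: str, records: list[ProteinRecord],
              taxa: tuple[str, ...] | None = None,
              excluded_clades: tuple[str, ...] = ()) -> "TaxonDb":
        excl = tuple(excluded_clades)
        kept = tuple(
            r for r in records
            if (taxa is None or r.taxon in taxa)
            and not any(c.lower() in (r.lineage.lower(), r.taxon.lower())
                        for c in excl)
        )
        return TaxonDb(role, kept, excl)


@dataclass(frozen=True)
class Hit:
    query_id: str
    subject_id: str
    raw_score: float
    bit_score: float
    query_start: int = 0
    query_end: int = 0
    subject_start: int = 0
    subject_end: int = 0
    subject_taxon: str = ""

    def __post_init__(self) -> None:
        if self.raw_score < 0:
            raise ValueError("raw_score must be non-negative")


@dataclass(frozen=True)
class SearchResult:
    """Best hit plus top-N hits per taxon; ``best is None`` marks "no hit"."""

    query_id: str
    best: Hit | None
    by_taxon: dict[str, tuple[Hit, ...]] = field(default_factory=dict)

    @property
    def hits(self) -> list[Hit]:
        out = [h for hs in self.by_taxon.values() for h in hs]
        out.sort(key=lambda h: (-h.bit_score, h.subject_id))
        return out


def bit_score(raw: float, s: ScoringScheme) -> float:
    """Karlin–Altschul normalised score: (lambda*S - ln K) / ln 2."""
    if raw < 0:
        raise ValueError("raw score must be non-negative")
    return (s.lam * raw - math.log(s.K)) / math.log(2)


def _check_alphabet(pep: str, alphabet: str, label: str) -> None:
    bad = set(pep) - set(alphabet)
    if bad:
        raise AlphabetError(f"{label} contains residues {sorted(bad)} "
                            f"outside alphabet {alphabet!r}")


def sw_align(a: str, b: str, s: ScoringScheme = ScoringScheme(),
             query_id: str = "query", subject_id: str = "subject",
             subject_taxon: str = "", with_traceback: bool = True) -> Hit:
    """Best affine-gap local alignment of two peptides.

    Returns raw score 0 with an empty interval when no positive-scoring local
    alignment exists.  Traceback (for the intervals) prefers the alignment
    biopython ranks first, which is deterministic for fixed inputs.
    """
    if not a or not b:
        raise ValueError("peptides must be non-empty")
    alphabet = str(s.matrix.alphabet)
    _check_alphabet(a, alphabet, query_id)
    _check_alphabet(b, alphabet, subject_id)
    aligner = s.make_aligner("local")
    raw = aligner.score(a, b)
    if raw <= 0:
        return Hit(query_id, subject_id, 0.0, bit_score(0.0, s),
                   subject_taxon=subject_taxon)
    qs = qe = ss = se = 0
    if with_traceback:
        aln = next(iter(aligner.align(a, b)))
        qblocks, sblocks = aln.aligned
        qs, qe = int(qblocks[0][0]), int(qblocks[-1][1])
        ss, se = int(sblocks[0][0]), int(sblocks[-1][1])
    return Hit(query_id, subject_id, float(raw), bit_score(raw, s),
               qs, qe, ss, se, subject_taxon)


def search_db(query_id: str, query_pep: str, db: TaxonDb,
              s: ScoringScheme = ScoringScheme(), top_n: int = 5) -> SearchResult:
    """Exhaustively score a query against a taxon database.

    Hits with positive raw score are ranked by bit score (ties by subject id);
    the overall best and the top ``top_n`` per taxon are returned.  Traceback
    is computed only for the returned hits.
    """
    if not db.records:
        return SearchResult(query_id, None)
    aligner = s.make_aligner("local")
    scored = []
    for rec in db.records:
        raw = float(aligner.score(query_pep, rec.sequence))
        if raw > 0:
            scored.append((raw, rec))
    scored.sort(key=lambda t: (-t[0], t[1].id))
    by_taxon: dict[str, list[Hit]] = {}
    picked: dict[str, list[tuple[float, ProteinRecord]]] = {}
    for raw, rec in scored:
        lst = picked.setdefault(rec.taxon, [])
        if len(lst) < top_n:
            lst.append((raw, rec))
    best_hit = None
    for taxon, pairs in picked.items():
        hits = []
        for raw, rec in pairs:
            h = sw_align(query_pep, rec.sequence, s, query_id, rec.id,
                         rec.taxon)
            hits.append(h)
        hits.sort(key=lambda h: (-h.bit_score, h.subject_id))
        by_taxon[taxon] = hits
    result = SearchResult(query_id, None, {t: tuple(v) for t, v in by_taxon.items()})
    allhits = result.hits
    return replace(result, best=allhits[0] if allhits else None)


def load_tabular_hits(path, s: ScoringScheme = ScoringScheme()) -> list[Hit]:
    """Read 12-column tabular hits (qid sid pident len mism gapo qs qe ss se evalue bits).

    File coordinates are 1-based inclusive and converted to 0-based half-open.
    Bit scores are taken as given; raw scores are back-computed from the scheme.
    """
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ValueError(f"{path}:{lineno}: expected 12 columns, "
                                 f"got {len(parts)}")
            try:
                qid, sid = parts[0], parts[1]
                qs, qe = int(parts[6]) - 1, int(parts[7])
                ss, se = int(parts[8]) - 1, int(parts[9])
                bits = float(parts[11])
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: malformed row: {e}") from None
            raw = max(0.0, (bits * math.log(2) + math.log(s.K)) / s.lam)
            hits.append(Hit(qid, sid, raw, bits, qs, qe, ss, se))
    return hits


def write_tabular_hits(path, hits: list[Hit]) -> None:
    """Write hits in the 12-column format (identity/mismatch columns zeroed)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write("\t".join([
                h.query_id, h.subject_id, "0.0",
                str(h.query_end - h.query_start), "0", "0",
                str(h.query_start + 1), str(h.query_end),
                str(h.subject_start + 1), str(h.subject_end),
                "0.0", repr(h.bit_score),
            ]) + "\n")
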