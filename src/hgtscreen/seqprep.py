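"""Query preparation for the homology screen.

The screen operates on *potential polypeptides* (PPPs): stop-free segments of
the six-frame translation of the repeat-masked genome, at least ``min_ppp_len``
residues long.  Repeat regions are hard-masked to ``N`` beforehand; ``N``-bearing
codons translate to ``X`` and segments dominated by ``X`` are discarded, so
repeat-derived sequence never reaches the alignment stage.

Coordinates are 0-based half-open on the forward strand throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Data import CodonTable

__all__ = [
    "GenomeSequence",
    "MaskInterval",
    "FrameTranslation",
    "Ppp",
    "TranscriptAlignmentSummary",
    "SeqprepConfig",
    "apply_mask",
    "six_frame_translate",
    "extract_ppps",
    "filter_transcripts",
    "reverse_complement",
    "translate_nt",
]

_DNA_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
_CODON_TO_AA = dict(_STANDARD.forward_table)
for _stop in _STANDARD.stop_codons:
    _CODON_TO_AA[_stop] = "*"


class AlphabetError(ValueError):
    """Sequence contains characters outside the expected alphabet."""


class CoordinateError(ValueError):
    """An interval lies outside its sequence."""


@dataclass(frozen=True)
class GenomeSequence:
    id: str
    residues: str

    def __post_init__(self) -> None:
        bad = set(self.residues) - _DNA_ALPHABET
        if bad:
            raise AlphabetError(
                f"sequence {self.id!r} contains non-DNA characters {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class MaskInterval:
    seq_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise CoordinateError(
                f"invalid mask interval [{self.start},{self.end}) on {self.seq_id}"
            )


@dataclass(frozen=True)
class FrameTranslation:
    """One of the six reading-frame translations of a genome sequence.

    ``frame`` is +1/+2/+3 (forward, offset frame-1) or -1/-2/-3 (reverse
    complement, offset |frame|-1).  ``codon_interval(i)`` maps peptide index
    ``i`` to the forward-strand bp interval of its codon.
    """

    seq_id: str
    frame: int
    peptide: str
    seq_length: int

    def codon_interval(self, i: int) -> tuple[int, int]:
        off = abs(self.frame) - 1
        if self.frame > 0:
            start = off + 3 * i
            return start, start + 3
        end = self.seq_length - off - 3 * i
        return end - 3, end


@dataclass(frozen=True)
class Ppp:
    """A potential polypeptide: stop-free ≥min-length translated segment."""

    id: str
    seq_id: str
    frame: int
    pep: str
    genome_start: int
    genome_end: int

    @property
    def length(self) -> int:
        return len(self.pep)

    def __post_init__(self) -> None:
        if "*" in self.pep:
            raise ValueError(f"PPP {self.id} contains a stop")
        if self.genome_end - self.genome_start != 3 * len(self.pep):
            raise CoordinateError(
                f"PPP {self.id}: genome interval does not cover 3x peptide length"
            )


@dataclass(frozen=True)
class TranscriptAlignmentSummary:
    transcript_id: str
    seq_id: str
    coverage: float
    identity: float
    genome_start: int = 0
    genome_end: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.coverage <= 1.0 and 0.0 <= self.identity <= 1.0):
            raise ValueError(
                f"coverage/identity out of [0,1] for {self.transcript_id}"
            )


@dataclass(frozen=True)
class SeqprepConfig:
    min_ppp_len: int = 60
    max_x_fraction: float = 0.10
    transcript_min_coverage: float = 0.90
    transcript_min_identity: float = 0.97

    def __post_init__(self) -> None:
        if self.min_ppp_len < 1:
            raise ValueError("min_ppp_len must be >= 1")
        for f in (self.max_x_fraction, self.transcript_min_coverage,
                  self.transcript_min_identity):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0,1]")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_nt(seq: str) -> str:
    """Translate a DNA string in frame; codons with N (or partial) become X."""
    aa = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i:i + 3]
        aa.append(_CODON_TO_AA.get(codon, "X"))
    return "".join(aa)


def apply_mask(genome: GenomeSequence, masks: list[MaskInterval]) -> GenomeSequence:
    """Hard-mask intervals to N.  Idempotent; unmasked positions untouched."""
    if not masks:
        return genome
    residues = list(genome.residues)
    for m in masks:
        if m.seq_id != genome.id:
            continue
        if m.end > genome.length:
            raise CoordinateError(
                f"mask [{m.start},{m.end}) exceeds length {genome.length} of {genome.id}"
            )
        residues[m.start:m.end] = "N" * (m.end - m.start)
    return GenomeSequence(genome.id, "".join(residues))


def six_frame_translate(genome: GenomeSequence) -> list[FrameTranslation]:
    """Translate all six reading frames under the standard genetic code."""
    if genome.length == 0:
        raise ValueError(f"genome sequence {genome.id!r} is empty")
    fwd = genome.residues
    rev = reverse_complement(fwd)
    out = []
    for frame in (1, 2, 3):
        out.append(FrameTranslation(genome.id, frame,
                                    translate_nt(fwd[frame - 1:]), genome.length))
    for frame in (1, 2, 3):
        out.append(FrameTranslation(genome.id, -frame,
                                    translate_nt(rev[frame - 1:]), genome.length))
    return out


_X_RUN_SPLIT = 10  # a masked (all-X) run this long splits a segment


def _segments(peptide: str):
    """(start, end) ranges of stop-free segments, also split at long X runs.

    Hard-masked repeat tracts translate to uninterrupted X runs that would
    otherwise fuse with flanking genic sequence and drag it over the
    X-fraction limit; a run of >= 10 X acts as a segment boundary.
    """
    start = 0
    xrun = 0
    for i, aa in enumerate(peptide):
        if aa == "*" or (aa == "X" and xrun + 1 >= _X_RUN_SPLIT):
            seg_end = i - xrun if aa == "X" else i
            if seg_end > start:
                yield start, seg_end
            start = i + 1
            xrun = 0
        elif aa == "X":
            xrun += 1
        else:
            xrun = 0
    if len(peptide) > start:
        yield start, len(peptide)


def extract_ppps(frames: list[FrameTranslation],
                 cfg: SeqprepConfig = SeqprepConfig()) -> list[Ppp]:
    """Split frame peptides at stops and keep qualifying segments.

    A segment qualifies if it is at least ``min_ppp_len`` residues and its X
    fraction is at most ``max_x_fraction``.  Output is sorted by
    (seq_id, genome_start, frame) and ids are assigned in that order.
    """
    raw = []
    for ft in frames:
        for a, b in _segments(ft.peptide):
            if b - a < cfg.min_ppp_len:
                continue
            pep = ft.peptide[a:b]
            if pep.count("X") / len(pep) > cfg.max_x_fraction:
                continue
            s0, _ = ft.codon_interval(a)
            s1, _ = ft.codon_interval(b - 1)
            lo, hi = (s0, s1 + 3) if ft.frame > 0 else (s1, s0 + 3)
            raw.append((ft.seq_id, lo, hi, ft.frame, pep))
    raw.sort(key=lambda r: (r[0], r[1], r[3]))
    return [
        Ppp(f"{seq_id}|ppp{i:05d}", seq_id, frame, pep, lo, hi)
        for i, (seq_id, lo, hi, frame, pep) in enumerate(raw)
    ]


def filter_transcripts(summaries: list[TranscriptAlignmentSummary],
                       cfg: SeqprepConfig = SeqprepConfig()) -> set[str]:
    """Keep transcripts aligned with coverage and identity at or above threshold."""
    return {
        s.transcript_id
        for s in summaries
        if s.coverage >= cfg.transcript_min_coverage
        and s.identity >= cfg.transcript_min_identity
    }
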