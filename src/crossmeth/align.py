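"""Global pairwise alignment of bisulfite-converted promoter sequences.

Cross-species CpG orthology is read off a global alignment of the two
species' amplicons, converted in the CpG-retaining (fully methylated)
mode so that CpG cytosines survive conversion and anchor the alignment.
The aligner is Needleman-Wunsch with affine gaps via Biopython's
PairwiseAligner; the exposed contract is the scoring scheme, determinism
for fixed scoring, and a per-column map from alignment columns back to
positions in each input sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align

from .sequence import NucleotideSequence

__all__ = ["AlignmentScoring", "PairwiseAlignment", "AlignmentError", "align_pair"]


class AlignmentError(ValueError):
    """Unalignable input (e.g. all-N sequence)."""


@dataclass(frozen=True)
class AlignmentScoring:
    """Affine-gap scoring.  A gap of length k scores open + (k-1)*extend."""

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -4.0
    gap_extend: float = -1.0
    end_gap_free: bool = False


@dataclass(frozen=True)
class PairwiseAlignment:
    """A global alignment of two sequences.

    ``aligned_a``/``aligned_b`` are equal-length gapped strings ('-' for
    gaps).  ``column_to_a``/``column_to_b`` map each alignment column to a
    0-based position in the respective ungapped input, or None at a gap.
    """

    id_a: str
    id_b: str
    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings must have equal length")

    @property
    def n_columns(self) -> int:
        return len(self.aligned_a)

    @property
    def column_to_a(self) -> list[int | None]:
        return _column_map(self.aligned_a)

    @property
    def column_to_b(self) -> list[int | None]:
        return _column_map(self.aligned_b)

    def position_map_a_to_b(self) -> dict[int, int | None]:
        """Map every position of sequence A to its aligned position in B."""
        out: dict[int, int | None] = {}
        for pa, pb in zip(self.column_to_a, self.column_to_b):
            if pa is not None:
                out[pa] = pb
            # gap in A: nothing to map
        return out

    def position_map_b_to_a(self) -> dict[int, int | None]:
        out: dict[int, int | None] = {}
        for pa, pb in zip(self.column_to_a, self.column_to_b):
            if pb is not None:
                out[pb] = pa
        return out

    @classmethod
    def identity(cls, seq_a: NucleotideSequence, seq_b: NucleotideSequence) -> "PairwiseAlignment":
        """Gap-free column map for equal-length sequences.

        Valid when the two sequences are known to differ only by
        substitutions (e.g. simulated evolution without indels).
        """
        if len(seq_a) != len(seq_b):
            raise AlignmentError("identity alignment requires equal lengths")
        score = sum(a == b for a, b in zip(seq_a.residues, seq_b.residues))
        return cls(seq_a.id, seq_b.id, seq_a.residues, seq_b.residues, float(score))


def _column_map(gapped: str) -> list[int | None]:
    out: list[int | None] = []
    pos = 0
    for ch in gapped:
        if ch == "-":
            out.append(None)
        else:
            out.append(pos)
            pos += 1
    return out


def align_pair(
    seq_a: NucleotideSequence,
    seq_b: NucleotideSequence,
    scoring: AlignmentScoring = AlignmentScoring(),
) -> PairwiseAlignment:
    """Globally align two sequences under affine-gap scoring.

    Deterministic for fixed inputs and scoring: among co-optimal
    alignments the aligner's canonical first traceback is returned.
    With ``scoring.end_gap_free`` terminal gaps are not penalized
    (semi-global alignment).
    """
    if len(seq_a) == 0 or len(seq_b) == 0:
        raise AlignmentError("cannot align empty sequence")
    if set(seq_a.residues) == {"N"} or set(seq_b.residues) == {"N"}:
        raise AlignmentError("cannot align all-N sequence")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    if scoring.end_gap_free:
        try:
            aligner.end_insertion_score = 0.0
            aligner.end_deletion_score = 0.0
        except AttributeError:  # older Biopython naming
            aligner.target_end_gap_score = 0.0
            aligner.query_end_gap_score = 0.0
    alignments = aligner.align(seq_a.residues, seq_b.residues)
    best = alignments[0]
    ga, gb = str(best[0]), str(best[1])
    return PairwiseAlignment(seq_a.id, seq_b.id, ga, gb, float(best.score))
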