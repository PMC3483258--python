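"""Sequence-level primitives for promoter methylation analysis.

CpG dinucleotides are the substrate of vertebrate DNA methylation; a
promoter's CpG density relative to its base composition (the observed/
expected CpG ratio, CpGo/e) separates CpG-island promoters from CpG-poor
ones.  Bisulfite chemistry converts unmethylated cytosine to uracil (read
as thymine) while 5-methyl-cytosine in a CpG context is protected; the
in-silico analogue here is used to prepare sequences for cross-species
alignment of bisulfite-assay amplicons.

All coordinates are 0-based; only plus-strand CpGs are enumerated (the
dinucleotide is its own reverse complement, so one strand suffices).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Literal

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "NucleotideSequence",
    "CpGSite",
    "UndefinedRatioError",
    "find_cpg_sites",
    "cpg_oe_ratio",
    "bisulfite_convert",
    "fraction_n",
    "read_fasta",
    "write_fasta",
]

_VALID = set("ACGTN")


class UndefinedRatioError(ValueError):
    """Raised when CpGo/e is requested for a sequence lacking C or G."""


@dataclass(frozen=True)
class NucleotideSequence:
    """An uppercase IUPAC DNA sequence (A, C, G, T, N).

    Parameters
    ----------
    id : str
        Record identifier (FASTA header word).
    residues : str
        Sequence text; lower-case input is upper-cased on construction.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        res = self.residues.upper()
        bad = set(res) - _VALID
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-ACGTN residues: {sorted(bad)}"
            )
        object.__setattr__(self, "residues", res)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True, order=True)
class CpGSite:
    """Position of the C of a plus-strand CpG dinucleotide (0-based)."""

    sequence_id: str
    position: int


def find_cpg_sites(seq: NucleotideSequence) -> list[CpGSite]:
    """Return all CpG sites of `seq` in ascending position order.

    A site is every offset ``i`` with ``residues[i:i+2] == "CG"``.
    """
    res = seq.residues
    out = []
    i = res.find("CG")
    while i != -1:
        out.append(CpGSite(seq.id, i))
        i = res.find("CG", i + 1)
    return out


def fraction_n(seq: NucleotideSequence) -> float:
    """Fraction of residues that are N (0 for the empty sequence)."""
    if len(seq) == 0:
        return 0.0
    return seq.residues.count("N") / len(seq)


def cpg_oe_ratio(seq: NucleotideSequence, *, max_n_fraction: float = 0.5) -> float:
    """Observed/expected CpG ratio: (N_CpG / (N_C * N_G)) * L.

    N bases are excluded from all counts, including the length ``L``.
    High values (approaching 1) mark CpG islands; bulk genomic DNA sits
    near 0.2-0.4 because methylated CpGs decay by deamination.

    Raises
    ------
    UndefinedRatioError
        If the sequence has no C or no G.
    ValueError
        If more than `max_n_fraction` of the residues are N; such
        intervals are low-quality and the ratio would be unstable.
    """
    if fraction_n(seq) > max_n_fraction:
        raise ValueError(
            f"sequence {seq.id!r}: >{max_n_fraction:.0%} N residues; "
            "CpGo/e not computed for low-quality intervals"
        )
    res = seq.residues
    n_c = res.count("C")
    n_g = res.count("G")
    if n_c == 0 or n_g == 0:
        raise UndefinedRatioError(
            f"sequence {seq.id!r} has N_C={n_c}, N_G={n_g}; CpGo/e undefined"
        )
    n_cpg = len(find_cpg_sites(seq))
    length = len(res) - res.count("N")
    return n_cpg / (n_c * n_g) * length


BisulfiteMode = Literal["methylated_CpG", "unmethylated_CpG"]


def bisulfite_convert(
    seq: NucleotideSequence, mode: BisulfiteMode = "methylated_CpG"
) -> NucleotideSequence:
    """In-silico bisulfite conversion.

    Every C outside a CpG context becomes T.  In mode ``methylated_CpG``
    (the default) CpG cytosines are retained — the fully-methylated
    template — which preserves CpG positions and lets them anchor a
    cross-species alignment.  In mode ``unmethylated_CpG`` every C is
    converted.  Length is always preserved.
    """
    if mode not in ("methylated_CpG", "unmethylated_CpG"):
        raise ValueError(f"unknown bisulfite mode: {mode!r}")
    res = seq.residues
    out = []
    n = len(res)
    for i, base in enumerate(res):
        if base != "C":
            out.append(base)
        elif mode == "methylated_CpG" and i + 1 < n and res[i + 1] == "G":
            out.append("C")
        else:
            out.append("T")
    return NucleotideSequence(seq.id, "".join(out))


def read_fasta(path: str | Path) -> list[NucleotideSequence]:
    """Read a FASTA file into NucleotideSequence records."""
    return [
        NucleotideSequence(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(seqs: Iterable[NucleotideSequence], path: str | Path) -> None:
    """Write records as 60-column wrapped FASTA."""
    records: Iterator[SeqRecord] = (
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs
    )
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
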