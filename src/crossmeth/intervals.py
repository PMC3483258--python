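"""Genomic intervals and the cross-species promoter region design.

The region-design procedure mirrors how a custom promoter tiling array for
a second species is derived from a reference species' promoter set: each
reference promoter is aligned to the target genome, queries with ambiguous
placement (too many hits) are discarded, surviving target intervals are
merged where they overlap, short merged regions are dropped as likely
false orthologs, and the remainder are extended symmetrically to a common
target length (the reference promoter span).

Internal coordinates are 0-based half-open.  Region strings of the form
``chrN:a-b`` are 1-based inclusive on input/output, the convention used in
genome browsers and in published coordinate tables.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

__all__ = [
    "GenomicInterval",
    "AlignmentHit",
    "RegionParseError",
    "parse_region_string",
    "format_region_string",
    "select_orthologous_regions",
    "merge_overlapping",
    "filter_and_extend",
    "read_bed",
    "write_bed",
]


class RegionParseError(ValueError):
    """Malformed region string."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Species-tagged interval, 0-based half-open.

    ``flags`` carries provenance markers such as ``clipped`` (extension
    truncated at a chromosome boundary).
    """

    chrom: str
    start: int
    end: int
    species: str = ""
    strand: str = "+"
    name: str = ""
    flags: frozenset[str] = field(default_factory=frozenset, compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class AlignmentHit:
    """One alignment hit of a query region onto a target genome (PSL-like)."""

    query: GenomicInterval
    target: GenomicInterval
    score: float


_REGION_RE = re.compile(r"^(?P<chrom>[\w.]+):(?P<start>\d+)-(?P<end>\d+)$")


def parse_region_string(text: str, species: str = "", strand: str = "+") -> GenomicInterval:
    """Parse ``chrN:a-b`` (1-based, inclusive) into a 0-based half-open interval.

    ``chr12:51281338-51281660`` becomes (chr12, 51281337, 51281660),
    length 323.
    """
    m = _REGION_RE.match(text.strip())
    if not m:
        raise RegionParseError(f"malformed region string: {text!r}")
    a, b = int(m["start"]), int(m["end"])
    if a < 1 or a > b:
        raise RegionParseError(f"region {text!r}: need 1 <= start <= end")
    return GenomicInterval(m["chrom"], a - 1, b, species=species, strand=strand)


def format_region_string(iv: GenomicInterval) -> str:
    """Render an interval back to 1-based inclusive ``chrN:a-b`` form."""
    return f"{iv.chrom}:{iv.start + 1}-{iv.end}"


def select_orthologous_regions(
    hits: Iterable[AlignmentHit], max_hits: int = 1
) -> list[GenomicInterval]:
    """Resolve alignment hits to one target interval per unambiguous query.

    Queries with more than `max_hits` hits are dropped entirely — a query
    hitting many places cannot be assigned a unique ortholog.  For each
    retained query the best-scoring target interval is kept (ties broken
    by target coordinate for determinism).

    ``max_hits=1`` demands unique placement; ``max_hits=2`` reproduces a
    literal reading of "more than two hits were removed".
    """
    if max_hits < 1:
        raise ValueError("max_hits must be >= 1")
    by_query: dict[tuple, list[AlignmentHit]] = {}
    for h in hits:
        key = (h.query.species, h.query.chrom, h.query.start, h.query.end, h.query.name)
        by_query.setdefault(key, []).append(h)
    out = []
    for key in sorted(by_query):
        group = by_query[key]
        if len(group) > max_hits:
            continue
        best = max(group, key=lambda h: (h.score, h.target.chrom, -h.target.start))
        out.append(best.target)
    return out


def merge_overlapping(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping (or touching) intervals per chromosome.

    Output is sorted and disjoint; the union of covered bases is exactly
    preserved.  Species/strand of the first interval in each merged run
    is retained.
    """
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    out: list[GenomicInterval] = []
    for iv in ivs:
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            prev = out[-1]
            if iv.end > prev.end:
                out[-1] = replace(prev, end=iv.end)
        else:
            out.append(iv)
    return out


def filter_and_extend(
    intervals: Iterable[GenomicInterval],
    min_length: int = 1700,
    target_length: int = 2700,
    chrom_bounds: Mapping[str, int] | None = None,
) -> list[GenomicInterval]:
    """Drop short merged regions and extend the rest to a common length.

    Regions shorter than `min_length` are removed (likely false orthologs
    or highly diverged regions).  Remaining regions shorter than
    `target_length` are extended symmetrically; an odd remainder puts the
    extra base on the 3' (right, in genome coordinates) side.  Extension
    is clipped at 0 and at ``chrom_bounds[chrom]`` when bounds are given;
    clipped intervals carry the ``clipped`` flag.
    """
    if target_length < min_length:
        raise ValueError(
            f"target_length ({target_length}) must be >= min_length ({min_length})"
        )
    out = []
    for iv in intervals:
        if iv.length < min_length:
            continue
        if iv.length >= target_length:
            out.append(iv)
            continue
        add = target_length - iv.length
        left = add // 2
        right = add - left  # odd remainder goes 3'
        start = iv.start - left
        end = iv.end + right
        flags = set(iv.flags)
        if start < 0:
            start = 0
            flags.add("clipped")
        bound = None if chrom_bounds is None else chrom_bounds.get(iv.chrom)
        if bound is not None and end > bound:
            end = bound
            flags.add("clipped")
        out.append(replace(iv, start=start, end=end, flags=frozenset(flags)))
    return out


def read_bed(path, species: str = "") -> list[GenomicInterval]:
    """Read a BED3+ file (0-based half-open, per the standard)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else ""
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "+"
            out.append(
                GenomicInterval(chrom, start, end, species=species, strand=strand, name=name)
            )
    return out


def write_bed(intervals: Sequence[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t0\t{iv.strand}\n")
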