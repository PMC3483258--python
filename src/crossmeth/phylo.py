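"""Lineage-specific methylation classification on a species tree.

Given mean methylation of an orthologous region in three or more species
plus a designated outgroup (e.g. human, chimpanzee, rhesus macaque with
rat as outgroup), classify the pattern of divergence: a single species
deviating from an otherwise-conserved background is a lineage-specific
gain (hypermethylation) or loss (hypomethylation) on that terminal
branch, polarized by the outgroup; broader scatter is multi-species
divergence.  The rule is threshold-based — this assay's effect sizes
(methylation fractions) are large relative to within-species noise, so a
parsimony/likelihood machinery over branch lengths would be overkill for
four taxa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import dendropy

__all__ = ["TaxonMethylation", "LineageCall", "classify_lineage_pattern"]

_PATTERNS = (
    "no_change",
    "lineage_specific_increase",
    "lineage_specific_decrease",
    "multi_species_divergence",
    "unresolved",
)


@dataclass(frozen=True)
class TaxonMethylation:
    """Per-species mean methylation of one region plus the species tree.

    `tree` is a newick string whose leaf labels include every species
    with data; `outgroup` names the taxon used to polarize changes.
    Species present in the tree but without data (failed assays, missing
    orthologs) are simply absent from `levels`.
    """

    levels: Mapping[str, float]
    tree: str
    outgroup: str
    stderr: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sp, v in self.levels.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"methylation of {sp!r} outside [0,1]: {v}")
        t = dendropy.Tree.get(data=self.tree, schema="newick")
        leaves = {lf.taxon.label for lf in t.leaf_node_iter()}
        unknown = set(self.levels) - leaves
        if unknown:
            raise ValueError(f"species not in tree: {sorted(unknown)}")
        if self.outgroup not in leaves:
            raise ValueError(f"outgroup {self.outgroup!r} not a tree leaf")

    @property
    def ingroup(self) -> dict[str, float]:
        return {sp: v for sp, v in self.levels.items() if sp != self.outgroup}

    @property
    def has_outgroup_data(self) -> bool:
        return self.outgroup in self.levels


@dataclass(frozen=True)
class LineageCall:
    """Classification of a region's cross-species methylation pattern."""

    pattern: str
    focal_species: str | None = None
    effect: float = math.nan  # focal level minus background median

    def __post_init__(self) -> None:
        if self.pattern not in _PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if self.pattern.startswith("lineage_specific") and not self.focal_species:
            raise ValueError("lineage-specific call must name a focal species")


def _median(values) -> float:
    s = sorted(values)
    n = len(s)
    return s[n // 2] if n % 2 else (s[n // 2 - 1] + s[n // 2]) / 2


def classify_lineage_pattern(data: TaxonMethylation, delta: float = 0.2) -> LineageCall:
    """Classify one region's methylation pattern across species.

    A species is a *qualified deviant* when its level differs from the
    median of the other measured species by more than `delta` while
    those background species span at most `delta` among themselves
    (both conditions together — with only two background species the
    median alone would flag spurious deviants).  Exactly one qualified
    ingroup deviant is a lineage-specific increase/decrease; that call
    is downgraded to ``unresolved`` when the outgroup has no data (the
    direction of change cannot be polarized).  A qualified deviant
    outgroup with a conserved ingroup is ``no_change`` (the shift lies
    on the outgroup branch, not on any ingroup lineage).  Otherwise:
    total range <= delta is ``no_change``; anything broader is
    ``multi_species_divergence``.
    """
    if not (0.0 < delta < 1.0):
        raise ValueError(f"delta must be in (0,1), got {delta}")
    levels = dict(data.levels)
    if len(levels) < 3:
        raise ValueError(f"need >=3 species with data, got {len(levels)}")

    qualified = []
    for sp, v in levels.items():
        background = [u for s, u in levels.items() if s != sp]
        dev = v - _median(background)
        if abs(dev) > delta and max(background) - min(background) <= delta:
            qualified.append((sp, dev))

    full_range = max(levels.values()) - min(levels.values())

    if len(qualified) == 1:
        sp, dev = qualified[0]
        if sp == data.outgroup:
            return LineageCall("no_change")
        if not data.has_outgroup_data:
            return LineageCall("unresolved", focal_species=sp, effect=dev)
        pattern = "lineage_specific_increase" if dev > 0 else "lineage_specific_decrease"
        return LineageCall(pattern, focal_species=sp, effect=dev)

    if not qualified and full_range <= delta:
        return LineageCall("no_change")
    return LineageCall("multi_species_divergence")
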