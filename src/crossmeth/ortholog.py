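"""Orthologous CpG-site and CpG-unit pairing between two species.

Mass-spectrometry bisulfite assays (EpiTYPER-style) report methylation per
*CpG unit* — one CpG site or several consecutive sites measured as a
single value.  Fragmentation differs between species, so units do not
correspond one-to-one across a species pair.  Pairing proceeds in two
steps:

1. *Site orthology*: two CpG sites are orthologous when their C residues
   occupy the same column of the cross-species alignment
   (`map_orthologous_sites`).  Sites whose counterpart position carries no
   CpG reflect lineage-specific CpG loss/gain and are permitted.

2. *Unit pairing with merging* (`pair_cpg_units`): units are nodes of a
   bipartite graph with an edge for every orthologous site pair linking
   them; each connected component becomes one merged unit group per side.
   A component is only eligible if every member site either has its
   orthologous partner inside the component or has no CpG counterpart at
   all — a partner measured in a different unit group (conflicting
   partner) or a CpG counterpart that was never measured (ineligible
   counterpart) disqualifies the whole component, because its merged
   means would not cover the same set of underlying sites in both
   species.  Units with no orthologous site at all are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .align import PairwiseAlignment

__all__ = [
    "CpGUnit",
    "OrthologousSitePair",
    "PairedUnitGroup",
    "PairedUnitSet",
    "SiteIntegrityError",
    "map_orthologous_sites",
    "pair_cpg_units",
    "write_paired_units_tsv",
]

NO_ORTHOLOGOUS_SITE = "no_orthologous_site"
CONFLICTING_PARTNER = "conflicting_partner"
INELIGIBLE_COUNTERPART = "ineligible_counterpart"


class SiteIntegrityError(ValueError):
    """Sites inconsistent with the aligned sequences or unit definitions."""


@dataclass(frozen=True, order=True)
class CpGUnit:
    """A measured CpG unit: consecutive CpG sites reported as one value."""

    unit_id: str
    sites: tuple[int, ...]  # positions of the member C residues, ascending

    def __post_init__(self) -> None:
        if not self.sites:
            raise ValueError(f"unit {self.unit_id!r} has no member sites")
        if list(self.sites) != sorted(set(self.sites)):
            raise ValueError(f"unit {self.unit_id!r} sites must be strictly ascending")


@dataclass(frozen=True, order=True)
class OrthologousSitePair:
    """CpG sites of two species whose Cs share an alignment column."""

    site_a: int
    site_b: int
    column: int


@dataclass(frozen=True)
class PairedUnitGroup:
    """One merged unit group per species, tied by >=1 orthologous site pair."""

    group_id: str
    units_a: tuple[str, ...]
    units_b: tuple[str, ...]
    site_pairs: tuple[OrthologousSitePair, ...]


@dataclass(frozen=True)
class PairedUnitSet:
    """Outcome of unit pairing: retained groups and per-unit exclusions."""

    groups: tuple[PairedUnitGroup, ...]
    excluded_a: Mapping[str, str] = field(default_factory=dict)  # unit_id -> reason
    excluded_b: Mapping[str, str] = field(default_factory=dict)

    @property
    def n_paired_a(self) -> int:
        return sum(len(g.units_a) for g in self.groups)

    @property
    def n_paired_b(self) -> int:
        return sum(len(g.units_b) for g in self.groups)

    def paired_unit_ids_a(self) -> set[str]:
        return {u for g in self.groups for u in g.units_a}

    def paired_unit_ids_b(self) -> set[str]:
        return {u for g in self.groups for u in g.units_b}


def map_orthologous_sites(
    aln: PairwiseAlignment,
    sites_a: Iterable[int],
    sites_b: Iterable[int],
) -> list[OrthologousSitePair]:
    """Pair CpG sites whose C residues share an alignment column.

    `sites_a`/`sites_b` are 0-based positions of CpG Cs in the *ungapped*
    sequences.  One-to-one by construction (alignment columns are).
    Raises SiteIntegrityError if a claimed site does not carry a C in the
    aligned sequence.
    """
    col_a = aln.column_to_a
    col_b = aln.column_to_b
    pos_to_col_a = {p: c for c, p in enumerate(col_a) if p is not None}
    pos_to_col_b = {p: c for c, p in enumerate(col_b) if p is not None}
    sa = sorted(set(sites_a))
    sb_set = set(sites_b)

    for p in sa:
        if p not in pos_to_col_a:
            raise SiteIntegrityError(f"site {p} beyond sequence A ({aln.id_a})")
        if aln.aligned_a[pos_to_col_a[p]] != "C":
            raise SiteIntegrityError(
                f"site {p} in {aln.id_a}: residue is {aln.aligned_a[pos_to_col_a[p]]!r}, not C"
            )
    for p in sb_set:
        if p not in pos_to_col_b:
            raise SiteIntegrityError(f"site {p} beyond sequence B ({aln.id_b})")
        if aln.aligned_b[pos_to_col_b[p]] != "C":
            raise SiteIntegrityError(
                f"site {p} in {aln.id_b}: residue is {aln.aligned_b[pos_to_col_b[p]]!r}, not C"
            )

    pairs = []
    for p in sa:
        c = pos_to_col_a[p]
        pb = col_b[c]
        if pb is not None and pb in sb_set:
            pairs.append(OrthologousSitePair(p, pb, c))
    return pairs


def _validate_units(units: Sequence[CpGUnit], label: str) -> dict[int, str]:
    """Check units are disjoint; return site -> unit_id map."""
    site_to_unit: dict[int, str] = {}
    seen_ids: set[str] = set()
    for u in units:
        if u.unit_id in seen_ids:
            raise SiteIntegrityError(f"duplicate unit id {u.unit_id!r} in species {label}")
        seen_ids.add(u.unit_id)
        for s in u.sites:
            if s in site_to_unit:
                raise SiteIntegrityError(
                    f"site {s} belongs to units {site_to_unit[s]!r} and "
                    f"{u.unit_id!r} in species {label}"
                )
            site_to_unit[s] = u.unit_id
    return site_to_unit


def pair_cpg_units(
    units_a: Sequence[CpGUnit],
    units_b: Sequence[CpGUnit],
    site_pairs: Iterable[OrthologousSitePair],
) -> PairedUnitSet:
    """Pair (and where needed merge) CpG units across two species.

    `site_pairs` must be the complete set of orthologous site pairs for
    the region — including pairs whose partner site is not covered by any
    measured unit; those mark the measured side's component ineligible.
    Sites with no entry in `site_pairs` are taken to have no CpG
    counterpart (lineage-specific loss), which is permitted.
    """
    site_to_unit_a = _validate_units(units_a, "A")
    site_to_unit_b = _validate_units(units_b, "B")
    pairs = sorted(set(site_pairs))

    # union-find over unit nodes, tagged ("A", id) / ("B", id)
    parent: dict[tuple[str, str], tuple[str, str]] = {
        ("A", u.unit_id): ("A", u.unit_id) for u in units_a
    }
    parent.update({("B", u.unit_id): ("B", u.unit_id) for u in units_b})

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    edges: list[OrthologousSitePair] = []
    # pairs touching unmeasured sites: the measured side's component is poisoned
    poison: list[tuple[tuple[str, str], str]] = []  # (unit node, reason)
    for sp in pairs:
        ua = site_to_unit_a.get(sp.site_a)
        ub = site_to_unit_b.get(sp.site_b)
        if ua is not None and ub is not None:
            union(("A", ua), ("B", ub))
            edges.append(sp)
        elif ua is not None:
            poison.append((("A", ua), INELIGIBLE_COUNTERPART))
        elif ub is not None:
            poison.append((("B", ub), INELIGIBLE_COUNTERPART))
        # neither side measured: irrelevant to unit pairing

    # collect components that have at least one edge
    comp_edges: dict[tuple[str, str], list[OrthologousSitePair]] = {}
    for sp in edges:
        root = find(("A", site_to_unit_a[sp.site_a]))
        comp_edges.setdefault(root, []).append(sp)

    comp_members: dict[tuple[str, str], list[tuple[str, str]]] = {}
    for node in parent:
        comp_members.setdefault(find(node), []).append(node)

    rejected: dict[tuple[str, str], str] = {}  # root -> reason
    for node, reason in poison:
        root = find(node)
        if root in comp_edges:  # component with pairing evidence but a bad site
            rejected[root] = reason
        else:
            rejected[root] = reason  # singleton unit with only an unmeasured partner

    # conflicting partners: a site pair bridging two *different* components
    # (impossible when the caller supplies the complete pair set, since the
    # union above joins them) — checked defensively.
    for sp in edges:
        ra = find(("A", site_to_unit_a[sp.site_a]))
        rb = find(("B", site_to_unit_b[sp.site_b]))
        if ra != rb:  # pragma: no cover - unreachable with consistent input
            rejected[ra] = CONFLICTING_PARTNER
            rejected[rb] = CONFLICTING_PARTNER

    groups: list[PairedUnitGroup] = []
    excluded_a: dict[str, str] = {}
    excluded_b: dict[str, str] = {}
    order_a = {u.unit_id: i for i, u in enumerate(units_a)}
    order_b = {u.unit_id: i for i, u in enumerate(units_b)}

    for root in sorted(comp_members):
        members = comp_members[root]
        ids_a = sorted((m[1] for m in members if m[0] == "A"), key=order_a.get)
        ids_b = sorted((m[1] for m in members if m[0] == "B"), key=order_b.get)
        has_edge = root in comp_edges
        if has_edge and root not in rejected:
            groups.append(
                PairedUnitGroup(
                    group_id="",
                    units_a=tuple(ids_a),
                    units_b=tuple(ids_b),
                    site_pairs=tuple(sorted(comp_edges[root])),
                )
            )
        else:
            reason = rejected.get(root, NO_ORTHOLOGOUS_SITE)
            for uid in ids_a:
                excluded_a[uid] = reason
            for uid in ids_b:
                excluded_b[uid] = reason

    groups.sort(key=lambda g: min(order_a[u] for u in g.units_a) if g.units_a else 0)
    groups = [
        PairedUnitGroup(f"pair{i + 1}", g.units_a, g.units_b, g.site_pairs)
        for i, g in enumerate(groups)
    ]
    return PairedUnitSet(tuple(groups), excluded_a, excluded_b)


def write_paired_units_tsv(paired: PairedUnitSet, path) -> None:
    """Write a paired-unit table: one row per group plus exclusion rows."""
    with open(path, "w") as fh:
        fh.write("group_id\tunits_a\tunits_b\tsite_pairs\tstatus\n")
        for g in paired.groups:
            sp = ",".join(f"{p.site_a}:{p.site_b}" for p in g.site_pairs)
            fh.write(
                f"{g.group_id}\t{'|'.join(g.units_a)}\t{'|'.join(g.units_b)}\t{sp}\tpaired\n"
            )
        for uid, reason in sorted(paired.excluded_a.items()):
            fh.write(f".\t{uid}\t.\t.\t{reason}\n")
        for uid, reason in sorted(paired.excluded_b.items()):
            fh.write(f".\t.\t{uid}\t.\t{reason}\n")
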