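"""Synthetic paired-species promoter methylation data.

The generator emulates the statistical structure a cross-species
promoter-methylation comparison assumes, so the whole pipeline is
testable without any real tissue data:

* one ancestral promoter sequence per region (−2200…+500 bp around the
  TSS) with a CpG-island-like TSS-proximal core of region-specific
  strength, so CpGo/e on the TSS window spans roughly 0.2–1.2;
* evolution along a species tree in which each CpG site is lost
  independently per branch with probability `cpg_loss_rate` (C→T),
  orthology of surviving sites recorded as ground truth;
* region baseline methylation as a decreasing logistic function of the
  region's TSS-window CpGo/e (CpG islands are hypomethylated);
* designated DMR regions shifted by `dmr_effect` in one species,
  clipped to [0, 1];
* per-site, per-sample beta noise parameterized by (mean,
  concentration); CpG units formed by grouping consecutive sites closer
  than `unit_max_gap` bp, unit values averaging their member sites;
* missingness at `na_rate`, and per-sample expression with a negative
  linear dependence on promoter methylation.

All randomness flows from the single seed in the config; identical
config gives byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import dendropy
import numpy as np
import pandas as pd

from .diffmeth import MethylationMatrix, SidedPairing
from .ortholog import CpGUnit
from .sequence import NucleotideSequence, cpg_oe_ratio, write_fasta

__all__ = [
    "SimulationConfig",
    "SimulatedSequences",
    "RegionAnnotation",
    "SyntheticDataset",
    "simulate_sequences",
    "simulate_methylation",
    "simulate",
    "group_units",
    "combined_matrix",
    "window_methylation",
    "write_dataset",
]

DEFAULT_TREE = "(human:0.03,macaque:0.03);"
FOUR_TAXON_TREE = "(((human:0.01,chimp:0.01):0.02,macaque:0.03):0.05,rat:0.08);"

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design constants and noise levels for the simulation.

    Defaults mirror the assayed design: 2700 bp promoter regions,
    three individuals per species, DMR effects of 0.4 methylation
    units, beta concentration 50 (within-species spreads ~0.01-0.1).
    """

    n_regions: int = 200
    region_length: int = 2700
    n_samples_per_species: int = 3
    dmr_fraction: float = 0.1
    dmr_effect: float = 0.4
    noise_concentration: float = 50.0
    na_rate: float = 0.05
    cpg_loss_rate: float = 0.05
    unit_max_gap: int = 15
    seed: int = 0
    tree: str = DEFAULT_TREE
    window_size: int = 540
    dmr_species: str | None = None  # None: second leaf of the tree
    dmr_direction: str = "auto"  # auto | random | increase | decrease
    expression_intercept: float = 8.0
    expression_slope: float = 4.0  # expression = a - b*methylation + noise
    expression_noise_sd: float = 0.5

    def __post_init__(self) -> None:
        for name in ("dmr_fraction", "dmr_effect", "na_rate", "cpg_loss_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.n_regions < 1 or self.region_length < 2:
            raise ValueError("need n_regions >= 1 and region_length >= 2")
        if self.region_length % self.window_size != 0:
            raise ValueError(
                f"region_length {self.region_length} not divisible by "
                f"window_size {self.window_size}"
            )
        if self.noise_concentration <= 0:
            raise ValueError("noise_concentration must be positive (inf allowed)")
        if self.dmr_direction not in ("auto", "random", "increase", "decrease"):
            raise ValueError(f"unknown dmr_direction {self.dmr_direction!r}")
        if not self.tree.strip():
            raise ValueError("empty species tree")
        if len(self.species()) < 2:
            raise ValueError("species tree needs >= 2 leaves")

    def species(self) -> list[str]:
        t = dendropy.Tree.get(data=self.tree, schema="newick")
        return [lf.taxon.label for lf in t.leaf_node_iter()]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class RegionAnnotation:
    """Ground-truth CpG orthology for one region."""

    region_id: str
    ancestral_sites: tuple[int, ...]
    retained: Mapping[str, tuple[int, ...]]  # species -> surviving site positions

    def orthologous(self, sp_a: str, sp_b: str) -> tuple[int, ...]:
        shared = set(self.retained[sp_a]) & set(self.retained[sp_b])
        return tuple(sorted(shared))


@dataclass(frozen=True)
class SimulatedSequences:
    config: SimulationConfig
    sequences: Mapping[str, list[NucleotideSequence]]  # species -> per-region
    annotations: tuple[RegionAnnotation, ...]

    @property
    def region_ids(self) -> list[str]:
        return [a.region_id for a in self.annotations]


@dataclass
class SyntheticDataset:
    """Full synthetic study: sequences, unit tables, truth, expression."""

    config: SimulationConfig
    sequences: SimulatedSequences
    unit_tables: dict[str, MethylationMatrix]  # species -> units x samples
    units: dict[str, dict[str, list[CpGUnit]]]  # species -> region -> units
    true_region_means: pd.DataFrame  # regions x species
    cpgoe: pd.DataFrame  # regions x species (TSS-proximal window)
    dmr_truth: dict[str, tuple[str, float]]  # region -> (species, signed effect)
    expression: dict[str, pd.DataFrame]  # species -> regions x samples
    n_clipped: int = 0

    @property
    def region_ids(self) -> list[str]:
        return self.sequences.region_ids


def _region_id(i: int) -> str:
    return f"region{i + 1:04d}"


def _draw_sequence(rng: np.random.Generator, length: int, island_strength: float) -> str:
    """One ancestral promoter: background flanks + CpG-island-like core.

    The core spans the TSS-proximal 40% of the region.  Base composition
    is drawn i.i.d. (GC-rich in the core), then the CG dinucleotide count
    is thinned or boosted to match `island_strength` (approximate CpGo/e
    of the core) — i.i.d. text has CpGo/e ~= 1 by construction.
    """
    core_start = int(length * 0.6)
    probs_bg = np.array([0.30, 0.20, 0.20, 0.30])
    probs_core = np.array([0.20, 0.30, 0.30, 0.20])
    idx = np.empty(length, dtype=np.int64)
    idx[:core_start] = rng.choice(4, size=core_start, p=probs_bg)
    idx[core_start:] = rng.choice(4, size=length - core_start, p=probs_core)
    seq = _BASES[idx].copy()

    def cg_positions(segment: np.ndarray) -> np.ndarray:
        is_c = segment[:-1] == b"C"
        is_g = segment[1:] == b"G"
        return np.flatnonzero(is_c & is_g)

    # thin background CpGs hard (bulk DNA is CpG-depleted)...
    for lo, hi, strength in ((0, core_start, 0.25), (core_start, length, island_strength)):
        seg = seq[lo:hi]
        pos = cg_positions(seg)
        if strength < 1.0 and len(pos):
            kill = pos[rng.random(len(pos)) > strength]
            seg[kill + 1] = _BASES[rng.choice([0, 3], size=len(kill))]  # G -> A/T
        elif strength > 1.0:
            # ...or plant extra CpGs to push the core above 1
            n_extra = rng.binomial(hi - lo - 1, (strength - 1.0) * 0.01)
            spots = rng.choice(hi - lo - 1, size=n_extra, replace=False)
            seg[spots] = b"C"
            seg[spots + 1] = b"G"
    return seq.tobytes().decode()


def _lose_cpgs(
    rng: np.random.Generator, seq: str, sites: tuple[int, ...], rate: float
) -> tuple[str, tuple[int, ...]]:
    """One branch of evolution: each CpG site lost (C->T) with prob `rate`."""
    if rate == 0.0 or not sites:
        return seq, sites
    lost = np.asarray(sites)[rng.random(len(sites)) < rate]
    if len(lost) == 0:
        return seq, sites
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    arr[lost] = b"T"
    kept = tuple(s for s in sites if s not in set(lost.tolist()))
    return arr.tobytes().decode(), kept


def simulate_sequences(config: SimulationConfig) -> SimulatedSequences:
    """Generate ancestral promoters and evolve them along the species tree."""
    rng = np.random.default_rng(config.seed)
    tree = dendropy.Tree.get(data=config.tree, schema="newick")
    species = [lf.taxon.label for lf in tree.leaf_node_iter()]

    seqs: dict[str, list[NucleotideSequence]] = {sp: [] for sp in species}
    annotations = []
    for i in range(config.n_regions):
        rid = _region_id(i)
        strength = rng.uniform(0.1, 1.3)
        anc = _draw_sequence(rng, config.region_length, strength)
        anc_sites = tuple(
            j for j in range(len(anc) - 1) if anc[j] == "C" and anc[j + 1] == "G"
        )
        retained: dict[str, tuple[int, ...]] = {}

        def descend(node, seq: str, sites: tuple[int, ...]) -> None:
            for child in node.child_nodes():
                cseq, csites = _lose_cpgs(rng, seq, sites, config.cpg_loss_rate)
                if child.is_leaf():
                    sp = child.taxon.label
                    seqs[sp].append(NucleotideSequence(f"{sp}|{rid}", cseq))
                    retained[sp] = csites
                else:
                    descend(child, cseq, csites)

        descend(tree.seed_node, anc, anc_sites)
        annotations.append(RegionAnnotation(rid, anc_sites, retained))
    return SimulatedSequences(config, seqs, tuple(annotations))


def group_units(sites, max_gap: int, prefix: str = "u") -> list[CpGUnit]:
    """Group consecutive CpG sites with inter-site gap < max_gap bp.

    A proxy for mass-spec assay fragmentation, which determines which
    sites are read out together as one CpG unit.
    """
    sites = sorted(sites)
    if not sites:
        return []
    runs: list[list[int]] = [[sites[0]]]
    for s in sites[1:]:
        if s - runs[-1][-1] < max_gap:
            runs[-1].append(s)
        else:
            runs.append([s])
    return [CpGUnit(f"{prefix}{k + 1}", tuple(run)) for k, run in enumerate(runs)]


def _logistic_baseline(cpgoe: float, steepness: float = 6.0, midpoint: float = 0.6) -> float:
    """Monotone decreasing CpGo/e -> methylation link (islands unmethylated)."""
    return 1.0 / (1.0 + math.exp(steepness * (cpgoe - midpoint)))


def _tss_window_cpgoe(seq: NucleotideSequence, window_size: int) -> float:
    """CpGo/e on the TSS-proximal window (last `window_size` bp of the region)."""
    sub = NucleotideSequence(seq.id, seq.residues[-window_size:])
    return cpg_oe_ratio(sub)


def simulate_methylation(
    config: SimulationConfig, sequences: SimulatedSequences
) -> SyntheticDataset:
    """Layer methylation readouts, missingness and expression on sequences."""
    rng = np.random.default_rng(config.seed + 1)  # independent stream from sequences
    species = list(sequences.sequences)
    samples = {
        sp: [f"{sp[0].upper()}{k + 1}" for k in range(config.n_samples_per_species)]
        for sp in species
    }
    region_ids = sequences.region_ids

    # region baselines from the TSS-window CpGo/e of each species' sequence
    cpgoe = pd.DataFrame(index=region_ids, columns=species, dtype=float)
    for sp in species:
        for rid, seq in zip(region_ids, sequences.sequences[sp]):
            cpgoe.loc[rid, sp] = _tss_window_cpgoe(seq, config.window_size)

    # designate DMR regions and the shifted species
    n_dmr = int(round(config.dmr_fraction * config.n_regions))
    dmr_regions = sorted(rng.choice(config.n_regions, size=n_dmr, replace=False).tolist())
    shift_species = config.dmr_species or species[1]
    if shift_species not in species:
        raise ValueError(f"dmr_species {shift_species!r} not in tree")

    true_means = pd.DataFrame(index=region_ids, columns=species, dtype=float)
    dmr_truth: dict[str, tuple[str, float]] = {}
    n_clipped = 0
    for i, rid in enumerate(region_ids):
        for sp in species:
            true_means.loc[rid, sp] = _logistic_baseline(cpgoe.loc[rid, sp])
        if i in dmr_regions:
            base = float(true_means.loc[rid, shift_species])
            if config.dmr_direction == "increase":
                sign = 1.0
            elif config.dmr_direction == "decrease":
                sign = -1.0
            elif config.dmr_direction == "random":
                sign = 1.0 if rng.random() < 0.5 else -1.0
            else:  # auto: shift away from the nearer boundary
                sign = 1.0 if base < 0.5 else -1.0
            shifted = base + sign * config.dmr_effect
            clipped = min(1.0, max(0.0, shifted))
            if clipped != shifted:
                n_clipped += 1
            true_means.loc[rid, shift_species] = clipped
            dmr_truth[rid] = (shift_species, clipped - base)

    # per-site beta noise -> unit values -> NA masking
    conc = config.noise_concentration
    unit_tables: dict[str, MethylationMatrix] = {}
    units_by_species: dict[str, dict[str, list[CpGUnit]]] = {}
    expression: dict[str, pd.DataFrame] = {}
    eps = 1e-9
    for sp in species:
        rows = []
        index = []
        units_by_species[sp] = {}
        expr = pd.DataFrame(index=region_ids, columns=samples[sp], dtype=float)
        for rid, ann in zip(region_ids, sequences.annotations):
            sites = ann.retained[sp]
            units = group_units(sites, config.unit_max_gap)
            units_by_species[sp][rid] = units
            mean = float(true_means.loc[rid, sp])
            m = min(1.0 - eps, max(eps, mean))
            n_sites = len(sites)
            if n_sites:
                if math.isinf(conc):
                    site_vals = np.full((n_sites, len(samples[sp])), mean)
                else:
                    site_vals = rng.beta(
                        m * conc, (1.0 - m) * conc, size=(n_sites, len(samples[sp]))
                    )
                pos_to_row = {p: k for k, p in enumerate(sites)}
                for u in units:
                    member = site_vals[[pos_to_row[p] for p in u.sites], :]
                    rows.append(member.mean(axis=0))
                    index.append((rid, u.unit_id))
            # per-sample realized promoter methylation drives expression
            sample_meth = (
                site_vals.mean(axis=0) if n_sites else np.full(len(samples[sp]), mean)
            )
            expr.loc[rid] = (
                config.expression_intercept
                - config.expression_slope * sample_meth
                + rng.normal(0.0, config.expression_noise_sd, size=len(samples[sp]))
            )
        values = pd.DataFrame(
            np.asarray(rows) if rows else np.empty((0, len(samples[sp]))),
            index=pd.MultiIndex.from_tuples(index, names=["region_id", "unit_id"])
            if index
            else pd.MultiIndex.from_arrays([[], []], names=["region_id", "unit_id"]),
            columns=samples[sp],
        )
        if config.na_rate > 0 and values.size:
            mask = rng.random(values.shape) < config.na_rate
            values = values.mask(mask)
        unit_tables[sp] = MethylationMatrix(values, {s: sp for s in samples[sp]})
        expression[sp] = expr

    return SyntheticDataset(
        config=config,
        sequences=sequences,
        unit_tables=unit_tables,
        units=units_by_species,
        true_region_means=true_means,
        cpgoe=cpgoe,
        dmr_truth=dmr_truth,
        expression=expression,
        n_clipped=n_clipped,
    )


def simulate(config: SimulationConfig) -> SyntheticDataset:
    """Convenience: sequences + methylation in one call."""
    return simulate_methylation(config, simulate_sequences(config))


def combined_matrix(
    dataset: SyntheticDataset, species_a: str, species_b: str
) -> tuple[MethylationMatrix, dict[str, "SidedPairing"]]:
    """Stack both species' unit tables into one matrix for the DMR model.

    Unit ids are species-tagged (units differ between species); returns
    the stacked matrix plus, per region, the pairing restriction to
    units whose member sites are orthologous between the two species
    (from the simulation's ground truth).
    """
    ta, tb = dataset.unit_tables[species_a], dataset.unit_tables[species_b]

    def retag(values: pd.DataFrame, sp: str) -> pd.DataFrame:
        idx = pd.MultiIndex.from_tuples(
            [(r, f"{sp}:{u}") for r, u in values.index], names=["region_id", "unit_id"]
        )
        return values.set_axis(idx)

    stacked = pd.concat(
        [retag(ta.values, species_a), retag(tb.values, species_b)], axis=1, join="outer"
    )
    # concat with axis=1 on disjoint columns: rows align by unit id; since
    # tags are disjoint every row has NaN in the other species' columns
    species_map = {s: species_a for s in ta.samples} | {s: species_b for s in tb.samples}
    matrix = MethylationMatrix(stacked, species_map)

    paired: dict[str, SidedPairing] = {}
    for ann in dataset.sequences.annotations:
        shared = set(ann.orthologous(species_a, species_b))
        ids_a = frozenset(
            f"{species_a}:{u.unit_id}"
            for u in dataset.units[species_a][ann.region_id]
            if set(u.sites) & shared
        )
        ids_b = frozenset(
            f"{species_b}:{u.unit_id}"
            for u in dataset.units[species_b][ann.region_id]
            if set(u.sites) & shared
        )
        paired[ann.region_id] = SidedPairing(ids_a, ids_b)
    return matrix, paired


def window_methylation(dataset: SyntheticDataset, species: str) -> pd.DataFrame:
    """Regions x window-index mean methylation for one species.

    A unit contributes to the window containing its first member site;
    the window value averages its units' sample means (NaN when a window
    holds no measured unit).  Window indexing follows `make_windows`
    (contiguous, 5' to 3').
    """
    cfg = dataset.config
    n_win = cfg.region_length // cfg.window_size
    mat = dataset.unit_tables[species]
    out = pd.DataFrame(
        index=dataset.region_ids, columns=range(n_win), dtype=float
    )
    sample_means = mat.values.mean(axis=1, skipna=True)
    for rid in dataset.region_ids:
        per_window: dict[int, list[float]] = {}
        for u in dataset.units[species][rid]:
            if (rid, u.unit_id) not in sample_means.index:
                continue
            v = sample_means.loc[(rid, u.unit_id)]
            if math.isnan(v):
                continue
            w = min(u.sites[0] // cfg.window_size, n_win - 1)
            per_window.setdefault(w, []).append(float(v))
        for w, vals in per_window.items():
            out.loc[rid, w] = float(np.mean(vals))
    return out


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> None:
    """Write FASTA/BED/TSV/JSON artifacts (deterministic for fixed seed)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = dataset.config
    for sp, seqs in dataset.sequences.sequences.items():
        write_fasta(seqs, outdir / f"{sp}.fasta")
        _write_unit_table(dataset, sp, outdir / f"{sp}_units.tsv")
        dataset.expression[sp].to_csv(
            outdir / f"{sp}_expression.tsv", sep="\t", na_rep="NA"
        )
    with open(outdir / "regions.bed", "w") as fh:
        for i, rid in enumerate(dataset.region_ids):
            start = i * cfg.region_length
            fh.write(f"chrSim\t{start}\t{start + cfg.region_length}\t{rid}\t0\t+\n")
    truth = dataset.true_region_means.copy()
    truth["dmr_species"] = [
        dataset.dmr_truth.get(r, ("", float("nan")))[0] for r in truth.index
    ]
    truth["dmr_effect"] = [
        dataset.dmr_truth.get(r, ("", float("nan")))[1] for r in truth.index
    ]
    truth.to_csv(outdir / "truth.tsv", sep="\t", na_rep="NA", index_label="region_id")
    manifest = {
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "n_regions": cfg.n_regions,
        "species": list(dataset.sequences.sequences),
        "n_clipped_dmr_effects": dataset.n_clipped,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _write_unit_table(dataset: SyntheticDataset, sp: str, path: Path) -> None:
    mat = dataset.unit_tables[sp]
    with open(path, "w") as fh:
        fh.write("region_id\tunit_id\tmember_site_positions\t" + "\t".join(mat.samples) + "\n")
        unit_sites = {
            (rid, u.unit_id): u.sites
            for rid, units in dataset.units[sp].items()
            for u in units
        }
        for (rid, uid), row in mat.values.iterrows():
            sites = ",".join(map(str, unit_sites[(rid, uid)]))
            vals = "\t".join("NA" if math.isnan(v) else f"{v:.6f}" for v in row)
            fh.write(f"{rid}\t{uid}\t{sites}\t{vals}\n")
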