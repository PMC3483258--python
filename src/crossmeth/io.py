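"""Tabular I/O: EpiTYPER-style unit tables and the pipeline config.

The unit-table dialect is tab-separated UTF-8 with '.' decimals and the
literal ``NA`` for missing values.  Columns are ``region_id``,
``unit_id``, ``member_site_positions`` (comma-separated, optional) and
one column per sample.  Sample-to-species assignment comes from a
``#species`` header line of the form::

    #species	H1=human	H2=human	M1=macaque	...

or from an explicit mapping passed by the caller.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .diffmeth import MethylationMatrix

__all__ = [
    "PipelineConfig",
    "UnitTableError",
    "read_unit_table",
    "read_unit_definitions",
    "write_manifest",
]


class UnitTableError(ValueError):
    """Malformed unit table."""


@dataclass(frozen=True)
class PipelineConfig:
    """All pipeline defaults in one serializable place.

    Every run writes its resolved config into the output manifest so a
    result can be re-derived bit-identically.
    """

    window_size: int = 540
    promoter_upstream: int = -2200
    promoter_downstream: int = 500
    min_region_length: int = 1700
    target_region_length: int = 2700
    diff_threshold: float = 0.2
    alpha: float = 0.05
    min_bin_size: int = 40
    lineage_delta: float = 0.2
    max_hits: int = 1
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        return cls(**dict(d))


def read_unit_table(
    path: str | Path, species: Mapping[str, str] | None = None
) -> tuple[MethylationMatrix, dict[tuple[str, str], tuple[int, ...]]]:
    """Read a unit-level methylation TSV.

    Returns the MethylationMatrix and a (region_id, unit_id) ->
    member-site-positions map (empty tuple when the column is absent).
    Values outside [0,1] and duplicate unit ids raise UnitTableError
    naming the offending row.
    """
    path = Path(path)
    species_from_file: dict[str, str] = {}
    header: list[str] | None = None
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#species"):
                for tok in line.split("\t")[1:]:
                    sample, _, sp = tok.partition("=")
                    species_from_file[sample.strip()] = sp.strip()
                continue
            if line.startswith("#"):
                continue
            if header is None:
                header = line.split("\t")
                continue
            rows.append((lineno, line.split("\t")))
    if header is None or not rows:
        warnings.warn(f"{path}: empty unit table")
        empty = pd.DataFrame(
            index=pd.MultiIndex.from_arrays([[], []], names=["region_id", "unit_id"])
        )
        return MethylationMatrix(empty, species or {}), {}

    if header[:2] != ["region_id", "unit_id"]:
        raise UnitTableError(f"{path}: header must start with region_id, unit_id")
    has_sites = len(header) > 2 and header[2] == "member_site_positions"
    first_sample = 3 if has_sites else 2
    samples = header[first_sample:]
    if not samples:
        raise UnitTableError(f"{path}: no sample columns")

    sites: dict[tuple[str, str], tuple[int, ...]] = {}
    index = []
    data = []
    for lineno, parts in rows:
        if len(parts) != len(header):
            raise UnitTableError(f"{path}:{lineno}: expected {len(header)} fields")
        rid, uid = parts[0], parts[1]
        key = (rid, uid)
        if key in sites:
            raise UnitTableError(f"{path}:{lineno}: duplicate unit id {key}")
        sites[key] = (
            tuple(int(x) for x in parts[2].split(",") if x) if has_sites else ()
        )
        vals = []
        for sample, tok in zip(samples, parts[first_sample:]):
            if tok == "NA" or tok == "":
                vals.append(np.nan)
                continue
            try:
                v = float(tok)
            except ValueError as e:
                raise UnitTableError(f"{path}:{lineno}: bad value {tok!r}") from e
            if not (0.0 <= v <= 1.0):
                raise UnitTableError(
                    f"{path}:{lineno}: methylation {v} outside [0,1] "
                    f"(unit {uid}, sample {sample})"
                )
            vals.append(v)
        index.append(key)
        data.append(vals)

    values = pd.DataFrame(
        data,
        index=pd.MultiIndex.from_tuples(index, names=["region_id", "unit_id"]),
        columns=samples,
    )
    sp = dict(species) if species else species_from_file
    missing = [s for s in samples if s not in sp]
    if missing:
        raise UnitTableError(
            f"{path}: no species assignment for samples {missing}; add a "
            "#species header line or pass a mapping"
        )
    return MethylationMatrix(values, sp), sites


def read_unit_definitions(path: str | Path) -> dict[tuple[str, str], tuple[int, ...]]:
    """Read only the unit structure (region, unit, member sites) of a table.

    Accepts tables with or without sample columns; used where the
    methylation values are irrelevant (e.g. unit pairing).
    """
    path = Path(path)
    out: dict[tuple[str, str], tuple[int, ...]] = {}
    header: list[str] | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if header is None:
                header = parts
                if header[:3] != ["region_id", "unit_id", "member_site_positions"]:
                    raise UnitTableError(
                        f"{path}: need columns region_id, unit_id, member_site_positions"
                    )
                continue
            key = (parts[0], parts[1])
            if key in out:
                raise UnitTableError(f"{path}:{lineno}: duplicate unit id {key}")
            out[key] = tuple(int(x) for x in parts[2].split(",") if x)
    return out


def write_manifest(path: str | Path, config, seed: int | None = None, **extra) -> None:
    """Write a JSON run manifest (config + seed + anything else relevant)."""
    payload = {
        "config": config.to_dict() if hasattr(config, "to_dict") else dict(config),
    }
    if seed is not None:
        payload["seed"] = seed
    payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
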