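"""Promoter methylation profiles: windows, CpGo/e bins, rank correlations.

Promoter regions span −2200…+500 bp around the transcription start site
(TSS) and are tiled into contiguous 540 bp windows (five per 2700 bp
region).  CpG density (CpGo/e) is summarized on the TSS-proximal window,
regions are binned by CpGo/e, and Spearman rank correlations relate
methylation to CpG density and to downstream gene expression, window by
window.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Window",
    "WindowGrid",
    "CpGoeBin",
    "make_windows",
    "bin_by_cpgoe",
    "spearman",
    "methylation_expression_profile",
    "PROMOTER_UPSTREAM",
    "PROMOTER_DOWNSTREAM",
]

PROMOTER_UPSTREAM = -2200  # promoter span relative to the TSS
PROMOTER_DOWNSTREAM = 500


@dataclass(frozen=True)
class Window:
    """One tiling window of a region, with TSS-relative coordinates."""

    index: int
    start: int  # offset within the region, 0-based
    end: int
    tss_start: int  # TSS-relative
    tss_end: int

    @property
    def distance_to_tss(self) -> int:
        """Unsigned distance from the window to the TSS (0 if it contains it)."""
        if self.tss_start <= 0 < self.tss_end:
            return 0
        return min(abs(self.tss_start), abs(self.tss_end - 1))


@dataclass(frozen=True)
class WindowGrid:
    region_id: str
    windows: tuple[Window, ...]
    closest_to_tss: int  # index of the TSS-proximal window

    def __len__(self) -> int:
        return len(self.windows)


def make_windows(
    region_id: str,
    region_length: int,
    size: int = 540,
    step: int | None = None,
    tss_offset: int = -PROMOTER_UPSTREAM,
) -> WindowGrid:
    """Tile a region with windows from its 5' end.

    `tss_offset` is the 0-based position of the TSS within the region
    (2200 for the canonical −2200…+500 promoter).  The default step
    equals the size (contiguous windows); a 2700 bp region yields five
    windows, the last one covering −40…+500 and flagged TSS-proximal.
    """
    if step is None:
        step = size
    if size > region_length:
        raise ValueError(f"window size {size} exceeds region length {region_length}")
    if step < 1:
        raise ValueError("step must be >= 1")
    windows = []
    i = 0
    for start in range(0, region_length - size + 1, step):
        end = start + size
        windows.append(Window(i, start, end, start - tss_offset, end - tss_offset))
        i += 1
    closest = min(windows, key=lambda w: (w.distance_to_tss, w.index)).index
    return WindowGrid(region_id, tuple(windows), closest)


@dataclass(frozen=True)
class CpGoeBin:
    """Regions grouped by CpGo/e; labeled by the bin's lower bound."""

    lower: float
    width: float
    region_ids: tuple[str, ...]
    mean_methylation: float

    @property
    def label(self) -> str:
        return f"{self.lower:g}"


def bin_by_cpgoe(
    regions: pd.DataFrame,
    width: float = 0.1,
    min_bin_size: int = 40,
) -> list[CpGoeBin]:
    """Bin regions into half-open CpGo/e bins [x, x+width).

    `regions` needs columns ``region_id``, ``cpgoe``, ``methylation``.
    Bins with fewer than `min_bin_size` members are dropped; each
    retained bin reports the mean methylation of its members.  A CpGo/e
    of 0.25 falls in the bin labeled 0.2.
    """
    req = {"region_id", "cpgoe", "methylation"}
    if not req.issubset(regions.columns):
        raise ValueError(f"regions table needs columns {sorted(req)}")
    idx = np.floor(regions["cpgoe"].to_numpy() / width).astype(int)
    out = []
    for k in sorted(set(idx)):
        members = regions[idx == k]
        if len(members) < min_bin_size:
            continue
        out.append(
            CpGoeBin(
                lower=round(k * width, 10),
                width=width,
                region_ids=tuple(members["region_id"].astype(str)),
                mean_methylation=float(members["methylation"].mean()),
            )
        )
    return out


def _rank_average(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def spearman(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = 10
) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    The p-value uses the t-approximation for n > `exact_max_n`; for small
    samples an exact permutation test over all n! orderings is run.
    Raises on constant input (correlation undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 4:
        raise ValueError("need n >= 4 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant vector: Spearman correlation undefined")
    rx, ry = _rank_average(x), _rank_average(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_max_n:
        # exact permutation null of |rho|; only sum(rx*ry) varies across
        # permutations, so rho reduces to an affine function of that sum
        sx, sy = rx.sum(), ry.sum()
        vx = (rx**2).sum() - sx**2 / n
        vy = (ry**2).sum() - sy**2 / n
        denom = math.sqrt(vx * vy)
        obs = abs(rho)
        ry_t = tuple(ry)
        count = total = 0
        for perm in itertools.permutations(ry_t):
            cross = sum(a * b for a, b in zip(rx, perm)) - sx * sy / n
            if abs(cross / denom) >= obs - 1e-12:
                count += 1
            total += 1
        return rho, count / total
    if abs(rho) == 1.0:
        return rho, 0.0
    t = rho * math.sqrt((n - 2) / (1 - rho**2))
    p = 2 * stats.t.sf(abs(t), n - 2)
    return rho, p


def methylation_expression_profile(
    window_methylation: pd.DataFrame,
    expression: pd.Series,
    min_regions: int = 10,
) -> pd.DataFrame:
    """Per-window Spearman correlation of methylation with expression.

    `window_methylation`: regions x window-index methylation means;
    `expression`: per-region expression values (shared region index).
    Returns a DataFrame with columns ``window``, ``rho``, ``p``, ``n``.
    """
    shared = window_methylation.index.intersection(expression.index)
    if len(shared) < min_regions:
        raise ValueError(
            f"only {len(shared)} regions shared between methylation and "
            f"expression tables; need >= {min_regions}"
        )
    rows = []
    for w in window_methylation.columns:
        meth = window_methylation.loc[shared, w].to_numpy(dtype=float)
        expr = expression.loc[shared].to_numpy(dtype=float)
        keep = ~(np.isnan(meth) | np.isnan(expr))
        if keep.sum() < min_regions:
            raise ValueError(
                f"window {w}: only {int(keep.sum())} regions with data; "
                f"need >= {min_regions}"
            )
        rho, p = spearman(meth[keep], expr[keep], exact_max_n=0)
        rows.append({"window": w, "rho": rho, "p": p, "n": int(keep.sum())})
    return pd.DataFrame(rows)
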