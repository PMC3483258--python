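"""Cross-species differential methylation: model and results objects.

The measurement is a units x samples matrix of methylation fractions in
[0, 1] with missing values, each unit belonging to a promoter region and
each sample to a species.  The comparison contrasts two species (three or
so individuals each) per region or per paired CpG-unit group:

* per-sample summary: mean methylation over the *paired* units of the
  region (units with no orthologous counterpart are excluded so that both
  species average over the same underlying CpG sites), skipping missing
  values;
* effect size: difference of species means, ``delta = mean(A) - mean(B)``;
* inference: two-sample pooled-variance Student t test on the per-sample
  summaries, Benjamini-Hochberg (default) or Bonferroni adjustment across
  the whole batch;
* verdict: a region (or unit group) is differentially methylated when
  ``|delta| > diff_threshold`` and adjusted ``p < alpha`` (both strict).

Usage follows the statsmodels pattern::

    model = DifferentialMethylation(matrix, species_a="human", species_b="macaque")
    res = model.fit(level="region")
    print(res.summary())
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ortholog import PairedUnitSet

__all__ = [
    "MethylationMatrix",
    "SidedPairing",
    "TestConfig",
    "DifferentialMethylation",
    "DMRResults",
    "pooled_t_test",
    "welch_t_test",
    "adjust_pvalues",
    "species_difference",
    "region_mean_per_sample",
]

P_UNDERFLOW = 0.0  # sentinel for zero pooled variance with nonzero difference


@dataclass(frozen=True)
class SidedPairing:
    """Minimal pairing record: which unit ids count as paired on each side.

    Interchangeable with PairedUnitSet wherever the model only needs the
    paired-unit id sets (e.g. pairing derived from simulation ground
    truth rather than from an alignment).
    """

    ids_a: frozenset
    ids_b: frozenset

    def paired_unit_ids_a(self) -> frozenset:
        return self.ids_a

    def paired_unit_ids_b(self) -> frozenset:
        return self.ids_b


@dataclass(frozen=True)
class TestConfig:
    """Thresholds and test choices for the DMR call.

    diff_threshold and alpha are both strict ("larger than" / "less
    than"); correction defaults to Benjamini-Hochberg FDR.
    """

    diff_threshold: float = 0.2
    alpha: float = 0.05
    correction: Literal["benjamini_hochberg", "bonferroni"] = "benjamini_hochberg"
    min_samples_per_species: int = 2
    test: Literal["pooled_t", "welch_t"] = "pooled_t"

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if not (0 <= self.diff_threshold <= 1):
            raise ValueError(f"diff_threshold must be in [0,1], got {self.diff_threshold}")
        if self.min_samples_per_species < 2:
            raise ValueError("min_samples_per_species must be >= 2")


class MethylationMatrix:
    """Units x samples methylation fractions with species labels.

    Parameters
    ----------
    values : DataFrame
        Index is a (region_id, unit_id) MultiIndex; columns are sample
        ids; entries are fractions in [0, 1] or NaN.
    species : Mapping or Series
        sample id -> species label; must cover every column.
    """

    def __init__(self, values: pd.DataFrame, species: Mapping[str, str] | pd.Series):
        if values.index.nlevels != 2:
            raise ValueError("values must have a (region_id, unit_id) MultiIndex")
        sp = pd.Series(dict(species) if not isinstance(species, pd.Series) else species)
        missing = [c for c in values.columns if c not in sp.index]
        if missing:
            raise ValueError(f"samples with no species label: {missing}")
        arr = values.to_numpy(dtype=float)
        bad = (arr < 0) | (arr > 1)
        if np.any(bad & ~np.isnan(arr)):
            r, c = np.argwhere(bad & ~np.isnan(arr))[0]
            raise ValueError(
                f"methylation value out of [0,1] at unit {values.index[r]}, "
                f"sample {values.columns[c]}: {arr[r, c]}"
            )
        if values.index.duplicated().any():
            dup = values.index[values.index.duplicated()][0]
            raise ValueError(f"duplicate unit id: {dup}")
        self.values = values.astype(float)
        self.species = sp.loc[list(values.columns)]

    @property
    def region_ids(self) -> list[str]:
        return list(dict.fromkeys(self.values.index.get_level_values(0)))

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def samples_of(self, species: str) -> list[str]:
        return [s for s in self.samples if self.species[s] == species]

    def region(self, region_id) -> pd.DataFrame:
        """Unit rows of one region, indexed by unit_id."""
        return self.values.xs(region_id, level=0)


def pooled_t_test(values_a: Sequence[float], values_b: Sequence[float]):
    """Two-sample pooled-variance Student t test (two-sided).

    Returns (t, df, p) with df = nA + nB - 2.  Degenerate case: zero
    pooled variance gives p = 1 for zero difference and the 0-underflow
    sentinel otherwise.
    """
    a = np.asarray([v for v in values_a if not _isnan(v)], dtype=float)
    b = np.asarray([v for v in values_b if not _isnan(v)], dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("pooled t test needs >=2 non-missing values per group")
    df = len(a) + len(b) - 2
    sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if sp2 == 0.0:
        if diff == 0.0:
            return 0.0, df, 1.0
        return math.copysign(math.inf, diff), df, P_UNDERFLOW
    se = math.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
    t = diff / se
    p = 2 * stats.t.sf(abs(t), df)
    return t, df, p


def welch_t_test(values_a: Sequence[float], values_b: Sequence[float]):
    """Welch's unequal-variance t test (two-sided); returns (t, df, p)."""
    a = np.asarray([v for v in values_a if not _isnan(v)], dtype=float)
    b = np.asarray([v for v in values_b if not _isnan(v)], dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("Welch t test needs >=2 non-missing values per group")
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    diff = a.mean() - b.mean()
    if va + vb == 0.0:
        df = len(a) + len(b) - 2
        return (0.0, df, 1.0) if diff == 0.0 else (math.copysign(math.inf, diff), df, P_UNDERFLOW)
    t = diff / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return t, df, p


def adjust_pvalues(
    pvals: Sequence[float],
    method: Literal["benjamini_hochberg", "bonferroni"] = "benjamini_hochberg",
    m: int | None = None,
) -> np.ndarray:
    """Multiple-testing adjustment, capped at 1.

    benjamini_hochberg: step-up p(i)*m/i with monotonicity enforcement.
    bonferroni: min(1, p*m).  ``m`` overrides the adjustment universe
    size when the tested batch is a subset of a larger family.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0,1]")
    n = len(p) if m is None else m
    if n < len(p):
        raise ValueError("family size m cannot be smaller than the number of p-values")
    if method == "bonferroni":
        return np.minimum(p * n, 1.0)
    if method != "benjamini_hochberg":
        raise ValueError(f"unknown correction method: {method!r}")
    if m is None:
        return multipletests(p, method="fdr_bh")[1]
    # subset of a larger family: explicit step-up at family size m
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / (np.arange(len(p)) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(adj, 1.0)
    return out


def species_difference(
    sample_means: Mapping[str, float],
    species: Mapping[str, str],
    species_a: str,
    species_b: str,
    min_samples: int = 2,
) -> float:
    """delta = mean over species-A samples minus mean over species-B samples."""
    a = [v for s, v in sample_means.items() if species[s] == species_a and not _isnan(v)]
    b = [v for s, v in sample_means.items() if species[s] == species_b and not _isnan(v)]
    if len(a) < min_samples or len(b) < min_samples:
        raise ValueError(
            f"need >={min_samples} non-missing samples per species "
            f"(got {len(a)} vs {len(b)})"
        )
    return float(np.mean(a) - np.mean(b))


def region_mean_per_sample(
    region_values: pd.DataFrame, paired_unit_ids: Iterable[str] | None = None
) -> pd.Series:
    """Per-sample mean over the (paired) units of one region.

    NaNs are skipped; a sample with no non-missing unit value gets NaN.
    `region_values` is units x samples; `paired_unit_ids` restricts the
    rows (None = all units are considered paired).
    """
    vals = region_values
    if paired_unit_ids is not None:
        keep = [u for u in vals.index if u in set(paired_unit_ids)]
        vals = vals.loc[keep]
    if vals.shape[0] == 0:
        raise ValueError("region has zero paired units")
    return vals.mean(axis=0, skipna=True)


def _isnan(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


# ---------------------------------------------------------------------------
# model / results


class DifferentialMethylation:
    """Cross-species differential methylation model.

    Parameters
    ----------
    matrix : MethylationMatrix
        Unit-level methylation fractions for both species' samples.
    species_a, species_b : str
        Species labels; delta is reported as A minus B.
    paired : mapping region_id -> PairedUnitSet, optional
        Orthology pairing per region.  When omitted, units are matched
        across species by identical unit_id (suitable for simulated or
        pre-harmonized tables where unit ids already encode orthology).
    config : TestConfig
    """

    def __init__(
        self,
        matrix: MethylationMatrix,
        species_a: str,
        species_b: str,
        paired: Mapping[str, PairedUnitSet] | None = None,
        config: TestConfig = TestConfig(),
    ):
        for sp in (species_a, species_b):
            if sp not in set(matrix.species):
                raise ValueError(f"species {sp!r} has no samples in the matrix")
        self.matrix = matrix
        self.species_a = species_a
        self.species_b = species_b
        self.paired = paired
        self.config = config

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        species: Mapping[str, str],
        species_a: str,
        species_b: str,
        **kwargs,
    ) -> "DifferentialMethylation":
        """Build from a DataFrame with a (region_id, unit_id) MultiIndex."""
        return cls(MethylationMatrix(df, species), species_a, species_b, **kwargs)

    # -- helpers -----------------------------------------------------------

    def _test(self, a, b):
        fn = pooled_t_test if self.config.test == "pooled_t" else welch_t_test
        return fn(a, b)

    def _paired_ids_for(self, region_id, side: str) -> set[str] | None:
        if self.paired is None:
            return None
        ps = self.paired.get(region_id)
        if ps is None:
            return set()  # region without pairing info: nothing usable
        return ps.paired_unit_ids_a() if side == "a" else ps.paired_unit_ids_b()

    # -- fitting -----------------------------------------------------------

    def fit(self, level: Literal["region", "unit"] = "region") -> "DMRResults":
        """Run the comparison at region or paired-unit-group level."""
        if level == "region":
            rows, skipped = self._fit_regions()
        elif level == "unit":
            rows, skipped = self._fit_units()
        else:
            raise ValueError(f"unknown level {level!r}")
        table = pd.DataFrame(rows)
        if len(table):
            table["p_adj"] = adjust_pvalues(table["p"].to_numpy(), self.config.correction)
            table["dmr"] = (table["delta"].abs() > self.config.diff_threshold) & (
                table["p_adj"] < self.config.alpha
            )
        else:
            table["p_adj"] = []
            table["dmr"] = []
        return DMRResults(self, level, table, skipped)

    def _fit_regions(self):
        cfg = self.config
        mat = self.matrix
        samples_a = mat.samples_of(self.species_a)
        samples_b = mat.samples_of(self.species_b)
        rows, skipped = [], []
        for rid in mat.region_ids:
            region = mat.region(rid)
            ids_a = self._paired_ids_for(rid, "a")
            ids_b = self._paired_ids_for(rid, "b")
            try:
                # species may measure different unit sets; restrict each
                # species' samples to its own paired units
                mean_a = region_mean_per_sample(region[samples_a], ids_a)
                mean_b = region_mean_per_sample(region[samples_b], ids_b)
            except ValueError:
                skipped.append((rid, "no_paired_units"))
                continue
            n_units = len(region.index if ids_a is None else [u for u in region.index if u in ids_a])
            row = self._compare(rid, mean_a, mean_b)
            if row is None:
                skipped.append((rid, "too_few_samples"))
                continue
            row["n_units"] = n_units
            rows.append(row)
        return rows, skipped

    def _fit_units(self):
        mat = self.matrix
        samples_a = mat.samples_of(self.species_a)
        samples_b = mat.samples_of(self.species_b)
        rows, skipped = [], []
        for rid in mat.region_ids:
            region = mat.region(rid)
            if self.paired is None:
                # unit ids encode orthology: one group per shared unit id
                groups = [(str(u), [u], [u]) for u in region.index]
            else:
                ps = self.paired.get(rid)
                if ps is None:
                    skipped.append((rid, "no_pairing"))
                    continue
                groups = [
                    (g.group_id, list(g.units_a), list(g.units_b)) for g in ps.groups
                ]
            for gid, units_a, units_b in groups:
                gkey = f"{rid}:{gid}"
                try:
                    mean_a = region_mean_per_sample(region[samples_a], units_a)
                    mean_b = region_mean_per_sample(region[samples_b], units_b)
                except ValueError:
                    skipped.append((gkey, "no_units"))
                    continue
                row = self._compare(gkey, mean_a, mean_b)
                if row is None:
                    skipped.append((gkey, "too_few_samples"))
                    continue
                row["units_a"] = "|".join(map(str, units_a))
                row["units_b"] = "|".join(map(str, units_b))
                rows.append(row)
        return rows, skipped

    def _compare(self, key, mean_a: pd.Series, mean_b: pd.Series):
        cfg = self.config
        a = mean_a.dropna()
        b = mean_b.dropna()
        if len(a) < cfg.min_samples_per_species or len(b) < cfg.min_samples_per_species:
            return None
        t, df, p = self._test(a.to_numpy(), b.to_numpy())
        row = {"id": key}
        for s, v in mean_a.items():
            row[f"mean[{s}]"] = v
        for s, v in mean_b.items():
            row[f"mean[{s}]"] = v
        row.update(
            {
                "mean_a": float(a.mean()),
                "mean_b": float(b.mean()),
                "delta": float(a.mean() - b.mean()),
                "t": t,
                "df": df,
                "p": p,
                "n_a": len(a),
                "n_b": len(b),
            }
        )
        return row


@dataclass
class DMRResults:
    """Results of a DifferentialMethylation fit.

    ``table`` has one row per compared region / unit group with species
    means, delta, t, raw and adjusted p and the DMR verdict; ``skipped``
    lists (id, reason) for comparisons that could not be made.
    """

    model: DifferentialMethylation
    level: str
    table: pd.DataFrame
    skipped: list = field(default_factory=list)

    @property
    def n_compared(self) -> int:
        return len(self.table)

    @property
    def n_dmrs(self) -> int:
        return int(self.table["dmr"].sum()) if len(self.table) else 0

    @property
    def dmrs(self) -> pd.DataFrame:
        return self.table[self.table["dmr"]]

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Cross-species differential methylation",
            "=" * 54,
            f"level: {self.level}    test: {cfg.test}    "
            f"correction: {cfg.correction}",
            f"species A: {self.model.species_a}    species B: {self.model.species_b}",
            f"compared: {self.n_compared}    skipped: {len(self.skipped)}    "
            f"DMRs (|delta|>{cfg.diff_threshold:g}, p_adj<{cfg.alpha:g}): {self.n_dmrs}",
            "-" * 54,
            f"{'id':<18}{'mean_A':>8}{'mean_B':>8}{'delta':>8}{'p':>10}{'p_adj':>10}  DMR",
        ]
        for _, r in self.table.iterrows():
            lines.append(
                f"{str(r['id']):<18}{r['mean_a']:>8.3f}{r['mean_b']:>8.3f}"
                f"{r['delta']:>8.3f}{_fmt_p(r['p']):>10}{_fmt_p(r['p_adj']):>10}"
                f"  {'*' if r['dmr'] else ''}"
            )
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        for col in out.columns:
            if col.startswith("mean") or col == "delta":
                out[col] = out[col].map(lambda v: round(v, 3))
            elif col in ("p", "p_adj"):
                out[col] = out[col].map(_fmt_p)
        out.to_csv(path, sep="\t", index=False, na_rep="NA")

    def to_json_summary(self) -> dict:
        return {
            "level": self.level,
            "species_a": self.model.species_a,
            "species_b": self.model.species_b,
            "n_compared": self.n_compared,
            "n_dmrs": self.n_dmrs,
            "dmr_ids": [str(i) for i in self.dmrs["id"]],
            "skipped": [list(s) for s in self.skipped],
        }


def _fmt_p(p: float) -> str:
    """Two-significant-digit scientific format, table style (2.8E-07)."""
    if _isnan(p):
        return "NA"
    if p == 0.0:
        return "<underflow"
    return f"{p:.1E}"
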