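import math

import numpy as np
import pandas as pd
import pytest

from crossmeth.diffmeth import (
    DifferentialMethylation,
    MethylationMatrix,
    SidedPairing,
    TestConfig as DMTestConfig,
    adjust_pvalues,
    pooled_t_test,
    region_mean_per_sample,
    species_difference,
    welch_t_test,
)
from crossmeth.ortholog import CpGUnit, OrthologousSitePair, pair_cpg_units

from _oracles import quadratic_bh

H_SAMPLES = {"H1": "human", "H2": "human", "H3": "human"}
M_SAMPLES = {"M1": "macaque", "M2": "macaque", "M3": "macaque"}
SPECIES = H_SAMPLES | M_SAMPLES


def matrix_from_rows(rows, samples=("H1", "H2", "H3", "M1", "M2", "M3")):
    """rows: {(region, unit): [values...]}"""
    values = pd.DataFrame.from_dict(rows, orient="index", columns=list(samples))
    values.index = pd.MultiIndex.from_tuples(values.index, names=["region_id", "unit_id"])
    return MethylationMatrix(values, SPECIES)


class TestPooledT:
    def test_reproduces_printed_p_for_strong_region(self):
        t, df, p = pooled_t_test([0.148, 0.145, 0.160], [0.540, 0.540, 0.530])
        assert df == 4
        assert f"{p:.1E}" == "2.8E-07"

    def test_reproduces_printed_p_for_weak_region(self):
        _, _, p = pooled_t_test([0.400, 0.355, 0.446], [0.183, 0.170, 0.130])
        assert f"{p:.1E}" == "1.5E-03"

    def test_group_against_itself_is_null(self):
        t, _, p = pooled_t_test([0.2, 0.3, 0.4], [0.2, 0.3, 0.4])
        assert t == 0.0 and p == 1.0

    def test_zero_variance_nonzero_difference_underflows(self):
        t, _, p = pooled_t_test([0.1, 0.1], [0.9, 0.9])
        assert p == 0.0 and t == -math.inf

    def test_zero_variance_zero_difference_is_one(self):
        assert pooled_t_test([0.5, 0.5], [0.5, 0.5])[2] == 1.0

    def test_nan_values_dropped(self):
        _, df, _ = pooled_t_test([0.1, float("nan"), 0.2], [0.3, 0.4, 0.5])
        assert df == 3

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            pooled_t_test([0.1], [0.2, 0.3])

    def test_matches_scipy_but_welch_does_not_on_unequal_variances(self):
        a, b = [0.1, 0.2, 0.35], [0.5, 0.52, 0.51]
        _, _, p_pooled = pooled_t_test(a, b)
        _, _, p_welch = welch_t_test(a, b)
        assert p_pooled != pytest.approx(p_welch, rel=1e-3)


class TestSpeciesDifference:
    def test_printed_differences(self):
        means = dict(zip(["H1", "H2", "H3"], [0.225, 0.235, 0.242])) | dict(
            zip(["M1", "M2", "M3"], [0.951, 0.801, 0.738])
        )
        assert species_difference(means, SPECIES, "human", "macaque") == pytest.approx(
            -0.596, abs=5e-4
        )

    def test_antisymmetric(self):
        means = {"H1": 0.4, "H2": 0.5, "M1": 0.1, "M2": 0.2}
        fwd = species_difference(means, SPECIES | {"M2": "macaque"}, "human", "macaque")
        rev = species_difference(means, SPECIES | {"M2": "macaque"}, "macaque", "human")
        assert fwd == -rev

    def test_identical_groups_zero(self):
        means = {"H1": 0.3, "H2": 0.3, "M1": 0.3, "M2": 0.3}
        assert species_difference(means, SPECIES, "human", "macaque") == 0.0

    def test_too_few_samples_rejected(self):
        means = {"H1": 0.3, "M1": 0.1, "M2": 0.2}
        with pytest.raises(ValueError, match="non-missing"):
            species_difference(means, SPECIES, "human", "macaque")


class TestAdjustPvalues:
    def test_bh_step_up_forces_equality(self):
        out = adjust_pvalues([0.01, 0.02, 0.03])
        assert np.allclose(out, [0.03, 0.03, 0.03])

    def test_bonferroni_times_family_size(self):
        out = adjust_pvalues([6.22e-05], method="bonferroni", m=3)
        assert f"{out[0]:.1E}" == "1.9E-04"

    def test_matches_quadratic_reference_on_random_vectors(self, rng):
        for _ in range(25):
            p = rng.random(int(rng.integers(1, 40)))
            assert np.allclose(adjust_pvalues(p), quadratic_bh(p))

    def test_adjusted_never_below_raw(self, rng):
        p = rng.random(50)
        adj = adjust_pvalues(p)
        assert np.all(adj >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5, 1.5])

    def test_subset_of_larger_family(self):
        # explicit family size m reproduces a step-up at that size
        out = adjust_pvalues([0.001, 0.01], m=10)
        assert np.allclose(out, [0.01, 0.05])


class TestRegionMeans:
    def test_na_skipped_symmetrically(self):
        region = pd.DataFrame(
            {"H1": [0.41, 0.41], "H2": [np.nan, np.nan]}, index=["u1", "u2"]
        )
        means = region_mean_per_sample(region)
        assert means["H1"] == pytest.approx(0.41)
        assert math.isnan(means["H2"])

    def test_restriction_to_paired_units(self):
        region = pd.DataFrame({"H1": [0.2, 0.8]}, index=["u1", "u2"])
        assert region_mean_per_sample(region, ["u1"])["H1"] == pytest.approx(0.2)

    def test_zero_paired_units_rejected(self):
        region = pd.DataFrame({"H1": [0.2]}, index=["u1"])
        with pytest.raises(ValueError, match="zero paired units"):
            region_mean_per_sample(region, [])


class TestModel:
    def test_region_level_call_requires_both_criteria(self):
        rows = {
            # big effect, consistent -> DMR
            ("r1", "u1"): [0.20, 0.21, 0.22, 0.80, 0.81, 0.82],
            # tiny effect, tiny p -> not a DMR (effect threshold strict)
            ("r2", "u1"): [0.500, 0.501, 0.502, 0.650, 0.651, 0.652],
            # big effect, noisy -> not a DMR (p)
            ("r3", "u1"): [0.05, 0.95, 0.40, 0.60, 0.10, 0.85],
        }
        res = DifferentialMethylation(matrix_from_rows(rows), "human", "macaque").fit()
        verdicts = dict(zip(res.table["id"], res.table["dmr"]))
        assert verdicts == {"r1": True, "r2": False, "r3": False}
        assert res.n_dmrs == 1

    def test_region_mean_uses_only_paired_units(self):
        rows = {
            ("r1", "human:u1"): [0.2, 0.2, 0.2, np.nan, np.nan, np.nan],
            ("r1", "human:u2"): [0.9, 0.9, 0.9, np.nan, np.nan, np.nan],
            ("r1", "macaque:v1"): [np.nan, np.nan, np.nan, 0.8, 0.8, 0.8],
        }
        paired = {"r1": SidedPairing(frozenset({"human:u1"}), frozenset({"macaque:v1"}))}
        res = DifferentialMethylation(
            matrix_from_rows(rows), "human", "macaque", paired=paired
        ).fit()
        assert res.table["delta"].iloc[0] == pytest.approx(0.2 - 0.8)

    def test_unit_level_merged_groups_average_members(self):
        rows = {
            ("r1", "a1"): [0.2, 0.2, 0.2, np.nan, np.nan, np.nan],
            ("r1", "b1"): [np.nan, np.nan, np.nan, 0.6, 0.6, 0.6],
            ("r1", "b2"): [np.nan, np.nan, np.nan, 0.8, 0.8, 0.8],
        }
        paired = pair_cpg_units(
            [CpGUnit("a1", (10, 20))],
            [CpGUnit("b1", (10,)), CpGUnit("b2", (20,))],
            [OrthologousSitePair(10, 10, 10), OrthologousSitePair(20, 20, 20)],
        )
        res = DifferentialMethylation(
            matrix_from_rows(rows), "human", "macaque", paired={"r1": paired}
        ).fit(level="unit")
        assert len(res.table) == 1
        assert res.table["delta"].iloc[0] == pytest.approx(0.2 - 0.7)

    def test_too_few_samples_skipped_with_reason(self):
        rows = {("r1", "u1"): [0.2, np.nan, np.nan, 0.8, 0.8, 0.8]}
        res = DifferentialMethylation(matrix_from_rows(rows), "human", "macaque").fit()
        assert res.n_compared == 0
        assert res.skipped == [("r1", "too_few_samples")]

    def test_two_nonmissing_per_species_suffice(self):
        rows = {("r1", "u1"): [0.41, np.nan, 0.41, 0.17, 0.12, 0.14]}
        res = DifferentialMethylation(matrix_from_rows(rows), "human", "macaque").fit()
        assert res.table["delta"].iloc[0] == pytest.approx(0.27, abs=5e-3)

    def test_summary_mentions_thresholds(self):
        rows = {("r1", "u1"): [0.2, 0.21, 0.22, 0.8, 0.81, 0.82]}
        res = DifferentialMethylation(matrix_from_rows(rows), "human", "macaque").fit()
        text = res.summary()
        assert "0.2" in text and "0.05" in text and "r1" in text

    def test_report_tsv_rounds_like_published_tables(self, tmp_path):
        rows = {("r1", "u1"): [0.148, 0.145, 0.160, 0.540, 0.540, 0.530]}
        res = DifferentialMethylation(matrix_from_rows(rows), "human", "macaque").fit()
        out = tmp_path / "res.tsv"
        res.to_tsv(out)
        text = out.read_text()
        assert "2.8E-07" in text and "-0.386" in text


class TestMethylationMatrix:
    def test_out_of_range_value_rejected(self):
        with pytest.raises(ValueError, match="out of"):
            matrix_from_rows({("r1", "u1"): [1.2, 0, 0, 0, 0, 0]})

    def test_unlabeled_sample_rejected(self):
        values = pd.DataFrame(
            [[0.1]],
            index=pd.MultiIndex.from_tuples([("r1", "u1")]),
            columns=["X9"],
        )
        with pytest.raises(ValueError, match="species"):
            MethylationMatrix(values, {})

    def test_config_validation(self):
        with pytest.raises(ValueError):
            DMTestConfig(alpha=1.5)
        with pytest.raises(ValueError):
            DMTestConfig(diff_threshold=-0.1)
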