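import filecmp
import math

import numpy as np
import pytest
from scipy import stats

from crossmeth.profile import spearman
from crossmeth.sequence import find_cpg_sites
from crossmeth.simulate import (
    FOUR_TAXON_TREE,
    SimulationConfig,
    SyntheticDataset,
    combined_matrix,
    group_units,
    simulate,
    simulate_methylation,
    simulate_sequences,
    window_methylation,
    write_dataset,
)


class TestConfigValidation:
    def test_defaults_are_valid(self):
        cfg = SimulationConfig()
        assert cfg.region_length == 2700
        assert cfg.n_samples_per_species == 3
        assert cfg.species() == ["human", "macaque"]

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"dmr_fraction": 1.5},
            {"na_rate": -0.1},
            {"region_length": 2500},  # not divisible by the 540 bp window
            {"tree": " "},
            {"tree": "(human:1);"},
            {"noise_concentration": 0.0},
            {"n_regions": 0},
            {"dmr_direction": "sideways"},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)


class TestSequences:
    def test_no_loss_keeps_cpg_sets_identical(self):
        sim = simulate_sequences(SimulationConfig(n_regions=4, seed=1, cpg_loss_rate=0.0))
        for ann in sim.annotations:
            assert ann.retained["human"] == ann.retained["macaque"] == ann.ancestral_sites

    def test_total_loss_removes_every_ancestral_site(self):
        sim = simulate_sequences(SimulationConfig(n_regions=3, seed=1, cpg_loss_rate=1.0))
        for ann in sim.annotations:
            assert ann.retained["human"] == ()
            assert ann.retained["macaque"] == ()

    def test_retention_within_binomial_interval(self):
        rate = 0.2
        sim = simulate_sequences(SimulationConfig(n_regions=30, seed=5, cpg_loss_rate=rate))
        total = sum(len(a.ancestral_sites) for a in sim.annotations)
        kept = sum(len(a.retained["human"]) for a in sim.annotations)
        assert total >= 1000
        lo, hi = stats.binom.interval(0.99, total, 1 - rate)
        assert lo <= kept <= hi

    def test_retained_sites_are_cpg_in_leaf_sequences(self):
        sim = simulate_sequences(SimulationConfig(n_regions=3, seed=2, cpg_loss_rate=0.3))
        for i, ann in enumerate(sim.annotations):
            seq = sim.sequences["human"][i]
            positions = {s.position for s in find_cpg_sites(seq)}
            assert set(ann.retained["human"]) <= positions

    def test_four_taxon_tree_gives_four_leaf_sets(self):
        cfg = SimulationConfig(n_regions=2, seed=1, tree=FOUR_TAXON_TREE)
        sim = simulate_sequences(cfg)
        assert set(sim.sequences) == {"human", "chimp", "macaque", "rat"}
        # shared internal branch: human/chimp losses overlap more than with rat
        ann = sim.annotations[0]
        assert len(ann.retained["human"]) <= len(ann.ancestral_sites)


class TestGroupUnits:
    def test_gap_threshold_splits_runs(self):
        units = group_units([0, 5, 30, 33], max_gap=15)
        assert [u.sites for u in units] == [(0, 5), (30, 33)]

    def test_empty_input(self):
        assert group_units([], max_gap=15) == []

    def test_all_sites_covered_exactly_once(self, rng):
        sites = sorted(rng.choice(2000, size=60, replace=False).tolist())
        units = group_units(sites, max_gap=15)
        flat = [s for u in units for s in u.sites]
        assert flat == sites


class TestMethylation:
    def test_degenerate_noise_reproduces_species_mean_exactly(self):
        cfg = SimulationConfig(
            n_regions=5, seed=3, noise_concentration=math.inf, na_rate=0.0
        )
        ds = simulate(cfg)
        for sp in ("human", "macaque"):
            vals = ds.unit_tables[sp].values
            for rid in ds.region_ids:
                region = vals.xs(rid, level=0)
                expected = ds.true_region_means.loc[rid, sp]
                assert np.allclose(region.to_numpy(), expected)

    def test_methylation_decreases_with_cpgoe(self):
        ds = simulate(SimulationConfig(n_regions=200, seed=11, dmr_fraction=0.0))
        obs = ds.unit_tables["human"].values.groupby(level=0).mean().mean(axis=1)
        rho, p = spearman(ds.cpgoe.loc[obs.index, "human"], obs)
        assert rho < -0.5 and p < 1e-10

    def test_na_fraction_within_binomial_bounds(self):
        rate = 0.1
        ds = simulate(SimulationConfig(n_regions=60, seed=9, na_rate=rate))
        vals = ds.unit_tables["human"].values
        n = vals.size
        n_missing = int(vals.isna().to_numpy().sum())
        lo, hi = stats.binom.interval(0.999, n, rate)
        assert lo <= n_missing <= hi

    def test_dmr_truth_matches_designated_fraction_and_sign(self):
        ds = simulate(SimulationConfig(n_regions=100, seed=4, dmr_fraction=0.2))
        assert len(ds.dmr_truth) == 20
        assert set(ds.dmr_truth) <= set(ds.region_ids)
        for rid, (sp, effect) in ds.dmr_truth.items():
            assert sp == "macaque"
            assert abs(effect) > 0.3  # auto direction avoids hard clipping

    def test_non_dmr_regions_share_species_mean_parameters(self):
        ds = simulate(SimulationConfig(n_regions=30, seed=6, cpg_loss_rate=0.0))
        for rid in ds.region_ids:
            if rid in ds.dmr_truth:
                continue
            # no CpG loss -> same sequence -> same CpGo/e -> same baseline
            assert ds.true_region_means.loc[rid, "human"] == pytest.approx(
                ds.true_region_means.loc[rid, "macaque"]
            )

    def test_clipping_counter_increments_when_forced_outward(self):
        cfg = SimulationConfig(
            n_regions=40, seed=8, dmr_fraction=0.5, dmr_direction="increase",
            dmr_effect=0.9,
        )
        ds = simulate(cfg)
        assert ds.n_clipped > 0

    def test_expression_negatively_coupled_to_methylation(self):
        ds = simulate(SimulationConfig(n_regions=150, seed=10, dmr_fraction=0.0))
        meth = ds.unit_tables["human"].values.groupby(level=0).mean().mean(axis=1)
        expr = ds.expression["human"].mean(axis=1).loc[meth.index]
        rho, p = spearman(meth, expr)
        assert rho < -0.5 and p < 1e-10


class TestDeterminismAndOutput:
    def test_identical_seed_gives_byte_identical_files(self, tmp_path):
        cfg = SimulationConfig(n_regions=6, seed=42)
        for sub in ("a", "b"):
            write_dataset(simulate(cfg), tmp_path / sub)
        match, mismatch, errors = filecmp.cmpfiles(
            tmp_path / "a",
            tmp_path / "b",
            [p.name for p in (tmp_path / "a").iterdir()],
            shallow=False,
        )
        assert not mismatch and not errors

    def test_different_seed_changes_output(self, tmp_path):
        ds1 = simulate(SimulationConfig(n_regions=4, seed=1))
        ds2 = simulate(SimulationConfig(n_regions=4, seed=2))
        assert not ds1.true_region_means.equals(ds2.true_region_means)

    def test_unit_table_file_round_trips_through_reader(self, tmp_path):
        from crossmeth.io import read_unit_table

        ds = simulate(SimulationConfig(n_regions=4, seed=13))
        write_dataset(ds, tmp_path)
        mat, sites = read_unit_table(
            tmp_path / "human_units.tsv",
            species={s: "human" for s in ds.unit_tables["human"].samples},
        )
        assert mat.values.shape == ds.unit_tables["human"].values.shape
        assert np.allclose(
            mat.values.to_numpy(),
            ds.unit_tables["human"].values.round(6).to_numpy(),
            equal_nan=True,
        )
        some_key = next(iter(sites))
        assert len(sites[some_key]) >= 1


class TestCombinedMatrix:
    def test_paired_restriction_covers_orthologous_units_only(self, small_dataset):
        ds = small_dataset
        mat, paired = combined_matrix(ds, "human", "macaque")
        assert set(mat.species) == {"human", "macaque"}
        for ann in ds.sequences.annotations:
            shared = set(ann.orthologous("human", "macaque"))
            ids_a = paired[ann.region_id].paired_unit_ids_a()
            for u in ds.units["human"][ann.region_id]:
                tagged = f"human:{u.unit_id}"
                if set(u.sites) & shared:
                    assert tagged in ids_a
                else:
                    assert tagged not in ids_a

    def test_window_methylation_shape_and_range(self, small_dataset):
        wm = window_methylation(small_dataset, "human")
        assert wm.shape == (40, 5)
        arr = wm.to_numpy()
        finite = arr[~np.isnan(arr)]
        assert ((finite >= 0) & (finite <= 1)).all()
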