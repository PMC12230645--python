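import numpy as np
import pytest

from woodchange.errors import ConfigurationError, PlacementError
from woodchange.grids import Grid, binarize_fractional
from woodchange.synth import (
    DEFAULT_EPOCHS,
    ArchetypeTemplate,
    SourceSpec,
    default_templates,
    generate_observer_samples,
    generate_source_maps,
    generate_species_ranges,
    generate_truth_series,
    min_template_separation,
)


def flat_template(value, n=3, sd=0.0):
    return ArchetypeTemplate("flat", (value,) * n, (sd,) * n)


class TestTemplates:
    def test_validation(self):
        with pytest.raises(ConfigurationError):
            ArchetypeTemplate("bad", (0.5, 1.2), (0.0, 0.0))
        with pytest.raises(ConfigurationError):
            ArchetypeTemplate("bad", (0.5,), (0.0, 0.0))

    def test_defaults_are_separated(self):
        templates = default_templates(noise_sd=0.02)
        assert len(templates) == 6
        assert min_template_separation(templates) >= 10 * 0.02

    def test_default_epoch_count(self):
        assert len(DEFAULT_EPOCHS) == 7
        for t in default_templates():
            assert len(t.trajectory) == 7


class TestGenerateTruthSeries:
    def test_zero_noise_identity(self):
        grid = Grid(0, 0, 1.0, 12, 12)
        series, labels, eco = generate_truth_series(
            [flat_template(0.8)], grid, [1990, 2000, 2010], seed=1, coarse_factor=4
        )
        for m in series.maps:
            np.testing.assert_allclose(m.values, 0.8)
        assert labels.shape == (3, 3)
        assert (labels == 0).all()

    def test_same_seed_bit_identical(self):
        grid = Grid(0, 0, 1.0, 20, 20)
        templates = default_templates(0.05, 3)
        a = generate_truth_series(templates, grid, [1, 2, 3], seed=9, coarse_factor=5)
        b = generate_truth_series(templates, grid, [1, 2, 3], seed=9, coarse_factor=5)
        for ma, mb in zip(a[0].maps, b[0].maps):
            np.testing.assert_array_equal(ma.values, mb.values)
        np.testing.assert_array_equal(a[1], b[1])
        np.testing.assert_array_equal(a[2], b[2])

    def test_empty_templates_error(self):
        with pytest.raises(ConfigurationError):
            generate_truth_series([], Grid(0, 0, 1.0, 4, 4), [1, 2], seed=0)

    def test_epoch_count_mismatch_error(self):
        with pytest.raises(ConfigurationError):
            generate_truth_series(
                [flat_template(0.5, n=2)], Grid(0, 0, 1.0, 4, 4), [1, 2, 3], seed=0
            )

    def test_nearest_template_recovery(self):
        # two well-separated templates: monotone decline vs flat high cover
        t1 = ArchetypeTemplate("decline", (0.95, 0.55, 0.15), (0.02,) * 3)
        t2 = ArchetypeTemplate("flat", (0.90, 0.90, 0.90), (0.02,) * 3)
        grid = Grid(0, 0, 1.0, 100, 100)
        series, labels, _ = generate_truth_series(
            [t1, t2], grid, [1, 2, 3], spatial_corr_len=3, seed=4, coarse_factor=10
        )
        traj = np.array([t1.trajectory, t2.trajectory])
        stack = series.stack().reshape(3, -1).T  # fine-cell trajectories
        d = ((stack[:, None, :] - traj[None, :, :]) ** 2).sum(axis=2)
        recovered = d.argmin(axis=1).reshape(grid.shape)
        fine_labels = np.kron(labels, np.ones((10, 10), dtype=int))
        agreement = (recovered == fine_labels).mean()
        assert agreement >= 0.99

    def test_ecoregion_blocks(self):
        _, _, eco = generate_truth_series(
            [flat_template(0.5)], Grid(0, 0, 1.0, 16, 16), [1, 2, 3], seed=0,
            n_ecoregions=8,
        )
        assert sorted(np.unique(eco)) == list(range(8))


class TestGenerateSourceMaps:
    def make_truth(self, seed=0, n=40):
        grid = Grid(0, 0, 1.0, n, n)
        templates = default_templates(0.05, 3)
        series, _, _ = generate_truth_series(templates, grid, [1, 2, 3], seed=seed,
                                             coarse_factor=5)
        return series

    def test_noise_free_identity(self):
        truth = self.make_truth()
        spec = SourceSpec("clean", 1, "binary", 0.0, 0.0)
        (src,) = generate_source_maps(truth, [spec], epoch=3, seed=1)
        expected = binarize_fractional(truth.map_for(3), 20).values
        np.testing.assert_array_equal(src.native_map.values, expected)
        assert src.confusion["fp"] == 0 and src.confusion["fn"] == 0

    def test_total_commission_flips_all_other(self):
        truth = self.make_truth()
        spec = SourceSpec("flip", 1, "binary", 0.0, 0.999999)
        (src,) = generate_source_maps(truth, [spec], epoch=3, seed=1)
        assert src.confusion["tn"] == 0

    def test_binomial_flip_rates(self):
        grid = Grid(0, 0, 1.0, 100, 100)
        series, _, _ = generate_truth_series(
            default_templates(0.05, 3), grid, [1, 2, 3], seed=3, coarse_factor=10
        )
        spec = SourceSpec("noisy", 1, "binary", 0.10, 0.05)
        (src,) = generate_source_maps(series, [spec], epoch=3, seed=7)
        c = src.confusion
        n_wood = c["tp"] + c["fn"]
        n_other = c["tn"] + c["fp"]
        om_hat = c["fn"] / n_wood
        com_hat = c["fp"] / n_other
        se_om = np.sqrt(0.10 * 0.90 / n_wood)
        se_com = np.sqrt(0.05 * 0.95 / n_other)
        assert abs(om_hat - 0.10) <= 3 * se_om
        assert abs(com_hat - 0.05) <= 3 * se_com

    def test_fractional_source_bias(self):
        truth = self.make_truth()
        spec = SourceSpec("biased", 1, "fractional", bias=0.1)
        (src,) = generate_source_maps(truth, [spec], epoch=3, seed=1)
        expected = np.clip(truth.map_for(3).values + 0.1, 0, 1)
        np.testing.assert_allclose(src.harmonized.values, expected, atol=1e-12)

    def test_finer_source_harmonizes_back_to_analysis_grid(self):
        truth = self.make_truth()
        spec = SourceSpec("fine", 2, "binary", 0.0, 0.0)
        (src,) = generate_source_maps(truth, [spec], epoch=3, seed=1)
        assert src.native_map.grid.cell_size == 0.5
        assert src.harmonized.grid == truth.grid

    def test_categorical_has_legend(self):
        truth = self.make_truth()
        spec = SourceSpec("cat", 1, "categorical", 0.05, 0.05)
        (src,) = generate_source_maps(truth, [spec], epoch=1, seed=1)
        assert set(src.native_map.class_legend) == {0, 1}

    def test_determinism(self):
        truth = self.make_truth()
        specs = [SourceSpec("a", 2, "binary", 0.1, 0.1), SourceSpec("b", 1, "fractional", bias=0.05)]
        s1 = generate_source_maps(truth, specs, epoch=2, seed=11)
        s2 = generate_source_maps(truth, specs, epoch=2, seed=11)
        for a, b in zip(s1, s2):
            np.testing.assert_array_equal(a.harmonized.values, b.harmonized.values)

    def test_spec_validation(self):
        with pytest.raises(ConfigurationError):
            SourceSpec("bad", 1, "binary", omission_rate=1.0)
        with pytest.raises(ConfigurationError):
            SourceSpec("bad", 0, "binary")
        with pytest.raises(ConfigurationError):
            SourceSpec("bad", 1, "hexagonal")


class TestGenerateObserverSamples:
    def make_truth_map(self, value=0.23, n=30):
        from woodchange.grids import FractionalCoverMap

        return FractionalCoverMap(Grid(0, 0, 1.0, n, n), np.full((n, n), value))

    def test_infeasible_placement_errors(self):
        truth = self.make_truth_map(n=2)
        with pytest.raises(PlacementError, match="1 of 5"):
            generate_observer_samples(truth, n=5, min_dist=100.0, seed=0,
                                      max_attempts_per_point=50)

    def test_zero_noise_interval_containment(self):
        truth = self.make_truth_map(0.23)
        samples = generate_observer_samples(truth, n=5, min_dist=2.0, obs_noise_sd=0.0, seed=0)
        assert (samples.observer_a_bin == 20).all()
        assert (samples.observer_b_bin == 20).all()
        assert (samples.fused_pct == 25).all()

    def test_pairwise_distance_oracle(self):
        truth = self.make_truth_map(0.5, n=50)
        samples = generate_observer_samples(truth, n=40, min_dist=4.0, seed=3)
        pts = np.column_stack([samples.x, samples.y])
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                assert np.linalg.norm(pts[i] - pts[j]) >= 4.0

    def test_full_cover_snaps_to_top_bin(self):
        truth = self.make_truth_map(1.0)
        samples = generate_observer_samples(truth, n=3, min_dist=1.5, seed=0)
        assert (samples.observer_a_bin == 90).all()

    def test_determinism(self):
        truth = self.make_truth_map(0.4)
        a = generate_observer_samples(truth, 10, 2.0, 0.05, seed=5)
        b = generate_observer_samples(truth, 10, 2.0, 0.05, seed=5)
        np.testing.assert_array_equal(a.x, b.x)
        np.testing.assert_array_equal(a.observer_a_bin, b.observer_a_bin)


class TestGenerateSpeciesRanges:
    def make_cover(self, seed=0, n=24):
        rng = np.random.default_rng(seed)
        from woodchange.grids import FractionalCoverMap

        # left half forested, right half bare, with light noise
        values = np.clip(
            np.where(np.arange(n)[None, :] < n // 2, 0.8, 0.05)
            + rng.normal(0, 0.02, (n, n)),
            0,
            1,
        )
        return FractionalCoverMap(Grid(0, 0, 1.0, n, n), values)

    def test_zero_affinity_matches_uniform_growth(self):
        cover = self.make_cover()
        (threatened,) = generate_species_ranges(cover, 1, 0, cover_affinity=0.0, seed=42)
        (uniform,) = generate_species_ranges(cover, 0, 1, cover_affinity=5.0, seed=42)
        # affinity 0 makes the threatened weights uniform, so with the same
        # seed the grown patch is identical to a non-threatened one
        np.testing.assert_array_equal(threatened.presence, uniform.presence)

    def test_empty_threatened_list(self):
        cover = self.make_cover()
        ranges = generate_species_ranges(cover, 0, 2, seed=0)
        assert all(not r.threatened for r in ranges)
        assert len(ranges) == 2

    def test_ranges_are_connected(self):
        from scipy import ndimage

        cover = self.make_cover()
        for r in generate_species_ranges(cover, 2, 2, seed=1):
            _, n_components = ndimage.label(r.presence)
            assert n_components == 1

    def test_affinity_concentrates_on_cover_smoke(self):
        # 20-replicate smoke version; the 100-replicate check lives in the
        # acceptance suite
        cover = self.make_cover()
        wins = 0
        for seed in range(20):
            ranges = generate_species_ranges(cover, 4, 4, cover_affinity=6.0, seed=seed)
            pooled_t = np.concatenate(
                [cover.values[r.presence] for r in ranges if r.threatened]
            )
            pooled_u = np.concatenate(
                [cover.values[r.presence] for r in ranges if not r.threatened]
            )
            wins += pooled_t.mean() > pooled_u.mean()
        assert wins >= 18

    def test_custom_names_and_flags(self):
        cover = self.make_cover()
        ranges = generate_species_ranges(
            cover, 1, 1, seed=0, threatened_names=["tiger"], nonthreatened_names=["nilgai"]
        )
        assert ranges[0].species_id == "tiger" and ranges[0].threatened
        assert ranges[1].species_id == "nilgai" and not ranges[1].threatened


class TestWorldSerialization:
    def test_save_writes_reconstructable_artifacts(self, tmp_path):
        from woodchange.config import PipelineConfig
        from woodchange.pipeline import simulate_world

        cfg = PipelineConfig(n_rows=30, n_cols=30, coarse_factor=5,
                             n_validation_samples=20, validation_min_dist_cells=1.0,
                             n_threatened=1, n_nonthreatened=1)
        world = simulate_world(cfg)
        out = world.save(tmp_path / "world")
        assert (out / "world_manifest.json").exists()
        assert (out / "validation_samples.csv").exists()
        assert (out / f"truth_{cfg.epochs[0]}.tif").exists()
        assert (out / "archetype_labels.tif").exists()
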