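"""Synthetic generator: determinism, collinearity control, truth surface,
presence sampling, and future-delta construction."""

import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import chisquare
from shapely.geometry import box

from zonesdm import (
    SyntheticConfig,
    ZoneSet,
    generate_env_stack,
    generate_future_stack,
    make_zones,
    sample_presences,
    true_suitability,
)


def small_config(**kw):
    defaults = dict(grid_rows=64, grid_cols=64, cell_km=10.0, rng_seed=7)
    defaults.update(kw)
    return SyntheticConfig(**defaults)


class TestGenerateEnvStack:
    def test_deterministic_given_seed(self):
        cfg = small_config(collinear_pairs=[("Bio1", "Bio6", 0.5)])
        a = generate_env_stack(cfg)
        b = generate_env_stack(cfg)
        np.testing.assert_array_equal(a.values, b.values)

    def test_different_seed_changes_fields(self):
        a = generate_env_stack(small_config(rng_seed=1))
        b = generate_env_stack(small_config(rng_seed=2))
        assert not np.allclose(a.values, b.values)

    @pytest.mark.parametrize("r", [0.0, 0.5, 0.9, 0.99])
    def test_collinear_pair_hits_requested_correlation(self, r):
        cfg = small_config(collinear_pairs=[("Bio1", "Bio6", r)])
        stack = generate_env_stack(cfg)
        got = np.corrcoef(stack.layer("Bio1").ravel(), stack.layer("Bio6").ravel())[0, 1]
        assert abs(got - r) <= 0.1
        if r == 0.99:
            assert got >= 0.9

    def test_zero_correlation_across_seeds(self):
        # residual orthogonalization keeps |corr| far below the 0.15 band
        for seed in range(10):
            cfg = small_config(rng_seed=seed, collinear_pairs=[("Bio3", "Bio8", 0.0)])
            stack = generate_env_stack(cfg)
            got = np.corrcoef(stack.layer("Bio3").ravel(), stack.layer("Bio8").ravel())[0, 1]
            assert abs(got) <= 0.15

    def test_layer_roster_and_finiteness(self):
        stack = generate_env_stack(small_config())
        assert len(stack.layer_names) == 26
        assert stack.layer_names[:2] == ["Bio1", "Bio2"]
        assert {"elevation", "slope", "aspect", "pH", "CEC", "BD", "OC"} <= set(stack.layer_names)
        assert np.isfinite(stack.values).all()
        assert (stack.layer("Bio12") >= 0).all()

    def test_unknown_layer_in_config_rejected(self):
        with pytest.raises(ValueError, match="unknown layer"):
            small_config(collinear_pairs=[("Bio1", "Bio99", 0.5)])
        with pytest.raises(ValueError, match="unknown layer"):
            small_config(true_coefficients={"NotALayer": 1.0})

    def test_correlation_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            small_config(collinear_pairs=[("Bio1", "Bio2", 1.0)])


class TestTrueSuitability:
    def test_zero_model_gives_half_everywhere(self):
        stack = generate_env_stack(small_config())
        truth = true_suitability(stack, {}, intercept=0.0)
        np.testing.assert_allclose(truth.probabilities[stack.mask], 0.5)

    def test_large_intercept_saturates(self):
        stack = generate_env_stack(small_config())
        truth = true_suitability(stack, {}, intercept=20.0)
        assert (truth.probabilities[stack.mask] > 0.999).all()

    def test_matches_logistic_of_standardized_layer(self):
        stack = generate_env_stack(small_config())
        truth = true_suitability(stack, {"pH": 1.0}, intercept=0.0)
        mean, sd = stack.standardize_stats()
        i = stack.index("pH")
        z = (stack.values[:, :, i] - mean[i]) / sd[i]
        np.testing.assert_allclose(truth.probabilities, expit(z), rtol=1e-12)
        # closed form: a cell at +2 SD scores logistic(2) ~ 0.8808
        assert expit(2.0) == pytest.approx(0.88079, abs=1e-4)

    def test_unknown_coefficient_layer_raises(self):
        stack = generate_env_stack(small_config())
        with pytest.raises(KeyError):
            true_suitability(stack, {"Bio99": 1.0})


class TestSamplePresences:
    def test_zero_per_zone_gives_empty_set(self):
        cfg = small_config()
        stack = generate_env_stack(cfg)
        zones = make_zones(cfg)
        truth = true_suitability(stack, {}, 0.0)
        occ = sample_presences(truth, zones, 0, seed=1)
        assert len(occ) == 0

    def test_single_hot_cell_always_chosen(self):
        cfg = small_config()
        stack = generate_env_stack(cfg)
        ck = cfg.cell_km
        zones = ZoneSet(
            zones=[("z", box(0, 0, 64 * ck, 64 * ck))],
            domain=box(0, 0, 64 * ck, 64 * ck),
        )
        truth = true_suitability(stack, {}, 0.0)
        truth.probabilities[:] = 0.0
        truth.probabilities[5, 9] = 1.0
        for seed in range(5):
            occ = sample_presences(truth, zones, 1, seed=seed)
            assert len(occ) == 1
            row, col = stack.xy_to_rowcol(occ.records.lon[0], occ.records.lat[0])
            assert (row, col) == (5, 9)

    def test_deterministic_per_seed(self):
        cfg = small_config()
        stack = generate_env_stack(cfg)
        zones = make_zones(cfg)
        truth = true_suitability(stack, {"Bio1": 1.0}, 0.0)
        a = sample_presences(truth, zones, 20, seed=3)
        b = sample_presences(truth, zones, 20, seed=3)
        assert a.records.equals(b.records)

    def test_uniform_truth_samples_uniformly(self):
        """Chi-square goodness of fit of sampled cells under flat truth."""
        cfg = small_config(grid_rows=16, grid_cols=16)
        stack = generate_env_stack(cfg)
        ck = cfg.cell_km
        zones = ZoneSet(
            zones=[("z", box(0, 0, 16 * ck, 16 * ck))],
            domain=box(0, 0, 16 * ck, 16 * ck),
        )
        truth = true_suitability(stack, {}, 0.0)  # 0.5 everywhere
        counts = np.zeros(16 * 16)
        for seed in range(500):
            occ = sample_presences(truth, zones, 4, seed=seed)
            row, col = stack.xy_to_rowcol(occ.records.lon.to_numpy(), occ.records.lat.to_numpy())
            np.add.at(counts, row * 16 + col, 1)
        assert chisquare(counts).pvalue > 0.01

    def test_insufficient_cells_names_zone(self):
        cfg = small_config()
        stack = generate_env_stack(cfg)
        ck = cfg.cell_km
        zones = ZoneSet(
            zones=[("tiny", box(0, 0, 2 * ck, 2 * ck))],
            domain=box(0, 0, 64 * ck, 64 * ck),
        )
        truth = true_suitability(stack, {}, 0.0)
        with pytest.raises(ValueError, match="tiny"):
            sample_presences(truth, zones, 100, seed=0)


class TestMakeZones:
    def test_tiles_are_disjoint_and_inside_domain(self):
        cfg = small_config(n_zones=5)
        zones = make_zones(cfg)
        assert len(zones.zones) == 5
        for i, (za, pa) in enumerate(zones.zones):
            assert pa.within(zones.domain.buffer(1e-6))
            for zb, pb in zones.zones[i + 1:]:
                assert pa.intersection(pb).area == pytest.approx(0.0, abs=1e-9)

    def test_cell_centre_partition(self):
        """Every cell centre lands in at most one zone; some land in none
        when the tile count exceeds the zone count."""
        cfg = small_config(n_zones=5)
        stack = generate_env_stack(cfg)
        zones = make_zones(cfg)
        total = np.zeros(stack.shape, dtype=int)
        for zid in zones.zone_ids:
            total += zones.zone_mask(stack, zid).astype(int)
        assert total.max() == 1
        assert (total == 0).sum() > 0  # leftover "other" tile


class TestGenerateFutureStack:
    def test_zero_delta_is_identity(self):
        stack = generate_env_stack(small_config())
        fut = generate_future_stack(stack, {"Bio1": 0.0, "Bio12": 0.0})
        np.testing.assert_array_equal(fut.values, stack.values)

    def test_additive_shift_exact(self):
        stack = generate_env_stack(small_config())
        fut = generate_future_stack(stack, {"Bio1": 2.0})
        np.testing.assert_allclose(fut.layer("Bio1"), stack.layer("Bio1") + 2.0)
        np.testing.assert_array_equal(fut.layer("pH"), stack.layer("pH"))

    def test_precipitation_floored_at_zero(self):
        stack = generate_env_stack(small_config())
        big = float(stack.layer("Bio12").max())
        fut = generate_future_stack(stack, {"Bio12": -(big + 10.0)})
        assert (fut.layer("Bio12") == 0.0).all()

    def test_delta_on_soil_layer_rejected(self):
        stack = generate_env_stack(small_config())
        with pytest.raises(ValueError, match="non-climate"):
            generate_future_stack(stack, {"pH": 1.0})
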