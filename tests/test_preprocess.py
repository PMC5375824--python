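import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leafnir import (Mode, PretreatmentRecord, SpectraSet, Spectrum,
                     WavelengthGrid, average_replicates, normalize_spectrum,
                     pca_outlier_screen, ratio_to_reference,
                     remove_atmospheric_bands, simulate_dataset,
                     split_calibration_validation)
from leafnir.synth import ATMOSPHERIC_WINDOWS, SimulationConfig

GRID = WavelengthGrid(400, 700, 10)


def flat(sample_id, level, mode=Mode.BLACK_BACKGROUND, grid=GRID):
    return Spectrum(sample_id, grid, np.full(grid.n_bands, level), mode,
                    {"leaf_id": "leaf1"})


class TestRatioToReference:
    def test_identity_and_zero(self):
        ref = np.linspace(1.0, 2.0, 11)
        assert np.allclose(ratio_to_reference(ref, ref), 1.0)
        assert np.allclose(ratio_to_reference(np.zeros(11), ref), 0.0)

    def test_matches_elementwise_division(self, rng):
        leaf = rng.random(50) + 0.1
        white = rng.random(50) + 0.5
        expected = np.array([leaf[i] / white[i] for i in range(50)])
        assert np.allclose(ratio_to_reference(leaf, white), expected)

    def test_bad_reference_named(self):
        white = np.ones(5)
        white[3] = 0.0
        with pytest.raises(ValueError, match="band index 3"):
            ratio_to_reference(np.ones(5), white)


class TestAverageReplicates:
    def test_mean_semantics(self):
        avg = average_replicates([flat("a_1", 0.2), flat("a_2", 0.4)])
        assert np.allclose(avg.values, 0.3)
        ident = average_replicates([flat("a", 0.25)] * 10)
        assert np.allclose(ident.values, 0.25)

    def test_mixed_leaves_rejected(self):
        a = flat("a", 0.2)
        b = flat("b", 0.2)
        b.meta["leaf_id"] = "leaf2"
        with pytest.raises(ValueError, match="mixed"):
            average_replicates([a, b])

    def test_noise_shrinks_like_sqrt_k(self, rng):
        # Monte Carlo: SD of a 10-scan mean ~ SD/sqrt(10)
        true = np.full(GRID.n_bands, 0.4)
        sd = 0.02
        means = []
        for _ in range(200):
            scans = [Spectrum("a", GRID,
                              np.clip(true + rng.normal(0, sd, GRID.n_bands), 0, 1),
                              Mode.BLACK_BACKGROUND, {"leaf_id": "leaf1"})
                     for _ in range(10)]
            means.append(average_replicates(scans).values)
        empirical = np.mean(np.std(means, axis=0))
        assert empirical == pytest.approx(sd / np.sqrt(10), rel=0.15)


class TestAtmosphericRemoval:
    def test_masked_count_matches_window_widths(self):
        ds = simulate_dataset(SimulationConfig(
            mode=Mode.SOLAR_25DEG, seed=3, n_trees_per_treatment=1, leaves_per_tree=1))
        rec = PretreatmentRecord()
        out = remove_atmospheric_bands(ds, record=rec)
        expected = sum(hi - lo + 1 for lo, hi in ATMOSPHERIC_WINDOWS)
        assert rec.n_bands_masked == expected
        assert out.mask.sum() == expected

    def test_non_solar_passthrough(self):
        ds = simulate_dataset(SimulationConfig(
            seed=3, n_trees_per_treatment=1, leaves_per_tree=1))
        out = remove_atmospheric_bands(ds)
        assert out is ds

    def test_window_outside_grid_rejected(self):
        ds = simulate_dataset(SimulationConfig(
            mode=Mode.SOLAR_25DEG, seed=3, n_trees_per_treatment=1, leaves_per_tree=1))
        with pytest.raises(ValueError):
            remove_atmospheric_bands(ds, windows=((100, 400),))


class TestNormalization:
    @given(scale=st.floats(0.1, 10), level=st.floats(0.05, 0.9), seed=st.integers(0, 100))
    @settings(max_examples=25, deadline=None)
    def test_unit_norm_scale_invariance_idempotence(self, scale, level, seed):
        r = np.random.default_rng(seed)
        vals = np.clip(level + 0.05 * r.random(GRID.n_bands), 1e-3, 1.0)
        s = Spectrum("a", GRID, vals, Mode.BLACK_BACKGROUND)
        n1 = normalize_spectrum(s)
        assert np.linalg.norm(n1.values) == pytest.approx(1.0, abs=1e-12)
        scaled = Spectrum("a", GRID, np.clip(vals * scale, 0, None), Mode.BLACK_BACKGROUND)
        n2 = normalize_spectrum(scaled)
        assert np.allclose(n1.values, n2.values, atol=1e-10)
        assert np.allclose(normalize_spectrum(n1).values, n1.values, atol=1e-12)

    def test_zero_spectrum_rejected(self):
        s = Spectrum("z", GRID, np.zeros(GRID.n_bands), Mode.BLACK_BACKGROUND)
        with pytest.raises(ValueError):
            normalize_spectrum(s)

    def test_norm_over_unmasked_bands_only(self):
        mask = np.zeros(GRID.n_bands, bool)
        mask[0] = True
        vals = np.full(GRID.n_bands, 0.5)
        vals[0] = 0.9  # masked band must not influence the constant
        s = Spectrum("a", GRID, vals, Mode.SOLAR_25DEG, mask=mask)
        rec = PretreatmentRecord()
        normalize_spectrum(s, rec)
        expected = np.sqrt((GRID.n_bands - 1) * 0.25)
        assert rec.normalization_constants["a"] == pytest.approx(expected)


class TestOutlierScreen:
    def test_single_gross_outlier_flagged(self):
        rng = np.random.default_rng(0)
        base = 0.3 + 0.01 * rng.random((40, GRID.n_bands))
        base[17] *= 4.0
        ss = SpectraSet([Spectrum(f"s{i}", GRID, np.clip(base[i], 0, 1.4),
                                  Mode.BLACK_BACKGROUND) for i in range(40)],
                        np.full(40, 25.0))
        kept, removed = pca_outlier_screen(ss, k_components=3, alpha=0.005,
                                           max_removed_fraction=0.2)
        assert removed == ["s17"]
        assert len(kept) == 39

    def test_false_flag_rate_near_alpha(self):
        # 50 clean homogeneous replicates; pooled flag rate ~ Binomial(n, alpha)
        total = flags = 0
        for rep in range(50):
            r = np.random.default_rng(rep)
            V = 0.3 + 0.02 * r.normal(size=(200, GRID.n_bands))
            ss = SpectraSet([Spectrum(f"s{i}", GRID, np.clip(V[i], 0, 1),
                                      Mode.BLACK_BACKGROUND) for i in range(200)],
                            np.full(200, 25.0))
            _, removed = pca_outlier_screen(ss, 5, alpha=0.005)
            total += 200
            flags += len(removed)
        rate = flags / total
        assert 0.5 * 0.005 <= rate <= 2.0 * 0.005

    def test_cap_guards_degenerate_sets(self):
        rng = np.random.default_rng(1)
        V = 0.3 + 0.01 * rng.normal(size=(30, GRID.n_bands))
        V[:3] *= 5  # 10% of the set is wild, above the 5% removal cap
        ss = SpectraSet([Spectrum(f"s{i}", GRID, np.clip(V[i], 0, 1.5),
                                  Mode.WHITE_BACKGROUND) for i in range(30)],
                        np.full(30, 25.0))
        with pytest.raises(ValueError, match="degenerate"):
            pca_outlier_screen(ss, 3, alpha=0.005, max_removed_fraction=0.05)


class TestSplit:
    def test_partition_law_and_determinism(self):
        ds = simulate_dataset(SimulationConfig(
            seed=9, n_trees_per_treatment=1, leaves_per_tree=4))  # 80 leaves
        cal, val = split_calibration_validation(ds, 60, seed=2)
        assert len(cal) == 60 and len(val) == 20
        assert set(cal.sample_ids).isdisjoint(val.sample_ids)
        assert set(cal.sample_ids) | set(val.sample_ids) == set(ds.sample_ids)
        cal2, val2 = split_calibration_validation(ds, 60, seed=2)
        assert cal2.sample_ids == cal.sample_ids

    def test_two_year_pool_splits_1000_420(self):
        # pooled two-sampling library of 1420 leaves -> 1000 calibration + 420 validation
        ds = simulate_dataset(SimulationConfig(
            seed=9, n_trees_per_treatment=1, leaves_per_tree=142, years=(2014,)))
        assert len(ds) == 1420
        cal, val = split_calibration_validation(ds, 1000, seed=0)
        assert len(cal) == 1000 and len(val) == 420

    def test_bounds(self):
        ds = simulate_dataset(SimulationConfig(
            seed=9, n_trees_per_treatment=1, leaves_per_tree=1))
        with pytest.raises(ValueError):
            split_calibration_validation(ds, len(ds), seed=0)
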