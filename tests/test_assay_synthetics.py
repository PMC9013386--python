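import numpy as np
import pytest

from magchip.assay_synthetics import (
    BindingModel,
    generate_dose_series,
    random_scene,
    recover_binding_params,
    render_chamber_image,
    simulate_binding,
)
from magchip.errors import FitFailureError, InvalidModelError
from magchip.pair_detection import PairSummary, classify_pairs, detect_beads, dose_response


class TestBindingModel:
    def test_limits(self):
        m = BindingModel()
        assert m.pair_probability(0.0, "3D") == pytest.approx(m.p_bg_3d)
        assert m.pair_probability(1e6 * m.K, "3D") == pytest.approx(m.p_max, rel=1e-4)

    def test_midpoint_at_half_saturation(self):
        m = BindingModel()
        assert m.pair_probability(m.K, "2D") == pytest.approx(
            (m.p_bg_2d + m.p_max) / 2)

    def test_strictly_increasing_and_bounded(self):
        m = BindingModel()
        c = np.logspace(-14, -8, 40)
        p = np.array([m.pair_probability(x, "3D") for x in c])
        assert np.all(np.diff(p) > 0)
        assert p[0] >= m.p_bg_3d and p[-1] <= m.p_max

    def test_invalid_params_rejected(self):
        with pytest.raises(InvalidModelError):
            BindingModel(p_bg_2d=0.01, p_bg_3d=0.05)
        with pytest.raises(InvalidModelError):
            BindingModel(p_max=0.0)
        with pytest.raises(InvalidModelError):
            BindingModel(K=0.0)

    def test_default_background_ratio_at_least_7(self):
        m = BindingModel()
        assert m.p_bg_2d / m.p_bg_3d >= 7.0


class TestSimulateBinding:
    def test_counts_conserve_beads(self):
        n_pairs, n_singles = simulate_binding(1e-11, BindingModel(), 200, seed=5)
        assert 2 * n_pairs + n_singles == 200

    def test_deterministic_given_seed(self):
        a = simulate_binding(1e-11, BindingModel(), 200, seed=42)
        b = simulate_binding(1e-11, BindingModel(), 200, seed=42)
        assert a == b

    def test_zero_concentration_rate_near_background(self):
        m = BindingModel()
        draws = [simulate_binding(0.0, m, 400, "3D", seed=s)[0]
                 for s in range(30)]
        rate = np.mean(draws) / 200
        assert rate == pytest.approx(m.p_bg_3d, abs=0.01)


class TestDoseSeries:
    def test_monotone_rising_3d_medians(self):
        concs = [0.0, 1e-13, 1e-12, 1e-11, 1e-10, 1e-9]
        ds = generate_dose_series(concs, BindingModel(), n_beads=200,
                                  replicates=8, field_mode="3D", seed=0)
        tab = dose_response(
            (r.concentration, PairSummary(int(r.n_singles), int(r.n_pairs)))
            for r in ds.itertuples())
        med = tab["median"].to_numpy()
        # rises clearly above the detection floor from 1e-13 upward; the two
        # lowest points sit at the 3D background within counting noise
        assert np.all(np.diff(med[1:]) >= 0)
        assert med[-1] > med[0] + 50.0

    def test_2d_low_concentration_flat_at_background(self):
        m = BindingModel()
        concs = [0.0, m.K / 1000, m.K / 100]
        ds = generate_dose_series(concs, m, n_beads=400, replicates=10,
                                  field_mode="2D", seed=1)
        med = ds.groupby("concentration")["pair_percentage"].median()
        level = 100 * 2 * m.p_bg_2d / (2 * m.p_bg_2d + (1 - 2 * m.p_bg_2d) * 2)
        # all medians within sampling noise of the 2D background level
        assert med.max() - med.min() < 8.0
        assert abs(med.iloc[0] - level) < 8.0

    def test_single_replicate_one_row_each(self):
        ds = generate_dose_series([0.0, 1e-11], BindingModel(), 100, 1)
        assert len(ds) == 2

    def test_bit_identical_reruns(self):
        a = generate_dose_series([0.0, 1e-11], BindingModel(), 100, 3, seed=9)
        b = generate_dose_series([0.0, 1e-11], BindingModel(), 100, 3, seed=9)
        assert a.equals(b)


class TestRenderRoundTrip:
    def test_snr_inf_roundtrip_counts(self):
        scene = random_scene(14, 3, bead_radius_um=1.4, extent_um=(140, 140),
                            snr=np.inf, seed=11)
        img, truth = render_chamber_image(scene)
        rpx = 1.4 / scene.scale_um_per_px
        dets = detect_beads(img, radius_range_px=(0.7 * rpx, 1.3 * rpx))
        assert len(dets) == 20
        summary = classify_pairs(dets, touch_tolerance=0.35)
        assert summary.n_pairs == 3
        assert summary.n_singles == 14
        assert summary.pair_percentage == pytest.approx(30.0)

    def test_same_seed_bit_identical(self):
        s1 = random_scene(5, 2, snr=8.0, seed=21)
        s2 = random_scene(5, 2, snr=8.0, seed=21)
        img1, _ = render_chamber_image(s1)
        img2, _ = render_chamber_image(s2)
        assert np.array_equal(img1, img2)


class TestRecoverBindingParams:
    def test_recovers_k_within_factor_two(self):
        true = BindingModel(p_bg_2d=0.15, p_bg_3d=0.02, p_max=0.8, K=1e-11)
        concs = [0.0, 1e-13, 1e-12, 1e-11, 1e-10, 1e-9]
        ds = generate_dose_series(concs, true, n_beads=200, replicates=10,
                                  field_mode="3D", seed=2)
        fit = recover_binding_params(ds, n_bootstrap=50, seed=0)
        assert true.K / 2 <= fit["K"] <= true.K * 2
        assert fit["p_max"] == pytest.approx(true.p_max, abs=0.15)

    def test_p_bg_matches_zero_concentration_binomial_ci(self):
        true = BindingModel()
        concs = [0.0, 1e-13, 1e-12, 1e-11, 1e-10, 1e-9]
        ds = generate_dose_series(concs, true, n_beads=200, replicates=10,
                                  field_mode="3D", seed=4)
        fit = recover_binding_params(ds, n_bootstrap=50, seed=0)
        zero = ds[ds.concentration == 0.0]
        n_enc = int(zero.n_beads.sum()) // 2
        k = int(zero.n_pairs.sum())
        from scipy.stats import binomtest
        ci = binomtest(k, n_enc).proportion_ci(0.99)
        assert ci.low <= fit["p_bg"] <= ci.high

    def test_all_zero_counts_rejected(self):
        import pandas as pd
        ds = pd.DataFrame({"concentration": [0, 1e-12, 1e-11, 1e-10],
                           "n_pairs": [0, 0, 0, 0],
                           "n_beads": [100] * 4})
        with pytest.raises(FitFailureError):
            recover_binding_params(ds)
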