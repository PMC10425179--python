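import numpy as np
import pandas as pd
import pytest

from cortarch import synthetic
from cortarch.gli import ContourPair, SectionImage, Traverse, build_traverses
from cortarch.quant import (RECEPTOR_ORDER, LigandParams, area_mean_density,
                            fit_calibration, linearize_autoradiograph,
                            radioactivity_to_density, table_extrema,
                            zscore_table)


class TestCalibration:
    def test_linear_standards_recovered_exactly(self):
        standards = pd.DataFrame({"grey_value": [10.0, 50.0, 90.0, 130.0],
                                  "radioactivity": [1.0, 5.0, 9.0, 13.0]})
        curve = fit_calibration(standards)
        g = np.array([10.0, 30.0, 70.0, 130.0])
        assert np.allclose(curve(g), g / 10.0, atol=1e-9)

    def test_exponential_standards_heldout_within_2pct(self):
        r = np.linspace(5, 500, 12)
        grey = 8.0 + 220.0 * (1 - np.exp(-0.004 * r))
        fit_idx = np.arange(0, 12, 2)
        held_idx = np.arange(1, 12, 2)
        curve = fit_calibration(pd.DataFrame({
            "grey_value": grey[fit_idx], "radioactivity": r[fit_idx]}))
        rec = curve(grey[held_idx])
        assert np.max(np.abs(rec - r[held_idx]) / r[held_idx]) < 0.02

    def test_two_standards_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            fit_calibration(pd.DataFrame({"grey_value": [1.0, 2.0],
                                          "radioactivity": [1.0, 2.0]}))

    def test_non_monotone_standards_rejected(self):
        with pytest.raises(ValueError, match="monotone"):
            fit_calibration(pd.DataFrame({"grey_value": [10.0, 50.0, 30.0],
                                          "radioactivity": [1.0, 2.0, 3.0]}))

    def test_darkening_film_supported(self):
        # grey decreasing with dose: orientation handled internally
        r = np.array([1.0, 5.0, 9.0, 13.0])
        grey = 200.0 - 10.0 * r
        curve = fit_calibration(pd.DataFrame({"grey_value": grey,
                                              "radioactivity": r}))
        assert curve(150.0) == pytest.approx(5.0, abs=1e-9)


class TestLinearization:
    def test_zero_radioactivity_zero_density(self, ligand):
        assert radioactivity_to_density(0.0, ligand) == 0.0

    def test_cancelling_factors_identity(self):
        # K_D = L and E*B*W_b*S_a = 2  =>  C_b = R
        p = LigandParams(E=1.0, B=2.0, W_b=1.0, S_a=1.0, K_D=10.0, L=10.0)
        assert radioactivity_to_density(123.4, p) == pytest.approx(123.4)

    def test_hand_evaluated_oracle(self, ligand):
        # R/(E*B*W_b*S_a) * (K_D+L)/L = 500/3.2 * 1.1 = 171.875
        assert radioactivity_to_density(500.0, ligand) == pytest.approx(
            171.875, rel=1e-12)

    def test_linear_in_r_increasing_in_kd(self, ligand):
        r = np.array([10.0, 20.0, 40.0])
        d = radioactivity_to_density(r, ligand)
        assert np.allclose(d / d[0], r / r[0])
        hi = LigandParams(E=ligand.E, B=ligand.B, W_b=ligand.W_b,
                          S_a=ligand.S_a, K_D=ligand.K_D + 5, L=ligand.L)
        assert radioactivity_to_density(10.0, hi) > radioactivity_to_density(10.0, ligand)

    def test_invalid_ligand_rejected(self):
        with pytest.raises(ValueError):
            LigandParams(E=0.4, B=2.0, W_b=0.05, S_a=80.0, K_D=1.0, L=0.0)

    def test_roundtrip_within_one_percent(self, ligand):
        dens = np.linspace(50.0, 800.0, 40)[None, :] * np.ones((16, 1))
        r_hi = 1000.0 / ligand.scale
        img, std = synthetic.make_autoradiograph(
            dens, (12.0, 210.0, 1.2 / r_hi), ligand,
            np.linspace(0.05, 1.0, 8) * r_hi)
        curve = fit_calibration(std)
        rec, n_clamped = linearize_autoradiograph(img, curve, ligand)
        assert n_clamped == 0
        assert np.max(np.abs(rec.pixels - dens) / dens) <= 0.01

    def test_constant_grey_constant_density(self, ligand):
        curve = fit_calibration(pd.DataFrame({
            "grey_value": [0.0, 100.0, 200.0], "radioactivity": [0.0, 10.0, 20.0]}))
        img = SectionImage(np.full((5, 5), 120.0))
        dens, _ = linearize_autoradiograph(img, curve, ligand)
        assert np.ptp(dens.pixels) == 0.0

    def test_saturated_pixels_counted(self, ligand):
        curve = fit_calibration(pd.DataFrame({
            "grey_value": [0.0, 100.0, 200.0], "radioactivity": [0.0, 10.0, 20.0]}))
        px = np.full((4, 4), 50.0)
        px[0, :3] = 255.0  # beyond the calibration domain
        with pytest.warns(UserWarning, match="clamped"):
            _, n_clamped = linearize_autoradiograph(SectionImage(px), curve, ligand)
        assert n_clamped == 3


class TestAreaMeanDensity:
    def _ribbon(self, n=10):
        contours = ContourPair(np.array([[0.0, 0.0], [19.0, 0.0]]),
                               np.array([[0.0, 19.0], [19.0, 19.0]]))
        return contours, build_traverses(contours, n)

    def test_constant_field(self):
        contours, traverses = self._ribbon()
        img = SectionImage(np.full((20, 20), 33.0))
        assert area_mean_density(img, contours, traverses) == pytest.approx(33.0)

    def test_depth_linear_field_trapezoid(self):
        contours, traverses = self._ribbon()
        depth = np.linspace(4.0, 10.0, 20)
        img = SectionImage(np.tile(depth[:, None], (1, 20)))
        assert area_mean_density(img, contours, traverses) == pytest.approx(
            7.0, rel=1e-6)

    def test_matches_pixel_mask_oracle(self, rng):
        from scipy.ndimage import gaussian_filter
        field = gaussian_filter(rng.uniform(10, 90, (20, 20)), sigma=3)
        contours, traverses = self._ribbon(n=40)
        img = SectionImage(field)
        est = area_mean_density(img, contours, traverses, n_depth=81)
        assert est == pytest.approx(field.mean(), rel=0.02)

    def test_no_traverses_rejected(self):
        contours, _ = self._ribbon()
        with pytest.raises(ValueError):
            area_mean_density(SectionImage(np.ones((20, 20))), contours, [])


class TestDensityTable:
    def test_zscore_moments(self, density_fixture):
        means, _ = density_fixture
        z = zscore_table(means)
        assert np.max(np.abs(z.mean(axis=0))) < 1e-12
        assert np.max(np.abs(z.std(axis=0, ddof=1) - 1)) < 1e-12

    def test_zscore_preserves_ordering_and_gabab_peak(self, density_fixture):
        means, _ = density_fixture
        z = zscore_table(means)
        for rec in RECEPTOR_ORDER:
            assert z[rec].idxmax() == means[rec].idxmax()
        assert z["GABAB"].idxmax() == "11l"

    def test_zscore_idempotent(self, density_fixture):
        means, _ = density_fixture
        z = zscore_table(means)
        assert np.allclose(zscore_table(z), z, atol=1e-12)

    def test_single_area_rejected(self, density_fixture):
        means, _ = density_fixture
        with pytest.raises(ValueError):
            zscore_table(means.iloc[:1])

    def test_constant_column_rejected(self):
        bad = pd.DataFrame({"AMPA": [1.0, 1.0, 1.0], "NMDA": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="constant"):
            zscore_table(bad)

    @pytest.mark.parametrize("receptor, amax, vmax, amin, vmin", [
        ("GABAB", "11l", 2644.0, "8Av", 1703.0),
        ("D1", "11l", 96.0, "9l", 67.0),
        ("M2", "13l", 223.0, "14r", 134.0),
        ("M1", "12m", 1152.0, "8Av", 708.0),
    ])
    def test_extrema(self, density_fixture, receptor, amax, vmax, amin, vmin):
        means, _ = density_fixture
        assert table_extrema(means, receptor) == (amax, vmax, amin, vmin)

    def test_unknown_receptor_rejected(self, density_fixture):
        means, _ = density_fixture
        with pytest.raises(ValueError, match="unknown receptor"):
            table_extrema(means, "dopamine-D5")
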