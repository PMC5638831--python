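"""Preprocessing: ASCII I/O, water exclusion, adaptive binning, PQN and
mean-centering, with integral-conservation and idempotence properties."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import trapezoid

import wormetab as w
from wormetab.spectra import Bin, BinTable
from wormetab.synthdata import lorentzian


def _write(path, ppm, y):
    np.savetxt(path, np.column_stack([ppm, y]))


class TestReadSpectra:
    def _manifest(self, tmp_path, rows):
        man = tmp_path / "manifest.csv"
        pd.DataFrame(rows, columns=["sample_id", "group", "file"]).to_csv(
            man, index=False)
        return str(man)

    def test_round_trip_three_files(self, tmp_path):
        ppm = np.linspace(0, 10, 512)
        for i in range(3):
            _write(tmp_path / f"s{i}.txt", ppm, np.full(512, float(i + 1)))
        man = self._manifest(tmp_path, [(f"s{i}", "g", f"s{i}.txt") for i in range(3)])
        sset = w.read_spectra(man)
        assert sset.n_samples == 3
        np.testing.assert_allclose(sset.ppm, ppm)
        np.testing.assert_allclose(sset.X[2], 3.0)

    def test_non_numeric_row_names_line(self, tmp_path):
        lines = ["0.1 1.0", "0.2 2.0", "0.3 oops", "0.4 1.0"]
        (tmp_path / "bad.txt").write_text("\n".join(lines))
        man = self._manifest(tmp_path, [("s0", "g", "bad.txt")])
        with pytest.raises(w.InputError, match="line 3"):
            w.read_spectra(man)

    def test_missing_file_named(self, tmp_path):
        man = self._manifest(tmp_path, [("s0", "g", "gone.txt")])
        with pytest.raises(w.InputError, match="gone.txt"):
            w.read_spectra(man)

    def test_duplicate_sample_id_rejected(self, tmp_path):
        ppm = np.linspace(0, 10, 64)
        _write(tmp_path / "a.txt", ppm, np.ones(64))
        man = self._manifest(tmp_path, [("s0", "g", "a.txt"), ("s0", "g", "a.txt")])
        with pytest.raises(w.InputError, match="duplicate"):
            w.read_spectra(man)

    def test_offset_axis_resampled_integral_preserved(self, tmp_path):
        ppm = np.linspace(0.2, 9.8, 4096)
        y = lorentzian(ppm, 5.0, 0.05) + lorentzian(ppm, 2.0, 0.05)
        half = 0.5 * (ppm[1] - ppm[0])
        _write(tmp_path / "a.txt", ppm, y)
        _write(tmp_path / "b.txt", ppm + half,
               lorentzian(ppm + half, 5.0, 0.05) + lorentzian(ppm + half, 2.0, 0.05))
        man = self._manifest(tmp_path, [("a", "g", "a.txt"), ("b", "g", "b.txt")])
        sset = w.read_spectra(man)
        np.testing.assert_allclose(sset.ppm, ppm)  # first spectrum's axis
        i_a = trapezoid(sset.X[0], ppm)
        i_b = trapezoid(sset.X[1], ppm)
        assert i_b == pytest.approx(i_a, rel=0.005)

    def test_descending_input_stored_ascending(self, tmp_path):
        ppm = np.linspace(0, 10, 128)
        _write(tmp_path / "d.txt", ppm[::-1], np.arange(128.0)[::-1])
        man = self._manifest(tmp_path, [("d", "g", "d.txt")])
        sset = w.read_spectra(man)
        assert (np.diff(sset.ppm) > 0).all()
        np.testing.assert_allclose(sset.X[0], np.arange(128.0))


class TestExcludeRegion:
    def test_water_band_removed(self, flat_spectra_set):
        out = w.exclude_region(flat_spectra_set, 4.70, 5.25)
        assert not ((out.ppm >= 4.70) & (out.ppm <= 5.25)).any()
        assert out.excluded_regions == [(4.70, 5.25)]

    def test_empty_region_rejected(self, flat_spectra_set):
        with pytest.raises(w.InputError):
            w.exclude_region(flat_spectra_set, 5.25, 4.70)

    def test_region_outside_axis_is_noop(self, flat_spectra_set):
        out = w.exclude_region(flat_spectra_set, -1.0, -0.5)
        assert out.ppm.size == flat_spectra_set.ppm.size

    def test_whole_axis_rejected(self, flat_spectra_set):
        with pytest.raises(w.InputError):
            w.exclude_region(flat_spectra_set, -1.0, 11.0)


class TestAdaptiveBin:
    def test_flat_spectrum_uniform_bins(self, flat_spectra_set):
        """0.2-8.8 minus the water band at target 0.015 -> ~537 bins."""
        trimmed = w.exclude_region(flat_spectra_set, 4.70, 5.25)
        bt = w.adaptive_bin(trimmed)
        assert abs(len(bt.bins) - 537) <= 2
        widths = np.array([b.width for b in bt.bins])
        assert 0.5 * 0.015 <= widths.mean() <= 2.0 * 0.015

    def test_mean_width_within_band_on_real_spectra(self, two_group_study):
        widths = np.array([b.width for b in two_group_study["bt"].bins])
        assert 0.5 * 0.015 <= widths.mean() <= 2.0 * 0.015

    def test_valley_between_two_peaks_gets_boundary(self):
        ppm = np.linspace(0, 3, 2**13)
        y = lorentzian(ppm, 1.40, 0.002) + lorentzian(ppm, 1.50, 0.002)
        man = pd.DataFrame({"group": ["a"]}, index=["s"])
        sset = w.SpectraSet(ppm, y[None, :], ["s"], man)
        bt = w.adaptive_bin(sset, lo=0.2, hi=2.8)
        assert any(1.42 < b.lo_ppm < 1.48 for b in bt.bins)
        # each peak's area captured on its own side of the valley
        for center in (1.40, 1.50):
            peak_area = trapezoid(lorentzian(ppm, center, 0.002), ppm)
            side = sum(
                bt.X[0, j] for j, b in enumerate(bt.bins)
                if (b.mid < 1.45) == (center < 1.45)
            )
            assert side >= 0.95 * peak_area * 0.95  # axis truncation loses a little

    def test_binning_conserves_total_integral(self, two_group_study):
        bt = two_group_study["bt"]
        trimmed = two_group_study["trimmed"]
        from wormetab.spectra import total_integral

        tot = total_integral(trimmed, lo=bt.bins[0].lo_ppm, hi=bt.bins[-1].hi_ppm)
        np.testing.assert_allclose(bt.X.sum(axis=1), tot, rtol=1e-6)

    def test_no_bin_intersects_excluded_region(self, two_group_study):
        for b in two_group_study["bt"].bins:
            assert b.hi_ppm <= 4.70 or b.lo_ppm >= 5.25

    def test_deterministic(self, flat_spectra_set):
        t = w.exclude_region(flat_spectra_set, 4.70, 5.25)
        b1, b2 = w.adaptive_bin(t), w.adaptive_bin(t)
        assert b1.bins == b2.bins
        np.testing.assert_array_equal(b1.X, b2.X)

    def test_too_few_points_rejected(self):
        ppm = np.linspace(0, 10, 32)
        man = pd.DataFrame({"group": ["a"]}, index=["s"])
        sset = w.SpectraSet(ppm, np.ones((1, 32)), ["s"], man)
        with pytest.raises(w.InputError):
            w.adaptive_bin(sset, lo=5.0, hi=5.5)


def _toy_bintable(X, ids=None):
    nb = X.shape[1]
    bins = [Bin(i * 0.1, (i + 1) * 0.1) for i in range(nb)]
    ids = ids or [f"s{i}" for i in range(X.shape[0])]
    man = pd.DataFrame({"group": ["g"] * len(ids)}, index=ids)
    return BinTable(bins, np.asarray(X, float), ids, man)


class TestPqn:
    def test_scaled_sample_gets_its_scale_as_quotient(self):
        base = np.array([1.0, 2.0, 3.0, 2.0, 1.0, 4.0])
        bt = _toy_bintable(np.vstack([base, 3.0 * base, base]))
        fm = w.pqn_normalize(bt)
        assert fm.normalization_quotients[1] == pytest.approx(3.0)
        np.testing.assert_allclose(fm.X[1], fm.X[0], rtol=1e-12)

    def test_self_reference_quotient_is_one(self):
        base = np.array([1.0, 2.0, 3.0, 2.0])
        bt = _toy_bintable(np.vstack([base, base]))
        fm = w.pqn_normalize(bt)
        np.testing.assert_allclose(fm.normalization_quotients, 1.0)

    def test_idempotent_exact_for_pure_scaling(self):
        """Samples that are scaled copies of one shape: after one PQN pass
        they coincide, so a second pass finds quotients of exactly 1."""
        rng = np.random.default_rng(40)
        base = rng.lognormal(0, 0.5, 30)
        scales = rng.lognormal(0, 0.3, 8)
        bt = _toy_bintable(np.outer(scales, base))
        fm = w.pqn_normalize(bt)
        fm2 = w.pqn_normalize(
            BinTable(fm.bins, fm.X, fm.sample_ids, fm.manifest))
        np.testing.assert_allclose(fm2.normalization_quotients, 1.0, atol=1e-6)

    def test_near_idempotent_on_noisy_study(self, two_group_study):
        """With biological variation the re-estimated reference shifts a
        little, so a second pass changes samples only marginally."""
        fm = two_group_study["fm"]
        fm2 = w.pqn_normalize(
            BinTable(fm.bins, fm.X, fm.sample_ids, fm.manifest))
        np.testing.assert_allclose(fm2.normalization_quotients, 1.0, atol=0.05)

    def test_all_zero_sample_rejected(self):
        base = np.array([1.0, 2.0, 3.0, 2.0])
        bt = _toy_bintable(np.vstack([base, 0.0 * base]), ids=["ok", "dead"])
        with pytest.raises(w.InputError, match="dead"):
            w.pqn_normalize(bt)

    def test_group_reference(self, two_group_study):
        bt = two_group_study["bt"]
        fm = w.pqn_normalize(bt, ("median-of-group", "CON"))
        assert (fm.normalization_quotients > 0).all()


class TestMeanCenter:
    def test_two_sample_column(self):
        bt = _toy_bintable(np.array([[1.0, 5.0], [3.0, 5.0]]))
        fm = w.pqn_normalize(bt)
        # work on a raw feature matrix to keep the arithmetic exact
        from wormetab.spectra import FeatureMatrix

        raw = FeatureMatrix(np.array([[1.0, 4.0], [3.0, 4.0]]), fm.bins,
                            fm.sample_ids, fm.manifest)
        cen = w.mean_center(raw)
        np.testing.assert_allclose(cen.X[:, 0], [-1.0, 1.0])
        np.testing.assert_allclose(cen.X[:, 1], [0.0, 0.0])

    def test_column_means_zero_and_round_trip(self, two_group_study):
        fm = two_group_study["fm"]
        cen = w.mean_center(fm)
        scale = np.abs(fm.X).max()
        assert np.abs(cen.X.mean(axis=0)).max() < 1e-10 * scale
        back = cen.X + cen.column_means
        np.testing.assert_allclose(back, fm.X, rtol=1e-12)

    def test_double_centering_rejected(self, two_group_study):
        cen = w.mean_center(two_group_study["fm"])
        with pytest.raises(w.InputError):
            w.mean_center(cen)

    def test_single_sample_rejected(self):
        from wormetab.spectra import FeatureMatrix

        bt = _toy_bintable(np.array([[1.0, 2.0]]), ids=["only"])
        fmx = FeatureMatrix(bt.X, bt.bins, bt.sample_ids, bt.manifest)
        with pytest.raises(w.InputError):
            w.mean_center(fmx)


def test_feature_matrix_csv_round_trip(tmp_path, two_group_study):
    fm = two_group_study["fm"]
    path = str(tmp_path / "fm.csv")
    fm.to_csv(path)
    back = w.FeatureMatrix.from_csv(path, fm.manifest)
    np.testing.assert_allclose(back.X, fm.X, rtol=1e-12)
    assert back.sample_ids == fm.sample_ids
    np.testing.assert_allclose(back.feature_ppm, fm.feature_ppm, atol=1e-6)
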