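import numpy as np
import pytest

from nircal import SpectrumSet, crop, read_csv, relative_spectrum, write_csv


def _const_set(wl, value, n=2, **kw):
    return SpectrumSet(wl, np.full((n, len(wl)), float(value)), **kw)


class TestRelativeSpectrum:
    wl = np.array([600.0, 602.0, 604.0])

    def test_sample_equal_to_white_gives_one(self):
        dark = _const_set(self.wl, 0.2, n=1)
        white = _const_set(self.wl, 1.3, n=1)
        raw = _const_set(self.wl, 1.3, n=4)
        rc = relative_spectrum(raw, dark, white)
        assert np.allclose(rc.intensities, 1.0)

    def test_sample_equal_to_dark_gives_zero(self):
        dark = _const_set(self.wl, 0.2, n=1)
        white = _const_set(self.wl, 1.3, n=1)
        rc = relative_spectrum(_const_set(self.wl, 0.2, n=3), dark, white)
        assert np.allclose(rc.intensities, 0.0)

    def test_printed_formula_value(self):
        # (0.6 - 0.1) / (1.1 - 0.1) = 0.5
        dark = _const_set(self.wl, 0.1, n=1)
        white = _const_set(self.wl, 1.1, n=1)
        rc = relative_spectrum(_const_set(self.wl, 0.6, n=1), dark, white)
        assert np.allclose(rc.intensities, 0.5)

    def test_carries_labels_from_raw(self):
        raw = _const_set(self.wl, 0.6, n=2, sample_ids=["p1", "p2"],
                         ssc=np.array([12.0, 13.0]))
        rc = relative_spectrum(raw, _const_set(self.wl, 0.1, n=1),
                               _const_set(self.wl, 1.1, n=1))
        assert rc.sample_ids == ["p1", "p2"]
        assert np.array_equal(rc.ssc, raw.ssc)

    def test_grid_mismatch_rejected(self):
        other = np.array([600.0, 602.0, 606.0])
        with pytest.raises(ValueError, match="grids"):
            relative_spectrum(_const_set(self.wl, 0.5), _const_set(other, 0.1),
                              _const_set(other, 1.0))

    def test_white_equals_dark_names_channel(self):
        dark = SpectrumSet(self.wl, np.array([[0.1, 0.1, 0.1]]))
        white = SpectrumSet(self.wl, np.array([[1.0, 0.1, 1.0]]))
        with pytest.raises(ValueError, match="602"):
            relative_spectrum(_const_set(self.wl, 0.5), dark, white)

    def test_commutes_with_crop(self):
        rng = np.random.default_rng(0)
        wl = 500.0 + 2.0 * np.arange(60)
        raw = SpectrumSet(wl, rng.uniform(0.3, 0.9, size=(4, 60)))
        dark = SpectrumSet(wl, rng.uniform(0.0, 0.1, size=(1, 60)))
        white = SpectrumSet(wl, rng.uniform(1.0, 1.2, size=(1, 60)))
        a = crop(relative_spectrum(raw, dark, white), 520, 600)
        b = relative_spectrum(crop(raw, 520, 600), crop(dark, 520, 600),
                              crop(white, 520, 600))
        assert np.allclose(a.intensities, b.intensities)
        assert np.array_equal(a.wavelengths, b.wavelengths)


class TestCrop:
    def test_study_range_channel_count(self):
        wl = 500.0 + 2.0 * np.arange(256)  # 500..1010 nm
        s = crop(_const_set(wl, 1.0), 550, 1000)
        assert s.n_channels == 226
        assert s.wavelengths[0] == 550.0
        assert s.wavelengths[-1] == 1000.0

    def test_full_range_is_identity(self, small_set):
        c = crop(small_set, small_set.wavelengths[0], small_set.wavelengths[-1])
        assert np.array_equal(c.intensities, small_set.intensities)

    def test_closed_interval_endpoints(self):
        wl = 500.0 + 2.0 * np.arange(256)
        s = crop(_const_set(wl, 1.0), 990, 1000)
        assert s.n_channels == 6

    def test_empty_result_rejected(self, small_set):
        with pytest.raises(ValueError, match="at least 2"):
            crop(small_set, 900.0, 910.0)


class TestCsvRoundTrip:
    def test_lossless_round_trip(self, small_set, tmp_path):
        p = tmp_path / "s.csv"
        write_csv(small_set, p)
        back = read_csv(p)
        assert np.array_equal(back.wavelengths, small_set.wavelengths)
        assert np.array_equal(back.intensities, small_set.intensities)
        assert np.array_equal(back.ssc, small_set.ssc)
        assert back.sample_ids == small_set.sample_ids

    def test_missing_ssc_column_is_fine(self, small_set, tmp_path):
        p = tmp_path / "s.csv"
        write_csv(small_set.replace(ssc=None), p)
        back = read_csv(p)
        assert back.ssc is None

    def test_decreasing_columns_resorted(self, tmp_path):
        p = tmp_path / "rev.csv"
        p.write_text("sample_id,604.0,602.0,600.0\na,3.0,2.0,1.0\n")
        back = read_csv(p)
        assert np.array_equal(back.wavelengths, [600.0, 602.0, 604.0])
        assert np.array_equal(back.intensities, [[1.0, 2.0, 3.0]])

    def test_non_numeric_cell_reports_context(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("sample_id,600.0,602.0\na,1.0,oops\n")
        with pytest.raises(ValueError, match=r"row 0.*602"):
            read_csv(p)

    def test_duplicate_wavelength_rejected(self, tmp_path):
        p = tmp_path / "dup.csv"
        p.write_text("sample_id,600.0,600.00\na,1.0,2.0\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_csv(p)

    def test_unnamed_column_rejected(self, tmp_path):
        p = tmp_path / "odd.csv"
        p.write_text("sample_id,colour,600.0\na,red,1.0\n")
        with pytest.raises(ValueError, match="colour"):
            read_csv(p)


class TestSpectrumSetInvariants:
    def test_rejects_nan(self):
        with pytest.raises(ValueError, match="NaN"):
            SpectrumSet(np.array([1.0, 2.0]), np.array([[1.0, np.nan]]))

    def test_rejects_nonpositive_ssc(self):
        with pytest.raises(ValueError, match="> 0"):
            SpectrumSet(np.array([1.0, 2.0]), np.ones((1, 2)), ssc=[0.0])

    def test_sorts_unsorted_grid(self):
        s = SpectrumSet(np.array([2.0, 1.0]), np.array([[10.0, 20.0]]))
        assert np.array_equal(s.wavelengths, [1.0, 2.0])
        assert np.array_equal(s.intensities, [[20.0, 10.0]])

    def test_subset_keeps_alignment(self, small_set):
        sub = small_set.subset([2, 0])
        assert sub.sample_ids == ["c", "a"]
        assert np.array_equal(sub.ssc, [13.0, 12.0])
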