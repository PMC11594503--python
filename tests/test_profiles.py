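"""Profile containers, porosity, outlier cleaning, and CSV round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from poregibbs import (
    DepthProfile,
    SiteConditions,
    clean_porosity_outliers,
    porosity_from_water_content,
    read_core_csv,
    read_site_yaml,
    write_core_csv,
    write_site_yaml,
)
from poregibbs.errors import InsufficientDataError, ParseError, RangeError
from poregibbs.profiles import CoreDataset, water_content_from_porosity


class TestPorosity:
    def test_hand_evaluated_value(self):
        # 0.7 * 2.5 / (2.5 * 0.7 + 0.3 * 1.025) = 1.75 / 2.0575
        assert porosity_from_water_content(0.7) == pytest.approx(1.75 / 2.0575)
        assert porosity_from_water_content(0.7) == pytest.approx(0.8506, abs=5e-4)

    def test_endpoints(self):
        assert porosity_from_water_content(0.0) == 0.0
        assert porosity_from_water_content(1.0) == 1.0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    def test_monotone_and_bounded(self, w1, w2):
        p1, p2 = porosity_from_water_content(w1), porosity_from_water_content(w2)
        assert 0.0 <= p1 <= 1.0
        if w1 < w2:
            assert p1 < p2 or (w1 == w2)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(0.01, 0.99))
    def test_inverse_round_trip(self, w):
        assert water_content_from_porosity(porosity_from_water_content(w)) == pytest.approx(w)

    def test_out_of_range(self):
        with pytest.raises(RangeError):
            porosity_from_water_content(1.2)


def _baseline_profile():
    depths = np.arange(1.0, 32.0, 2.0)  # 16 shallow points
    # period-5 jitter: every 5-point window sees the same five offsets, so
    # the IQR fence (q3 + 1.5 iqr = 0.008 above baseline) is never crossed
    offsets = np.array([0.0, 0.004, -0.004, 0.002, -0.002])
    values = 0.78 + offsets[np.arange(len(depths)) % 5]
    return DepthProfile.from_arrays("porosity", depths, values)


class TestOutlierCleaning:
    def test_injected_spike_replaced_by_iqr_rule(self):
        prof = _baseline_profile()
        values = prof.values.copy()
        spike_idx = 7
        values[spike_idx] = 0.99
        spiked = DepthProfile.from_arrays("porosity", prof.depths, values)
        cleaned, report = clean_porosity_outliers(spiked)

        # brute-force oracle: with a 5-point window the quartiles are simply
        # the 2nd and 4th smallest values (linear interpolation at n=5)
        window = np.sort(values[spike_idx - 2 : spike_idx + 3])
        q1, q3 = window[1], window[3]
        assert values[spike_idx] > q3 + 1.5 * (q3 - q1)

        assert len(report) == 1
        rep = report[0]
        assert rep.rule == "iqr"
        assert rep.depth_cm == spiked.depths[spike_idx]
        neighbors = [values[spike_idx - 1], values[spike_idx + 1], values[spike_idx - 2]]
        assert rep.new_value == pytest.approx(np.mean(neighbors))
        assert cleaned.values[spike_idx] == pytest.approx(rep.new_value)

    def test_clean_profile_unchanged(self):
        prof = _baseline_profile()
        cleaned, report = clean_porosity_outliers(prof)
        assert report == []
        np.testing.assert_array_equal(cleaned.values, prof.values)

    def test_idempotence(self):
        prof = _baseline_profile()
        values = prof.values.copy()
        values[4] = 0.99
        spiked = DepthProfile.from_arrays("porosity", prof.depths, values)
        once, report1 = clean_porosity_outliers(spiked)
        twice, report2 = clean_porosity_outliers(once)
        assert report1 and report2 == []
        np.testing.assert_array_equal(once.values, twice.values)

    def test_deep_rule_boundary_is_strict(self):
        depths = np.array([34.0, 36.0, 38.0, 40.0, 42.0])
        surrounding = np.array([0.70, 0.72, 0.74, 0.76])
        mean, sd = surrounding.mean(), surrounding.std(ddof=1)
        exactly = np.insert(surrounding, 2, mean + 3.0 * sd)
        prof = DepthProfile.from_arrays("porosity", depths, exactly)
        _, report = clean_porosity_outliers(prof)
        assert report == []  # exactly 3 SD is retained

        beyond = np.insert(surrounding, 2, mean + 3.0 * sd + 1e-6)
        prof2 = DepthProfile.from_arrays("porosity", depths, beyond)
        cleaned2, report2 = clean_porosity_outliers(prof2)
        assert [r.rule for r in report2] == ["3sd"]
        assert cleaned2.values[2] == pytest.approx(mean)

    def test_too_few_shallow_points(self):
        prof = DepthProfile.from_arrays("porosity", [1.0, 5.0, 9.0], [0.8, 0.8, 0.8])
        with pytest.raises(InsufficientDataError):
            clean_porosity_outliers(prof)


class TestCoreCsvRoundTrip:
    def _dataset(self):
        site = SiteConditions(temperature=24.0, salinity=35.0, pH=7.2)
        profiles = {
            "so4_mM": DepthProfile.from_arrays("so4_mM", [1.0, 3.0, 5.0], [24.0, 22.0, 20.0]),
            "h2_nM": DepthProfile.from_arrays(
                "h2_nM", [1.0, 1.0, 3.0], [0.5, 0.52, 0.6], replicate=[0, 1, 0]
            ),
        }
        return CoreDataset(site=site, profiles=profiles)

    def test_lossless_round_trip(self, tmp_path):
        ds = self._dataset()
        core_path = tmp_path / "core.csv"
        site_path = tmp_path / "site.yaml"
        write_core_csv(ds, core_path, site_path=site_path)
        back = read_core_csv(core_path, site_path)
        assert back.site == ds.site
        for name, prof in ds.profiles.items():
            np.testing.assert_allclose(back[name].depths, prof.depths)
            np.testing.assert_allclose(back[name].values, prof.values)

    def test_replicate_rows_retained(self, tmp_path):
        ds = self._dataset()
        path = tmp_path / "core.csv"
        write_core_csv(ds, path, site_path=tmp_path / "site.yaml")
        back = read_core_csv(path, tmp_path / "site.yaml")
        h2 = back["h2_nM"].data
        assert (h2["depth_cm"] == 1.0).sum() == 2
        assert sorted(h2.loc[h2["depth_cm"] == 1.0, "replicate"]) == [0, 1]

    def test_missing_depth_column(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("so4_mM\n24.0\n")
        site = SiteConditions(temperature=24.0, salinity=35.0, pH=7.2)
        with pytest.raises(ParseError, match="depth_cm"):
            read_core_csv(p, site)

    def test_unknown_column(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("depth_cm,mystery\n1.0,2.0\n")
        site = SiteConditions(temperature=24.0, salinity=35.0, pH=7.2)
        with pytest.raises(ParseError, match="mystery"):
            read_core_csv(p, site)

    def test_non_numeric_cell_reports_line(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("depth_cm,so4_mM\n1.0,24.0\n3.0,oops\n")
        site = SiteConditions(temperature=24.0, salinity=35.0, pH=7.2)
        with pytest.raises(ParseError, match="line 3"):
            read_core_csv(p, site)


class TestSiteYaml:
    def test_round_trip(self, tmp_path):
        site = SiteConditions(temperature=28.5, salinity=18.9, pH=7.2, ionic_strength=0.7)
        path = tmp_path / "site.yaml"
        write_site_yaml(site, path)
        assert read_site_yaml(path) == site

    def test_missing_field_named(self, tmp_path):
        path = tmp_path / "site.yaml"
        path.write_text("temperature_C: 24\nsalinity_permil: 35\nionic_strength_M: 0.7\n")
        with pytest.raises(Exception, match="pH"):
            read_site_yaml(path)
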