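"""CDR/MAL/rMAL arithmetic, live calling, counting and plateau logic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ramavit as rv
from ramavit.errors import RamavitError
from ramavit.vitality import CdrBands, VitalityRecord, viable_rate


def _spectrum_with_band_areas(a_cd, a_ch):
    """Baseline-free spectrum with known C-D and C-H areas (Gaussian bumps
    deep inside each band, where the trapezoid rule is exact to rounding)."""
    w = np.arange(1900.0, 3201.0)
    norm = 1.0 / (12.0 * np.sqrt(2 * np.pi))
    y = a_cd * norm * np.exp(-0.5 * ((w - 2170.0) / 12.0) ** 2)
    y += a_ch * norm * np.exp(-0.5 * ((w - 2950.0) / 12.0) ** 2)
    return rv.Spectrum(w, y)


class TestBandArea:
    def test_zero_spectrum(self):
        s = rv.Spectrum(np.arange(2000.0, 2401.0), np.zeros(401))
        assert rv.band_area(s, rv.Band("cd", 2040, 2300)) == 0.0

    def test_constant_one_over_cd_band(self):
        w = np.arange(2040.0, 2301.0)
        s = rv.Spectrum(w, np.ones(w.size))
        assert rv.band_area(s, rv.Band("cd", 2040, 2300)) == pytest.approx(260.0)

    def test_band_outside_axis_errors(self):
        s = rv.Spectrum(np.arange(600.0, 1800.0), np.zeros(1200))
        with pytest.raises(RamavitError, match="outside"):
            rv.band_area(s, rv.Band("cd", 2040, 2300))

    def test_negative_intensities_clipped(self):
        w = np.arange(2040.0, 2301.0)
        s = rv.Spectrum(w, np.full(w.size, -1.0))
        assert rv.band_area(s, rv.Band("cd", 2040, 2300)) == 0.0


class TestCdr:
    def test_unlabelled_cell_is_zero(self):
        assert rv.compute_cdr(_spectrum_with_band_areas(0.0, 5.0)) == 0.0

    def test_equal_areas_give_half(self):
        assert rv.compute_cdr(_spectrum_with_band_areas(3.0, 3.0)) == pytest.approx(0.5, abs=1e-6)

    def test_one_to_three_gives_quarter(self):
        assert rv.compute_cdr(_spectrum_with_band_areas(1.0, 3.0)) == pytest.approx(0.25, abs=1e-6)

    def test_both_zero_convention(self):
        assert rv.compute_cdr(_spectrum_with_band_areas(0.0, 0.0)) == 0.0

    def test_band_order_invariant(self):
        with pytest.raises(RamavitError):
            CdrBands(cd_band=rv.Band("cd", 2800, 3100), ch_band=rv.Band("ch", 2040, 2300))


class TestMalAndRmal:
    @pytest.mark.parametrize(
        "cdr_sample,cdr_0h,expected",
        [(0.0140, 0.0084, 0.0056), (0.0247, 0.0075, 0.0172), (0.3, 0.3, 0.0)],
    )
    def test_mal_arithmetic(self, cdr_sample, cdr_0h, expected):
        assert rv.compute_mal(cdr_sample, cdr_0h) == pytest.approx(expected, abs=1e-12)

    def test_rmal_endpoints_and_midpoint(self):
        assert rv.compute_rmal(0.05, 0.05, 0.01) == pytest.approx(1.0)
        assert rv.compute_rmal(0.01, 0.05, 0.01) == pytest.approx(0.0)
        assert rv.compute_rmal(0.03, 0.05, 0.01) == pytest.approx(0.5)

    def test_degenerate_control(self):
        with pytest.raises(RamavitError, match="degenerate"):
            rv.compute_rmal(0.03, 0.01, 0.01)

    @given(
        st.floats(0, 1, allow_nan=False), st.floats(0, 1, allow_nan=False)
    )
    @settings(max_examples=50, deadline=None)
    def test_mal_bounded(self, a, b):
        assert -1.0 <= rv.compute_mal(a, b) <= 1.0


class TestViabilityCall:
    @pytest.mark.parametrize("mal,live", [(0.0056, True), (0.0, False), (-0.001, False)])
    def test_threshold_rule(self, mal, live):
        assert rv.call_viability(mal) is live

    def test_margin(self):
        assert rv.call_viability(0.005, margin=0.01) is False
        assert rv.call_viability(0.02, margin=0.01) is True


class TestSummarize:
    def _records(self, mals, live=None):
        live = live or [m > 0 for m in mals]
        return [
            VitalityRecord(cell_id=f"c{i}", cdr=0.1, mal=m, live=l)
            for i, (m, l) in enumerate(zip(mals, live))
        ]

    def test_constant_mal_gives_zero_hi(self):
        s = rv.summarize_sample(self._records([0.02, 0.02, 0.02]))
        assert s.hi == 0.0

    def test_hand_computed_hi(self):
        s = rv.summarize_sample(self._records([0.01, 0.03]))
        assert s.hi == pytest.approx(0.0141421356, abs=1e-9)

    def test_viable_rate_half(self):
        s = rv.summarize_sample(self._records([0.1, 0.2, -0.1, 0.0]))
        assert s.viable_rate == 0.5

    def test_single_cell_has_no_hi(self):
        assert rv.summarize_sample(self._records([0.1])).hi is None

    def test_empty_errors(self):
        with pytest.raises(RamavitError):
            rv.summarize_sample([])

    def test_hi_zero_iff_constant(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            mals = rng.normal(0.02, 0.01, size=5)
            s = rv.summarize_sample(self._records(list(mals)))
            assert (s.hi == 0.0) == bool(np.all(mals == mals[0]))


class TestCounting:
    def test_hemocytometer_arithmetic(self):
        got = rv.total_count_from_fields([10, 10, 10, 10, 10], 1e6, 100, 1.0)
        assert got == pytest.approx(1.0e9)

    def test_zero_field(self):
        assert rv.total_count_from_fields([0], 1e6, 10, 1.0) == 0.0

    def test_empty_fields_error(self):
        with pytest.raises(RamavitError):
            rv.total_count_from_fields([], 1e6, 10, 1.0)

    @pytest.mark.parametrize(
        "live,total,pct", [(1.35e10, 1.99e10, 67.84), (3.84e11, 4.13e11, 92.98)]
    )
    def test_viable_rates_from_counts(self, live, total, pct):
        assert round(viable_rate(live, total) * 100, 2) == pct

    def test_live_count(self):
        assert rv.live_count(4.13e11, 3.84e11 / 4.13e11) == pytest.approx(3.84e11)
        assert rv.live_count(1e10, 0.0) == 0.0

    def test_species_resolved_counts_conserve_total(self):
        props = {"a": 0.2679, "b": 0.5422, "c": 0.0228, "d": 0.1566, "e": 0.0105}
        counts = rv.species_resolved_counts(3.84e11, props)
        assert sum(counts.values()) == pytest.approx(3.84e11, rel=1e-9)
        assert counts["a"] == pytest.approx(1.03e11, rel=5e-3)

    def test_species_counts_even_split(self):
        assert rv.species_resolved_counts(100.0, {"A": 0.5, "B": 0.5}) == {
            "A": 50.0,
            "B": 50.0,
        }

    def test_species_counts_bad_proportions(self):
        with pytest.raises(RamavitError, match="sum to 1"):
            rv.species_resolved_counts(100.0, {"A": 0.6, "B": 0.3})


class TestSurvival:
    def test_product_arithmetic(self):
        assert round(rv.survival_rate(3.57e7, 3.40e9) * 100, 2) == 1.05

    def test_equal_counts(self):
        assert rv.survival_rate(1e9, 1e9) == 1.0

    def test_growth_warns(self):
        with pytest.warns(UserWarning, match="growth"):
            assert rv.survival_rate(2e9, 1e9) == 2.0

    def test_zero_before_errors(self):
        with pytest.raises(RamavitError):
            rv.survival_rate(1.0, 0.0)


class TestPlateau:
    def test_saturating_series(self):
        t = [1, 2, 2.5, 3, 3.5, 4]
        f = [0.23, 0.60, 0.90, 0.939, 0.941, 0.941]
        assert rv.plateau_time(t, f, epsilon=0.01) == 3.0

    def test_never_plateaus_warns(self):
        with pytest.warns(UserWarning, match="plateau"):
            assert rv.plateau_time([1, 2, 3], [0.1, 0.5, 0.9], epsilon=1e-6) == 3.0

    def test_constant_series_returns_first(self):
        assert rv.plateau_time([1, 2, 3], [0.5, 0.5, 0.5], epsilon=0.01) == 1.0

    def test_length_mismatch(self):
        with pytest.raises(RamavitError):
            rv.plateau_time([1, 2], [0.1], epsilon=0.1)
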