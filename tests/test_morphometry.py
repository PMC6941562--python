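"""Infarct-size arithmetic: per-section ratios, averages, volumetric weighting."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amac import (SectionMeasurement, SectionSeries, UndefinedMeasurementError,
                  average_infarct_fraction, collagen_content_pct,
                  infarct_fraction_section, interstitial_fibrosis_pct,
                  summarize_series, volumetric_infarct_fraction)
from amac.datasets import example_series


def sec(i, total, infarct, **kw):
    return SectionMeasurement(section_index=i, total_area_px=total,
                              infarct_area_px=infarct, **kw)


@st.composite
def measurement_lists(draw):
    n = draw(st.integers(1, 8))
    out = []
    for i in range(n):
        total = draw(st.integers(1, 10**6))
        infarct = draw(st.integers(0, total))
        out.append(sec(i + 1, total, infarct))
    return out


class TestSectionFractions:
    @pytest.mark.parametrize("total, infarct, expected, tol", [
        # tolerance is half a unit in the last printed decimal place
        (65841, 21610, 32.82, 0.005),   # published automated section 2
        (275569, 27678, 10.04, 0.005),  # published automated section 5
        (79048, 43023, 54.4, 0.05),     # published manual section 2
        (1000, 0, 0.0, 0.0),
    ])
    def test_matches_published_per_section_values(self, total, infarct,
                                                  expected, tol):
        got = infarct_fraction_section(sec(1, total, infarct))
        assert got == pytest.approx(expected, abs=max(tol, 1e-12))

    def test_zero_total_area_is_undefined(self):
        with pytest.raises(UndefinedMeasurementError):
            infarct_fraction_section(sec(1, 0, 0))

    def test_infarct_cannot_exceed_total(self):
        with pytest.raises(ValueError):
            sec(1, 10, 11)


class TestVolumetricFraction:
    def test_single_section_collapses_to_section_fraction(self):
        s = SectionSeries(sections=[sec(1, 5000, 700)])
        assert volumetric_infarct_fraction(s) == \
            infarct_fraction_section(s.sections[0])

    def test_spacing_invariance_under_uniform_n(self):
        secs = [sec(1, 1000, 100), sec(2, 3000, 900)]
        ref = volumetric_infarct_fraction(SectionSeries(sections=secs))
        for n in (2, 5, 17):
            s = SectionSeries(sections=secs, n_px_per_spacing=n)
            assert volumetric_infarct_fraction(s) == ref

    def test_equals_area_weighted_mean_not_plain_average(self):
        secs = [sec(1, 1000, 500), sec(2, 9000, 900)]  # 50% and 10%
        s = SectionSeries(sections=secs)
        vol = volumetric_infarct_fraction(s)
        assert vol == pytest.approx(100 * 1400 / 10000)
        assert vol != pytest.approx(average_infarct_fraction(s))

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            volumetric_infarct_fraction(SectionSeries(sections=[]))

    @given(measurement_lists())
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_volumetric_between_zero_and_hundred_and_order_invariant(self, ms):
        s = SectionSeries(sections=ms)
        vol = volumetric_infarct_fraction(s)
        assert 0.0 <= vol <= 100.0
        rev = [SectionMeasurement(section_index=i + 1,
                                  total_area_px=m.total_area_px,
                                  infarct_area_px=m.infarct_area_px)
               for i, m in enumerate(reversed(ms))]
        assert vol == pytest.approx(
            volumetric_infarct_fraction(SectionSeries(sections=rev)))


class TestAverageFraction:
    def test_identical_sections_average_to_their_value(self):
        secs = [sec(i, 2000, 500) for i in range(1, 5)]
        assert average_infarct_fraction(SectionSeries(sections=secs)) == 25.0

    def test_order_invariance(self):
        secs = [sec(1, 100, 10), sec(2, 200, 150), sec(3, 300, 7)]
        a = average_infarct_fraction(SectionSeries(sections=secs))
        rev = [sec(i + 1, m.total_area_px, m.infarct_area_px)
               for i, m in enumerate(reversed(secs))]
        b = average_infarct_fraction(SectionSeries(sections=rev))
        assert a == pytest.approx(b)


class TestRoiPercentages:
    @pytest.mark.parametrize("fn, num_field, den_field, num, den, expected", [
        (collagen_content_pct, "scar_collagen_px", "scar_total_px",
         1711, 10000, 17.11),
        (collagen_content_pct, "scar_collagen_px", "scar_total_px",
         0, 5000, 0.0),
        (interstitial_fibrosis_pct, "remote_fibrosis_px", "remote_total_px",
         615, 10000, 6.15),
        (interstitial_fibrosis_pct, "remote_fibrosis_px", "remote_total_px",
         4321, 4321, 100.0),
    ])
    def test_ratio_values(self, fn, num_field, den_field, num, den, expected):
        m = sec(2, 10**6, 0, **{num_field: num, den_field: den})
        assert fn(m) == pytest.approx(expected)

    @given(st.integers(1, 10**6), st.data())
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_direct_division(self, den, data):
        num = data.draw(st.integers(0, den))
        m = sec(2, 10**6, 0, scar_collagen_px=num, scar_total_px=den,
                remote_fibrosis_px=num, remote_total_px=den)
        assert collagen_content_pct(m) == pytest.approx(100 * num / den)
        assert interstitial_fibrosis_pct(m) == pytest.approx(100 * num / den)

    def test_missing_roi_yields_not_available(self):
        m = sec(1, 100, 10)
        assert collagen_content_pct(m) is None
        assert interstitial_fibrosis_pct(m) is None


class TestSummarizeSeries:
    def test_single_section_summary_is_that_section(self):
        m = sec(1, 4000, 1000, scar_collagen_px=50, scar_total_px=200,
                remote_fibrosis_px=10, remote_total_px=500)
        s = summarize_series(SectionSeries(sections=[m]))
        assert s.per_section_pct == [25.0]
        assert s.average_infarct_pct == 25.0
        assert s.volumetric_infarct_pct == 25.0
        assert s.avg_collagen_pct == pytest.approx(25.0)
        assert s.avg_fibrosis_pct == pytest.approx(2.0)

    def test_missing_roi_sections_do_not_change_roi_averages(self):
        with_roi = [sec(1, 1000, 100, scar_collagen_px=30, scar_total_px=100),
                    sec(2, 1000, 100, scar_collagen_px=50, scar_total_px=100)]
        base = summarize_series(SectionSeries(sections=with_roi))
        extended = summarize_series(SectionSeries(
            sections=with_roi + [sec(3, 1000, 100)]))
        assert extended.avg_collagen_pct == base.avg_collagen_pct == \
            pytest.approx(40.0)

    def test_all_sections_missing_roi_gives_none(self):
        s = summarize_series(SectionSeries(sections=[sec(1, 100, 1)]))
        assert s.avg_collagen_pct is None and s.avg_fibrosis_pct is None

    @given(measurement_lists())
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_every_percentage_in_range(self, ms):
        s = summarize_series(SectionSeries(sections=ms))
        for p in s.per_section_pct + [s.average_infarct_pct,
                                      s.volumetric_infarct_pct]:
            assert 0.0 <= p <= 100.0


class TestExampleDataset:
    """The bundled serial-section comparison study behaves as published."""

    def test_weighted_vs_unweighted_discrepancy(self):
        s = example_series("auto")
        avg = average_infarct_fraction(s)
        vol = volumetric_infarct_fraction(s)
        # small apical sections have the largest infarct fractions, so the
        # area-weighted (volumetric) estimate sits well below the plain mean
        assert vol < avg

    def test_series_ordering_and_spacing(self):
        s = example_series("manual")
        assert [m.section_index for m in s.sections] == list(range(2, 11))
        assert s.spacing_um == 300.0
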