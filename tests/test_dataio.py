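"""Format parsing, validation and round-trip fidelity."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from peatcarbon import dataio
from peatcarbon.dataio import (ActivityRow, ActivityTable, CoreTable,
                               DateEntry, DateTable, Increment, PlotCensus,
                               RingSeries, RingSeriesSet, SiteConfig,
                               bp_to_ce, ce_to_bp)
from peatcarbon.errors import ParseError, ValidationError


def make_core(n=5, site="t"):
    return CoreTable(site, [Increment(i, i + 1, 0.05 + 0.01 * i,
                                      0.9, i % 3) for i in range(n)])


class TestAgeConventions:
    def test_coring_year_2017_maps_to_minus_67(self):
        assert ce_to_bp(2017) == -67

    def test_bp_ce_round_trip(self):
        assert bp_to_ce(ce_to_bp(1839)) == 1839


class TestCoreCsv:
    def test_single_row_identity_parse(self, tmp_path):
        p = tmp_path / "core.csv"
        p.write_text("depth_top,depth_bottom,bulk_density,om_fraction,"
                     "charcoal_count\n0,1,0.05,0.95,0\n")
        core = dataio.read_core_csv(p)
        assert len(core) == 1
        inc = core.increments[0]
        assert (inc.depth_top, inc.depth_bottom) == (0, 1)
        assert inc.bulk_density == 0.05 and inc.om_fraction == 0.95

    def test_95_contiguous_rows(self, tmp_path):
        p = tmp_path / "core.csv"
        rows = "\n".join(f"{i},{i+1},0.1,0.9,0" for i in range(95))
        p.write_text("depth_top,depth_bottom,bulk_density,om_fraction,"
                     "charcoal_count\n" + rows + "\n")
        assert len(dataio.read_core_csv(p)) == 95

    def test_gap_rejected(self, tmp_path):
        p = tmp_path / "core.csv"
        p.write_text("depth_top,depth_bottom,bulk_density,om_fraction,"
                     "charcoal_count\n0,1,0.1,0.9,0\n2,3,0.1,0.9,0\n")
        with pytest.raises(ValidationError, match="contiguous"):
            dataio.read_core_csv(p)

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "core.csv"
        p.write_text("depth_top,depth_bottom,bulk_density,om_fraction,"
                     "charcoal_count\n0,1,oops,0.9,0\n")
        with pytest.raises(ParseError, match="line 2"):
            dataio.read_core_csv(p)

    def test_om_density_alternative(self, tmp_path):
        p = tmp_path / "core.csv"
        p.write_text("depth_top,depth_bottom,bulk_density,om_density,"
                     "charcoal_count\n0,1,0.10,0.08,0\n")
        core = dataio.read_core_csv(p)
        assert core.om_fraction[0] == pytest.approx(0.8)

    def test_both_om_columns_rejected(self, tmp_path):
        p = tmp_path / "core.csv"
        p.write_text("depth_top,depth_bottom,bulk_density,om_fraction,"
                     "om_density,charcoal_count\n0,1,0.1,0.9,0.09,0\n")
        with pytest.raises(ParseError, match="exactly one"):
            dataio.read_core_csv(p)

    def test_round_trip(self, tmp_path):
        core = make_core(8)
        dataio.write_core_csv(core, tmp_path / "c.csv")
        back = dataio.read_core_csv(tmp_path / "c.csv", site_id="t")
        np.testing.assert_allclose(back.bulk_density, core.bulk_density, rtol=1e-9)
        np.testing.assert_array_equal(back.charcoal_count, core.charcoal_count)

    def test_thicknesses_sum_to_span(self):
        core = make_core(9)
        assert core.thickness.sum() == pytest.approx(core.total_depth)


class TestMergeIncrements:
    def test_mass_is_conserved(self):
        core = make_core(10)
        merged = dataio.merge_increments(core, 2)
        om_orig = np.sum(core.bulk_density * core.om_fraction * core.thickness)
        om_merg = np.sum(merged.bulk_density * merged.om_fraction
                         * merged.thickness)
        assert om_merg == pytest.approx(om_orig, rel=1e-12)
        assert merged.total_depth == pytest.approx(core.total_depth)


class TestDateTable:
    def test_two_surface_entries_rejected(self):
        with pytest.raises(ValidationError, match="surface"):
            DateTable([DateEntry(0, "surface", -67, 0),
                       DateEntry(0.5, "surface", -67, 0)])

    def test_c14_requires_positive_sigma(self):
        with pytest.raises(ValidationError, match="sigma"):
            DateTable([DateEntry(10, "c14", 1000, 0)])

    def test_round_trip(self, tmp_path):
        t = DateTable([DateEntry(0, "surface", -67, 0, "top"),
                       DateEntry(26.5, "c14", 218, 57, "fire"),
                       DateEntry(38, "c14", 1255, 57, "base")])
        dataio.write_dates_csv(t, tmp_path / "d.csv")
        back = dataio.read_dates_csv(tmp_path / "d.csv")
        assert [e.kind for e in back.entries] == ["surface", "c14", "c14"]
        assert back.entries[2].age_value == pytest.approx(1255)


class TestCalCurve:
    def test_three_line_identity(self, tmp_path):
        p = tmp_path / "cc.txt"
        p.write_text("# header\n0,0,1\n100,100,1\n200,200,1\n")
        curve = dataio.read_calcurve(p)
        assert len(curve) == 3
        assert curve.c14_at(150) == pytest.approx(150)

    def test_row_count_equals_noncomment_lines(self, tmp_path):
        # oracle: count the data lines independently of the parser
        lines = ["# c\n"] + [f"{10 * i} {10 * i} 2\n" for i in range(17)]
        p = tmp_path / "cc.txt"
        p.write_text("".join(lines))
        expected = sum(1 for l in lines if not l.startswith("#"))
        assert len(dataio.read_calcurve(p)) == expected

    def test_reversed_order_sorted(self, tmp_path):
        p = tmp_path / "cc.txt"
        p.write_text("200,210,1\n100,105,1\n0,0,1\n")
        curve = dataio.read_calcurve(p)
        assert curve.cal_age[0] == 0 and curve.cal_age[-1] == 200

    def test_non_monotone_rejected(self, tmp_path):
        p = tmp_path / "cc.txt"
        p.write_text("0,0,1\n100,90,1\n50,50,1\n")
        with pytest.raises(ValidationError, match="monotone"):
            dataio.read_calcurve(p)

    def test_round_trip(self, tmp_path):
        from peatcarbon.synthetic import make_calcurve
        c = make_calcurve(0, 500, 10, 8.0)
        dataio.write_calcurve(c, tmp_path / "cc.txt")
        back = dataio.read_calcurve(tmp_path / "cc.txt")
        np.testing.assert_allclose(back.cal_age, c.cal_age, atol=1e-9)
        np.testing.assert_allclose(back.c14_age, c.c14_age, atol=0.01)


class TestRwl:
    def test_simple_series(self, tmp_path):
        p = tmp_path / "t.rwl"
        p.write_text("T01     1839   100   100   100   100   100   100   100"
                     "   100   100   100\nT01     1849   999\n")
        rset = dataio.read_rwl(p)
        rs = rset.series["T01"]
        assert rs.first_year == 1839
        assert rs.widths_mm.size == 10
        np.testing.assert_allclose(rs.widths_mm, 1.0)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "e.rwl"
        p.write_text("")
        assert len(dataio.read_rwl(p)) == 0

    def test_terminator_mid_decade_truncates(self, tmp_path):
        # oracle: token count before the terminator
        body = "T02     1900   120   130   140  -9999    55    66\n"
        tokens = body.split()[2:]
        n_expected = tokens.index("-9999")
        p = tmp_path / "t.rwl"
        p.write_text(body)
        rs = dataio.read_rwl(p).series["T02"]
        assert rs.widths_mm.size == n_expected
        np.testing.assert_allclose(rs.widths_mm, [1.2, 1.3, 1.4])

    def test_year_misalignment_rejected(self, tmp_path):
        p = tmp_path / "t.rwl"
        p.write_text("T03     1900   100   100\nT03     1905   100   999\n")
        with pytest.raises(ParseError, match="expected decade year"):
            dataio.read_rwl(p)

    def test_round_trip(self, tmp_path, rng):
        widths = np.round(rng.uniform(0.1, 3.0, size=37), 2)
        rset = RingSeriesSet({"A01": RingSeries("A01", 1954, widths)})
        dataio.write_rwl(rset, tmp_path / "t.rwl")
        back = dataio.read_rwl(tmp_path / "t.rwl").series["A01"]
        assert back.first_year == 1954
        np.testing.assert_allclose(back.widths_mm, widths, atol=5e-3)

    def test_combine_radii_averages(self, tmp_path):
        rset = RingSeriesSet({
            "A01A": RingSeries("A01A", 1900, np.array([1.0, 2.0, 3.0])),
            "A01B": RingSeries("A01B", 1900, np.array([3.0, 4.0, 5.0])),
        })
        combined = dataio.combine_radii_by_prefix(rset)
        rs = combined.series["A01"]
        np.testing.assert_allclose(rs.widths_mm, [2.0, 3.0, 4.0])
        assert rs.radius_count == 2


class TestActivityAndCensus:
    def test_activity_round_trip(self, tmp_path):
        t = ActivityTable([ActivityRow(i, i + 1, 50.0 - i, 2.0)
                           for i in range(10)])
        dataio.write_activity_csv(t, tmp_path / "a.csv")
        back = dataio.read_activity_csv(tmp_path / "a.csv")
        np.testing.assert_allclose(back.total_activity, t.total_activity,
                                   rtol=1e-9)

    def test_census_round_trip(self, tmp_path):
        c = PlotCensus("s", 100.0, [("a", 10.0), ("b", 5.5)])
        dataio.write_census_csv(c, tmp_path / "c.csv")
        back = dataio.read_census_csv(tmp_path / "c.csv", "s")
        assert back.plot_area_m2 == 100.0
        np.testing.assert_allclose(back.dbh, c.dbh)


class TestSiteConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = SiteConfig(site_id="x", coring_year=2017, mc_iterations=500)
        cfg.to_yaml(tmp_path / "cfg.yml")
        back = SiteConfig.from_yaml(tmp_path / "cfg.yml")
        assert back == cfg

    def test_surface_age(self):
        assert SiteConfig(coring_year=2017).surface_age_bp == -67.0

    def test_bad_carbon_fraction_rejected(self):
        with pytest.raises(ValidationError):
            SiteConfig(carbon_fraction_peat=1.5)


@given(st.lists(st.tuples(st.floats(0.01, 0.4), st.floats(0.0, 1.0),
                          st.integers(0, 50)), min_size=1, max_size=30))
def test_core_round_trip_property(tmp_path_factory, rows):
    """Any valid core table survives a CSV write/read cycle."""
    core = CoreTable("p", [Increment(i, i + 1, r[0], r[1], r[2])
                           for i, r in enumerate(rows)])
    p = tmp_path_factory.mktemp("rt") / "c.csv"
    dataio.write_core_csv(core, p)
    back = dataio.read_core_csv(p, "p")
    np.testing.assert_allclose(back.om_fraction, core.om_fraction, atol=1e-9)
    np.testing.assert_array_equal(back.charcoal_count, core.charcoal_count)
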