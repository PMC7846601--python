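"""Carbon density, stocks, CAR, LORCA and RERCA arithmetic."""

import numpy as np
import pytest

from peatcarbon.agedepth import build_ensemble
from peatcarbon.calibration import gaussian_date
from peatcarbon.carbon import (carbon_profile, lorca, lorca_from_stock,
                               postfire_stock, rerca)
from peatcarbon.charcoal import FireLayer, FireRecord, detect_layers
from peatcarbon.dataio import (CoreTable, Increment, SiteConfig,
                               merge_increments)
from peatcarbon.errors import ValidationError


def uniform_core(n, bulk, om_frac, charcoal=None):
    charcoal = charcoal or [0] * n
    return CoreTable("c", [Increment(i, i + 1, bulk, om_frac, charcoal[i])
                           for i in range(n)])


def exact_linear_ens(depth, dep_time, surface=-67.0, n_iter=150):
    dates = [gaussian_date(surface, 0.0, depth=0.0),
             gaussian_date(surface + dep_time * depth, 0.0, depth=depth)]
    return build_ensemble(dates, surface_age=surface, n_iter=n_iter, seed=0)


class TestCarbonProfile:
    def test_single_increment_arithmetic(self):
        """rho 0.1, om 1.0, dep time 100 -> c 0.05, CAR 5 g C m-2 yr-1."""
        core = uniform_core(1, bulk=0.1, om_frac=1.0)
        ens = exact_linear_ens(1.0, 100.0)
        prof = carbon_profile(core, ens, SiteConfig())
        assert prof.c_density[0] == pytest.approx(0.05)
        assert prof.car[0] == pytest.approx(5.0)
        assert prof.total_stock == pytest.approx(0.5)  # kg C m-2

    def test_car_stock_conservation_identity(self, cas0_default):
        """sum(car * dep_time * thickness) reproduces the total stock."""
        prof = cas0_default[0].profile
        total_g_m2 = np.sum(prof.car * prof.dep_time * prof.thickness)
        assert total_g_m2 == pytest.approx(1000.0 * prof.total_stock,
                                           rel=1e-9)

    def test_rebinning_invariance(self):
        core = CoreTable("c", [Increment(i, i + 1, 0.05 + 0.01 * (i % 4),
                                         0.90 + 0.005 * (i % 3), 0)
                               for i in range(12)])
        ens = exact_linear_ens(12.0, 50.0)
        cfg = SiteConfig()
        fine = carbon_profile(core, ens, cfg)
        coarse = carbon_profile(merge_increments(core, 3), ens, cfg)
        assert coarse.total_stock == pytest.approx(fine.total_stock, rel=1e-9)

    def test_stock_above_partial_increment(self):
        core = uniform_core(10, bulk=0.1, om_frac=0.8)   # c = 0.04 g/cm3
        ens = exact_linear_ens(10.0, 10.0)
        prof = carbon_profile(core, ens, SiteConfig())
        assert prof.stock_above(2.5) == pytest.approx(10 * 0.04 * 2.5)


class TestLorca:
    def test_printed_worked_examples(self):
        v1, _ = lorca_from_stock(22.6, 1255.0)
        assert v1 == pytest.approx(18.0, abs=0.05)
        v2, _ = lorca_from_stock(66.0, 7522.0)
        assert v2 == pytest.approx(8.8, abs=0.05)

    def test_zero_stock(self):
        v, s = lorca_from_stock(0.0, 1000.0)
        assert v == 0.0 and s == 0.0

    def test_sigma_propagation_and_inverse_identity(self):
        v, s = lorca_from_stock(30.0, 5000.0, basal_sigma=100.0)
        assert v * 5000.0 / 1000.0 == pytest.approx(30.0, rel=1e-12)
        assert s == pytest.approx(v * 100.0 / 5000.0)

    def test_nonpositive_basal_age_rejected(self):
        with pytest.raises(ValidationError):
            lorca_from_stock(10.0, 0.0)


class TestRerca:
    def test_uniform_hand_computed_case(self):
        """c 0.0088 g/cm3, 1 cm/yr, coring 2017: RERCA(1950) = 88.0."""
        core = uniform_core(100, bulk=0.0176, om_frac=1.0)
        ens = exact_linear_ens(100.0, 1.0)
        cfg = SiteConfig(coring_year=2017, mc_iterations=150)
        prof = carbon_profile(core, ens, cfg)
        est = rerca(prof, ens, 1950, cfg)
        assert est.depth_cm == pytest.approx(67.0, abs=1e-9)
        assert est.value == pytest.approx(88.0, abs=1e-6)

    def test_boundary_one_year_window(self):
        core = uniform_core(100, bulk=0.02, om_frac=1.0)
        ens = exact_linear_ens(100.0, 1.0)
        cfg = SiteConfig(coring_year=2017)
        prof = carbon_profile(core, ens, cfg)
        est = rerca(prof, ens, 2016, cfg)
        assert est.years == 1.0
        assert est.value == pytest.approx(1e4 * 0.01 * 1.0, rel=1e-9)

    def test_horizon_after_coring_rejected(self):
        core = uniform_core(10, bulk=0.02, om_frac=1.0)
        ens = exact_linear_ens(10.0, 1.0)
        cfg = SiteConfig(coring_year=2017)
        prof = carbon_profile(core, ens, cfg)
        with pytest.raises(ValidationError):
            rerca(prof, ens, 2018, cfg)


class TestPostfireStock:
    def make_profile(self, n=30, bulk=0.046, om_frac=1.0):
        core = uniform_core(n, bulk=bulk, om_frac=om_frac)
        ens = exact_linear_ens(float(n), 10.0)
        return carbon_profile(core, ens, SiteConfig())

    def test_boundary_at_surface_gives_zero(self):
        prof = self.make_profile()
        rec = FireRecord([FireLayer(0.0, 1.0, 5)])
        assert postfire_stock(prof, rec) == 0.0

    def test_uniform_arithmetic(self):
        """c 0.023 g/cm3 above 25 cm -> 5.75 kg C m-2."""
        prof = self.make_profile()
        rec = FireRecord([FireLayer(25.0, 26.0, 5)])
        assert postfire_stock(prof, rec) == pytest.approx(5.75)

    def test_no_fire_returns_total(self):
        prof = self.make_profile()
        rec = FireRecord([])
        assert postfire_stock(prof, rec) == prof.total_stock

    def test_generator_truth_recovered_exactly(self, cas0_zero):
        res, truth, _ = cas0_zero
        assert postfire_stock(res.profile, res.fires) == \
            pytest.approx(truth.postfire_c_stock, abs=1e-9)

    def test_charcoal_below_boundary_does_not_change_stock(self):
        """Deep charcoal must not affect the post-fire section."""
        counts_a = [0] * 10 + [8] + [0] * 19
        counts_b = [0] * 10 + [8] + [0] * 9 + [9] + [0] * 9
        cfg = SiteConfig()
        ens = exact_linear_ens(30.0, 10.0)
        stocks = []
        for counts in (counts_a, counts_b):
            core = uniform_core(30, bulk=0.05, om_frac=0.9, charcoal=counts)
            prof = carbon_profile(core, ens, cfg)
            rec = detect_layers(core)
            stocks.append(postfire_stock(prof, rec))
        assert stocks[0] == pytest.approx(stocks[1], abs=1e-12)


class TestSiteSummary:
    def test_summary_consistency(self, cas0_default):
        s = cas0_default[0].summary
        assert s.postfire_stock <= s.total_stock
        assert s.lorca == pytest.approx(
            1000.0 * s.total_stock / s.basal_age, rel=1e-9)
        assert s.rerca_1950.years == 67.0 and s.rerca_1900.years == 117.0
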