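"""Forward simulation of complete study sites with known ground truth.

Scenarios describe a peat core as a stack of constant-rate segments
(thickness, deposition time, organic-matter density) mimicking a boreal
forested-peatland transect: a fast, light *Sphagnum*-dominated acrotelm over
dense, slowly accumulating woody peat. Fires deposit charcoal spikes into
the increment their calendar age falls in; unsupported 210Pb accumulates
under a constant flux and decays with true age; 14C lab ages are the true
calendar ages mapped through the supplied calibration curve. Tree cohorts
are even-aged post-fire stands with sigmoid diameter growth.

Every observable carries Gaussian noise whose magnitude (and whose reported
sigma) scales with ``noise_scale``, so ``noise_scale=0`` produces exactly
invertible observations — the property the zero-noise recovery tests rely
on. Compaction is not modelled as a process: segments state final
per-increment densities directly, because the pipeline only ever consumes
the compacted observables.

Presets ``cas0/cas50/cas100`` mirror a paludification gradient (shallow
young core to deep old core) with a last fire ~175 cal yr BP and deep
charcoal layers between ~7000 and ~1000 cal yr BP.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .dataio import (ActivityRow, ActivityTable, CalCurve, CoreTable,
                     DateEntry, DateTable, Increment, PlotCensus, RingSeries,
                     RingSeriesSet, ce_to_bp, LAMBDA_PB210)
from .errors import ValidationError

log = logging.getLogger(__name__)

#: Reported sigmas are floored here so that zero-noise data still satisfy
#: the sigma > 0 invariants while behaving as exact.
_SIGMA_FLOOR = 1e-9


@dataclass(frozen=True)
class Segment:
    """A constant-rate stretch of peat, shallowest first."""

    thickness_cm: int
    dep_time_yr_cm: float     # yr cm^-1
    om_density: float         # g cm^-3
    om_fraction: float = 0.96


@dataclass
class CoreScenario:
    site_id: str
    segments: list[Segment]
    fire_ages_bp: list[float]          # cal yr BP, any order
    coring_year: int = 2017
    pb_flux: float = 150.0             # Bq m^-2 yr^-1
    supported: float = 15.0            # Bq kg^-1
    pb_depth_max_cm: float | None = 30.0   # None = measure the whole core
    c14_sigma_range: tuple = (40.0, 70.0)  # reported lab sigma, yr
    c14_extra_depths: int = 2          # mid-core dates between last fire and base
    pb_cv: float = 0.05
    noise_scale: float = 1.0
    charcoal_peak: int = 25            # fragments cm^-3 deposited per fire
    carbon_fraction: float = 0.5

    @property
    def total_depth(self):
        return sum(s.thickness_cm for s in self.segments)


@dataclass
class SyntheticSiteTruth:
    """Ground truth for one generated core."""

    site_id: str
    boundaries: np.ndarray        # cm, 0..N
    ages_before_coring: np.ndarray  # yr, per boundary
    ages_bp: np.ndarray           # cal yr BP, per boundary
    c_deposited: np.ndarray       # g C cm^-2 per increment
    fire_events: list[tuple]      # (age_bp, depth_cm, increment_top_cm)
    pb_flux: float
    supported: float
    basal_age_bp: float
    total_c_stock: float          # kg C m^-2
    postfire_c_stock: float       # kg C m^-2 above the last fire layer top
    lorca: float                  # g C m^-2 yr^-1, stock / basal cal BP age
    seed: int | None
    scenario: CoreScenario

    def age_at_depth(self, depth):
        """True age (cal yr BP) at any depth, piecewise linear."""
        return np.interp(depth, self.boundaries, self.ages_bp)


def make_calcurve(cal_min=-1000.0, cal_max=10000.0, step=5.0, curve_sigma=10.0,
                  wiggle_amp=0.0, wiggle_period=500.0) -> CalCurve:
    """A synthetic calibration curve: identity plus an optional sinusoidal
    wiggle (kept monotone when ``wiggle_amp * 2 pi / wiggle_period < 1``)."""
    cal = np.arange(cal_min, cal_max + step / 2, step)
    c14 = cal + wiggle_amp * np.sin(2 * np.pi * cal / wiggle_period)
    if np.any(np.diff(c14) <= 0):
        raise ValidationError("wiggle parameters make the curve non-monotone")
    return CalCurve(cal, c14, np.full(cal.size, float(curve_sigma)))


def _segment_arrays(scenario: CoreScenario):
    dep, om, frac = [], [], []
    for s in scenario.segments:
        dep += [s.dep_time_yr_cm] * s.thickness_cm
        om += [s.om_density] * s.thickness_cm
        frac += [s.om_fraction] * s.thickness_cm
    return np.array(dep), np.array(om), np.array(frac)


def generate_core(scenario: CoreScenario, seed=None, curve: CalCurve = None):
    """Deposit a synthetic core and all its dating observables.

    Returns ``(CoreTable, DateTable, ActivityTable, SyntheticSiteTruth)``.
    The same seed reproduces bit-identical outputs.
    """
    rng = np.random.default_rng(seed)
    if curve is None:
        curve = make_calcurve()
    dep, om, frac = _segment_arrays(scenario)
    if np.any(dep <= 0):
        raise ValidationError("deposition times must be positive")
    n = dep.size
    bounds = np.arange(n + 1, dtype=float)
    ages_bc = np.concatenate([[0.0], np.cumsum(dep)])   # yr before coring
    surface_bp = float(ce_to_bp(scenario.coring_year))
    ages_bp = ages_bc + surface_bp
    basal_bp = float(ages_bp[-1])

    bulk = om / frac
    charcoal = np.zeros(n, dtype=int)
    fires = []
    for fbp in sorted(scenario.fire_ages_bp):
        t = fbp - surface_bp
        if t <= 0 or t >= ages_bc[-1]:
            raise ValidationError(f"fire age {fbp} cal BP outside the core's span")
        d = float(np.interp(t, ages_bc, bounds))
        idx = min(int(d), n - 1)
        charcoal[idx] += scenario.charcoal_peak
        fires.append((float(fbp), d, float(idx)))

    core = CoreTable(scenario.site_id, [
        Increment(float(bounds[i]), float(bounds[i + 1]), float(bulk[i]),
                  float(frac[i]), int(charcoal[i]))
        for i in range(n)
    ])

    # --- 210Pb: constant flux, decayed by true age, plus supported level ---
    lam = LAMBDA_PB210
    zmax = scenario.pb_depth_max_cm
    n_pb = n if zmax is None else int(min(n, np.ceil(zmax)))
    rows = []
    for i in range(n_pb):
        inv = scenario.pb_flux / lam * (np.exp(-lam * ages_bc[i])
                                        - np.exp(-lam * ages_bc[i + 1]))
        mass_kg_m2 = bulk[i] * 1.0 * 10.0
        act = inv / mass_kg_m2 + scenario.supported
        sig = scenario.pb_cv * act
        noisy = act + scenario.noise_scale * sig * rng.standard_normal()
        rows.append(ActivityRow(float(bounds[i]), float(bounds[i + 1]),
                                max(float(noisy), 0.0),
                                max(scenario.noise_scale * sig, _SIGMA_FLOOR)))
    activity = ActivityTable(rows)

    # --- 14C: one date per fire layer, extras mid-core, one basal date ---
    depths = [f[2] + 0.5 for f in fires]
    if fires and scenario.c14_extra_depths:
        lo = min(f[2] for f in fires)
        for k in range(1, scenario.c14_extra_depths + 1):
            d = np.floor(lo + (n - lo) * k / (scenario.c14_extra_depths + 1)) + 0.5
            depths.append(float(d))
    depths.append(float(n))   # basal age at the organic-mineral interface
    entries = [DateEntry(0.0, "surface", surface_bp, 0.0, "surface")]
    for d in sorted(set(depths)):
        true_bp = float(np.interp(d, bounds, ages_bp))
        sig = float(rng.uniform(*scenario.c14_sigma_range))
        lab = float(curve.c14_at(true_bp)
                    + scenario.noise_scale * sig * rng.standard_normal())
        entries.append(DateEntry(float(d), "c14", lab,
                                 max(scenario.noise_scale * sig, _SIGMA_FLOOR),
                                 f"synth_{d:g}cm"))
    dates = DateTable(entries)

    c_dep = scenario.carbon_fraction * om * 1.0   # g C cm^-2 per 1 cm increment
    total_stock = 10.0 * float(np.sum(c_dep))
    if fires:
        top = min(f[2] for f in fires)
        postfire = 10.0 * float(np.sum(c_dep[: int(top)]))
    else:
        postfire = total_stock
    truth = SyntheticSiteTruth(
        site_id=scenario.site_id, boundaries=bounds,
        ages_before_coring=ages_bc, ages_bp=ages_bp, c_deposited=c_dep,
        fire_events=fires, pb_flux=scenario.pb_flux,
        supported=scenario.supported, basal_age_bp=basal_bp,
        total_c_stock=total_stock, postfire_c_stock=postfire,
        lorca=1000.0 * total_stock / basal_bp, seed=seed, scenario=scenario)
    log.info("generate_core[%s]: %d cm, basal %.0f cal BP, %d fire(s)",
             scenario.site_id, n, basal_bp, len(fires))
    return core, dates, activity, truth


# ---------------------------------------------------------------------------
# Presets: a paludification gradient
# ---------------------------------------------------------------------------
# Shared acrotelm: ~20 cm of light Sphagnum peat accumulating at 3 yr cm^-1
# over a denser transition to the last fire horizon at ~26 cm (~175 cal BP);
# below it, dense slowly accumulating woody peat.

def cas0_scenario(noise_scale=1.0) -> CoreScenario:
    """Shallow end of the transect: 38 cm, basal age 1255 cal yr BP."""
    return CoreScenario(
        site_id="cas0",
        segments=[
            Segment(20, 3.0, 0.080, 0.97),
            Segment(6, 30.0, 0.150, 0.95),
            Segment(12, 1082.0 / 12.0, 0.168, 0.94),
        ],
        fire_ages_bp=[175.0, 1100.0],
        noise_scale=noise_scale,
    )


def cas50_scenario(noise_scale=1.0) -> CoreScenario:
    """Middle of the transect: 69 cm, basal age 7667 cal yr BP."""
    return CoreScenario(
        site_id="cas50",
        segments=[
            Segment(20, 3.0, 0.075, 0.97),
            Segment(6, 30.0, 0.150, 0.95),
            Segment(20, 170.0, 0.160, 0.94),
            Segment(23, 4094.0 / 23.0, 0.1565, 0.94),
        ],
        fire_ages_bp=[175.0, 3000.0, 7000.0],
        noise_scale=noise_scale,
    )


def cas100_scenario(noise_scale=1.0) -> CoreScenario:
    """Deep end of the transect: 95 cm, basal age 7522 cal yr BP."""
    return CoreScenario(
        site_id="cas100",
        segments=[
            Segment(20, 3.0, 0.080, 0.97),
            Segment(6, 30.0, 0.150, 0.95),
            Segment(24, 170.0, 0.165, 0.94),
            Segment(45, 3269.0 / 45.0, 0.150, 0.94),
        ],
        fire_ages_bp=[175.0, 2500.0, 5000.0, 7200.0],
        noise_scale=noise_scale,
    )


SCENARIOS = {"cas0": cas0_scenario, "cas50": cas50_scenario,
             "cas100": cas100_scenario}


# ---------------------------------------------------------------------------
# Tree cohorts
# ---------------------------------------------------------------------------

@dataclass
class TreeCohortScenario:
    """An even-aged post-fire cohort with sigmoid diameter growth."""

    site_id: str
    n_trees: int = 20           # ring-sampled trees
    n_census: int | None = None  # all trees in the plot; defaults to n_trees
    establishment_year: int = 1839
    final_year: int = 2018
    mean_dbh_cm: float = 10.0
    dbh_sd_cm: float = 2.0
    inflection_frac: float = 0.45   # fraction of the lifespan at peak growth
    steepness: float = 8.0          # logistic steepness over the lifespan
    width_cv: float = 0.10
    plot_area_m2: float = 100.0
    noise_scale: float = 1.0


@dataclass
class TreeCohortTruth:
    site_id: str
    establishment_year: int
    final_dbh_cm: dict[str, float]
    seed: int | None
    scenario: TreeCohortScenario


def generate_trees(cohort: TreeCohortScenario, seed=None):
    """Grow a synthetic cohort.

    Ring widths follow a logistic-increment (sech^2) curve scaled per tree to
    its target radius, with multiplicative lognormal noise; the census DBH is
    the final diameter implied by the (noisy) widths, so ring series and
    census are exactly consistent.

    Returns ``(RingSeriesSet, PlotCensus, TreeCohortTruth)``.
    """
    rng = np.random.default_rng(seed)
    n_yr = cohort.final_year - cohort.establishment_year + 1
    t = np.arange(n_yr)
    k = cohort.steepness / n_yr
    shape = 1.0 / np.cosh(k * (t - cohort.inflection_frac * n_yr)) ** 2
    shape /= shape.sum()

    def draw_target():
        target = rng.normal(cohort.mean_dbh_cm, cohort.dbh_sd_cm)
        while target < 2.0:
            target = rng.normal(cohort.mean_dbh_cm, cohort.dbh_sd_cm)
        return target

    series = {}
    census = []
    finals = {}
    n_census = cohort.n_census if cohort.n_census is not None else cohort.n_trees
    for j in range(max(n_census, cohort.n_trees)):
        tid = f"{cohort.site_id.upper()}T{j + 1:02d}"
        target = draw_target()
        if j < cohort.n_trees:
            radius_mm = target * 10.0 / 2.0
            widths = radius_mm * shape
            if cohort.noise_scale > 0 and cohort.width_cv > 0:
                cv = cohort.noise_scale * cohort.width_cv
                widths = widths * np.exp(cv * rng.standard_normal(n_yr)
                                         - cv ** 2 / 2)
            dbh_final = 2.0 * float(widths.sum()) / 10.0
            series[tid] = RingSeries(tid, cohort.establishment_year, widths)
        else:
            dbh_final = target   # censused but not ring-sampled
        census.append((tid, dbh_final))
        finals[tid] = dbh_final
    truth = TreeCohortTruth(cohort.site_id, cohort.establishment_year,
                            finals, seed, cohort)
    return (RingSeriesSet(series),
            PlotCensus(cohort.site_id, cohort.plot_area_m2, census), truth)


def cas0_cohort(noise_scale=1.0) -> TreeCohortScenario:
    return TreeCohortScenario("cas0", n_census=35, mean_dbh_cm=10.0,
                              dbh_sd_cm=2.0, noise_scale=noise_scale)


def cas50_cohort(noise_scale=1.0) -> TreeCohortScenario:
    return TreeCohortScenario("cas50", n_census=37, mean_dbh_cm=9.1,
                              dbh_sd_cm=1.9, noise_scale=noise_scale)


def cas100_cohort(noise_scale=1.0) -> TreeCohortScenario:
    # growth slows late in the deep-peat stand: later inflection, gentler
    # curve, and a denser plot of thinner stems
    return TreeCohortScenario("cas100", n_census=64, establishment_year=1838,
                              mean_dbh_cm=5.6, dbh_sd_cm=1.2,
                              inflection_frac=0.55, steepness=5.0,
                              noise_scale=noise_scale)


COHORTS = {"cas0": cas0_cohort, "cas50": cas50_cohort, "cas100": cas100_cohort}
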