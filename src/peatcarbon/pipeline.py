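"""End-to-end orchestration: observables in, site comparison out.

``run_site`` wires the stages together for one core:
calibration -> CRS 210Pb ages -> Monte-Carlo age-depth ensemble -> charcoal
fire record -> carbon profile and summary -> (optionally) tree stocks and the
peat-vs-tree comparison. ``run_synthetic_site`` does the same starting from a
generator scenario and also returns the ground truth for recovery checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from . import agedepth, calibration, carbon, charcoal, compare, lead210, trees
from .dataio import (ActivityTable, CalCurve, CoreTable, DateTable,
                     PlotCensus, RingSeriesSet, SiteConfig)
from .synthetic import (CoreScenario, TreeCohortScenario, generate_core,
                        generate_trees, make_calcurve)

log = logging.getLogger(__name__)


@dataclass
class SiteResult:
    cfg: SiteConfig
    core: CoreTable
    calibrated: list
    crs: lead210.CrsResult | None
    ensemble: agedepth.ChronologyEnsemble
    fires: charcoal.FireRecord
    profile: carbon.CarbonProfile
    summary: carbon.SiteCarbonSummary
    stand: trees.StandStocks | None = None
    mean_agb: object = None            # pandas Series indexed by year
    comparison: compare.SiteComparison | None = None


def run_site(core: CoreTable, dates: DateTable, activity: ActivityTable | None,
             curve: CalCurve, cfg: SiteConfig,
             rings: RingSeriesSet | None = None,
             census: PlotCensus | None = None,
             supported=None) -> SiteResult:
    """Run the full pipeline for one site.

    ``supported`` overrides the deep-tail estimate of supported 210Pb when a
    site-specific value is known. Tree stages run only when a census (and,
    for the growth curve, ring series) is given.
    """
    calibrated = calibration.summarize_dates(dates, curve, cfg.grid_step_yr)

    crs = None
    if activity is not None:
        if supported is None:
            supported, _ = lead210.estimate_supported(activity, cfg.supported_tail_n)
        crs = lead210.crs_ages(activity, core, supported, cfg.lambda_pb210)

    ens = agedepth.build_ensemble(
        calibrated, crs=crs, surface_age=cfg.surface_age_bp,
        n_iter=cfg.mc_iterations, seed=cfg.rng_seed,
        depth_grid=core.boundaries, crs_step_cm=cfg.pb_horizon_step_cm,
        crs_depth_max=cfg.pb_model_depth_max_cm)

    fires = charcoal.detect_layers(core, cfg.charcoal_threshold,
                                   cfg.charcoal_min_gap_cm)
    if fires.layers:
        fires = charcoal.date_last_fire(fires, ens)

    profile = carbon.carbon_profile(core, ens, cfg)
    c14_dates = [d for d in calibrated if d.kind == "c14"]
    basal_sigma = c14_dates[-1].sd() if c14_dates else None
    summary = carbon.site_summary(profile, ens, fires, cfg, basal_sigma)

    stand = mean_agb = comparison = None
    if census is not None:
        allo = trees.build_allometry(cfg.allometry)
        stand = trees.stand_stocks(census, allo, cfg)
        if rings is not None:
            finals = dict(census.trees)
            usable = {tid: rs for tid, rs in rings.series.items() if tid in finals}
            if usable:
                mean_agb = trees.mean_cumulative_agb(
                    RingSeriesSet(usable), finals, allo)
        comparison = compare.compare_site(summary, stand, cfg.carbon_fraction_wood)

    return SiteResult(cfg, core, calibrated, crs, ens, fires, profile,
                      summary, stand, mean_agb, comparison)


def run_synthetic_site(scenario: CoreScenario,
                       cohort: TreeCohortScenario | None = None,
                       cfg: SiteConfig | None = None, seed=0,
                       curve: CalCurve | None = None):
    """Generate a synthetic site and push it through the pipeline.

    The seed drives the generator and the Monte-Carlo chronology through
    independent streams. Returns ``(SiteResult, core_truth, tree_truth)``
    (``tree_truth`` is None without a cohort).
    """
    ss = np.random.SeedSequence(seed)
    core_seed, tree_seed, mc_seed = (int(s.generate_state(1)[0] % (2 ** 31))
                                     for s in ss.spawn(3))
    if curve is None:
        curve = make_calcurve()
    core, dates, activity, truth = generate_core(scenario, core_seed, curve)
    rings = census = tree_truth = None
    if cohort is not None:
        rings, census, tree_truth = generate_trees(cohort, tree_seed)
    base = cfg if cfg is not None else SiteConfig()
    cfg = replace(base, site_id=scenario.site_id, rng_seed=mc_seed,
                  coring_year=scenario.coring_year)
    result = run_site(core, dates, activity, curve, cfg, rings, census,
                      supported=None)
    return result, truth, tree_truth
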