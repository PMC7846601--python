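"""Ring-width-based tree biomass and plot-level carbon stocks.

Aboveground biomass (AGB) per tree is the sum of power-law components
``m = b1 * DBH^b2`` (kg, DBH in cm) for stem wood, bark, branches and
foliage. Belowground biomass (BGB) comes from several alternative equations
(functions of DBH or of AGB); their mean is reported as the central value and
their min/max as the range. Tree carbon is a fixed fraction (default 0.50)
of total biomass.

Annual DBH trajectories are reconstructed from ring widths: twice the
cumulative (mean-of-radii) width, rescaled multiplicatively so the final year
matches the measured field DBH — the rescaling absorbs bark thickness and
missed-pith bias, which ring widths alone cannot resolve.

The shipped :data:`DEFAULT_ALLOMETRY` uses black-spruce-like coefficients as
documented placeholders; for scientific use supply a coefficient set with
explicit provenance through the configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .dataio import PlotCensus, RingSeries, RingSeriesSet, SiteConfig
from .errors import ValidationError

log = logging.getLogger(__name__)

MIN_CENSUS_DBH_CM = 1.0


@dataclass(frozen=True)
class AgbComponent:
    name: str
    beta1: float
    beta2: float

    def __post_init__(self):
        if self.beta1 <= 0 or self.beta2 <= 0:
            raise ValidationError(f"{self.name}: allometric betas must be > 0")


@dataclass(frozen=True)
class BgbEquation:
    """A root-biomass equation; ``fn(dbh_cm, agb_kg) -> kg``."""

    name: str
    fn: Callable[[float, float], float]


@dataclass
class AllometrySet:
    agb_components: list[AgbComponent]
    bgb_equations: list[BgbEquation]
    provenance: str

    def __post_init__(self):
        if not self.agb_components:
            raise ValidationError("need at least one AGB component")
        if not self.bgb_equations:
            raise ValidationError("need at least one BGB equation")


def _root_ratio(dbh, agb):
    return 0.222 * agb


def _root_ratio_high(dbh, agb):
    return 0.30 * agb


def _root_power_dbh(dbh, agb):
    return 0.0239 * dbh ** 2.23


DEFAULT_ALLOMETRY = AllometrySet(
    agb_components=[
        AgbComponent("stem_wood", 0.0477, 2.5094),
        AgbComponent("stem_bark", 0.0153, 2.2122),
        AgbComponent("branches", 0.0291, 2.0751),
        AgbComponent("foliage", 0.1648, 1.4143),
    ],
    bgb_equations=[
        BgbEquation("root_shoot_ratio_0.222", _root_ratio),
        BgbEquation("root_shoot_ratio_0.30", _root_ratio_high),
        BgbEquation("root_power_dbh", _root_power_dbh),
    ],
    provenance=(
        "package default: black-spruce-like power laws shipped as documented "
        "placeholders; replace with a published, cited coefficient set for "
        "scientific use"
    ),
)

_BGB_FACTORIES = {
    "ratio_agb": lambda p: (lambda dbh, agb: p["factor"] * agb),
    "power_dbh": lambda p: (lambda dbh, agb: p["beta1"] * dbh ** p["beta2"]),
    "power_agb": lambda p: (lambda dbh, agb: p["beta1"] * agb ** p["beta2"]),
}


def build_allometry(spec: dict | None) -> AllometrySet:
    """Build an :class:`AllometrySet` from a raw config mapping, or return
    the documented default when ``spec`` is None."""
    if spec is None:
        return DEFAULT_ALLOMETRY
    comps = [AgbComponent(c["name"], float(c["beta1"]), float(c["beta2"]))
             for c in spec["agb_components"]]
    eqs = []
    for e in spec["bgb_equations"]:
        kind = e["kind"]
        if kind not in _BGB_FACTORIES:
            raise ValidationError(f"unknown BGB equation kind '{kind}'")
        eqs.append(BgbEquation(e["name"], _BGB_FACTORIES[kind](e)))
    return AllometrySet(comps, eqs, spec.get("provenance", "user-supplied"))


def agb_kg(dbh, allo: AllometrySet):
    """Aboveground biomass (kg) at a DBH (cm); accepts arrays."""
    d = np.asarray(dbh, dtype=float)
    if np.any(d < 0):
        raise ValidationError("dbh must be >= 0")
    total = sum(c.beta1 * d ** c.beta2 for c in allo.agb_components)
    return float(total) if np.isscalar(dbh) else total


def dbh_series(widths_mm, final_dbh):
    """Annual DBH trajectory (cm) from ring widths (mm).

    Raw diameters are twice the cumulative width; the series is rescaled
    multiplicatively so its last value equals ``final_dbh``.
    """
    w = np.asarray(widths_mm, dtype=float)
    if final_dbh <= 0:
        raise ValidationError("final_dbh must be > 0")
    raw_cm = 2.0 * np.cumsum(w) / 10.0
    if raw_cm[-1] <= 0:
        raise ValidationError("total ring width is zero; cannot rescale")
    return raw_cm * (final_dbh / raw_cm[-1])


def tree_agb_series(series: RingSeries, final_dbh, allo: AllometrySet):
    """(years, annual cumulative AGB in kg) for one tree."""
    d = dbh_series(series.widths_mm, final_dbh)
    return series.years, agb_kg(d, allo)


@dataclass
class StandStocks:
    """Plot-level tree biomass and carbon, all per m^2 of ground."""

    site_id: str
    agb_per_m2: float
    bgb_central: float
    bgb_lo: float
    bgb_hi: float
    tree_c: float              # kg C m^-2
    n_trees: int
    bgb_by_equation: dict[str, float] = field(default_factory=dict)

    def to_dataframe(self):
        return pd.DataFrame([{
            "site_id": self.site_id, "agb_kg_m2": self.agb_per_m2,
            "bgb_lo": self.bgb_lo, "bgb_central": self.bgb_central,
            "bgb_hi": self.bgb_hi, "tree_c_kg_m2": self.tree_c,
            "n_trees": self.n_trees,
        }])


def stand_stocks(census: PlotCensus, allo: AllometrySet,
                 cfg: SiteConfig) -> StandStocks:
    """Scale per-tree allometry to the plot.

    Trees below 1 cm DBH are rejected with a log notice (census convention).
    BGB central = mean over equations; lo/hi = min/max. Tree carbon is
    ``carbon_fraction_wood * (AGB + central BGB)``.
    """
    kept = [(tid, d) for tid, d in census.trees if d >= MIN_CENSUS_DBH_CM]
    dropped = len(census) - len(kept)
    if dropped:
        log.info("stand_stocks: rejected %d tree(s) with DBH < %g cm",
                 dropped, MIN_CENSUS_DBH_CM)
    if not kept:
        log.warning("stand_stocks: census empty after DBH filter; zero stocks")
        return StandStocks(census.site_id, 0.0, 0.0, 0.0, 0.0, 0.0, 0)
    dbh = np.array([d for _, d in kept])
    agb_each = agb_kg(dbh, allo)
    area = census.plot_area_m2
    agb_m2 = float(np.sum(agb_each) / area)
    per_eq = {
        eq.name: float(sum(eq.fn(d, a) for d, a in zip(dbh, agb_each)) / area)
        for eq in allo.bgb_equations
    }
    vals = np.array(list(per_eq.values()))
    central, lo, hi = float(vals.mean()), float(vals.min()), float(vals.max())
    tree_c = cfg.carbon_fraction_wood * (agb_m2 + central)
    return StandStocks(census.site_id, agb_m2, central, lo, hi,
                       float(tree_c), len(kept), per_eq)


def mean_cumulative_agb(rset: RingSeriesSet, final_dbhs: dict,
                        allo: AllometrySet) -> pd.Series:
    """Site mean of the per-tree annual cumulative AGB (kg), indexed by
    calendar year; each year averages over the trees alive in it."""
    if not rset.series:
        raise ValidationError("need at least one ring series")
    cols = {}
    for tid, rs in rset.series.items():
        years, agb = tree_agb_series(rs, final_dbhs[tid], allo)
        cols[tid] = pd.Series(agb, index=years)
    return pd.DataFrame(cols).mean(axis=1)
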