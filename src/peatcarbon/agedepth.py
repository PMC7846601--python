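"""Monte-Carlo age-depth modelling combining 14C and 210Pb chronologies.

The model is a clam-style piecewise-linear interpolator: each iteration draws
one calendar age per dated horizon (14C dates from their calibrated
posteriors, 210Pb/surface/event dates from Gaussians), rejects and redraws
until the age sequence increases strictly with depth, and interpolates the
accepted sequence onto the depth grid. Medians, central 95 % bands and
per-increment deposition times (yr cm^-1, the iteration-wise slopes) are
summarised across accepted iterations. This is deliberately not an
autoregressive accumulation-prior model (Bacon-style); the chronology is used
downstream only for deposition times and horizon lookups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import CalibratedDate, gaussian_date
from .errors import ChronologyError, OutOfSpanError, ValidationError
from .lead210 import CrsResult

log = logging.getLogger(__name__)


@dataclass
class ChronologyEnsemble:
    """Accepted Monte-Carlo age-depth realizations plus summaries."""

    depths: np.ndarray          # grid, cm
    realizations: np.ndarray    # (n_accepted, n_depths) cal yr BP
    horizon_depths: np.ndarray  # dated depths used
    n_requested: int
    n_discarded: int
    median_age: np.ndarray = None
    lo95: np.ndarray = None
    hi95: np.ndarray = None
    dep_time_median: np.ndarray = None   # per increment, yr cm^-1
    dep_time_lo: np.ndarray = None
    dep_time_hi: np.ndarray = None

    def __post_init__(self):
        q = np.quantile(self.realizations, [0.5, 0.025, 0.975], axis=0)
        self.median_age, self.lo95, self.hi95 = q
        slopes = np.diff(self.realizations, axis=1) / np.diff(self.depths)
        qd = np.quantile(slopes, [0.5, 0.025, 0.975], axis=0)
        self.dep_time_median, self.dep_time_lo, self.dep_time_hi = qd

    @property
    def n_accepted(self):
        return self.realizations.shape[0]

    def ages_at(self, depth) -> np.ndarray:
        """Per-iteration interpolated ages at one depth."""
        g = self.depths
        d = float(depth)
        if d <= g[0]:
            return self.realizations[:, 0].copy()
        if d >= g[-1]:
            return self.realizations[:, -1].copy()
        j = int(np.searchsorted(g, d, side="right"))
        w = (d - g[j - 1]) / (g[j] - g[j - 1])
        return (1 - w) * self.realizations[:, j - 1] + w * self.realizations[:, j]

    def age_at_depth(self, depth):
        """Ensemble median age and central 95 % interval at one depth."""
        a = self.ages_at(depth)
        med, lo, hi = np.quantile(a, [0.5, 0.025, 0.975])
        return float(med), (float(lo), float(hi))

    def to_dataframe(self):
        dep = np.append(self.dep_time_median, np.nan)
        lo = np.append(self.dep_time_lo, np.nan)
        hi = np.append(self.dep_time_hi, np.nan)
        return pd.DataFrame({
            "depth_cm": self.depths, "median_cal_BP": self.median_age,
            "lo95": self.lo95, "hi95": self.hi95,
            "dep_time_median": dep, "dep_time_lo": lo, "dep_time_hi": hi,
        })


def _crs_to_dates(crs: CrsResult, surface_age, step_cm, depth_max):
    """Pick CRS boundaries every ~step_cm down to depth_max and express them
    as Gaussian calendar dates (cal BP = surface age + yr before coring)."""
    out = []
    if crs is None:
        return out
    limit = depth_max if depth_max is not None else np.inf
    next_target = step_cm
    for d, a, s in zip(crs.depths, crs.ages, crs.sigmas):
        if d <= 0 or d > limit:
            continue
        if d + 1e-9 >= next_target:
            out.append(gaussian_date(surface_age + a, s, depth=d, kind="pb210",
                                     label=f"crs_{d:g}cm"))
            next_target += step_cm
    return out


def build_ensemble(dates: list[CalibratedDate], crs: CrsResult | None = None,
                   surface_age=-67.0, n_iter=2000, seed=None,
                   depth_grid=None, crs_step_cm=5.0, crs_depth_max=20.0,
                   max_attempts=1000) -> ChronologyEnsemble:
    """Draw a Monte-Carlo ensemble of monotone age-depth models.

    ``dates`` may include surface/event pass-through dates from
    :func:`peatcarbon.calibration.summarize_dates`; a degenerate surface date
    at depth 0 is added when absent. CRS horizons are thinned to one date per
    ``crs_step_cm`` down to ``crs_depth_max`` so that closely spaced, nearly
    coeval 210Pb ages do not dominate the monotonicity rejection.
    """
    horizons = [d for d in dates if np.isfinite(d.depth)]
    horizons += _crs_to_dates(crs, surface_age, crs_step_cm, crs_depth_max)
    if not any(abs(h.depth) < 1e-9 for h in horizons):
        horizons.append(gaussian_date(surface_age, 0.0, depth=0.0, kind="surface",
                                      label="surface"))
    horizons.sort(key=lambda h: h.depth)
    h_depths = np.array([h.depth for h in horizons])
    if np.any(np.diff(h_depths) <= 0):
        raise ValidationError("dated horizons must have unique depths")
    if len(horizons) < 2:
        raise ValidationError("need at least two dated horizons including the surface")
    if n_iter < 100:
        raise ValidationError("n_iter must be >= 100")

    rng = np.random.default_rng(seed)

    def draw(n):
        return np.column_stack([h.sample(n, rng) for h in horizons])

    draws = draw(n_iter)
    bad = ~np.all(np.diff(draws, axis=1) > 0, axis=1)
    attempt = 0
    while bad.any() and attempt < max_attempts:
        idx = np.flatnonzero(bad)
        draws[idx] = draw(idx.size)
        ok = np.all(np.diff(draws[idx], axis=1) > 0, axis=1)
        bad[idx[ok]] = False
        attempt += 1
    n_discarded = int(bad.sum())
    if n_discarded:
        log.info("build_ensemble: discarded %d/%d iterations after %d redraw rounds",
                 n_discarded, n_iter, attempt)
    accepted = draws[~bad]
    if accepted.shape[0] < 0.5 * n_iter:
        raise ChronologyError(
            f"only {accepted.shape[0]}/{n_iter} iterations accepted; "
            "inspect the dated horizons for age reversals")

    if depth_grid is None:
        d_last = h_depths[-1]
        depth_grid = np.unique(np.concatenate(
            [np.arange(h_depths[0], d_last, 1.0), [d_last]]))
    depth_grid = np.asarray(depth_grid, dtype=float)

    real = np.empty((accepted.shape[0], depth_grid.size))
    for i, row in enumerate(accepted):
        real[i] = np.interp(depth_grid, h_depths, row)

    return ChronologyEnsemble(depths=depth_grid, realizations=real,
                              horizon_depths=h_depths, n_requested=n_iter,
                              n_discarded=n_discarded)


def depth_at_age(ens: ChronologyEnsemble, target_age):
    """Invert the chronology: ensemble median depth (and central 95 %
    interval) at which ``target_age`` (cal yr BP) is reached."""
    basal_median = float(np.median(ens.realizations[:, -1]))
    if target_age > basal_median:
        raise OutOfSpanError(
            f"target age {target_age:g} is older than the basal median "
            f"{basal_median:g}")
    depths = np.empty(ens.n_accepted)
    for i, row in enumerate(ens.realizations):
        depths[i] = np.interp(target_age, row, ens.depths)
    med, lo, hi = np.quantile(depths, [0.5, 0.025, 0.975])
    return float(med), (float(lo), float(hi))
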