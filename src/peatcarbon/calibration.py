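"""Radiocarbon calibration against an arbitrary calibration curve.

A lab age ``t ± s`` is mapped onto the calendar grid ``theta`` by

    p(theta)  ∝  exp( −(t − mu(theta))² / 2 (s² + sigma_c(theta)²) )
                 / sqrt(s² + sigma_c(theta)²)

where ``mu`` and ``sigma_c`` are the curve mean and one-sigma error at
``theta``. Posteriors are kept in full (multimodality included); summaries
are the weighted 50th percentile and the central 2.5–97.5 % quantile
interval — not an HPD region — which keeps the summary deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .dataio import CalCurve, DateTable
from .errors import CoverageError, ValidationError

log = logging.getLogger(__name__)

#: Sigmas below this are treated as exact (degenerate single-point dates).
_DEGENERATE_SIGMA = 1e-8

#: Relative posterior mass below which leading/trailing grid cells are trimmed.
_MASS_TRIM = 1e-12


@dataclass
class CalibratedDate:
    """A date expressed as a probability mass function on a cal-age grid."""

    depth: float
    grid: np.ndarray        # cal yr BP, ascending
    posterior: np.ndarray   # mass per grid step, sums to 1
    median: float
    interval_95: tuple[float, float]
    kind: str = "c14"
    label: str = ""

    def sd(self) -> float:
        m = float(np.sum(self.grid * self.posterior))
        return float(np.sqrt(np.sum(self.posterior * (self.grid - m) ** 2)))

    def sample(self, n, rng) -> np.ndarray:
        if self.grid.size == 1:
            return np.full(n, self.grid[0])
        return rng.choice(self.grid, size=n, p=self.posterior)


def _weighted_quantiles(grid, w, qs):
    if grid.size == 1:
        return np.full(len(qs), float(grid[0]))
    cum = np.cumsum(w) - 0.5 * w   # midpoint cumulative: symmetric posteriors
    return np.interp(qs, cum, grid)  # get an exactly central median


def _summaries(grid, w):
    med, lo, hi = _weighted_quantiles(grid, w, [0.5, 0.025, 0.975])
    return float(med), (float(lo), float(hi))


def calibrate(lab_age, lab_sigma, curve: CalCurve, grid_step=1.0,
              depth=np.nan, label="") -> CalibratedDate:
    """Calibrate one 14C lab age.

    Raises :class:`CoverageError` when the curve's 14C range does not span
    ``lab_age ± 10 lab_sigma`` or when non-negligible posterior mass sits on
    a grid boundary.
    """
    if not lab_sigma > 0:
        raise ValidationError("lab_sigma must be > 0")
    c14_lo = float(np.min(curve.c14_age))
    c14_hi = float(np.max(curve.c14_age))
    pad = 10.0 * max(lab_sigma, _DEGENERATE_SIGMA * 0)
    if lab_age - pad < c14_lo or lab_age + pad > c14_hi:
        raise CoverageError(
            f"curve 14C range [{c14_lo:g}, {c14_hi:g}] does not span "
            f"{lab_age:g} ± 10·{lab_sigma:g}"
        )
    lo, hi = curve.cal_span
    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    mu = curve.c14_at(grid)
    var = lab_sigma ** 2 + curve.sigma_at(grid) ** 2
    logw = -0.5 * (lab_age - mu) ** 2 / var - 0.5 * np.log(var)
    w = np.exp(logw - np.max(logw))   # log-sum-exp keeps near-degenerate dates finite
    w /= w.sum()
    if w.size > 1 and (w[0] > 1e-6 or w[-1] > 1e-6):
        raise CoverageError("posterior support truncated by the curve's cal-age span")
    keep = np.flatnonzero(w > _MASS_TRIM)
    grid, w = grid[keep[0]:keep[-1] + 1], w[keep[0]:keep[-1] + 1]
    w /= w.sum()
    med, iv = _summaries(grid, w)
    return CalibratedDate(float(depth), grid, w, med, iv, "c14", label)


def gaussian_date(mean, sigma, depth=np.nan, kind="pb210", grid_step=1.0,
                  label="") -> CalibratedDate:
    """A calendar-scale Gaussian (or exact, if sigma ~ 0) point date."""
    if sigma < 0:
        raise ValidationError("sigma must be >= 0")
    if sigma < _DEGENERATE_SIGMA:
        g = np.array([float(mean)])
        return CalibratedDate(float(depth), g, np.array([1.0]), float(mean),
                              (float(mean), float(mean)), kind, label)
    half = 8.0 * sigma
    grid = np.arange(mean - half, mean + half + grid_step / 2, grid_step)
    w = np.exp(-0.5 * ((grid - mean) / sigma) ** 2)
    w /= w.sum()
    med, iv = _summaries(grid, w)
    return CalibratedDate(float(depth), grid, w, med, iv, kind, label)


def summarize_dates(table: DateTable, curve: CalCurve,
                    grid_step=1.0) -> list[CalibratedDate]:
    """Calibrate every 14C entry of a date table; pass other kinds through
    as Gaussian point dates on the calendar scale. Order is preserved."""
    out = []
    for e in table.entries:
        if e.kind == "c14":
            out.append(calibrate(e.age_value, e.age_sigma, curve, grid_step,
                                 depth=e.depth, label=e.label))
        else:
            out.append(gaussian_date(e.age_value, e.age_sigma, depth=e.depth,
                                     kind=e.kind, grid_step=grid_step,
                                     label=e.label))
    log.info("summarize_dates: %d entries -> %d calibrated dates",
             len(table), len(out))
    return out
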