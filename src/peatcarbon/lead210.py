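"""Constant-rate-of-supply (CRS) 210Pb dating of the upper core.

The CRS model assumes a constant atmospheric flux of unsupported 210Pb to the
peat surface. With ``A(z)`` the unsupported inventory (Bq m^-2) below depth
``z`` and ``A(0)`` the whole-profile inventory, the age of depth ``z`` is

    age(z) = (1/lambda) * ln( A(0) / A(z) ),        lambda = ln 2 / 22.3 yr

relative to the coring year. Supported (226Ra-equilibrium) activity is taken
as the mean of the deepest measurements, where the unsupported component has
decayed away. Age uncertainties follow by first-order propagation of the
per-sample activity sigmas through the two log-inventories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .dataio import ActivityTable, CoreTable, LAMBDA_PB210
from .errors import ValidationError

log = logging.getLogger(__name__)


def estimate_supported(activity: ActivityTable, tail_n: int):
    """Supported activity as the mean of the deepest ``tail_n`` totals.

    Returns ``(mean, standard_error)`` in Bq kg^-1.
    """
    if tail_n < 2:
        raise ValidationError("tail_n must be >= 2")
    if len(activity) < tail_n:
        raise ValidationError(
            f"activity table has {len(activity)} rows < tail_n = {tail_n}")
    tail = activity.total_activity[-tail_n:]
    se = float(np.std(tail, ddof=1) / np.sqrt(tail_n))
    return float(np.mean(tail)), se


@dataclass
class CrsResult:
    """CRS ages at increment boundaries, in years before the coring date."""

    depths: np.ndarray        # boundaries (cm), depths[0] = top of profile
    ages: np.ndarray          # yr before coring; ages[0] = 0
    sigmas: np.ndarray        # yr
    supported: float          # Bq kg^-1
    inventory_total: float    # Bq m^-2
    flux: float               # Bq m^-2 yr^-1 (= lambda * inventory_total)
    lam: float                # yr^-1
    n_dropped: int            # boundaries below the dateable horizon
    _ln_inventory: np.ndarray = None  # ln A at retained boundaries

    def age_at(self, depth):
        """Mid-increment age by linear interpolation of ln A(z)."""
        ln_a = np.interp(depth, self.depths, self._ln_inventory)
        return (self._ln_inventory[0] - ln_a) / self.lam

    def to_dataframe(self, coring_year=None):
        import pandas as pd
        df = pd.DataFrame({"depth_cm": self.depths, "age_yr_before_coring": self.ages,
                           "age_sigma_yr": self.sigmas})
        if coring_year is not None:
            df["age_CE"] = coring_year - df["age_yr_before_coring"]
            df["age_cal_BP"] = 1950 - df["age_CE"]
        return df


def crs_ages(activity: ActivityTable, core: CoreTable, supported,
             lam=LAMBDA_PB210) -> CrsResult:
    """Apply the CRS model to an activity profile.

    The core table supplies dry bulk density for the mass conversion
    (Bq kg^-1 -> Bq m^-2: ``activity * bulk_density * thickness * 10``).
    Boundaries whose remaining inventory is not positive lie below the
    dateable horizon and are dropped with a log notice.
    """
    tops = activity.depth_top
    bottoms = activity.depth_bottom
    mids = 0.5 * (tops + bottoms)
    c_tops = core.depth_top
    c_bottoms = core.depth_bottom
    idx = np.searchsorted(c_bottoms, mids, side="right")
    if np.any(idx >= len(core)) or np.any(mids < c_tops[0]):
        raise ValidationError("core table does not cover the activity depths")
    rho = core.bulk_density[idx]

    h = bottoms - tops
    unsup = activity.total_activity - supported
    n_neg = int(np.sum(unsup < 0))
    if n_neg:
        log.info("crs_ages: %d sample(s) at/below supported level clipped to zero",
                 n_neg)
    unsup = np.clip(unsup, 0.0, None)
    inv = unsup * rho * h * 10.0          # Bq m^-2 per increment
    sig_inv = activity.activity_sigma * rho * h * 10.0
    a0 = float(np.sum(inv))
    if a0 <= 0:
        raise ValidationError("no unsupported 210Pb inventory above the supported level")

    below = a0 - np.cumsum(inv)           # A at each increment bottom
    bounds = np.append(tops[0], bottoms)
    a_bound = np.append(a0, below)
    dateable = a_bound > 0
    n_dropped = int(np.sum(~dateable))
    if n_dropped:
        log.info("crs_ages: %d boundary(ies) below the dateable horizon dropped",
                 n_dropped)
    depths = bounds[dateable]
    a_keep = a_bound[dateable]
    ages = np.log(a0 / a_keep) / lam

    # first-order propagation: d age_k / d I_j = (1/lam) (1/A0 - [j below k]/A_k)
    k_idx = np.flatnonzero(dateable)      # boundary index = # increments above it
    var = np.empty(depths.size)
    for m, k in enumerate(k_idx):
        d = (1.0 / a0) - (np.arange(inv.size) >= k) / a_keep[m]
        var[m] = np.sum((d * sig_inv) ** 2) / lam ** 2
    sigmas = np.sqrt(var)

    return CrsResult(depths=depths, ages=ages, sigmas=sigmas,
                     supported=float(supported), inventory_total=a0,
                     flux=lam * a0, lam=lam, n_dropped=n_dropped,
                     _ln_inventory=np.log(a_keep))
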