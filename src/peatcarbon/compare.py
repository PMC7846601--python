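"""Peat-versus-tree carbon comparisons on a common timescale.

Whole-profile peat stocks integrate millennia of accumulation, whereas the
even-aged post-fire tree cohort is at most two centuries old; the comparison
is therefore made twice: on totals and on the post-fire window only (peat
above the last charcoal layer versus the same tree stocks, since the stand
established immediately after the fire).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .carbon import SiteCarbonSummary
from .trees import StandStocks

log = logging.getLogger(__name__)


def round_half_away(x, ndigits=1):
    """Round half away from zero (the convention used in printed reports,
    as opposed to banker's rounding). Works on the decimal repr so that
    e.g. 5.65 -> 5.7 despite binary representation."""
    from decimal import Decimal, ROUND_HALF_UP
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class SiteComparison:
    site_id: str
    peat_total: float          # kg C m^-2
    peat_postfire: float       # kg C m^-2
    tree_c: float              # kg C m^-2 (AGB + central BGB, as carbon)
    ecosystem_total: float     # peat_total + tree_c
    ratio_total: float         # peat_total / tree_c
    ratio_postfire: float      # peat_postfire / tree_c (same tree stock)
    agb_multiplier: float      # factor by which AGB carbon must grow to match peat

    def to_dict(self):
        return {
            "site_id": self.site_id, "peat_total": self.peat_total,
            "peat_postfire": self.peat_postfire, "tree_c": self.tree_c,
            "ecosystem_total": self.ecosystem_total,
            "ratio_total": self.ratio_total,
            "ratio_postfire": self.ratio_postfire,
            "agb_multiplier": self.agb_multiplier,
        }


def compare_site(summary: SiteCarbonSummary, stand: StandStocks,
                 carbon_fraction_wood=0.5) -> SiteComparison:
    """Headline comparison for one site.

    The post-fire ratio uses the same tree carbon as the total ratio (the
    trees postdate the fire). With zero tree carbon the ratios are undefined
    and flagged as NaN.
    """
    peat_total = summary.total_stock
    peat_postfire = summary.postfire_stock
    tree_c = stand.tree_c
    if tree_c > 0:
        ratio_total = peat_total / tree_c
        ratio_postfire = peat_postfire / tree_c
    else:
        log.warning("compare_site[%s]: zero tree carbon; ratios undefined",
                    summary.site_id)
        ratio_total = ratio_postfire = float("nan")
    agb_c = carbon_fraction_wood * stand.agb_per_m2
    mult = peat_total / agb_c if agb_c > 0 else float("nan")
    return SiteComparison(summary.site_id, peat_total, peat_postfire, tree_c,
                          peat_total + tree_c, ratio_total, ratio_postfire,
                          mult)


def summary_report(comparisons: list[SiteComparison]):
    """Cross-site table plus a plain-text summary.

    Returns ``(DataFrame, text)``. Means are site-order invariant; the text
    prints to one decimal (half away from zero) while the table keeps raw
    values.
    """
    if not comparisons:
        raise ValueError("need at least one site")
    df = pd.DataFrame([c.to_dict() for c in comparisons])
    means = df[["peat_total", "peat_postfire", "tree_c", "ecosystem_total"]].mean()
    r1 = lambda v: round_half_away(float(v), 1)
    lines = ["Peat vs tree carbon stocks (kg C m-2)", ""]
    lines.append(f"{'site':<10}{'peat':>8}{'post-fire':>11}{'trees':>8}"
                 f"{'ecosystem':>11}{'ratio':>8}")
    for c in comparisons:
        lines.append(f"{c.site_id:<10}{r1(c.peat_total):>8}"
                     f"{r1(c.peat_postfire):>11}{r1(c.tree_c):>8}"
                     f"{r1(c.ecosystem_total):>11}{r1(c.ratio_total):>8}")
    lines.append("")
    lines.append(f"mean post-fire peat C: {r1(means['peat_postfire'])} kg m-2; "
                 f"mean tree C: {r1(means['tree_c'])} kg m-2")
    lines.append("Note: recent (post-fire) peat has undergone less decomposition "
                 "than older peat; recent and long-term rates are not comparable.")
    return df, "\n".join(lines)
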