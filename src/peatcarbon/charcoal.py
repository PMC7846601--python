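"""Charcoal-stratigraphy fire layers and the post-fire boundary.

Macroscopic charcoal counts (> 0.5 mm fragments per cm^3, counted at 1 cm
intervals) mark local fire events. A fire layer is a maximal run of
increments at or above a count threshold; runs separated by less than a
minimum gap are merged. The post-fire core section is everything above the
TOP of the shallowest (most recent) layer, i.e. the half-open interval
``[0, last_fire_depth)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .agedepth import ChronologyEnsemble
from .dataio import CoreTable
from .errors import OutOfSpanError, ValidationError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FireLayer:
    depth_top: float
    depth_bottom: float
    peak_count: int


@dataclass
class FireRecord:
    layers: list[FireLayer]
    last_fire_depth: float | None = None     # cm, top of the shallowest layer
    last_fire_age: float | None = None       # cal yr BP, ensemble median
    last_fire_interval: tuple[float, float] | None = None

    def __post_init__(self):
        if self.layers and self.last_fire_depth is None:
            self.last_fire_depth = min(l.depth_top for l in self.layers)

    def to_dataframe(self):
        df = pd.DataFrame([(l.depth_top, l.depth_bottom, l.peak_count)
                           for l in self.layers],
                          columns=["layer_top", "layer_bottom", "peak_count"])
        df["median_age"] = np.nan
        df["lo95"] = np.nan
        df["hi95"] = np.nan
        if self.layers and self.last_fire_age is not None:
            i = int(np.argmin([l.depth_top for l in self.layers]))
            df.loc[i, ["median_age", "lo95", "hi95"]] = (
                self.last_fire_age, *self.last_fire_interval)
        return df


def detect_layers(core: CoreTable, threshold=1.0, min_gap_cm=2.0) -> FireRecord:
    """Find charcoal layers: runs of increments with count >= threshold,
    merging runs separated by gaps smaller than ``min_gap_cm``."""
    if threshold < 1:
        raise ValidationError("threshold must be >= 1 fragment cm^-3")
    counts = core.charcoal_count
    hot = counts >= threshold
    runs = []
    i = 0
    while i < len(counts):
        if hot[i]:
            j = i
            while j + 1 < len(counts) and hot[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    tops = core.depth_top
    bottoms = core.depth_bottom
    merged = []
    for run in runs:
        if merged and tops[run[0]] - bottoms[merged[-1][1]] < min_gap_cm:
            merged[-1] = (merged[-1][0], run[1])
        else:
            merged.append(run)
    layers = [FireLayer(float(tops[a]), float(bottoms[b]),
                        int(np.max(counts[a:b + 1]))) for a, b in merged]
    log.info("detect_layers: %d layer(s) at threshold %g", len(layers), threshold)
    return FireRecord(layers)


def date_last_fire(rec: FireRecord, ens: ChronologyEnsemble) -> FireRecord:
    """Attach the chronology's median age (and 95 % interval) at the top of
    the shallowest layer. An empty record is returned unchanged."""
    if not rec.layers:
        log.warning("date_last_fire: no fire layers to date")
        return rec
    d = rec.last_fire_depth
    if d > ens.depths[-1] + 1e-9 or d < ens.depths[0] - 1e-9:
        raise OutOfSpanError(f"chronology does not cover fire depth {d:g} cm")
    med, iv = ens.age_at_depth(d)
    return replace(rec, last_fire_age=med, last_fire_interval=iv)
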