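"""Readers, writers and core data containers.

All external formats consumed or produced by the pipeline are decided here:
per-centimetre core tables, dated-horizon tables, lead-210 activity profiles,
plot censuses and site configuration as UTF-8 CSV/YAML; ring widths as Tucson
``.rwl`` decadal text; calibration curves as IntCal-style (comma- or
whitespace-separated) text.

Conventions
-----------
* Depths are in cm, positive downward, surface = 0; every per-increment table
  uses contiguous half-open intervals ``[depth_top, depth_bottom)``.
* Calendar ages are in cal yr BP with BP = 1950 CE, so a coring year of
  2017 CE maps to −67 cal yr BP (``ce_to_bp``).
* Ring widths are stored in mm; Tucson files hold integers in 0.01 mm with
  either a ``999`` or ``-9999`` series terminator.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .errors import ParseError, ValidationError

log = logging.getLogger(__name__)

VALID_DATE_KINDS = ("c14", "pb210", "surface", "event")

#: 210Pb decay constant, yr^-1 (half-life 22.3 yr).
LAMBDA_PB210 = math.log(2.0) / 22.3


def ce_to_bp(year_ce):
    """Convert a CE calendar year to cal yr BP (BP = 1950 CE).

    >>> ce_to_bp(2017)
    -67
    """
    return 1950 - year_ce


def bp_to_ce(age_bp):
    """Convert cal yr BP to a CE calendar year."""
    return 1950 - age_bp


# ---------------------------------------------------------------------------
# Core table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Increment:
    """One contiguous depth slice of a peat core."""

    depth_top: float      # cm
    depth_bottom: float   # cm
    bulk_density: float   # g cm^-3 dry
    om_fraction: float    # unitless, 0..1 (loss-on-ignition organic fraction)
    charcoal_count: int   # macroscopic fragments cm^-3


def _check_contiguous(tops, bottoms, what):
    tops = np.asarray(tops, dtype=float)
    bottoms = np.asarray(bottoms, dtype=float)
    if np.any(bottoms <= tops):
        raise ValidationError(f"{what}: depth_bottom must exceed depth_top in every row")
    gaps = tops[1:] - bottoms[:-1]
    if np.any(np.abs(gaps) > 1e-9):
        i = int(np.argmax(np.abs(gaps) > 1e-9))
        raise ValidationError(
            f"{what}: increments must be contiguous; gap/overlap of "
            f"{gaps[i]:g} cm between rows {i} and {i + 1}"
        )


@dataclass
class CoreTable:
    """Per-increment physical and charcoal measurements of one peat core."""

    site_id: str
    increments: list[Increment]

    def __post_init__(self):
        if not self.increments:
            raise ValidationError("CoreTable needs at least one increment")
        _check_contiguous(
            [i.depth_top for i in self.increments],
            [i.depth_bottom for i in self.increments],
            f"CoreTable[{self.site_id}]",
        )
        for k, inc in enumerate(self.increments):
            if inc.bulk_density <= 0:
                raise ValidationError(f"row {k}: bulk_density must be > 0")
            if not 0.0 <= inc.om_fraction <= 1.0:
                raise ValidationError(f"row {k}: om_fraction must be within [0, 1]")
            if inc.charcoal_count < 0:
                raise ValidationError(f"row {k}: charcoal_count must be >= 0")

    def __len__(self):
        return len(self.increments)

    @property
    def depth_top(self):
        return np.array([i.depth_top for i in self.increments])

    @property
    def depth_bottom(self):
        return np.array([i.depth_bottom for i in self.increments])

    @property
    def thickness(self):
        return self.depth_bottom - self.depth_top

    @property
    def bulk_density(self):
        return np.array([i.bulk_density for i in self.increments])

    @property
    def om_fraction(self):
        return np.array([i.om_fraction for i in self.increments])

    @property
    def charcoal_count(self):
        return np.array([i.charcoal_count for i in self.increments])

    @property
    def boundaries(self):
        """Depth boundaries, length ``len(core) + 1`` (tops plus final bottom)."""
        return np.append(self.depth_top, self.depth_bottom[-1])

    @property
    def total_depth(self):
        return float(self.depth_bottom[-1] - self.depth_top[0])

    def to_dataframe(self):
        return pd.DataFrame(
            {
                "depth_top": self.depth_top,
                "depth_bottom": self.depth_bottom,
                "bulk_density": self.bulk_density,
                "om_fraction": self.om_fraction,
                "charcoal_count": self.charcoal_count,
            }
        )


def read_core_csv(path, site_id=None) -> CoreTable:
    """Read a per-increment core CSV.

    The file must have columns ``depth_top, depth_bottom, bulk_density,
    charcoal_count`` and exactly one of ``om_fraction`` or ``om_density``
    (the latter in g cm^-3, converted via the bulk density).
    """
    df = pd.read_csv(path)
    required = {"depth_top", "depth_bottom", "bulk_density", "charcoal_count"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    has_frac = "om_fraction" in df.columns
    has_dens = "om_density" in df.columns
    if has_frac == has_dens:
        raise ParseError(f"{path}: exactly one of om_fraction/om_density must be present")
    cols = list(required) + (["om_fraction"] if has_frac else ["om_density"])
    for col in cols:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna() | df[col].isna()
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header is line 1
            raise ParseError(f"{path}: malformed value in column '{col}' at line {line}")
        df[col] = pd.to_numeric(df[col])
    if has_dens:
        df["om_fraction"] = df["om_density"] / df["bulk_density"]
    incs = [
        Increment(r.depth_top, r.depth_bottom, r.bulk_density, r.om_fraction,
                  int(r.charcoal_count))
        for r in df.itertuples()
    ]
    core = CoreTable(site_id or str(path), incs)
    log.info("read_core_csv: %s -> %d increments", path, len(core))
    return core


def write_core_csv(core: CoreTable, path):
    core.to_dataframe().to_csv(path, index=False)


def merge_increments(core: CoreTable, n: int) -> CoreTable:
    """Re-bin a core by merging runs of ``n`` adjacent increments.

    Bulk density is thickness-weighted, the organic fraction mass-weighted and
    charcoal thickness-averaged, so organic-matter (and hence carbon) mass per
    unit area is conserved exactly. A shorter final bin keeps the remainder.
    """
    incs = []
    rows = core.increments
    for start in range(0, len(rows), n):
        chunk = rows[start:start + n]
        h = np.array([c.depth_bottom - c.depth_top for c in chunk])
        rho = np.array([c.bulk_density for c in chunk])
        om = np.array([c.om_fraction for c in chunk])
        cc = np.array([c.charcoal_count for c in chunk])
        bulk = float(np.sum(rho * h) / np.sum(h))
        frac = float(np.sum(rho * om * h) / np.sum(rho * h))
        incs.append(Increment(chunk[0].depth_top, chunk[-1].depth_bottom, bulk,
                              frac, int(round(float(np.sum(cc * h) / np.sum(h))))))
    return CoreTable(core.site_id, incs)


# ---------------------------------------------------------------------------
# Dated horizons
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DateEntry:
    """One dated horizon.

    ``age_value`` is a 14C yr BP lab age for ``kind='c14'`` and a cal yr BP
    age for every other kind.
    """

    depth: float
    kind: str
    age_value: float
    age_sigma: float
    label: str = ""


@dataclass
class DateTable:
    entries: list[DateEntry]

    def __post_init__(self):
        n_surface = 0
        for k, e in enumerate(self.entries):
            if e.kind not in VALID_DATE_KINDS:
                raise ValidationError(f"entry {k}: unknown kind '{e.kind}'")
            if e.kind in ("c14", "pb210") and not e.age_sigma > 0:
                raise ValidationError(f"entry {k}: sigma must be > 0 for kind '{e.kind}'")
            n_surface += e.kind == "surface"
        if n_surface > 1:
            raise ValidationError("at most one surface entry per core")

    def __len__(self):
        return len(self.entries)

    def of_kind(self, kind):
        return [e for e in self.entries if e.kind == kind]

    def to_dataframe(self):
        return pd.DataFrame([asdict(e) for e in self.entries])


def read_dates_csv(path) -> DateTable:
    df = pd.read_csv(path)
    required = {"depth", "kind", "age_value", "age_sigma"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    if "label" not in df.columns:
        df["label"] = ""
    entries = [
        DateEntry(float(r.depth), str(r.kind), float(r.age_value),
                  float(r.age_sigma), "" if pd.isna(r.label) else str(r.label))
        for r in df.itertuples()
    ]
    table = DateTable(entries)
    log.info("read_dates_csv: %s -> %d entries", path, len(table))
    return table


def write_dates_csv(table: DateTable, path):
    table.to_dataframe().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Calibration curve
# ---------------------------------------------------------------------------

@dataclass
class CalCurve:
    """Radiocarbon calibration curve on a strictly monotone cal-age grid."""

    cal_age: np.ndarray     # cal yr BP
    c14_age: np.ndarray     # 14C yr BP
    curve_sigma: np.ndarray  # yr

    def __post_init__(self):
        self.cal_age = np.asarray(self.cal_age, dtype=float)
        self.c14_age = np.asarray(self.c14_age, dtype=float)
        self.curve_sigma = np.asarray(self.curve_sigma, dtype=float)
        if self.cal_age.size < 2:
            raise ValidationError("calibration curve needs at least two points")
        d = np.diff(self.cal_age)
        if np.all(d < 0):
            log.info("CalCurve: input in descending cal-age order; sorted ascending")
            self.cal_age = self.cal_age[::-1]
            self.c14_age = self.c14_age[::-1]
            self.curve_sigma = self.curve_sigma[::-1]
            d = -d
        if np.any(d <= 0):
            raise ValidationError("cal ages must be strictly monotone")
        if np.any(self.curve_sigma < 0):
            raise ValidationError("curve sigma must be >= 0")

    def __len__(self):
        return int(self.cal_age.size)

    def c14_at(self, cal):
        """Curve mean mu(theta) by linear interpolation."""
        return np.interp(cal, self.cal_age, self.c14_age)

    def sigma_at(self, cal):
        return np.interp(cal, self.cal_age, self.curve_sigma)

    @property
    def cal_span(self):
        return float(self.cal_age[0]), float(self.cal_age[-1])


def read_calcurve(path) -> CalCurve:
    """Read an IntCal-style curve: comment lines (#, %) skipped, first three
    columns interpreted as cal age, 14C age, sigma; commas or whitespace."""
    cal, c14, sig = [], [], []
    n_data = 0
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith(("#", "%")):
                continue
            parts = s.replace(",", " ").split()
            if len(parts) < 3:
                raise ParseError(f"{path}: line {ln}: expected >= 3 columns")
            try:
                vals = [float(p) for p in parts[:3]]
            except ValueError as exc:
                raise ParseError(f"{path}: line {ln}: {exc}") from None
            cal.append(vals[0])
            c14.append(vals[1])
            sig.append(vals[2])
            n_data += 1
    curve = CalCurve(np.array(cal), np.array(c14), np.array(sig))
    log.info("read_calcurve: %s -> %d rows", path, n_data)
    return curve


def write_calcurve(curve: CalCurve, path):
    with open(path, "w") as fh:
        fh.write("# cal_age_BP, c14_age_BP, sigma\n")
        for a, c, s in zip(curve.cal_age, curve.c14_age, curve.curve_sigma):
            fh.write(f"{a:.1f},{c:.2f},{s:.2f}\n")


# ---------------------------------------------------------------------------
# 210Pb activity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ActivityRow:
    depth_top: float        # cm
    depth_bottom: float     # cm
    total_activity: float   # Bq kg^-1 dry mass
    activity_sigma: float   # Bq kg^-1


@dataclass
class ActivityTable:
    rows: list[ActivityRow]

    def __post_init__(self):
        if not self.rows:
            raise ValidationError("ActivityTable needs at least one row")
        _check_contiguous(
            [r.depth_top for r in self.rows],
            [r.depth_bottom for r in self.rows],
            "ActivityTable",
        )
        for k, r in enumerate(self.rows):
            if r.total_activity < 0:
                raise ValidationError(f"row {k}: total_activity must be >= 0")
            if r.activity_sigma < 0:
                raise ValidationError(f"row {k}: activity_sigma must be >= 0")

    def __len__(self):
        return len(self.rows)

    @property
    def depth_top(self):
        return np.array([r.depth_top for r in self.rows])

    @property
    def depth_bottom(self):
        return np.array([r.depth_bottom for r in self.rows])

    @property
    def total_activity(self):
        return np.array([r.total_activity for r in self.rows])

    @property
    def activity_sigma(self):
        return np.array([r.activity_sigma for r in self.rows])

    def to_dataframe(self):
        return pd.DataFrame([asdict(r) for r in self.rows])


def read_activity_csv(path) -> ActivityTable:
    df = pd.read_csv(path)
    required = {"depth_top", "depth_bottom", "total_activity", "activity_sigma"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    rows = [
        ActivityRow(float(r.depth_top), float(r.depth_bottom),
                    float(r.total_activity), float(r.activity_sigma))
        for r in df.itertuples()
    ]
    table = ActivityTable(rows)
    log.info("read_activity_csv: %s -> %d rows", path, len(table))
    return table


def write_activity_csv(table: ActivityTable, path):
    table.to_dataframe().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Tree-ring series (Tucson .rwl)
# ---------------------------------------------------------------------------

@dataclass
class RingSeries:
    tree_id: str
    first_year: int          # CE year of the first ring
    widths_mm: np.ndarray    # one value per year, contiguous
    radius_count: int = 1

    def __post_init__(self):
        self.widths_mm = np.asarray(self.widths_mm, dtype=float)
        if np.any(self.widths_mm < 0):
            raise ValidationError(f"{self.tree_id}: ring widths must be >= 0")

    @property
    def years(self):
        return np.arange(self.first_year, self.first_year + self.widths_mm.size)


@dataclass
class RingSeriesSet:
    series: dict[str, RingSeries]

    def __len__(self):
        return len(self.series)


_RWL_TERMINATORS = (999, -9999)


def read_rwl(path, combine_radii=False) -> RingSeriesSet:
    """Parse a Tucson-format ring-width file.

    Values are integers in 0.01 mm; a series ends at a ``999`` or ``-9999``
    terminator (both dialects accepted). When ``combine_radii`` is true,
    series whose ids differ only in a trailing letter (e.g. ``T01A``/``T01B``)
    are averaged per calendar year into one per-tree series.
    """
    open_series: dict[str, dict] = {}
    done: dict[str, RingSeries] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            tokens = line.split()
            if len(tokens) < 2:
                raise ParseError(f"{path}: line {ln}: expected id, year and values")
            sid = tokens[0]
            if sid in done:
                raise ParseError(f"{path}: line {ln}: data after terminator of '{sid}'")
            try:
                year = int(tokens[1])
                vals = [int(t) for t in tokens[2:]]
            except ValueError as exc:
                raise ParseError(f"{path}: line {ln}: {exc}") from None
            state = open_series.get(sid)
            if state is None:
                state = {"first": year, "widths": [], "next": year}
                open_series[sid] = state
            elif year != state["next"]:
                raise ParseError(
                    f"{path}: line {ln}: series '{sid}' expected decade year "
                    f"{state['next']}, found {year}"
                )
            terminated = False
            for v in vals:
                if v in _RWL_TERMINATORS:
                    terminated = True
                    break
                state["widths"].append(v / 100.0)
            state["next"] = year + len(vals) if not terminated else state["next"]
            if terminated:
                done[sid] = RingSeries(sid, state["first"], np.array(state["widths"]))
                del open_series[sid]
    for sid, state in open_series.items():  # unterminated series kept, with a notice
        log.warning("read_rwl: series '%s' has no terminator", sid)
        done[sid] = RingSeries(sid, state["first"], np.array(state["widths"]))
    log.info("read_rwl: %s -> %d series", path, len(done))
    rset = RingSeriesSet(done)
    if combine_radii:
        rset = combine_radii_by_prefix(rset)
    return rset


def combine_radii_by_prefix(rset: RingSeriesSet) -> RingSeriesSet:
    """Average series sharing an id prefix (id minus trailing letter)."""
    groups: dict[str, list[RingSeries]] = {}
    for sid, rs in rset.series.items():
        prefix = sid[:-1] if len(sid) > 1 and sid[-1].isalpha() else sid
        groups.setdefault(prefix, []).append(rs)
    out = {}
    for prefix, members in groups.items():
        if len(members) == 1:
            rs = members[0]
            out[prefix] = RingSeries(prefix, rs.first_year, rs.widths_mm, 1)
            continue
        first = min(m.first_year for m in members)
        last = max(m.first_year + m.widths_mm.size for m in members)
        acc = np.zeros(last - first)
        cnt = np.zeros(last - first)
        for m in members:
            i0 = m.first_year - first
            acc[i0:i0 + m.widths_mm.size] += m.widths_mm
            cnt[i0:i0 + m.widths_mm.size] += 1
        out[prefix] = RingSeries(prefix, first, acc / np.maximum(cnt, 1), len(members))
    return RingSeriesSet(out)


def write_rwl(rset: RingSeriesSet, path):
    """Write a Tucson file (0.01 mm units, 999 terminator)."""
    with open(path, "w") as fh:
        for sid in sorted(rset.series):
            rs = rset.series[sid]
            vals = [int(round(w * 100)) for w in rs.widths_mm] + [999]
            year = rs.first_year
            i = 0
            while i < len(vals):
                decade_end = (year // 10) * 10 + 10
                n = min(decade_end - year, len(vals) - i)
                row = vals[i:i + n]
                fh.write(f"{sid:<8}{year:>4}" + "".join(f"{v:>6d}" for v in row) + "\n")
                year += n
                i += n


# ---------------------------------------------------------------------------
# Plot census
# ---------------------------------------------------------------------------

@dataclass
class PlotCensus:
    site_id: str
    plot_area_m2: float
    trees: list[tuple[str, float]]   # (tree_id, dbh in cm)

    def __post_init__(self):
        if self.plot_area_m2 <= 0:
            raise ValidationError("plot_area must be > 0")

    def __len__(self):
        return len(self.trees)

    @property
    def dbh(self):
        return np.array([d for _, d in self.trees])

    def to_dataframe(self):
        return pd.DataFrame(self.trees, columns=["tree_id", "dbh_cm"])


def read_census_csv(path, site_id="site", plot_area_m2=100.0) -> PlotCensus:
    df = pd.read_csv(path)
    if not {"tree_id", "dbh_cm"} <= set(df.columns):
        raise ParseError(f"{path}: need columns tree_id, dbh_cm")
    if "plot_area_m2" in df.columns:
        plot_area_m2 = float(df["plot_area_m2"].iloc[0])
    trees = [(str(r.tree_id), float(r.dbh_cm)) for r in df.itertuples()]
    log.info("read_census_csv: %s -> %d trees", path, len(trees))
    return PlotCensus(site_id, plot_area_m2, trees)


def write_census_csv(census: PlotCensus, path):
    df = census.to_dataframe()
    df["plot_area_m2"] = census.plot_area_m2
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Site configuration
# ---------------------------------------------------------------------------

@dataclass
class SiteConfig:
    """Run configuration shared by all pipeline stages.

    Carbon fractions default to 0.5 for both peat organic matter and tree
    biomass; the 210Pb decay constant to ln 2 / 22.3 yr. ``allometry`` is an
    optional raw mapping handed to :func:`peatcarbon.trees.build_allometry`.
    """

    site_id: str = "site"
    coring_year: int = 2017
    lambda_pb210: float = LAMBDA_PB210
    charcoal_threshold: float = 1.0
    charcoal_min_gap_cm: float = 2.0
    carbon_fraction_peat: float = 0.5
    carbon_fraction_wood: float = 0.5
    mc_iterations: int = 2000
    rng_seed: int = 1
    grid_step_yr: float = 1.0
    supported_tail_n: int = 4
    pb_model_depth_max_cm: float = 20.0
    pb_horizon_step_cm: float = 5.0
    plot_area_m2: float = 100.0
    combine_radii: bool = False
    allometry: dict | None = None

    def __post_init__(self):
        if self.coring_year <= 1900:
            raise ValidationError("coring_year must be > 1900")
        for name in ("carbon_fraction_peat", "carbon_fraction_wood"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValidationError(f"{name} must lie in (0, 1)")

    @property
    def surface_age_bp(self):
        return float(ce_to_bp(self.coring_year))

    @classmethod
    def from_yaml(cls, path) -> "SiteConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
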