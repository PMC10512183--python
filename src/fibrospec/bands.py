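"""Band regions, integrated areas, ratio panels, and second-derivative peaks.

The band table holds the 14 standard assignment regions for cultured-cell
absorbance spectra (amide bands, C-H stretches, carbonyl ester, acyl chain,
and the mixed carbohydrate/phosphate region).  Areas are trapezoids over the
axis points inside a closed region; ratios divide two areas on the same
sample and are therefore invariant to any global rescaling of the spectrum
(vector normalization included).  Peak analysis locates local minima of the
second-derivative trace, whose positions mark band centers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .spectra import (
    ABSORBANCE,
    CohortTable,
    EmptyRegionError,
    SampleRecord,
    SpectraError,
    Spectrum,
)

__all__ = [
    "BandRegion",
    "RatioDefinition",
    "RatioPanelResult",
    "PeakReport",
    "default_band_table",
    "default_ratio_panel",
    "integrate_band",
    "compute_ratio_panel",
    "locate_band_minima",
    "compare_peak_positions",
]


@dataclass(frozen=True)
class BandRegion:
    """A named closed wavenumber interval [lo, hi] cm^-1."""

    name: str
    lo: float
    hi: float
    category: str = "mixed"  # protein | lipid | mixed

    def __post_init__(self):
        if self.lo >= self.hi:
            raise SpectraError(f"region {self.name}: need lo < hi")
        if self.category not in ("protein", "lipid", "mixed"):
            raise SpectraError(f"region {self.name}: unknown category {self.category!r}")


@dataclass(frozen=True)
class RatioDefinition:
    name: str
    numerator: BandRegion
    denominator: BandRegion


def default_band_table() -> list[BandRegion]:
    """The 14 standard assignment regions (cm^-1)."""
    return [
        BandRegion("Amide A", 3260, 3315, "protein"),
        BandRegion("Amide B", 3000, 3120, "protein"),
        BandRegion("Amide I", 1580, 1700, "protein"),
        BandRegion("Amide II", 1480, 1580, "protein"),
        BandRegion("Amide II choline", 1485, 1500, "protein"),
        BandRegion("Amide III", 1185, 1300, "protein"),
        BandRegion("Total lipids", 2800, 3000, "lipid"),
        BandRegion("Asymmetric CH3", 2950, 2972, "lipid"),
        BandRegion("Asymmetric CH2", 2912, 2936, "lipid"),
        BandRegion("Symmetric CH3", 2865, 2880, "lipid"),
        BandRegion("Symmetric CH2", 2843, 2860, "lipid"),
        BandRegion("Carbonyl ester", 1725, 1750, "lipid"),
        BandRegion("Acyl chain", 1430, 1470, "lipid"),
        BandRegion("Mixed region", 1000, 1300, "mixed"),
    ]


def _region(name: str) -> BandRegion:
    for r in default_band_table():
        if r.name == name:
            return r
    raise KeyError(name)


def default_ratio_panel() -> list[RatioDefinition]:
    """The 12-ratio panel: 8 primary area ratios plus 4 lipid-order ratios.

    The lipid-order ratios conventionally quoted by single wavenumbers
    (~2920/2870 membrane polarity, ~2850/2870 chain packing, ~2920/2960
    saturation, ~2920/total-lipids chain length) are implemented as ratios of
    the integrated C-H stretch regions containing those wavenumbers.
    """

    def ratio(num: str, den: str, label: str | None = None) -> RatioDefinition:
        return RatioDefinition(label or f"{num}/{den}", _region(num), _region(den))

    return [
        ratio("Carbonyl ester", "Total lipids"),
        ratio("Carbonyl ester", "Acyl chain"),
        ratio("Carbonyl ester", "Asymmetric CH3"),
        ratio("Amide I", "Amide II"),
        ratio("Amide I", "Amide A"),
        ratio("Amide I", "Total lipids"),
        ratio("Amide I", "Carbonyl ester"),
        ratio("Carbonyl ester", "Mixed region"),
        ratio("Asymmetric CH2", "Symmetric CH3"),   # membrane polarity
        ratio("Symmetric CH2", "Symmetric CH3"),    # lipid chain packing
        ratio("Asymmetric CH2", "Asymmetric CH3"),  # degree of saturation
        ratio("Asymmetric CH2", "Total lipids"),    # phospholipid chain length
    ]


# ---------------------------------------------------------------------------
# integration


def integrate_band(spectrum: Spectrum, region: BandRegion) -> float:
    """Trapezoidal area (AU*cm^-1) under the absorbance spectrum over the
    closed region.  The region must lie within a single retained segment."""
    if spectrum.kind != ABSORBANCE:
        raise SpectraError("band integration is defined on absorbance spectra")
    v = spectrum.axis.values
    idx = np.flatnonzero((v >= region.lo) & (v <= region.hi))
    if idx.size == 0:
        raise EmptyRegionError(f"region {region.name}: no axis points in [{region.lo}, {region.hi}]")
    segs = {spectrum.axis.segment_of(int(i)) for i in (idx[0], idx[-1])}
    if len(segs) > 1 or idx[-1] - idx[0] + 1 != idx.size:
        raise SpectraError(f"region {region.name} bridges the excised gap")
    if idx.size == 1:
        return 0.0
    return float(np.trapezoid(spectrum.intensity[idx], v[idx]))


# ---------------------------------------------------------------------------
# ratio panel


@dataclass
class RatioPanelResult:
    """Per-sample ratio values plus per-group summaries.

    ``values``: DataFrame (sample_id x ratio name); ``group_means`` /
    ``group_sds``: DataFrames (group x ratio name).  A ratio whose
    denominator area is <= 0 is NaN for that sample (flagged, run continues).
    """

    values: pd.DataFrame
    groups: pd.Series
    group_means: pd.DataFrame = field(init=False)
    group_sds: pd.DataFrame = field(init=False)

    def __post_init__(self):
        g = self.values.groupby(self.groups)
        self.group_means = g.mean()
        self.group_sds = g.std(ddof=1)


def compute_ratio_panel(
    cohort: CohortTable, panel: list[RatioDefinition] | None = None
) -> RatioPanelResult:
    """Evaluate every ratio on every sample's mean absorbance spectrum."""
    panel = panel or default_ratio_panel()
    rows = {}
    for rec in cohort:
        vals = {}
        areas: dict[str, float] = {}
        for rd in panel:
            for reg in (rd.numerator, rd.denominator):
                if reg.name not in areas:
                    areas[reg.name] = integrate_band(rec.mean_absorbance, reg)
            den = areas[rd.denominator.name]
            if den <= 0:
                warnings.warn(
                    f"sample {rec.sample_id}, ratio {rd.name}: denominator area <= 0; flagged"
                )
                vals[rd.name] = np.nan
            else:
                vals[rd.name] = areas[rd.numerator.name] / den
        rows[rec.sample_id] = vals
    values = pd.DataFrame.from_dict(rows, orient="index")[[rd.name for rd in panel]]
    groups = pd.Series({r.sample_id: r.group for r in cohort}, name="group")
    return RatioPanelResult(values=values, groups=groups.loc[values.index])


# ---------------------------------------------------------------------------
# second-derivative peaks


@dataclass
class PeakReport:
    """Per-sample second-derivative minima inside one region."""

    region: BandRegion
    positions: dict[str, np.ndarray]  # sample_id -> ascending positions (cm^-1)
    counts: dict[str, int]
    primary: dict[str, float]  # deepest minimum per sample (NaN if none)


def _minima(
    spectrum: Spectrum, region: BandRegion, prominence_frac: float, refine: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Positions and depths of local minima of a trace inside a region.

    A minimum must be strictly lower than both neighbors, have prominence
    above ``prominence_frac`` of the region's dynamic range, and lie below
    zero -- absorption bands produce negative second-derivative lobes, while
    the shallow dips between the positive side-lobes of well-separated bands
    hover at or above zero and are not bands.  With ``refine``,
    positions are interpolated by a parabola through the minimum and its two
    neighbors (sub-grid resolution, standard practice for band positions).
    """
    v = spectrum.axis.values
    idx = np.flatnonzero((v >= region.lo) & (v <= region.hi))
    if idx.size < 3:
        raise EmptyRegionError(f"region {region.name}: needs >= 3 axis points")
    x, y = v[idx], spectrum.intensity[idx]
    dyn = float(y.max() - y.min())
    if dyn == 0.0:
        return np.array([]), np.array([])
    peaks, _ = find_peaks(-y, prominence=prominence_frac * dyn)
    peaks = peaks[y[peaks] < 0]
    positions = []
    for p in peaks:
        pos = x[p]
        if refine and 0 < p < x.size - 1:
            # parabola through (x[p-1..p+1], y[...]); vertex = position
            denom = y[p - 1] - 2 * y[p] + y[p + 1]
            if denom > 0:
                # assumes locally uniform spacing, which holds away from bins'
                # remainder edges; fall back to the grid point otherwise
                h1, h2 = x[p] - x[p - 1], x[p + 1] - x[p]
                if abs(h1 - h2) < 1e-9:
                    pos = x[p] + 0.5 * h1 * (y[p - 1] - y[p + 1]) / denom
        positions.append(pos)
    positions = np.asarray(positions)
    depths = y[peaks]
    order = np.argsort(positions)
    return positions[order], depths[order]


def locate_band_minima(
    record: SampleRecord,
    region: BandRegion,
    prominence_frac: float = 0.05,
    refine: bool = True,
) -> tuple[np.ndarray, int]:
    """Local minima of one sample's second-derivative trace inside a region.

    Returns (ascending positions in cm^-1, count).
    """
    if record.second_derivative is None:
        raise SpectraError(f"record {record.sample_id} has no second derivative")
    pos, _ = _minima(record.second_derivative, region, prominence_frac, refine)
    return pos, int(pos.size)


def peak_report(
    cohort: CohortTable,
    region: BandRegion,
    prominence_frac: float = 0.05,
    refine: bool = True,
) -> PeakReport:
    positions, counts, primary = {}, {}, {}
    for rec in cohort:
        pos, depth = _minima(rec.second_derivative, region, prominence_frac, refine)
        positions[rec.sample_id] = pos
        counts[rec.sample_id] = int(pos.size)
        if pos.size:
            # deepest minimum; ties broken toward lower wavenumber
            best = int(np.lexsort((pos, depth))[0])
            primary[rec.sample_id] = float(pos[best])
        else:
            primary[rec.sample_id] = np.nan
    return PeakReport(region, positions, counts, primary)


def compare_peak_positions(
    cohort: CohortTable,
    region: BandRegion,
    reference_group: str = "CTRL",
    prominence_frac: float = 0.05,
    refine: bool = True,
) -> pd.DataFrame:
    """Group means of the deepest-minimum position, and shifts vs reference.

    Shift convention: positive = shifted toward *higher* wavenumber relative
    to the reference group.  Samples without a minimum are excluded with a
    warning.
    """
    rep = peak_report(cohort, region, prominence_frac, refine)
    rows = []
    group_of = {r.sample_id: r.group for r in cohort}
    by_group: dict[str, list[float]] = {}
    for sid, pos in rep.primary.items():
        if np.isnan(pos):
            warnings.warn(f"sample {sid}: no minimum in {region.name}; excluded")
            continue
        by_group.setdefault(group_of[sid], []).append(pos)
    if reference_group not in by_group:
        raise SpectraError(f"reference group {reference_group!r} has no usable samples")
    ref_mean = float(np.mean(by_group[reference_group]))
    for g, vals in by_group.items():
        rows.append(
            {
                "group": g,
                "n": len(vals),
                "mean_position_cm1": float(np.mean(vals)),
                "shift_vs_reference_cm1": float(np.mean(vals)) - ref_mean,
            }
        )
    return pd.DataFrame(rows).set_index("group")
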