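"""Core domain types for FTIR spectra and their plain-text interchange formats.

The unit of measurement is a *spectrum*: absorbance (or a derivative thereof)
sampled on a wavenumber axis in cm^-1.  A focal-plane-array acquisition yields
a :class:`SpectralImage` -- a pixel grid of spectra; averaging the cell pixels
of one image yields the per-sample :class:`SampleRecord`; a study is a
:class:`CohortTable` of records.

Two conventions are enforced globally so that downstream integration and
differentiation never have to worry about orientation or gaps:

* wavenumber axes are stored strictly ascending; descending input (the usual
  instrument convention, high to low wavenumber) is normalized at I/O time;
* an axis carries explicit *segments*: contiguous index ranges that remain
  after a region (e.g. the CO2 window) has been excised.  Operations that act
  locally (baseline, smoothing, derivatives, integration) act per segment and
  never bridge a gap.

Interchange format is delimiter-separated text with the wavenumber as the
first column and one column per pixel/sample, plus a JSON sidecar holding
geometry and labels.  Floats are written with ``%.17g`` so a write/read
round trip reproduces every value exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ABSORBANCE",
    "SECOND_DERIVATIVE",
    "CELL",
    "BACKGROUND",
    "UNASSIGNED",
    "SpectraError",
    "SpectralParseError",
    "EmptyRegionError",
    "WavenumberAxis",
    "Spectrum",
    "SpectralImage",
    "SampleRecord",
    "CohortTable",
    "slice_region",
    "read_spectral_matrix",
    "write_spectral_matrix",
    "read_cohort_metadata",
    "write_cohort_metadata",
]

ABSORBANCE = "absorbance"
SECOND_DERIVATIVE = "second_derivative"

CELL = "cell"
BACKGROUND = "background"
UNASSIGNED = "unassigned"

#: float format used by all writers; %.17g round-trips IEEE doubles exactly.
FLOAT_FORMAT = "%.17g"

_HEADER_COMMENT = "# fibrospec spectral matrix v1 (floats written as %.17g)"


class SpectraError(ValueError):
    """Domain-model violation (invalid axis, mismatched lengths, ...)."""


class SpectralParseError(SpectraError):
    """A spectral text file could not be parsed; the message names the spot."""


class EmptyRegionError(SpectraError):
    """A requested wavenumber interval contains no axis points."""


# ---------------------------------------------------------------------------
# axis


class WavenumberAxis:
    """A strictly ascending wavenumber axis (cm^-1) with contiguity segments.

    Parameters
    ----------
    values : array-like
        Strictly increasing, finite, positive wavenumbers; length >= 2.
    segments : sequence of (start, stop) index pairs, optional
        Half-open index ranges that are contiguous in the underlying
        measurement.  Defaults to one segment covering the whole axis.
        Segments must be disjoint, ordered, and cover every index.
    """

    __slots__ = ("values", "segments")

    def __init__(self, values, segments: Sequence[tuple[int, int]] | None = None):
        v = np.asarray(values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise SpectraError(f"axis needs >= 2 points, got shape {v.shape}")
        if not np.all(np.isfinite(v)) or np.any(v <= 0):
            raise SpectraError("axis values must be finite and positive")
        if np.any(np.diff(v) <= 0):
            raise SpectraError("axis must be strictly ascending (sort/dedup at I/O)")
        v.setflags(write=False)
        self.values = v
        if segments is None:
            segments = ((0, v.size),)
        segs = tuple((int(a), int(b)) for a, b in segments)
        pos = 0
        for a, b in segs:
            if a != pos or b <= a:
                raise SpectraError(f"segments must tile the axis, got {segs}")
            pos = b
        if pos != v.size:
            raise SpectraError(f"segments must cover all {v.size} points, got {segs}")
        self.segments = segs

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return self.values.size

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, WavenumberAxis)
            and self.segments == other.segments
            and np.array_equal(self.values, other.values)
        )

    def __repr__(self) -> str:
        return (
            f"WavenumberAxis({self.values[0]:g}..{self.values[-1]:g} cm-1, "
            f"n={len(self)}, segments={len(self.segments)})"
        )

    @property
    def step(self) -> float:
        """Median point spacing, cm^-1 (exact for uniform axes)."""
        return float(np.median(np.diff(self.values)))

    def segment_slices(self) -> list[slice]:
        return [slice(a, b) for a, b in self.segments]

    def segment_of(self, index: int) -> int:
        """Return the segment id containing ``index``."""
        for i, (a, b) in enumerate(self.segments):
            if a <= index < b:
                return i
        raise IndexError(index)

    def subset(self, keep: np.ndarray) -> tuple["WavenumberAxis", np.ndarray]:
        """Restrict the axis to a boolean/index mask, recomputing segments.

        Consecutive kept points stay in one segment only if they were adjacent
        in this axis *and* belonged to the same segment.  Returns the new axis
        and the integer indices (into this axis) that were kept.
        """
        keep = np.asarray(keep)
        idx = np.flatnonzero(keep) if keep.dtype == bool else keep.astype(int)
        if idx.size < 2:
            raise EmptyRegionError("subset would leave fewer than 2 axis points")
        seg_id = np.empty(len(self), dtype=int)
        for i, (a, b) in enumerate(self.segments):
            seg_id[a:b] = i
        breaks = [0]
        for k in range(1, idx.size):
            if idx[k] != idx[k - 1] + 1 or seg_id[idx[k]] != seg_id[idx[k - 1]]:
                breaks.append(k)
        breaks.append(idx.size)
        segments = [(breaks[i], breaks[i + 1]) for i in range(len(breaks) - 1)]
        return WavenumberAxis(self.values[idx], segments), idx


# ---------------------------------------------------------------------------
# spectra containers


@dataclass
class Spectrum:
    """One intensity trace on a wavenumber axis.

    ``kind`` is :data:`ABSORBANCE` (AU) or :data:`SECOND_DERIVATIVE`
    (AU * cm^2, i.e. d2A/dnu2).
    """

    axis: WavenumberAxis
    intensity: np.ndarray
    kind: str = ABSORBANCE

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != (len(self.axis),):
            raise SpectraError(
                f"intensity length {self.intensity.shape} != axis length {len(self.axis)}"
            )
        if not np.all(np.isfinite(self.intensity)):
            raise SpectraError("intensities must be finite")
        if self.kind not in (ABSORBANCE, SECOND_DERIVATIVE):
            raise SpectraError(f"unknown spectrum kind {self.kind!r}")

    def with_intensity(self, intensity, kind: str | None = None) -> "Spectrum":
        return Spectrum(self.axis, intensity, self.kind if kind is None else kind)


@dataclass
class SpectralImage:
    """A pixel grid of spectra sharing one axis.

    ``cube`` has shape (n_rows * n_cols, n_points), pixels in row-major order.
    ``mask`` (optional) labels every pixel ``cell``/``background``/``unassigned``.
    """

    n_rows: int
    n_cols: int
    axis: WavenumberAxis
    cube: np.ndarray
    mask: np.ndarray | None = None
    sample_id: str = ""
    group: str = ""

    def __post_init__(self):
        self.cube = np.asarray(self.cube, dtype=float)
        n_pix = self.n_rows * self.n_cols
        if self.cube.shape != (n_pix, len(self.axis)):
            raise SpectraError(
                f"cube shape {self.cube.shape} != ({n_pix}, {len(self.axis)})"
            )
        if not np.all(np.isfinite(self.cube)):
            raise SpectraError("cube intensities must be finite")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=object).astype(str)
            if self.mask.shape != (n_pix,):
                raise SpectraError(f"mask shape {self.mask.shape} != ({n_pix},)")
            bad = set(self.mask) - {CELL, BACKGROUND, UNASSIGNED}
            if bad:
                raise SpectraError(f"unknown mask labels {sorted(bad)}")

    @property
    def n_pixels(self) -> int:
        return self.n_rows * self.n_cols

    def pixels(self, label: str) -> np.ndarray:
        """Spectra of all pixels carrying ``label`` (requires a mask)."""
        if self.mask is None:
            raise SpectraError("image has no mask")
        return self.cube[self.mask == label]


@dataclass
class SampleRecord:
    """Per-sample result of preprocessing: mean absorbance + second derivative."""

    sample_id: str
    group: str
    mean_absorbance: Spectrum
    second_derivative: Spectrum | None = None

    def __post_init__(self):
        if self.mean_absorbance.kind != ABSORBANCE:
            raise SpectraError("mean_absorbance must be an absorbance spectrum")
        if self.second_derivative is not None:
            if self.second_derivative.kind != SECOND_DERIVATIVE:
                raise SpectraError("second_derivative has wrong kind")
            if self.second_derivative.axis != self.mean_absorbance.axis:
                raise SpectraError("both spectra of a record must share one axis")


class CohortTable:
    """An ordered collection of :class:`SampleRecord` on one common axis."""

    def __init__(self, records: Iterable[SampleRecord]):
        self.records = list(records)
        if not self.records:
            raise SpectraError("cohort must contain at least one record")
        ids = [r.sample_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise SpectraError("sample ids must be unique")
        axis = self.records[0].mean_absorbance.axis
        for r in self.records:
            if r.mean_absorbance.axis != axis:
                raise SpectraError("all records must share one axis")
        self.axis = axis

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.records]

    @property
    def groups(self) -> list[str]:
        return [r.group for r in self.records]

    def group_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for g in self.groups:
            sizes[g] = sizes.get(g, 0) + 1
        return sizes

    def matrix(self, kind: str = ABSORBANCE) -> np.ndarray:
        """Stack spectra into an (n_samples, n_points) array."""
        if kind == ABSORBANCE:
            return np.vstack([r.mean_absorbance.intensity for r in self.records])
        rows = []
        for r in self.records:
            if r.second_derivative is None:
                raise SpectraError(f"record {r.sample_id} has no second derivative")
            rows.append(r.second_derivative.intensity)
        return np.vstack(rows)


# ---------------------------------------------------------------------------
# region slicing


def slice_region(spectrum: Spectrum, lo: float, hi: float) -> Spectrum:
    """Restrict a spectrum to the closed wavenumber interval [lo, hi].

    Region bounds snap to measured points: exactly the axis points with
    lo <= nu <= hi are retained (no interpolation of endpoints).
    """
    if lo >= hi:
        raise SpectraError(f"need lo < hi, got [{lo}, {hi}]")
    v = spectrum.axis.values
    keep = (v >= lo) & (v <= hi)
    if not np.any(keep):
        raise EmptyRegionError(f"no axis point inside [{lo}, {hi}] cm-1")
    if keep.sum() < 2:
        # a single point cannot form an axis; treat as an empty region
        raise EmptyRegionError(f"fewer than 2 axis points inside [{lo}, {hi}] cm-1")
    axis, idx = spectrum.axis.subset(keep)
    return Spectrum(axis, spectrum.intensity[idx], spectrum.kind)


# ---------------------------------------------------------------------------
# text I/O


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _deriv_path(path: Path) -> Path:
    return path.with_name(path.stem + ".deriv.csv")


def _format_matrix(axis: WavenumberAxis, columns: dict[str, np.ndarray]) -> str:
    names = list(columns)
    lines = [_HEADER_COMMENT, "wavenumber," + ",".join(names)]
    cols = [axis.values] + [columns[n] for n in names]
    for row in zip(*cols):
        lines.append(",".join(FLOAT_FORMAT % x for x in row))
    return "\n".join(lines) + "\n"


def write_spectral_matrix(obj, path) -> Path:
    """Write a Spectrum, SpectralImage, or CohortTable as CSV + JSON sidecar.

    Column order is deterministic (sorted sample ids; row-major pixels) and the
    float format is fixed, so writing the same object twice is byte-identical.
    A cohort whose records carry second derivatives writes a companion
    ``<stem>.deriv.csv`` next to the absorbance matrix.
    """
    path = Path(path)
    meta: dict = {"segments": None}

    if isinstance(obj, Spectrum):
        columns = {"intensity": obj.intensity}
        meta.update(type="spectrum", kind=obj.kind)
        axis = obj.axis
    elif isinstance(obj, SpectralImage):
        names = [
            f"px_{r:03d}_{c:03d}" for r in range(obj.n_rows) for c in range(obj.n_cols)
        ]
        columns = {n: obj.cube[i] for i, n in enumerate(names)}
        meta.update(
            type="image",
            n_rows=obj.n_rows,
            n_cols=obj.n_cols,
            sample_id=obj.sample_id,
            group=obj.group,
            mask=None if obj.mask is None else list(obj.mask),
        )
        axis = obj.axis
    elif isinstance(obj, CohortTable):
        order = sorted(range(len(obj)), key=lambda i: obj.records[i].sample_id)
        recs = [obj.records[i] for i in order]
        columns = {r.sample_id: r.mean_absorbance.intensity for r in recs}
        has_deriv = all(r.second_derivative is not None for r in recs)
        meta.update(
            type="cohort",
            samples=[{"sample_id": r.sample_id, "group": r.group} for r in recs],
            derivative_file=_deriv_path(path).name if has_deriv else None,
        )
        axis = obj.axis
        if has_deriv:
            dcols = {r.sample_id: r.second_derivative.intensity for r in recs}
            _deriv_path(path).write_text(_format_matrix(axis, dcols))
    else:
        raise SpectraError(f"cannot write object of type {type(obj).__name__}")

    meta["segments"] = [list(s) for s in axis.segments]
    path.write_text(_format_matrix(axis, columns))
    _sidecar_path(path).write_text(
        json.dumps(meta, sort_keys=True, indent=1) + "\n"
    )
    return path


def _load_matrix(path: Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise SpectralParseError(f"{path}: {exc}") from exc
    if df.shape[1] < 2:
        raise SpectralParseError(f"{path}: need a wavenumber column plus data columns")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SpectralParseError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} in column "
                f"{col!r}, data row {row + 1}"
            )
        if coerced.isna().any():
            row = int(np.flatnonzero(coerced.isna().to_numpy())[0])
            raise SpectralParseError(f"{path}: missing value in column {col!r}, data row {row + 1}")
        df[col] = coerced
    return df


def read_spectral_matrix(path, orientation: str = "auto"):
    """Read a spectral matrix written by :func:`write_spectral_matrix`.

    The first column is the wavenumber axis; remaining columns are pixels or
    samples.  The axis is normalized to ascending order (``orientation='auto'``
    accepts either direction; ``'ascending'``/``'descending'`` assert it).
    Returns a :class:`SpectralImage` when the JSON sidecar declares an image
    geometry, a :class:`Spectrum` for a declared single spectrum, and a
    :class:`CohortTable` otherwise.
    """
    path = Path(path)
    df = _load_matrix(path)
    wn = df.iloc[:, 0].to_numpy(dtype=float)
    data = df.iloc[:, 1:].to_numpy(dtype=float).T  # columns x points
    names = [str(c) for c in df.columns[1:]]

    diffs = np.diff(wn)
    if orientation == "ascending" and np.any(diffs <= 0):
        raise SpectralParseError(f"{path}: axis is not ascending")
    if orientation == "descending" and np.any(diffs >= 0):
        raise SpectralParseError(f"{path}: axis is not descending")
    order = np.argsort(wn, kind="stable")
    wn, data = wn[order], data[:, order]
    if np.any(np.diff(wn) == 0):
        dup = wn[np.flatnonzero(np.diff(wn) == 0)[0]]
        raise SpectralParseError(f"{path}: duplicate wavenumber {dup:g} after sorting")

    meta = {}
    if _sidecar_path(path).exists():
        meta = json.loads(_sidecar_path(path).read_text())
    segments = meta.get("segments")
    axis = WavenumberAxis(wn, None if segments is None else [tuple(s) for s in segments])

    kind = meta.get("kind", ABSORBANCE)
    if meta.get("type") == "spectrum":
        return Spectrum(axis, data[0], kind)
    if meta.get("type") == "image":
        mask = meta.get("mask")
        return SpectralImage(
            n_rows=int(meta["n_rows"]),
            n_cols=int(meta["n_cols"]),
            axis=axis,
            cube=data,
            mask=None if mask is None else np.asarray(mask, dtype=object),
            sample_id=meta.get("sample_id", ""),
            group=meta.get("group", ""),
        )

    group_of = {s["sample_id"]: s["group"] for s in meta.get("samples", [])}
    deriv: dict[str, np.ndarray] = {}
    if meta.get("derivative_file"):
        ddf = _load_matrix(path.with_name(meta["derivative_file"]))
        dwn = ddf.iloc[:, 0].to_numpy(dtype=float)
        dorder = np.argsort(dwn, kind="stable")
        for c in ddf.columns[1:]:
            deriv[str(c)] = ddf[c].to_numpy(dtype=float)[dorder]
    records = []
    for i, name in enumerate(names):
        sd = None
        if name in deriv:
            sd = Spectrum(axis, deriv[name], SECOND_DERIVATIVE)
        records.append(
            SampleRecord(
                sample_id=name,
                group=group_of.get(name, "unknown"),
                mean_absorbance=Spectrum(axis, data[i], ABSORBANCE),
                second_derivative=sd,
            )
        )
    return CohortTable(records)


def write_cohort_metadata(table: pd.DataFrame, path) -> Path:
    """Write the cohort metadata CSV (sample_id, group, optional age/sex/passage)."""
    path = Path(path)
    cols = [c for c in ("sample_id", "group", "age", "sex", "passage") if c in table.columns]
    if "sample_id" not in cols or "group" not in cols:
        raise SpectraError("metadata needs sample_id and group columns")
    table.sort_values("sample_id")[cols].to_csv(path, index=False)
    return path


def read_cohort_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    if "sample_id" not in df.columns or "group" not in df.columns:
        raise SpectralParseError(f"{path}: metadata needs sample_id and group columns")
    df["sample_id"] = df["sample_id"].astype(str)
    return df
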