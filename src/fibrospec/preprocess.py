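"""FTIR pre-processing chain for cell imaging data.

Stage order follows the standard cultured-cell workflow: CO2-region excision
-> rubber-band baseline correction -> k-means cell/background segmentation ->
binning -> clustered scatter (EMSC) correction -> Savitzky-Golay smoothing ->
pixel averaging -> vector normalization -> SG second derivative -> vector
normalization.  All stages respect axis *segments* (see
:mod:`fibrospec.spectra`): nothing ever bridges the excised gap.

Numerical notes
---------------
* The SG filter is implemented as a local least-squares polynomial fit in the
  physical wavenumber coordinate, so derivative outputs are in AU*cm^2
  regardless of binning, non-uniform spacing near a remainder bin is handled
  correctly, and edge points are fitted on the truncated window.
* The scatter correction is a clustered, non-iterative EMSC: each spectrum is
  regressed on the reference plus a polynomial baseline and (optionally) a
  PCA-compressed basis of van-de-Hulst Mie extinction curves, then rescaled by
  the fitted reference coefficient.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.cluster import KMeans

from .spectra import (
    ABSORBANCE,
    BACKGROUND,
    CELL,
    SECOND_DERIVATIVE,
    CohortTable,
    SampleRecord,
    SpectraError,
    SpectralImage,
    Spectrum,
    WavenumberAxis,
)

__all__ = [
    "SGParams",
    "ScatterParams",
    "PreprocessParams",
    "ALT_DERIV_PRESET",
    "excise_region",
    "rubberband_baseline",
    "segment_pixels",
    "bin_spectra",
    "bin_image_spatial",
    "build_mie_basis",
    "scatter_correct",
    "savgol",
    "vector_normalize",
    "preprocess_sample",
    "preprocess_cohort",
]


# ---------------------------------------------------------------------------
# parameters


@dataclass(frozen=True)
class SGParams:
    """Savitzky-Golay window/order (window odd and > polyorder)."""

    window: int = 5
    polyorder: int = 2
    order: int = 0  # derivative order

    def __post_init__(self):
        if self.window % 2 == 0 or self.window <= self.polyorder:
            raise SpectraError(
                f"SG window must be odd and > polyorder, got ({self.window}, {self.polyorder})"
            )
        if not 0 <= self.order <= self.polyorder:
            raise SpectraError("derivative order must be within the polynomial order")


#: alternative second-derivative preset used for robustness re-analysis
ALT_DERIV_PRESET = SGParams(window=15, polyorder=5, order=2)


@dataclass(frozen=True)
class ScatterParams:
    """Clustered EMSC configuration.

    ``emsc_poly`` fits reference + polynomial only; ``emsc_mie`` adds the
    PCA-compressed van-de-Hulst Mie extinction basis spanning sphere radii
    ``mie_radius_range`` (micrometres) and refractive indices
    ``mie_refidx_range``.
    """

    mode: str = "emsc_mie"
    n_clusters: int = 5
    poly_order: int = 2
    n_mie_components: int = 7
    mie_radius_range: tuple[float, float] = (2.0, 8.0)
    mie_refidx_range: tuple[float, float] = (1.1, 1.5)
    n_radii: int = 10
    n_refidx: int = 10
    a_min: float = 1e-6

    def __post_init__(self):
        if self.mode not in ("emsc_poly", "emsc_mie"):
            raise SpectraError(f"unknown scatter mode {self.mode!r}")
        if self.n_clusters < 1 or self.poly_order < 0 or self.n_mie_components < 1:
            raise SpectraError("invalid scatter parameters")


@dataclass(frozen=True)
class PreprocessParams:
    excise_lo: float = 2000.0
    excise_hi: float = 2700.0
    kmeans_k: int = 2
    kmeans_seed: int = 0
    bin_factor: int = 2
    #: "spatial" averages bin_factor x bin_factor pixel blocks (the default;
    #: preserves spectral resolution); "spectral" averages adjacent axis points.
    bin_mode: str = "spatial"
    scatter: ScatterParams = field(default_factory=ScatterParams)
    smooth: SGParams = field(default_factory=lambda: SGParams(5, 2, 0))
    deriv: SGParams = field(default_factory=lambda: SGParams(7, 2, 2))

    def __post_init__(self):
        if self.excise_lo >= self.excise_hi:
            raise SpectraError("excise_lo must be < excise_hi")
        if self.bin_factor < 1:
            raise SpectraError("bin_factor must be >= 1")
        if self.bin_mode not in ("spatial", "spectral"):
            raise SpectraError(f"unknown bin_mode {self.bin_mode!r}")
        if self.kmeans_k < 1:
            raise SpectraError("kmeans_k must be >= 1")


# ---------------------------------------------------------------------------
# excision


def excise_region(obj, lo: float, hi: float):
    """Drop all axis points with lo <= nu <= hi, tracking the gap as a
    segment boundary so later windowed operations never bridge it.

    An interval that removes nothing returns the object unchanged.  Removing
    points must leave >= 8 points on each side of the gap.
    """
    axis = obj.axis
    keep = (axis.values < lo) | (axis.values > hi)
    if keep.all():
        return obj
    n_below = int(np.sum(axis.values < lo))
    n_above = int(np.sum(axis.values > hi))
    if n_below < 8 or n_above < 8:
        raise SpectraError(
            f"excising [{lo}, {hi}] leaves {n_below}/{n_above} points on the "
            "low/high side; need >= 8 on each"
        )
    new_axis, idx = axis.subset(keep)
    if isinstance(obj, Spectrum):
        return Spectrum(new_axis, obj.intensity[idx], obj.kind)
    if isinstance(obj, SpectralImage):
        return SpectralImage(
            obj.n_rows, obj.n_cols, new_axis, obj.cube[:, idx], obj.mask,
            obj.sample_id, obj.group,
        )
    if isinstance(obj, CohortTable):
        recs = []
        for r in obj:
            sd = r.second_derivative
            recs.append(
                SampleRecord(
                    r.sample_id,
                    r.group,
                    Spectrum(new_axis, r.mean_absorbance.intensity[idx]),
                    None if sd is None else Spectrum(new_axis, sd.intensity[idx], SECOND_DERIVATIVE),
                )
            )
        return CohortTable(recs)
    raise SpectraError(f"cannot excise object of type {type(obj).__name__}")


# ---------------------------------------------------------------------------
# rubber-band baseline


def _lower_hull_indices(x: np.ndarray, y: np.ndarray) -> list[int]:
    """Indices of the lower convex hull of (x, y), x strictly ascending
    (Andrew monotone chain, lower branch)."""
    hull: list[int] = []
    for i in range(x.size):
        while len(hull) >= 2:
            o, a = hull[-2], hull[-1]
            cross = (x[a] - x[o]) * (y[i] - y[o]) - (y[a] - y[o]) * (x[i] - x[o])
            if cross <= 0:
                hull.pop()
            else:
                break
        hull.append(i)
    return hull


def _rubberband_1d(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    if x.size < 3:
        raise SpectraError("rubber-band baseline needs >= 3 points per segment")
    h = _lower_hull_indices(x, y)
    return np.interp(x, x[h], y[h])


def rubberband_baseline(spectrum: Spectrum) -> tuple[Spectrum, Spectrum]:
    """Rubber-band baseline: the lower convex hull of (nu, A), per segment.

    Returns ``(baseline, corrected)``; the corrected spectrum is nonnegative
    and exactly zero at every hull support point (at least the two segment
    endpoints).
    """
    x = spectrum.axis.values
    y = spectrum.intensity
    base = np.empty_like(y)
    for s in spectrum.axis.segment_slices():
        base[s] = _rubberband_1d(x[s], y[s])
    corrected = np.maximum(y - base, 0.0)
    return (
        spectrum.with_intensity(base),
        spectrum.with_intensity(corrected),
    )


def _rubberband_matrix(axis: WavenumberAxis, Y: np.ndarray) -> np.ndarray:
    """Baseline-correct every row of a spectra matrix."""
    out = np.empty_like(Y)
    x = axis.values
    slices = axis.segment_slices()
    for i in range(Y.shape[0]):
        for s in slices:
            out[i, s] = Y[i, s] - _rubberband_1d(x[s], Y[i, s])
    np.maximum(out, 0.0, out=out)
    return out


# ---------------------------------------------------------------------------
# segmentation


def _quantile_init(X: np.ndarray, totals: np.ndarray, k: int) -> np.ndarray:
    """Deterministic initial centroids: the spectra at the (j+1/2)/k
    quantiles of total absorbance.  Order-independent, so segmentation is
    equivariant under pixel permutations."""
    order = np.argsort(totals, kind="stable")
    pos = [min(int((j + 0.5) / k * X.shape[0]), X.shape[0] - 1) for j in range(k)]
    return X[order[pos]].astype(float)


def segment_pixels(image: SpectralImage, k: int = 2, seed: int = 0) -> np.ndarray:
    """Cluster pixel spectra into k groups; label the cluster with the
    highest mean total absorbance ``cell`` and the rest ``background``.

    Lloyd's algorithm with deterministic quantile-of-total-absorbance
    initialization (a single seeded run; ``seed`` is accepted for interface
    stability but the procedure is fully deterministic).
    """
    X = image.cube
    if X.shape[0] < k:
        raise SpectraError(f"image has {X.shape[0]} pixels < k={k}")
    if k == 1:
        return np.full(X.shape[0], CELL, dtype=object)
    if np.allclose(X, X[0]):
        warnings.warn("all pixels identical; labeling everything 'cell'")
        return np.full(X.shape[0], CELL, dtype=object)
    totals = X.sum(axis=1)
    km = KMeans(
        n_clusters=k,
        init=_quantile_init(X, totals, k),
        n_init=1,
        max_iter=300,
        random_state=int(seed) % (2**32),
    )
    labels = km.fit_predict(X)
    mean_total = np.array([
        totals[labels == j].mean() if np.any(labels == j) else -np.inf for j in range(k)
    ])
    cell_cluster = int(np.argmax(mean_total))
    mask = np.where(labels == cell_cluster, CELL, BACKGROUND).astype(object)
    return mask


# ---------------------------------------------------------------------------
# binning


def _bin_groups(axis: WavenumberAxis, factor: int) -> list[np.ndarray]:
    groups = []
    for a, b in axis.segments:
        i = a
        while i < b:
            groups.append(np.arange(i, min(i + factor, b)))
            i += factor
    return groups


def bin_spectra(obj, factor: int):
    """Spectral binning: average non-overlapping groups of ``factor``
    adjacent axis points (axis mean, intensity mean) per segment; a trailing
    remainder is kept as a smaller bin."""
    if factor < 1:
        raise SpectraError("bin factor must be >= 1")
    if factor == 1:
        return obj
    axis = obj.axis
    if factor > len(axis):
        raise SpectraError(f"bin factor {factor} exceeds axis length {len(axis)}")
    groups = _bin_groups(axis, factor)
    new_vals = np.array([axis.values[g].mean() for g in groups])
    # segment boundaries: a bin inherits the segment of its members
    seg_of = [axis.segment_of(int(g[0])) for g in groups]
    segments = []
    start = 0
    for i in range(1, len(groups) + 1):
        if i == len(groups) or seg_of[i] != seg_of[i - 1]:
            segments.append((start, i))
            start = i
    new_axis = WavenumberAxis(new_vals, segments)

    def _bin_rows(Y: np.ndarray) -> np.ndarray:
        return np.column_stack([Y[:, g].mean(axis=1) for g in groups])

    if isinstance(obj, Spectrum):
        return Spectrum(new_axis, _bin_rows(obj.intensity[None, :])[0], obj.kind)
    if isinstance(obj, SpectralImage):
        return SpectralImage(
            obj.n_rows, obj.n_cols, new_axis, _bin_rows(obj.cube), obj.mask,
            obj.sample_id, obj.group,
        )
    raise SpectraError(f"cannot bin object of type {type(obj).__name__}")


def bin_image_spatial(image: SpectralImage, factor: int) -> SpectralImage:
    """Spatial binning: average ``factor x factor`` pixel blocks.

    With a mask, a block containing any cell pixel averages *only* its cell
    pixels and is labeled ``cell``; otherwise the block averages its
    background pixels.  This keeps cell spectra undiluted by background.
    """
    if factor < 1:
        raise SpectraError("bin factor must be >= 1")
    if factor == 1:
        return image
    nr = math.ceil(image.n_rows / factor)
    nc = math.ceil(image.n_cols / factor)
    cube = image.cube.reshape(image.n_rows, image.n_cols, -1)
    mask2 = None if image.mask is None else image.mask.reshape(image.n_rows, image.n_cols)
    out = np.empty((nr * nc, cube.shape[2]))
    out_mask = np.empty(nr * nc, dtype=object)
    k = 0
    for r in range(nr):
        for c in range(nc):
            block = cube[r * factor:(r + 1) * factor, c * factor:(c + 1) * factor]
            block = block.reshape(-1, cube.shape[2])
            if mask2 is None:
                out[k] = block.mean(axis=0)
                out_mask[k] = CELL
            else:
                mblock = mask2[r * factor:(r + 1) * factor, c * factor:(c + 1) * factor].ravel()
                if np.any(mblock == CELL):
                    out[k] = block[mblock == CELL].mean(axis=0)
                    out_mask[k] = CELL
                else:
                    out[k] = block.mean(axis=0)
                    out_mask[k] = BACKGROUND
            k += 1
    return SpectralImage(
        nr, nc, image.axis, out,
        None if image.mask is None else out_mask,
        image.sample_id, image.group,
    )


# ---------------------------------------------------------------------------
# Mie extinction basis + EMSC


def _van_de_hulst_q(rho: np.ndarray) -> np.ndarray:
    """Extinction efficiency of a non-absorbing sphere, van de Hulst
    anomalous-diffraction approximation."""
    rho = np.asarray(rho, dtype=float)
    small = np.abs(rho) < 1e-6
    safe = np.where(small, 1.0, rho)
    q = 2.0 - (4.0 / safe) * np.sin(safe) + (4.0 / safe**2) * (1.0 - np.cos(safe))
    return np.where(small, rho**2 / 2.0, q)


def build_mie_basis(
    axis: WavenumberAxis,
    radius_range_um: tuple[float, float] = (2.0, 8.0),
    refidx_range: tuple[float, float] = (1.1, 1.5),
    n_components: int = 7,
    n_radii: int = 10,
    n_refidx: int = 10,
) -> np.ndarray:
    """Orthonormal PCA basis of van-de-Hulst extinction curves.

    Curves Q(nu) with rho = 4*pi*r*(m-1)*nu are evaluated on a (radius,
    refractive-index) grid (radii in micrometres; nu in cm^-1, so r is
    converted to cm).  Returns the first ``n_components`` principal
    directions (rows), mutually orthonormal.
    """
    radii = np.linspace(radius_range_um[0], radius_range_um[1], n_radii)
    ms = np.linspace(refidx_range[0], refidx_range[1], n_refidx)
    nu = axis.values
    curves = []
    for r in np.atleast_1d(radii):
        r_cm = r * 1e-4
        for m in np.atleast_1d(ms):
            rho = 4.0 * np.pi * r_cm * (m - 1.0) * nu
            curves.append(_van_de_hulst_q(rho))
    C = np.asarray(curves)
    if C.shape[0] == 1:
        return C / np.linalg.norm(C)
    n_components = min(n_components, C.shape[0], C.shape[1])
    Cc = C - C.mean(axis=0)
    _, _, vt = np.linalg.svd(Cc, full_matrices=False)
    return vt[:n_components]


def scatter_correct(
    spectra: np.ndarray,
    axis: WavenumberAxis,
    reference: Spectrum,
    params: ScatterParams | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Clustered EMSC scatter correction of a spectra matrix.

    Each spectrum ``s`` is modeled as ``a*ref + sum_j b_j poly_j(nu) [+ sum_k
    c_k mie_k(nu)]`` by least squares and corrected to ``(s - baseline - mie
    part)/a``.  Spectra are first k-means-clustered (deterministic quantile
    init) and solved cluster-wise in one batched least-squares each; the
    solution is identical to per-spectrum fits since this variant is
    non-iterative.  Spectra whose fitted ``a`` falls below ``a_min`` are
    passed through unchanged and flagged.

    Returns ``(corrected, info)`` where ``info`` has the fitted reference
    coefficients ``a``, the ``uncorrectable`` flag vector, and cluster labels.
    """
    params = params or ScatterParams()
    if reference.axis != axis:
        raise SpectraError("reference must share the spectra's axis")
    S = np.atleast_2d(np.asarray(spectra, dtype=float))
    nu = axis.values
    x = (nu - 0.5 * (nu[0] + nu[-1])) / (0.5 * (nu[-1] - nu[0]))
    design = [reference.intensity]
    design += [x**j for j in range(params.poly_order + 1)]
    if params.mode == "emsc_mie":
        basis = build_mie_basis(
            axis, params.mie_radius_range, params.mie_refidx_range,
            params.n_mie_components, params.n_radii, params.n_refidx,
        )
        design += list(basis)
    D = np.column_stack(design)

    n = S.shape[0]
    k = min(params.n_clusters, n)
    if k > 1:
        totals = S.sum(axis=1)
        if np.allclose(S, S[0]):
            labels = np.zeros(n, dtype=int)
        else:
            km = KMeans(
                n_clusters=k, init=_quantile_init(S, totals, k), n_init=1,
                max_iter=300, random_state=int(seed) % (2**32),
            )
            labels = km.fit_predict(S)
    else:
        labels = np.zeros(n, dtype=int)

    corrected = np.empty_like(S)
    a = np.empty(n)
    flags = np.zeros(n, dtype=bool)
    pinv = np.linalg.pinv(D)
    for j in np.unique(labels):
        idx = np.flatnonzero(labels == j)
        coef = pinv @ S[idx].T  # (n_terms, n_in_cluster)
        aj = coef[0]
        rest = D[:, 1:] @ coef[1:]
        a[idx] = aj
        ok = aj > params.a_min
        good = idx[ok]
        corrected[good] = ((S[idx].T - rest)[:, ok] / aj[ok]).T
        bad = idx[~ok]
        corrected[bad] = S[bad]
        flags[bad] = True
    if flags.any():
        warnings.warn(f"{int(flags.sum())} spectra uncorrectable (a <= {params.a_min})")
    info = {"a": a, "uncorrectable": flags, "cluster_labels": labels}
    return corrected, info


# ---------------------------------------------------------------------------
# Savitzky-Golay


def _sg_weights(xw: np.ndarray, center: float, polyorder: int, deriv: int) -> np.ndarray:
    """Least-squares weights giving the ``deriv``-th derivative of the local
    polynomial fit at ``center`` (physical wavenumber units)."""
    V = np.vander(xw - center, polyorder + 1, increasing=True)
    return math.factorial(deriv) * np.linalg.pinv(V)[deriv]


def savgol_matrix(
    axis: WavenumberAxis, Y: np.ndarray, window: int, polyorder: int, deriv: int = 0
) -> np.ndarray:
    """Savitzky-Golay filter of every row of ``Y``, per axis segment.

    Local polynomial fit in the physical wavenumber coordinate; derivative
    outputs are scaled by the axis step (units AU*cm^2 for deriv=2).  Edge
    points are fitted on the truncated window.  Errors if any segment is
    shorter than the window.
    """
    SGParams(window, polyorder, deriv)  # validate
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    out = np.empty_like(Y)
    x = axis.values
    half = window // 2
    # positions sharing a window stencil (same offsets) share weights and are
    # applied in one batched pass -- on a uniform axis that is a handful of
    # stencils regardless of length
    stencils: dict[bytes, tuple[np.ndarray, list[int], list[int]]] = {}
    for seg_a, seg_b in axis.segments:
        if seg_b - seg_a < window:
            raise SpectraError(
                f"segment of {seg_b - seg_a} points is shorter than window {window}"
            )
        for i in range(seg_a, seg_b):
            a = max(seg_a, i - half)
            b = min(seg_b, i + half + 1)
            offs = x[a:b] - x[i]
            key = np.round(offs, 9).tobytes()
            entry = stencils.get(key)
            if entry is None:
                w = math.factorial(deriv) * np.linalg.pinv(
                    np.vander(offs, polyorder + 1, increasing=True)
                )[deriv]
                stencils[key] = (w, [i], [a])
            else:
                entry[1].append(i)
                entry[2].append(a)
    for w, pos, starts in stencils.values():
        pos_a = np.asarray(pos)
        starts_a = np.asarray(starts)
        acc = np.zeros((Y.shape[0], pos_a.size))
        for k in range(w.size):
            acc += w[k] * Y[:, starts_a + k]
        out[:, pos_a] = acc
    return out


def savgol(spectrum: Spectrum, window: int, polyorder: int, deriv: int = 0) -> Spectrum:
    """SG-filter a single spectrum; deriv=2 yields a second-derivative
    spectrum (kind updated accordingly)."""
    y = savgol_matrix(spectrum.axis, spectrum.intensity[None, :], window, polyorder, deriv)[0]
    kind = SECOND_DERIVATIVE if deriv == 2 else spectrum.kind
    return Spectrum(spectrum.axis, y, kind)


# ---------------------------------------------------------------------------
# normalization


def vector_normalize(spectrum: Spectrum) -> Spectrum:
    """Scale to unit Euclidean norm; a zero spectrum is an error."""
    norm = float(np.linalg.norm(spectrum.intensity))
    if norm == 0.0 or not np.isfinite(norm):
        raise SpectraError("cannot vector-normalize a zero spectrum")
    return spectrum.with_intensity(spectrum.intensity / norm)


# ---------------------------------------------------------------------------
# the full per-sample chain


def preprocess_sample(
    image: SpectralImage,
    reference: Spectrum,
    params: PreprocessParams | None = None,
    sample_id: str | None = None,
    group: str | None = None,
) -> tuple[SampleRecord, dict]:
    """Run the full chain on one image, producing its :class:`SampleRecord`.

    Order: excise -> rubber-band baseline -> segmentation (cell pixels kept)
    -> binning -> scatter correction -> SG smoothing -> pixel mean -> vector
    normalization (=> mean absorbance) -> SG second derivative -> vector
    normalization (=> second derivative).

    Returns the record and an ``info`` dict with per-stage counts.
    """
    params = params or PreprocessParams()
    info: dict = {"n_pixels": image.n_pixels, "n_points_raw": len(image.axis)}

    img = excise_region(image, params.excise_lo, params.excise_hi)
    info["n_points_excised"] = len(img.axis)

    cube = _rubberband_matrix(img.axis, img.cube)
    img = SpectralImage(
        img.n_rows, img.n_cols, img.axis, cube, img.mask, img.sample_id, img.group
    )

    mask = segment_pixels(img, params.kmeans_k, params.kmeans_seed)
    n_cell = int(np.sum(mask == CELL))
    info["n_cell_pixels"] = n_cell
    info["n_background_pixels"] = int(np.sum(mask == BACKGROUND))
    if n_cell == 0:
        raise SpectraError(f"{image.sample_id}: no cell pixels after segmentation")
    img = SpectralImage(
        img.n_rows, img.n_cols, img.axis, img.cube, mask, img.sample_id, img.group
    )

    ref = excise_region(reference, params.excise_lo, params.excise_hi)
    if params.bin_mode == "spatial":
        img = bin_image_spatial(img, params.bin_factor)
        cells = img.pixels(CELL)
        axis = img.axis
    else:
        cells = img.pixels(CELL)
        tmp = Spectrum(img.axis, cells[0])
        binned_axis = bin_spectra(tmp, params.bin_factor).axis
        groups = _bin_groups(img.axis, params.bin_factor)
        cells = np.column_stack([cells[:, g].mean(axis=1) for g in groups])
        ref = Spectrum(binned_axis, np.array([
            ref.intensity[g].mean() for g in groups
        ]))
        axis = binned_axis
    info["n_cell_pixels_binned"] = cells.shape[0]
    info["n_points_binned"] = cells.shape[1]

    cells, sc_info = scatter_correct(cells, axis, ref, params.scatter, params.kmeans_seed)
    info["n_uncorrectable"] = int(sc_info["uncorrectable"].sum())

    cells = savgol_matrix(axis, cells, params.smooth.window, params.smooth.polyorder, params.smooth.order)
    mean_abs = vector_normalize(Spectrum(axis, cells.mean(axis=0), ABSORBANCE))
    d2 = savgol(mean_abs, params.deriv.window, params.deriv.polyorder, params.deriv.order)
    d2 = vector_normalize(d2)

    rec = SampleRecord(
        sample_id=sample_id or image.sample_id or "sample",
        group=group or image.group or "unknown",
        mean_absorbance=mean_abs,
        second_derivative=d2,
    )
    return rec, info


def preprocess_cohort(
    images,
    reference: Spectrum,
    params: PreprocessParams | None = None,
) -> tuple[CohortTable, list[dict]]:
    """Preprocess a sequence of images into a :class:`CohortTable`."""
    records, infos = [], []
    for image in images:
        rec, info = preprocess_sample(image, reference, params)
        records.append(rec)
        infos.append(info)
    return CohortTable(records), infos
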