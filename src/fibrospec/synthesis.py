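"""Synthetic three-group fibroblast cohorts with known injected effects.

The generator emulates the statistical structure of an FTIR imaging study of
cultured cells: per sample, a small hyperspectral image whose *cell* pixels
carry a sum-of-bands biological spectrum and whose *background* pixels carry
only baseline drift, an atmospheric CO2 feature near 2350 cm^-1, and detector
noise.  Disease-like groups differ from the control template through
:class:`GroupEffect`: per-band amplitude multipliers, band-center shifts, and
dropped sub-peaks.  Because every distortion is injected explicitly, each
pipeline stage can be validated against exact ground truth.

Two entry points exist:

* :func:`generate_cohort` -- full images, the input of the preprocessing chain;
* :func:`generate_cohort_spectra` -- per-sample mean spectra drawn directly
  (noise scaled as the mean over cell pixels), for calibration and power
  studies where thousands of cohorts are needed.

Everything is a pure function of the configuration, seed included.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .spectra import (
    ABSORBANCE,
    BACKGROUND,
    CELL,
    CohortTable,
    SampleRecord,
    SpectraError,
    SpectralImage,
    Spectrum,
    WavenumberAxis,
)

__all__ = [
    "BandSpec",
    "GroupEffect",
    "SyntheticCohortConfig",
    "SampleTruth",
    "default_band_library",
    "default_group_effects",
    "band_model",
    "apply_group_effect",
    "generate_reference_spectrum",
    "generate_cell_image",
    "generate_cohort",
    "generate_cohort_spectra",
]


# ---------------------------------------------------------------------------
# band primitives


@dataclass(frozen=True)
class BandSpec:
    """One vibrational band: a Gaussian (sigma ``width``) or Lorentzian
    (half-width ``width``) peak of height ``amplitude`` at ``center`` cm^-1."""

    name: str
    center: float
    width: float
    amplitude: float
    shape: str = "gaussian"

    def __post_init__(self):
        if self.width <= 0:
            raise SpectraError(f"band {self.name}: width must be > 0")
        if self.amplitude < 0:
            raise SpectraError(f"band {self.name}: amplitude must be >= 0")
        if self.shape not in ("gaussian", "lorentzian"):
            raise SpectraError(f"band {self.name}: unknown shape {self.shape!r}")

    def evaluate(self, nu: np.ndarray) -> np.ndarray:
        d = nu - self.center
        if self.shape == "gaussian":
            return self.amplitude * np.exp(-0.5 * (d / self.width) ** 2)
        return self.amplitude * self.width**2 / (d**2 + self.width**2)


@dataclass(frozen=True)
class GroupEffect:
    """How one group's band template differs from the control template."""

    group: str
    amplitude_multipliers: dict[str, float] = field(default_factory=dict)
    center_shifts: dict[str, float] = field(default_factory=dict)
    drop_bands: frozenset[str] = frozenset()

    def __post_init__(self):
        for name, m in self.amplitude_multipliers.items():
            if m <= 0:
                raise SpectraError(f"effect {self.group}/{name}: multiplier must be > 0")
        for name, s in self.center_shifts.items():
            if abs(s) > 15:
                raise SpectraError(
                    f"effect {self.group}/{name}: |shift| must be <= 15 cm^-1"
                )
        object.__setattr__(self, "drop_bands", frozenset(self.drop_bands))


def default_band_library() -> list[BandSpec]:
    """Control-template band library for a cultured-cell absorbance spectrum.

    Centers sit inside the standard assignment regions (amides, C-H
    stretches, carbonyl ester, the two acyl-chain sub-peaks, and the mixed
    carbohydrate/phosphate region); amplitudes make Amide I the dominant band,
    as in measured fibroblast spectra.  Widths are Gaussian sigmas in cm^-1.
    """
    return [
        BandSpec("amide_a", 3290.0, 40.0, 0.55),
        BandSpec("amide_b", 3065.0, 22.0, 0.12),
        BandSpec("asym_ch3", 2960.0, 9.0, 0.22),
        BandSpec("asym_ch2", 2925.0, 10.0, 0.30),
        BandSpec("sym_ch3", 2872.0, 7.0, 0.12),
        BandSpec("sym_ch2", 2852.0, 7.0, 0.18),
        BandSpec("carbonyl_ester", 1738.0, 10.0, 0.25),
        BandSpec("amide_i", 1652.0, 18.0, 1.00),
        BandSpec("amide_ii", 1545.0, 15.0, 0.55),
        BandSpec("amide_ii_choline", 1492.0, 6.0, 0.08),
        BandSpec("acyl_ch2", 1455.0, 6.0, 0.20),
        BandSpec("acyl_ch3", 1435.0, 6.0, 0.15),
        BandSpec("amide_iii", 1240.0, 25.0, 0.18),
        BandSpec("mixed_phosphate", 1155.0, 18.0, 0.12),
        BandSpec("mixed_carbohydrate", 1080.0, 28.0, 0.25),
    ]


def default_group_effects() -> list[GroupEffect]:
    """Default disease-like effect templates.

    The MS-like template lowers the carbonyl-ester band (x0.8), raises Amide I
    (x1.15), shifts the Amide I center +4 cm^-1 toward higher wavenumbers, and
    drops the 1435 cm^-1 acyl sub-peak, reproducing the qualitative pattern of
    reduced lipid-ester content, altered protein secondary structure, and a
    single acyl-chain peak.  The ALS-like template shares the structural
    changes but differs through reduced Amide II and CH2 stretch intensity.
    """
    return [
        GroupEffect("CTRL"),
        GroupEffect(
            "MS",
            amplitude_multipliers={"carbonyl_ester": 0.8, "amide_i": 1.15},
            center_shifts={"amide_i": 4.0},
            drop_bands=frozenset({"acyl_ch3"}),
        ),
        GroupEffect(
            "ALS",
            amplitude_multipliers={
                "carbonyl_ester": 0.85,
                "amide_ii": 0.88,
                "asym_ch2": 0.90,
                "sym_ch2": 0.90,
            },
            center_shifts={"amide_i": 4.0},
            drop_bands=frozenset({"acyl_ch3"}),
        ),
    ]


def band_model(axis: WavenumberAxis, bands: Sequence[BandSpec]) -> Spectrum:
    """Sum of band shapes evaluated on the axis (all-zero for no bands)."""
    y = np.zeros(len(axis))
    for b in bands:
        y += b.evaluate(axis.values)
    return Spectrum(axis, y, ABSORBANCE)


def apply_group_effect(bands: Sequence[BandSpec], effect: GroupEffect) -> list[BandSpec]:
    """Return the band library modified by one group's effect template."""
    out = []
    for b in bands:
        if b.name in effect.drop_bands:
            continue
        out.append(
            replace(
                b,
                amplitude=b.amplitude * effect.amplitude_multipliers.get(b.name, 1.0),
                center=b.center + effect.center_shifts.get(b.name, 0.0),
            )
        )
    return out


# ---------------------------------------------------------------------------
# configuration


@dataclass
class SyntheticCohortConfig:
    """Full generative description of a three-group synthetic cohort."""

    axis_lo: float = 950.0
    axis_hi: float = 3500.0
    axis_step: float = 4.0
    n_per_group: int = 10
    groups: tuple[str, ...] = ("CTRL", "MS", "ALS")
    band_library: list[BandSpec] = field(default_factory=default_band_library)
    effects: list[GroupEffect] = field(default_factory=default_group_effects)
    n_rows: int = 16
    n_cols: int = 16
    background_fraction: float = 0.4
    #: baseline polynomial coefficients in the scaled coordinate
    #: x = (nu - mid)/half_span, low order first; per-image jitter is additive
    #: Gaussian noise on each coefficient.
    baseline_coeffs: tuple[float, ...] = (0.05, 0.02, 0.01)
    baseline_jitter_sd: float = 0.01
    mie_amplitude: float = 0.03
    #: ripple period in cm^-1; van de Hulst oscillation periods for
    #: cell-sized spheres (r 2-8 um, m 1.1-1.5) fall around 1250-5000 cm^-1
    mie_period: float = 1800.0
    mie_phase_jitter: float = math.pi
    co2_band: BandSpec = field(default_factory=lambda: BandSpec("co2", 2350.0, 12.0, 0.15))
    noise_sd: float = 0.005
    between_sample_sd: float = 0.08
    #: per-sample, per-band log-normal amplitude jitter (biological band-level
    #: variability; 0 disables).
    band_jitter_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.background_fraction < 1.0:
            raise SpectraError("background_fraction must be in (0, 1)")
        if self.noise_sd < 0 or self.between_sample_sd < 0 or self.band_jitter_sd < 0:
            raise SpectraError("noise parameters must be >= 0")
        if self.axis_lo >= self.axis_hi or self.axis_step <= 0:
            raise SpectraError("invalid axis specification")
        if self.n_per_group < 1 or self.n_rows < 1 or self.n_cols < 1:
            raise SpectraError("counts must be >= 1")
        for b in self.band_library:
            if not self.axis_lo <= b.center <= self.axis_hi:
                raise SpectraError(f"band {b.name} center outside the axis span")

    def axis(self) -> WavenumberAxis:
        n = int(math.floor((self.axis_hi - self.axis_lo) / self.axis_step)) + 1
        return WavenumberAxis(self.axis_lo + self.axis_step * np.arange(n))

    def effect_for(self, group: str) -> GroupEffect:
        for e in self.effects:
            if e.group == group:
                return e
        return GroupEffect(group)

    @property
    def n_background_pixels(self) -> int:
        # round-half-even, declared rounding rule
        return round(self.background_fraction * self.n_rows * self.n_cols)


@dataclass
class SampleTruth:
    """Ground truth for one generated sample: the noise-free mean cell
    spectrum (per-sample biological factors included), the true pixel mask,
    and the sample-level nuisance parameters."""

    sample_id: str
    group: str
    spectrum: Spectrum
    mask: np.ndarray
    bio_factor: float
    band_amplitudes: dict[str, float]


# ---------------------------------------------------------------------------
# generators


def generate_reference_spectrum(axis: WavenumberAxis, seed: int = 0) -> Spectrum:
    """Scatter-correction reference: a smooth protein/carbohydrate spectrum.

    Emulates a reference measured on an extracellular-matrix gel: amide and
    mixed-region bands only, no cell-specific lipid features, no noise.  The
    output is a deterministic function of (axis, seed).
    """
    del seed  # deterministic by construction; kept for interface stability
    keep = {
        "amide_a",
        "amide_b",
        "amide_i",
        "amide_ii",
        "amide_iii",
        "mixed_phosphate",
        "mixed_carbohydrate",
    }
    bands = [b for b in default_band_library() if b.name in keep]
    return band_model(axis, bands)


def _sample_bands(
    config: SyntheticCohortConfig, group: str, rng: np.random.Generator
) -> tuple[list[BandSpec], float, dict[str, float]]:
    """Draw one sample's band set: group effect + biological variability."""
    bands = apply_group_effect(config.band_library, config.effect_for(group))
    if config.band_jitter_sd > 0:
        bands = [
            replace(b, amplitude=b.amplitude * rng.lognormal(0.0, config.band_jitter_sd))
            for b in bands
        ]
    bio = float(rng.lognormal(0.0, config.between_sample_sd)) if config.between_sample_sd > 0 else 1.0
    return bands, bio, {b.name: b.amplitude * bio for b in bands}


def generate_cell_image(
    config: SyntheticCohortConfig,
    group: str,
    sample_seed,
    sample_id: str | None = None,
) -> tuple[SpectralImage, SampleTruth]:
    """Generate one sample's hyperspectral image plus its ground truth.

    Background pixels carry baseline drift + the CO2 band + noise; cell pixels
    additionally carry the group-modified band model scaled by the per-sample
    biological factor, distorted by a per-pixel sinusoidal Mie-like ripple
    ``amplitude * sin(2*pi*nu/period + phase)``.
    """
    if group not in config.groups:
        raise SpectraError(f"unknown group {group!r}; configured: {config.groups}")
    rng = np.random.default_rng(sample_seed)
    axis = config.axis()
    nu = axis.values
    n_pix = config.n_rows * config.n_cols
    sample_id = sample_id or f"{group}_00"

    bands, bio, amps = _sample_bands(config, group, rng)
    truth = band_model(axis, bands).intensity * bio

    # true mask: background pixels drawn uniformly over the grid
    n_bg = config.n_background_pixels
    mask = np.full(n_pix, CELL, dtype=object)
    mask[rng.permutation(n_pix)[:n_bg]] = BACKGROUND

    # shared per-image additive structure
    x = (nu - 0.5 * (nu[0] + nu[-1])) / (0.5 * (nu[-1] - nu[0]))
    coeffs = np.asarray(config.baseline_coeffs, dtype=float)
    if config.baseline_jitter_sd > 0:
        coeffs = coeffs + rng.normal(0.0, config.baseline_jitter_sd, coeffs.size)
    baseline = np.polynomial.polynomial.polyval(x, coeffs) if coeffs.size else np.zeros_like(nu)
    common = baseline + config.co2_band.evaluate(nu)

    cube = np.tile(common, (n_pix, 1))
    cell_idx = np.flatnonzero(mask == CELL)
    cube[cell_idx] += truth
    if config.mie_amplitude > 0:
        phases = rng.uniform(-config.mie_phase_jitter, config.mie_phase_jitter, cell_idx.size)
        ripple = config.mie_amplitude * np.sin(
            2.0 * np.pi * nu[None, :] / config.mie_period + phases[:, None]
        )
        cube[cell_idx] += ripple
    if config.noise_sd > 0:
        cube += rng.normal(0.0, config.noise_sd, cube.shape)

    image = SpectralImage(
        n_rows=config.n_rows,
        n_cols=config.n_cols,
        axis=axis,
        cube=cube,
        mask=None,  # segmentation is the pipeline's job; truth keeps the mask
        sample_id=sample_id,
        group=group,
    )
    truth_rec = SampleTruth(
        sample_id=sample_id,
        group=group,
        spectrum=Spectrum(axis, truth, ABSORBANCE),
        mask=mask,
        bio_factor=bio,
        band_amplitudes=amps,
    )
    return image, truth_rec


def _sample_seeds(config: SyntheticCohortConfig) -> list[np.random.SeedSequence]:
    n = config.n_per_group * len(config.groups)
    return np.random.SeedSequence(config.seed).spawn(n)


def generate_cohort(
    config: SyntheticCohortConfig,
) -> tuple[list[tuple[SpectralImage, SampleTruth]], pd.DataFrame]:
    """Generate the full cohort: ``n_per_group`` images per group.

    Per-sample seeds are spawned deterministically from ``config.seed``, so
    the entire cohort is a pure function of the configuration.  Returns the
    (image, truth) pairs plus a metadata table (sample_id, group).
    """
    seeds = _sample_seeds(config)
    out = []
    rows = []
    k = 0
    for group in config.groups:
        for i in range(config.n_per_group):
            sid = f"{group}_{i:02d}"
            out.append(generate_cell_image(config, group, seeds[k], sample_id=sid))
            rows.append({"sample_id": sid, "group": group})
            k += 1
    return out, pd.DataFrame(rows)


def generate_cohort_spectra(
    config: SyntheticCohortConfig,
    compute_derivative: bool = True,
    params=None,
) -> tuple[CohortTable, dict[str, Spectrum]]:
    """Draw per-sample mean spectra directly, bypassing the image stage.

    Each sample's mean absorbance is its noise-free truth spectrum plus
    Gaussian noise of standard deviation ``noise_sd / sqrt(n_cell_pixels)`` --
    the noise level a pixel average over the configured cell area would have.
    The spectra then pass through the tail of the standard chain (CO2-region
    excision, SG smoothing, vector normalization, and optionally the SG second
    derivative + renormalization), mirroring what the image pipeline produces.

    Intended for calibration and power studies; baseline drift, Mie ripple and
    segmentation errors are deliberately absent.  Returns the cohort and the
    per-group noise-free template spectra (on the raw axis).
    """
    from . import preprocess as pp

    params = params or pp.PreprocessParams()
    axis = config.axis()
    n_cell = config.n_rows * config.n_cols - config.n_background_pixels
    sd = config.noise_sd / math.sqrt(max(n_cell, 1))
    seeds = _sample_seeds(config)

    truth_by_group = {
        g: band_model(axis, apply_group_effect(config.band_library, config.effect_for(g)))
        for g in config.groups
    }

    records = []
    k = 0
    for group in config.groups:
        for i in range(config.n_per_group):
            rng = np.random.default_rng(seeds[k])
            bands, bio, _ = _sample_bands(config, group, rng)
            y = band_model(axis, bands).intensity * bio
            if sd > 0:
                y = y + rng.normal(0.0, sd, y.size)
            spec = Spectrum(axis, y, ABSORBANCE)
            spec = pp.excise_region(spec, params.excise_lo, params.excise_hi)
            spec = pp.savgol(spec, params.smooth.window, params.smooth.polyorder, 0)
            mean_abs = pp.vector_normalize(spec)
            sd_spec = None
            if compute_derivative:
                d = pp.savgol(mean_abs, params.deriv.window, params.deriv.polyorder, params.deriv.order)
                sd_spec = pp.vector_normalize(d)
            records.append(
                SampleRecord(f"{group}_{i:02d}", group, mean_abs, sd_spec)
            )
            k += 1
    return CohortTable(records), truth_by_group
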