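"""Synthetic burn-spectra generator.

Emulates the qualitative structure of visible/NIR reflectance curves of
skin burned at contact temperatures from 50 to 300 degC: a smooth
baseline rising from the visible into the near infrared, a hemoglobin /
keratin absorption dip near 670 nm whose depth *decreases* with burn
temperature (burned tissue loses its 600-700 nm absorption components),
class-dependent NIR features around 850 and 970 nm (organic-compound
overtone/combination bands and water), per-curve multiplicative
illumination variation — a scalar brightness factor plus a smooth
wavelength-dependent interference field emulating illumination-geometry
and surface effects that distort measured curves — and additive
per-band sensor noise.

Per-class parameter schedules are chosen so that the 150 and 200 degC
templates are the closest pair — the hardest distinction in practice —
while all schedules stay monotone in temperature. The generator is a
study-conditions stand-in, not a radiative-transfer skin model: curves
are smooth analytic shapes, noise is i.i.d., and real-tissue effects
(spatial texture, specular glints, moisture gradients) are absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .data import SpectralDataset

__all__ = ["SyntheticConfig", "class_template", "generate", "difficulty_sweep",
           "DEFAULT_TEMPERATURES"]

DEFAULT_TEMPERATURES = (50, 100, 150, 200, 250, 300)  # degC

# monotone schedules with their smallest gap between classes 2 and 3
# (150 vs 200 degC), making that pair the closest templates by construction
_DIP_DEPTHS = (0.40, 0.30, 0.21, 0.17, 0.10, 0.03)
_NIR_AMPS = (0.010, 0.022, 0.032, 0.036, 0.046, 0.058)
_ALBEDO = (1.00, 0.965, 0.930, 0.915, 0.880, 0.845)


@dataclass
class SyntheticConfig:
    """Full parameterization of the simulated burn-spectra generator.

    Defaults mirror the instrument and protocol being emulated: 260 bands
    over 400-1000 nm, six burn-temperature classes, an absorption dip
    centered at 670 nm inside the 600-700 nm window whose depth decreases
    with temperature, and NIR features of increasing amplitude.
    """

    n_bands: int = 260
    wavelength_range: tuple[float, float] = (400.0, 1000.0)
    n_classes: int = 6
    class_temperatures: tuple[int, ...] = DEFAULT_TEMPERATURES
    samples_per_class: int = 1000
    dip_center: float = 670.0
    dip_width: float = 28.0                      # nm, Gaussian sigma
    dip_window: tuple[float, float] = (600.0, 700.0)
    dip_depth_by_class: tuple[float, ...] = _DIP_DEPTHS
    nir_amp_by_class: tuple[float, ...] = _NIR_AMPS
    albedo_by_class: tuple[float, ...] = _ALBEDO
    nir_centers: tuple[float, float] = (850.0, 970.0)
    nir_widths: tuple[float, float] = (45.0, 30.0)
    illum_scale_sd: float = 0.05                 # per-curve multiplicative
    interference_sd: float = 0.03                # smooth multiplicative field
    interference_length: float = 40.0            # bands, field correlation
    noise_sd: float = 0.01                       # per-band additive
    smoothness: float = 2.0                      # bands, template smoothing
    seed: int = 0

    def __post_init__(self):
        if self.n_classes != len(self.dip_depth_by_class):
            raise ValueError("dip_depth_by_class must have one entry per class")
        if min(self.illum_scale_sd, self.noise_sd, self.interference_sd) < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if any(np.diff(self.dip_depth_by_class) >= 0):
            raise ValueError("dip depths must strictly decrease with temperature")

    @property
    def wavelengths(self) -> np.ndarray:
        return np.linspace(*self.wavelength_range, self.n_bands)

    @property
    def class_names(self) -> list[str]:
        return [f"{t} degC" for t in self.class_temperatures]


def class_template(cfg: SyntheticConfig, class_index: int) -> np.ndarray:
    """Deterministic noise-free reflectance template of one class."""
    if not 0 <= class_index < cfg.n_classes:
        raise ValueError(f"class_index must be in [0, {cfg.n_classes})")
    wl = cfg.wavelengths
    # smooth skin-like baseline rising into the NIR
    base = 0.18 + 0.42 / (1.0 + np.exp(-(wl - 620.0) / 75.0))
    base = base * cfg.albedo_by_class[class_index]
    # 600-700 nm absorption, lost progressively with burn severity
    dip = cfg.dip_depth_by_class[class_index] * np.exp(
        -0.5 * ((wl - cfg.dip_center) / cfg.dip_width) ** 2)
    # NIR overtone bump + water absorption notch, amplitude grows with class
    amp = cfg.nir_amp_by_class[class_index]
    nir = amp * np.exp(-0.5 * ((wl - cfg.nir_centers[0]) / cfg.nir_widths[0]) ** 2)
    water = (0.04 + 0.6 * amp) * np.exp(
        -0.5 * ((wl - cfg.nir_centers[1]) / cfg.nir_widths[1]) ** 2)
    curve = base - dip + nir - water
    if cfg.smoothness > 0:
        curve = gaussian_filter1d(curve, cfg.smoothness, mode="nearest")
    return np.clip(curve, 0.0, 1.2)


def _interference(rng: np.random.Generator, n_per: int,
                  cfg: SyntheticConfig) -> np.ndarray:
    """Per-curve smooth multiplicative gain field, 1 + a Gaussian-filtered
    white-noise process rescaled to sd ``interference_sd``; emulates slowly
    varying illumination-geometry / surface interference across wavelength."""
    if cfg.interference_sd == 0:
        return np.ones((n_per, cfg.n_bands))
    white = rng.standard_normal((n_per, cfg.n_bands))
    smooth = gaussian_filter1d(white, cfg.interference_length, axis=1,
                               mode="nearest")
    # remove the per-curve constant (that is illum_scale's job) and rescale
    # the remaining smooth shape to the requested amplitude
    smooth -= smooth.mean(axis=1, keepdims=True)
    sd = smooth.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return 1.0 + cfg.interference_sd * smooth / sd


def generate(cfg: SyntheticConfig) -> SpectralDataset:
    """Draw a balanced labeled dataset: per class,
    ``template * (1 + illumination scale) + additive noise``, clipped to
    [0, 1.2]. Bit-identical for identical (cfg, seed)."""
    if cfg.samples_per_class < 1:
        raise ValueError("samples_per_class must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xB5EC]))
    n_per = cfg.samples_per_class
    spectra = np.empty((cfg.n_classes * n_per, cfg.n_bands))
    labels = np.empty(cfg.n_classes * n_per, dtype=np.int64)
    for c in range(cfg.n_classes):
        tmpl = class_template(cfg, c)
        scale = 1.0 + cfg.illum_scale_sd * rng.standard_normal((n_per, 1))
        field = _interference(rng, n_per, cfg)
        noise = cfg.noise_sd * rng.standard_normal((n_per, cfg.n_bands))
        block = np.clip(tmpl * scale * field + noise, 0.0, 1.2)
        spectra[c * n_per:(c + 1) * n_per] = block
        labels[c * n_per:(c + 1) * n_per] = c
    return SpectralDataset(spectra, labels, cfg.wavelengths,
                           class_names=cfg.class_names,
                           provenance=f"synthetic(seed={cfg.seed})")


def difficulty_sweep(cfg: SyntheticConfig, noise_levels) -> list[SpectralDataset]:
    """One dataset per additive-noise level; templates, seeds, and the
    illumination noise schedule are held fixed across levels so only the
    additive noise changes; a level equal to ``cfg.noise_sd`` reproduces
    ``generate(cfg)`` bit for bit."""
    levels = [float(v) for v in noise_levels]
    if any(v < 0 for v in levels):
        raise ValueError("noise levels must be non-negative")
    if any(b < a for a, b in zip(levels, levels[1:])):
        raise ValueError("noise levels must be non-decreasing")
    out = []
    for lv in levels:
        c = SyntheticConfig(**{**cfg.__dict__, "noise_sd": lv})
        out.append(generate(c))
    return out
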