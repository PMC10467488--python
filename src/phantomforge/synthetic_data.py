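"""Synthetic inputs for the full phantom-analysis pipeline.

Two generators, both seeded and fully deterministic:

* chip-image rendering — the fluorophore chip drawn over a tissue-colored
  background, with emission proportional to well concentration, attenuated
  by an overlying tissue film via the diffusion-approximation effective
  coefficient (or plain Beer-Lambert), composited additively with hard
  clipping (sensor saturation) and i.i.d. Gaussian sensor noise;
* Beer-Lambert transmission spectra — replicate %T(lambda) curves for
  absorber dilution series with Gaussian replicate noise.

These emulate the measurement designs the analysis modules consume; they
are oracle generators with known ground truth, not device models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .spectro import TransmissionSpectrum
from .wellclass import ChipLayout, Registration, WellROI, build_mask, well_centers_um

__all__ = [
    "BandOptics",
    "SceneConfig",
    "SpectrumSimConfig",
    "effective_attenuation",
    "depth_attenuation_factor",
    "render_chip_image",
    "render_depth_series",
    "simulate_transmission",
]


@dataclass(frozen=True)
class BandOptics:
    """Film optical properties (cm^-1) within one spectral band."""

    mu_a: float
    mu_s_prime: float

    def __post_init__(self) -> None:
        if self.mu_a < 0 or self.mu_s_prime < 0:
            raise ValueError("optical coefficients must be >= 0")


def effective_attenuation(optics: BandOptics) -> float:
    """Diffusion-approximation effective coefficient sqrt(3*mu_a*(mu_a+mu_s'))."""
    return math.sqrt(3.0 * optics.mu_a * (optics.mu_a + optics.mu_s_prime))


def depth_attenuation_factor(
    excitation: BandOptics,
    emission: BandOptics,
    depth_um: float,
    *,
    model: str = "diffusion",
) -> float:
    """Round-trip attenuation of fluorescence under ``depth_um`` of film.

    ``model='diffusion'`` uses mu_eff per band; ``model='beer_lambert'``
    uses the total attenuation mu_a + mu_s' per band.  Depth is converted
    to cm for coefficients in cm^-1.
    """
    z_cm = depth_um / 1.0e4
    if model == "diffusion":
        mu_ex, mu_em = effective_attenuation(excitation), effective_attenuation(emission)
    elif model == "beer_lambert":
        mu_ex = excitation.mu_a + excitation.mu_s_prime
        mu_em = emission.mu_a + emission.mu_s_prime
    else:
        raise ValueError("model must be 'diffusion' or 'beer_lambert'")
    return math.exp(-(mu_ex + mu_em) * z_cm)


@dataclass(frozen=True)
class SceneConfig:
    """Configuration of one rendered chip scene.

    ``gain`` is emission intensity per unit concentration (sRGB units per
    ug/mL) before depth attenuation; ``emission_color`` the chromaticity of
    the fluorophore emission (default red, emulating 630 nm quantum dots);
    ``background_color`` the tissue-base appearance.  ``noise_sigma`` is
    the per-channel additive Gaussian sigma in sRGB units.
    """

    layout: ChipLayout = field(default_factory=ChipLayout)
    depth_um: float = 0.0
    excitation_optics: BandOptics = BandOptics(mu_a=1.44, mu_s_prime=22.84)
    emission_optics: BandOptics = BandOptics(mu_a=0.5, mu_s_prime=15.0)
    emission_color: tuple[float, float, float] = (1.0, 0.0, 0.0)
    background_color: tuple[float, float, float] = (0.10, 0.35, 0.12)
    gain: float = 2.0e-3
    noise_sigma: float = 0.0
    seed: int = 0
    um_per_px: float = 50.0
    image_shape: tuple[int, int] | None = None
    attenuation_model: str = "diffusion"

    def __post_init__(self) -> None:
        if self.depth_um < 0:
            raise ValueError("depth must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.gain < 0:
            raise ValueError("gain must be >= 0")
        for ch in (*self.emission_color, *self.background_color):
            if not 0.0 <= ch <= 1.0:
                raise ValueError("colors must have channels in [0, 1]")

    def resolved_shape(self) -> tuple[int, int]:
        if self.image_shape is not None:
            return self.image_shape
        margin_um = 2.0 * self.um_per_px  # keep outer wells off the border
        side = int(math.ceil(2.0 * (self.layout.extent_um + margin_um) / self.um_per_px)) + 1
        return (side, side)

    def registration(self) -> Registration:
        h, w = self.resolved_shape()
        return Registration(
            center_row=(h - 1) / 2.0, center_col=(w - 1) / 2.0, um_per_px=self.um_per_px
        )


def _render(cfg: SceneConfig, rng: np.random.Generator) -> tuple[np.ndarray, list[WellROI]]:
    h, w = cfg.resolved_shape()
    reg = cfg.registration()
    image = np.empty((h, w, 3), dtype=float)
    image[...] = np.asarray(cfg.background_color, dtype=float)

    atten = depth_attenuation_factor(
        cfg.excitation_optics, cfg.emission_optics, cfg.depth_um,
        model=cfg.attenuation_model,
    )
    emission = np.asarray(cfg.emission_color, dtype=float)
    rows, cols = np.ogrid[:h, :w]
    for x_um, y_um, j, diameter in well_centers_um(cfg.layout):
        conc = cfg.layout.concentrations[j]
        if conc == 0.0:
            continue
        row = reg.center_row - y_um / reg.um_per_px
        col = reg.center_col + x_um / reg.um_per_px
        # sub-resolution wells still render >= 1 px so the nearest-pixel
        # ROI fallback always lands inside the drawn disc
        radius_px = max((diameter / 2.0) / reg.um_per_px, 1.0)
        disc = (rows - row) ** 2 + (cols - col) ** 2 <= radius_px**2
        intensity = cfg.gain * conc * atten
        image[disc] += intensity * emission
    if cfg.noise_sigma > 0:
        image += rng.normal(0.0, cfg.noise_sigma, size=image.shape)
    np.clip(image, 0.0, 1.0, out=image)  # hard clip = sensor saturation
    ground_truth = build_mask(cfg.layout, (h, w), reg)
    return image, ground_truth


def render_chip_image(cfg: SceneConfig) -> tuple[np.ndarray, list[WellROI]]:
    """Render one chip image; returns (float RGB image in [0,1], ground-truth ROIs).

    Identical config (including seed) gives byte-identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    return _render(cfg, rng)


def render_depth_series(
    cfg: SceneConfig, depths_um: list[float]
) -> list[tuple[float, np.ndarray]]:
    """Render one image per film depth with a shared layout and registration.

    Depths must be nonnegative and strictly increasing.  Noise streams are
    spawned per image from the master seed, so each depth gets an
    independent but reproducible draw.
    """
    if any(d < 0 for d in depths_um):
        raise ValueError("depths must be >= 0")
    if any(b <= a for a, b in zip(depths_um, depths_um[1:])):
        raise ValueError("depths must be strictly increasing")
    streams = np.random.SeedSequence(cfg.seed).spawn(len(depths_um))
    series = []
    for depth, ss in zip(depths_um, streams):
        image, _ = _render(replace(cfg, depth_um=depth), np.random.default_rng(ss))
        series.append((depth, image))
    return series


@dataclass(frozen=True)
class SpectrumSimConfig:
    """Configuration of a simulated absorber dilution series.

    ``slope`` is mu_a per unit concentration (cm^-1 per concentration
    unit), assumed wavelength-flat unless ``slope_spectrum`` (one value per
    grid wavelength) is given.  ``noise_sigma`` is additive Gaussian noise
    on %T in percent units, applied independently per replicate.
    """

    slope: float
    concentrations: tuple[float, ...]
    path_length: float = 1.0
    wavelengths: tuple[float, ...] = tuple(float(w) for w in range(350, 701, 5))
    n_replicates: int = 3
    noise_sigma: float = 0.0
    seed: int = 0
    slope_spectrum: tuple[float, ...] | None = None
    name: str = "absorber"

    def __post_init__(self) -> None:
        if self.slope < 0:
            raise ValueError("slope must be >= 0")
        if self.path_length <= 0:
            raise ValueError("path length must be > 0")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.slope_spectrum is not None and len(self.slope_spectrum) != len(self.wavelengths):
            raise ValueError("slope_spectrum must match the wavelength grid")


def simulate_transmission(cfg: SpectrumSimConfig) -> list[TransmissionSpectrum]:
    """One Beer-Lambert transmission spectrum per concentration.

    %T(lambda) = 100 * exp(-slope(lambda) * C * d), plus seeded Gaussian
    replicate noise, clipped into (0, 100].
    """
    rng = np.random.default_rng(cfg.seed)
    grid = np.asarray(cfg.wavelengths, dtype=float)
    slope = (
        np.full_like(grid, cfg.slope)
        if cfg.slope_spectrum is None
        else np.asarray(cfg.slope_spectrum, dtype=float)
    )
    out = []
    for c in cfg.concentrations:
        clean = 100.0 * np.exp(-slope * c * cfg.path_length)
        reps = np.repeat(clean[:, None], cfg.n_replicates, axis=1)
        if cfg.noise_sigma > 0:
            reps = reps + rng.normal(0.0, cfg.noise_sigma, size=reps.shape)
        reps = np.clip(reps, 1.0e-9, 100.0)
        out.append(
            TransmissionSpectrum(
                wavelengths=grid,
                replicates=reps,
                path_length=cfg.path_length,
                label=f"{cfg.name} C={c:g}",
            )
        )
    return out
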