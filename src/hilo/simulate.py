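"""Synthetic speckle illumination, phantoms and a widefield imaging model.

This module renders uniform/speckle image pairs with the statistical
structure the HiLo reconstruction assumes, so that every stage of the
pipeline can be exercised and measured without microscope data.

Illumination
    Fully developed laser speckle is generated by the pupil-phase method:
    uniform random phases on a centred disk in the frequency plane, zero
    outside, intensity = |inverse FFT|^2.  The disk radius sets the
    transverse grain size (FWHM of the intensity autocovariance peak).
    Rotating-diffuser uniform illumination is emulated by averaging many
    independent speckle realizations, which reduces the residual contrast
    as 1/sqrt(n).

Detection
    A widefield system is modelled by its in-focus lateral PSF FWHM, its
    axial response FWHM and the detector pixel pitch (defaults emulate a
    0.47-NA mesoscope: 0.7 um lateral, 7 um axial, 224 nm pixels).  Each
    specimen slice is multiplied by the (z-invariant) illumination,
    filtered by a defocus-dependent MTF, and the slices are summed — a
    widefield camera performs no axial rejection, so total energy is
    conserved.  Two defocus laws are available:

    ``"otf"`` (default)
        The classic defocused incoherent OTF approximation: the
        diffraction-limited in-focus MTF (the pupil autocorrelation
        "chat" function) times the Hopkins defocus factor 2 J1(a)/a with
        a ∝ dz * k~ (1 - k~), where k~ is frequency over the detection
        cut-off.  Mid-band frequencies defocus fastest while frequencies
        near the cut-off decay slowly — the behaviour that makes the
        measured optical section thicken as the band-pass moves up in
        frequency.
    ``"gaussian"``
        A Gaussian blur whose FWHM grows as
        FWHM(dz) = lateral_fwhm * sqrt(1 + (dz/z_R)^2), z_R = axial/2.
        A smooth, parameter-light stand-in whose decay is monotone in
        frequency; retained for comparison.

Noise
    Poisson photon noise (Gaussian approximation above 20 expected
    counts), additive Gaussian read noise and a constant camera offset.
    All randomness flows from a single seed via numpy SeedSequence
    spawning, so every fixture is bit-reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.special import j1

from .core import ImagePair
from .errors import FitError, GeometryError, ParameterError, ShapeError

__all__ = [
    "SpeckleParams",
    "NoiseModel",
    "ImagingModel",
    "Specimen3D",
    "TiltGeometry",
    "generate_speckle",
    "estimate_grain_size",
    "uniform_illumination",
    "tilted_layer_phantom",
    "bilayer_phantom",
    "render_widefield",
    "render_pair",
    "mesoscope_model",
]

# Intensity autocovariance of disk-pupil speckle is the squared jinc; its
# FWHM equals 0.5145 / (pupil radius in cycles/pixel).
_GRAIN_TO_PUPIL = 0.51446

# Widefield axial PSF FWHM ~= 1.772 lambda / NA^2; used to calibrate the
# Hopkins defocus coefficient from the stated axial FWHM.
_AXIAL_FWHM_COEF = 1.772

# Incoherent lateral cut-off 2 NA / lambda expressed through the lateral
# PSF FWHM (~0.514 lambda / NA): k_cut = 1.029 / lateral_fwhm.
_LATERAL_CUTOFF_COEF = 1.029

_GAUSS_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548


@dataclass(frozen=True)
class SpeckleParams:
    """Target statistics of a generated speckle pattern."""

    grain_px: float = 3.0  # FWHM of the intensity autocovariance peak
    modulation: float = 1.0  # contrast in [0, 1]; 1 = fully developed
    seed: int = 0

    def __post_init__(self):
        if self.grain_px < 2.0:
            raise ParameterError(f"grain_px must be >= 2, got {self.grain_px}")
        if not 0.0 <= self.modulation <= 1.0:
            raise ParameterError(f"modulation must lie in [0, 1], got {self.modulation}")


@dataclass(frozen=True)
class NoiseModel:
    """Camera noise: photon scaling, read noise sd and constant offset.

    ``photon_scale`` converts the noiseless render (arbitrary emission
    units) into expected photoelectron counts; ``None`` disables all
    noise and the offset is still added.
    """

    photon_scale: Optional[float] = None
    read_sd: float = 0.0
    offset: float = 0.0


@dataclass(frozen=True)
class ImagingModel:
    """Widefield detection model and pixel geometry."""

    lateral_fwhm_um: float = 0.7
    axial_fwhm_um: float = 7.0
    pixel_size_um: float = 0.224
    noise: NoiseModel = field(default_factory=NoiseModel)
    defocus_model: str = "otf"  # "otf" (Hopkins) or "gaussian"

    def __post_init__(self):
        if min(self.lateral_fwhm_um, self.axial_fwhm_um, self.pixel_size_um) <= 0:
            raise ParameterError("all model widths and the pixel size must be positive")
        if self.defocus_model not in ("otf", "gaussian"):
            raise ParameterError(f"unknown defocus model {self.defocus_model!r}")

    @property
    def lateral_sd_px(self) -> float:
        """In-focus PSF standard deviation in pixels."""
        return self.lateral_fwhm_um / _GAUSS_FWHM / self.pixel_size_um

    @property
    def cutoff_cpp(self) -> float:
        """Detection cut-off frequency in cycles/pixel."""
        return _LATERAL_CUTOFF_COEF / self.lateral_fwhm_um * self.pixel_size_um

    def mtf(self, radial_cpp: np.ndarray, dz_um: float) -> np.ndarray:
        """Detection MTF at defocus ``dz_um`` on a radial frequency grid."""
        k2 = np.square(radial_cpp)
        if self.defocus_model == "gaussian":
            s0 = self.lateral_sd_px
            z_r = 0.5 * self.axial_fwhm_um
            s2 = s0 * s0 * (1.0 + (dz_um / z_r) ** 2)
            return np.exp(-2.0 * np.pi**2 * k2 * s2)
        # Diffraction-limited in-focus MTF (pupil autocorrelation) times
        # the Hopkins defocus factor.
        k_t = np.clip(radial_cpp / self.cutoff_cpp, 0.0, 1.0)
        base = (2.0 / np.pi) * (np.arccos(k_t) - k_t * np.sqrt(1.0 - k_t * k_t))
        a = (
            4.0
            * np.pi
            * _AXIAL_FWHM_COEF
            / self.axial_fwhm_um
            * abs(dz_um)
            * k_t
            * (1.0 - k_t)
        )
        defocus = np.ones_like(a)
        nz = a > 1e-9
        defocus[nz] = 2.0 * j1(a[nz]) / a[nz]
        # DC always passes unattenuated: widefield detection has no axial
        # rejection at zero frequency, which is what conserves energy.
        return base * defocus


def mesoscope_model(noise: Optional[NoiseModel] = None, **overrides) -> ImagingModel:
    """Convenience constructor for the default mesoscope-like model."""
    kwargs = {} if noise is None else {"noise": noise}
    kwargs.update(overrides)
    return ImagingModel(**kwargs)


@dataclass
class Specimen3D:
    """Voxelized fluorophore density.

    ``density`` has logical shape (nz, ny, nx) but each lateral slice may
    be stored broadcast-compressed (e.g. (nz, 1, nx) for a specimen that
    is uniform along rows); ``shape`` records the logical extent.
    ``z_start_um`` is the axial position of slice 0, slices advancing by
    ``voxel_size_um[0]``.
    """

    density: np.ndarray
    voxel_size_um: Tuple[float, float, float]  # (z, y, x)
    shape: Tuple[int, int, int]  # logical (nz, ny, nx)
    z_start_um: float = 0.0

    def __post_init__(self):
        d = np.asarray(self.density, dtype=np.float64)
        if d.ndim != 3:
            raise ShapeError(f"density must be 3-D, got shape {d.shape}")
        if not np.all(np.isfinite(d)) or np.any(d < 0):
            raise ParameterError("density must be finite and non-negative")
        if not np.any(d > 0):
            raise ParameterError("density has no positive voxel")
        self.density = d

    def z_um(self, iz: int) -> float:
        return self.z_start_um + iz * self.voxel_size_um[0]


@dataclass(frozen=True)
class TiltGeometry:
    """A thin layer tilted by wedging one end of its slide up.

    The tilt converts the lateral width of the in-focus strip into an
    axial extent: dz/dx = pixel_size * height_difference / base_length.
    """

    height_difference_um: float
    base_length_um: float
    focus_column: int = 0

    def __post_init__(self):
        if self.base_length_um <= 0:
            raise ParameterError("base_length_um must be positive")
        if self.height_difference_um < 0:
            raise ParameterError("height_difference_um must be non-negative")
        if self.height_difference_um >= 0.2 * self.base_length_um:
            raise GeometryError(
                "tilt violates the small-angle assumption "
                f"(height {self.height_difference_um} vs base {self.base_length_um})"
            )

    @property
    def slope(self) -> float:
        """Axial advance per unit lateral distance."""
        return self.height_difference_um / self.base_length_um


# ---------------------------------------------------------------------------
# illumination


def generate_speckle(shape: Tuple[int, int], params: SpeckleParams) -> np.ndarray:
    """Fully developed speckle with a controllable transverse grain size.

    Pupil-phase method: unit amplitudes with uniform random phases on a
    centred disk of radius 0.5145/grain in the frequency plane; the
    intensity is the squared magnitude of the inverse transform,
    normalized to mean 1.  ``modulation`` m < 1 mixes with a constant:
    out = (1 - m) + m * speckle.
    """
    ny, nx = shape
    if params.grain_px >= min(ny, nx) / 4.0:
        raise ParameterError(
            f"grain {params.grain_px} px too large for shape {shape} "
            "(needs at least 4 grains per side)"
        )
    rho = _GRAIN_TO_PUPIL / params.grain_px
    fr = np.fft.fftfreq(ny)
    fc = np.fft.fftfreq(nx)
    radial = np.hypot(fr[:, None], fc[None, :])
    pupil_mask = radial <= rho
    if pupil_mask.sum() < 8:
        raise ParameterError(
            f"grain {params.grain_px} px leaves too few pupil modes on shape {shape}"
        )
    rng = np.random.default_rng(params.seed)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=shape)
    pupil = np.where(pupil_mask, np.exp(1j * phases), 0.0)
    field_ = np.fft.ifft2(pupil)
    intensity = np.abs(field_) ** 2
    intensity /= intensity.mean()
    m = params.modulation
    return (1.0 - m) + m * intensity


def estimate_grain_size(speckle: np.ndarray) -> float:
    """FWHM (pixels) of the central peak of the intensity autocovariance.

    The mean-subtracted spatial autocorrelation is evaluated via the
    Wiener–Khinchin theorem; the half-maximum crossing is located by
    linear interpolation along each axis and the two axis widths are
    averaged.
    """
    speckle = np.asarray(speckle, dtype=np.float64)
    if speckle.mean() <= 0:
        raise ParameterError("speckle mean must be positive")
    x = speckle - speckle.mean()
    power = np.abs(np.fft.fft2(x)) ** 2
    ac = np.fft.ifft2(power).real
    if ac[0, 0] <= 1e-12 * speckle.size * speckle.mean() ** 2:
        raise FitError("image is flat: autocorrelation has no peak")
    ac /= ac[0, 0]

    widths = []
    for profile in (ac[: speckle.shape[0] // 2, 0], ac[0, : speckle.shape[1] // 2]):
        below = np.nonzero(profile < 0.5)[0]
        if below.size == 0:
            raise FitError("autocorrelation peak wider than half the image")
        i = int(below[0])
        # linear interpolation between samples i-1 and i
        p0, p1 = profile[i - 1], profile[i]
        r_half = (i - 1) + (p0 - 0.5) / (p0 - p1)
        widths.append(2.0 * r_half)
    return float(np.mean(widths))


def _spawn_seeds(seed: int, n: int) -> list:
    return [int(s.generate_state(1)[0]) for s in np.random.SeedSequence(seed).spawn(n)]


def uniform_illumination(
    shape: Tuple[int, int], params: SpeckleParams, n_realizations: int
) -> np.ndarray:
    """Rotating-diffuser illumination: mean of independent speckle patterns.

    Residual contrast decays as modulation/sqrt(n_realizations).
    """
    if n_realizations < 1:
        raise ParameterError(f"n_realizations must be >= 1, got {n_realizations}")
    seeds = _spawn_seeds(params.seed, n_realizations)
    acc = np.zeros(shape, dtype=np.float64)
    for s in seeds:
        acc += generate_speckle(shape, dataclasses.replace(params, seed=s))
    return acc / n_realizations


# ---------------------------------------------------------------------------
# phantoms


def tilted_layer_phantom(
    geometry: TiltGeometry,
    layer_thickness_um: float,
    fov_shape: Tuple[int, int],
    model: ImagingModel,
    z_range_um: Optional[Tuple[float, float]] = None,
    z_step_um: Optional[float] = None,
) -> Specimen3D:
    """A thin fluorescent layer crossing the focal plane at a known tilt.

    Per column x the layer's axial centre is
    z(x) = (x - focus_column) * pixel_size * slope; the density is a
    Gaussian axial profile of FWHM ``layer_thickness_um`` around z(x),
    uniform along rows, with the integrated density per column
    normalized to 1.
    """
    if layer_thickness_um >= model.axial_fwhm_um / 3.0:
        raise ParameterError(
            f"layer thickness {layer_thickness_um} um is not thin relative to the "
            f"axial FWHM {model.axial_fwhm_um} um (must be < 1/3)"
        )
    ny, nx = fov_shape
    cols = np.arange(nx)
    z_centre = (cols - geometry.focus_column) * model.pixel_size_um * geometry.slope
    pad = 3.0 * layer_thickness_um
    if z_range_um is None:
        z_range_um = (float(z_centre.min()) - pad, float(z_centre.max()) + pad)
    z_lo, z_hi = z_range_um
    if z_centre.min() - pad < z_lo or z_centre.max() + pad > z_hi:
        raise GeometryError(
            f"tilted layer (z in [{z_centre.min():.2f}, {z_centre.max():.2f}] um) "
            f"exits the simulated z-range {z_range_um}"
        )
    if z_step_um is None:
        z_step_um = layer_thickness_um / 2.5
    z_grid = np.arange(z_lo, z_hi + z_step_um / 2, z_step_um)
    w = layer_thickness_um / _GAUSS_FWHM
    profile = np.exp(-((z_grid[:, None] - z_centre[None, :]) ** 2) / (2.0 * w * w))
    profile /= profile.sum(axis=0, keepdims=True)  # unit mass per column
    density = profile[:, None, :]  # uniform along rows, broadcast-compressed
    return Specimen3D(
        density=density,
        voxel_size_um=(z_step_um, model.pixel_size_um, model.pixel_size_um),
        shape=(len(z_grid), ny, nx),
        z_start_um=float(z_grid[0]),
    )


def bilayer_phantom(
    separation_um: float,
    fov_shape: Tuple[int, int],
    model: ImagingModel,
    band_period_px: int = 64,
    band_fwhm_px: float = 8.0,
    background_level: float = 1.0,
) -> Specimen3D:
    """Two thin planes: patterned bands in focus, a second plane above.

    The plane at z = 0 carries isolated bright horizontal bands on a dark
    background, so a vertical line profile has well-defined peaks and
    background minima; the plane at z = ``separation_um`` has uniform
    density ``background_level`` and supplies out-of-focus blur.
    """
    if separation_um <= model.axial_fwhm_um:
        raise ParameterError(
            f"separation {separation_um} um must exceed the axial FWHM "
            f"{model.axial_fwhm_um} um"
        )
    ny, nx = fov_shape
    rows = np.arange(ny, dtype=np.float64)
    w = band_fwhm_px / _GAUSS_FWHM
    centres = np.arange(band_period_px // 2, ny, band_period_px, dtype=np.float64)
    bands = np.zeros(ny)
    for c in centres:
        bands += np.exp(-((rows - c) ** 2) / (2.0 * w * w))
    density = np.stack(
        [bands[:, None], np.full((ny, 1), background_level)], axis=0
    )  # (2, ny, 1): uniform along columns
    return Specimen3D(
        density=density,
        voxel_size_um=(separation_um, model.pixel_size_um, model.pixel_size_um),
        shape=(2, ny, nx),
        z_start_um=0.0,
    )


# ---------------------------------------------------------------------------
# rendering


def _apply_noise(image: np.ndarray, noise: NoiseModel, rng: np.random.Generator):
    if noise.photon_scale is None:
        return image + noise.offset
    expected = np.maximum(image * noise.photon_scale, 0.0)
    counts = np.empty_like(expected)
    low = expected < 20.0
    counts[low] = rng.poisson(expected[low])
    high = ~low
    counts[high] = expected[high] + rng.normal(size=int(high.sum())) * np.sqrt(
        expected[high]
    )
    out = counts / noise.photon_scale
    if noise.read_sd > 0:
        out = out + rng.normal(scale=noise.read_sd, size=out.shape) / noise.photon_scale
    return out + noise.offset


def render_widefield(
    specimen: Specimen3D,
    model: ImagingModel,
    focus_z_um: float,
    illumination: np.ndarray,
    seed: Optional[int] = None,
) -> np.ndarray:
    """Widefield image of a specimen under a given (z-invariant) illumination.

    Emission per slice is density x illumination; each slice is filtered
    by the defocus MTF for its distance to the focal plane and the slices
    are summed (no axial rejection).  Noise is applied per the model when
    ``seed`` is given or the model carries a noise description.
    """
    nz, ny, nx = specimen.shape
    illumination = np.asarray(illumination, dtype=np.float64)
    if illumination.shape != (ny, nx):
        raise ShapeError(
            f"illumination shape {illumination.shape} does not match specimen "
            f"lateral shape {(ny, nx)}"
        )
    fr = np.fft.fftfreq(ny)
    fc = np.fft.rfftfreq(nx)
    radial = np.hypot(fr[:, None], fc[None, :])
    acc = np.zeros_like(radial, dtype=np.complex128)
    for iz in range(nz):
        sl = specimen.density[iz]
        if not np.any(sl > 0):
            continue
        emission = sl * illumination  # broadcasts compressed slices
        dz = specimen.z_um(iz) - focus_z_um
        acc += np.fft.rfft2(emission) * model.mtf(radial, dz)
    image = np.fft.irfft2(acc, s=(ny, nx))
    rng = np.random.default_rng(seed)
    return _apply_noise(image, model.noise, rng)


def render_pair(
    specimen: Specimen3D,
    model: ImagingModel,
    focus_z_um: float,
    speckle_params: SpeckleParams,
    n_uniform_realizations: int = 100,
    seed: int = 0,
) -> ImagePair:
    """Render a co-registered uniform/speckle image pair of one specimen.

    The speckle member uses a single frozen speckle pattern; the uniform
    member averages ``n_uniform_realizations`` independent patterns.  All
    per-stream seeds (patterns and the two noise draws) are derived from
    ``seed``, decorrelated between members.
    """
    ny, nx = specimen.shape[1:]
    s_speckle, s_uniform, s_noise_s, s_noise_u = _spawn_seeds(seed, 4)
    speckle_illum = generate_speckle(
        (ny, nx), dataclasses.replace(speckle_params, seed=s_speckle)
    )
    uniform_illum = uniform_illumination(
        (ny, nx),
        dataclasses.replace(speckle_params, seed=s_uniform),
        n_uniform_realizations,
    )
    i_s = render_widefield(specimen, model, focus_z_um, speckle_illum, seed=s_noise_s)
    i_u = render_widefield(specimen, model, focus_z_um, uniform_illum, seed=s_noise_u)
    # Photon noise can push near-zero pixels slightly negative after the
    # offset; clip so the pair satisfies the non-negativity contract.
    return ImagePair(
        uniform=np.maximum(i_u, 0.0),
        speckle=np.maximum(i_s, 0.0),
        pixel_size_um=model.pixel_size_um,
    )
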