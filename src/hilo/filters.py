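"""Radially symmetric Fourier-domain Gaussian filters.

All spatial frequencies are expressed in cycles/pixel, so the Nyquist
frequency of each axis is 0.5 and the largest radial frequency on a 2-D
grid is sqrt(2)/2.  Filters are pure real gains applied bin-by-bin to the
unnormalized forward FFT; the FFT convention therefore cancels out.

Three filter shapes are used by the HiLo reconstruction:

* a Gaussian high-pass ``HP`` with half-gain at its cut-off ``k_c``,
  HP(k) = 1 - exp(-k^2 / (2 s^2)) with s = k_c / sqrt(2 ln 2);
* its exact complement ``LP = 1 - HP``;
* a difference-of-Gaussians band-pass
  BP(k) = exp(-k^2 / (4 sigma^2)) - exp(-k^2 / (2 sigma^2)),
  which is zero at DC and peaks at 0.25 when k = 2 sigma sqrt(ln 2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, ParameterError, ShapeError

__all__ = [
    "FrequencyGrid",
    "FilterProfile",
    "build_frequency_grid",
    "gaussian_highpass",
    "lowpass_complement",
    "bandpass",
    "apply_filter",
    "highpass_gain",
    "lowpass_gain",
    "bandpass_gain",
]

_MIN_SIDE = 8
_MAX_SIGMA_BP = 0.5


def highpass_gain(k, k_c: float):
    """Scalar/array Gaussian high-pass gain with HP(k_c) = 1/2 exactly."""
    s2 = k_c * k_c / (2.0 * np.log(2.0))
    return 1.0 - np.exp(-np.square(k) / (2.0 * s2))


def lowpass_gain(k, k_c: float):
    """Complement of :func:`highpass_gain`; LP + HP = 1 identically."""
    return 1.0 - highpass_gain(k, k_c)


def bandpass_gain(k, sigma: float):
    """Difference-of-Gaussians band-pass gain."""
    k2 = np.square(k)
    return np.exp(-k2 / (4.0 * sigma * sigma)) - np.exp(-k2 / (2.0 * sigma * sigma))


@dataclass(frozen=True)
class FrequencyGrid:
    """Per-bin radial spatial frequency |k| for an (n_rows, n_cols) DFT.

    ``radial_frequency`` follows numpy's default FFT bin ordering (DC in
    the corner), so it can be multiplied directly onto ``np.fft.fft2``
    output.
    """

    n_rows: int
    n_cols: int
    radial_frequency: np.ndarray = field(repr=False)

    @property
    def bin_halfwidth(self) -> float:
        """Half of the coarser axis' frequency bin spacing."""
        return 0.5 * max(1.0 / self.n_rows, 1.0 / self.n_cols)


@dataclass(frozen=True)
class FilterProfile:
    """A radially symmetric gain evaluated on a :class:`FrequencyGrid`."""

    gains: np.ndarray = field(repr=False)
    kind: str  # "highpass" | "lowpass" | "bandpass"
    defining_parameter: float  # k_c for high/low-pass, sigma for band-pass
    grid: FrequencyGrid = field(repr=False)


def build_frequency_grid(n_rows: int, n_cols: int) -> FrequencyGrid:
    """Radial frequency magnitude grid in cycles/pixel.

    Bin (r, c) holds sqrt(f_r^2 + f_c^2) where f_r, f_c are the standard
    DFT frequencies for the respective axis lengths.
    """
    if n_rows < _MIN_SIDE or n_cols < _MIN_SIDE:
        raise ParameterError(
            f"grid dimensions must be >= {_MIN_SIDE}, got {(n_rows, n_cols)}"
        )
    fr = np.fft.fftfreq(n_rows)
    fc = np.fft.fftfreq(n_cols)
    radial = np.hypot(fr[:, None], fc[None, :])
    return FrequencyGrid(n_rows=n_rows, n_cols=n_cols, radial_frequency=radial)


def gaussian_highpass(grid: FrequencyGrid, k_c: float) -> FilterProfile:
    """Gaussian high-pass with half gain at the cut-off frequency ``k_c``."""
    if not 0.0 < k_c < 0.5:
        raise ParameterError(f"cut-off k_c must lie in (0, 0.5) cycles/pixel, got {k_c}")
    gains = highpass_gain(grid.radial_frequency, k_c)
    return FilterProfile(gains=gains, kind="highpass", defining_parameter=k_c, grid=grid)


def lowpass_complement(hp: FilterProfile) -> FilterProfile:
    """Exact per-bin complement LP = 1 - HP of a high-pass profile."""
    if hp.kind != "highpass":
        raise TypeError(f"lowpass_complement expects a highpass profile, got {hp.kind!r}")
    return FilterProfile(
        gains=1.0 - hp.gains,
        kind="lowpass",
        defining_parameter=hp.defining_parameter,
        grid=hp.grid,
    )


def bandpass(grid: FrequencyGrid, sigma_bp: float) -> FilterProfile:
    """Difference-of-Gaussians band-pass of width ``sigma_bp`` (cycles/pixel)."""
    if not 0.0 < sigma_bp <= _MAX_SIGMA_BP:
        raise ParameterError(
            f"band-pass sigma must lie in (0, {_MAX_SIGMA_BP}] cycles/pixel, got {sigma_bp}"
        )
    gains = bandpass_gain(grid.radial_frequency, sigma_bp)
    return FilterProfile(gains=gains, kind="bandpass", defining_parameter=sigma_bp, grid=grid)


def apply_filter(image: np.ndarray, profile: FilterProfile) -> np.ndarray:
    """Multiply an image's spectrum by a filter profile.

    Forward FFT, per-bin gain, inverse FFT; the (numerically negligible)
    imaginary residue is discarded.  Periodic boundary conditions are
    assumed; callers processing large frames tile with halos instead of
    padding here.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.shape != profile.gains.shape:
        raise ShapeError(
            f"image shape {image.shape} does not match filter grid "
            f"{profile.gains.shape}"
        )
    if not np.all(np.isfinite(image)):
        raise DataError("image contains non-finite values")
    spectrum = np.fft.fft2(image)
    return np.fft.ifft2(spectrum * profile.gains).real
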