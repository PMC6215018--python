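"""The HiLo reconstruction pipeline.

HiLo fuses two co-registered widefield images of the same field — one
under uniform illumination (``i_u``) and one under stationary laser
speckle (``i_s``) — into an optically sectioned image:

1. the difference image ``i_d = i_s - i_u`` removes specimen structure,
   leaving the illumination modulation;
2. a band-pass of ``i_d`` isolates speckle frequencies whose contrast
   decays with defocus;
3. a sliding-window contrast map ``C = sd/mu`` weights the uniform image,
   keeping in-focus low frequencies (``Lo``);
4. the high frequencies of ``i_u`` are inherently in focus (``Hi``);
5. ``i_HiLo = i_HP + eta * i_LP`` with ``eta`` chosen so the two spectra
   match at the cut-off frequency ``k_c``.

A single user parameter ``sigma`` sets the section thickness.  Section
thickness grows roughly linearly with sigma, and defocus makes speckle
contrast decay at a rate proportional to the band-pass frequency, so
sigma maps inversely onto the internal filter width:
``sigma_bp = 0.1 / sigma`` cycles/pixel (0.1 at the calibrated minimum
sigma = 1), ``k_c = 0.18 sigma_bp`` and window side
``window = 1 / (2 k_c)`` rounded to the nearest odd integer.  The
window therefore *widens* as sigma grows, which is also why speckle
leakage artifacts vanish at larger sigma.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .errors import (
    ConfigurationError,
    DataError,
    DegenerateSpectrumWarning,
    ParameterError,
    ShapeError,
)
from .filters import (
    FrequencyGrid,
    apply_filter,
    bandpass,
    build_frequency_grid,
    gaussian_highpass,
    lowpass_complement,
)

__all__ = [
    "ImagePair",
    "HiLoParams",
    "ContrastMap",
    "HiLoResult",
    "resolve_params",
    "difference_image",
    "local_contrast",
    "weighted_uniform",
    "compute_eta",
    "hilo_reconstruct",
]

#: Band-pass width at the calibrated minimum sigma = 1: 1/10 cycles/pixel,
#: the highest band frequency for which the section thickness still
#: responds linearly to sigma.  Larger sigma lowers the band frequency
#: (sigma_bp = SIGMA_BP_AT_UNIT / sigma), thickening the section.
SIGMA_BP_AT_UNIT = 0.1

#: Cut-off frequency as a fraction of the band-pass width.
KC_PER_SIGMA_BP = 0.18

#: Neighbourhoods whose local mean of i_u falls below this fraction of the
#: global mean carry no usable signal and get contrast 0.
MU_FLOOR_FRACTION = 1e-6


def _as_float_image(arr, name: str) -> np.ndarray:
    out = np.asarray(arr, dtype=np.float64)
    if out.ndim != 2:
        raise ShapeError(f"{name} must be 2-D, got shape {out.shape}")
    if not np.all(np.isfinite(out)):
        raise DataError(f"{name} contains non-finite values")
    return out


@dataclass
class ImagePair:
    """A co-registered uniform/speckle illumination image pair."""

    uniform: np.ndarray
    speckle: np.ndarray
    pixel_size_um: Optional[float] = None

    def __post_init__(self):
        self.uniform = _as_float_image(self.uniform, "uniform")
        self.speckle = _as_float_image(self.speckle, "speckle")
        if self.uniform.shape != self.speckle.shape:
            raise ShapeError(
                f"uniform {self.uniform.shape} and speckle {self.speckle.shape} "
                "images must have identical dimensions"
            )
        if np.any(self.uniform < 0) or np.any(self.speckle < 0):
            raise DataError("image values must be non-negative")
        if not np.any(self.uniform > 0):
            raise DataError("uniform image is identically zero")

    @property
    def shape(self):
        return self.uniform.shape


def _round_to_odd(x: float) -> int:
    """Nearest odd integer, at least 3 (windows must be centred)."""
    return max(3, 2 * int(round((x - 1.0) / 2.0)) + 1)


@dataclass(frozen=True)
class HiLoParams:
    """Resolved reconstruction parameters (build via :func:`resolve_params`)."""

    sigma_user: float
    sigma_bp: float  # cycles/pixel, Gaussian band-pass width
    k_c: float  # cycles/pixel, high/low-pass cut-off
    window_side: int  # pixels, odd, contrast-evaluation window
    eta_override: Optional[float] = None
    clamp_negative_output: bool = False


def resolve_params(
    sigma_user: float,
    *,
    sigma_bp: Optional[float] = None,
    k_c: Optional[float] = None,
    window_side: Optional[int] = None,
    eta_override: Optional[float] = None,
    clamp_negative_output: bool = False,
) -> HiLoParams:
    """Resolve the user sectioning parameter into concrete filter settings.

    ``sigma_user`` must be >= 1: below that calibrated minimum the
    thickness-versus-sigma response is no longer linear.  Keyword
    overrides replace individual derived fields after validation.
    """
    if sigma_user < 1.0:
        raise ParameterError(
            f"sigma must be >= 1 (the calibrated linear-regime minimum), got {sigma_user}"
        )
    if sigma_bp is None:
        sigma_bp = SIGMA_BP_AT_UNIT / sigma_user
    if sigma_bp <= 0:
        raise ParameterError(f"sigma_bp must be positive, got {sigma_bp}")
    if k_c is None:
        k_c = KC_PER_SIGMA_BP * sigma_bp
    if not 0.0 < k_c < 0.5:
        raise ParameterError(f"k_c must lie in (0, 0.5) cycles/pixel, got {k_c}")
    if window_side is None:
        window_side = _round_to_odd(1.0 / (2.0 * k_c))
    window_side = int(window_side)
    if window_side < 3 or window_side % 2 == 0:
        raise ParameterError(f"window_side must be an odd integer >= 3, got {window_side}")
    if eta_override is not None and eta_override <= 0:
        raise ParameterError(f"eta_override must be positive, got {eta_override}")
    return HiLoParams(
        sigma_user=float(sigma_user),
        sigma_bp=float(sigma_bp),
        k_c=float(k_c),
        window_side=window_side,
        eta_override=eta_override,
        clamp_negative_output=clamp_negative_output,
    )


def difference_image(pair: ImagePair) -> np.ndarray:
    """Speckle minus uniform; removes the specimen-induced bias.

    Signed values are retained — the residual is the illumination
    modulation around zero.
    """
    return pair.speckle - pair.uniform


@dataclass
class ContrastMap:
    """Local speckle contrast C = sd/mu evaluated in a sliding window."""

    values: np.ndarray
    window_side: int


def local_contrast(
    difference_bp: np.ndarray, uniform: np.ndarray, window_side: int
) -> ContrastMap:
    """Sliding-window contrast of the band-passed difference image.

    Per pixel, ``sd`` is the population standard deviation of
    ``difference_bp`` over a window_side x window_side neighbourhood and
    ``mu`` is the mean of the *uniform* image over the same neighbourhood
    (the difference image is zero-mean by construction, so normalising by
    the specimen brightness is what makes the quotient a contrast).
    Neighbourhoods with negligible uniform signal get contrast 0.  Edges
    use reflective padding.
    """
    difference_bp = np.asarray(difference_bp, dtype=np.float64)
    uniform = np.asarray(uniform, dtype=np.float64)
    if difference_bp.shape != uniform.shape:
        raise ShapeError(
            f"difference {difference_bp.shape} vs uniform {uniform.shape} shape mismatch"
        )
    if window_side % 2 == 0 or window_side < 3:
        raise ParameterError(f"window_side must be an odd integer >= 3, got {window_side}")
    if window_side >= min(difference_bp.shape):
        raise ConfigurationError(
            f"window_side {window_side} does not fit into image of shape "
            f"{difference_bp.shape}"
        )
    mean_d = ndimage.uniform_filter(difference_bp, size=window_side, mode="reflect")
    mean_d2 = ndimage.uniform_filter(difference_bp**2, size=window_side, mode="reflect")
    var = np.maximum(mean_d2 - mean_d**2, 0.0)
    sd = np.sqrt(var)
    mu = ndimage.uniform_filter(uniform, size=window_side, mode="reflect")
    mu_floor = MU_FLOOR_FRACTION * float(uniform.mean())
    values = np.where(mu > mu_floor, sd / np.where(mu > mu_floor, mu, 1.0), 0.0)
    return ContrastMap(values=values, window_side=window_side)


def weighted_uniform(uniform: np.ndarray, contrast: ContrastMap) -> np.ndarray:
    """Apply the contrast map as a weighting function to the uniform image."""
    uniform = np.asarray(uniform, dtype=np.float64)
    if uniform.shape != contrast.values.shape:
        raise ShapeError(
            f"uniform {uniform.shape} vs contrast {contrast.values.shape} shape mismatch"
        )
    return uniform * contrast.values


def _annulus_mean_magnitude(image: np.ndarray, grid: FrequencyGrid, k_c: float) -> float:
    mask = np.abs(grid.radial_frequency - k_c) <= grid.bin_halfwidth
    if not np.any(mask):
        raise ConfigurationError(
            f"no frequency bins within half a bin-width of k_c={k_c}; "
            "image too small for this cut-off"
        )
    spectrum = np.fft.fft2(image)
    return float(np.abs(spectrum[mask]).mean())


def compute_eta(
    highpassed_uniform: np.ndarray,
    lofreq: np.ndarray,
    k_c: float,
    grid: Optional[FrequencyGrid] = None,
) -> float:
    """Seam scaling factor between the Hi and Lo components.

    eta is the ratio of the azimuthally averaged spectral magnitudes of
    ``i_HP`` and ``i_LP`` over a one-bin-wide annulus at the cut-off
    frequency.  Point evaluation of the spectra at a single bin would be
    noise-dominated, so the annulus average is used as the stable
    estimator of the radial spectrum at ``k_c``.  If the Lo spectrum is
    degenerate (e.g. the speckle image equals the uniform image) eta
    falls back to 1 with a warning.
    """
    highpassed_uniform = np.asarray(highpassed_uniform, dtype=np.float64)
    lofreq = np.asarray(lofreq, dtype=np.float64)
    if highpassed_uniform.shape != lofreq.shape:
        raise ShapeError(
            f"i_HP {highpassed_uniform.shape} vs i_LP {lofreq.shape} shape mismatch"
        )
    if grid is None:
        grid = build_frequency_grid(*highpassed_uniform.shape)
    a_hp = _annulus_mean_magnitude(highpassed_uniform, grid, k_c)
    a_lp = _annulus_mean_magnitude(lofreq, grid, k_c)
    if a_lp <= 1e-15 + 1e-12 * a_hp:
        warnings.warn(
            "low-frequency spectrum at k_c is degenerate; eta set to 1",
            DegenerateSpectrumWarning,
            stacklevel=2,
        )
        return 1.0
    return a_hp / a_lp


@dataclass
class HiLoResult:
    """Sectioned image plus every intermediate of the reconstruction."""

    hilo: np.ndarray
    difference: np.ndarray
    highpassed_uniform: np.ndarray
    lofreq: np.ndarray
    weighted_uniform: np.ndarray
    contrast: ContrastMap
    eta: float
    params: HiLoParams
    warnings: list = field(default_factory=list)


def hilo_reconstruct(pair: ImagePair, params: HiLoParams) -> HiLoResult:
    """Full HiLo reconstruction of an image pair.

    Executes, in order: difference image, band-pass, local contrast,
    contrast weighting, low-pass (Lo), high-pass of the uniform image
    (Hi), seam factor eta, and the fusion ``i_HP + eta * i_LP``.  All
    intermediates are retained on the result; negative output values are
    kept unless ``params.clamp_negative_output`` is set.
    """
    n_rows, n_cols = pair.shape
    grid = build_frequency_grid(n_rows, n_cols)
    hp = gaussian_highpass(grid, params.k_c)
    lp = lowpass_complement(hp)
    bp = bandpass(grid, params.sigma_bp)

    i_d = difference_image(pair)
    d_bp = apply_filter(i_d, bp)
    contrast = local_contrast(d_bp, pair.uniform, params.window_side)
    i_su = weighted_uniform(pair.uniform, contrast)
    i_lp = apply_filter(i_su, lp)
    i_hp = apply_filter(pair.uniform, hp)

    caught: list = []
    if params.eta_override is not None:
        eta = params.eta_override
    else:
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            eta = compute_eta(i_hp, i_lp, params.k_c, grid)
        for w in wlist:
            caught.append(str(w.message))
            warnings.warn_explicit(
                w.message, w.category, w.filename, w.lineno
            )

    hilo = i_hp + eta * i_lp
    if params.clamp_negative_output:
        hilo = np.maximum(hilo, 0.0)

    return HiLoResult(
        hilo=hilo,
        difference=i_d,
        highpassed_uniform=i_hp,
        lofreq=i_lp,
        weighted_uniform=i_su,
        contrast=contrast,
        eta=eta,
        params=params,
        warnings=caught,
    )
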