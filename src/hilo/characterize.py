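"""Measurement procedures: section thickness, contrast, speckle leakage.

The optical section thickness of a reconstruction is measured the way it
is measured on a physical system: a thin fluorescent layer is imaged at a
known tilt, the in-focus strip's lateral FWHM is obtained from Gaussian
fits to one-pixel-thick horizontal line profiles, and the tilt converts
lateral pixels into axial microns.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import pearsonr

from .core import HiLoParams, ImagePair, hilo_reconstruct, resolve_params
from .errors import (
    DegenerateGeometryWarning,
    FitError,
    ParameterError,
    ShapeError,
    SpeckleLeakageWarning,
)
from .filters import apply_filter, build_frequency_grid, gaussian_highpass
from .simulate import TiltGeometry

__all__ = [
    "SectionMeasurement",
    "fit_line_fwhm",
    "section_thickness",
    "sigma_sweep",
    "contrast_ratio",
    "speckle_leakage",
    "measurement_report",
]

_GAUSS_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))

#: High-passed HiLo/speckle correlation above which leakage is flagged.
LEAKAGE_SCORE_THRESHOLD = 0.2

#: Minimum imaged grains per contrast-window side for a safe reconstruction.
GRAINS_PER_WINDOW = 3.0


@dataclass
class SectionMeasurement:
    """Optical section thickness from tilted-layer line fits."""

    per_line_fwhm_px: List[float]
    mean_thickness_um: float
    sd_thickness_um: float
    geometry: TiltGeometry
    pixel_size_um: float
    rows: List[int]


def _gauss_baseline(x, amp, x0, w, baseline):
    return amp * np.exp(-((x - x0) ** 2) / (2.0 * w * w)) + baseline


def fit_line_fwhm(image: np.ndarray, row: int) -> float:
    """Lateral FWHM (pixels) of a Gaussian fit to one row of an image.

    Fits amplitude * exp(-(x - x0)^2 / (2 w^2)) + baseline by least
    squares to the one-pixel-thick row profile, initialised from the
    profile's maximum, centroid and second moment.  The peak must rise at
    least 3 noise standard deviations above the baseline.
    """
    image = np.asarray(image, dtype=np.float64)
    if not 0 <= row < image.shape[0]:
        raise ParameterError(f"row {row} outside image of {image.shape[0]} rows")
    profile = image[row].astype(np.float64)
    x = np.arange(profile.size, dtype=np.float64)

    baseline0 = float(np.percentile(profile, 10))
    # robust noise estimate from first differences (peak-insensitive)
    diffs = np.diff(profile)
    noise_sd = float(1.4826 * np.median(np.abs(diffs - np.median(diffs))) / np.sqrt(2.0))
    amp0 = float(profile.max() - baseline0)
    if amp0 <= 3.0 * max(noise_sd, 1e-30) or amp0 <= 0:
        raise FitError(f"row {row}: no prominent peak above the noise floor")

    # Initialise from a lightly smoothed copy so single-pixel speckle
    # residue cannot hijack the moments; the fit itself uses raw data.
    from scipy.ndimage import uniform_filter1d

    smooth = uniform_filter1d(profile, size=5, mode="nearest")
    weights = np.clip(smooth - baseline0 - 0.25 * amp0, 0.0, None)
    if weights.sum() <= 0:
        weights = np.clip(smooth - baseline0, 0.0, None)
    x0 = float((weights * x).sum() / weights.sum())
    var = float((weights * (x - x0) ** 2).sum() / weights.sum())
    w0 = float(np.clip(np.sqrt(var), 1.0, profile.size / 2))

    n = profile.size
    try:
        popt, _ = curve_fit(
            _gauss_baseline,
            x,
            profile,
            p0=[amp0, x0, w0, baseline0],
            bounds=(
                [0.0, 0.0, 0.5, -np.inf],
                [np.inf, float(n - 1), float(n), np.inf],
            ),
            maxfev=10000,
        )
    except RuntimeError as exc:  # pragma: no cover - depends on data
        raise FitError(f"row {row}: Gaussian fit did not converge") from exc
    amp, _, w, _ = popt
    if amp <= 0 or not np.isfinite(w):
        raise FitError(f"row {row}: degenerate Gaussian fit")
    return float(_GAUSS_FWHM * abs(w))


def section_thickness(
    hilo_image: np.ndarray,
    geometry: TiltGeometry,
    pixel_size_um: float,
    n_lines: int = 5,
) -> SectionMeasurement:
    """Optical section thickness from the tilted-layer strip.

    ``n_lines`` rows, evenly spaced within the central 50% of image rows,
    are fitted individually; each lateral FWHM is converted to axial
    microns via the tilt and the mean and standard deviation over lines
    are reported.
    """
    hilo_image = np.asarray(hilo_image, dtype=np.float64)
    if n_lines < 1:
        raise ParameterError(f"n_lines must be >= 1, got {n_lines}")
    ny = hilo_image.shape[0]
    rows = np.unique(np.round(np.linspace(0.25 * ny, 0.75 * ny, n_lines)).astype(int))
    if geometry.slope == 0.0:
        warnings.warn(
            "zero tilt: lateral widths convert to 0 um axial thickness",
            DegenerateGeometryWarning,
            stacklevel=2,
        )
    fwhms = []
    for r in rows:
        try:
            fwhms.append(fit_line_fwhm(hilo_image, int(r)))
        except FitError as exc:
            raise FitError(f"line fit failed at row {r}: {exc}") from exc
    factor = pixel_size_um * geometry.slope
    thickness = np.asarray(fwhms) * factor
    return SectionMeasurement(
        per_line_fwhm_px=[float(f) for f in fwhms],
        mean_thickness_um=float(thickness.mean()),
        sd_thickness_um=float(thickness.std()),
        geometry=geometry,
        pixel_size_um=pixel_size_um,
        rows=[int(r) for r in rows],
    )


def sigma_sweep(
    pair: ImagePair,
    geometry: TiltGeometry,
    pixel_size_um: float,
    sigma_list: Sequence[float],
    n_lines: int = 5,
    clamp_negative_output: bool = True,
) -> List[Tuple[float, SectionMeasurement]]:
    """Reprocess one raw pair at several sigma settings and measure each.

    The same acquisition is reused throughout — section thickness is a
    property of the processing, so no reacquisition is needed.
    """
    sig = list(sigma_list)
    if sig != sorted(sig) or (sig and sig[0] < 1.0):
        raise ParameterError("sigma_list must be ascending with all values >= 1")
    out = []
    for s in sig:
        params = resolve_params(s, clamp_negative_output=clamp_negative_output)
        result = hilo_reconstruct(pair, params)
        out.append((float(s), section_thickness(result.hilo, geometry, pixel_size_um, n_lines)))
    return out


def contrast_ratio(
    image: np.ndarray, column: int, row_range: Optional[Tuple[int, int]] = None
) -> float:
    """Peak-to-minimum ratio along a one-pixel vertical line.

    The contrast of a line profile is its maximum divided by its minimum
    (the out-of-focus background).  The minimum must be positive; callers
    should subtract any camera offset first or keep the offset in both
    images being compared.
    """
    image = np.asarray(image, dtype=np.float64)
    if not 0 <= column < image.shape[1]:
        raise ParameterError(f"column {column} outside image of {image.shape[1]} columns")
    r0, r1 = (0, image.shape[0]) if row_range is None else row_range
    if not (0 <= r0 < r1 <= image.shape[0]):
        raise ParameterError(f"row range {(r0, r1)} outside image of {image.shape[0]} rows")
    profile = image[r0:r1, column]
    lo = float(profile.min())
    if lo <= 0:
        raise ParameterError(
            "line minimum is not positive; subtract the camera offset upstream "
            "or enable output clamping with a pedestal"
        )
    return float(profile.max() / lo)


def speckle_leakage(
    hilo_image: np.ndarray,
    speckle_pattern: np.ndarray,
    window_side: int,
    grain_px: float,
) -> Tuple[float, bool]:
    """Score how much illumination structure leaked into the output.

    Both the reconstruction and the raw speckle pattern are high-pass
    filtered at the grain frequency (1/grain_px, capped just below
    Nyquist) and their Pearson correlation is the leakage score.  The
    warning flag is set when the score exceeds 0.2 or when the contrast
    window holds fewer than ~3 grains per side — the regime in which the
    weighting function follows the imaged speckle instead of the
    specimen.
    """
    hilo_image = np.asarray(hilo_image, dtype=np.float64)
    speckle_pattern = np.asarray(speckle_pattern, dtype=np.float64)
    if hilo_image.shape != speckle_pattern.shape:
        raise ShapeError(
            f"image {hilo_image.shape} vs speckle {speckle_pattern.shape} shape mismatch"
        )
    if grain_px <= 0:
        raise ParameterError(f"grain_px must be positive, got {grain_px}")
    k_grain = min(1.0 / grain_px, 0.45)
    grid = build_frequency_grid(*hilo_image.shape)
    hp = gaussian_highpass(grid, k_grain)
    a = apply_filter(hilo_image, hp).ravel()
    b = apply_filter(speckle_pattern, hp).ravel()
    score = float(pearsonr(a, b).statistic)
    undersampled = window_side < GRAINS_PER_WINDOW * grain_px
    flagged = bool(score > LEAKAGE_SCORE_THRESHOLD or undersampled)
    if flagged:
        warnings.warn(
            f"speckle leakage risk: score={score:.3f}, window={window_side}px, "
            f"grain={grain_px}px",
            SpeckleLeakageWarning,
            stacklevel=2,
        )
    return score, flagged


def measurement_report(
    sweep: Sequence[Tuple[float, SectionMeasurement]],
    contrast: Optional[dict] = None,
    leakage: Optional[dict] = None,
    path=None,
) -> dict:
    """Bundle measurements into a plain JSON-serializable report."""
    report = {
        "sections": [
            {
                "sigma": s,
                "thickness_um": m.mean_thickness_um,
                "sd_um": m.sd_thickness_um,
                "per_line_fwhm_px": m.per_line_fwhm_px,
                "rows": m.rows,
            }
            for s, m in sweep
        ]
    }
    if contrast is not None:
        report["contrast"] = contrast
    if leakage is not None:
        report["leakage"] = leakage
    if path is not None:
        with open(path, "w") as fh:
            json.dump(report, fh, indent=2)
    return report
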