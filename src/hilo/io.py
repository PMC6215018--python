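"""TIFF I/O, stack pairing and tiled processing of very large frames.

Camera frames from a mesoscope reach hundreds of megapixels; whole-frame
FFTs at that size are memory-hostile, so the reconstruction can run on
halo-padded tiles whose cores are stitched back together.  The seam
factor eta is a global spectral constant and is computed once per frame
(on a block-averaged pass when the frame is large), never per tile —
per-tile values would create visible brightness steps between tiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple, Union

import numpy as np
import tifffile

from .core import (
    ContrastMap,
    HiLoParams,
    HiLoResult,
    ImagePair,
    hilo_reconstruct,
    resolve_params,
)
from .errors import ConfigurationError, FormatError, PairingError, ShapeError

__all__ = [
    "ImageMetadata",
    "StackEntry",
    "StackManifest",
    "read_image",
    "write_image",
    "pair_stacks",
    "tiled_reconstruct",
    "required_halo",
]

_TIFF_SUFFIXES = (".tif", ".tiff")

#: Frames whose longest side exceeds this are block-averaged before the
#: global eta pass.
ETA_DECIMATION_THRESHOLD = 1024


@dataclass(frozen=True)
class ImageMetadata:
    bit_depth: int
    dtype: str
    n_pages: int
    resolution: Optional[tuple] = None


def read_image(path) -> Tuple[List[np.ndarray], ImageMetadata]:
    """Read a single- or multi-page grayscale TIFF.

    Returns the pages in order as float64 rasters (integer inputs are
    preserved exactly) plus metadata with the bit depth and any
    resolution tags.  RGB/multi-sample files are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    with tifffile.TiffFile(path) as tf:
        pages = []
        resolution = None
        for page in tf.pages:
            if page.samplesperpixel != 1:
                raise FormatError(
                    f"{path}: SamplesPerPixel={page.samplesperpixel} — only "
                    "grayscale TIFF is supported"
                )
            arr = page.asarray()
            if arr.ndim != 2:
                raise FormatError(f"{path}: page is not a 2-D raster (shape {arr.shape})")
            pages.append(np.asarray(arr, dtype=np.float64))
            if resolution is None and "XResolution" in page.tags:
                xres = page.tags["XResolution"].value
                yres = page.tags.get("YResolution")
                resolution = (xres, yres.value if yres else None)
        dtype = tf.pages[0].dtype
    meta = ImageMetadata(
        bit_depth=dtype.itemsize * 8,
        dtype=str(dtype),
        n_pages=len(pages),
        resolution=resolution,
    )
    return pages, meta


def write_image(path, image: np.ndarray, dtype: str = "float32") -> None:
    """Write a raster as TIFF.

    Default is 32-bit float with no rescaling, preserving the linear
    Hi + eta*Lo identity for downstream checks.  ``dtype='uint16'``
    applies a global min-max normalization to the full integer range.
    """
    image = np.asarray(image)
    if dtype == "float32":
        tifffile.imwrite(path, image.astype(np.float32))
    elif dtype == "uint16":
        lo, hi = float(image.min()), float(image.max())
        scale = 65535.0 / (hi - lo) if hi > lo else 0.0
        tifffile.imwrite(path, ((image - lo) * scale).astype(np.uint16))
    else:
        raise FormatError(f"unsupported output dtype {dtype!r}")


@dataclass(frozen=True)
class StackEntry:
    z_index: int
    uniform_path: Path
    speckle_path: Path
    uniform_page: int = 0
    speckle_page: int = 0


@dataclass
class StackManifest:
    """An ordered list of co-registered uniform/speckle slice sources."""

    entries: List[StackEntry]
    pixel_size_um: Optional[float] = None
    bit_depth: Optional[int] = None
    sigma_user: Optional[float] = None
    tile_spec: Optional[Tuple[int, int]] = None  # (tile_side, halo)

    def load_pair(self, entry: StackEntry) -> ImagePair:
        u_pages, _ = read_image(entry.uniform_path)
        s_pages, _ = read_image(entry.speckle_path)
        return ImagePair(
            uniform=u_pages[entry.uniform_page],
            speckle=s_pages[entry.speckle_page],
            pixel_size_um=self.pixel_size_um,
        )


def _list_tiffs(directory: Path) -> List[Path]:
    return sorted(p for p in directory.iterdir() if p.suffix.lower() in _TIFF_SUFFIXES)


def _page_shapes(path: Path) -> List[tuple]:
    with tifffile.TiffFile(path) as tf:
        return [tuple(p.shape) for p in tf.pages]


def pair_stacks(
    uniform_source: Union[str, Path], speckle_source: Union[str, Path]
) -> StackManifest:
    """Match uniform and speckle sources into a z-ordered manifest.

    Each source is either a directory of single-page TIFFs (matched in
    sorted filename order) or one multi-page TIFF (matched page by
    page).  Counts must agree and every matched pair must share its
    dimensions.
    """
    u, s = Path(uniform_source), Path(speckle_source)
    entries: List[StackEntry] = []
    if u.is_dir() and s.is_dir():
        u_files, s_files = _list_tiffs(u), _list_tiffs(s)
        if len(u_files) != len(s_files):
            raise PairingError(
                f"count mismatch: {len(u_files)} uniform vs {len(s_files)} speckle "
                f"files (uniform: {[p.name for p in u_files]}, "
                f"speckle: {[p.name for p in s_files]})"
            )
        if not u_files:
            raise PairingError(f"no TIFF files found in {u}")
        for z, (uf, sf) in enumerate(zip(u_files, s_files)):
            if _page_shapes(uf)[0] != _page_shapes(sf)[0]:
                raise ShapeError(
                    f"dimension mismatch at z={z}: {uf.name} {_page_shapes(uf)[0]} "
                    f"vs {sf.name} {_page_shapes(sf)[0]}"
                )
            entries.append(StackEntry(z, uf, sf))
        bit_depth = read_image(u_files[0])[1].bit_depth
    elif u.is_file() and s.is_file():
        u_shapes, s_shapes = _page_shapes(u), _page_shapes(s)
        if len(u_shapes) != len(s_shapes):
            raise PairingError(
                f"page count mismatch: {len(u_shapes)} uniform vs {len(s_shapes)} speckle"
            )
        for z, (us, ss) in enumerate(zip(u_shapes, s_shapes)):
            if us != ss:
                raise ShapeError(f"dimension mismatch at z={z}: {us} vs {ss}")
            entries.append(StackEntry(z, u, s, uniform_page=z, speckle_page=z))
        bit_depth = read_image(u)[1].bit_depth
    else:
        raise PairingError(
            "sources must be two directories or two (multi-page) TIFF files"
        )
    return StackManifest(entries=entries, bit_depth=bit_depth)


# ---------------------------------------------------------------------------
# tiled processing


def _min_frequency_sd(params: HiLoParams) -> float:
    """Smallest frequency-domain Gaussian sd among the HP/LP/BP filters."""
    hp_sd = params.k_c / math.sqrt(2.0 * math.log(2.0))
    return min(hp_sd, params.sigma_bp)


def required_halo(params: HiLoParams) -> int:
    """Minimum halo: window side plus 3 sd of the widest spatial kernel."""
    s_max_px = 1.0 / (2.0 * math.pi * _min_frequency_sd(params))
    return params.window_side + math.ceil(3.0 * s_max_px)


def _block_mean(image: np.ndarray, factor: int) -> np.ndarray:
    ny, nx = image.shape
    ny2, nx2 = ny - ny % factor, nx - nx % factor
    v = image[:ny2, :nx2].reshape(ny2 // factor, factor, nx2 // factor, factor)
    return v.mean(axis=(1, 3))


def _global_eta(pair: ImagePair, params: HiLoParams) -> float:
    """Frame-wide eta, from a block-averaged pass on very large frames."""
    longest = max(pair.shape)
    factor = max(1, math.ceil(longest / ETA_DECIMATION_THRESHOLD))
    if factor == 1:
        return hilo_reconstruct(pair, params).eta
    dec = ImagePair(
        uniform=_block_mean(pair.uniform, factor),
        speckle=_block_mean(pair.speckle, factor),
        pixel_size_um=pair.pixel_size_um,
    )
    # frequencies in cycles/pixel scale by the decimation factor
    dec_params = resolve_params(
        params.sigma_user,
        sigma_bp=min(params.sigma_bp * factor, 1.0),
        k_c=min(params.k_c * factor, 0.45),
        clamp_negative_output=params.clamp_negative_output,
    )
    return hilo_reconstruct(dec, dec_params).eta


def tiled_reconstruct(
    pair: ImagePair, params: HiLoParams, tile_side: int, halo: int
) -> HiLoResult:
    """HiLo reconstruction on halo-padded tiles, stitched seamlessly.

    ``tile_side`` is the stitched core size; each tile is processed on a
    core + 2*halo window (image edges reflected) and only the core is
    kept.  The halo must cover the contrast window plus the slowest
    spatial filter tail, and eta is computed once globally so tiles share
    one seam factor.  If a single tile covers the image the plain
    full-frame path is used.
    """
    min_halo = required_halo(params)
    if halo < min_halo:
        raise ConfigurationError(
            f"halo {halo} px is below the required minimum {min_halo} px "
            f"(window {params.window_side} + filter tails)"
        )
    if tile_side < 4 * halo:
        raise ConfigurationError(
            f"tile_side {tile_side} must be at least 4x the halo ({4 * halo})"
        )
    ny, nx = pair.shape
    if tile_side >= ny and tile_side >= nx:
        return hilo_reconstruct(pair, params)

    eta = _global_eta(pair, params)
    tile_params = resolve_params(
        params.sigma_user,
        sigma_bp=params.sigma_bp,
        k_c=params.k_c,
        window_side=params.window_side,
        eta_override=eta,
        clamp_negative_output=params.clamp_negative_output,
    )

    pad_u = np.pad(pair.uniform, halo, mode="reflect")
    pad_s = np.pad(pair.speckle, halo, mode="reflect")

    fields = [
        "hilo",
        "difference",
        "highpassed_uniform",
        "lofreq",
        "weighted_uniform",
    ]
    out = {f: np.zeros((ny, nx)) for f in fields}
    out_contrast = np.zeros((ny, nx))

    for r0 in range(0, ny, tile_side):
        for c0 in range(0, nx, tile_side):
            r1, c1 = min(r0 + tile_side, ny), min(c0 + tile_side, nx)
            sl = (slice(r0, r1 + 2 * halo), slice(c0, c1 + 2 * halo))
            if not np.any(pad_u[sl] > 0):
                continue  # fully dark tile: every output stays 0
            tile_pair = ImagePair(
                uniform=pad_u[sl],
                speckle=np.maximum(pad_s[sl], 0.0),
                pixel_size_um=pair.pixel_size_um,
            )
            res = hilo_reconstruct(tile_pair, tile_params)
            core = (slice(halo, halo + (r1 - r0)), slice(halo, halo + (c1 - c0)))
            dest = (slice(r0, r1), slice(c0, c1))
            for f in fields:
                out[f][dest] = getattr(res, f)[core]
            out_contrast[dest] = res.contrast.values[core]

    return HiLoResult(
        hilo=out["hilo"],
        difference=out["difference"],
        highpassed_uniform=out["highpassed_uniform"],
        lofreq=out["lofreq"],
        weighted_uniform=out["weighted_uniform"],
        contrast=ContrastMap(values=out_contrast, window_side=params.window_side),
        eta=eta,
        params=params,
        warnings=[],
    )
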