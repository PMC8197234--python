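"""Mask-based preprocessing: the five input-preparation configurations.

Each configuration turns a (image, mask) pair into a model-ready real-valued
patch:

1. whole-cell mask -> RGB-fraction colour normalisation -> centre & resize
2. whole-cell mask -> centre & resize -> per-channel z-score over foreground
3. raw patch, 8-bit values rescaled to [0, 1] (background kept)
4. whole-cell mask only, rescaled to [0, 1]
5. nucleus-only mask -> centre & resize -> z-score

Configurations 2 and 5 z-score after the geometric transform so the
zero-mean / unit-variance contract holds exactly on the delivered pixels;
statistics are computed over foreground pixels only, making them independent
of how much zero background surrounds the cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from monoclass.synthetic_cells import CellRecord

BACKGROUND, CYTOPLASM, NUCLEUS = 0, 1, 2

_CONFIG_TABLE = {
    1: ("whole-cell", "rgb-fraction"),
    2: ("whole-cell", "z-score"),
    3: ("none", "rescale"),
    4: ("whole-cell", "rescale"),
    5: ("nucleus-only", "z-score"),
}


@dataclass(frozen=True)
class PreprocessConfig:
    """One of the five named configurations; the id fixes mask region and
    normalisation, only the output geometry is free."""

    config_id: int
    target_size: int = 200

    def __post_init__(self) -> None:
        if self.config_id not in _CONFIG_TABLE:
            raise ValueError(f"config_id must be one of {sorted(_CONFIG_TABLE)}")
        if self.target_size < 2:
            raise ValueError("target_size must be >= 2")

    @property
    def mask_region(self) -> str:
        return _CONFIG_TABLE[self.config_id][0]

    @property
    def normalization(self) -> str:
        return _CONFIG_TABLE[self.config_id][1]


@dataclass
class PreparedPatch:
    """Model-ready patch: real-valued pixels, a boolean foreground grid
    (pixels outside it are exactly 0), and provenance."""

    pixels: np.ndarray      # target_size x target_size x 3 float
    foreground: np.ndarray  # target_size x target_size bool
    provenance: tuple[str, int]


class EmptyRegionError(ValueError):
    """Raised when masking retains no pixels."""


def apply_mask(image: np.ndarray, mask: np.ndarray, region: str = "whole-cell"):
    """Zero out pixels outside the requested mask region.

    ``whole-cell`` keeps cytoplasm + nucleus; ``nucleus-only`` keeps the
    nucleus.  Returns (masked image as float, boolean foreground grid).
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask)
    if image.shape[:2] != mask.shape:
        raise ValueError(f"image {image.shape[:2]} and mask {mask.shape} shapes differ")
    if region == "whole-cell":
        foreground = mask > BACKGROUND
    elif region == "nucleus-only":
        foreground = mask == NUCLEUS
    else:
        raise ValueError(f"unknown mask region {region!r}")
    if not foreground.any():
        raise EmptyRegionError(f"mask retains no pixels for region {region!r}")
    out = np.where(foreground[..., None], image, 0.0)
    return out, foreground


def color_normalize(image: np.ndarray, foreground: np.ndarray) -> np.ndarray:
    """Replace each foreground pixel's channels by their fraction of R+G+B.

    Background stays 0; pixels whose channel sum is 0 map to 0.
    """
    image = np.asarray(image, dtype=float)
    if np.any(image < 0):
        raise ValueError("color_normalize expects nonnegative pixel values")
    total = image.sum(axis=2, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(total > 0, image / total, 0.0)
    return np.where(np.asarray(foreground, bool)[..., None], frac, 0.0)


def zscore(image: np.ndarray, foreground: np.ndarray) -> np.ndarray:
    """Standardise each channel to zero mean / unit SD over the foreground.

    Population SD (n denominator); background pixels remain 0; a constant
    channel maps to all zeros.
    """
    image = np.asarray(image, dtype=float)
    fg = np.asarray(foreground, bool)
    if fg.sum() < 2:
        raise ValueError("z-scoring needs at least 2 foreground pixels")
    out = np.zeros_like(image)
    vals = image[fg]                       # n_fg x 3
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0)                  # population SD
    scaled = np.where(sd > 0, (vals - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    out[fg] = scaled
    return out


def center_and_resize(image: np.ndarray, foreground: np.ndarray, target_size: int):
    """Centre the foreground bounding box and isotropically fit it to the patch.

    The bounding-box crop is scaled preserving aspect ratio so its longer
    side equals ``target_size``, then zero-padded to target_size^2 with the
    content centred.  The image is interpolated bilinearly, the foreground
    grid nearest-neighbour; pixels outside the transformed foreground are
    re-zeroed so the background-zero contract survives interpolation.
    Returns (image, foreground).
    """
    fg = np.asarray(foreground, bool)
    if not fg.any():
        raise EmptyRegionError("cannot centre an empty foreground")
    image = np.asarray(image, dtype=float)
    rows = np.flatnonzero(fg.any(axis=1))
    cols = np.flatnonzero(fg.any(axis=0))
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    crop = image[r0:r1, c0:c1]
    crop_fg = fg[r0:r1, c0:c1]

    h, w = crop.shape[:2]
    scale = target_size / max(h, w)
    nh, nw = max(1, round(h * scale)), max(1, round(w * scale))
    crop = resize(crop, (nh, nw), order=1, mode="constant", cval=0.0,
                  anti_aliasing=scale < 1, preserve_range=True)
    crop_fg = resize(crop_fg.astype(float), (nh, nw), order=0, mode="constant",
                     cval=0.0, preserve_range=True) > 0.5

    out = np.zeros((target_size, target_size, 3), dtype=float)
    out_fg = np.zeros((target_size, target_size), dtype=bool)
    top = (target_size - nh) // 2
    left = (target_size - nw) // 2
    out[top:top + nh, left:left + nw] = crop
    out_fg[top:top + nh, left:left + nw] = crop_fg
    out[~out_fg] = 0.0
    return out, out_fg


def run_configuration(record: CellRecord, config: PreprocessConfig) -> PreparedPatch:
    """Apply one named configuration to a cell record."""
    image = np.asarray(record.image, dtype=float)
    if config.mask_region == "none":
        pixels = image / 255.0
        fg = np.ones(image.shape[:2], dtype=bool)
        if pixels.shape[0] != config.target_size:
            pixels, fg = center_and_resize(pixels, fg, config.target_size)
        return PreparedPatch(pixels, fg, (record.cell_id, config.config_id))

    if record.mask is None:
        raise ValueError(f"configuration {config.config_id} needs a mask "
                         f"(cell {record.cell_id})")
    try:
        masked, fg = apply_mask(image, record.mask, config.mask_region)
    except EmptyRegionError as e:
        raise EmptyRegionError(f"cell {record.cell_id}: {e}") from e

    cid = config.config_id
    if cid == 1:
        masked = color_normalize(masked, fg)
        pixels, fg = center_and_resize(masked, fg, config.target_size)
        # interpolation at the foreground edge mixes in zero background;
        # renormalising is a no-op on interior pixels and restores the
        # channel-sum-to-one contract at the edge
        pixels = color_normalize(pixels, fg)
    elif cid in (2, 5):
        pixels, fg = center_and_resize(masked, fg, config.target_size)
        pixels = zscore(pixels, fg)
    else:  # config 4: masked raw patch rescaled, no geometric transform
        pixels = masked / 255.0
        if pixels.shape[0] != config.target_size:
            pixels, fg = center_and_resize(pixels, fg, config.target_size)
    return PreparedPatch(pixels, fg, (record.cell_id, cid))
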