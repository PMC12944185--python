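"""Standardized radiomics feature extraction from a tumor ROI.

For one intensity image + mask, the extractor produces:

* 14 shape features of the (resampled) mask — ``original_shape_*``;
* 18 first-order and 75 texture features (GLCM 24, GLDM 14, GLRLM 16,
  GLSZM 16, NGTDM 5) on the original image — ``original_<class>_*``;
* the same 93 intensity/texture features on each of the 8 undecimated
  wavelet bands — ``wavelet-LLL_<class>_*`` .. ``wavelet-HHH_<class>_*``;

851 features in total per image, with deterministic column order.
"""

from __future__ import annotations

import warnings
from collections import OrderedDict
from dataclasses import dataclass, field

import numpy as np

from .firstorder import firstorder_features
from .preprocess import WAVELET_BAND_NAMES, discretize, resample, wavelet_bands
from .shape import shape_features
from .texture import (
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)

TEXTURE_CLASSES = ("glcm", "gldm", "glrlm", "glszm", "ngtdm")
DEFAULT_FEATURE_CLASSES = ("firstorder", "shape") + TEXTURE_CLASSES

EXPECTED_FEATURE_COUNT = 851  # 14 shape + 9 images x (18 first-order + 75 texture)


@dataclass
class ExtractionConfig:
    """Extraction settings.

    ``bin_width`` is in the intensity units of the image it is applied to;
    the default of 5 suits raw MR signal but is far too coarse for kinetic
    maps whose values are orders of magnitude smaller — use per-source
    widths there (a warning is issued when a source yields < 4 levels).
    """

    target_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    bin_width: float = 5.0
    wavelet: str = "coif1"
    wavelet_mode: str = "mirror"
    feature_classes: tuple[str, ...] = DEFAULT_FEATURE_CLASSES
    gldm_alpha: int = 0
    pad_voxels: int = 8  # bounding-box margin so wavelet support sees context

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if any(s <= 0 for s in self.target_spacing):
            raise ValueError("target_spacing must be positive")
        unknown = set(self.feature_classes) - set(DEFAULT_FEATURE_CLASSES)
        if unknown:
            raise ValueError(f"unknown feature classes: {sorted(unknown)}")


class DegenerateROIError(ValueError):
    """ROI too small to support texture analysis."""


def _crop_to_mask(image: np.ndarray, mask: np.ndarray, pad: int):
    idx = np.argwhere(mask)
    lo = np.maximum(idx.min(axis=0) - pad, 0)
    hi = np.minimum(idx.max(axis=0) + pad + 1, mask.shape)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    return image[sl], mask[sl]


def _intensity_features(
    image: np.ndarray,
    mask: np.ndarray,
    config: ExtractionConfig,
    voxel_volume: float,
    classes: tuple[str, ...],
) -> "OrderedDict[str, float]":
    values = image[mask]
    levels_flat = discretize(values, config.bin_width)
    levels = np.zeros(image.shape, dtype=np.int64)
    levels[mask] = levels_flat

    out: OrderedDict[str, float] = OrderedDict()
    calculators = {
        "firstorder": lambda: firstorder_features(values, levels_flat, voxel_volume),
        "glcm": lambda: glcm_features(levels),
        "gldm": lambda: gldm_features(levels, config.gldm_alpha),
        "glrlm": lambda: glrlm_features(levels),
        "glszm": lambda: glszm_features(levels),
        "ngtdm": lambda: ngtdm_features(levels),
    }
    for cls in ("firstorder",) + TEXTURE_CLASSES:
        if cls in classes:
            for name, val in sorted(calculators[cls]().items()):
                out[f"{cls}_{name}"] = float(val)
    return out


def extract_features(
    image: np.ndarray,
    mask: np.ndarray,
    spacing,
    config: ExtractionConfig | None = None,
) -> "OrderedDict[str, float]":
    """Extract the full feature set from one image/mask pair.

    The pair is resampled to ``config.target_spacing`` first; shape
    features describe the resampled mask; intensity/texture features are
    computed on the original image and on each wavelet band.
    """
    config = config or ExtractionConfig()
    mask = np.asarray(mask) > 0
    if mask.sum() < 2:
        raise DegenerateROIError("mask has fewer than 2 voxels")
    image_r, mask_r = resample(image, mask, spacing, config.target_spacing)
    mask_r = mask_r > 0
    if mask_r.sum() < 2:
        raise DegenerateROIError("mask has fewer than 2 voxels after resampling")
    image_c, mask_c = _crop_to_mask(image_r, mask_r, config.pad_voxels)
    voxel_volume = float(np.prod(config.target_spacing))

    n_levels = len(np.unique(discretize(image_c[mask_c], config.bin_width)))
    if n_levels < 4:
        warnings.warn(
            f"bin width {config.bin_width} yields only {n_levels} gray level(s) "
            "for this image; texture features will be near-degenerate",
            stacklevel=2,
        )

    out: OrderedDict[str, float] = OrderedDict()
    if "shape" in config.feature_classes:
        for name, val in sorted(
            shape_features(mask_r, config.target_spacing).items()
        ):
            out[f"original_shape_{name}"] = float(val)

    intensity_classes = tuple(c for c in config.feature_classes if c != "shape")
    for name, val in _intensity_features(
        image_c, mask_c, config, voxel_volume, intensity_classes
    ).items():
        out[f"original_{name}"] = val

    bands = wavelet_bands(image_c, config.wavelet, config.wavelet_mode)
    for band_name in WAVELET_BAND_NAMES:
        for name, val in _intensity_features(
            bands[band_name], mask_c, config, voxel_volume, intensity_classes
        ).items():
            out[f"wavelet-{band_name}_{name}"] = val
    return out
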