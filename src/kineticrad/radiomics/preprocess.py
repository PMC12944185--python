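"""Image preprocessing for feature extraction.

Pipeline order: resample image and mask to isotropic spacing (cubic
B-spline for the image, nearest-neighbour for the mask), compute the
undecimated single-level 3D wavelet filter bank on the resampled image,
then discretize in-mask intensities with a fixed bin width.
"""

from __future__ import annotations

import numpy as np
import pywt
import SimpleITK as sitk
from scipy import ndimage

from ..io import SegmentationError

WAVELET_BAND_NAMES = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")


def _to_sitk(arr: np.ndarray, spacing) -> sitk.Image:
    # numpy arrays are (x, y, z); SimpleITK expects (z, y, x) buffers
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr.T))
    img.SetSpacing(tuple(float(s) for s in spacing))
    return img


def _from_sitk(img: sitk.Image) -> np.ndarray:
    return sitk.GetArrayFromImage(img).T


def resample(
    image: np.ndarray,
    mask: np.ndarray,
    spacing,
    target_spacing=(1.0, 1.0, 1.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Resample an image/mask pair to ``target_spacing`` (mm).

    The intensity image is interpolated with a cubic B-spline; the mask
    with nearest neighbour so it stays binary.
    """
    spacing = tuple(float(s) for s in spacing)
    target_spacing = tuple(float(s) for s in target_spacing)
    if spacing == target_spacing:
        return np.asarray(image, dtype=np.float64), (np.asarray(mask) > 0).astype(np.uint8)

    src = _to_sitk(np.asarray(image, dtype=np.float64), spacing)
    msk = _to_sitk((np.asarray(mask) > 0).astype(np.uint8), spacing)
    # keep the output voxel centres inside the input extent (no extrapolation)
    new_size = [
        max(1, int(np.floor((n - 1) * s / t)) + 1)
        for n, s, t in zip(image.shape, spacing, target_spacing)
    ]
    rs = sitk.ResampleImageFilter()
    rs.SetOutputSpacing(target_spacing)
    rs.SetSize(new_size)
    rs.SetOutputOrigin(src.GetOrigin())
    rs.SetOutputDirection(src.GetDirection())
    rs.SetInterpolator(sitk.sitkBSpline)
    image_r = _from_sitk(rs.Execute(src))
    rs.SetInterpolator(sitk.sitkNearestNeighbor)
    mask_r = _from_sitk(rs.Execute(msk)).astype(np.uint8)
    if mask_r.sum() == 0:
        raise SegmentationError("mask empty after resampling")
    return image_r, mask_r


def discretize(values: np.ndarray, bin_width: float) -> np.ndarray:
    """Fixed-bin-width gray-level discretization of in-mask intensities.

    level(v) = floor((v - min) / bin_width) + 1; levels start at 1, so the
    result is translation invariant and a constant region maps to level 1.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("cannot discretize an empty value set")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    return (np.floor((values - values.min()) / bin_width) + 1).astype(np.int64)


def wavelet_bands(
    image: np.ndarray, wavelet: str = "coif1", mode: str = "mirror"
) -> dict[str, np.ndarray]:
    """Undecimated separable single-level 3D wavelet decomposition.

    Returns the 8 bands labelled LLL..HHH where letter i is the filter
    (L = low pass, H = high pass) applied along axis i in (x, y, z) order.
    Every band has the input's shape (stationary transform, no decimation);
    boundaries are handled by symmetric reflection.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 3:
        raise ValueError("expected a 3D image")
    wav = pywt.Wavelet(wavelet)
    filters = {"L": np.asarray(wav.dec_lo), "H": np.asarray(wav.dec_hi)}
    out: dict[str, np.ndarray] = {}
    for name in WAVELET_BAND_NAMES:
        band = image
        for axis, letter in enumerate(name):
            band = ndimage.correlate1d(band, filters[letter], axis=axis, mode=mode)
        out[name] = band
    return out
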