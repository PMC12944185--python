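"""Data model and NIfTI/CSV/JSON I/O for registered DCE-MRI series.

A DCE series is one pre-contrast 3D volume plus an ordered list of
post-contrast volumes acquired at known times after contrast injection.
All volumes are assumed to be registered onto a common grid; registration
itself is out of scope and must be done upstream (e.g. with Elastix).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

SUBTYPES = ("HR+/HER2-", "HER2+", "TNBC")

AFFINE_TOL_MM = 1e-4


class GridError(ValueError):
    """Volumes or masks do not share the same grid/affine."""


class ProtocolError(ValueError):
    """The series violates the acquisition protocol contract."""


class TimingError(ValueError):
    """Phase times are not strictly increasing and positive."""


class SegmentationError(ValueError):
    """The tumor mask is unusable (empty, off-grid, degenerate)."""


@dataclass
class DCESeries:
    """A registered 4D DCE-MRI acquisition.

    Parameters
    ----------
    pre_contrast : 3D float array of raw signal intensities before injection.
    post_contrast : list of 3D arrays, one per post-contrast phase,
        in acquisition order, same shape as ``pre_contrast``.
    phase_times : seconds after contrast injection for each post phase;
        strictly increasing, all positive. At least three post phases are
        required because the peak used by the wash-in rate is searched
        within the first three post-contrast phases.
    voxel_spacing : (dx, dy, dz) in millimetres.
    patient_id : identifier string.
    affine : optional 4x4 NIfTI affine; defaults to a diagonal scaling.
    """

    pre_contrast: np.ndarray
    post_contrast: list[np.ndarray]
    phase_times: np.ndarray
    voxel_spacing: tuple[float, float, float]
    patient_id: str = "unknown"
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pre_contrast = np.asarray(self.pre_contrast, dtype=np.float64)
        self.post_contrast = [np.asarray(v, dtype=np.float64) for v in self.post_contrast]
        self.phase_times = np.asarray(self.phase_times, dtype=np.float64)
        if self.pre_contrast.ndim != 3:
            raise GridError("pre-contrast volume must be 3D")
        if len(self.post_contrast) < 3:
            raise ProtocolError(
                "at least 3 post-contrast phases are required "
                f"(got {len(self.post_contrast)})"
            )
        for i, vol in enumerate(self.post_contrast):
            if vol.shape != self.pre_contrast.shape:
                raise GridError(
                    f"post-contrast phase {i} shape {vol.shape} != "
                    f"pre-contrast shape {self.pre_contrast.shape}"
                )
        if len(self.phase_times) != len(self.post_contrast):
            raise TimingError("one phase time per post-contrast volume is required")
        if np.any(self.phase_times <= 0) or np.any(np.diff(self.phase_times) <= 0):
            raise TimingError(
                f"phase times must be strictly increasing and positive: "
                f"{self.phase_times.tolist()}"
            )
        if len(self.voxel_spacing) != 3 or any(s <= 0 for s in self.voxel_spacing):
            raise GridError(f"voxel spacing must be 3 positive values: {self.voxel_spacing}")
        if self.affine is None:
            self.affine = np.diag(list(self.voxel_spacing) + [1.0])

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pre_contrast.shape

    @property
    def n_post_phases(self) -> int:
        return len(self.post_contrast)


@dataclass
class TumorMask:
    """Binary tumor mask on the same grid as its source series."""

    data: np.ndarray
    voxel_spacing: tuple[float, float, float]
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = (np.asarray(self.data) > 0).astype(np.uint8)
        if self.data.ndim != 3:
            raise GridError("mask must be 3D")
        if self.data.sum() == 0:
            raise SegmentationError("tumor mask is empty")
        if self.affine is None:
            self.affine = np.diag(list(self.voxel_spacing) + [1.0])
        n_comp = ndimage.label(self.data, structure=np.ones((3, 3, 3)))[1]
        if n_comp > 1:
            warnings.warn(
                f"tumor mask has {n_comp} connected components; expected 1",
                stacklevel=2,
            )

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass
class LabelTable:
    """patient_id -> molecular subtype mapping (closed 3-class set)."""

    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {s for s in self.labels.values() if s not in SUBTYPES}
        if bad:
            raise ValueError(f"unknown subtypes {bad}; allowed: {SUBTYPES}")

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {"patient_id": list(self.labels), "subtype": list(self.labels.values())}
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "LabelTable":
        import pandas as pd

        df = pd.read_csv(path, dtype=str)
        if df["patient_id"].duplicated().any():
            raise ValueError("duplicate patient_ids in label table")
        return cls(dict(zip(df["patient_id"], df["subtype"])))

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _check_affine(a: np.ndarray, b: np.ndarray, what: str) -> None:
    if np.max(np.abs(np.asarray(a) - np.asarray(b))) > AFFINE_TOL_MM:
        raise GridError(f"{what}: affines differ by more than {AFFINE_TOL_MM} mm")


def save_volume(
    data: np.ndarray,
    path: str | Path,
    voxel_spacing: Sequence[float] = (1.0, 1.0, 1.0),
    affine: np.ndarray | None = None,
) -> None:
    """Write a 3D volume as NIfTI-1."""
    if affine is None:
        affine = np.diag(list(voxel_spacing) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine), str(path))


def load_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a 3D NIfTI volume; returns (data, affine)."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if data.ndim != 3:
        raise GridError(f"{path}: expected a 3D volume, got ndim={data.ndim}")
    return data, np.asarray(img.affine)


def load_series(
    paths: Sequence[str | Path],
    timing: Sequence[float] | str | Path,
    pre_index: int = 0,
    patient_id: str = "unknown",
) -> DCESeries:
    """Load a registered DCE series from per-phase NIfTI files.

    ``timing`` is either the phase times in seconds (one per post-contrast
    phase) or a path to a JSON sidecar with key ``phase_times_s``.
    ``pre_index`` says which file in ``paths`` is the pre-contrast phase;
    the remaining files are the post-contrast phases in list order.
    """
    if isinstance(timing, (str, Path)):
        with open(timing) as fh:
            timing = json.load(fh)["phase_times_s"]
    vols, affines = [], []
    for p in paths:
        d, a = load_volume(p)
        vols.append(d)
        affines.append(a)
    for i, a in enumerate(affines[1:], 1):
        _check_affine(affines[0], a, f"phase {i}")
    pre = vols.pop(pre_index)
    spacing = tuple(np.sqrt((affines[0][:3, :3] ** 2).sum(axis=0)))
    return DCESeries(
        pre_contrast=pre,
        post_contrast=vols,
        phase_times=np.asarray(timing, dtype=float),
        voxel_spacing=spacing,
        patient_id=patient_id,
        affine=affines[0],
    )


def load_mask(path: str | Path, series: DCESeries) -> TumorMask:
    """Load a binary tumor mask and validate it against a series' grid."""
    data, affine = load_volume(path)
    if data.shape != series.shape:
        raise GridError(f"mask shape {data.shape} != series shape {series.shape}")
    _check_affine(affine, series.affine, "mask")
    if not (data > 0).any():
        raise SegmentationError(f"{path}: mask is empty")
    return TumorMask(data=data, voxel_spacing=series.voxel_spacing, affine=affine)


def save_series(series: DCESeries, out_dir: str | Path) -> list[Path]:
    """Write a series as one NIfTI per phase plus a JSON timing sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    p = out / f"{series.patient_id}_pre.nii.gz"
    save_volume(series.pre_contrast, p, series.voxel_spacing, series.affine)
    paths.append(p)
    for i, vol in enumerate(series.post_contrast):
        p = out / f"{series.patient_id}_post{i + 1}.nii.gz"
        save_volume(vol, p, series.voxel_spacing, series.affine)
        paths.append(p)
    with open(out / f"{series.patient_id}_timing.json", "w") as fh:
        json.dump({"phase_times_s": series.phase_times.tolist()}, fh)
    return paths
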