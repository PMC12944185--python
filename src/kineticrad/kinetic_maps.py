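"""Voxel-wise time-intensity-curve (TIC) parametric maps.

Each voxel's post-contrast signals are normalized by its pre-contrast
signal, giving a dimensionless enhancement curve s(t) with s(0) = 1 at the
time of contrast injection. Two semi-quantitative kinetic parameters are
computed per voxel and assembled into 3D parametric images:

* wash-in rate (WIR, s^-1): ``(I_peak_norm - 1) / T_peak`` where
  ``I_peak_norm`` is the maximum normalized intensity within the first
  three post-contrast phases and ``T_peak`` its time post-injection
  (ties broken toward the earliest phase);
* TIC area (dimensionless): trapezoidal area under the normalized curve
  from injection (point (0, 1)) to the last post-contrast phase, divided
  by the time of the last phase.

Voxels with a pre-contrast signal at or below a small floor (1e-6 of the
volume maximum) cannot be normalized; their map value is set to 0 and they
are counted in the map's QC field rather than propagating NaN/Inf.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import DCESeries, TumorMask

PRE_FLOOR_FRACTION = 1e-6


@dataclass
class ParametricMap:
    """A 3D voxel-wise kinetic image derived from a DCE series."""

    data: np.ndarray
    kind: str  # "WIR" (s^-1) or "Area" (dimensionless)
    patient_id: str
    phase_times: np.ndarray
    voxel_spacing: tuple[float, float, float]
    affine: np.ndarray
    n_degenerate_voxels: int = 0

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"{self.kind} map contains non-finite values")


def _normalized_curves(series: DCESeries) -> tuple[np.ndarray, np.ndarray]:
    """Stack of normalized post-contrast volumes plus degenerate-voxel mask.

    Returns (s, degenerate) where s has shape (n_phases, *grid) and
    degenerate marks voxels whose pre-contrast signal is at/below the floor.
    s is set to 1 (flat curve) at degenerate voxels.
    """
    pre = series.pre_contrast
    floor = PRE_FLOOR_FRACTION * max(pre.max(), *(v.max() for v in series.post_contrast))
    degenerate = pre <= floor
    safe_pre = np.where(degenerate, 1.0, pre)
    s = np.stack([v / safe_pre for v in series.post_contrast])
    s[:, degenerate] = 1.0
    return s, degenerate


def compute_wir_map(series: DCESeries) -> ParametricMap:
    """Voxel-wise wash-in rate map (s^-1).

    The peak is searched over the first three post-contrast phases only,
    regardless of how many phases the protocol acquired; a tie in the
    normalized peak goes to the earliest phase.
    """
    s, degenerate = _normalized_curves(series)
    first3 = s[:3]
    peak_idx = np.argmax(first3, axis=0)  # argmax takes the first maximum
    i_peak = np.take_along_axis(first3, peak_idx[None], axis=0)[0]
    t_peak = series.phase_times[:3][peak_idx]
    wir = (i_peak - 1.0) / t_peak
    wir[degenerate] = 0.0
    return ParametricMap(
        data=wir,
        kind="WIR",
        patient_id=series.patient_id,
        phase_times=series.phase_times.copy(),
        voxel_spacing=series.voxel_spacing,
        affine=series.affine,
        n_degenerate_voxels=int(degenerate.sum()),
    )


def compute_area_map(series: DCESeries) -> ParametricMap:
    """Voxel-wise normalized TIC-area map (dimensionless).

    Trapezoid over the points (0, 1), (t_1, s_1), ..., (t_N, s_N),
    divided by t_N. A flat curve (no enhancement) therefore has area 1,
    and the value is invariant to rescaling all raw intensities.
    """
    s, degenerate = _normalized_curves(series)
    times = np.concatenate([[0.0], series.phase_times])
    curves = np.concatenate([np.ones((1,) + series.shape), s])
    area = np.trapezoid(curves, x=times, axis=0) / series.phase_times[-1]
    area[degenerate] = 0.0
    return ParametricMap(
        data=area,
        kind="Area",
        patient_id=series.patient_id,
        phase_times=series.phase_times.copy(),
        voxel_spacing=series.voxel_spacing,
        affine=series.affine,
        n_degenerate_voxels=int(degenerate.sum()),
    )


def peak_enhancement_phase(
    series: DCESeries, mask: TumorMask
) -> tuple[np.ndarray, int]:
    """Post-contrast volume with the highest mean in-mask normalized intensity.

    Used as the single-phase baseline image. Returns (volume, phase_index);
    ties go to the earliest phase.
    """
    s, _ = _normalized_curves(series)
    m = mask.data.astype(bool)
    means = s[:, m].mean(axis=1)
    idx = int(np.argmax(means))
    return series.post_contrast[idx].copy(), idx
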