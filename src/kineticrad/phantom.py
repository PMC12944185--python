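"""Synthetic DCE-MRI phantoms with known voxel-wise kinetics.

Each phantom patient is an ellipsoidal enhancing lesion embedded in a
non-enhancing background. In-lesion voxels follow a piecewise-linear
normalized enhancement curve

    s(t) = 1 + a_v * min(t, t_peak) / t_peak + slope_v * max(0, t - t_peak)

with a_v = wir_v * t_peak, so that when t_peak coincides with a sampled
phase inside the first three post-contrast phases and slope_v <= 0, the
wash-in-rate map recovers wir_v exactly and the TIC-area map equals its
closed form (the trapezoidal rule is exact on piecewise-linear curves
sampled at the kink).

The three molecular-subtype classes share a common peak enhancement
amplitude but differ in time-to-peak (hence wash-in rate), washout slope
and spatial heterogeneity of the kinetic fields. Class separation thus
lives in the kinetic maps and in their texture, while a single
post-contrast phase image carries far weaker class signal — the regime
the kinetic-map radiomics method is designed for.

Voxel-level heterogeneity is Gaussian-filtered white noise added to the
per-voxel kinetic parameters; its correlation length and relative
amplitude are per-class knobs that create texture differences the
size-zone / co-occurrence features can detect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .io import SUBTYPES, DCESeries, LabelTable, ProtocolError, TumorMask, save_series, save_volume

#: class mix of the development cohort the generator mirrors by default
DEFAULT_CLASS_COUNTS = {"HR+/HER2-": 299, "HER2+": 235, "TNBC": 142}


@dataclass
class ClassKinetics:
    """Per-class voxel kinetic parameter distributions.

    wash_in_rate is in s^-1 (the quantity the WIR map estimates);
    t_peak_s must coincide with a sampled phase time for exact oracles;
    washout_slope is the post-peak slope of the normalized curve (s^-1,
    non-positive so the first-three-phase peak sits at t_peak).
    """

    wash_in_rate_mean: float
    wash_in_rate_sd: float
    t_peak_s: float
    washout_slope_mean: float
    washout_slope_sd: float
    corr_length_mm: float  # spatial correlation length of the kinetic fields
    rel_heterogeneity: float  # sd of the voxel field relative to the patient mean


def _default_class_kinetics() -> dict[str, ClassKinetics]:
    # common peak amplitude wir * t_peak ~ 1.3 across classes; classes differ
    # in speed (t_peak), washout and heterogeneity
    return {
        "HR+/HER2-": ClassKinetics(0.0072, 0.0012, 180.0, -1e-4, 3e-5, 2.5, 0.15),
        "HER2+": ClassKinetics(0.0108, 0.0018, 120.0, -3e-4, 5e-5, 2.0, 0.20),
        "TNBC": ClassKinetics(0.0217, 0.0035, 60.0, -6e-4, 8e-5, 1.5, 0.28),
    }


@dataclass
class PhantomSpec:
    """Study conditions for a synthetic cohort."""

    n_patients_per_class: dict[str, int] = field(
        default_factory=lambda: {"HR+/HER2-": 15, "HER2+": 12, "TNBC": 7}
    )
    grid_shape: tuple[int, int, int] = (40, 40, 28)
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    phase_times: tuple[float, ...] = (60.0, 120.0, 180.0, 240.0, 300.0)
    class_kinetics: dict[str, ClassKinetics] = field(default_factory=_default_class_kinetics)
    lesion_radius_range_mm: tuple[float, float] = (5.0, 9.0)
    pre_contrast_mean: float = 100.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.phase_times) < 3:
            raise ProtocolError("at least 3 post-contrast phases are required")
        times = np.asarray(self.phase_times, dtype=float)
        if np.any(times <= 0) or np.any(np.diff(times) <= 0):
            raise ValueError("phase_times must be strictly increasing and positive")
        if any(g <= 0 for g in self.grid_shape) or any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("grid_shape and voxel_spacing must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        missing = set(self.n_patients_per_class) - set(self.class_kinetics)
        if missing:
            raise ValueError(f"no kinetics configured for classes {missing}")


@dataclass
class PhantomPatient:
    """One generated patient plus its generating ground truth."""

    series: DCESeries
    mask: TumorMask
    subtype: str
    truth: dict


def _correlated_field(rng, shape, corr_length_vox) -> np.ndarray:
    """Unit-variance Gaussian random field with the given correlation length."""
    white = rng.standard_normal(shape)
    if corr_length_vox <= 0:
        return white
    smooth = ndimage.gaussian_filter(white, sigma=corr_length_vox)
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def _ellipsoid_mask(rng, spec: PhantomSpec) -> np.ndarray:
    shape = np.asarray(spec.grid_shape)
    spacing = np.asarray(spec.voxel_spacing)
    lo, hi = spec.lesion_radius_range_mm
    for _ in range(50):
        radii = rng.uniform(lo, hi, size=3)
        center = shape / 2.0 + rng.uniform(-2.0, 2.0, size=3) / spacing
        grids = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")
        dist2 = sum(
            ((g - c) * s / r) ** 2 for g, c, s, r in zip(grids, center, spacing, radii)
        )
        mask = dist2 <= 1.0
        if mask.sum() >= 200:
            return mask
    raise ValueError("could not fit a >=200-voxel lesion in the grid")


def generate_patient(
    spec: PhantomSpec, class_label: str, seed: int, patient_id: str | None = None
) -> PhantomPatient:
    """Generate one patient's registered DCE series, mask and ground truth."""
    if class_label not in spec.class_kinetics:
        raise ValueError(f"unknown class {class_label!r}")
    rng = np.random.default_rng(seed)
    kin = spec.class_kinetics[class_label]
    shape = spec.grid_shape
    spacing = np.asarray(spec.voxel_spacing)
    times = np.asarray(spec.phase_times, dtype=float)

    mask = _ellipsoid_mask(rng, spec)

    # strictly positive, smoothly varying baseline
    pre = spec.pre_contrast_mean * (
        1.0 + 0.05 * _correlated_field(rng, shape, 4.0 / spacing.mean())
    )
    pre = np.clip(pre, 0.2 * spec.pre_contrast_mean, None)

    wir_mu = max(1e-4, rng.normal(kin.wash_in_rate_mean, kin.wash_in_rate_sd))
    slope_mu = min(0.0, rng.normal(kin.washout_slope_mean, kin.washout_slope_sd))
    corr_vox = kin.corr_length_mm / spacing.mean()
    wir_field = wir_mu * (
        1.0 + kin.rel_heterogeneity * _correlated_field(rng, shape, corr_vox)
    )
    wir_field = np.clip(wir_field, 1e-4, None)
    slope_field = np.clip(
        slope_mu * (1.0 + kin.rel_heterogeneity * _correlated_field(rng, shape, corr_vox)),
        None,
        0.0,
    )

    tp = kin.t_peak_s
    amp = wir_field * tp
    posts = []
    for t in times:
        s = np.ones(shape)
        enh = 1.0 + amp * min(t, tp) / tp + slope_field * max(0.0, t - tp)
        s = np.where(mask, enh, 1.0)
        vol = pre * s
        if spec.noise_sd > 0:
            vol = vol + rng.normal(0.0, spec.noise_sd, size=shape)
        posts.append(np.clip(vol, 1e-3, None))

    series = DCESeries(
        pre_contrast=pre,
        post_contrast=posts,
        phase_times=times,
        voxel_spacing=tuple(spec.voxel_spacing),
        patient_id=patient_id or f"phantom_{class_label}_{seed}",
    )
    truth = {
        "subtype": class_label,
        "wir_patient_mean": float(wir_field[mask].mean()),
        "wir_field_mean_param": wir_mu,
        "slope_patient_mean": float(slope_field[mask].mean()),
        "t_peak_s": tp,
        "n_lesion_voxels": int(mask.sum()),
        "wir_field": wir_field,
        "slope_field": slope_field,
    }
    return PhantomPatient(
        series=series,
        mask=TumorMask(mask, tuple(spec.voxel_spacing)),
        subtype=class_label,
        truth=truth,
    )


def generate_cohort(
    spec: PhantomSpec, out_dir: str | Path | None = None
) -> tuple[list[PhantomPatient], LabelTable]:
    """Generate a full cohort; a pure function of (spec, spec.seed).

    If ``out_dir`` is given, writes per-phase NIfTI volumes, masks, a
    labels CSV and a JSON ground-truth sidecar per patient.
    """
    seeds = np.random.SeedSequence(spec.seed).generate_state(
        sum(spec.n_patients_per_class.values())
    )
    patients: list[PhantomPatient] = []
    labels: dict[str, str] = {}
    i = 0
    for cls in SUBTYPES:
        for k in range(spec.n_patients_per_class.get(cls, 0)):
            pid = f"P{i:04d}"
            pat = generate_patient(spec, cls, int(seeds[i] % 2**31), patient_id=pid)
            patients.append(pat)
            labels[pid] = cls
            i += 1
    table = LabelTable(labels)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for pat in patients:
            save_series(pat.series, out)
            save_volume(
                pat.mask.data,
                out / f"{pat.series.patient_id}_mask.nii.gz",
                pat.series.voxel_spacing,
                pat.series.affine,
            )
            sidecar = {
                k: v for k, v in pat.truth.items() if not isinstance(v, np.ndarray)
            }
            sidecar["phase_times_s"] = list(spec.phase_times)
            with open(out / f"{pat.series.patient_id}_truth.json", "w") as fh:
                json.dump(sidecar, fh, indent=1)
        table.to_csv(out / "labels.csv")
    return patients, table


def scaled_class_counts(scale: float) -> dict[str, int]:
    """Class counts mirroring the development cohort's imbalance, scaled."""
    return {cls: round(n * scale) for cls, n in DEFAULT_CLASS_COUNTS.items()}
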