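"""Synthetic two-class 3D tumor-phantom cohorts.

The generator emulates cohorts of peripherally located lung tumors imaged on
CT: each subject is a compact ellipsoidal ROI of textured tissue on an
air-like background (-1000 HU), with clinical covariates (age, gender,
smoking, race) drawn from class-conditional distributions matching typical
small-cell vs. adenocarcinoma demographics (smoking strongly associated with
the positive class).

Texture model: white Gaussian noise convolved with an isotropic Gaussian
kernel of width ``corr_len`` (voxels), affinely rescaled so the within-mask
voxels have exactly the class's target mean/SD in HU.  The two classes can
therefore be separated by texture statistics (correlation length, variance,
mean HU) with a tunable effect size.  No attempt is made to simulate lungs,
vasculature, breathing artifacts or reconstruction kernels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .volume_io import ROIMask, VoxelVolume

AIR_HU = -1000.0

RACE_CATEGORIES = ("Asian", "Caucasian", "Other")


@dataclass
class ClassSpec:
    """Class-conditional generative parameters for one tumor class."""

    mean_hu: float = 30.0
    sd_hu: float = 100.0
    corr_len: float = 1.5          # Gaussian kernel sigma, voxels
    mask_radii: tuple[float, float, float] = (6.0, 5.0, 5.0)
    smoking_prob: float = 0.5
    age_mean: float = 62.0
    age_sd: float = 10.0
    male_prob: float = 0.5
    race_probs: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)

    def __post_init__(self) -> None:
        if self.sd_hu < 0:
            raise ValueError("sd_hu must be >= 0")
        if self.corr_len <= 0:
            raise ValueError("corr_len must be > 0")
        if any(r < 2 for r in self.mask_radii):
            raise ValueError("mask_radii must each be >= 2 voxels")
        if not 0 <= self.smoking_prob <= 1:
            raise ValueError("smoking_prob must lie in [0, 1]")


# class-conditional defaults emulating a SCLC-like positive class (smokers,
# older, coarser/higher-variance texture) vs. an adenocarcinoma-like negative
# class; demographic rates follow typical published two-class lung cohorts
SCLC_LIKE = ClassSpec(mean_hu=45.0, sd_hu=140.0, corr_len=2.5,
                      mask_radii=(6.0, 5.0, 5.0), smoking_prob=0.9714,
                      age_mean=66.91, age_sd=9.75, male_prob=0.6857,
                      race_probs=(0.20, 0.743, 0.057))
NSCLC_LIKE = ClassSpec(mean_hu=25.0, sd_hu=90.0, corr_len=1.0,
                       mask_radii=(6.0, 5.0, 5.0), smoking_prob=0.2647,
                       age_mean=58.55, age_sd=11.94, male_prob=0.3529,
                       race_probs=(0.4706, 0.4412, 0.0882))

DEFAULT_GRID = (18, 18, 18)


@dataclass
class ClinicalRecord:
    subject_id: str
    age: float
    gender: int      # male = 1
    smoking: int     # ever-smoker = 1
    race: str


@dataclass
class SyntheticSubject:
    volume: VoxelVolume
    mask: ROIMask
    clinical: ClinicalRecord
    label: int       # 1 = positive ("SCLC-like"), 0 = negative

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")
        if self.volume.shape != self.mask.shape:
            raise ValueError("mask does not fit the volume grid")


def ellipsoid_mask(grid: tuple[int, int, int],
                   radii: tuple[float, float, float]) -> np.ndarray:
    """Boolean ellipsoid centered on the grid."""
    centers = [(n - 1) / 2.0 for n in grid]
    axes = np.ogrid[tuple(slice(0, n) for n in grid)]
    q = sum(((ax - c) / r) ** 2 for ax, c, r in zip(axes, centers, radii))
    return q <= 1.0


def generate_textured_volume(spec: ClassSpec, grid: tuple[int, int, int],
                             seed: int) -> tuple[VoxelVolume, ROIMask]:
    """One textured ellipsoidal phantom on an air background.

    The within-mask field is a Gaussian random field with correlation length
    ``spec.corr_len`` rescaled to exactly (mean_hu, sd_hu); all randomness is
    fixed by ``seed``.
    """
    from scipy.ndimage import gaussian_filter

    if any(n < 2 * r for n, r in zip(grid, spec.mask_radii)):
        raise ValueError(
            f"grid {grid} too small for mask radii {spec.mask_radii}"
        )
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(grid)
    field_arr = gaussian_filter(noise, sigma=spec.corr_len, mode="reflect")
    flags = ellipsoid_mask(grid, spec.mask_radii)
    vals = field_arr[flags]
    mu, sd = vals.mean(), vals.std()
    out = np.full(grid, AIR_HU)
    if spec.sd_hu == 0 or sd == 0:
        out[flags] = spec.mean_hu
    else:
        out[flags] = (vals - mu) / sd * spec.sd_hu + spec.mean_hu
    return VoxelVolume(out, spacing=(0.76, 0.76, 1.0)), ROIMask(flags)


def generate_cohort(n_pos: int, n_neg: int,
                    spec_pos: ClassSpec = SCLC_LIKE,
                    spec_neg: ClassSpec = NSCLC_LIKE,
                    grid: tuple[int, int, int] = DEFAULT_GRID,
                    seed: int = 0) -> list[SyntheticSubject]:
    """A reproducible two-class cohort: positives first, then negatives."""
    if n_pos < 1 or n_neg < 1:
        raise ValueError("need at least one subject per class")
    rng = np.random.default_rng(seed)
    subjects: list[SyntheticSubject] = []
    for label, n, spec in ((1, n_pos, spec_pos), (0, n_neg, spec_neg)):
        for k in range(n):
            vol_seed = int(rng.integers(0, 2**31 - 1))
            vol, msk = generate_textured_volume(spec, grid, vol_seed)
            clin = ClinicalRecord(
                subject_id=f"{'P' if label else 'N'}{k:03d}",
                age=float(rng.normal(spec.age_mean, spec.age_sd)),
                gender=int(rng.random() < spec.male_prob),
                smoking=int(rng.random() < spec.smoking_prob),
                race=RACE_CATEGORIES[int(rng.choice(len(RACE_CATEGORIES),
                                                    p=spec.race_probs))],
            )
            subjects.append(SyntheticSubject(vol, msk, clin, label))
    return subjects


def clinical_frame(subjects: list[SyntheticSubject]) -> pd.DataFrame:
    """Clinical table with header subject_id,age,gender,smoking,race,label."""
    return pd.DataFrame([
        {"subject_id": s.clinical.subject_id, "age": s.clinical.age,
         "gender": s.clinical.gender, "smoking": s.clinical.smoking,
         "race": s.clinical.race, "label": s.label}
        for s in subjects
    ])


def write_cohort(subjects: list[SyntheticSubject], out_dir) -> None:
    """Write volumes/masks as NIfTI (.nii.gz) and the clinical table as CSV."""
    import os

    from .volume_io import write_mask, write_volume

    os.makedirs(out_dir, exist_ok=True)
    for s in subjects:
        sid = s.clinical.subject_id
        write_volume(s.volume, os.path.join(out_dir, f"{sid}_volume.nii.gz"))
        write_mask(s.mask, os.path.join(out_dir, f"{sid}_mask.nii.gz"),
                   spacing=s.volume.spacing)
    clinical_frame(subjects).to_csv(os.path.join(out_dir, "clinical.csv"),
                                    index=False)
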