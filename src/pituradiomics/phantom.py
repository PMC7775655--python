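"""Synthetic MRI cohorts with the statistical structure the pipeline assumes.

Phantoms are ellipsoidal "tumors" with spatially correlated internal texture
embedded in Gaussian background noise, rendered in two channels (T1CE and
T2) on a shared, possibly anisotropic grid. Cohorts pair the phantoms with
clinical covariates, lesion dimensions at baseline/follow-up obeying the
>2 mm progression rule, and right-censored progression-free survival times.

The generator makes no attempt at pituitary anatomy, scanner artifacts or
bias fields; it emulates only the statistical contrasts the analysis relies
on (class-dependent size and texture granularity, class prevalence, censored
time-to-event structure).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .records import CaseRecord, records_to_frame
from .volume import ImageVolume, LesionMask


@dataclass
class PhantomSpec:
    """Geometry and texture parameters of a single two-channel phantom.

    ``intensity_contrast`` is the tumor-background mean separation in units
    of the background noise SD. ``texture_granularity_mm`` is the spatial
    correlation length (Gaussian smoothing sigma) of the within-tumor random
    field; larger values give locally more uniform ("coarser") texture.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 24)
    voxel_spacing_mm: tuple[float, float, float] = (1.0, 1.0, 3.0)
    tumor_center_mm: tuple[float, float, float] | None = None
    tumor_radii_mm: tuple[float, float, float] = (15.0, 12.0, 12.0)
    intensity_contrast: float = 3.0
    texture_granularity_mm: float = 1.5
    heterogeneity_sd: float = 0.8
    noise_sd: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValueError("voxel spacing must be strictly positive")
        if any(r <= 0 for r in self.tumor_radii_mm):
            raise ValueError("tumor radii must be strictly positive")
        if self.texture_granularity_mm <= 0 or self.noise_sd <= 0:
            raise ValueError("texture_granularity_mm and noise_sd must be positive")
        if self.heterogeneity_sd < 0:
            raise ValueError("heterogeneity_sd must be non-negative")
        if self.tumor_center_mm is None:
            self.tumor_center_mm = tuple(
                (n - 1) * s / 2.0 for n, s in zip(self.grid_shape, self.voxel_spacing_mm)
            )
        # tumor must fit inside the grid with a >= 2-voxel margin per axis
        for ax in range(3):
            c, r = self.tumor_center_mm[ax], self.tumor_radii_mm[ax]
            sp, n = self.voxel_spacing_mm[ax], self.grid_shape[ax]
            lo, hi = 2 * sp, (n - 3) * sp
            if c - r < lo or c + r > hi:
                raise ValueError(
                    f"tumor exceeds grid on axis {ax}: extent "
                    f"[{c - r:.1f}, {c + r:.1f}] mm outside margin [{lo:.1f}, {hi:.1f}] mm"
                )


def _correlated_field(rng: np.random.Generator, shape, spacing, granularity_mm, sd) -> np.ndarray:
    """White noise smoothed to the requested correlation length, rescaled to ``sd``."""
    white = rng.standard_normal(shape)
    sigma_vox = [granularity_mm / s for s in spacing]
    f = gaussian_filter(white, sigma=sigma_vox, mode="nearest")
    fs = f.std()
    if fs > 0:
        f *= sd / fs
    return f


def ellipsoid_mask(grid_shape, spacing, center_mm, radii_mm) -> np.ndarray:
    """Exact digitization of an ellipsoid: voxel centers with Σ((x−c)/r)² ≤ 1."""
    axes = [(np.arange(n) * s - c) / r
            for n, s, c, r in zip(grid_shape, spacing, center_mm, radii_mm)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij", sparse=True)
    return (gx**2 + gy**2 + gz**2) <= 1.0


def generate_phantom(spec: PhantomSpec) -> tuple[ImageVolume, ImageVolume, LesionMask]:
    """Render one phantom: (T1CE volume, T2 volume, ground-truth mask).

    Both channels share the geometry but have independent noise and texture
    draws. Deterministic given ``spec.rng_seed``.
    """
    mask = ellipsoid_mask(spec.grid_shape, spec.voxel_spacing_mm,
                          spec.tumor_center_mm, spec.tumor_radii_mm)
    seeds = np.random.SeedSequence(spec.rng_seed).spawn(2)
    vols = []
    for child, modality in zip(seeds, ("T1CE", "T2")):
        rng = np.random.default_rng(child)
        data = rng.normal(0.0, spec.noise_sd, spec.grid_shape)
        texture = _correlated_field(rng, spec.grid_shape, spec.voxel_spacing_mm,
                                    spec.texture_granularity_mm, spec.heterogeneity_sd)
        data[mask] += spec.intensity_contrast * spec.noise_sd + texture[mask]
        vols.append(ImageVolume(data, spec.voxel_spacing_mm, modality))
    truth = LesionMask(mask, spec.voxel_spacing_mm, "original")
    return vols[0], vols[1], truth


# ---------------------------------------------------------------------------
# survival simulation
# ---------------------------------------------------------------------------

@dataclass
class HazardParams:
    """Weibull proportional-hazards parameters: h(t|z) = rate·exp(β z)·k·t^(k−1)."""

    baseline_rate: float = math.log(2) / 90.0  # per month; median 90 mo at latent 0
    log_hr_per_latent: float = math.log(3.0)
    shape: float = 1.0  # k = 1: exponential

    def __post_init__(self) -> None:
        if self.baseline_rate <= 0 or self.shape <= 0:
            raise ValueError("baseline_rate and shape must be positive")


def simulate_survival(latent, hazard: HazardParams, censor_months: float, seed: int):
    """Draw right-censored event times under the Weibull PH model.

    Returns ``(time_months, event_flag)`` arrays; ``event_flag`` is False iff
    the latent event time exceeds ``censor_months`` (administrative censoring).
    """
    if censor_months <= 0:
        raise ValueError("censor_months must be positive")
    latent = np.atleast_1d(np.asarray(latent, dtype=float))
    rng = np.random.default_rng(seed)
    rate = hazard.baseline_rate * np.exp(hazard.log_hr_per_latent * latent)
    u = rng.uniform(size=latent.shape)
    t = (-np.log(u) / rate) ** (1.0 / hazard.shape)
    event = t <= censor_months
    return np.minimum(t, censor_months), event


def _truncated_event_time(rng, rate, shape, censor_months):
    """Event time conditioned on occurring before ``censor_months`` (inverse CDF)."""
    s_c = math.exp(-rate * censor_months**shape)
    u = rng.uniform(0.0, 1.0)
    # survival value uniform on (s_c, 1) ⇒ time in (0, censor)
    s = s_c + u * (1.0 - s_c)
    t = (-math.log(s) / rate) ** (1.0 / shape)
    return min(max(t, 1e-6), censor_months * (1 - 1e-9))


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

@dataclass
class ClassParams:
    """Class-conditional phantom parameter distributions.

    Tumor height (largest diameter) is log-normal around ``height_median_mm``;
    texture granularity and heterogeneity control NGTDM-coarseness-like
    contrast between the outcome classes.
    """

    height_median_mm: float
    height_log_sd: float = 0.28
    granularity_mm: float = 1.5
    heterogeneity_sd: float = 0.8
    intensity_contrast: float = 3.0


#: covariate prevalences per class (P/R, non-P/R), matching the cohort's
#: reported clinical profile
_COVARIATE_PROBS = {
    "sex_male": (0.679, 0.455),
    "visual_disturbance": (0.929, 0.591),
    "headache": (0.286, 0.500),
    "sex_hormone_symptoms": (0.179, 0.045),
    "incidental": (0.071, 0.182),
    "hyperprolactinemia": (0.357, 0.273),
    "chiasm_decompression": (0.321, 0.773),
    "knosp_high_grade": (0.357, 0.136),
    "hardy_high_grade": (0.393, 0.136),
    "optic_chiasm_compression": (0.964, 0.773),
    "third_ventricle_compression": (0.750, 0.409),
    "hydrocephalus": (0.071, 0.045),
}
_HYPOPIT_PROBS = {True: (0.429, 0.286, 0.285), False: (0.773, 0.136, 0.091)}
_GTR_PROB = {True: 0.107, False: 0.273}
_AGE = {True: (53.5, 13.0), False: (42.0, 16.0)}


@dataclass
class CohortSpec:
    """Cohort-level design: size, prevalence, class distributions, survival."""

    n_cases: int = 50
    pr_prevalence: float = 0.56
    pr_params: ClassParams = field(default_factory=lambda: ClassParams(
        height_median_mm=35.5, granularity_mm=3.0, heterogeneity_sd=1.0))
    non_pr_params: ClassParams = field(default_factory=lambda: ClassParams(
        height_median_mm=18.0, granularity_mm=1.2, heterogeneity_sd=0.6))
    hazard: HazardParams = field(default_factory=HazardParams)
    latent_size_coef: float = 0.3   # extra log-hazard per SD of log tumor height
    censor_months: float = 96.0
    grid_shape: tuple[int, int, int] = (64, 64, 24)
    voxel_spacing_mm: tuple[float, float, float] = (1.0, 1.0, 3.0)
    noise_sd: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.pr_prevalence < 1.0:
            raise ValueError("pr_prevalence must lie strictly between 0 and 1")
        n_pr = round(self.n_cases * self.pr_prevalence)
        if n_pr < 2 or self.n_cases - n_pr < 2:
            raise ValueError(
                f"degenerate class split: {n_pr} P/R vs {self.n_cases - n_pr} non-P/R "
                "(need >= 2 cases per class)")
        if self.censor_months <= 0:
            raise ValueError("censor_months must be positive")


@dataclass
class PhantomCase:
    """One generated case: the two channels, the truth mask, and the record."""

    t1ce: ImageVolume
    t2: ImageVolume
    truth_mask: LesionMask
    record: CaseRecord


def _draw_radii(rng, params: ClassParams, spec: CohortSpec) -> tuple[float, float, float]:
    # height = largest diameter, along the in-plane row axis (coronal height)
    max_fit = min((n - 7) * s for n, s in zip(spec.grid_shape, spec.voxel_spacing_mm))
    height = float(np.exp(rng.normal(np.log(params.height_median_mm), params.height_log_sd)))
    height = float(np.clip(height, 8.0, max_fit))
    r0 = height / 2.0
    r1 = r0 * rng.uniform(0.7, 1.0)
    r2 = r0 * rng.uniform(0.7, 1.0)
    return (r0, r1, r2)


def _draw_covariates(rng, is_pr: bool, height_mm: float, volume_cm3: float) -> dict:
    j = 0 if is_pr else 1
    cov = {k: bool(rng.uniform() < p[j]) for k, p in _COVARIATE_PROBS.items()}
    cov["age_years"] = float(np.clip(rng.normal(*_AGE[is_pr]), 19, 80))
    cov["hypopituitarism"] = ("none", "single", "multiple")[
        rng.choice(3, p=np.asarray(_HYPOPIT_PROBS[is_pr]) / sum(_HYPOPIT_PROBS[is_pr]))]
    cov["resection"] = "GTR" if rng.uniform() < _GTR_PROB[is_pr] else "STR"
    cov["giant_tumor"] = bool(height_mm > 40.0)
    cov["tumor_height_mm"] = height_mm
    cov["tumor_volume_cm3"] = volume_cm3
    return cov


def generate_cohort(spec: CohortSpec) -> list[PhantomCase]:
    """Generate the full synthetic cohort.

    The number of P/R cases is ``round(n_cases · pr_prevalence)`` exactly
    (labels are assigned deterministically and shuffled), so the class split
    is reproducible at any seed. Follow-up lesion dimensions satisfy the
    >2 mm progression rule by construction: events grow by more than 2 mm on
    at least one axis, non-events on none.
    """
    rng = np.random.default_rng(spec.rng_seed)
    n_pr = round(spec.n_cases * spec.pr_prevalence)
    labels = np.array([True] * n_pr + [False] * (spec.n_cases - n_pr))
    rng.shuffle(labels)

    radii_all = [
        _draw_radii(rng, spec.pr_params if pr else spec.non_pr_params, spec)
        for pr in labels
    ]
    heights = np.array([2 * r[0] for r in radii_all])
    z_logh = (np.log(heights) - np.log(heights).mean()) / max(np.log(heights).std(), 1e-12)

    cases: list[PhantomCase] = []
    for i, is_pr in enumerate(labels):
        params = spec.pr_params if is_pr else spec.non_pr_params
        radii = radii_all[i]
        pspec = PhantomSpec(
            grid_shape=spec.grid_shape,
            voxel_spacing_mm=spec.voxel_spacing_mm,
            tumor_radii_mm=radii,
            intensity_contrast=params.intensity_contrast,
            texture_granularity_mm=params.granularity_mm,
            heterogeneity_sd=params.heterogeneity_sd,
            noise_sd=spec.noise_sd,
            rng_seed=int(rng.integers(0, 2**31 - 1)),
        )
        t1ce, t2, truth = generate_phantom(pspec)

        baseline = tuple(2.0 * r for r in radii)
        growth = rng.uniform(-1.0, 2.0, size=3)
        if is_pr:
            growth[rng.integers(0, 3)] = rng.uniform(3.0, 15.0)
        followup = tuple(max(b + g, 1.0) for b, g in zip(baseline, growth))

        latent = (1.0 if is_pr else 0.0) + spec.latent_size_coef * z_logh[i]
        rate = spec.hazard.baseline_rate * math.exp(spec.hazard.log_hr_per_latent * latent)
        if is_pr:
            t = _truncated_event_time(rng, rate, spec.hazard.shape, spec.censor_months)
        else:
            t = spec.censor_months

        volume_cm3 = (4.0 / 3.0) * math.pi * radii[0] * radii[1] * radii[2] / 1000.0
        record = CaseRecord(
            case_id=f"case_{i:03d}",
            pr_event=bool(is_pr),
            time_months=float(t),
            baseline_dims_mm=baseline,
            followup_dims_mm=followup,
            covariates=_draw_covariates(rng, bool(is_pr), baseline[0], volume_cm3),
        )
        cases.append(PhantomCase(t1ce, t2, truth, record))
    return cases


def cohort_table(cases: list[PhantomCase]) -> pd.DataFrame:
    return records_to_frame([c.record for c in cases])


def write_cohort(cases: list[PhantomCase], out_dir) -> None:
    """Write volumes/masks as NIfTI-1 and the cohort table as CSV."""
    from pathlib import Path

    out = Path(out_dir)
    (out / "volumes").mkdir(parents=True, exist_ok=True)
    for c in cases:
        cid = c.record.case_id
        c.t1ce.save(out / "volumes" / f"{cid}_t1ce.nii.gz")
        c.t2.save(out / "volumes" / f"{cid}_t2.nii.gz")
        c.truth_mask.save(out / "volumes" / f"{cid}_truth_mask.nii.gz")
    cohort_table(cases).to_csv(out / "cohort.csv")
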