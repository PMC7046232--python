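"""Synthetic foot-shaped pressure cohorts with known ground truth.

Real plantar pressure cohorts cannot ship with the package, so every
pipeline stage is exercised on synthetic peak-pressure images whose ground
truth is known in closed form:

* a foot phenotype is a sum of anisotropic Gaussian blobs at anatomical
  loci (heel, midfoot, metatarsal heads 1-5, hallux, lesser toes) plus a
  broad base ridge that keeps the 5 kPa footprint connected;
* each locus amplitude depends **linearly** on the demographics deviation
  from a fixed reference, so the pixel-wise linear regression is correctly
  specified and its true coefficient maps are available exactly;
* residual noise is spatially smoothed Gaussian noise (pressure fields are
  smooth; smoothness is also what random-field-theory thresholding
  assumes), truncated at zero only where pressures are near zero;
* repeated measurements of one foot differ by small random rigid
  misalignments and independent within-foot noise, emulating step-to-step
  placement variation on the plate;
* regional abnormalities of a chosen magnitude (in units of the model's
  residual SD) can be injected with a known ground-truth mask.

Default cohort sizes mirror the study conditions the model targets: 55
healthy subjects, 24 measurements per foot.  Everything is deterministic
given the spec seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .pixel_model import Demographics, PixelwiseModel, predict_pressures
from .pressure_io import PressureImage
from .registration import RigidTransform2D, apply_transform

__all__ = [
    "FootPhenotype",
    "CohortSpec",
    "CohortResult",
    "generate_foot_image",
    "generate_cohort",
    "inject_abnormality",
    "simulate_patient_from_model",
    "smooth_unit_noise",
    "DEFAULT_REFERENCE_DEMOGRAPHICS",
]

# order matches the model covariates (without intercept)
COVARIATES = ("age", "sex", "weight", "height", "shoe_size")

# fixed reference demographics: effects are linear in (z - reference)
DEFAULT_REFERENCE_DEMOGRAPHICS = {
    "age": 45.0,
    "sex": 0.5,
    "weight": 75.0,
    "height": 172.0,
    "shoe_size": 41.0,
}


@dataclass(frozen=True)
class Blob:
    """One anisotropic Gaussian pressure locus.

    ``row_frac`` is the position along the foot axis (0 = heel end,
    1 = toe end); ``col_offset_px`` the medial-lateral offset from the foot
    axis in pixels (positive = medial for left-oriented feet).
    """

    row_frac: float
    col_offset_px: float
    sigma_row_px: float
    sigma_col_px: float
    amplitude_kpa: float


@dataclass(frozen=True)
class FootPhenotype:
    """Blob layout of a left-oriented synthetic foot on a fixed canvas."""

    shape: tuple[int, int] = (72, 40)
    spacing_mm: float = 3.0
    foot_row_start: int = 6
    foot_row_end: int = 66  # exclusive
    axis_col: float = 20.0
    loci: dict = field(default_factory=lambda: {
        "heel":    Blob(0.12,  0.0, 3.5, 3.0, 240.0),
        "midfoot": Blob(0.40, -3.0, 5.0, 2.5, 55.0),
        "mt1":     Blob(0.66,  5.0, 2.5, 2.2, 190.0),
        "mt2":     Blob(0.69,  2.0, 2.5, 2.0, 210.0),
        "mt3":     Blob(0.70, -1.0, 2.5, 2.0, 190.0),
        "mt4":     Blob(0.69, -4.0, 2.3, 1.8, 150.0),
        "mt5":     Blob(0.67, -6.5, 2.2, 1.8, 120.0),
        "hallux":  Blob(0.88,  4.5, 2.5, 2.0, 160.0),
        "toes2_5": Blob(0.86, -2.5, 2.0, 3.5, 60.0),
    })
    base_ridge: tuple = (
        Blob(0.15,  0.0, 6.0, 4.0, 40.0),
        Blob(0.40, -1.0, 8.0, 4.0, 30.0),
        Blob(0.69,  0.0, 5.0, 6.0, 40.0),
        Blob(0.87,  1.0, 3.0, 6.0, 25.0),
    )

    @property
    def foot_length_rows(self) -> int:
        return self.foot_row_end - self.foot_row_start

    def blob_center_px(self, blob: Blob) -> tuple[float, float]:
        row = self.foot_row_start + blob.row_frac * self.foot_length_rows
        col = self.axis_col + blob.col_offset_px
        return (row, col)

    def blob_field(self, blob: Blob) -> np.ndarray:
        """Unit-amplitude Gaussian field of one blob on the canvas."""
        rc, cc = self.blob_center_px(blob)
        rows = np.arange(self.shape[0])[:, None]
        cols = np.arange(self.shape[1])[None, :]
        return np.exp(
            -((rows - rc) ** 2) / (2.0 * blob.sigma_row_px**2)
            - ((cols - cc) ** 2) / (2.0 * blob.sigma_col_px**2)
        )


# default linear demographic effects on locus amplitudes,
# kPa per unit covariate deviation, order (age, sex, weight, height, shoe_size);
# magnitudes chosen so each nonzero effect is resolvable from a 55-subject
# cohort with the default residual noise
DEFAULT_EFFECTS = {
    "heel":    (-1.0, 25.0, 1.2, 1.5, 0.0),
    "midfoot": (0.0,  0.0, 1.0, 0.0, 0.0),
    "mt1":     (0.0,  25.0, 1.0, 0.0, 5.0),
    "mt2":     (0.0,  30.0, 1.2, 0.0, 0.0),
    "mt3":     (0.0,  20.0, 1.0, 1.5, 0.0),
    "mt4":     (0.0,  18.0, 0.8, 0.0, 0.0),
    "mt5":     (0.0,  16.0, 0.8, 0.0, 0.0),
    "hallux":  (-1.0, 0.0, 0.8, 0.0, 6.0),
    "toes2_5": (-0.8, 0.0, 0.8, 0.0, 0.0),
}


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for a synthetic healthy cohort.

    Defaults mirror a healthy-control modelling cohort: 55 subjects, 24
    measurements per foot, smooth residual noise, and small step-to-step
    rigid misalignments.  Fully deterministic given ``seed``.
    """

    n_subjects: int = 55
    k_repeats: int = 24
    phenotype: FootPhenotype = field(default_factory=FootPhenotype)
    effects: dict = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    reference: dict = field(default_factory=lambda: dict(DEFAULT_REFERENCE_DEMOGRAPHICS))
    noise_sd_kpa: float = 8.0          # between-subject residual SD
    repeat_noise_sd_kpa: float = 6.0   # within-foot, per-measurement SD
    noise_corr_sigma_px: float = 2.0   # spatial correlation of the noise
    misalign_rot_deg: float = 5.0
    misalign_trans_mm: float = 6.0
    age_range: tuple[float, float] = (20.0, 70.0)
    sex_ratio: float = 0.5
    weight_mean_sd: tuple[float, float] = (75.0, 12.0)
    height_mean_sd: tuple[float, float] = (172.0, 9.0)
    shoe_mean_sd: tuple[float, float] = (41.0, 2.5)
    seed: int = 0


@dataclass
class CohortResult:
    """A generated cohort plus its closed-form ground truth."""

    images: list           # aligned mode: one PressureImage per foot;
                           # repeats mode: one list of K images per foot
    demographics: pd.DataFrame
    demographics_records: list
    truth_coefficients: np.ndarray  # (6, nx, ny), covariate order + intercept
    noise_sd_map: np.ndarray
    spec: CohortSpec
    mode: str


def smooth_unit_noise(shape: tuple[int, int], sigma_px: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Spatially smooth Gaussian noise with (approximately) unit pixel variance.

    White noise convolved with a Gaussian kernel of ``sigma_px`` and rescaled
    by the theoretical 2D variance reduction factor ``2 sqrt(pi) sigma``.
    """
    white = rng.standard_normal(shape)
    if sigma_px <= 0:
        return white
    smooth = ndimage.gaussian_filter(white, sigma_px, mode="constant")
    return smooth * (2.0 * np.sqrt(np.pi) * sigma_px)


def _signal_image(phenotype: FootPhenotype, z: "Demographics | dict",
                  effects: dict, reference: dict) -> np.ndarray:
    """Noise-free pressure field for demographics z (linear in z by construction)."""
    if isinstance(z, dict):
        zvec = {name: z[name] for name in COVARIATES}
    else:
        zvec = {name: getattr(z, name) for name in COVARIATES}
    img = np.zeros(phenotype.shape)
    for name, blob in phenotype.loci.items():
        amp = blob.amplitude_kpa
        eff = effects.get(name)
        if eff is not None:
            amp += sum(e * (zvec[c] - reference[c]) for e, c in zip(eff, COVARIATES))
        img += amp * phenotype.blob_field(blob)
    for blob in phenotype.base_ridge:
        img += blob.amplitude_kpa * phenotype.blob_field(blob)
    return img


def ground_truth_coefficient_maps(spec: CohortSpec) -> np.ndarray:
    """True coefficient maps (6, nx, ny) implied by the effect matrix.

    Covariate map j is the effect-weighted sum of the blob fields; the
    intercept map is the pressure field at zero covariates (reference
    amplitudes minus the effects evaluated at the reference demographics).
    """
    ph = spec.phenotype
    maps = np.zeros((6, *ph.shape))
    for name, blob in ph.loci.items():
        g = ph.blob_field(blob)
        eff = spec.effects.get(name, (0.0,) * 5)
        for j, e in enumerate(eff):
            maps[j] += e * g
        intercept_amp = blob.amplitude_kpa - sum(
            e * spec.reference[c] for e, c in zip(eff, COVARIATES)
        )
        maps[5] += intercept_amp * g
    for blob in ph.base_ridge:
        maps[5] += blob.amplitude_kpa * ph.blob_field(blob)
    return maps


def generate_foot_image(
    phenotype: FootPhenotype,
    z: Demographics,
    spec: CohortSpec,
    seed: int | np.random.Generator = 0,
    noise_sd_kpa: float | None = None,
) -> PressureImage:
    """One synthetic peak-pressure image: linear blob signal + smooth noise.

    Noise is clipped at zero (pressures are non-negative); at loaded pixels
    the noise SD is far below the signal so the induced skew is negligible.
    Deterministic for a given seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sd = spec.noise_sd_kpa if noise_sd_kpa is None else noise_sd_kpa
    img = _signal_image(phenotype, z, spec.effects, spec.reference)
    if sd > 0:
        envelope = _noise_envelope(
            _signal_image(phenotype, spec.reference, spec.effects, spec.reference)
        )
        noise = sd * smooth_unit_noise(phenotype.shape, spec.noise_corr_sigma_px, rng)
        img = img + noise * envelope
    return PressureImage(
        data=np.clip(img, 0.0, None),
        spacing=(phenotype.spacing_mm, phenotype.spacing_mm),
        side="left",
    )


SUPPORT_FLOOR_KPA = 2.0
NOISE_REFERENCE_KPA = 60.0  # pressure level above which noise SD saturates


def _noise_envelope(reference_signal: np.ndarray) -> np.ndarray:
    """Pixel-wise noise scale: variability grows with local loading.

    Pressure variability is proportional to the local pressure level up to a
    saturation at ``NOISE_REFERENCE_KPA``, and zero off the foot (sensors
    off the foot record nothing).  The envelope is computed from the
    *reference* (mean-demographics) pressure field, so it is identical for
    every subject -- each pixel keeps a single residual SD across the cohort
    and the per-pixel regression stays exactly specified.
    """
    env = np.clip(reference_signal / NOISE_REFERENCE_KPA, 0.0, 1.0)
    env[reference_signal <= SUPPORT_FLOOR_KPA] = 0.0
    return env


def _draw_demographics(spec: CohortSpec, rng: np.random.Generator) -> Demographics:
    age = rng.uniform(*spec.age_range)
    sex = float(rng.random() < spec.sex_ratio)
    weight = float(np.clip(rng.normal(*spec.weight_mean_sd), 45.0, 120.0))
    height = float(np.clip(rng.normal(*spec.height_mean_sd), 150.0, 200.0))
    shoe = float(np.clip(rng.normal(*spec.shoe_mean_sd), 35.0, 48.0))
    return Demographics(age=age, sex=sex, weight=weight, height=height, shoe_size=shoe)


def generate_cohort(spec: CohortSpec, mode: str = "aligned") -> CohortResult:
    """Generate a synthetic healthy cohort.

    ``mode="aligned"`` emits one per-foot image per subject, already on the
    common grid: the signal plus one between-subject residual field of SD
    ``noise_sd_kpa`` (the within-foot measurement noise is taken as averaged
    out over the K repeats).  This is the correctly specified input for
    model fitting.

    ``mode="repeats"`` emits K images per foot, each under an independent
    small rigid misalignment and independent within-foot noise on top of the
    subject's field -- the raw input for the alignment and averaging stages.
    """
    if spec.n_subjects < 2:
        raise ValueError("a cohort needs at least two subjects")
    if mode not in ("aligned", "repeats"):
        raise ValueError("mode must be 'aligned' or 'repeats'")
    root = np.random.default_rng(spec.seed)
    demo_rng, noise_rng, mis_rng = (
        np.random.default_rng(s) for s in root.integers(0, 2**31 - 1, size=3)
    )
    ph = spec.phenotype
    spacing = (ph.spacing_mm, ph.spacing_mm)
    center_mm = (
        ph.shape[0] / 2.0 * ph.spacing_mm,
        ph.shape[1] / 2.0 * ph.spacing_mm,
    )
    envelope = _noise_envelope(
        _signal_image(ph, spec.reference, spec.effects, spec.reference)
    )

    records, rows, images = [], [], []
    for i in range(spec.n_subjects):
        z = _draw_demographics(spec, demo_rng)
        records.append(z)
        rows.append({
            "subject_id": f"S{i:03d}", "foot_id": f"S{i:03d}_L", "side": "left",
            "age": z.age, "sex": z.sex, "weight": z.weight,
            "height": z.height, "shoe_size": z.shoe_size,
        })
        signal = _signal_image(ph, z, spec.effects, spec.reference)
        subject_field = envelope * spec.noise_sd_kpa * smooth_unit_noise(
            ph.shape, spec.noise_corr_sigma_px, noise_rng
        )
        if mode == "aligned":
            data = np.clip(signal + subject_field, 0.0, None)
            images.append(PressureImage(data=data, spacing=spacing, side="left",
                                        subject_id=rows[-1]["subject_id"],
                                        foot_id=rows[-1]["foot_id"]))
        else:
            repeats = []
            for k in range(spec.k_repeats):
                noise = envelope * spec.repeat_noise_sd_kpa * smooth_unit_noise(
                    ph.shape, spec.noise_corr_sigma_px, noise_rng
                )
                img = PressureImage(
                    data=np.clip(signal + subject_field + noise, 0.0, None),
                    spacing=spacing, side="left",
                    subject_id=rows[-1]["subject_id"], foot_id=rows[-1]["foot_id"],
                )
                angle = np.deg2rad(mis_rng.uniform(-spec.misalign_rot_deg,
                                                   spec.misalign_rot_deg))
                trans = mis_rng.uniform(-spec.misalign_trans_mm,
                                        spec.misalign_trans_mm, size=2)
                perturb = RigidTransform2D(angle=angle, translation=tuple(trans),
                                           center=center_mm)
                repeats.append(apply_transform(img, rigid=perturb, interpolation="cubic"))
            images.append(repeats)

    return CohortResult(
        images=images,
        demographics=pd.DataFrame(rows),
        demographics_records=records,
        truth_coefficients=ground_truth_coefficient_maps(spec),
        noise_sd_map=spec.noise_sd_kpa * envelope,
        spec=spec,
        mode=mode,
    )


def inject_abnormality(
    image: PressureImage,
    region_center: tuple[float, float],
    radius_px: float,
    magnitude_in_model_sd: float,
    model: PixelwiseModel,
) -> tuple[PressureImage, np.ndarray]:
    """Add a regional abnormality of ``magnitude * s(x)`` to an image.

    The bump is flat (full magnitude) within ``radius_px`` of the center and
    Gaussian-tapered outside, restricted to the model domain.  Negative
    magnitudes create pressure deficits.  Returns the modified image and the
    ground-truth boolean mask of affected pixels (taper >= 0.5).
    """
    rows = np.arange(image.data.shape[0])[:, None]
    cols = np.arange(image.data.shape[1])[None, :]
    dist = np.sqrt((rows - region_center[0]) ** 2 + (cols - region_center[1]) ** 2)
    taper_sigma = max(radius_px / 2.0, 1e-6)
    taper = np.where(
        dist <= radius_px, 1.0,
        np.exp(-((dist - radius_px) ** 2) / (2.0 * taper_sigma**2)),
    )
    taper = np.where(model.domain.data, taper, 0.0)
    if not (model.domain.data[
        int(round(region_center[0])), int(round(region_center[1]))
    ]):
        raise ValueError("abnormality center must lie inside the model domain")
    bump = magnitude_in_model_sd * model.residual_sd * taper
    modified = replace(image, data=np.clip(image.data + bump, 0.0, None))
    return modified, taper >= 0.5


def simulate_patient_from_model(
    model: PixelwiseModel,
    z: Demographics,
    seed: int | np.random.Generator = 0,
    noise_corr_sigma_px: float = 2.0,
    noise_scale: float = 1.0,
) -> PressureImage:
    """Simulate a null patient image from the fitted model.

    The personalized prediction plus a smooth residual field with pixel SD
    ``noise_scale * s(x)`` -- exactly the population the model believes
    healthy feet are drawn from.  Used for null calibration of the
    family-wise error rate.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pred = predict_pressures(model, z)
    noise = smooth_unit_noise(pred.data.shape, noise_corr_sigma_px, rng)
    data = pred.data + noise_scale * model.residual_sd * noise
    data = np.where(model.domain.data, data, pred.data)
    return replace(pred, data=np.clip(data, 0.0, None))
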