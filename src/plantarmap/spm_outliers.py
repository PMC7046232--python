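"""Single-case statistical parametric mapping of plantar pressure outliers.

Given a patient's aligned peak-pressure image and their personalized
prediction from the pixel-wise model, this module computes the residual map
R(x), converts it to a statistical parametric map of t-statistics SPM{t},
thresholds it with random field theory (RFT) at a family-wise significance
level, extracts suprathreshold clusters, and classifies them into
clinically meaningful foot-region patterns (heel, midfoot, metatarsal 1,
metatarsals 2-5, toes).

t-statistic variants
--------------------
The default "crawford" variant is the Crawford-Howell / prediction-interval
form used in single-case comparisons against a normative regression:

    t(x) = R(x) / ( s(x) * sqrt(1 + z (Z^T Z)^{-1} z^T) ),  dof = N - p.

It accounts for the uncertainty of the predicted baseline at the patient's
design point (the leverage term) and has correct single-case type-I
behaviour.  A "naive" variant (R/s) and a "literal" variant (R/(s/sqrt(N)))
are available for sensitivity analysis; the literal form treats the single
residual as if it were a sample mean of N observations and is therefore
strongly anti-conservative.

RFT thresholding uses the expected Euler characteristic of a 2D t-field
(Worsley EC densities, resel counts of order 0-2) with the field smoothness
(FWHM) estimated from the model's standardized residuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import lgamma

import numpy as np
from scipy import optimize, stats
from skimage import measure

from .pixel_model import Demographics, PixelwiseModel, predict_pressures
from .pressure_io import (
    PressureImage,
    PressureVideo,
    SilhouetteMask,
    compute_silhouette,
    flip_to_left,
    normalize_video,
    peak_pressure_image,
    resample_square,
)
from .registration import (
    DemonsConfig,
    RigidRegistrationConfig,
    apply_transform,
    demons_register,
    dice_overlap,
    rigid_register,
)
from .templating import TemplateResult

__all__ = [
    "TMap",
    "AbnormalityMap",
    "Cluster",
    "RegionMask",
    "RegionGeometry",
    "PatternReport",
    "SmoothnessEstimate",
    "residual_map",
    "t_map",
    "estimate_smoothness",
    "rft_threshold",
    "build_region_mask",
    "classify_patterns",
    "analyze_patient",
    "REGION_NAMES",
]

REGION_NAMES = ("background", "heel", "midfoot", "mt1", "mt2_5", "toes")
PATTERN_NAMES = (
    "mt1_increase",
    "toes_abnormal",
    "midfoot_increase",
    "mt2_5_abnormal",
    "heel_abnormal",
)


# ---------------------------------------------------------------------------
# t-maps
# ---------------------------------------------------------------------------

@dataclass
class TMap:
    """Per-pixel t-statistics inside the model domain."""

    t: np.ndarray
    dof: int
    variant: str
    domain: SilhouetteMask
    capped_pixels: int = 0


def residual_map(aligned_patient: PressureImage, predicted: PressureImage,
                 domain: SilhouetteMask | None = None) -> PressureImage:
    """Residuals R(x) = measured - predicted, restricted to the model domain.

    Positive residuals mean the patient's measured pressure exceeds the
    personalized healthy baseline.
    """
    if aligned_patient.data.shape != predicted.data.shape:
        raise ValueError("patient and predicted images must share a grid")
    resid = aligned_patient.data - predicted.data
    if domain is not None:
        resid = np.where(domain.data, resid, 0.0)
    out = PressureImage(
        data=resid,
        spacing=predicted.spacing,
        side=predicted.side,
        normalized=predicted.normalized,
        norm_divisor=predicted.norm_divisor,
    )
    return out


def t_map(
    residuals: PressureImage,
    model: PixelwiseModel,
    z_new: Demographics,
    variant: str = "crawford",
    cap: float = 1e6,
) -> TMap:
    """Convert a residual map into a single-case SPM{t}.

    ``variant``: "crawford" (default; leverage-corrected prediction-interval
    t), "naive" (R/s), or "literal" (R/(s/sqrt(N))).  Pixels with s = 0 and
    R = 0 give t = 0; s = 0 with R != 0 caps at +-``cap`` and is counted.
    """
    if variant not in ("crawford", "naive", "literal"):
        raise ValueError(f"unknown t variant {variant!r}")
    rows, cols = model.domain_indices
    r = residuals.data[rows, cols]
    s = model.residual_sd[rows, cols]

    if variant == "crawford":
        denom_scale = np.sqrt(1.0 + model.leverage(z_new))
    elif variant == "naive":
        denom_scale = 1.0
    else:  # literal
        denom_scale = 1.0 / np.sqrt(model.n_subjects)

    denom = s * denom_scale
    t = np.zeros_like(r)
    ok = denom > 0
    t[ok] = r[ok] / denom[ok]
    bad = (~ok) & (r != 0)
    t[bad] = np.sign(r[bad]) * cap
    capped = int(bad.sum())

    t_full = np.zeros(model.domain.data.shape)
    t_full[rows, cols] = t
    return TMap(
        t=t_full,
        dof=model.dof,
        variant=variant,
        domain=model.domain,
        capped_pixels=capped,
    )


# ---------------------------------------------------------------------------
# Smoothness estimation and random field theory
# ---------------------------------------------------------------------------

@dataclass
class SmoothnessEstimate:
    """Estimated residual-field smoothness and resel counts of the domain."""

    fwhm: float          # geometric-mean FWHM in pixels
    fwhm_per_axis: tuple[float, float]
    resels: tuple[float, float, float]  # (R0, R1, R2)
    area_px: int


def estimate_smoothness(model: PixelwiseModel) -> SmoothnessEstimate:
    """Estimate residual-field FWHM from standardized residual derivatives.

    The N residual fields are normalized pixel-wise by the residual sum of
    squares, and the variance of their spatial partial derivatives gives the
    roughness per axis; FWHM_d = sqrt(4 ln 2 / lambda_d) (the standard SPM
    resel formulation).  Resel counts: R2 = area / (FWHM_x * FWHM_y),
    R1 = half-perimeter / FWHM, R0 = 1 (Euler characteristic of the
    footprint domain).
    """
    mask = model.domain.data
    rows, cols = np.nonzero(mask)
    if len(rows) == 0:
        raise ValueError("empty model domain")
    extent = (rows.max() - rows.min() + 1, cols.max() - cols.min() + 1)
    if min(extent) < 4:
        raise ValueError("model domain too small for smoothness estimation (< 4 px extent)")

    shape = mask.shape
    n = model.residual_matrix.shape[0]
    # embed standardized residuals: u_i(x) = eps_i(x) / sqrt(sum_i eps_i(x)^2)
    ss = np.sqrt((model.residual_matrix**2).sum(axis=0))
    ss = np.where(ss > 0, ss, np.inf)
    u = np.full((n, *shape), np.nan)
    u[:, rows, cols] = model.residual_matrix / ss

    lambdas = []
    for axis in (0, 1):
        du = np.diff(u, axis=axis + 1)
        valid = ~np.isnan(du)
        # an edge is valid when both endpoints lie inside the domain
        if valid.any():
            lam = float(np.nanmean(np.where(valid, du, np.nan) ** 2) * n)
        else:
            lam = np.inf
        lambdas.append(lam)

    fwhms = []
    for lam in lambdas:
        if lam <= 0 or not np.isfinite(lam):
            fwhms.append(1.0)
        else:
            fwhms.append(max(float(np.sqrt(4.0 * np.log(2.0) / lam)), 1.0))
    fwhm = float(np.sqrt(fwhms[0] * fwhms[1]))

    area = int(mask.sum())
    perimeter = float(measure.perimeter(mask, neighborhood=4))
    r2 = area / (fwhms[0] * fwhms[1])
    r1 = perimeter / (2.0 * fwhm)
    return SmoothnessEstimate(
        fwhm=fwhm,
        fwhm_per_axis=(fwhms[0], fwhms[1]),
        resels=(1.0, r1, r2),
        area_px=area,
    )


def _ec_density_t(t: float, dof: float, order: int) -> float:
    """Worsley EC densities of a t-field (order 0, 1, 2), per unit resel."""
    nu = float(dof)
    if order == 0:
        return float(stats.t.sf(t, nu))
    base = (1.0 + t * t / nu) ** (-(nu - 1.0) / 2.0)
    four_ln2 = 4.0 * np.log(2.0)
    if order == 1:
        return float(np.sqrt(four_ln2) / (2.0 * np.pi) * base)
    if order == 2:
        lg = lgamma((nu + 1.0) / 2.0) - lgamma(nu / 2.0)
        const = four_ln2 / (2.0 * np.pi) ** 1.5 * np.exp(lg) / np.sqrt(nu / 2.0)
        return float(const * t * base)
    raise ValueError("order must be 0, 1 or 2")


def expected_euler_characteristic(t: float, dof: float,
                                  resels: tuple[float, float, float]) -> float:
    """Expected EC of the suprathreshold set of a smooth 2D t-field."""
    r0, r1, r2 = resels
    return (
        r0 * _ec_density_t(t, dof, 0)
        + r1 * _ec_density_t(t, dof, 1)
        + r2 * _ec_density_t(t, dof, 2)
    )


def critical_t_rft(dof: float, resels: tuple[float, float, float],
                   alpha: float = 0.05, two_sided: bool = True) -> float:
    """Solve expected-EC(t) = alpha (alpha/2 per tail if two-sided)."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    tail = alpha / 2.0 if two_sided else alpha

    def f(t: float) -> float:
        return expected_euler_characteristic(t, dof, resels) - tail

    lo, hi = 0.5, 100.0
    if f(lo) < 0:  # already below alpha at a trivial threshold
        return lo
    if f(hi) > 0:
        # for dof <= 2 the second-order EC density does not decay to zero,
        # so no finite threshold controls the family-wise rate
        raise ValueError(
            f"no RFT threshold exists at dof={dof} with resels={resels}; "
            "the model needs more subjects"
        )
    return float(optimize.brentq(f, lo, hi, xtol=1e-8))


@dataclass
class Cluster:
    """One 8-connected suprathreshold component of the thresholded SPM{t}."""

    pixels: np.ndarray  # (k, 2) array of (row, col) indices
    sign: int           # +1: measured > predicted, -1: measured < predicted
    peak_t: float
    extent: int


@dataclass
class AbnormalityMap:
    """RFT-thresholded SPM{t} with its suprathreshold clusters."""

    thresholded_t: np.ndarray
    critical_t: float
    clusters: list[Cluster]
    fwhm: float
    resels: tuple[float, float, float]
    alpha: float
    two_sided: bool
    dof: int

    @property
    def n_suprathreshold(self) -> int:
        return int(np.count_nonzero(self.thresholded_t))


def _extract_clusters(t: np.ndarray, critical_t: float) -> list[Cluster]:
    clusters: list[Cluster] = []
    for sign in (1, -1):
        mask = (sign * t) >= critical_t
        labels = measure.label(mask, connectivity=2)
        for lab in range(1, labels.max() + 1):
            px = np.argwhere(labels == lab)
            vals = t[px[:, 0], px[:, 1]]
            peak = vals[np.argmax(np.abs(vals))]
            clusters.append(Cluster(pixels=px, sign=sign, peak_t=float(peak), extent=len(px)))
    return clusters


def rft_threshold(
    tmap: TMap,
    smoothness: SmoothnessEstimate,
    alpha: float = 0.05,
    two_sided: bool = True,
) -> AbnormalityMap:
    """Threshold a t-map at the RFT family-wise critical value.

    Pixels with |t| below the critical value are zeroed; the surviving
    pixels are grouped into signed 8-connected clusters.
    """
    if tmap.dof < 1:
        raise ValueError("t-map degrees of freedom must be >= 1")
    if smoothness.resels[2] <= 0:
        raise ValueError("resel count must be positive")
    tc = critical_t_rft(tmap.dof, smoothness.resels, alpha=alpha, two_sided=two_sided)
    thresholded = np.where(np.abs(tmap.t) >= tc, tmap.t, 0.0)
    if not two_sided:
        thresholded = np.where(tmap.t >= tc, tmap.t, 0.0)
    clusters = _extract_clusters(tmap.t if two_sided else np.clip(tmap.t, 0, None), tc)
    if not two_sided:
        clusters = [c for c in clusters if c.sign > 0]
    return AbnormalityMap(
        thresholded_t=thresholded,
        critical_t=tc,
        clusters=clusters,
        fwhm=smoothness.fwhm,
        resels=smoothness.resels,
        alpha=alpha,
        two_sided=two_sided,
        dof=tmap.dof,
    )


# ---------------------------------------------------------------------------
# Foot regions and pattern classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionGeometry:
    """Fractional anatomical bands along the anterior-posterior foot axis.

    Fractions are measured from the posterior (heel) end of the silhouette.
    The metatarsal band is split medially for MT1: the medial
    ``mt1_width_fraction`` of each row's footprint width.  ``medial_side``
    states which column border is medial for left-oriented images.
    """

    heel_end: float = 0.31
    midfoot_end: float = 0.55
    metatarsal_end: float = 0.81
    mt1_width_fraction: float = 0.36
    medial_side: str = "high"  # "high": medial at high column index

    def __post_init__(self) -> None:
        if not (0 < self.heel_end < self.midfoot_end < self.metatarsal_end < 1):
            raise ValueError("region fractions must be increasing within (0, 1)")
        if self.medial_side not in ("high", "low"):
            raise ValueError("medial_side must be 'high' or 'low'")


@dataclass
class RegionMask:
    """Per-pixel foot-region labels on the template grid.

    Label ids index into REGION_NAMES: 0 background, 1 heel, 2 midfoot,
    3 MT1, 4 MT2-5, 5 toes.  The labelled regions partition the silhouette.
    """

    labels: np.ndarray
    geometry: RegionGeometry

    def region(self, name: str) -> np.ndarray:
        return self.labels == REGION_NAMES.index(name)


def build_region_mask(
    template: TemplateResult | SilhouetteMask,
    geometry: RegionGeometry | None = None,
) -> RegionMask:
    """Partition the template silhouette into the five merged foot regions.

    Bands along the anterior-posterior axis (fractions of foot length):
    heel, midfoot, metatarsals, toes; within the metatarsal band the medial
    fraction of each row's footprint width is labelled MT1.  This mirrors
    the conventional 10-region pedobarographic mask with medial/lateral
    heel merged, metatarsals 2-5 merged, and hallux merged with the toes.
    """
    geometry = geometry or RegionGeometry()
    sil = template.silhouette if isinstance(template, TemplateResult) else template
    mask = sil.data
    if not mask.any():
        raise ValueError("cannot build regions from an empty silhouette")
    rows = np.nonzero(mask.any(axis=1))[0]
    r0, r1 = rows.min(), rows.max()
    length = r1 - r0 + 1

    labels = np.zeros(mask.shape, dtype=np.int8)
    for r in range(r0, r1 + 1):
        cols = np.nonzero(mask[r])[0]
        if cols.size == 0:
            continue
        frac = (r - r0 + 0.5) / length
        if frac < geometry.heel_end:
            labels[r, cols] = REGION_NAMES.index("heel")
        elif frac < geometry.midfoot_end:
            labels[r, cols] = REGION_NAMES.index("midfoot")
        elif frac < geometry.metatarsal_end:
            width = cols.max() - cols.min() + 1
            n_mt1 = max(int(round(geometry.mt1_width_fraction * width)), 1)
            if geometry.medial_side == "high":
                mt1_cols = cols[cols > cols.max() - n_mt1]
            else:
                mt1_cols = cols[cols < cols.min() + n_mt1]
            labels[r, cols] = REGION_NAMES.index("mt2_5")
            labels[r, mt1_cols] = REGION_NAMES.index("mt1")
        else:
            labels[r, cols] = REGION_NAMES.index("toes")
    return RegionMask(labels=labels, geometry=geometry)


@dataclass
class PatternReport:
    """Which of the five abnormality patterns a foot displays.

    The MT1 and midfoot patterns require pressure increases (positive
    clusters); toes, MT2-5 and heel accept either sign.  ``no_abnormality``
    is true exactly when no pattern flag is set.
    """

    mt1_increase: bool = False
    toes_abnormal: bool = False
    midfoot_increase: bool = False
    mt2_5_abnormal: bool = False
    heel_abnormal: bool = False
    region_overlap: dict = field(default_factory=dict)

    @property
    def no_abnormality(self) -> bool:
        return not any(getattr(self, name) for name in PATTERN_NAMES)

    def to_dict(self) -> dict:
        out = {name: bool(getattr(self, name)) for name in PATTERN_NAMES}
        out["no_abnormality"] = self.no_abnormality
        return out


def classify_patterns(
    abmap: AbnormalityMap,
    regions: RegionMask,
    min_overlap_px: int = 4,
) -> PatternReport:
    """Classify suprathreshold clusters into foot-region abnormality patterns.

    A pattern flag is raised when a significant cluster of the required sign
    overlaps its region by at least ``min_overlap_px`` pixels (default 4, a
    minimally meaningful extent).
    """
    overlap: dict[str, dict[str, int]] = {
        name: {"positive": 0, "negative": 0} for name in REGION_NAMES[1:]
    }
    for cluster in abmap.clusters:
        lab = regions.labels[cluster.pixels[:, 0], cluster.pixels[:, 1]]
        key = "positive" if cluster.sign > 0 else "negative"
        for rid, name in enumerate(REGION_NAMES):
            if rid == 0:
                continue
            overlap[name][key] += int((lab == rid).sum())

    def hit(name: str, signs: tuple[str, ...]) -> bool:
        return any(overlap[name][s] >= min_overlap_px for s in signs)

    return PatternReport(
        mt1_increase=hit("mt1", ("positive",)),
        midfoot_increase=hit("midfoot", ("positive",)),
        toes_abnormal=hit("toes", ("positive", "negative")),
        mt2_5_abnormal=hit("mt2_5", ("positive", "negative")),
        heel_abnormal=hit("heel", ("positive", "negative")),
        region_overlap=overlap,
    )


# ---------------------------------------------------------------------------
# End-to-end patient analysis
# ---------------------------------------------------------------------------

def _preprocess_video(video: PressureVideo, target_mm: float, tau_kpa: float) -> PressureImage:
    video = resample_square(video, target_mm)
    video = normalize_video(video, tau_kpa)
    image = peak_pressure_image(video)
    if image.side is not None:
        image = flip_to_left(image)
    return image


def analyze_patient(
    patient: PressureVideo | PressureImage,
    demographics: Demographics,
    model: PixelwiseModel,
    regions: RegionMask | None = None,
    t_variant: str = "crawford",
    alpha: float = 0.05,
    two_sided: bool = True,
    min_overlap_px: int = 4,
    dice_floor: float = 0.85,
    align: bool = True,
    seed: int = 0,
    rigid_config: RigidRegistrationConfig | None = None,
    demons_config: DemonsConfig | None = None,
    target_mm: float = 3.0,
    tau_kpa: float = 5.0,
) -> tuple[AbnormalityMap, PatternReport, dict]:
    """Full single-case analysis of one patient's plantar pressures.

    Preprocesses the measurement (if given as a video), predicts the
    personalized baseline, aligns the patient image to the prediction
    (rigid + silhouette demons; skipped with ``align=False`` for images
    already on the template grid), computes residuals, the single-case
    SPM{t}, the RFT-thresholded abnormality map, and the region-pattern
    report.  The QC record carries the alignment Dice; below ``dice_floor``
    the result is flagged unreliable (severe deformity caveat).
    """
    if isinstance(patient, PressureVideo):
        patient_img = _preprocess_video(patient, target_mm, tau_kpa)
    else:
        patient_img = patient

    predicted = predict_pressures(model, demographics)
    sil_threshold = model.domain.threshold_kpa

    if align:
        rigid = rigid_register(patient_img, predicted, config=rigid_config, seed=seed)
        moved = apply_transform(patient_img, rigid=rigid, interpolation="cubic")
        moving_sil = compute_silhouette(moved, sil_threshold)
        fixed_sil = SilhouetteMask(
            model.domain.data, sil_threshold, model.template.spacing
        )
        if moving_sil.data.any() and fixed_sil.data.any():
            defo = demons_register(moving_sil, fixed_sil, config=demons_config)
        else:
            defo = None
        aligned = apply_transform(patient_img, rigid=rigid, deformation=defo,
                                  interpolation="cubic")
    else:
        if patient_img.data.shape != model.domain.data.shape:
            raise ValueError("align=False requires the patient image on the template grid")
        aligned = patient_img

    aligned_sil = compute_silhouette(aligned, sil_threshold)
    dice = dice_overlap(aligned_sil.data, model.domain.data)

    residuals = residual_map(aligned, predicted, domain=model.domain)
    tmap = t_map(residuals, model, demographics, variant=t_variant)
    smoothness = estimate_smoothness(model)
    abmap = rft_threshold(tmap, smoothness, alpha=alpha, two_sided=two_sided)
    regions = regions or build_region_mask(
        SilhouetteMask(model.domain.data, sil_threshold, model.template.spacing)
    )
    report = classify_patterns(abmap, regions, min_overlap_px=min_overlap_px)

    qc = {
        "alignment_dice": float(dice),
        "unreliable": bool(dice < dice_floor),
        "critical_t": abmap.critical_t,
        "fwhm_px": smoothness.fwhm,
        "resels": smoothness.resels,
        "t_variant": t_variant,
        "n_suprathreshold": abmap.n_suprathreshold,
        "n_clusters": len(abmap.clusters),
        "n_clamped_predictions": getattr(predicted, "n_clamped", 0),
        "capped_t_pixels": tmap.capped_pixels,
        "aligned_image": aligned,
        "predicted_image": predicted,
        "t_map": tmap,
    }
    return abmap, report, qc
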