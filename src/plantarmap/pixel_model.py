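"""Pixel-wise linear regression of healthy peak pressures on demographics.

At every pixel x inside the template silhouette, healthy peak pressures are
modelled as

    y(x) = Z b(x) + eps(x),    eps(x) ~ N(0, s^2(x)),

where each row of the design matrix Z is a subject's demographics vector
[age, sex, weight, height, shoe_size, 1] and y(x) stacks the N subjects'
aligned peak pressures at that pixel.  The coefficients b(x) are the OLS
solution; the residual standard deviation s(x) (divisor N - p by default,
p = 6 regressors) captures the pressure variation demographics do not
explain and is the yardstick against which a new patient's residuals are
later judged.

The residual matrix is retained: it feeds both the normality diagnostics
(per-pixel Kolmogorov-Smirnov tests with Benjamini-Hochberg FDR control)
and the spatial smoothness estimate required for random-field-theory
thresholding.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .pressure_io import PressureImage, SilhouetteMask

__all__ = [
    "Demographics",
    "PixelwiseModel",
    "NormalityReport",
    "fit_pixelwise_model",
    "predict_pressures",
    "check_normality",
    "demographics_from_frame",
]

COVARIATE_NAMES = ("age", "sex", "weight", "height", "shoe_size", "intercept")
N_REGRESSORS = len(COVARIATE_NAMES)


@dataclass(frozen=True)
class Demographics:
    """One participant's demographic covariates.

    Units: age in years, sex coded 0 = female / 1 = male, weight in kg,
    height in cm, shoe size on the EU scale.  The assembled design vector is
    [age, sex, weight, height, shoe_size, 1].
    """

    age: float
    sex: float
    weight: float
    height: float
    shoe_size: float

    def __post_init__(self) -> None:
        if self.sex not in (0, 1, 0.0, 1.0):
            raise ValueError("sex must be coded 0 (female) or 1 (male)")

    @property
    def vector(self) -> np.ndarray:
        return np.array([self.age, self.sex, self.weight, self.height, self.shoe_size, 1.0])


def demographics_from_frame(df: pd.DataFrame) -> list[Demographics]:
    """Build Demographics records from a table with the standard columns."""
    return [
        Demographics(
            age=float(row["age"]),
            sex=float(row["sex"]),
            weight=float(row["weight"]),
            height=float(row["height"]),
            shoe_size=float(row["shoe_size"]),
        )
        for _, row in df.iterrows()
    ]


@dataclass
class PixelwiseModel:
    """A fitted per-pixel regression model over the template silhouette.

    ``coefficients`` has shape (6, nx, ny) (zero outside the domain);
    ``residual_sd`` is s(x); ``residual_matrix`` has shape (N, n_domain)
    in the flat ordering of ``domain_indices``.
    """

    template: PressureImage
    domain: SilhouetteMask
    coefficients: np.ndarray
    residual_sd: np.ndarray
    residual_matrix: np.ndarray
    design: np.ndarray
    n_subjects: int
    variance_divisor: str = "model"  # "model": N - p; "sample": N - 1

    def __post_init__(self) -> None:
        self._xtx_inv = np.linalg.pinv(self.design.T @ self.design)

    @property
    def domain_indices(self) -> tuple[np.ndarray, np.ndarray]:
        return np.nonzero(self.domain.data)

    @property
    def n_pixels(self) -> int:
        return int(self.domain.data.sum())

    @property
    def dof(self) -> int:
        return self.n_subjects - N_REGRESSORS

    def leverage(self, z: Demographics | np.ndarray) -> float:
        """Design-space leverage z^T (Z^T Z)^{-1} z of a demographics vector."""
        v = z.vector if isinstance(z, Demographics) else np.asarray(z, float)
        return float(v @ self._xtx_inv @ v)

    def residual_sd_map(self) -> np.ndarray:
        return self.residual_sd

    def save(self, directory: str | Path) -> None:
        """Persist coefficient/SD maps (NIfTI), design matrix (CSV) and metadata."""
        from .pressure_io import write_pressure_image

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        spacing = self.template.spacing
        for j, name in enumerate(COVARIATE_NAMES):
            write_pressure_image(
                PressureImage(self.coefficients[j], spacing), directory / f"coef_{name}.nii"
            )
        write_pressure_image(PressureImage(self.residual_sd, spacing), directory / "residual_sd.nii")
        write_pressure_image(self.template, directory / "template.nii")
        np.savetxt(directory / "residual_matrix.csv", self.residual_matrix, delimiter=",")
        pd.DataFrame(self.design, columns=COVARIATE_NAMES).to_csv(
            directory / "design.csv", index=False
        )
        meta = {
            "n_subjects": self.n_subjects,
            "covariate_order": list(COVARIATE_NAMES),
            "variance_divisor": self.variance_divisor,
            "spacing_mm": list(spacing),
            "domain_threshold_kpa": self.domain.threshold_kpa,
        }
        with open(directory / "model.json", "w") as fh:
            json.dump(meta, fh, indent=2)
        np.savetxt(directory / "domain.csv", self.domain.data.astype(int), fmt="%d", delimiter=",")

    @classmethod
    def load(cls, directory: str | Path) -> "PixelwiseModel":
        from .pressure_io import read_pressure_image

        directory = Path(directory)
        with open(directory / "model.json") as fh:
            meta = json.load(fh)
        spacing = tuple(meta["spacing_mm"])
        coeffs = np.stack(
            [read_pressure_image(directory / f"coef_{n}.nii").data for n in COVARIATE_NAMES]
        )
        residual_sd = read_pressure_image(directory / "residual_sd.nii").data
        template = read_pressure_image(directory / "template.nii")
        template.spacing = spacing
        domain_data = np.loadtxt(directory / "domain.csv", delimiter=",").astype(bool)
        design = pd.read_csv(directory / "design.csv").to_numpy(float)
        residual_matrix = np.loadtxt(directory / "residual_matrix.csv", delimiter=",")
        if residual_matrix.ndim == 1:
            residual_matrix = residual_matrix[:, None]
        return cls(
            template=template,
            domain=SilhouetteMask(domain_data, meta["domain_threshold_kpa"], spacing),
            coefficients=coeffs,
            residual_sd=residual_sd,
            residual_matrix=residual_matrix,
            design=design,
            n_subjects=int(meta["n_subjects"]),
            variance_divisor=meta["variance_divisor"],
        )


@dataclass
class NormalityReport:
    """Per-pixel Kolmogorov-Smirnov normality diagnostics after FDR control."""

    p_map: np.ndarray
    rejected: np.ndarray
    corrected_alpha: float
    fraction_rejected: float
    degenerate_pixels: int = 0


def _check_design_rank(design: np.ndarray) -> None:
    rank = np.linalg.matrix_rank(design)
    if rank >= design.shape[1]:
        return
    offenders = []
    for j in range(design.shape[1]):
        others = np.delete(design, j, axis=1)
        col = design[:, j]
        fitted, *_ = np.linalg.lstsq(others, col, rcond=None)
        resid = col - others @ fitted
        scale = np.linalg.norm(col) or 1.0
        if np.linalg.norm(resid) / scale < 1e-8:
            offenders.append(COVARIATE_NAMES[j])
    raise ValueError(
        "design matrix is rank deficient; collinear columns: "
        + (", ".join(offenders) if offenders else "undetermined")
    )


def fit_pixelwise_model(
    aligned_images: list[PressureImage],
    demographics: list[Demographics],
    domain: SilhouetteMask,
    template: PressureImage | None = None,
    variance_divisor: str = "model",
) -> PixelwiseModel:
    """Fit the per-pixel OLS model over the template silhouette.

    All images must already be aligned to the template grid.  The solution
    uses a numerically stable least-squares factorization (not explicit
    normal equations).  ``variance_divisor='model'`` uses N - p (p = 6,
    unbiased under the regression model); ``'sample'`` uses N - 1.
    """
    n = len(aligned_images)
    if n != len(demographics):
        raise ValueError("need one demographics record per image")
    if n <= N_REGRESSORS:
        raise ValueError(
            f"need more subjects ({n}) than regressors ({N_REGRESSORS}) to fit the model"
        )
    if variance_divisor not in ("model", "sample"):
        raise ValueError("variance_divisor must be 'model' or 'sample'")
    shapes = {img.data.shape for img in aligned_images}
    if len(shapes) != 1 or aligned_images[0].data.shape != domain.data.shape:
        raise ValueError("all images and the domain mask must share a grid")

    design = np.stack([d.vector for d in demographics])
    _check_design_rank(design)

    rows, cols = np.nonzero(domain.data)
    y = np.stack([img.data[rows, cols] for img in aligned_images])  # (N, P)
    coefs, _, _, _ = np.linalg.lstsq(design, y, rcond=None)  # (6, P)
    residuals = y - design @ coefs  # (N, P)
    divisor = n - N_REGRESSORS if variance_divisor == "model" else n - 1
    s2 = (residuals**2).sum(axis=0) / divisor
    s = np.sqrt(s2)

    shape = domain.data.shape
    coef_maps = np.zeros((N_REGRESSORS, *shape))
    coef_maps[:, rows, cols] = coefs
    sd_map = np.zeros(shape)
    sd_map[rows, cols] = s

    tmpl = template if template is not None else aligned_images[0]
    return PixelwiseModel(
        template=tmpl,
        domain=domain,
        coefficients=coef_maps,
        residual_sd=sd_map,
        residual_matrix=residuals,
        design=design,
        n_subjects=n,
        variance_divisor=variance_divisor,
    )


def predict_pressures(model: PixelwiseModel, z_new: Demographics) -> PressureImage:
    """Personalized baseline peak-pressure image ``I_predict(x) = z_new . b(x)``.

    Zero outside the model domain; negative predictions are clamped to zero
    (with the count recorded on the returned image as ``n_clamped``).  A
    demographics vector outside the training ranges triggers an
    extrapolation warning, not an error.
    """
    v = z_new.vector
    lo = model.design.min(axis=0)
    hi = model.design.max(axis=0)
    outside = (v < lo) | (v > hi)
    if outside.any():
        names = [COVARIATE_NAMES[j] for j in np.nonzero(outside)[0]]
        warnings.warn(
            f"demographics outside training range for {names}; prediction extrapolates",
            stacklevel=2,
        )
    pred = np.tensordot(v, model.coefficients, axes=(0, 0))
    pred[~model.domain.data] = 0.0
    n_clamped = int((pred < 0).sum())
    pred = np.clip(pred, 0.0, None)
    image = PressureImage(
        data=pred,
        spacing=model.template.spacing,
        side="left",
        normalized=model.template.normalized,
        norm_divisor=model.template.norm_divisor,
    )
    image.n_clamped = n_clamped
    return image


def check_normality(model: PixelwiseModel, alpha: float = 0.05) -> NormalityReport:
    """Kolmogorov-Smirnov normality diagnostics of the per-pixel residuals.

    Each pixel's N residuals are tested against N(0, s^2(x)); the per-pixel
    p-values are corrected across the domain with Benjamini-Hochberg FDR at
    level ``alpha``.  Degenerate pixels (s = 0, perfect fit) record p = 1.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    rows, cols = model.domain_indices
    n_pix = len(rows)
    pvals = np.ones(n_pix)
    s = model.residual_sd[rows, cols]
    degenerate = 0
    for k in range(n_pix):
        if s[k] <= 0:
            degenerate += 1
            continue
        res = model.residual_matrix[:, k]
        pvals[k] = stats.kstest(res, "norm", args=(0.0, s[k])).pvalue
    reject, _, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    # realized BH cutoff: largest p-value among rejected tests (0 if none)
    corrected_alpha = float(pvals[reject].max()) if reject.any() else 0.0

    shape = model.domain.data.shape
    p_map = np.ones(shape)
    p_map[rows, cols] = pvals
    rejected_map = np.zeros(shape, dtype=bool)
    rejected_map[rows, cols] = reject
    return NormalityReport(
        p_map=p_map,
        rejected=rejected_map,
        corrected_alpha=corrected_alpha,
        fraction_rejected=float(reject.mean()) if n_pix else 0.0,
        degenerate_pixels=degenerate,
    )
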