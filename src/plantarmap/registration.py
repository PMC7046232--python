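"""Anatomical correspondence between plantar pressure images.

Two registration stages establish pixel-wise correspondence between feet:

1. **Rigid alignment** (rotation + translation) by maximizing histogram-based
   mutual information between peak-pressure images, optimized with a 1+1
   evolution strategy (single parent, Gaussian mutation, adaptive step size).
2. **Deformable alignment** of the binary footprint silhouettes by
   diffeomorphic demons: alternating demons force steps and Gaussian
   regularization, with the incremental update exponentiated via scaling and
   squaring so the accumulated field stays a diffeomorphism (positive
   Jacobian determinant everywhere).

Intensity information drives only the rigid stage; the deformable stage
matches foot outlines, which avoids warping pressure magnitude differences
away (those are exactly what the statistical analysis must preserve).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field, replace

import numpy as np
from scipy import ndimage

from .pressure_io import PressureImage, SilhouetteMask, compute_silhouette

__all__ = [
    "RigidTransform2D",
    "DeformationField",
    "RegistrationResult",
    "RigidRegistrationConfig",
    "DemonsConfig",
    "mutual_information",
    "rigid_register",
    "demons_register",
    "apply_transform",
    "average_transforms",
    "align_and_average_foot",
    "dice_overlap",
    "center_of_pressure",
]


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RigidTransform2D:
    """A 2D rigid transform: rotation about ``center`` followed by translation.

    Maps a physical point p (mm) to ``R (p - c) + c + t`` where R is the
    rotation by ``angle`` radians, c the center and t the translation in mm.
    """

    angle: float = 0.0
    translation: tuple[float, float] = (0.0, 0.0)
    center: tuple[float, float] = (0.0, 0.0)

    @property
    def rotation_matrix(self) -> np.ndarray:
        c, s = np.cos(self.angle), np.sin(self.angle)
        return np.array([[c, -s], [s, c]])

    def apply_points(self, points: np.ndarray) -> np.ndarray:
        """Apply the transform to an (n, 2) array of physical points."""
        p = np.atleast_2d(points)
        c = np.asarray(self.center)
        t = np.asarray(self.translation)
        out = (p - c) @ self.rotation_matrix.T + c + t
        return out.reshape(np.shape(points))

    def inverse(self) -> "RigidTransform2D":
        rinv = self.rotation_matrix.T
        t = np.asarray(self.translation)
        return RigidTransform2D(
            angle=-self.angle,
            translation=tuple(-rinv @ t),
            center=self.center,
        )

    def compose(self, other: "RigidTransform2D") -> "RigidTransform2D":
        """Return the transform equivalent to applying ``other`` first, then self."""
        r1, d1 = other.rotation_matrix, other._offset()
        r2, d2 = self.rotation_matrix, self._offset()
        # combined: p -> R2 (R1 p + d1) + d2
        angle = self.angle + other.angle
        d = r2 @ d1 + d2
        return RigidTransform2D(angle=angle, translation=tuple(d), center=(0.0, 0.0))

    def _offset(self) -> np.ndarray:
        """Offset d of the centered-at-origin form p -> R p + d."""
        c = np.asarray(self.center)
        t = np.asarray(self.translation)
        return c + t - self.rotation_matrix @ c

    def with_center(self, center: tuple[float, float]) -> "RigidTransform2D":
        """Re-express the same mapping with a different rotation center."""
        c_new = np.asarray(center)
        d = self._offset()
        t_new = self.rotation_matrix @ c_new + d - c_new
        return RigidTransform2D(angle=self.angle, translation=tuple(t_new), center=tuple(c_new))

    def is_identity(self, tol: float = 1e-12) -> bool:
        return abs(self.angle) < tol and np.allclose(self.translation, 0.0, atol=tol)


@dataclass
class DeformationField:
    """Dense per-pixel displacement field on the fixed-image grid.

    ``displacements`` has shape (2, nx, ny), in mm; the warp of an image A is
    ``A_warped(x) = A(x + u(x))`` (pull-back convention).
    """

    displacements: np.ndarray
    spacing: tuple[float, float]

    def __post_init__(self) -> None:
        self.displacements = np.asarray(self.displacements, dtype=float)
        if self.displacements.ndim != 3 or self.displacements.shape[0] != 2:
            raise ValueError("displacements must have shape (2, nx, ny)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.displacements.shape[1:]

    @property
    def jacobian_min(self) -> float:
        return float(jacobian_determinant(self.displacements, self.spacing).min())

    def is_identity(self, tol: float = 1e-12) -> bool:
        return bool(np.all(np.abs(self.displacements) < tol))

    @classmethod
    def identity(cls, shape: tuple[int, int], spacing: tuple[float, float]) -> "DeformationField":
        return cls(np.zeros((2, *shape)), spacing)

    def invert(self, n_iter: int = 8) -> "DeformationField":
        """Fixed-point inverse: v such that v(x) = -u(x + v(x))."""
        spacing = np.asarray(self.spacing)[:, None, None]
        u_px = self.displacements / spacing
        v_px = -u_px
        for _ in range(n_iter):
            v_px = -np.stack([_warp_by_disp_px(u_px[d], v_px, order=1) for d in range(2)])
        return DeformationField(v_px * spacing, self.spacing)


@dataclass
class RegistrationResult:
    """Bookkeeping for one pairwise registration."""

    rigid: RigidTransform2D
    field: DeformationField | None = None
    metric_trace: list[float] = dc_field(default_factory=list)
    dice: float | None = None
    converged: bool = True
    warning: str | None = None


def jacobian_determinant(displacements: np.ndarray, spacing: tuple[float, float]) -> np.ndarray:
    """Jacobian determinant of x -> x + u(x) from finite differences."""
    u0, u1 = displacements
    d00 = np.gradient(u0, spacing[0], axis=0)
    d01 = np.gradient(u0, spacing[1], axis=1)
    d10 = np.gradient(u1, spacing[0], axis=0)
    d11 = np.gradient(u1, spacing[1], axis=1)
    return (1.0 + d00) * (1.0 + d11) - d01 * d10


# ---------------------------------------------------------------------------
# Similarity metric
# ---------------------------------------------------------------------------

def mutual_information(image_a, image_b, bins: int = 50) -> float:
    """Histogram-based mutual information (nats) between two images.

    The joint histogram (``bins`` per dimension, default 50) is built over
    the union of both supports (pixels where either image is nonzero), with
    each image binned on [0, max].  Encourages homogeneous regions --
    including the background/foot boundary -- to overlap.
    """
    a = image_a.data if isinstance(image_a, PressureImage) else np.asarray(image_a, float)
    b = image_b.data if isinstance(image_b, PressureImage) else np.asarray(image_b, float)
    if a.shape != b.shape:
        raise ValueError("images must share a grid for mutual information")
    mask = (a > 0) | (b > 0)
    if not mask.any():
        return 0.0
    av, bv = a[mask], b[mask]
    amax = av.max() if av.max() > 0 else 1.0
    bmax = bv.max() if bv.max() > 0 else 1.0
    joint, _, _ = np.histogram2d(av, bv, bins=bins, range=[[0, amax], [0, bmax]])
    total = joint.sum()
    if total == 0:
        return 0.0
    pxy = joint / total
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    mi = float(np.sum(pxy[nz] * np.log(pxy[nz] / (px @ py)[nz])))
    return max(mi, 0.0)


def center_of_pressure(image: PressureImage) -> np.ndarray:
    """Intensity-weighted centroid in physical coordinates (mm)."""
    data = image.data
    total = data.sum()
    if total <= 0:
        return np.array([s * (n - 1) / 2 for s, n in zip(image.spacing, data.shape)])
    idx = np.indices(data.shape)
    com = np.array([float((idx[d] * data).sum() / total) for d in range(2)])
    return com * np.asarray(image.spacing) + np.asarray(image.origin)


# ---------------------------------------------------------------------------
# Rigid registration (1+1 evolution strategy on mutual information)
# ---------------------------------------------------------------------------

@dataclass
class RigidRegistrationConfig:
    """Hyper-parameters of the 1+1 evolution strategy.

    The strategy keeps a single parent, mutates (angle, translation) with
    Gaussian noise, accepts only improvements, and adapts the mutation step:
    grow on success, shrink on failure.
    """

    bins: int = 50
    initial_step_deg: float = 2.0
    initial_step_mm: float = 4.0
    grow: float = 1.05
    shrink: float = 0.98
    max_iter: int = 500
    tol_deg: float = 0.1
    tol_mm: float = 0.1
    centroid_init: bool = True
    multi_start_rotations_deg: tuple[float, ...] = ()


def _warp_rigid(data: np.ndarray, transform: RigidTransform2D,
                spacing: tuple[float, float], order: int = 1,
                out_shape: tuple[int, int] | None = None) -> np.ndarray:
    """Resample ``data`` through the moving->fixed transform onto the fixed grid."""
    inv = transform.inverse()
    s = np.diag(spacing)
    s_inv = np.diag([1.0 / spacing[0], 1.0 / spacing[1]])
    # index-space affine: idx_m = A idx_f + b
    a_mat = s_inv @ inv.rotation_matrix @ s
    b_vec = s_inv @ (inv.rotation_matrix @ (-np.asarray(inv.center))
                     + np.asarray(inv.center) + np.asarray(inv.translation))
    out = ndimage.affine_transform(
        data, a_mat, offset=b_vec, order=order, mode="constant", cval=0.0,
        output_shape=out_shape or data.shape,
    )
    if order > 1:
        out = np.clip(out, 0.0, None)
    return out


def rigid_register(
    moving: PressureImage,
    fixed: PressureImage,
    config: RigidRegistrationConfig | None = None,
    seed: int = 0,
    full_output: bool = False,
):
    """Rigid registration maximizing mutual information with a 1+1 evolution strategy.

    Rotation is parameterized about the moving image's center of pressure,
    which conditions the search well.  Translation is initialized from the
    center-of-pressure difference (configurable).  Returns the moving->fixed
    transform; with ``full_output=True`` a :class:`RegistrationResult` with
    the accepted-objective trace.
    """
    cfg = config or RigidRegistrationConfig()
    if moving.spacing != fixed.spacing:
        raise ValueError("rigid_register requires images with equal spacing")
    rng = np.random.default_rng(seed)
    spacing = moving.spacing
    center = tuple(center_of_pressure(moving))

    def objective(angle: float, t: np.ndarray) -> float:
        tr = RigidTransform2D(angle=angle, translation=tuple(t), center=center)
        warped = _warp_rigid(moving.data, tr, spacing, order=1, out_shape=fixed.data.shape)
        return mutual_information(fixed.data, warped, bins=cfg.bins)

    identity_mi = objective(0.0, np.zeros(2))

    init_t = np.zeros(2)
    if cfg.centroid_init:
        init_t = center_of_pressure(fixed) - center_of_pressure(moving)

    starts = [0.0] + [np.deg2rad(a) for a in cfg.multi_start_rotations_deg]
    best_angle, best_t, best_mi = 0.0, np.zeros(2), identity_mi
    trace: list[float] = [identity_mi]

    for start_angle in starts:
        angle, t = start_angle, init_t.copy()
        current = objective(angle, t)
        if current > best_mi:
            best_angle, best_t, best_mi = angle, t.copy(), current
        step_angle = np.deg2rad(cfg.initial_step_deg)
        step_mm = cfg.initial_step_mm
        for _ in range(cfg.max_iter):
            cand_angle = angle + step_angle * rng.standard_normal()
            cand_t = t + step_mm * rng.standard_normal(2)
            cand = objective(cand_angle, cand_t)
            if cand > current:
                angle, t, current = cand_angle, cand_t, cand
                step_angle *= cfg.grow
                step_mm *= cfg.grow
                trace.append(current)
                if current > best_mi:
                    best_angle, best_t, best_mi = angle, t.copy(), current
            else:
                step_angle *= cfg.shrink
                step_mm *= cfg.shrink
            if step_angle < np.deg2rad(cfg.tol_deg) and step_mm < cfg.tol_mm:
                break

    warning = None
    if best_mi <= identity_mi + 1e-12:
        best_angle, best_t = 0.0, np.zeros(2)
        warning = "optimizer failed to improve over identity"
        warnings.warn("rigid_register: " + warning, stacklevel=2)

    transform = RigidTransform2D(angle=best_angle, translation=tuple(best_t), center=center)
    if full_output:
        return RegistrationResult(
            rigid=transform, metric_trace=trace, converged=warning is None, warning=warning
        )
    return transform


# ---------------------------------------------------------------------------
# Diffeomorphic demons on silhouettes
# ---------------------------------------------------------------------------

@dataclass
class DemonsConfig:
    """Demons settings.

    ``lambda1`` couples the correspondence field to the smoothed field;
    ``lambda2`` penalizes field gradients.  Their ratio sets the diffusion
    smoothing, with ``sigma_fluid``/``sigma_diffusion`` (pixels) the
    realized Gaussian kernels for the update and accumulated field (both
    1.5 px at the default lambda1 = lambda2 = 2).
    """

    lambda1: float = 2.0
    lambda2: float = 2.0
    sigma_fluid: float = 1.5
    sigma_diffusion: float | None = None  # derived from lambda2/lambda1 if None
    max_iter: int = 60
    tol: float = 1e-4
    mask_presmooth: float = 1.0
    step_cap_px: float = 2.0
    n_squarings: int = 6

    def resolved_sigma_diffusion(self) -> float:
        if self.sigma_diffusion is not None:
            return self.sigma_diffusion
        return 1.5 * float(np.sqrt(self.lambda2 / self.lambda1))


def _warp_by_disp_px(data: np.ndarray, disp_px: np.ndarray, order: int = 1) -> np.ndarray:
    idx = np.indices(data.shape, dtype=float)
    coords = idx + disp_px
    return ndimage.map_coordinates(data, coords, order=order, mode="constant", cval=0.0)


def _compose_disp_px(outer: np.ndarray, inner: np.ndarray) -> np.ndarray:
    """Displacement of x -> x + inner(x) followed by x -> x + outer(x).

    Composite(x) = inner(x) + outer(x + inner(x)).
    """
    warped_outer = np.stack([_warp_by_disp_px(outer[d], inner, order=1) for d in range(2)])
    return inner + warped_outer


def _exp_disp_px(velocity_px: np.ndarray, n_squarings: int) -> np.ndarray:
    """Exponentiate a velocity field by scaling and squaring (diffeomorphic update)."""
    disp = velocity_px / (2.0 ** n_squarings)
    for _ in range(n_squarings):
        disp = _compose_disp_px(disp, disp)
    return disp


def dice_overlap(mask_a, mask_b) -> float:
    """Dice coefficient between two binary masks."""
    a = mask_a.data if isinstance(mask_a, SilhouetteMask) else np.asarray(mask_a, bool)
    b = mask_b.data if isinstance(mask_b, SilhouetteMask) else np.asarray(mask_b, bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * float(np.logical_and(a, b).sum()) / float(denom)


def demons_register(
    moving_mask: SilhouetteMask,
    fixed_mask: SilhouetteMask,
    config: DemonsConfig | None = None,
) -> DeformationField:
    """Diffeomorphic demons alignment of two footprint silhouettes.

    Alternates (i) a demons force step pulling the moving silhouette toward
    the fixed one with (ii) Gaussian smoothing of both the update and the
    accumulated field.  Each update is exponentiated by scaling and squaring
    before composition, so every accepted iterate has a strictly positive
    Jacobian determinant.  The returned field never worsens the silhouette
    Dice overlap relative to no deformation (identity fallback).
    """
    cfg = config or DemonsConfig()
    if moving_mask.data.shape != fixed_mask.data.shape:
        raise ValueError("demons_register requires masks on a common grid")
    if not moving_mask.data.any() or not fixed_mask.data.any():
        raise ValueError("demons_register requires nonempty masks")
    spacing = moving_mask.spacing
    fixed = ndimage.gaussian_filter(fixed_mask.data.astype(float), cfg.mask_presmooth)
    movs = ndimage.gaussian_filter(moving_mask.data.astype(float), cfg.mask_presmooth)

    disp = np.zeros((2, *fixed.shape))
    base_dice = dice_overlap(moving_mask, fixed_mask)
    best_disp = disp.copy()
    best_ssd = float(np.sum((fixed - movs) ** 2))
    prev_ssd = best_ssd
    eps = 1e-12

    for _ in range(cfg.max_iter):
        warped = _warp_by_disp_px(movs, disp, order=1)
        diff = fixed - warped
        grad = np.gradient(warped)
        g2 = grad[0] ** 2 + grad[1] ** 2
        denom = g2 + diff ** 2
        force = np.where(denom > eps, diff / np.maximum(denom, eps), 0.0)
        vel = np.stack([force * grad[0], force * grad[1]])
        norms = np.sqrt(vel[0] ** 2 + vel[1] ** 2)
        scale = np.where(norms > cfg.step_cap_px, cfg.step_cap_px / np.maximum(norms, eps), 1.0)
        vel *= scale
        vel = np.stack([ndimage.gaussian_filter(vel[d], cfg.sigma_fluid) for d in range(2)])
        update = _exp_disp_px(vel, cfg.n_squarings)
        cand = _compose_disp_px(disp, update)
        cand = np.stack(
            [ndimage.gaussian_filter(cand[d], cfg.resolved_sigma_diffusion()) for d in range(2)]
        )
        jac = jacobian_determinant(cand * np.asarray(spacing)[:, None, None], spacing)
        if jac.min() <= 0:
            break  # reject non-diffeomorphic iterate, keep best so far
        disp = cand
        warped_now = _warp_by_disp_px(movs, disp, order=1)
        ssd = float(np.sum((fixed - warped_now) ** 2))
        if ssd < best_ssd:
            best_ssd = ssd
            best_disp = disp.copy()
        if abs(prev_ssd - ssd) < cfg.tol * max(prev_ssd, eps):
            break
        prev_ssd = ssd

    field = DeformationField(best_disp * np.asarray(spacing)[:, None, None], spacing)
    warped_mask = _warp_by_disp_px(moving_mask.data.astype(float), best_disp, order=1) > 0.5
    if dice_overlap(warped_mask, fixed_mask) < base_dice:
        field = DeformationField.identity(fixed.shape, spacing)
    return field


# ---------------------------------------------------------------------------
# Transform application and averaging
# ---------------------------------------------------------------------------

def apply_transform(
    image: PressureImage,
    rigid: RigidTransform2D | None = None,
    deformation: DeformationField | None = None,
    interpolation: str = "cubic",
) -> PressureImage:
    """Resample an image through (deformation o rigid) onto the fixed grid.

    The composed mapping is the standard pull-back: the output at pixel x
    samples the input at ``T^{-1}(x + u(x))``.  Cubic interpolation (with
    non-negativity clamping) for pressures, nearest for masks; out-of-domain
    pixels are 0.
    """
    order = {"cubic": 3, "nearest": 0, "linear": 1}[interpolation]
    spacing = np.asarray(image.spacing)
    out_shape = deformation.shape if deformation is not None else image.data.shape

    idx = np.indices(out_shape, dtype=float)
    phys = idx * spacing[:, None, None]
    if deformation is not None:
        if deformation.shape != out_shape:
            raise ValueError("deformation field grid does not match the target grid")
        phys = phys + deformation.displacements
    if rigid is not None and not rigid.is_identity():
        inv = rigid.inverse()
        pts = phys.reshape(2, -1).T
        pts = inv.apply_points(pts)
        phys = pts.T.reshape(2, *out_shape)
    coords = phys / spacing[:, None, None]
    out = ndimage.map_coordinates(image.data, coords, order=order, mode="constant", cval=0.0)
    if order > 1:
        out = np.clip(out, 0.0, None)
    return replace(image, data=out)


def average_transforms(
    rigids: list[RigidTransform2D],
    fields: list[DeformationField] | None = None,
) -> tuple[RigidTransform2D, DeformationField | None]:
    """Average rigid transforms (circular-mean angle) and displacement fields.

    Transforms are first re-expressed about a common rotation center (the
    mean of the individual centers); the averaged rotation is the circular
    mean of the angles and the translation the arithmetic mean.  Fields are
    averaged per pixel.
    """
    if not rigids:
        raise ValueError("cannot average an empty list of transforms")
    common_center = tuple(np.mean([np.asarray(r.center) for r in rigids], axis=0))
    recentered = [r.with_center(common_center) for r in rigids]
    angles = np.array([r.angle for r in recentered])
    mean_angle = float(np.arctan2(np.sin(angles).mean(), np.cos(angles).mean()))
    mean_t = tuple(np.mean([np.asarray(r.translation) for r in recentered], axis=0))
    mean_rigid = RigidTransform2D(angle=mean_angle, translation=mean_t, center=common_center)

    mean_field = None
    if fields:
        shapes = {f.shape for f in fields}
        if len(shapes) != 1:
            raise ValueError("all deformation fields must share a grid")
        mean_disp = np.mean([f.displacements for f in fields], axis=0)
        mean_field = DeformationField(mean_disp, fields[0].spacing)
    return mean_rigid, mean_field


def align_and_average_foot(
    images: list[PressureImage],
    seed: int = 0,
    config: RigidRegistrationConfig | None = None,
) -> PressureImage:
    """Average a foot's repeated peak-pressure images after rigid alignment.

    One image is chosen as the reference by a seeded random draw; the others
    are rigidly aligned to it by mutual information and the aligned stack is
    averaged, reducing biological and measurement noise.
    """
    if not images:
        raise ValueError("need at least one image")
    if len(images) == 1:
        return images[0].copy()
    rng = np.random.default_rng(seed)
    ref_idx = int(rng.integers(len(images)))
    reference = images[ref_idx]
    stack = [reference.data]
    for j, img in enumerate(images):
        if j == ref_idx:
            continue
        transform = rigid_register(img, reference, config=config, seed=seed + 1000 + j)
        aligned = apply_transform(img, rigid=transform, interpolation="cubic")
        stack.append(aligned.data)
    return replace(reference, data=np.mean(stack, axis=0))
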