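"""Anatomically unbiased peak-pressure template by iterative groupwise registration.

Pixel-wise statistics require one common coordinate frame.  Picking a single
subject as the reference would bias that frame toward that subject's foot
shape; instead the template is iterated toward the population average
(Guimond-style):

1. pick a random initial template from the cohort (seeded);
2. register every cohort image onto the current template, rigidly by mutual
   information and deformably by silhouette demons, and average the aligned
   images into a mean-intensity image;
3. average the *inverse* transforms (which capture how the template frame
   differs from each subject);
4. apply the averaged inverse transform to the mean image, moving the
   template toward the average foot shape and size.

Steps 2-4 repeat until the template stops changing (relative L2 drift below
tolerance) or the iteration budget runs out.  Averaging intensities as well
as geometry is what makes the result insensitive to the initial reference:
the initial choice only sets the starting coordinate frame, and the shape
correction in step 4 removes that bias.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .pressure_io import PressureImage, SilhouetteMask, compute_silhouette
from .registration import (
    DemonsConfig,
    RigidRegistrationConfig,
    apply_transform,
    average_transforms,
    demons_register,
    rigid_register,
)

__all__ = ["TemplateResult", "build_template"]


@dataclass
class TemplateResult:
    """A built template with its silhouette and convergence diagnostics."""

    template: PressureImage
    silhouette: SilhouetteMask
    iterations: int
    drift_trace: list[float] = field(default_factory=list)
    converged: bool = True
    seed: int | None = None


def _relative_change(new: np.ndarray, old: np.ndarray) -> float:
    denom = np.linalg.norm(old)
    if denom == 0:
        return float(np.linalg.norm(new))
    return float(np.linalg.norm(new - old) / denom)


def build_template(
    images: list[PressureImage],
    seed: int = 0,
    max_iter: int = 10,
    tol: float = 1e-3,
    silhouette_threshold_kpa: float = 5.0,
    rigid_config: RigidRegistrationConfig | None = None,
    demons_config: DemonsConfig | None = None,
) -> TemplateResult:
    """Build the groupwise template from left-oriented per-foot averaged images.

    Parameters
    ----------
    images:
        N >= 2 peak-pressure images (one per foot) on a common grid.
    seed:
        Seeds both the initial template draw and the registration optimizers;
        the same seed reproduces the template bit-for-bit.
    tol:
        Convergence tolerance on the relative L2 change of the template
        between iterations.
    """
    if len(images) < 2:
        raise ValueError("template construction needs at least two images")
    shapes = {img.data.shape for img in images}
    if len(shapes) != 1:
        raise ValueError("all cohort images must share a grid")

    rng = np.random.default_rng(seed)
    template = images[int(rng.integers(len(images)))].copy()

    drift_trace: list[float] = []
    converged = False
    iterations = 0
    for iteration in range(max_iter):
        iterations = iteration + 1
        template_sil = compute_silhouette(template, silhouette_threshold_kpa)
        warped_stack, inv_rigids, inv_fields = [], [], []
        for i, source in enumerate(images):
            # iteration-independent seed: registration noise is then a fixed
            # function of the template, so the loop can actually settle
            pair_seed = seed + 7919 + i
            rigid = rigid_register(source, template, config=rigid_config, seed=pair_seed)
            moved = apply_transform(source, rigid=rigid, interpolation="cubic")
            moving_sil = compute_silhouette(moved, silhouette_threshold_kpa)
            if moving_sil.data.any() and template_sil.data.any():
                defo = demons_register(moving_sil, template_sil, config=demons_config)
            else:
                defo = None
            warped = apply_transform(source, rigid=rigid, deformation=defo,
                                     interpolation="cubic")
            warped_stack.append(warped.data)
            inv_rigids.append(rigid.inverse())
            if defo is not None:
                inv_fields.append(defo.invert())
        mean_image = replace(template, data=np.mean(warped_stack, axis=0))
        mean_rigid, mean_field = average_transforms(inv_rigids, inv_fields or None)
        new_template = apply_transform(
            mean_image, rigid=mean_rigid, deformation=mean_field, interpolation="cubic"
        )
        drift = _relative_change(new_template.data, template.data)
        drift_trace.append(drift)
        template = new_template
        if drift < tol:
            converged = True
            break

    if not converged:
        warnings.warn(
            f"template construction did not converge in {max_iter} iterations "
            f"(last drift {drift_trace[-1]:.2e})",
            stacklevel=2,
        )

    silhouette = compute_silhouette(template, silhouette_threshold_kpa)
    return TemplateResult(
        template=template,
        silhouette=silhouette,
        iterations=iterations,
        drift_trace=drift_trace,
        converged=converged,
        seed=seed,
    )
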