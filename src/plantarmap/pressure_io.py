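"""Reading, preprocessing, and derived images for dynamic plantar pressure data.

A dynamic plantar pressure measurement is a 2D+time grid ``V(x, t)`` of
pressures in kPa recorded by a sensor plate during one stance phase.  This
module turns such measurements into the derived images used throughout the
pipeline:

* the thresholded temporal-mean image ``M(x)`` (mean over frames where the
  pixel exceeds a contact threshold, 5 kPa by default);
* the total-mean-pressure normalized video (every sample divided by
  ``sum_x M(x)``, removing walking-speed magnitude effects while keeping the
  spatial distribution);
* the peak-pressure image ``I(x) = max_t V(x, t)``;
* the binary silhouette (footprint) mask at the 5 kPa contact threshold.

Grid convention
---------------
Axis 0 runs anterior-posterior with the toes at high row index; axis 1 runs
medial-lateral.  For left-oriented images the medial border (big-toe side)
sits at the high column index.  Right-foot images are mirrored across the
anterior-posterior axis (`flip_to_left`) so that a single left-foot model
covers both sides.  Pixel indices are 0-based and physical coordinates are
``origin + index * spacing`` in millimetres.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

DEFAULT_CONTACT_THRESHOLD_KPA = 5.0
DEFAULT_GRID_MM = 3.0

DEMOGRAPHICS_COLUMNS = ["subject_id", "foot_id", "side", "age", "sex", "weight", "height", "shoe_size"]


class PressureIOError(ValueError):
    """Raised for malformed pressure files or missing metadata."""


@dataclass
class PressureVideo:
    """A 2D+time plantar pressure measurement.

    Attributes
    ----------
    data:
        Array of shape ``(nx, ny, nt)``; pressures in kPa (or dimensionless
        once ``normalized``).
    spacing:
        Physical pixel size in mm per spatial axis; may be anisotropic as
        acquired.
    frequency:
        Temporal sampling rate in Hz.
    side:
        ``"left"`` or ``"right"``.
    norm_divisor:
        The scalar ``sum_x M(x)`` the video was divided by, if normalized.
        Thresholds stated in kPa are divided by this value when applied to
        normalized data.
    """

    data: np.ndarray
    spacing: tuple[float, float]
    frequency: float
    side: str | None = None
    foot_id: str | None = None
    subject_id: str | None = None
    normalized: bool = False
    norm_divisor: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise PressureIOError(
                f"not a pressure video: expected 3 axes (x, y, t), got {self.data.ndim}"
            )
        if np.any(self.data < 0):
            raise PressureIOError("pressure values must be non-negative")
        if not all(s > 0 for s in self.spacing):
            raise PressureIOError("spacing components must be positive")
        if self.frequency <= 0:
            raise PressureIOError("sampling frequency must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[2]


@dataclass
class PressureImage:
    """A 2D scalar pressure image on a uniform grid.

    ``data`` is in kPa, or dimensionless if ``normalized`` (in which case
    ``norm_divisor`` records the kPa scale that was divided out).
    """

    data: np.ndarray
    spacing: tuple[float, float]
    origin: tuple[float, float] = (0.0, 0.0)
    side: str | None = None
    foot_id: str | None = None
    subject_id: str | None = None
    normalized: bool = False
    norm_divisor: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise PressureIOError(f"expected a 2D image, got {self.data.ndim} axes")
        if not np.all(np.isfinite(self.data)):
            raise PressureIOError("image values must be finite")

    def copy(self) -> "PressureImage":
        return replace(self, data=self.data.copy())

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def kpa_threshold(self, threshold_kpa: float) -> float:
        """Translate a threshold stated in kPa onto this image's intensity scale."""
        if self.normalized and self.norm_divisor:
            return threshold_kpa / self.norm_divisor
        return threshold_kpa


@dataclass
class SilhouetteMask:
    """Binary footprint mask: pixels where the source pressure exceeds a cutoff."""

    data: np.ndarray
    threshold_kpa: float = DEFAULT_CONTACT_THRESHOLD_KPA
    spacing: tuple[float, float] = (DEFAULT_GRID_MM, DEFAULT_GRID_MM)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)

    @property
    def area_px(self) -> int:
        return int(self.data.sum())


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_pressure_video(path: str | Path, metadata: dict | None = None) -> PressureVideo:
    """Load a plantar pressure video from a 3D NIfTI volume.

    The first two axes are spatial, the third is time.  Spatial spacing is
    taken from the NIfTI header (``pixdim``, assumed in mm) unless overridden
    via ``metadata['spacing_mm']``.  The sampling frequency must come from
    ``metadata['frequency_hz']`` or a JSON sidecar next to the file, since
    exported headers often carry an unreliable temporal pixdim.
    """
    path = Path(path)
    metadata = dict(metadata or {})
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types
        raise PressureIOError(f"unreadable pressure file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise PressureIOError(
            f"not a pressure video: {path} has {data.ndim} axes, expected 3 (x, y, t)"
        )

    sidecar = path.with_suffix("").with_suffix("")  # strip .nii or .nii.gz
    sidecar = sidecar.parent / (sidecar.name + ".json")
    if sidecar.exists():
        with open(sidecar) as fh:
            side_meta = json.load(fh)
        for key, value in side_meta.items():
            metadata.setdefault(key, value)

    if "spacing_mm" in metadata:
        spacing = tuple(float(s) for s in metadata["spacing_mm"])
    else:
        zooms = img.header.get_zooms()[:2]
        if any(z <= 0 for z in zooms):
            raise PressureIOError(
                f"missing spacing metadata for {path}: header pixdim invalid and "
                "no 'spacing_mm' override given"
            )
        spacing = (float(zooms[0]), float(zooms[1]))

    if "frequency_hz" not in metadata:
        raise PressureIOError(
            f"missing 'frequency_hz' for {path}: provide it in metadata or a JSON sidecar"
        )

    return PressureVideo(
        data=np.clip(data, 0.0, None),
        spacing=spacing,
        frequency=float(metadata["frequency_hz"]),
        side=metadata.get("side"),
        foot_id=metadata.get("foot_id"),
        subject_id=metadata.get("subject_id"),
    )


def write_pressure_image(image: PressureImage, path: str | Path) -> None:
    """Save a pressure image as NIfTI with spacing in the header."""
    affine = np.diag([image.spacing[0], image.spacing[1], 1.0, 1.0])
    affine[0, 3], affine[1, 3] = image.origin
    nii = nib.Nifti1Image(image.data[:, :, None].astype(np.float32), affine)
    nii.header.set_zooms((image.spacing[0], image.spacing[1], 1.0))
    nib.save(nii, str(path))


def read_pressure_image(path: str | Path, metadata: dict | None = None) -> PressureImage:
    """Load a 2D pressure image (stored as a single-slice NIfTI)."""
    metadata = dict(metadata or {})
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    data = np.squeeze(data)
    if data.ndim != 2:
        raise PressureIOError(f"expected a 2D image in {path}, got shape {data.shape}")
    zooms = img.header.get_zooms()[:2]
    spacing = metadata.get("spacing_mm", (float(zooms[0]), float(zooms[1])))
    return PressureImage(
        data=data,
        spacing=tuple(spacing),
        side=metadata.get("side"),
        foot_id=metadata.get("foot_id"),
        subject_id=metadata.get("subject_id"),
    )


def read_demographics_table(path: str | Path) -> pd.DataFrame:
    """Read the per-foot demographics CSV.

    Expected columns: subject_id, foot_id, side, age [years],
    sex [0=female, 1=male], weight [kg], height [cm], shoe_size [EU].
    """
    df = pd.read_csv(path)
    missing = [c for c in DEMOGRAPHICS_COLUMNS if c not in df.columns]
    if missing:
        raise PressureIOError(f"demographics table missing columns: {missing}")
    return df


# ---------------------------------------------------------------------------
# Preprocessing operations
# ---------------------------------------------------------------------------

def _resample_frame(frame: np.ndarray, spacing: tuple[float, float], target_mm: float) -> np.ndarray:
    zoom = (spacing[0] / target_mm, spacing[1] / target_mm)
    # grid_mode=True: pixel areas tile the physical extent, conserving the
    # pressure-area integral of smooth fields; reflect boundary keeps
    # constants exact and is equivalent to zero-padding for footprints that
    # decay to zero before the plate border
    out = ndimage.zoom(frame, zoom, order=3, mode="reflect", grid_mode=True)
    # cubic interpolation can overshoot below zero; pressures are non-negative
    return np.clip(out, 0.0, None)


def resample_square(video: PressureVideo, target_mm: float = DEFAULT_GRID_MM) -> PressureVideo:
    """Resample every frame onto an isotropic square grid by cubic interpolation.

    The sensor plates acquire on anisotropic grids (7.62 x 5.08 mm), which
    compresses the foot along the anterior-posterior axis; resampling to a
    square grid (3 mm default) restores the foot geometry.
    """
    if target_mm <= 0:
        raise PressureIOError("target_mm must be positive")
    frames = [
        _resample_frame(video.data[:, :, t], video.spacing, target_mm)
        for t in range(video.n_frames)
    ]
    return replace(
        video,
        data=np.stack(frames, axis=2),
        spacing=(target_mm, target_mm),
    )


def mean_pressure_image(
    video: PressureVideo, tau_kpa: float = DEFAULT_CONTACT_THRESHOLD_KPA
) -> PressureImage:
    """Thresholded temporal-mean pressure image ``M(x)``.

    At each pixel, the mean of the samples strictly above the contact
    threshold ``tau``; pixels that never exceed the threshold get 0.  The
    threshold excludes no-contact frames so that the mean reflects loading
    during contact only.
    """
    tau = tau_kpa
    if video.normalized and video.norm_divisor:
        tau = tau_kpa / video.norm_divisor
    above = video.data > tau
    counts = above.sum(axis=2)
    sums = np.where(above, video.data, 0.0).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    return PressureImage(
        data=mean,
        spacing=video.spacing,
        side=video.side,
        foot_id=video.foot_id,
        subject_id=video.subject_id,
        normalized=video.normalized,
        norm_divisor=video.norm_divisor,
    )


def normalize_video(
    video: PressureVideo, tau_kpa: float = DEFAULT_CONTACT_THRESHOLD_KPA
) -> PressureVideo:
    """Divide every sample by the total mean pressure ``sum_x M(x)``.

    This removes the influence of walking speed on the overall pressure
    magnitude while leaving the spatial distribution untouched.  The divisor
    is recorded so that kPa-stated thresholds can later be mapped onto the
    dimensionless scale.
    """
    mean_img = mean_pressure_image(video, tau_kpa=tau_kpa)
    divisor = float(mean_img.data.sum())
    if divisor <= 0:
        raise PressureIOError("empty measurement: no pixel exceeds the contact threshold")
    prior = video.norm_divisor or 1.0
    return replace(
        video,
        data=video.data / divisor,
        normalized=True,
        norm_divisor=prior * divisor,
    )


def peak_pressure_image(video: PressureVideo) -> PressureImage:
    """Peak-pressure image: the per-pixel maximum over the stance phase."""
    return PressureImage(
        data=video.data.max(axis=2),
        spacing=video.spacing,
        side=video.side,
        foot_id=video.foot_id,
        subject_id=video.subject_id,
        normalized=video.normalized,
        norm_divisor=video.norm_divisor,
    )


def flip_to_left(image: PressureImage) -> PressureImage:
    """Mirror a right-foot image across the anterior-posterior axis.

    Left and right plantar pressures are treated as independent samples of
    one (left) foot model, so right feet are mirrored along the
    medial-lateral axis and relabeled.  Left images pass through unchanged.
    """
    if image.side not in ("left", "right"):
        raise PressureIOError(f"unknown foot side {image.side!r}; expected 'left' or 'right'")
    if image.side == "left":
        return image.copy()
    return replace(image, data=image.data[:, ::-1].copy(), side="left")


def compute_silhouette(
    image: PressureImage, threshold_kpa: float = DEFAULT_CONTACT_THRESHOLD_KPA
) -> SilhouetteMask:
    """Binary footprint mask: pixels strictly above the contact threshold.

    The threshold is stated in kPa; for normalized (dimensionless) images it
    is rescaled by the recorded normalization divisor so the mask matches the
    pre-normalization support.
    """
    thr = image.kpa_threshold(threshold_kpa)
    return SilhouetteMask(
        data=image.data > thr,
        threshold_kpa=threshold_kpa,
        spacing=image.spacing,
    )
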