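"""Affine co-registration of the RGB camera frame onto the HSI frame.

The microscope carries two cameras on separate ports sharing one field of
view.  Once per session, both cameras image a calibration target; the two
frames are reduced to grayscale and an affine transform mapping the RGB
(moving) frame onto the hyperspectral (fixed) frame is estimated from ORB
keypoint matches with RANSAC outlier rejection.  That single transform is
then applied to every RGB slide image of the session.  Output pixels whose
preimage falls outside the RGB frame are filled with black and recorded in
a margin mask so that nuclei overlapping them can be excluded downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.feature import ORB, match_descriptors
from skimage.measure import ransac
from skimage.transform import AffineTransform as _SkAffine
from skimage.transform import warp

from .cube_io import HyperCube

__all__ = [
    "AffineTransform",
    "RegistrationError",
    "to_grayscale",
    "estimate_affine",
    "apply_affine",
]

#: Luminance weights for RGB -> gray (ITU-R BT.601).
GRAY_WEIGHTS = np.array([0.299, 0.587, 0.114])

DEFAULT_MIN_FEATURES = 50
RANSAC_REPROJECTION_THRESHOLD = 3.0  # px


class RegistrationError(RuntimeError):
    """Raised when too few features match to estimate a transform."""


@dataclass
class AffineTransform:
    """2x3 affine matrix mapping moving (x=col, y=row) to fixed coordinates."""

    matrix: np.ndarray
    inlier_ratio: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (2, 3):
            raise ValueError(f"affine matrix must be 2x3, got {self.matrix.shape}")
        if abs(np.linalg.det(self.matrix[:, :2])) < 1e-12:
            raise ValueError("affine linear block is singular")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]))

    @property
    def homogeneous(self) -> np.ndarray:
        return np.vstack([self.matrix, [0.0, 0.0, 1.0]])

    def __call__(self, xy: np.ndarray) -> np.ndarray:
        """Map an (n, 2) array of (x, y) points moving -> fixed."""
        xy = np.atleast_2d(xy)
        return xy @ self.matrix[:, :2].T + self.matrix[:, 2]

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.homogeneous)
        return AffineTransform(inv[:2, :])

    def to_json(self, path: str | Path) -> None:
        payload = {"matrix": self.matrix.tolist(), "inlier_ratio": self.inlier_ratio,
                   "meta": self.meta}
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "AffineTransform":
        payload = json.loads(Path(path).read_text())
        return cls(np.array(payload["matrix"]), payload.get("inlier_ratio"),
                   payload.get("meta", {}))


def to_grayscale(image: np.ndarray | HyperCube) -> np.ndarray:
    """Reduce an RGB image or hyperspectral cube to a [0, 1] gray image.

    RGB images use fixed luminance weights (0.299/0.587/0.114); integer
    images are first scaled by their dtype maximum.  Hyperspectral cubes
    are averaged over bands.  Output is clipped to [0, 1].
    """
    if isinstance(image, HyperCube):
        gray = image.data.astype(np.float64).mean(axis=2)
        return np.clip(gray, 0.0, 1.0)
    arr = np.asarray(image)
    if arr.size == 0:
        raise ValueError("empty image")
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float64) / np.iinfo(arr.dtype).max
    else:
        arr = arr.astype(np.float64)
    if arr.ndim == 2:
        return np.clip(arr, 0.0, 1.0)
    if arr.ndim == 3 and arr.shape[2] == 3:
        return np.clip(arr @ GRAY_WEIGHTS, 0.0, 1.0)
    raise ValueError(f"expected 2-D gray or rows x cols x 3 RGB, got {arr.shape}")


def estimate_affine(
    fixed_gray: np.ndarray,
    moving_gray: np.ndarray,
    min_features: int = DEFAULT_MIN_FEATURES,
    n_keypoints: int = 800,
    seed: int = 0,
) -> AffineTransform:
    """Estimate the affine transform mapping the moving image onto the fixed.

    ORB keypoints are detected in both grayscale images, matched by binary
    descriptor distance, and an affine model is fit with RANSAC
    (reprojection threshold 3 px).  Raises :class:`RegistrationError` with
    the feature counts when either image yields fewer than ``min_features``
    keypoints or too few matches survive.
    """
    fixed_gray = np.asarray(fixed_gray, dtype=np.float64)
    moving_gray = np.asarray(moving_gray, dtype=np.float64)

    kp: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for name, img in (("fixed", fixed_gray), ("moving", moving_gray)):
        orb = ORB(n_keypoints=n_keypoints, fast_threshold=0.05)
        try:
            orb.detect_and_extract(img)
        except RuntimeError as exc:  # no features at all
            raise RegistrationError(f"no ORB features in {name} image: {exc}") from exc
        kp[name] = (orb.keypoints, orb.descriptors)
        if len(orb.keypoints) < min_features:
            raise RegistrationError(
                f"{len(orb.keypoints)} ORB features in {name} image "
                f"(minimum {min_features})"
            )

    matches = match_descriptors(kp["moving"][1], kp["fixed"][1],
                                cross_check=True, max_ratio=0.9)
    if len(matches) < max(3, min_features // 5):
        raise RegistrationError(
            f"only {len(matches)} descriptor matches "
            f"({len(kp['moving'][0])} moving / {len(kp['fixed'][0])} fixed features)"
        )

    # skimage keypoints are (row, col); the transform convention is (x, y).
    src = kp["moving"][0][matches[:, 0]][:, ::-1]
    dst = kp["fixed"][0][matches[:, 1]][:, ::-1]
    model, inliers = ransac(
        (src, dst),
        _SkAffine,
        min_samples=3,
        residual_threshold=RANSAC_REPROJECTION_THRESHOLD,
        max_trials=2000,
        rng=seed,
    )
    if model is None or inliers is None or inliers.sum() < 3:
        raise RegistrationError(
            f"RANSAC failed on {len(matches)} matches "
            f"({0 if inliers is None else int(inliers.sum())} inliers)"
        )
    ratio = float(inliers.sum()) / len(matches)
    return AffineTransform(model.params[:2, :], inlier_ratio=ratio,
                           meta={"n_matches": int(len(matches)),
                                 "n_inliers": int(inliers.sum())})


def apply_affine(
    moving_rgb: np.ndarray,
    t: AffineTransform,
    out_shape: tuple[int, int],
) -> tuple[np.ndarray, np.ndarray]:
    """Resample an RGB image into the fixed frame under transform ``t``.

    Returns ``(registered, margin_mask)``: ``registered`` has spatial shape
    ``out_shape`` with unmapped pixels black, and ``margin_mask`` is True
    exactly where the output pixel's preimage falls outside the moving
    image bounds.
    """
    moving = np.asarray(moving_rgb)
    if moving.ndim == 2:
        moving = moving[:, :, None]
    rows, cols = out_shape

    inv = t.inverse().homogeneous  # fixed (x, y) -> moving (x, y)
    xx, yy = np.meshgrid(np.arange(cols, dtype=float), np.arange(rows, dtype=float))
    src_x = inv[0, 0] * xx + inv[0, 1] * yy + inv[0, 2]
    src_y = inv[1, 0] * xx + inv[1, 1] * yy + inv[1, 2]
    h, w = moving.shape[:2]
    margin = (src_x < 0) | (src_x > w - 1) | (src_y < 0) | (src_y > h - 1)

    sk = _SkAffine(matrix=t.homogeneous)
    out = np.empty((rows, cols, moving.shape[2]), dtype=np.float64)
    for c in range(moving.shape[2]):
        out[:, :, c] = warp(
            moving[:, :, c].astype(np.float64),
            inverse_map=sk.inverse,
            output_shape=out_shape,
            order=1,
            cval=0.0,
            preserve_range=True,
        )
    out[margin] = 0.0
    if np.issubdtype(np.asarray(moving_rgb).dtype, np.integer):
        out = np.clip(np.rint(out), np.iinfo(moving_rgb.dtype).min,
                      np.iinfo(moving_rgb.dtype).max).astype(moving_rgb.dtype)
    if np.asarray(moving_rgb).ndim == 2:
        out = out[:, :, 0]
    return out, margin
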