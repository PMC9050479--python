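"""PCA-based nuclei segmentation and patch extraction.

Hematoxylin (nuclei) and eosin (cytoplasm) absorb differently across the
470-720 nm range, so a principal component analysis over pixel spectra
separates nuclei, cytoplasm, and blank background into the top component
images.  The segmentation recipe:

1. PCA over pixels-as-samples, bands-as-variables (``pca_spectral``).
2. Min-max normalize PC1 and PC2 (``normalize_pc``).
3. Fix the inherent PCA sign ambiguity so nuclei come out low in PC1 and
   high in PC2 (``orient_components``).
4. Difference image ``PC2_norm - PC1_norm``: nuclei positive, cytoplasm
   negative (``difference_image``).
5. Hard-threshold at 0, drop small components — lymphocytes and debris
   fall below ``min_area`` (``mask_nuclei``).
6. Split touching nuclei with a marker-controlled watershed
   (``split_touching``).
7. Extract nucleus-centered 101x101 HSI and RGB patches, dropping any
   window that leaves the frame or touches the registration margin
   (``extract_patches``).

Nuclear boundaries from this mask are approximate; the purpose is
locating nuclei for patch extraction, not precise delineation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .cube_io import HyperCube

__all__ = [
    "PCAResult",
    "NormalizedPC",
    "NucleiMask",
    "NucleusRecord",
    "pca_spectral",
    "normalize_pc",
    "orient_components",
    "difference_image",
    "mask_nuclei",
    "split_touching",
    "extract_patches",
    "segment_cube",
]

#: Minimum connected-component area kept as a nucleus, in pixels.  At the
#: instrument's 139 nm/px sampling this excludes lymphocyte-scale objects.
DEFAULT_MIN_AREA = 200

DEFAULT_PATCH_SIZE = 101

#: Minimum separation (px) between watershed seed maxima.  Of the order
#: of a nucleus radius; smaller values over-split elongated nuclei.
WATERSHED_SEED_SEPARATION = 10

#: Gaussian sigma applied to the distance map before seed detection,
#: suppressing spurious maxima from rasterized boundaries.
WATERSHED_SEED_SMOOTHING = 2.0


@dataclass
class PCAResult:
    """Principal-component score images over the spectral axis."""

    scores: np.ndarray  # rows x cols x k
    explained_variance: np.ndarray
    components: np.ndarray  # k x bands eigenvectors
    mean: np.ndarray  # band means used for centering
    degenerate: bool = False

    @property
    def n_components(self) -> int:
        return self.scores.shape[2]

    def pc(self, i: int) -> np.ndarray:
        """1-based accessor: ``pc(1)`` is the top-variance score image."""
        return self.scores[:, :, i - 1]


@dataclass
class NormalizedPC:
    """A min-max normalized score image in [0, 1]."""

    image: np.ndarray
    degenerate: bool = False


@dataclass
class NucleiMask:
    binary: np.ndarray
    labels: np.ndarray
    centroids: np.ndarray  # (n, 2) in (row, col)

    @property
    def n_nuclei(self) -> int:
        return len(self.centroids)


@dataclass
class NucleusRecord:
    """One segmented nucleus with its co-registered patches."""

    centroid: tuple[float, float]
    hsi_patch: np.ndarray  # size x size x bands transmittance
    rgb_patch: np.ndarray  # size x size x 3
    mask_patch: np.ndarray  # size x size bool, this nucleus only
    label: str = "unknown"  # cancerous / normal / unknown
    patient_id: str = ""
    image_id: str = ""
    nucleus_id: int = -1
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Spectral PCA
# ---------------------------------------------------------------------------

def pca_spectral(cube: HyperCube, n_components: int = 3) -> PCAResult:
    """PCA of pixel spectra; score images sorted by explained variance.

    The cube is reshaped to an (n_pixels, bands) matrix, mean-centered per
    band, and decomposed via the band covariance matrix.  Invalid pixels
    (masked by calibration) are excluded from the fit but still projected.
    """
    rows, cols, bands = cube.shape
    if bands < n_components:
        raise ValueError(f"{bands} bands < {n_components} requested components")
    x = cube.data.reshape(-1, bands).astype(np.float64)
    if cube.valid_mask is not None:
        fit_x = x[cube.valid_mask.ravel()]
    else:
        fit_x = x
    if fit_x.shape[0] < n_components:
        raise ValueError(
            f"{fit_x.shape[0]} valid pixels < {n_components} requested components"
        )
    mean = fit_x.mean(axis=0)
    centered = fit_x - mean
    cov = centered.T @ centered / max(fit_x.shape[0] - 1, 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1][:n_components]
    eigvals = np.clip(eigvals[order], 0.0, None)
    components = eigvecs[:, order].T  # k x bands
    scores = (x - mean) @ components.T
    degenerate = bool(eigvals[0] <= 1e-15 * max(1.0, np.abs(fit_x).max()) ** 2)
    return PCAResult(
        scores=scores.reshape(rows, cols, n_components),
        explained_variance=eigvals,
        components=components,
        mean=mean,
        degenerate=degenerate,
    )


def normalize_pc(pc: np.ndarray) -> NormalizedPC:
    """Min-max rescale a score image to [0, 1].

    A constant image has no contrast to rescale; it maps to all zeros with
    the ``degenerate`` flag set instead of raising.
    """
    pc = np.asarray(pc, dtype=np.float64)
    if not np.isfinite(pc).all():
        raise ValueError("PC image contains non-finite values")
    lo, hi = pc.min(), pc.max()
    if hi == lo:
        return NormalizedPC(np.zeros_like(pc), degenerate=True)
    return NormalizedPC((pc - lo) / (hi - lo))


def orient_components(
    pca: PCAResult,
    brightness: np.ndarray | None = None,
    threshold: float = 0.0,
) -> PCAResult:
    """Fix PCA sign ambiguity to the convention the difference image assumes.

    Eigenvector signs are arbitrary, so the convention — nuclei low in
    PC1, high in PC2, hence positive in ``PC2_norm - PC1_norm`` — must be
    restored from the data.  All four sign combinations of (PC1, PC2) are
    evaluated; among those whose difference image calls a minority of
    pixels positive (nuclei never cover most of a field), the one whose
    positive set is darkest (lowest mean band sum: nuclei are
    hematoxylin-dense) wins.  Exhaustive search makes the result
    invariant to any sign flips of the input.  An exact tie between the
    remaining orientations is broken toward the one whose positive set
    has the higher mean boundary gradient.
    """
    if pca.n_components < 2:
        raise ValueError("need at least 2 components to orient")
    scores = pca.scores.copy()
    if pca.degenerate:
        return PCAResult(scores, pca.explained_variance.copy(), pca.components.copy(),
                         pca.mean.copy(), degenerate=True)
    if brightness is None:
        # Per-pixel band sum up to a constant, reconstructed from scores:
        # sum_lam x = const + sum_k score_k * (sum_lam v_k).
        brightness = scores @ pca.components.sum(axis=1)

    n1 = normalize_pc(scores[:, :, 0])
    n2 = normalize_pc(scores[:, :, 1])
    if n1.degenerate or n2.degenerate:
        return PCAResult(scores, pca.explained_variance.copy(), pca.components.copy(),
                         pca.mean.copy(), degenerate=True)

    best: tuple[float, float, tuple[float, float]] | None = None
    for s1 in (1.0, -1.0):
        pc1n = n1.image if s1 > 0 else 1.0 - n1.image
        for s2 in (1.0, -1.0):
            pc2n = n2.image if s2 > 0 else 1.0 - n2.image
            diff = pc2n - pc1n
            positive = diff > threshold
            frac = float(positive.mean())
            if not 0.0 < frac <= 0.5:
                continue
            darkness = -float(brightness[positive].mean())  # darker = larger
            grad = _boundary_gradient(diff, threshold)
            key = (darkness, grad, (s1, s2))
            if best is None or key[:2] > best[:2]:
                best = key
    if best is None:  # no orientation yields a positive minority
        return PCAResult(scores, pca.explained_variance.copy(), pca.components.copy(),
                         pca.mean.copy(), degenerate=True)
    s1, s2 = best[2]
    flips = np.ones(pca.n_components)
    flips[0], flips[1] = s1, s2
    scores *= flips
    components = pca.components * flips[:, None]
    return PCAResult(scores, pca.explained_variance.copy(), components,
                     pca.mean.copy(), degenerate=False)


def _boundary_gradient(diff: np.ndarray, threshold: float) -> float:
    positive = diff > threshold
    gy, gx = np.gradient(diff)
    grad = np.hypot(gy, gx)
    boundary = positive ^ ndi.binary_erosion(positive)
    if not boundary.any():
        return 0.0
    return float(grad[boundary].mean())


def difference_image(pc1n: NormalizedPC, pc2n: NormalizedPC) -> np.ndarray:
    """``PC2_norm - PC1_norm``; nuclei positive, cytoplasm negative."""
    if pc1n.image.shape != pc2n.image.shape:
        raise ValueError(
            f"shape mismatch {pc1n.image.shape} vs {pc2n.image.shape}"
        )
    return pc2n.image - pc1n.image


# ---------------------------------------------------------------------------
# Masking, splitting, extraction
# ---------------------------------------------------------------------------

def mask_nuclei(
    diff: np.ndarray,
    threshold: float = 0.0,
    min_area: int = DEFAULT_MIN_AREA,
) -> NucleiMask:
    """Threshold the difference image and drop small components.

    Components are 8-connected; strictly-greater thresholding is used.  An
    empty mask is a valid result (blank or all-background fields).
    """
    diff = np.asarray(diff, dtype=np.float64)
    if not np.isfinite(diff).all():
        raise ValueError("difference image contains non-finite values")
    binary = diff > threshold
    labels = cc_label(binary, connectivity=2)
    if min_area > 1 and labels.max() > 0:
        counts = np.bincount(labels.ravel())
        small = np.flatnonzero(counts < min_area)
        small = small[small > 0]
        if small.size:
            labels[np.isin(labels, small)] = 0
            binary = labels > 0
            labels, _, _ = _compact_labels(labels)
    return _finalize_mask(binary, labels)


def _finalize_mask(binary: np.ndarray, labels: np.ndarray) -> NucleiMask:
    props = regionprops(labels)
    centroids = np.array([p.centroid for p in props], dtype=float).reshape(-1, 2)
    return NucleiMask(binary=binary, labels=labels, centroids=centroids)


def split_touching(
    mask: NucleiMask,
    diff: np.ndarray | None = None,
    min_area: int = DEFAULT_MIN_AREA,
    seed_separation: int = WATERSHED_SEED_SEPARATION,
    seed_smoothing: float = WATERSHED_SEED_SMOOTHING,
) -> NucleiMask:
    """Separate merged nuclei with a marker-controlled watershed.

    Seeds are local maxima of the (lightly smoothed) distance transform
    at least ``seed_separation`` px apart; the watershed floods the
    inverted distance map within the binary mask.  Fragments below
    ``min_area`` are dropped.  Single isolated nuclei are left unchanged.
    """
    binary = mask.binary
    if not binary.any():
        return NucleiMask(binary.copy(), np.zeros_like(mask.labels), np.empty((0, 2)))
    distance = ndi.distance_transform_edt(binary)
    seed_map = ndi.gaussian_filter(distance, seed_smoothing) if seed_smoothing else distance
    peaks = peak_local_max(
        seed_map,
        min_distance=seed_separation,
        labels=mask.labels,
        exclude_border=False,
    )
    markers = np.zeros_like(mask.labels)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        return mask
    labels = watershed(-distance, markers=markers, mask=binary)
    # Watershed can carve off slivers; re-apply the area floor.
    counts = np.bincount(labels.ravel())
    small = np.flatnonzero((counts < min_area) & (np.arange(counts.size) > 0))
    if small.size:
        labels[np.isin(labels, small)] = 0
    labels, _, _ = _compact_labels(labels)
    return _finalize_mask(labels > 0, labels)


def _compact_labels(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    vals = np.unique(labels)
    vals = vals[vals > 0]
    remap = np.zeros(labels.max() + 1 if labels.size else 1, dtype=labels.dtype)
    for new, old in enumerate(vals, start=1):
        remap[old] = new
    return remap[labels], vals, len(vals)


def extract_patches(
    cube: HyperCube,
    rgb: np.ndarray,
    mask: NucleiMask,
    margin_mask: np.ndarray | None = None,
    size: int = DEFAULT_PATCH_SIZE,
    label: str = "unknown",
    patient_id: str = "",
    image_id: str = "",
) -> list[NucleusRecord]:
    """Cut nucleus-centered windows from the HSI cube and registered RGB.

    One record per centroid whose ``size x size`` window (centered on the
    rounded centroid) lies fully inside both images and contains no
    registration-margin pixels; nuclei failing either test are dropped, as
    their RGB patch would include black fill.
    """
    if size % 2 == 0:
        raise ValueError(f"patch size must be odd, got {size}")
    rgb = np.asarray(rgb)
    if rgb.shape[:2] != cube.shape[:2]:
        raise ValueError(
            f"RGB shape {rgb.shape[:2]} does not match cube {cube.shape[:2]}"
        )
    half = size // 2
    rows, cols = cube.shape[:2]
    records: list[NucleusRecord] = []
    for idx, (r, c) in enumerate(mask.centroids):
        ri, ci = int(round(r)), int(round(c))
        r0, r1 = ri - half, ri + half + 1
        c0, c1 = ci - half, ci + half + 1
        if r0 < 0 or c0 < 0 or r1 > rows or c1 > cols:
            continue
        if margin_mask is not None and margin_mask[r0:r1, c0:c1].any():
            continue
        lab_id = mask.labels[ri, ci]
        if lab_id == 0:
            # Centroid of a concave component can fall off the component;
            # recover the label from the nearest labeled pixel in-window.
            window_labels = mask.labels[r0:r1, c0:c1]
            nz = window_labels[window_labels > 0]
            lab_id = np.bincount(nz).argmax() if nz.size else 0
        mask_patch = mask.labels[r0:r1, c0:c1] == lab_id if lab_id else \
            np.zeros((size, size), dtype=bool)
        records.append(
            NucleusRecord(
                centroid=(float(r), float(c)),
                hsi_patch=cube.data[r0:r1, c0:c1, :],
                rgb_patch=rgb[r0:r1, c0:c1],
                mask_patch=mask_patch,
                label=label,
                patient_id=patient_id,
                image_id=image_id,
                nucleus_id=idx,
            )
        )
    return records


def focus_filter(
    records: list[NucleusRecord],
    min_sharpness: float = 5e-4,
) -> list[NucleusRecord]:
    """Optional out-of-focus rejection by variance of the Laplacian.

    Replaces the manual review step of flagging defocused nuclei: a
    record is kept when the Laplacian variance of its band-mean (or
    luminance) patch reaches ``min_sharpness``.  Off by default in the
    pipeline — defocused nuclei are mostly never segmented in the first
    place.
    """
    kept = []
    for rec in records:
        img = rec.hsi_patch.mean(axis=2)
        lap = ndi.laplace(img)
        if float(lap.var()) >= min_sharpness:
            kept.append(rec)
    return kept


def segment_cube(
    cube: HyperCube,
    threshold: float = 0.0,
    min_area: int = DEFAULT_MIN_AREA,
    split: bool = True,
) -> tuple[NucleiMask, np.ndarray, PCAResult]:
    """Full segmentation: PCA -> orient -> difference -> mask -> watershed.

    Returns ``(mask, difference_image, oriented_pca)``.
    """
    pca = orient_components(pca_spectral(cube))
    if pca.degenerate:
        empty = np.zeros(cube.shape[:2], dtype=bool)
        return (
            NucleiMask(empty, np.zeros(cube.shape[:2], dtype=int), np.empty((0, 2))),
            np.zeros(cube.shape[:2]),
            pca,
        )
    diff = difference_image(normalize_pc(pca.pc(1)), normalize_pc(pca.pc(2)))
    mask = mask_nuclei(diff, threshold=threshold, min_area=min_area)
    if split:
        mask = split_touching(mask, diff, min_area=min_area)
    return mask, diff, pca
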