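"""Synthetic transmitted-light H&E scenes with ground truth.

No patient data accompanies the method, so every pipeline stage is
exercised on simulated hyperspectral cubes built from a simple stain
physics: per pixel, hematoxylin and eosin absorbances add (Beer-Lambert,
base 10)::

    A(p, lam) = thickness * (c_hem(p) * hem(lam) + c_eos(p) * eos(lam))
    T(p, lam) = 10 ** (-A(p, lam)) * tilt_class(lam)

Nuclei are rotated ellipses rich in hematoxylin on an eosin-stained
cytoplasm field, with a blank (unstained) background region so the three
phases the spectral PCA separates are all present.  Cancerous nuclei draw
a larger mean area and a wider eccentricity spread than normal nuclei,
and their spectra carry a multiplicative tilt that puts cancerous
transmittance above normal below the crossover wavelength (default
645 nm) and below it beyond — the class-mean spectra cross exactly once.
Per-patient staining-strength and section-thickness multipliers emulate
slide-to-slide variation; a configurable fraction of patients can carry a
reversed spectral trend, a phenomenon observed in real cohorts whose
cause is unexplained and which is therefore modeled as a free flag, not a
mechanism.  Raw digital-number cubes are produced with a white/dark
reference pair and Gaussian shot noise so that reference calibration
recovers the ground-truth transmittance to within the noise level.
Lymphocyte-scale distractors (small, hematoxylin-rich) exercise the
minimum-area filter; a fraction of nuclei can be defocus-blurred.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi

from .cube_io import DEFAULT_WAVELENGTHS, HyperCube, ReferencePair
from .registration import AffineTransform, apply_affine
from .rgb_synthesis import build_default_weights, synthesize_rgb
from .spectra import SpectrumRecord

__all__ = [
    "StainModel",
    "NucleusShapeModel",
    "SceneSpec",
    "SceneBundle",
    "PatientData",
    "generate_scene",
    "misalign_rgb",
    "generate_patient_set",
    "generate_calibration_target",
    "generate_spectrum_records",
    "generate_patch_dataset",
    "sample_nucleus_counts",
]


@dataclass(frozen=True)
class StainModel:
    """Gaussian unit-peak absorbance curves for the two stains.

    The eosin and hematoxylin absorbance peaks fall near 525 and 600 nm in
    the transmitted-light window; exact positions and widths are free
    parameters of the simulator.
    """

    wavelengths: np.ndarray = field(default_factory=lambda: DEFAULT_WAVELENGTHS.copy())
    eosin_peak: float = 525.0
    eosin_width: float = 40.0
    hematoxylin_peak: float = 600.0
    hematoxylin_width: float = 60.0

    @property
    def eosin_absorbance(self) -> np.ndarray:
        lam = np.asarray(self.wavelengths, float)
        curve = np.exp(-0.5 * ((lam - self.eosin_peak) / self.eosin_width) ** 2)
        return curve / curve.max()  # exact unit peak on the sampled grid

    @property
    def hematoxylin_absorbance(self) -> np.ndarray:
        lam = np.asarray(self.wavelengths, float)
        curve = np.exp(-0.5 * ((lam - self.hematoxylin_peak) / self.hematoxylin_width) ** 2)
        return curve / curve.max()


@dataclass(frozen=True)
class NucleusShapeModel:
    """Equivalent-radius and axis-ratio distributions for one class."""

    radius_mean: float
    radius_sd: float
    ratio_min: float
    ratio_max: float

    def sample(self, rng: np.random.Generator) -> tuple[float, float, float]:
        """Return (semi_major, semi_minor, orientation)."""
        r = max(9.0, rng.normal(self.radius_mean, self.radius_sd))
        ratio = rng.uniform(self.ratio_min, self.ratio_max)
        return r * np.sqrt(ratio), r / np.sqrt(ratio), rng.uniform(0, np.pi)


#: Normal epithelial nuclei: ~12 px equivalent radius, nearly round.
NORMAL_SHAPE = NucleusShapeModel(12.0, 1.2, 1.0, 1.35)
#: SCC nuclei: enlarged with wider shape variation.
CANCEROUS_SHAPE = NucleusShapeModel(16.0, 2.5, 1.0, 2.0)


@dataclass(frozen=True)
class SceneSpec:
    """Everything needed to render one single-class field of view."""

    shape: tuple[int, int] = (512, 512)
    n_nuclei: int = 80
    label: str = "normal"  # cancerous / normal
    normal_shape: NucleusShapeModel = NORMAL_SHAPE
    cancerous_shape: NucleusShapeModel = CANCEROUS_SHAPE
    tilt_amplitude: float = 0.035
    tilt_crossover: float = 645.0  # nm
    tilt_softness: float = 25.0  # nm
    staining: float = 1.0  # per-patient staining-strength multiplier
    thickness: float = 1.0  # per-patient section-thickness multiplier
    reversed_trend: bool = False
    equalize_morphology: bool = False  # both classes draw NORMAL_SHAPE
    noise_sd: float = 0.01  # shot noise, transmittance units
    blur_fraction: float = 0.05
    blur_sigma: float = 2.5
    n_lymphocytes: int = 15
    background_fraction: float = 0.12
    min_gap: int = 3  # px clearance between nuclei (non-touching scenes)
    max_retries: int = 40  # placement attempts per nucleus
    white_level: float = 3000.0  # DN
    dark_level: float = 96.0  # DN
    seed: int = 0

    def __post_init__(self) -> None:
        if self.label not in ("cancerous", "normal"):
            raise ValueError(f"unknown class label {self.label!r}")


@dataclass
class SceneBundle:
    """One rendered scene with its references and ground truth."""

    raw: HyperCube
    white: HyperCube
    dark: HyperCube
    truth: HyperCube  # noiseless ground-truth transmittance
    truth_labels: np.ndarray  # nucleus label image (0 = not a nucleus)
    truth_centroids: np.ndarray  # (n, 2) row/col
    lymphocyte_centroids: np.ndarray
    label: str
    n_placed: int
    n_requested: int
    rgb: np.ndarray  # paired color-camera image, in its own (moving) frame
    rgb_transform: AffineTransform  # maps the RGB frame onto the HSI frame

    @property
    def references(self) -> ReferencePair:
        return ReferencePair(self.white, self.dark)


def _tilt(spec: SceneSpec, wavelengths: np.ndarray) -> np.ndarray:
    """Class tilt factor applied to nucleus spectra.

    Cancerous nuclei gain transmittance below the crossover and lose it
    above; normal nuclei take the mirrored factor, so the class means
    cross exactly once at the crossover wavelength.
    """
    g = np.tanh((spec.tilt_crossover - np.asarray(wavelengths, float))
                / spec.tilt_softness)
    sign = 1.0 if spec.label == "cancerous" else -1.0
    if spec.reversed_trend:
        sign = -sign
    return 1.0 + sign * spec.tilt_amplitude * g


def _place_ellipses(
    spec: SceneSpec,
    shape_model: NucleusShapeModel,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Rasterize non-overlapping rotated ellipses; returns label image."""
    rows, cols = spec.shape
    labels = np.zeros((rows, cols), dtype=np.int32)
    occupied = np.zeros((rows, cols), dtype=bool)
    centroids: list[tuple[float, float]] = []
    yy, xx = np.mgrid[0:rows, 0:cols]
    placed = 0
    for _ in range(spec.n_nuclei):
        for _attempt in range(spec.max_retries):
            a, b, theta = shape_model.sample(rng)
            margin = a + spec.min_gap + 1
            if rows - 2 * margin <= 0 or cols - 2 * margin <= 0:
                continue
            cy = rng.uniform(margin, rows - margin)
            cx = rng.uniform(margin, cols - margin)
            ct, st = np.cos(theta), np.sin(theta)
            r0 = max(0, int(cy - a - spec.min_gap - 1))
            r1 = min(rows, int(cy + a + spec.min_gap + 2))
            c0 = max(0, int(cx - a - spec.min_gap - 1))
            c1 = min(cols, int(cx + a + spec.min_gap + 2))
            ys = yy[r0:r1, c0:c1] - cy
            xs = xx[r0:r1, c0:c1] - cx
            u = xs * ct + ys * st
            v = -xs * st + ys * ct
            inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
            grown = (u / (a + spec.min_gap)) ** 2 + (v / (b + spec.min_gap)) ** 2 <= 1.0
            if (occupied[r0:r1, c0:c1] & grown).any():
                continue
            placed += 1
            labels[r0:r1, c0:c1][inside] = placed
            occupied[r0:r1, c0:c1] |= grown
            rr, cc = np.nonzero(inside)  # centroid of the rasterized pixels
            centroids.append((float(rr.mean() + r0), float(cc.mean() + c0)))
            break
    return labels, centroids


def generate_scene(spec: SceneSpec, stains: StainModel | None = None) -> SceneBundle:
    """Render one scene: raw + references + ground truth, reproducibly.

    If fewer than ``spec.n_nuclei`` ellipses can be placed without overlap
    within ``max_retries`` attempts each, the scene carries fewer nuclei
    and reports the placed count in ``n_placed``.
    """
    stains = stains or StainModel()
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.shape
    lam = np.asarray(stains.wavelengths, float)
    n_bands = lam.size

    shape_model = spec.normal_shape if (
        spec.label == "normal" or spec.equalize_morphology
    ) else spec.cancerous_shape
    labels, centroids = _place_ellipses(spec, shape_model, rng)
    nucleus_mask = labels > 0

    # Blank background: thresholded smooth random field.
    if spec.background_fraction > 0:
        f = ndi.gaussian_filter(rng.standard_normal((rows, cols)), sigma=rows / 8)
        cut = np.quantile(f, 1.0 - spec.background_fraction)
        background = (f > cut) & ~nucleus_mask
    else:
        background = np.zeros((rows, cols), dtype=bool)
    tissue = ~background

    # Lymphocyte-scale distractors in the cytoplasm.
    lymph_mask = np.zeros((rows, cols), dtype=bool)
    lymph_centers = []
    yy, xx = np.mgrid[0:rows, 0:cols]
    for _ in range(spec.n_lymphocytes):
        for _attempt in range(spec.max_retries):
            r = float(np.clip(rng.normal(4.5, 0.6), 3.0, 6.0))
            cy = rng.uniform(r + 2, rows - r - 2)
            cx = rng.uniform(r + 2, cols - r - 2)
            r0, r1 = int(cy - r - 1), int(cy + r + 2)
            c0, c1 = int(cx - r - 1), int(cx + r + 2)
            disc = ((yy[r0:r1, c0:c1] - cy) ** 2 + (xx[r0:r1, c0:c1] - cx) ** 2) <= r * r
            region = np.zeros((rows, cols), dtype=bool)
            region[r0:r1, c0:c1] = disc
            if (region & (nucleus_mask | lymph_mask | background)).any():
                continue
            lymph_mask |= region
            lymph_centers.append((cy, cx))
            break

    # Stain concentration fields.
    texture = 1.0 + 0.25 * ndi.gaussian_filter(rng.standard_normal((rows, cols)), 6.0)
    c_eos = np.where(tissue, 0.35 * texture, 0.0)
    c_hem = np.where(tissue, 0.06, 0.0)
    per_nucleus = rng.normal(1.0, 0.12, size=max(labels.max(), 1) + 1).clip(0.5)
    c_hem = np.where(nucleus_mask, per_nucleus[labels], c_hem)
    c_eos = np.where(nucleus_mask, 0.05, c_eos)
    c_hem = np.where(lymph_mask, 1.5, c_hem)
    c_eos = np.where(lymph_mask, 0.05, c_eos)
    c_hem *= spec.staining
    c_eos *= spec.staining

    absorbance = (
        c_hem[:, :, None] * stains.hematoxylin_absorbance[None, None, :]
        + c_eos[:, :, None] * stains.eosin_absorbance[None, None, :]
    ) * spec.thickness
    t = np.power(10.0, -absorbance)
    tilt = _tilt(spec, lam)
    t[nucleus_mask] *= tilt

    # Defocus blur on a fraction of nuclei.
    if spec.blur_fraction > 0 and labels.max() > 0:
        n_blur = int(round(spec.blur_fraction * labels.max()))
        if n_blur:
            which = rng.choice(np.arange(1, labels.max() + 1), size=n_blur,
                               replace=False)
            for lab in which:
                rr, cc = np.nonzero(labels == lab)
                pad = int(3 * spec.blur_sigma)
                r0, r1 = max(0, rr.min() - pad), min(rows, rr.max() + pad + 1)
                c0, c1 = max(0, cc.min() - pad), min(cols, cc.max() + pad + 1)
                t[r0:r1, c0:c1, :] = ndi.gaussian_filter(
                    t[r0:r1, c0:c1, :], sigma=(spec.blur_sigma, spec.blur_sigma, 0)
                )

    truth = HyperCube(t, lam.copy(), "transmittance",
                      {"scene_seed": spec.seed, "class": spec.label})

    # References and raw counts.
    ramp = 0.7 + 0.3 * (lam - lam.min()) / max(lam.max() - lam.min(), 1.0)
    white_plane = spec.white_level * ramp
    white = HyperCube(
        np.broadcast_to(white_plane, (rows, cols, n_bands)).copy(), lam.copy(), "raw_dn"
    )
    dark = HyperCube(
        np.full((rows, cols, n_bands), spec.dark_level), lam.copy(), "raw_dn"
    )
    span = white.data - dark.data
    raw = dark.data + t * span + rng.normal(0.0, spec.noise_sd, t.shape) * span
    raw_cube = HyperCube(raw, lam.copy(), "raw_dn", {"scene_seed": spec.seed})

    # Paired color-camera frame (identity alignment unless warped later).
    rgb = synthesize_rgb(truth, build_default_weights(lam))
    centroid_arr = np.array(centroids, dtype=float).reshape(-1, 2)
    return SceneBundle(
        raw=raw_cube, white=white, dark=dark, truth=truth,
        truth_labels=labels, truth_centroids=centroid_arr,
        lymphocyte_centroids=np.array(lymph_centers, dtype=float).reshape(-1, 2),
        label=spec.label, n_placed=int(labels.max()), n_requested=spec.n_nuclei,
        rgb=rgb, rgb_transform=AffineTransform.identity(),
    )


def misalign_rgb(bundle: SceneBundle, transform: AffineTransform) -> SceneBundle:
    """Re-render the scene's RGB frame as seen by a misaligned camera.

    ``transform`` maps the RGB (moving) frame onto the HSI (fixed) frame;
    the stored RGB becomes the moving-frame view, so that applying the
    estimated transform registers it back onto the cube.
    """
    moving, _ = apply_affine(bundle.rgb, transform.inverse(),
                             bundle.rgb.shape[:2])
    bundle.rgb = moving
    bundle.rgb_transform = transform
    return bundle


@dataclass
class PatientData:
    patient_id: str
    staining: float
    thickness: float
    reversed_trend: bool
    scenes: list[SceneBundle]


def generate_patient_set(
    n_patients: int,
    images_per_patient: int = 4,
    reversed_fraction: float = 0.0,
    base_spec: SceneSpec | None = None,
    seed: int = 0,
) -> list[PatientData]:
    """Simulate a cohort: per-patient effects drawn once, then scenes.

    Each patient gets a staining and thickness multiplier (lognormal,
    drawn once), and ``round(reversed_fraction * n_patients)`` patients
    carry the reversed spectral trend.  Scenes alternate cancerous and
    normal fields so every patient contributes both classes.
    """
    if n_patients < 2:
        raise ValueError("need at least 2 patients")
    if not 0.0 <= reversed_fraction <= 1.0:
        raise ValueError(f"reversed_fraction {reversed_fraction} outside [0, 1]")
    base = base_spec or SceneSpec()
    rng = np.random.default_rng(seed)
    n_reversed = int(round(reversed_fraction * n_patients))
    reversed_ids = set(rng.choice(n_patients, size=n_reversed, replace=False).tolist())
    patients = []
    for p in range(n_patients):
        staining = float(np.exp(rng.normal(0.0, 0.15)))
        thickness = float(np.exp(rng.normal(0.0, 0.2)))
        reversed_trend = p in reversed_ids
        scenes = []
        for i in range(images_per_patient):
            label = "cancerous" if i % 2 == 0 else "normal"
            spec = replace(
                base,
                label=label,
                staining=staining,
                thickness=thickness,
                reversed_trend=reversed_trend,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            scenes.append(generate_scene(spec))
        patients.append(PatientData(f"P{p + 1:02d}", staining, thickness,
                                    reversed_trend, scenes))
    return patients


# ---------------------------------------------------------------------------
# Lightweight generators for classifier-level studies
# ---------------------------------------------------------------------------

def generate_calibration_target(
    shape: tuple[int, int],
    transform: AffineTransform | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthesize a (fixed, moving) grayscale calibration-target pair.

    The fixed image is a high-contrast random rectangle/disc pattern (the
    kind of corner-rich target used for camera co-registration); the
    moving image is the same scene viewed by a camera displaced by
    ``transform`` (mapping moving onto fixed).
    """
    rng = np.random.default_rng(seed)
    rows, cols = shape
    img = np.zeros((rows, cols))
    for _ in range(60):
        r0 = rng.integers(0, rows - 12)
        c0 = rng.integers(0, cols - 12)
        h = rng.integers(6, max(7, rows // 8))
        w = rng.integers(6, max(7, cols // 8))
        img[r0:r0 + h, c0:c0 + w] = rng.uniform(0.2, 1.0)
    img = ndi.gaussian_filter(img, 1.0)
    img += 0.02 * rng.standard_normal(img.shape)
    img = np.clip(img, 0, 1)
    if transform is None:
        return img, img.copy()
    moving, _ = apply_affine(img, transform.inverse(), shape)
    return img, moving


def generate_spectrum_records(
    n_patients: int = 6,
    nuclei_per_patient: int = 40,
    tilt_amplitude: float = 0.035,
    reversed_patients: tuple[int, ...] = (),
    stains: StainModel | None = None,
    noise_sd: float = 0.004,
    seed: int = 0,
) -> list[SpectrumRecord]:
    """Draw per-nucleus mean spectra directly from the stain model.

    Equivalent to rendering scenes and averaging nucleus pixels, but at
    record level: each nucleus gets a hematoxylin concentration, the
    patient's staining/thickness multipliers, its class tilt, and small
    per-band noise.  ``tilt_amplitude`` 0 gives the null simulator with no
    class difference.  Balanced classes per patient.
    """
    stains = stains or StainModel()
    rng = np.random.default_rng(seed)
    lam = np.asarray(stains.wavelengths, float)
    hem = stains.hematoxylin_absorbance
    eos = stains.eosin_absorbance
    g = np.tanh((645.0 - lam) / 25.0)
    records = []
    for p in range(n_patients):
        staining = float(np.exp(rng.normal(0.0, 0.15)))
        thickness = float(np.exp(rng.normal(0.0, 0.2)))
        rev = -1.0 if p in reversed_patients else 1.0
        for i in range(nuclei_per_patient):
            label = "cancerous" if i % 2 == 0 else "normal"
            sign = rev if label == "cancerous" else -rev
            c_hem = max(0.5, rng.normal(1.0, 0.12)) * staining
            absorb = thickness * (c_hem * hem + 0.05 * staining * eos)
            s = np.power(10.0, -absorb) * (1.0 + sign * tilt_amplitude * g)
            s = np.clip(s + rng.normal(0.0, noise_sd, lam.size), 1e-4, None)
            records.append(SpectrumRecord.from_raw(
                s, label, f"P{p + 1:02d}", image_id=f"I{i // 10}", nucleus_id=i))
    return records


#: Nucleus shapes at the realistic nucleus-to-patch scale: a 101-px patch
#: at 139 nm/px spans ~14 um, and epithelial/SCC nuclei (7-12 um across)
#: fill a large part of it.  The scene generator uses smaller nuclei to
#: keep whole fields affordable; patch-level studies model the true ratio.
PATCH_NORMAL_SHAPE = NucleusShapeModel(24.0, 3.0, 1.0, 1.35)
PATCH_CANCEROUS_SHAPE = NucleusShapeModel(30.0, 4.5, 1.0, 2.0)


def generate_patch_dataset(
    n_patients: int = 6,
    patches_per_class: int = 10,
    patch_size: int = 101,
    tilt_amplitude: float = 0.035,
    equalize_morphology: bool = True,
    noise_sd: float = 0.01,
    stains: StainModel | None = None,
    seed: int = 0,
) -> dict:
    """Nucleus-centered HSI + RGB patch pairs for classifier studies.

    Each patch holds one centered nucleus on a cytoplasm field, rendered
    with the same Beer-Lambert physics as full scenes and with nuclei at
    the realistic nucleus-to-patch scale.  With ``equalize_morphology``
    both classes draw the same shape model, so the classes differ only
    spectrally — the regime in which the hyperspectral patch classifier
    should beat the RGB one.  ``patches_per_class`` is per patient.
    Returns a dict with float32 arrays ``hsi`` (N, s, s, 87), ``rgb``
    (N, s, s, 3), int ``labels`` (1 = cancerous), and ``patients``
    (string ids).
    """
    stains = stains or StainModel()
    rng = np.random.default_rng(seed)
    lam = np.asarray(stains.wavelengths, float)
    weights = build_default_weights(lam)
    hsi_list, labels, patients = [], [], []
    rgb_list = []
    half = patch_size // 2
    yy, xx = np.mgrid[0:patch_size, 0:patch_size]
    for p in range(n_patients):
        staining = float(np.exp(rng.normal(0.0, 0.15)))
        thickness = float(np.exp(rng.normal(0.0, 0.2)))
        for i in range(2 * patches_per_class):
            label = "cancerous" if i % 2 == 0 else "normal"
            shape_model = PATCH_NORMAL_SHAPE if (
                label == "normal" or equalize_morphology
            ) else PATCH_CANCEROUS_SHAPE
            a, b, theta = shape_model.sample(rng)
            ct, st = np.cos(theta), np.sin(theta)
            u = (xx - half) * ct + (yy - half) * st
            v = -(xx - half) * st + (yy - half) * ct
            inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
            texture = 1.0 + 0.25 * ndi.gaussian_filter(
                rng.standard_normal((patch_size, patch_size)), 6.0)
            c_eos = np.where(inside, 0.05, 0.35 * texture) * staining
            c_hem = np.where(inside, max(0.5, rng.normal(1.0, 0.12)), 0.06) * staining
            absorb = (
                c_hem[:, :, None] * stains.hematoxylin_absorbance
                + c_eos[:, :, None] * stains.eosin_absorbance
            ) * thickness
            t = np.power(10.0, -absorb)
            sign = 1.0 if label == "cancerous" else -1.0
            tilt = 1.0 + sign * tilt_amplitude * np.tanh((645.0 - lam) / 25.0)
            t[inside] *= tilt
            t += rng.normal(0.0, noise_sd, t.shape)
            t = np.clip(t, 0.0, 1.5)
            cube = HyperCube(t, lam.copy(), "transmittance")
            hsi_list.append(t.astype(np.float32))
            rgb_list.append(synthesize_rgb(cube, weights).astype(np.float32))
            labels.append(1 if label == "cancerous" else 0)
            patients.append(f"P{p + 1:02d}")
    return {
        "hsi": np.stack(hsi_list),
        "rgb": np.stack(rgb_list),
        "labels": np.array(labels),
        "patients": np.array(patients),
    }


def sample_nucleus_counts(n_images: int, rng: np.random.Generator,
                          minimum: int = 21) -> np.ndarray:
    """Nuclei-per-image counts matching the observed field-of-view mix.

    Lognormal (median ~52 nuclei, sigma 0.5) truncated at ``minimum``,
    which reproduces the reported proportions of fields with 21-50,
    51-100, and >100 nuclei.
    """
    counts = np.empty(n_images, dtype=int)
    filled = 0
    while filled < n_images:
        draw = np.rint(rng.lognormal(np.log(52.0), 0.5, size=2 * n_images)).astype(int)
        draw = draw[draw >= minimum][: n_images - filled]
        counts[filled:filled + draw.size] = draw
        filled += draw.size
    return counts
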