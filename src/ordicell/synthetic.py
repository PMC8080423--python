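"""Synthetic ordinal data: feature sampler, toy cell renderer, preprocessing.

The feature sampler draws class-conditional Gaussians whose means sit on a
line — a latent severity axis — so adjacent classes overlap and the overlap
shrinks as ``class_separation`` grows.  The optional imbalance profile matches
the 8/7/11/19/16/22/17% split of the seven-class cervical-cytology grading
problem that motivates the package.

The toy cell renderer draws a single cell per image — an elliptical cytoplasm
containing a darker nuclear disc whose radius grows with abnormality grade,
mimicking the key morphological cue that abnormal cells present larger nuclei
than healthy ones.  Ground-truth masks are emitted alongside.

Image preprocessing mirrors the standard pipeline for pretrained-backbone
fine-tuning: zero-pad to square (preserving cell shape), resize to 224 x 224,
ImageNet channel normalization, and label-preserving augmentation (shift, zoom,
rotation, flips, saturation jitter).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage import draw as _draw
from skimage.color import hsv2rgb, rgb2hsv
from skimage.transform import AffineTransform, resize, warp

from .encodings import OrdinalLabel

__all__ = [
    "HERLEV_CLASS_COUNTS",
    "HERLEV_IMBALANCE_PERCENT",
    "OrdinalDatasetSpec",
    "ToyCellSpec",
    "AugmentParams",
    "sample_ordinal_features",
    "render_toy_cells",
    "zero_pad_to_square",
    "resize_and_normalize",
    "augment",
    "sample_augment_params",
    "IMAGENET_MEAN",
    "IMAGENET_STD",
]

#: Per-class cell counts of the seven-class Pap-smear grading benchmark
#: (three normal cell types followed by four abnormality grades).
HERLEV_CLASS_COUNTS = {
    1: ("superficial squamous epithelial", 74),
    2: ("intermediate squamous epithelial", 70),
    3: ("columnar epithelial", 98),
    4: ("mild squamous non-keratinizing dysplasia", 182),
    5: ("moderate squamous non-keratinizing dysplasia", 146),
    6: ("severe squamous non-keratinizing dysplasia", 197),
    7: ("squamous cell carcinoma in situ intermediate", 150),
}

#: The same class imbalance as integer percentages.
HERLEV_IMBALANCE_PERCENT = (8, 7, 11, 19, 16, 22, 17)

IMAGENET_MEAN = np.array([0.485, 0.456, 0.406])
IMAGENET_STD = np.array([0.229, 0.224, 0.225])


@dataclass(frozen=True)
class OrdinalDatasetSpec:
    """Sampling plan for the ordinal Gaussian feature generator.

    Either give explicit ``n_per_class`` or a ``total`` plus an ``imbalance``
    profile (``"balanced"``, ``"herlev"`` or a tuple of proportions).
    ``class_separation`` is the distance between adjacent class means in units
    of the within-class spread ``noise_sd``.
    """

    K: int = 7
    n_per_class: tuple[int, ...] | None = None
    total: int | None = None
    imbalance: str | tuple[float, ...] = "balanced"
    feature_dim: int = 2
    class_separation: float = 1.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if self.class_separation < 0:
            raise ValueError("class_separation must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.n_per_class is None and self.total is None:
            raise ValueError("give either n_per_class or total")

    def resolve_counts(self) -> np.ndarray:
        """Per-class sample counts implied by the spec."""
        if self.n_per_class is not None:
            counts = np.asarray(self.n_per_class, dtype=int)
            if counts.size != self.K or np.any(counts < 1):
                raise ValueError("n_per_class must list K counts >= 1")
            return counts
        if self.imbalance == "balanced":
            props = np.full(self.K, 1.0 / self.K)
        elif self.imbalance == "herlev":
            if self.K != 7:
                raise ValueError("the herlev imbalance profile requires K = 7")
            props = np.asarray(HERLEV_IMBALANCE_PERCENT, dtype=float) / 100.0
        else:
            props = np.asarray(self.imbalance, dtype=float)
            if props.size != self.K or np.any(props <= 0):
                raise ValueError("imbalance proportions must list K positive values")
            props = props / props.sum()
        # Largest-remainder rounding keeps the total exact.
        raw = props * self.total
        counts = np.floor(raw).astype(int)
        remainder = self.total - counts.sum()
        order = np.argsort(-(raw - counts))
        counts[order[:remainder]] += 1
        if np.any(counts < 1):
            raise ValueError("total too small for the requested imbalance profile")
        return counts


def sample_ordinal_features(spec: OrdinalDatasetSpec) -> pd.DataFrame:
    """Draw a labelled feature table from ordered Gaussian class conditionals.

    Class k has mean ``class_separation * noise_sd * (k - 1)`` on the first
    feature axis, zero elsewhere, and isotropic s.d. ``noise_sd``.  Returns a
    DataFrame with columns ``feature_0 .. feature_{d-1}`` and ``label``
    (1-based), rows shuffled, reproducible under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    counts = spec.resolve_counts()
    rows, labels = [], []
    for k in range(1, spec.K + 1):
        mean = np.zeros(spec.feature_dim)
        mean[0] = spec.class_separation * spec.noise_sd * (k - 1)
        x = rng.normal(mean, spec.noise_sd, size=(counts[k - 1], spec.feature_dim))
        rows.append(x)
        labels.append(np.full(counts[k - 1], k))
    X = np.vstack(rows)
    y = np.concatenate(labels)
    perm = rng.permutation(y.size)
    df = pd.DataFrame(X[perm], columns=[f"feature_{i}" for i in range(spec.feature_dim)])
    df["label"] = y[perm]
    return df


@dataclass(frozen=True)
class ToyCellSpec:
    """Rendering plan for toy single-cell images with ordinal morphology.

    ``nucleus_radius_by_class`` must be non-decreasing over the grades so the
    nucleus/cytoplasm area ratio grows with severity; every nucleus must fit
    inside the cytoplasm.
    """

    image_size: int = 64
    nucleus_radius_by_class: tuple[float, ...] = (5, 5, 6, 8, 10, 12, 14)
    cytoplasm_radius: float = 26.0
    stain_noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        radii = np.asarray(self.nucleus_radius_by_class, dtype=float)
        if np.any(np.diff(radii) < 0):
            raise ValueError("nucleus radii must be non-decreasing over grades")
        if radii.max() >= self.cytoplasm_radius:
            raise ValueError("nucleus radius must be smaller than the cytoplasm radius")
        if self.cytoplasm_radius >= self.image_size / 2:
            raise ValueError("cytoplasm must fit inside the image")


# Flat stain colours (RGB in [0, 1]); Pap staining renders cytoplasm pale
# pink/cyan and nuclei dark blue-purple.
_BACKGROUND = np.array([0.95, 0.95, 0.97])
_CYTOPLASM = np.array([0.80, 0.75, 0.88])
_NUCLEUS = np.array([0.30, 0.15, 0.45])


def render_toy_cells(
    spec: ToyCellSpec, labels: list[OrdinalLabel] | list[int]
) -> tuple[np.ndarray, np.ndarray]:
    """Render one toy cell image per label.

    Returns ``(images, masks)``: images are float RGB in [0, 1] with shape
    (N, H, W, 3); masks are uint8 with 0 background, 1 cytoplasm, 2 nucleus.
    Pixel-identical under the same ``spec.seed`` and labels.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.image_size
    centre = n / 2.0
    images = np.empty((len(labels), n, n, 3), dtype=float)
    masks = np.zeros((len(labels), n, n), dtype=np.uint8)
    for i, lab in enumerate(labels):
        k = int(lab)
        if not (1 <= k <= len(spec.nucleus_radius_by_class)):
            raise ValueError(f"label {k} has no nucleus radius in the spec")
        img = np.tile(_BACKGROUND, (n, n, 1)).copy()
        mask = masks[i]
        # Cytoplasm: ellipse with mild eccentricity and random orientation.
        angle = rng.uniform(0, np.pi)
        rr, cc = _draw.ellipse(
            centre, centre, spec.cytoplasm_radius, 0.8 * spec.cytoplasm_radius,
            shape=(n, n), rotation=angle,
        )
        img[rr, cc] = _CYTOPLASM
        mask[rr, cc] = 1
        # Nucleus: centred disc, radius set by the class grade.  Drawn from an
        # explicit distance grid (|x - c|^2 <= r^2) so the pixel count tracks
        # pi r^2 within the lattice-point (Gauss circle) error; the quarter-pixel
        # centre offset avoids the symmetric-lattice worst case.
        r_nuc = spec.nucleus_radius_by_class[k - 1]
        yy, xx = np.mgrid[0:n, 0:n]
        c_nuc = centre - 0.25
        disc = (yy - c_nuc) ** 2 + (xx - c_nuc) ** 2 <= r_nuc**2
        img[disc] = _NUCLEUS
        mask[disc] = 2
        if spec.stain_noise_sd > 0:
            img = img + rng.normal(0.0, spec.stain_noise_sd, img.shape)
        images[i] = np.clip(img, 0.0, 1.0)
    return images, masks


def zero_pad_to_square(image: np.ndarray) -> np.ndarray:
    """Zero-pad to a square of side max(h, w) with the content centred."""
    image = np.asarray(image)
    h, w = image.shape[:2]
    side = max(h, w)
    pad_h, pad_w = side - h, side - w
    pads = [(pad_h // 2, pad_h - pad_h // 2), (pad_w // 2, pad_w - pad_w // 2)]
    pads += [(0, 0)] * (image.ndim - 2)
    return np.pad(image, pads, mode="constant", constant_values=0)


def resize_and_normalize(image: np.ndarray, size: int = 224) -> np.ndarray:
    """Bilinear-resize to ``size x size`` and apply ImageNet channel statistics.

    Grayscale input is broadcast to three channels first.  Returns an HWC float
    array with each channel standardized as ``(x - mean) / std``.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim == 2:
        image = np.repeat(image[:, :, None], 3, axis=2)
    if image.shape[:2] != (size, size):
        image = resize(image, (size, size), order=1, anti_aliasing=False,
                       preserve_range=True)
    return (image - IMAGENET_MEAN) / IMAGENET_STD


@dataclass(frozen=True)
class AugmentParams:
    """One draw of the augmentation transforms; ``neutral()`` is the identity."""

    shift_x: float = 0.0  # fraction of width
    shift_y: float = 0.0  # fraction of height
    zoom: float = 1.0
    rotation_deg: float = 0.0
    flip_h: bool = False
    flip_v: bool = False
    saturation: float = 1.0

    @classmethod
    def neutral(cls) -> "AugmentParams":
        return cls()

    def is_neutral(self) -> bool:
        return self == AugmentParams()


def sample_augment_params(
    rng: np.random.Generator,
    max_shift: float = 0.1,
    zoom_range: tuple[float, float] = (0.9, 1.1),
    max_rotation_deg: float = 15.0,
    saturation_range: tuple[float, float] = (0.8, 1.2),
) -> AugmentParams:
    """Sample shift/zoom/rotation/flip/saturation parameters for one image."""
    return AugmentParams(
        shift_x=rng.uniform(-max_shift, max_shift),
        shift_y=rng.uniform(-max_shift, max_shift),
        zoom=rng.uniform(*zoom_range),
        rotation_deg=rng.uniform(-max_rotation_deg, max_rotation_deg),
        flip_h=bool(rng.integers(2)),
        flip_v=bool(rng.integers(2)),
        saturation=rng.uniform(*saturation_range),
    )


def augment(
    image: np.ndarray,
    seed: int | None = None,
    params: AugmentParams | None = None,
) -> np.ndarray:
    """Apply a random label-preserving augmentation; shape is preserved.

    Give either a ``seed`` (parameters are drawn deterministically from it) or
    explicit ``params``.  A neutral parameter draw returns the input bit-exact.
    """
    image = np.asarray(image, dtype=float)
    if params is None:
        if seed is None:
            raise ValueError("give either seed or params")
        params = sample_augment_params(np.random.default_rng(seed))
    if params.is_neutral():
        return image.copy()
    h, w = image.shape[:2]
    out = image
    if params.flip_h:
        out = out[:, ::-1]
    if params.flip_v:
        out = out[::-1, :]
    centre = np.array([w / 2.0, h / 2.0])
    # zoom + rotation about the image centre, then the shift
    tf = (
        AffineTransform(translation=-centre)
        + AffineTransform(scale=params.zoom, rotation=np.deg2rad(params.rotation_deg))
        + AffineTransform(translation=centre)
        + AffineTransform(translation=(params.shift_x * w, params.shift_y * h))
    )
    out = warp(out, tf.inverse, order=1, mode="constant", cval=0.0,
               preserve_range=True)
    if out.ndim == 3 and out.shape[2] == 3 and params.saturation != 1.0:
        hsv = rgb2hsv(np.clip(out, 0.0, 1.0))
        hsv[:, :, 1] = np.clip(hsv[:, :, 1] * params.saturation, 0.0, 1.0)
        out = hsv2rgb(hsv)
    return out


def write_provenance(path: Path, payload: dict) -> None:
    """Write a generator provenance record (seed, parameters) as JSON."""
    Path(path).write_text(json.dumps(payload, indent=2, default=str))
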