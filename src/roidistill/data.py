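"""Dataset loading, patient-level splits, preprocessing and paired augmentation.

The augmentation pipelines mirror the two standard recipes used for
radiograph classifiers: a *weak* pipeline (resize, shift/scale with zero
rotation, ImageNet normalization) and a *strong* pipeline that additionally
applies, each with probability 0.9, exactly one operation from three groups
(contrast-type: CLAHE / brightness-contrast / gamma; sharpness-type:
sharpen / blur / motion blur; color-type: brightness-contrast / HSV shift).

A central correctness requirement is *paired randomness*: a raw image and
its ROI-annotated counterpart must be transformed with the identical
sampled parameters so their feature maps stay spatially comparable; see
:func:`augment_pair`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .synthetic import CLASS_NAMES

IMAGENET_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float32)
IMAGENET_STD = np.array([0.229, 0.224, 0.225], dtype=np.float32)

LABEL_TO_INDEX = {name: i for i, name in enumerate(CLASS_NAMES)}


@dataclass
class PairedRecord:
    """One dataset row: identifiers, class label and the two image paths."""

    image_id: str
    patient_id: str
    label: int
    raw_path: str
    roi_path: str
    view: str | None = None


@dataclass
class SplitResult:
    train: list
    validation: list
    seed: int
    val_fraction_achieved: float


def load_manifest(path) -> list[PairedRecord]:
    """Read a delimited manifest into records, validating labels and paths."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"image_id", "patient_id", "label", "raw_path", "roi_path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} lacks columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        if row.label not in LABEL_TO_INDEX:
            raise ValueError(
                f"unknown label {row.label!r} for image {row.image_id!r}; "
                f"expected one of {sorted(LABEL_TO_INDEX)}"
            )
        for p in (row.raw_path, row.roi_path):
            if p and not Path(p).exists():
                raise FileNotFoundError(f"image file missing for {row.image_id!r}: {p}")
        records.append(PairedRecord(
            image_id=row.image_id, patient_id=row.patient_id,
            label=LABEL_TO_INDEX[row.label],
            raw_path=row.raw_path, roi_path=row.roi_path,
            view=getattr(row, "view", None) or None,
        ))
    return records


def load_image(path) -> np.ndarray:
    from PIL import Image

    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"))
    return arr


def patient_level_split(records, val_fraction: float = 0.2, seed: int = 0) -> SplitResult:
    """Subject-based split: no patient contributes images to both sides.

    Patients are shuffled by ``seed`` and assigned greedily to the
    validation side while doing so improves a joint objective combining the
    deviation of the achieved validation image fraction from
    ``val_fraction`` and the per-class deviation of validation shares from
    ``val_fraction`` (an attempt to preserve label proportions under the
    non-overlap constraint).
    """
    records = list(records)
    if not records:
        raise ValueError("cannot split an empty record collection")
    if not 0.0 < val_fraction < 1.0:
        raise ValueError("val_fraction must be in (0, 1)")

    by_patient: dict[str, list] = {}
    for r in records:
        by_patient.setdefault(r.patient_id, []).append(r)
    if len(by_patient) < 2:
        raise ValueError("cannot split: dataset contains a single patient")

    n_total = len(records)
    classes = sorted({r.label for r in records})
    class_total = {c: sum(r.label == c for r in records) for c in classes}

    def objective(val_images: int, val_class: dict) -> float:
        # summed per-class deviations outweigh the overall-fraction term so
        # that single-patient moves improving stratification are accepted
        j = abs(val_images / n_total - val_fraction)
        dev = [abs(val_class[c] / class_total[c] - val_fraction) for c in classes]
        return j + float(np.sum(dev))

    rng = np.random.default_rng(seed)
    order = list(by_patient)
    rng.shuffle(order)

    val_patients: set[str] = set()
    val_images = 0
    val_class = {c: 0 for c in classes}
    current = objective(val_images, val_class)
    for pid in order:
        group = by_patient[pid]
        cand_images = val_images + len(group)
        cand_class = dict(val_class)
        for r in group:
            cand_class[r.label] += 1
        cand = objective(cand_images, cand_class)
        if cand < current and cand_images < n_total:
            val_patients.add(pid)
            val_images, val_class, current = cand_images, cand_class, cand

    # local refinement: toggle patients across sides while it improves the
    # objective (the single greedy pass cannot revisit earlier choices)
    for _ in range(5):
        improved = False
        for pid in order:
            group = by_patient[pid]
            sign = -1 if pid in val_patients else 1
            cand_images = val_images + sign * len(group)
            if cand_images <= 0 or cand_images >= n_total:
                continue
            cand_class = dict(val_class)
            for r in group:
                cand_class[r.label] += sign
            cand = objective(cand_images, cand_class)
            if cand < current - 1e-12:
                if sign > 0:
                    val_patients.add(pid)
                else:
                    val_patients.discard(pid)
                val_images, val_class, current = cand_images, cand_class, cand
                improved = True
        if not improved:
            break

    if not val_patients:  # degenerate granularity: force the best single patient
        best = min(
            (pid for pid in order if len(by_patient[pid]) < n_total),
            key=lambda pid: objective(
                len(by_patient[pid]),
                {c: sum(r.label == c for r in by_patient[pid]) for c in classes},
            ),
        )
        val_patients.add(best)
        val_images = len(by_patient[best])

    train = [r for r in records if r.patient_id not in val_patients]
    val = [r for r in records if r.patient_id in val_patients]
    return SplitResult(train=train, validation=val, seed=seed,
                       val_fraction_achieved=len(val) / n_total)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def _to_float01(image: np.ndarray) -> np.ndarray:
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected a (H, W, 3) image, got shape {image.shape}")
    if image.dtype == np.uint8:
        return image.astype(np.float32) / 255.0
    return image.astype(np.float32)


def _resize_bilinear(image: np.ndarray, size: int) -> np.ndarray:
    if image.shape[0] == size and image.shape[1] == size:
        return image
    from skimage.transform import resize

    return resize(image, (size, size), order=1, anti_aliasing=False,
                  preserve_range=True).astype(np.float32)


def normalize(image: np.ndarray) -> np.ndarray:
    """ImageNet channel normalization of a float [0,1] HWC image -> CHW."""
    out = (image - IMAGENET_MEAN) / IMAGENET_STD
    return np.ascontiguousarray(out.transpose(2, 0, 1)).astype(np.float32)


def preprocess(image: np.ndarray, target_size: int = 224) -> np.ndarray:
    """Bilinear resize + ImageNet normalization; returns (3, T, T) float32."""
    return normalize(_resize_bilinear(_to_float01(image), target_size))


def preprocess_batch(images, target_size: int | None = None) -> np.ndarray:
    size = target_size if target_size is not None else images[0].shape[0]
    return np.stack([preprocess(im, size) for im in images])


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

_STRONG_PARAMS = {
    "shift_limit": 0.1, "scale_limit": 0.5, "rotate_limit": 0,
    "clahe_clip_limit": 4.0, "clahe_grid": (8, 8),
    "brightness_limit": 0.2, "contrast_limit": 0.2,
    "gamma_limit": (80, 120),
    "sharpen_alpha": (0.2, 0.5), "sharpen_lightness": (0.5, 1.0),
    "blur_limit": 7, "motion_blur_limit": 7,
    "hue_shift_limit": 20, "sat_shift_limit": 30, "val_shift_limit": 20,
    "group_p": 0.9,
}


@dataclass(frozen=True)
class AugmentationSpec:
    """Named augmentation recipe with its parameter table."""

    name: str
    target_size: int = 224
    params: dict = field(default_factory=lambda: dict(_STRONG_PARAMS))
    mean: tuple = tuple(IMAGENET_MEAN.tolist())
    std: tuple = tuple(IMAGENET_STD.tolist())

    def __post_init__(self):
        if self.name not in ("strong", "weak"):
            raise ValueError(f"unknown augmentation spec name {self.name!r}")
        if not 0.0 <= self.params.get("group_p", 0.9) <= 1.0:
            raise ValueError("group probability must be in [0, 1]")

    @classmethod
    def strong(cls, target_size: int = 224) -> "AugmentationSpec":
        return cls(name="strong", target_size=target_size)

    @classmethod
    def weak(cls, target_size: int = 224) -> "AugmentationSpec":
        return cls(name="weak", target_size=target_size)


def _reflect_101(coords: np.ndarray, n: int) -> np.ndarray:
    """Map sampling coordinates into [0, n-1] by edge-excluding reflection
    (… c b | a b c | b a …), the standard border mode of affine augmenters."""
    if n == 1:
        return np.zeros_like(coords)
    period = 2.0 * (n - 1)
    c = np.mod(coords, period)
    return np.where(c > n - 1, period - c, c)


def _warp_scale_shift(img: np.ndarray, scale: float, dy: float, dx: float) -> np.ndarray:
    """Axis-aligned bilinear warp (shift then scale about the center).

    Valid because the pipelines never rotate (rotate_limit = 0); the warp is
    separable, with reflect-101 border handling.
    """
    h, w = img.shape[:2]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    ys = _reflect_101(cy + (np.arange(h, dtype=np.float32) - cy - dy * h) / scale, h)
    xs = _reflect_101(cx + (np.arange(w, dtype=np.float32) - cx - dx * w) / scale, w)

    def gather_1d(a: np.ndarray, coords: np.ndarray, axis: int) -> np.ndarray:
        n = a.shape[axis]
        i0 = np.floor(coords).astype(np.int64)
        frac = (coords - i0).astype(np.float32)
        idx0 = np.clip(i0, 0, n - 1)
        idx1 = np.clip(i0 + 1, 0, n - 1)
        t0 = np.take(a, idx0, axis=axis)
        t1 = np.take(a, idx1, axis=axis)
        shape = [1] * a.ndim
        shape[axis] = -1
        return t0 * (1.0 - frac.reshape(shape)) + t1 * frac.reshape(shape)

    tmp = gather_1d(img.astype(np.float32), ys, axis=0)
    return gather_1d(tmp, xs, axis=1)


def _apply_clahe(img: np.ndarray, clip_limit: float, grid: tuple) -> np.ndarray:
    from skimage import exposure

    out = np.empty_like(img)
    ks = (max(1, img.shape[0] // grid[0]), max(1, img.shape[1] // grid[1]))
    for c in range(3):
        out[:, :, c] = exposure.equalize_adapthist(
            np.clip(img[:, :, c], 0, 1), kernel_size=ks, clip_limit=clip_limit / 100.0)
    return out.astype(np.float32)


def _apply_brightness_contrast(img, brightness, contrast):
    return np.clip((img - 0.5) * (1.0 + contrast) + 0.5 + brightness, 0.0, 1.0)


def _apply_gamma(img, gamma):
    return np.clip(img, 0.0, 1.0) ** gamma


def _apply_sharpen(img, alpha, lightness):
    blurred = ndimage.gaussian_filter(img, sigma=(1.0, 1.0, 0.0))
    return np.clip(img + alpha * lightness * (img - blurred), 0.0, 1.0)


def _apply_blur(img, k):
    return ndimage.uniform_filter(img, size=(k, k, 1))


def _apply_motion_blur(img, k, horizontal):
    axis = 1 if horizontal else 0
    return ndimage.uniform_filter1d(img, size=k, axis=axis)


def _apply_hsv(img, dh, ds, dv):
    from skimage import color

    hsv = color.rgb2hsv(np.clip(img, 0, 1))
    hsv[:, :, 0] = (hsv[:, :, 0] + dh) % 1.0
    hsv[:, :, 1] = np.clip(hsv[:, :, 1] + ds, 0, 1)
    hsv[:, :, 2] = np.clip(hsv[:, :, 2] + dv, 0, 1)
    return color.hsv2rgb(hsv).astype(np.float32)


class PairedTransform:
    """A seeded augmentation whose sampled parameters can be reused.

    ``sample_params`` draws every random decision; ``apply`` is then fully
    deterministic, so the same parameter set can be applied to both members
    of a raw/ROI pair.
    """

    def __init__(self, spec: AugmentationSpec):
        self.spec = spec

    def sample_params(self, rng: np.random.Generator) -> dict:
        p = self.spec.params
        params = {
            "shift": (float(rng.uniform(-p["shift_limit"], p["shift_limit"])),
                      float(rng.uniform(-p["shift_limit"], p["shift_limit"]))),
            "scale": float(rng.uniform(1.0 - p["scale_limit"], 1.0 + p["scale_limit"])),
        }
        if self.spec.name == "strong":
            gp = p["group_p"]
            g1 = rng.random() < gp
            c1 = int(rng.integers(3))
            bc1 = (float(rng.uniform(-p["brightness_limit"], p["brightness_limit"])),
                   float(rng.uniform(-p["contrast_limit"], p["contrast_limit"])))
            gamma = float(rng.uniform(p["gamma_limit"][0], p["gamma_limit"][1])) / 100.0
            g2 = rng.random() < gp
            c2 = int(rng.integers(3))
            sharpen = (float(rng.uniform(*p["sharpen_alpha"])),
                       float(rng.uniform(*p["sharpen_lightness"])))
            blur_k = int(rng.choice([3, 5, 7]))
            mb_k = int(rng.choice([3, 5, 7]))
            mb_horiz = bool(rng.random() < 0.5)
            g3 = rng.random() < gp
            c3 = int(rng.integers(2))
            bc3 = (float(rng.uniform(-p["brightness_limit"], p["brightness_limit"])),
                   float(rng.uniform(-p["contrast_limit"], p["contrast_limit"])))
            hsv = (float(rng.uniform(-p["hue_shift_limit"], p["hue_shift_limit"])) / 360.0,
                   float(rng.uniform(-p["sat_shift_limit"], p["sat_shift_limit"])) / 255.0,
                   float(rng.uniform(-p["val_shift_limit"], p["val_shift_limit"])) / 255.0)
            params.update(g1=g1, c1=c1, bc1=bc1, gamma=gamma,
                          g2=g2, c2=c2, sharpen=sharpen, blur_k=blur_k,
                          mb_k=mb_k, mb_horiz=mb_horiz,
                          g3=g3, c3=c3, bc3=bc3, hsv=hsv)
        return params

    def apply(self, image: np.ndarray, params: dict) -> np.ndarray:
        p = self.spec.params
        img = _resize_bilinear(_to_float01(image), self.spec.target_size)
        img = _warp_scale_shift(img, params["scale"], *params["shift"])
        if self.spec.name == "strong":
            if params["g1"]:
                if params["c1"] == 0:
                    img = _apply_clahe(img, p["clahe_clip_limit"], p["clahe_grid"])
                elif params["c1"] == 1:
                    img = _apply_brightness_contrast(img, *params["bc1"])
                else:
                    img = _apply_gamma(img, params["gamma"])
            if params["g2"]:
                if params["c2"] == 0:
                    img = _apply_sharpen(img, *params["sharpen"])
                elif params["c2"] == 1:
                    img = _apply_blur(img, params["blur_k"])
                else:
                    img = _apply_motion_blur(img, params["mb_k"], params["mb_horiz"])
            if params["g3"]:
                if params["c3"] == 0:
                    img = _apply_brightness_contrast(img, *params["bc3"])
                else:
                    img = _apply_hsv(img, *params["hsv"])
        return normalize(img)

    def __call__(self, image: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        return self.apply(image, self.sample_params(rng))


def build_augmentation(spec: AugmentationSpec) -> PairedTransform:
    """Build the transform for a spec (raises on unknown spec names)."""
    return PairedTransform(spec)


def augment_pair(raw: np.ndarray, roi: np.ndarray, transform: PairedTransform,
                 shared_seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Apply one sampled transform to both members of a raw/ROI pair.

    All spatial *and* photometric parameters are shared, preserving the
    pixelwise correspondence that makes teacher and student feature maps
    comparable.
    """
    if raw.shape != roi.shape:
        raise ValueError(f"pair size mismatch: raw {raw.shape} vs roi {roi.shape}")
    rng = np.random.default_rng(shared_seed)
    params = transform.sample_params(rng)
    return transform.apply(raw, params), transform.apply(roi, params)
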