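"""Synthetic paired raw/ROI image benchmark.

Emulates the statistical structure of an expert-annotated chest-radiograph
dataset: five classes (healthy plus four pneumonia etiologies), a handful of
images per patient, and for every image a *raw* variant plus an *ROI*
variant on which an expert has traced the lesion boundary in one shared
color (the same color for every disease class, so the annotation conveys
localization but never the label) and the organ outline in a second color.

Disease classes differ by a procedural texture (dot, stripe, blob or
speckle pattern with a subtle per-class tint — a stand-in for the subtle
opacification patterns that distinguish pneumonia etiologies) rendered
inside an elliptical lesion.  Distractor patches carrying *random* classes'
textures at the same amplitude are scattered over the whole frame; only a
faint luminance halo around the true lesion (and, on ROI images, the
expert's outline) distinguishes it, so knowing *where* the lesion sits
genuinely helps classification: this is the property the annotation is
meant to transfer.

Everything is driven by a single integer seed; two runs with the same
configuration produce byte-identical images.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

CLASS_NAMES: tuple[str, ...] = ("healthy", "bacterial", "fungal", "viral", "covid19")
HEALTHY = 0

#: class priors matching the study-like label distribution
#: (673 healthy, 100 bacterial, 125 fungal, 74 viral, 110 covid of 1082)
DEFAULT_CLASS_PROBS: tuple[float, ...] = (
    673 / 1082, 100 / 1082, 125 / 1082, 74 / 1082, 110 / 1082,
)

#: one shared annotation color for every disease class (lesion outline)
LESION_COLOR: tuple[int, int, int] = (60, 90, 160)
#: second color for the organ (lung) outline, present on every ROI image
ORGAN_COLOR: tuple[int, int, int] = (160, 90, 60)


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic benchmark generator.

    ``lesion_signal`` controls how much of the class-discriminative texture
    is confined to the lesion (1.0 = all of it); ``background_clutter``
    scales the amplitude and number of distractor texture patches outside
    the lesion.
    """

    n_patients: int = 200
    images_per_patient: int = 1
    class_probs: tuple[float, ...] = DEFAULT_CLASS_PROBS
    image_size: int = 64
    lesion_signal: float = 1.0
    background_clutter: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError("n_patients must be a positive integer")
        if self.images_per_patient < 1:
            raise ValueError("images_per_patient must be >= 1")
        if self.image_size < 16:
            raise ValueError("image_size must be >= 16")
        probs = np.asarray(self.class_probs, dtype=float)
        if probs.shape != (5,) or (probs < 0).any():
            raise ValueError("class_probs must be 5 non-negative probabilities")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError(f"class_probs must sum to 1 (got {probs.sum()!r})")
        if not 0.0 <= self.lesion_signal <= 1.0:
            raise ValueError("lesion_signal must be in [0, 1]")
        if self.background_clutter < 0:
            raise ValueError("background_clutter must be >= 0")


@dataclass
class SyntheticSample:
    """One paired sample: raw image, ROI image, label, patient, lesion mask.

    ``lesion_mask`` is ground truth used only by tests and attribution
    scoring; training code never reads it.
    """

    image_id: str
    patient_id: str
    label: int
    raw_image: np.ndarray   # (H, W, 3) uint8
    roi_image: np.ndarray   # (H, W, 3) uint8
    lesion_mask: np.ndarray  # (H, W) bool
    organ_mask: np.ndarray = field(repr=False, default=None)
    view: str = "PA"


# ---------------------------------------------------------------------------
# procedural textures: one per disease class, zero-mean, unit max amplitude
# ---------------------------------------------------------------------------

#: per-class channel weighting of the opacity texture: a subtle spectral
#: signature that, like the granularity pattern, distinguishes etiologies
_CLASS_TINTS = {
    1: (1.45, 0.80, 0.75),   # bacterial
    2: (0.75, 1.45, 0.80),   # fungal
    3: (0.80, 0.75, 1.45),   # viral
    4: (1.25, 1.25, 0.50),   # covid19
}


def _texture(class_index: int, size: int, rng: np.random.Generator) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float32)
    if class_index == 1:  # bacterial: dense bright dots
        t = (rng.random((size, size)) < 0.10).astype(np.float32)
        t = ndimage.gaussian_filter(t, 0.9)
    elif class_index == 2:  # fungal: oriented stripes
        theta = rng.uniform(0, np.pi)
        freq = rng.uniform(4.0, 6.5) / size
        t = np.sin(2 * np.pi * freq * (xx * np.cos(theta) + yy * np.sin(theta)))
    elif class_index == 3:  # viral: large smooth blobs
        t = ndimage.gaussian_filter(rng.standard_normal((size, size)), 3.5)
    elif class_index == 4:  # covid19: fine ground-glass speckle
        t = ndimage.gaussian_filter(rng.standard_normal((size, size)), 1.3)
    else:
        raise ValueError(f"no texture for class index {class_index}")
    t = t - t.mean()
    peak = np.abs(t).max()
    if peak > 0:
        t = t / peak
    return t.astype(np.float32)


def _ellipse_mask(size: int, cy: float, cx: float, ry: float, rx: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float32)
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def _boundary(mask: np.ndarray, width: int = 1) -> np.ndarray:
    """Inner morphological boundary: mask minus its ``width``-fold erosion."""
    if not mask.any():
        return np.zeros_like(mask, dtype=bool)
    return mask & ~ndimage.binary_erosion(mask, border_value=0, iterations=width)


def render_annotation(raw: np.ndarray, lesion_mask: np.ndarray,
                      organ_mask: np.ndarray, stroke_width: int = 3) -> np.ndarray:
    """Draw annotation outlines on a copy of ``raw``.

    The boundary (not the fill) of ``lesion_mask`` is drawn in the shared
    disease-annotation color and the boundary of ``organ_mask`` in the organ
    color; every pixel off both boundaries is returned unchanged.
    """
    if raw.ndim != 3 or raw.shape[2] != 3:
        raise ValueError(f"raw must be (H, W, 3), got {raw.shape}")
    if lesion_mask.shape != raw.shape[:2] or organ_mask.shape != raw.shape[:2]:
        raise ValueError(
            f"mask sizes {lesion_mask.shape}/{organ_mask.shape} do not match "
            f"image size {raw.shape[:2]}"
        )
    roi = raw.copy()
    roi[_boundary(organ_mask, stroke_width)] = ORGAN_COLOR
    roi[_boundary(lesion_mask, stroke_width)] = LESION_COLOR
    return roi


def _render_sample(size: int, label: int, lesion_signal: float, clutter: float,
                   anatomy: dict, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (raw uint8, lesion_mask bool, organ_mask bool) for one image."""
    base = np.full((size, size), anatomy["base_intensity"], dtype=np.float32)
    # gentle illumination gradient
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float32) / size
    base += 0.05 * (yy - 0.5) * anatomy["gradient_sign"]

    organ = _ellipse_mask(size, anatomy["cy"] * size, anatomy["cx"] * size,
                          anatomy["ry"] * size, anatomy["rx"] * size)
    gray = base + 0.10 * organ.astype(np.float32)
    img = np.repeat(gray[:, :, None], 3, axis=2)

    amp = 0.35  # texture peak amplitude before signal/clutter scaling

    def add_texture(mask: np.ndarray, t_class: int, strength: float) -> None:
        tex = _texture(t_class, size, rng)
        tint = np.asarray(_CLASS_TINTS[t_class], dtype=np.float32)
        img[mask] += strength * tex[mask, None] * tint[None, :]

    lesion_mask = np.zeros((size, size), dtype=bool)
    if label != HEALTHY:
        # lesion placed inside the organ region
        cy, cx, ry, rx = anatomy["cy"], anatomy["cx"], 0.14, 0.14
        for _ in range(20):
            t_cy = rng.uniform(anatomy["cy"] - 0.6 * anatomy["ry"], anatomy["cy"] + 0.6 * anatomy["ry"])
            t_cx = rng.uniform(anatomy["cx"] - 0.6 * anatomy["rx"], anatomy["cx"] + 0.6 * anatomy["rx"])
            t_ry, t_rx = rng.uniform(0.12, 0.20), rng.uniform(0.12, 0.20)
            cand = _ellipse_mask(size, t_cy * size, t_cx * size, t_ry * size, t_rx * size)
            if (cand & organ).sum() >= 0.7 * cand.sum() and cand.any():
                cy, cx, ry, rx = t_cy, t_cx, t_ry, t_rx
                break
        lesion_mask = _ellipse_mask(size, cy * size, cx * size, ry * size, rx * size)
        # a faint inflammation halo around the true lesion: the only raw-
        # visible cue separating it from distractor patches
        halo = _ellipse_mask(size, cy * size, cx * size,
                             1.5 * ry * size, 1.5 * rx * size)
        img[halo] += 0.04

    # distractor patches: textures of *random* classes at full lesion
    # amplitude, scattered over the whole frame (organ and background
    # alike) but never overlapping the true lesion; without the halo or
    # the expert's outline nothing distinguishes them from a real lesion
    n_distract = rng.poisson(2.0 + 2.0 * clutter)
    for _ in range(n_distract):
        d_class = int(rng.integers(1, 5))
        for _ in range(10):
            d_mask = _ellipse_mask(size,
                                   rng.uniform(0.1, 0.9) * size,
                                   rng.uniform(0.1, 0.9) * size,
                                   rng.uniform(0.12, 0.20) * size,
                                   rng.uniform(0.12, 0.20) * size)
            if not (d_mask & lesion_mask).any():
                break
        else:
            continue
        add_texture(d_mask & ~lesion_mask, d_class, amp * min(1.0, clutter))

    if label != HEALTHY:
        add_texture(lesion_mask, label, amp * lesion_signal)
        if lesion_signal < 1.0:
            # diluted class signal outside the lesion
            add_texture(organ & ~lesion_mask, label, amp * (1.0 - lesion_signal))

    img += 0.02 * rng.standard_normal((size, size, 3)).astype(np.float32)
    raw = (np.clip(img, 0.0, 1.0) * 255.0 + 0.5).astype(np.uint8)
    return raw, lesion_mask, organ


def generate_dataset(config: GeneratorConfig, out_dir=None):
    """Generate the paired benchmark; deterministic given ``config.seed``.

    Returns ``(samples, manifest)`` where manifest is a DataFrame with
    columns image_id, patient_id, label, raw_path, roi_path, view.  When
    ``out_dir`` is given, PNG pairs and a tab-separated ``manifest.tsv`` are
    written there and the path columns point at the files; otherwise the
    path columns are empty.
    """
    import pandas as pd

    rng = np.random.default_rng(config.seed)
    n_pat = config.n_patients
    patient_ids = [f"P{i:05d}" for i in range(n_pat)]
    labels = rng.choice(5, size=n_pat, p=np.asarray(config.class_probs, dtype=float))
    anatomies = []
    for _ in range(n_pat):
        anatomies.append({
            "base_intensity": rng.uniform(0.15, 0.30),
            "gradient_sign": rng.choice([-1.0, 1.0]),
            "cy": rng.uniform(0.46, 0.54),
            "cx": rng.uniform(0.46, 0.54),
            "ry": rng.uniform(0.34, 0.40),
            "rx": rng.uniform(0.30, 0.36),
        })
    views = rng.choice(["AP", "PA"], size=n_pat, p=[0.275, 0.725])

    # one image per patient, extras round-robined to random patients
    image_owner = list(range(n_pat))
    n_extra = n_pat * (config.images_per_patient - 1)
    if n_extra:
        image_owner += list(rng.integers(0, n_pat, size=n_extra))

    samples: list[SyntheticSample] = []
    counts = [0] * n_pat
    for owner in image_owner:
        label = int(labels[owner])
        raw, lesion_mask, organ = _render_sample(
            config.image_size, label, config.lesion_signal,
            config.background_clutter, anatomies[owner], rng,
        )
        roi = render_annotation(raw, lesion_mask, organ)
        samples.append(SyntheticSample(
            image_id=f"{patient_ids[owner]}_{counts[owner]:02d}",
            patient_id=patient_ids[owner],
            label=label,
            raw_image=raw,
            roi_image=roi,
            lesion_mask=lesion_mask,
            organ_mask=organ,
            view=str(views[owner]),
        ))
        counts[owner] += 1

    rows = []
    for s in samples:
        raw_path = roi_path = ""
        if out_dir is not None:
            from pathlib import Path

            from PIL import Image

            out = Path(out_dir)
            (out / "images").mkdir(parents=True, exist_ok=True)
            raw_path = str(out / "images" / f"{s.image_id}_raw.png")
            roi_path = str(out / "images" / f"{s.image_id}_roi.png")
            Image.fromarray(s.raw_image).save(raw_path)
            Image.fromarray(s.roi_image).save(roi_path)
        rows.append({
            "image_id": s.image_id, "patient_id": s.patient_id,
            "label": CLASS_NAMES[s.label], "raw_path": raw_path,
            "roi_path": roi_path, "view": s.view,
        })
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        from pathlib import Path

        manifest.to_csv(Path(out_dir) / "manifest.tsv", sep="\t", index=False)
    return samples, manifest


# ---------------------------------------------------------------------------
# annotation-leak audit
# ---------------------------------------------------------------------------

@dataclass
class LeakReport:
    """Per-class annotation statistics and leak flags.

    ``color_leak``: some disease class uses an annotation color that another
    does not.  ``count_leak``: the per-class stroke-pixel-count distributions
    separate some pair of disease classes with an absolute standardized mean
    difference above ``threshold``.
    """

    per_class_colors: dict
    per_class_count_mean: dict
    per_class_count_std: dict
    max_pairwise_separation: float
    threshold: float
    color_leak: bool
    count_leak: bool

    @property
    def any_leak(self) -> bool:
        return self.color_leak or self.count_leak


def audit_label_leak(samples, threshold: float = 1.0) -> LeakReport:
    """Audit whether annotation strokes alone could reveal the disease class.

    Compares, across disease classes, the set of stroke colors and the
    distribution of stroke-pixel counts (strokes = pixels where the ROI
    image differs from the raw image, excluding the organ outline which is
    shared by every class).
    """
    by_class: dict[int, list] = {}
    for s in samples:
        if s.label == HEALTHY:
            continue
        by_class.setdefault(s.label, []).append(s)
    if len(by_class) < 2:
        raise ValueError("leak audit needs at least 2 disease classes present")

    organ_color = np.array(ORGAN_COLOR, dtype=np.uint8)
    colors: dict[int, set] = {}
    counts: dict[int, np.ndarray] = {}
    for label, group in sorted(by_class.items()):
        cset: set = set()
        cnt = []
        for s in group:
            stroke = (s.raw_image != s.roi_image).any(axis=2)
            stroke_rgb = s.roi_image[stroke]
            not_organ = ~(stroke_rgb == organ_color).all(axis=1)
            cnt.append(int(not_organ.sum()))
            for rgb in np.unique(stroke_rgb[not_organ], axis=0) if not_organ.any() else []:
                cset.add(tuple(int(v) for v in rgb))
        colors[label] = cset
        counts[label] = np.asarray(cnt, dtype=float)

    union = set().union(*colors.values())
    inter = set(union)
    for cset in colors.values():
        inter &= cset
    color_leak = union != inter

    max_d = 0.0
    labels_ = sorted(counts)
    for i, a in enumerate(labels_):
        for b in labels_[i + 1:]:
            xa, xb = counts[a], counts[b]
            pooled = np.sqrt((xa.var(ddof=1) if len(xa) > 1 else 0.0)
                             / 2 + (xb.var(ddof=1) if len(xb) > 1 else 0.0) / 2)
            if pooled == 0:
                d = np.inf if xa.mean() != xb.mean() else 0.0
            else:
                d = abs(xa.mean() - xb.mean()) / pooled
            max_d = max(max_d, float(d))

    return LeakReport(
        per_class_colors={k: sorted(v) for k, v in colors.items()},
        per_class_count_mean={k: float(v.mean()) for k, v in counts.items()},
        per_class_count_std={k: float(v.std(ddof=1)) if len(v) > 1 else 0.0
                             for k, v in counts.items()},
        max_pairwise_separation=float(max_d),
        threshold=threshold,
        color_leak=color_leak,
        count_leak=bool(max_d > threshold),
    )
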