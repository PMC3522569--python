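"""Synthetic lip-image and feature-table generators.

The image generator emulates the statistical structure the pipeline
assumes: an elliptical lip of a class-specific color (four color-separable
classes caricaturing Deep-red, Red, Purple and Pale lips) on a white
background whose saturation stays below the 0.1 gate, with Gaussian color
noise and a smooth within-lip texture field.  Default class counts mirror
the clinical imbalance (90 Deep-red, 12 Pale, 62 Purple, 93 Red; 257
total).

A second, faster generator emits labeled Gaussian feature tables with a
declared set of informative columns, so selection and classification can
be unit-tested independently of the imaging stack.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError

#: Class RGB presets on [0, 1]: caricatures of the four lip colors.
CLASS_COLOR_MEANS = {
    "Deep-red": (0.45, 0.05, 0.10),
    "Red": (0.80, 0.15, 0.20),
    "Purple": (0.45, 0.10, 0.45),
    "Pale": (0.92, 0.62, 0.62),
}

#: Clinical class counts the default fixture mirrors.
DEFAULT_N_PER_CLASS = {"Deep-red": 90, "Pale": 12, "Purple": 62, "Red": 93}


@dataclass(frozen=True)
class FixtureConfig:
    n_per_class: dict = field(default_factory=lambda: dict(DEFAULT_N_PER_CLASS))
    class_color_means: dict = field(default_factory=lambda: dict(CLASS_COLOR_MEANS))
    image_size: int = 64
    color_noise_sd: float = 0.02
    texture_amp: float = 0.05
    background_noise_sd: float = 0.01   # achromatic: keeps background saturation 0
    semi_major: tuple[float, float] = (16.0, 22.0)
    semi_minor: tuple[float, float] = (9.0, 14.0)
    max_rotation_deg: float = 25.0
    center_jitter: float = 4.0
    seed: int = 0

    def validate(self) -> None:
        s = self.image_size
        if self.semi_major[0] <= 1 or self.semi_minor[0] <= 1:
            raise ParameterError("ellipse axes must exceed one pixel")
        if self.semi_major[1] + self.center_jitter >= s / 2:
            raise ParameterError("ellipse cannot fit inside the image")
        means = list(self.class_color_means.values())
        if len({tuple(m) for m in means}) != len(means):
            raise ParameterError("class color means must be pairwise distinct")


def make_lip_image(
    cfg: FixtureConfig, cls: str, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, dict]:
    """One synthetic lip image, its ground-truth mask, and the geometry.

    Returns ``(image, mask, info)`` where ``info`` records the sampled
    ellipse parameters (center, semi-axes, rotation) so tests can check
    e.g. the analytic area pi*a*b.
    """
    cfg.validate()
    if cls not in cfg.class_color_means:
        raise ParameterError(f"unknown class {cls!r}")
    s = cfg.image_size
    a = rng.uniform(*cfg.semi_major)
    b = rng.uniform(*cfg.semi_minor)
    angle = np.radians(rng.uniform(-cfg.max_rotation_deg, cfg.max_rotation_deg))
    cy = s / 2 + rng.uniform(-cfg.center_jitter, cfg.center_jitter)
    cx = s / 2 + rng.uniform(-cfg.center_jitter, cfg.center_jitter)

    yy, xx = np.mgrid[0:s, 0:s]
    dx, dy = xx - cx, yy - cy
    u = dx * np.cos(angle) + dy * np.sin(angle)
    v = -dx * np.sin(angle) + dy * np.cos(angle)
    mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0

    img = np.ones((s, s, 3), dtype=np.float64)
    img += rng.normal(0.0, cfg.background_noise_sd, (s, s))[..., None]  # achromatic

    color = np.asarray(cfg.class_color_means[cls], dtype=np.float64)
    fy, fx = rng.uniform(1.0, 3.0, 2)
    phase = rng.uniform(0, 2 * np.pi)
    texture = 1.0 + cfg.texture_amp * np.sin(2 * np.pi * (fy * yy + fx * xx) / s + phase)
    lip = color[None, None, :] * texture[..., None]
    lip = lip + rng.normal(0.0, cfg.color_noise_sd, (s, s, 3))
    img[mask] = lip[mask]
    img = np.clip(img, 0.0, 1.0)
    info = {"center": (cy, cx), "axes": (a, b), "rotation": angle, "class": cls}
    return img, mask, info


def make_dataset(
    cfg: FixtureConfig | None = None,
) -> tuple[list[np.ndarray], list[np.ndarray], list[str]]:
    """The full labeled image set: sum(n_per_class) images with masks."""
    cfg = cfg or FixtureConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    images, masks, labels = [], [], []
    for cls in sorted(cfg.n_per_class):
        for _ in range(cfg.n_per_class[cls]):
            img, mask, _ = make_lip_image(cfg, cls, rng)
            images.append(img)
            masks.append(mask)
            labels.append(cls)
    return images, masks, labels


def make_feature_table(
    n_per_class: dict | None = None,
    n_features: int = 20,
    n_informative: int = 3,
    effect_size: float = 2.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, tuple[int, ...]]:
    """Labeled Gaussian feature table with declared informative columns.

    Noise columns are N(0, 1) for every class; each informative column
    carries class-dependent means drawn once at scale ``effect_size``
    (and re-drawn until no two classes collide within 0.8 * effect_size,
    so the declared columns are genuinely informative).  Returns
    ``(X, y, informative_idx)``; the informative columns are 0..k-1.
    """
    n_per_class = dict(n_per_class or DEFAULT_N_PER_CLASS)
    if n_informative > n_features:
        raise ParameterError("n_informative exceeds n_features")
    rng = np.random.default_rng(seed)
    classes = sorted(n_per_class)
    k = len(classes)
    means = np.zeros((k, n_informative))
    for j in range(n_informative):
        for _ in range(100):
            col = rng.normal(0.0, effect_size, k)
            gaps = np.abs(col[:, None] - col[None, :])[np.triu_indices(k, 1)]
            if k < 2 or gaps.min() >= 0.8 * effect_size:
                break
        means[:, j] = col

    rows, labels = [], []
    for i, cls in enumerate(classes):
        n = n_per_class[cls]
        block = rng.normal(0.0, 1.0, (n, n_features))
        block[:, :n_informative] += means[i]
        rows.append(block)
        labels.extend([cls] * n)
    X = np.vstack(rows)
    y = np.asarray(labels, dtype=object)
    return X, y, tuple(range(n_informative))
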