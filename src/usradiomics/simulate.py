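"""Synthetic study inputs: textured nodule images with red-curve
annotations and a clinical covariate table.

The generator emulates the structure of an ultrasound radiomics study of
papillary thyroid carcinoma: grayscale speckle backgrounds, an
elliptical nodule per patient whose *interior texture* (not its mean
brightness) carries the class signal, an annotated duplicate with the
lesion boundary drawn as a 2-px red curve, and a covariate table with
~81% mutation prevalence, ages ~ N(42, 14) truncated to [15, 82], tumor
sizes lognormal around 16 mm with an optional negative label-size
association, and a 387:140 training:validation split ratio.

The class signal is planted through the correlation length and contrast
of a smoothed multiplicative noise field, so per-ROI min-max
normalization cannot erase it: it must be recovered through second-order
(GLCM/GLRLM/wavelet) features, the mechanism a texture signature relies
on.  All randomness flows from a single seeded generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import draw, morphology

from .roi import AnnotatedPair, RoiMask

TRAIN_VAL_RATIO = (387, 140)  # training : validation


@dataclass
class SimConfig:
    """Study conditions for the synthetic generator.

    texture_effect: "null" (no class difference), "weak" or "strong" —
    controls how far apart the two classes' texture correlation lengths
    and contrasts are.
    """

    n_patients: int = 527
    prevalence: float = 0.812
    texture_effect: str = "null"
    image_size: Tuple[int, int] = (64, 64)
    roi_semiaxis_range: Tuple[float, float] = (8.0, 15.0)
    background_mean: float = 60.0
    background_sd: float = 18.0
    nodule_mean: float = 110.0
    speckle_sd: float = 0.35           # multiplicative log-field SD inside nodule
    # per-class (negative, positive) texture parameters by effect size
    corr_length: Dict[str, Tuple[float, float]] = field(default_factory=lambda: {
        "null": (2.0, 2.0), "weak": (1.7, 2.4), "strong": (1.2, 3.2)})
    contrast: Dict[str, Tuple[float, float]] = field(default_factory=lambda: {
        "null": (0.35, 0.35), "weak": (0.32, 0.40), "strong": (0.25, 0.50)})
    age_mean: float = 42.0
    age_sd: float = 14.0
    age_bounds: Tuple[float, float] = (15.0, 82.0)
    female_ratio: float = 0.768
    size_mean_mm: float = 16.4
    size_sd_mm: float = 7.9
    size_label_association: bool = True  # mutation-positive tumors run smaller
    size_shift_mm: Tuple[float, float] = (18.0, 16.0)  # class means when on
    levels: int = 256
    image_format: str = "png"            # "png" (lossless) or "jpeg" (quality 90)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")
        if self.texture_effect not in self.corr_length:
            raise ValueError(f"unknown texture_effect: {self.texture_effect!r}")
        if self.background_sd <= 0 or self.speckle_sd <= 0 or self.size_sd_mm <= 0:
            raise ValueError("dispersion parameters must be positive")
        lo, hi = self.roi_semiaxis_range
        if 2 * hi + 6 >= min(self.image_size):
            raise ValueError("ROI larger than image: shrink roi_semiaxis_range")


def _smooth_field(shape, corr_length: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian random field with the given correlation length."""
    raw = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(raw, sigma=corr_length, mode="reflect")
    sd = f.std()
    return f / sd if sd > 0 else f


def generate_image(class_label: int, cfg: SimConfig,
                   rng: np.random.Generator,
                   lesion_id: str = "") -> Tuple[AnnotatedPair, RoiMask]:
    """One synthetic annotated pair plus the ground-truth ROI mask.

    The original is background speckle with an elliptical nodule whose
    interior is a smoothed multiplicative noise field with
    class-dependent correlation length and contrast.  The annotated copy
    is the original replicated to RGB with the true boundary drawn as a
    2-px-wide red curve.
    """
    H, W = cfg.image_size
    cl = cfg.corr_length[cfg.texture_effect][int(class_label)]
    ct = cfg.contrast[cfg.texture_effect][int(class_label)]

    bg = cfg.background_mean + cfg.background_sd * _smooth_field((H, W), 1.0, rng)

    a = rng.uniform(*cfg.roi_semiaxis_range)
    b = rng.uniform(*cfg.roi_semiaxis_range)
    margin = max(a, b) + 3
    cy = rng.uniform(margin, H - margin)
    cx = rng.uniform(margin, W - margin)
    rr, cc = draw.ellipse(cy, cx, a, b, shape=(H, W))
    truth = np.zeros((H, W), dtype=bool)
    truth[rr, cc] = True

    field_ = _smooth_field((H, W), cl, rng)
    nodule = cfg.nodule_mean * np.exp(ct * cfg.speckle_sd * field_ * 3.0)
    img = bg.copy()
    img[truth] = nodule[truth]
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    # 2-px-wide boundary: mask minus its double erosion
    inner = ndimage.binary_erosion(truth, structure=morphology.disk(1), iterations=2)
    boundary = truth & ~inner

    ann = np.stack([img] * 3, axis=-1).astype(np.uint8)
    ann[boundary] = (230, 20, 20)

    pair = AnnotatedPair(original=img, annotated=ann, lesion_id=lesion_id)
    return pair, RoiMask(mask=truth)


def _truncated_normal(mean, sd, lo, hi, size, rng) -> np.ndarray:
    out = rng.normal(mean, sd, size=size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


@dataclass
class SimulatedCohort:
    """In-memory result of :func:`generate_cohort`."""

    cohort: pd.DataFrame
    pairs: List[AnnotatedPair]
    truth_masks: List[RoiMask]
    config: SimConfig


def generate_cohort(cfg: SimConfig, out_dir: Optional[Path] = None,
                    images: bool = True) -> SimulatedCohort:
    """Draw a full synthetic study: labels, covariates, images, split.

    Labels are Bernoulli(prevalence) (redrawn if a class comes up
    empty); the training/validation split follows the 387:140 ratio.
    With ``out_dir`` set, writes originals/, annotated/, masks/ PNGs (or
    JPEGs), cohort.csv and the config as YAML.
    """
    if cfg.n_patients < 20:
        raise ValueError("n_patients must be at least 20")
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients

    labels = rng.binomial(1, cfg.prevalence, size=n)
    while labels.sum() in (0, n):
        labels = rng.binomial(1, cfg.prevalence, size=n)

    ages = _truncated_normal(cfg.age_mean, cfg.age_sd, *cfg.age_bounds,
                             size=n, rng=rng)
    sex = np.where(rng.random(n) < cfg.female_ratio, "F", "M")

    sigma2 = math.log(1.0 + (cfg.size_sd_mm / cfg.size_mean_mm) ** 2)
    sigma = math.sqrt(sigma2)
    if cfg.size_label_association:
        means = np.where(labels == 1, cfg.size_shift_mm[1], cfg.size_shift_mm[0])
    else:
        means = np.full(n, cfg.size_mean_mm)
    mu = np.log(means) - sigma2 / 2.0
    sizes = np.round(np.exp(rng.normal(mu, sigma)), 1)

    n_train = int(round(n * TRAIN_VAL_RATIO[0] / sum(TRAIN_VAL_RATIO)))
    split = np.array(["training"] * n_train + ["validation"] * (n - n_train))

    cohort = pd.DataFrame({
        "id": [f"les{k:04d}" for k in range(n)],
        "age": np.round(ages, 1),
        "age_class": np.where(ages >= 55, ">=55", "<55"),
        "sex": sex,
        "size_mm": sizes,
        "size_class": np.where(sizes < 20, "<20mm", ">=20mm"),
        "subtype": "cPTC",
        "cohort_split": split,
        "braf_label": labels.astype(int),
    })

    pairs: List[AnnotatedPair] = []
    masks: List[RoiMask] = []
    if images:
        for k in range(n):
            pair, truth = generate_image(int(labels[k]), cfg, rng,
                                         lesion_id=cohort["id"].iloc[k])
            pairs.append(pair)
            masks.append(truth)

    sim = SimulatedCohort(cohort=cohort, pairs=pairs, truth_masks=masks, config=cfg)
    if out_dir is not None:
        _write_cohort(sim, Path(out_dir))
    return sim


def _write_cohort(sim: SimulatedCohort, out_dir: Path) -> None:
    import yaml
    from PIL import Image

    fmt = sim.config.image_format.lower()
    ext = "jpg" if fmt in ("jpg", "jpeg") else "png"
    for sub in ("originals", "annotated", "masks"):
        (out_dir / sub).mkdir(parents=True, exist_ok=True)
    for pair, mask in zip(sim.pairs, sim.truth_masks):
        kw = {"quality": 90} if ext == "jpg" else {}
        Image.fromarray(pair.original).save(
            out_dir / "originals" / f"{pair.lesion_id}.{ext}", **kw)
        Image.fromarray(pair.annotated).save(
            out_dir / "annotated" / f"{pair.lesion_id}.{ext}", **kw)
        Image.fromarray((mask.mask * np.uint8(255))).save(
            out_dir / "masks" / f"{pair.lesion_id}.png")
    sim.cohort.to_csv(out_dir / "cohort.csv", index=False)
    with open(out_dir / "sim_config.yaml", "w") as fh:
        yaml.safe_dump(asdict(sim.config), fh)
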