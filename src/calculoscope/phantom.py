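"""Synthetic histology phantoms and labeled feature tables.

No public image set exists for prostatic-calculus histology, so this
module emulates the appearance the pipeline targets: a heavily textured
fibromuscular stroma, bright near-homogeneous elliptical gland lumina,
and round calculus bodies with a concentric "tree-ring" lamellar texture
placed inside some lumina.  Every phantom carries exact ground-truth
masks so segmentation and region extraction can be scored, and a separate
generator produces labeled Gaussian feature tables for exercising the
PCA-SVM stage in isolation.

Intensity model (8-bit per channel): stroma ~ 120 with strong Gaussian
texture noise, lumina ~ 230 with faint noise, calculus lamellae
oscillating 160 +/- 30.  The stroma/lumen homogeneity contrast is what the
local-entropy transform keys on; the lamellar oscillation is what the
co-occurrence texture features key on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import ellipse as _draw_ellipse

__all__ = [
    "PhantomConfig",
    "PhantomTruth",
    "generate_concentric_texture",
    "generate_phantom",
    "generate_feature_dataset",
]

STROMA_LEVEL = 120.0
LUMEN_LEVEL = 230.0
LUMEN_NOISE_SD = 2.0
CALCULUS_BASE = 160.0
CALCULUS_AMPLITUDE = 30.0
CALCULUS_NOISE_SD = 2.0
#: channel gains giving the gray phantom an H&E-like pink cast
TINT = (1.0, 0.82, 0.90)

_PLACEMENT_RETRIES = 200


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and noise parameters of one phantom image.

    ``seed`` fully determines the output; ``n_calculi`` lumina (chosen at
    random) each receive one concentric-ring calculus at their center.
    """

    image_height: int = 384
    image_width: int = 384
    n_lumina: int = 5
    n_calculi: int = 3
    lumen_axis_range: tuple[int, int] = (28, 48)
    calculus_radius_range: tuple[int, int] = (9, 16)
    n_rings: int = 4
    stroma_noise_sd: float = 35.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height < 1 or self.image_width < 1:
            raise ValueError("image dimensions must be positive")
        if self.n_lumina < 0 or self.n_calculi < 0:
            raise ValueError("counts must be non-negative")
        if self.n_calculi > self.n_lumina:
            raise ValueError(
                f"n_calculi ({self.n_calculi}) exceeds n_lumina ({self.n_lumina})"
            )
        lo, hi = self.lumen_axis_range
        clo, chi = self.calculus_radius_range
        if lo < 1 or hi < lo or clo < 1 or chi < clo:
            raise ValueError("geometric ranges must be positive and ordered")
        if self.stroma_noise_sd < 0:
            raise ValueError("stroma_noise_sd must be >= 0")
        if self.n_lumina > 0 and 2 * hi + 2 >= min(self.image_height, self.image_width):
            raise ValueError("largest lumen cannot fit inside the image")


@dataclass
class PhantomTruth:
    """A phantom image together with its ground truth.

    ``calculus_mask`` is a subset of ``lumen_mask`` by construction
    (calculi sit inside lumina); all masks share the image's height/width.
    """

    image: np.ndarray  # (H, W, 3) uint8
    lumen_mask: np.ndarray  # (H, W) bool
    calculus_mask: np.ndarray  # (H, W) bool
    calculus_centers: list[tuple[int, int]] = field(default_factory=list)


def generate_concentric_texture(
    radius: int,
    n_rings: int,
    base_level: float = CALCULUS_BASE,
    amplitude: float = CALCULUS_AMPLITUDE,
) -> np.ndarray:
    """Square patch with a concentric-ring (tree-ring) intensity profile.

    Inside the inscribed disk of the (2*radius+1)-sided patch the
    intensity is ``base + amplitude*cos(2*pi*n_rings*r/radius)`` — n_rings
    full oscillation periods from center to rim, phase 0 (peak) at the
    center.  Outside the disk the patch is constant at ``base_level``.
    """
    if radius < 1:
        raise ValueError(f"radius must be >= 1, got {radius}")
    if n_rings < 1 or n_rings > radius:
        raise ValueError(
            f"need radius >= n_rings >= 1, got radius={radius}, n_rings={n_rings}"
        )
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    side = 2 * radius + 1
    rr, cc = np.mgrid[0:side, 0:side]
    r = np.hypot(rr - radius, cc - radius)
    patch = np.full((side, side), float(base_level))
    inside = r <= radius
    patch[inside] += amplitude * np.cos(2.0 * np.pi * n_rings * r[inside] / radius)
    return patch


def _place_ellipses(cfg: PhantomConfig, rng: np.random.Generator):
    """Rejection-sample non-overlapping lumen ellipses with a border margin."""
    h, w = cfg.image_height, cfg.image_width
    lo, hi = cfg.lumen_axis_range
    occupied = np.zeros((h, w), dtype=bool)
    lumina = []
    tries = 0
    budget = _PLACEMENT_RETRIES * max(cfg.n_lumina, 1)
    while len(lumina) < cfg.n_lumina:
        if tries >= budget:
            raise RuntimeError(
                f"could not place {cfg.n_lumina} non-overlapping lumina in "
                f"{budget} attempts; enlarge the image or shrink the lumina"
            )
        tries += 1
        a = rng.integers(lo, hi + 1)
        b = rng.integers(lo, hi + 1)
        theta = rng.uniform(0.0, np.pi)
        margin = int(max(a, b)) + 2
        if h - margin <= margin or w - margin <= margin:
            raise ValueError("lumina too large for the image")
        r0 = int(rng.integers(margin, h - margin))
        c0 = int(rng.integers(margin, w - margin))
        rr, cc = _draw_ellipse(r0, c0, a, b, shape=(h, w), rotation=theta)
        mask = np.zeros((h, w), dtype=bool)
        mask[rr, cc] = True
        # 2-px moat keeps adjacent lumina from fusing after windowed entropy
        grown = np.zeros((h, w), dtype=bool)
        rr2, cc2 = _draw_ellipse(r0, c0, a + 4, b + 4, shape=(h, w), rotation=theta)
        grown[rr2, cc2] = True
        if np.any(occupied & grown):
            continue
        occupied |= grown
        lumina.append({"center": (r0, c0), "axes": (int(a), int(b)), "mask": mask})
    return lumina


def generate_phantom(config: PhantomConfig) -> PhantomTruth:
    """Render one phantom image plus ground-truth masks.

    Identical ``config`` (including seed) yields bit-identical output.
    Calculi are placed at the centers of ``n_calculi`` randomly chosen
    lumina, with radius capped so the body stays strictly interior to its
    lumen.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.image_height, config.image_width

    gray = STROMA_LEVEL + rng.normal(0.0, config.stroma_noise_sd, size=(h, w))
    lumen_mask = np.zeros((h, w), dtype=bool)
    calculus_mask = np.zeros((h, w), dtype=bool)
    centers: list[tuple[int, int]] = []

    lumina = _place_ellipses(config, rng)
    for lum in lumina:
        m = lum["mask"]
        lumen_mask |= m
        gray[m] = LUMEN_LEVEL + rng.normal(0.0, LUMEN_NOISE_SD, size=int(m.sum()))

    if config.n_calculi > 0:
        chosen = rng.choice(len(lumina), size=config.n_calculi, replace=False)
        clo, chi = config.calculus_radius_range
        for li in chosen:
            lum = lumina[int(li)]
            r0, c0 = lum["center"]
            max_fit = int(0.6 * min(lum["axes"]))  # strictly interior to the lumen
            radius = min(chi, max_fit)
            if radius < clo:
                raise ValueError(
                    "calculus_radius_range cannot fit inside the sampled lumen"
                )
            patch = generate_concentric_texture(radius, config.n_rings)
            side = 2 * radius + 1
            rr, cc = np.mgrid[0:side, 0:side]
            disk = np.hypot(rr - radius, cc - radius) <= radius
            rows = slice(r0 - radius, r0 + radius + 1)
            cols = slice(c0 - radius, c0 + radius + 1)
            noise = rng.normal(0.0, CALCULUS_NOISE_SD, size=patch.shape)
            target = gray[rows, cols]
            target[disk] = patch[disk] + noise[disk]
            calculus_mask[rows, cols] |= disk
            centers.append((r0, c0))

    calculus_mask &= lumen_mask  # guaranteed by construction; enforce anyway
    gray8 = np.clip(gray, 0.0, 255.0)
    image = np.clip(
        np.stack([gray8 * g for g in TINT], axis=-1), 0.0, 255.0
    ).astype(np.uint8)
    return PhantomTruth(
        image=image,
        lumen_mask=lumen_mask,
        calculus_mask=calculus_mask,
        calculus_centers=centers,
    )


def generate_feature_dataset(
    n_pos: int,
    n_neg: int,
    n_features: int = 70,
    separation: float = 6.0,
    seed: int = 0,
    n_informative: int = 5,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Two-class Gaussian feature table with correlated nuisance features.

    Both classes have unit within-class variance per feature.  The first
    ``n_informative`` features carry a mean shift of
    ``separation / sqrt(n_informative)`` for the positive class, so
    ``separation`` is the overall between-class Mahalanobis distance.
    The remaining features are class-independent linear mixes of a few
    shared latent factors (plus noise), giving PCA genuinely correlated
    structure to compress.

    Returns ``(features, labels)``: a DataFrame with columns
    ``f00..f{n-1}`` (positives first) and an int array of {0,1} labels
    with exactly ``n_pos`` ones and ``n_neg`` zeros.
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("need at least one sample per class")
    if n_features < 1:
        raise ValueError(f"n_features must be >= 1, got {n_features}")
    if separation < 0:
        raise ValueError("separation must be >= 0")
    rng = np.random.default_rng(seed)
    n = n_pos + n_neg
    k_inf = min(n_informative, n_features)
    shift = separation / np.sqrt(k_inf)

    X = np.empty((n, n_features))
    X[:, :k_inf] = rng.normal(size=(n, k_inf))
    X[:n_pos, :k_inf] += shift

    n_nuis = n_features - k_inf
    if n_nuis > 0:
        n_lat = max(3, n_nuis // 10)
        z = rng.normal(size=(n, n_lat))
        # two distinct latent factors + private noise per nuisance feature,
        # scaled to unit variance
        picks = np.array(
            [rng.choice(n_lat, size=2, replace=False) for _ in range(n_nuis)]
        )
        e = rng.normal(size=(n, n_nuis))
        X[:, k_inf:] = (z[:, picks[:, 0]] + z[:, picks[:, 1]] + e) / np.sqrt(3.0)

    labels = np.concatenate([np.ones(n_pos, dtype=int), np.zeros(n_neg, dtype=int)])
    cols = [f"f{i:02d}" for i in range(n_features)]
    return pd.DataFrame(X, columns=cols), labels
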