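"""Morphological mask refinement and suspicious-region extraction.

After entropy thresholding the lumen mask is cleaned with the classic
binary operators — opening, closing, regional hole filling — and small
components are discarded.  Hole filling matters scientifically: a calculus
inside a lumen is *textured*, so the entropy transform excludes it from
the homogeneous-lumen mask, leaving a hole that regional filling restores.
A second Otsu pass on the gray values restricted to lumen pixels then
separates the (darker, lamellar) calculus candidates from the bright
lumen interior, and each connected candidate becomes a cropped
:class:`Region` handed to texture-feature extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage import measure, morphology as skmorph
from skimage.color import rgb2gray

from .entropy import binarize, channel_entropy_compose, otsu_threshold
from .exceptions import DegenerateInputError

__all__ = [
    "MorphConfig",
    "LabeledRegions",
    "Region",
    "refine_mask",
    "label_regions",
    "extract_lumina",
    "segment_suspicious_regions",
]


@dataclass(frozen=True)
class MorphConfig:
    """Structuring element and filtering knobs for mask refinement."""

    selem_shape: str = "disk"  # "disk" or "square"
    selem_radius: int = 3
    min_area: int = 30  # px^2; components below this are dropped
    fill_holes: bool = True
    exclude_border: bool = True

    def __post_init__(self) -> None:
        if self.selem_shape not in ("disk", "square"):
            raise ValueError(f"selem_shape must be disk|square, got {self.selem_shape!r}")
        if self.selem_radius < 1:
            raise ValueError("selem_radius must be >= 1")
        if self.min_area < 0:
            raise ValueError("min_area must be >= 0")

    def footprint(self) -> np.ndarray:
        if self.selem_shape == "disk":
            return skmorph.disk(self.selem_radius)
        return skmorph.footprint_rectangle(
            (2 * self.selem_radius + 1, 2 * self.selem_radius + 1)
        )


@dataclass
class RegionInfo:
    label: int
    area: int
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col)
    centroid: tuple[float, float]
    touches_border: bool


@dataclass
class LabeledRegions:
    """Connected-component inventory of a binary mask."""

    label_image: np.ndarray  # int array, 0 = background
    n_regions: int
    regions: list[RegionInfo] = field(default_factory=list)


@dataclass
class Region:
    """A cropped candidate region: gray patch + its mask, same shape."""

    patch: np.ndarray
    mask: np.ndarray
    source_label: int
    bbox: tuple[int, int, int, int]
    source_image_id: str | None = None


def refine_mask(mask: np.ndarray, config: MorphConfig = MorphConfig()) -> np.ndarray:
    """Open -> close -> regional hole filling -> small-object removal."""
    m = np.asarray(mask, dtype=bool)
    if m.ndim != 2:
        raise ValueError("mask must be 2-D")
    if not m.any():
        return m.copy()
    fp = config.footprint()
    out = skmorph.opening(m, fp)
    out = skmorph.closing(out, fp)
    if config.fill_holes:
        out = ndimage.binary_fill_holes(out)
    if config.min_area > 0:
        out = _drop_small(out, config.min_area)
    return out


def _drop_small(mask: np.ndarray, min_area: int) -> np.ndarray:
    """Remove connected components (8-conn) with area < min_area."""
    lab, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return mask
    areas = np.bincount(lab.ravel())
    keep = areas >= min_area
    keep[0] = False
    return keep[lab]


def label_regions(mask: np.ndarray, connectivity: int = 8) -> LabeledRegions:
    """Connected-component labeling with deterministic raster-scan order."""
    if connectivity not in (4, 8):
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    m = np.asarray(mask, dtype=bool)
    lab = measure.label(m, connectivity=1 if connectivity == 4 else 2)
    h, w = m.shape
    infos: list[RegionInfo] = []
    for rp in measure.regionprops(lab):
        minr, minc, maxr, maxc = rp.bbox
        infos.append(
            RegionInfo(
                label=int(rp.label),
                area=int(rp.area),
                bbox=(int(minr), int(minc), int(maxr), int(maxc)),
                centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
                touches_border=bool(
                    minr == 0 or minc == 0 or maxr == h or maxc == w
                ),
            )
        )
    return LabeledRegions(label_image=lab, n_regions=int(lab.max()), regions=infos)


def to_gray(image: np.ndarray) -> np.ndarray:
    """Luminance of an RGB image on the 0-255 scale (2-D input passes through)."""
    img = np.asarray(image)
    if img.ndim == 2:
        return img.astype(np.float64)
    if img.ndim == 3 and img.shape[2] == 3:
        return rgb2gray(img) * 255.0
    raise ValueError(f"expected (H,W) or (H,W,3) image, got {img.shape}")


def extract_lumina(
    image: np.ndarray,
    window: int = 9,
    compose_mode: str = "mean",
    morph: MorphConfig = MorphConfig(),
    lumen_polarity: str = "above",
    n_bins: int = 256,
    max_cv: "float | None" = 0.1,
) -> tuple[np.ndarray, LabeledRegions]:
    """Full lumen-extraction pipeline on one RGB image.

    channel entropy -> Otsu -> binarize -> morphological refinement ->
    homogeneity verification -> labeling.  ``lumen_polarity`` selects
    which side of the entropy threshold holds the lumina; homogeneous
    regions sit at the top of the normalized-gray-value entropy scale,
    hence the "above" default.

    Otsu always returns *some* cut, so on an image with no homogeneous
    region it merely splits the stroma texture noise; the verification
    step rejects such spurious components by requiring the *robust* gray
    coefficient of variation (1.4826 * MAD / median) over each
    component's pre-filling support to stay below ``max_cv`` — lumina
    are homogeneous almost by definition, textured tissue is not.  The
    median/MAD form keeps the check insensitive to a minority of darker
    calculus or boundary pixels inside a genuine lumen.  Set
    ``max_cv=None`` to disable.
    """
    ent = channel_entropy_compose(image, window=window, mode=compose_mode)
    res = otsu_threshold(ent, n_bins=n_bins)
    raw = binarize(ent, res, polarity=lumen_polarity)
    refined = refine_mask(raw, morph)
    if max_cv is not None and refined.any():
        gray = to_gray(image)
        lab, n = ndimage.label(refined, structure=np.ones((3, 3), dtype=int))
        keep = np.zeros(n + 1, dtype=bool)
        for lbl in range(1, n + 1):
            support = (lab == lbl) & raw  # exclude filled holes (e.g. calculi)
            if not support.any():
                continue
            vals = gray[support]
            med = float(np.median(vals))
            mad = float(np.median(np.abs(vals - med)))
            if med > 0 and 1.4826 * mad / med <= max_cv:
                keep[lbl] = True
        refined = keep[lab]
    return refined, label_regions(refined)


def segment_suspicious_regions(
    image: np.ndarray,
    lumen_mask: np.ndarray,
    morph: MorphConfig = MorphConfig(),
    polarity: str = "below",
    n_bins: int = 256,
    source_image_id: str | None = None,
) -> list[Region]:
    """Segment calculus candidates inside the lumina of a gray image.

    Otsu is applied to the gray values restricted to lumen pixels; the
    ``polarity`` side (default "below": calculi are darker than the bright
    lumen interior) is refined morphologically, labeled, optionally
    stripped of border-touching components, and returned as cropped
    regions.  Region masks always stay inside ``lumen_mask``.
    """
    gray = to_gray(image)
    lum = np.asarray(lumen_mask, dtype=bool)
    if gray.shape != lum.shape:
        raise ValueError("image and lumen mask shapes differ")
    if not lum.any():
        return []
    vals = gray[lum]
    if np.ptp(vals) == 0:
        return []
    try:
        res = otsu_threshold(vals, n_bins=n_bins)
    except DegenerateInputError:
        return []
    cand = binarize(gray, res, polarity=polarity) & lum
    cand = refine_mask(cand, replace(morph, fill_holes=True))
    cand &= lum  # closing/filling must never leak outside the lumina
    if morph.min_area > 0:
        cand = _drop_small(cand, morph.min_area)  # re-filter after clipping
    labeled = label_regions(cand)
    regions: list[Region] = []
    for info in labeled.regions:
        if morph.exclude_border and info.touches_border:
            continue
        r0, c0, r1, c1 = info.bbox
        sub = labeled.label_image[r0:r1, c0:c1] == info.label
        regions.append(
            Region(
                patch=gray[r0:r1, c0:c1].copy(),
                mask=sub,
                source_label=info.label,
                bbox=info.bbox,
                source_image_id=source_image_id,
            )
        )
    return regions
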