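"""Gray-level co-occurrence matrices and the 14 Haralick-style statistics.

Each suspicious region is described by co-occurrence matrices
p(i, j | theta, d) accumulated over ordered pixel pairs at distance d = 1
in the four principal directions (0, 45, 90, 135 degrees), plus the mean
of the four count matrices as a fifth "direction".  Both pixels of a pair
must lie inside the region mask, so background never contaminates the
texture.  After normalization, 14 scalar statistics are computed per
matrix, giving the 70-dimensional descriptor (14 statistics x 5
directions) used by the classifier.

Offsets follow the image convention (row, col), row increasing downward:

    0 deg   -> ( 0, +d)    45 deg  -> (-d, +d)
    90 deg  -> (-d,  0)    135 deg -> (-d, -d)

Matrices are ordered (non-symmetric) as literally defined; pass
``symmetric=True`` to also count each pair in the reverse order.
"""

from __future__ import annotations

import numpy as np

from .exceptions import ContractViolationError, DegenerateInputError
from .morphology import Region

__all__ = [
    "DIRECTIONS",
    "OFFSETS",
    "FEATURE_NAMES",
    "feature_names",
    "quantize_gray",
    "glcm",
    "mean_glcm",
    "normalize_glcm",
    "haralick_features",
    "region_feature_vector",
]

DIRECTIONS = (0, 45, 90, 135)
OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

#: the 14 statistics, in the order they enter the feature vector
FEATURE_NAMES = (
    "energy",
    "contrast",
    "correlation",
    "entropy",
    "variance",
    "sum_average",
    "sum_variance",
    "homogeneity",
    "difference_variance",
    "sum_entropy",
    "difference_entropy",
    "cluster_shade",
    "cluster_prominence",
    "max_probability",
)

_DIRECTION_TAGS = ("0", "45", "90", "135", "mean")


def feature_names() -> list[str]:
    """The 70 column names, grouped by direction: ``<statistic>_<direction>``."""
    return [f"{f}_{d}" for d in _DIRECTION_TAGS for f in FEATURE_NAMES]


def quantize_gray(patch: np.ndarray, levels: int = 16, mask: np.ndarray | None = None) -> np.ndarray:
    """Uniformly quantize a gray patch to integer levels 0..levels-1.

    The quantization range is the min/max of the patch (or of the masked
    pixels when ``mask`` is given; values outside that range clip to the
    extreme bins).  A constant patch maps to all zeros.
    """
    if levels < 2:
        raise ValueError(f"levels must be >= 2, got {levels}")
    p = np.asarray(patch, dtype=np.float64)
    ref = p[np.asarray(mask, dtype=bool)] if mask is not None else p
    if ref.size == 0:
        raise DegenerateInputError("mask selects no pixels to quantize")
    vmin, vmax = float(ref.min()), float(ref.max())
    if vmax == vmin:
        return np.zeros(p.shape, dtype=np.intp)
    q = np.floor((p - vmin) / (vmax - vmin) * levels).astype(np.intp)
    return np.clip(q, 0, levels - 1)


def glcm(
    patch: np.ndarray,
    theta: int,
    d: int = 1,
    levels: int | None = None,
    mask: np.ndarray | None = None,
    symmetric: bool = False,
) -> np.ndarray:
    """Co-occurrence count matrix for one direction.

    ``patch`` must already be quantized to small non-negative integers.
    A pair (reference pixel, pixel at the directional offset) counts only
    if both pixels fall inside ``mask`` (full mask when omitted).

    Returns an L x L float array of raw counts.

    Raises
    ------
    DegenerateInputError
        If no valid pair exists (patch or mask too small).
    """
    q = np.asarray(patch)
    if q.ndim != 2:
        raise ValueError("patch must be 2-D")
    if not np.issubdtype(q.dtype, np.integer):
        raise ValueError("patch must be an integer (quantized) image")
    if theta not in OFFSETS:
        raise ValueError(f"theta must be one of {DIRECTIONS}, got {theta}")
    if d < 1:
        raise ValueError(f"d must be >= 1, got {d}")
    if q.size and q.min() < 0:
        raise ValueError("quantized levels must be non-negative")
    L = int(levels) if levels is not None else int(q.max()) + 1 if q.size else 1
    if q.size and q.max() >= L:
        raise ValueError(f"patch has level {q.max()} >= levels {L}")
    m = np.ones(q.shape, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    if m.shape != q.shape:
        raise ValueError("mask and patch shapes differ")

    dr, dc = OFFSETS[theta]
    dr, dc = dr * d, dc * d
    h, w = q.shape
    # slices of the reference pixel such that (r+dr, c+dc) stays in bounds
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    if r0 >= r1 or c0 >= c1:
        raise DegenerateInputError("patch too small for this offset")
    a = q[r0:r1, c0:c1]
    b = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    valid = m[r0:r1, c0:c1] & m[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    if not valid.any():
        raise DegenerateInputError("no co-occurring pixel pair lies inside the mask")
    counts = np.zeros((L, L), dtype=np.float64)
    np.add.at(counts, (a[valid], b[valid]), 1.0)
    if symmetric:
        counts = counts + counts.T
    return counts


def mean_glcm(four: "list[np.ndarray]") -> np.ndarray:
    """Element-wise mean of the four directional count matrices."""
    if len(four) != 4:
        raise ValueError(f"expected exactly 4 matrices, got {len(four)}")
    shapes = {m.shape for m in map(np.asarray, four)}
    if len(shapes) != 1:
        raise ValueError(f"matrices have mismatched shapes: {shapes}")
    return np.mean([np.asarray(m, dtype=np.float64) for m in four], axis=0)


def normalize_glcm(m: np.ndarray) -> np.ndarray:
    """Scale a count matrix to probabilities summing to 1."""
    a = np.asarray(m, dtype=np.float64)
    total = a.sum()
    if total <= 0:
        raise DegenerateInputError("cannot normalize an all-zero matrix")
    return a / total


def _entropy_bits(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-np.sum(nz * np.log2(nz)))


def haralick_features(p: np.ndarray) -> dict[str, float]:
    """The 14 texture statistics of one normalized co-occurrence matrix.

    Definitions (p the L x L probability matrix, i row index, j column
    index, p_x / p_y the marginals, p_{x+y} / p_{x-y} the distributions of
    i+j and |i-j|, logs base 2):

    - energy              sum p^2
    - contrast            sum (i-j)^2 p
    - correlation         (sum ij p - mu_x mu_y) / (sigma_x sigma_y); 0 when
                          either sigma vanishes
    - entropy             -sum p log p
    - variance            sum [((i-mu)^2 + (j-mu)^2)/2] p, mu = (mu_x+mu_y)/2
                          (symmetric in the two indices, so invariant under
                          matrix transposition)
    - sum_average         sum k p_{x+y}(k)
    - sum_variance        sum (k - sum_average)^2 p_{x+y}(k)
    - homogeneity         sum p / (1 + (i-j)^2)
    - difference_variance variance of p_{x-y}
    - sum_entropy         -sum p_{x+y} log p_{x+y}
    - difference_entropy  -sum p_{x-y} log p_{x-y}
    - cluster_shade       sum (i+j-mu_x-mu_y)^3 p
    - cluster_prominence  sum (i+j-mu_x-mu_y)^4 p
    - max_probability     max p
    """
    p = np.asarray(p, dtype=np.float64)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise ValueError("p must be a square matrix")
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-8:
        raise ContractViolationError("p must be a normalized probability matrix")
    L = p.shape[0]
    i = np.arange(L)[:, None]
    j = np.arange(L)[None, :]
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float(np.sum(np.arange(L) * px))
    mu_y = float(np.sum(np.arange(L) * py))
    sigma_x = float(np.sqrt(np.sum((np.arange(L) - mu_x) ** 2 * px)))
    sigma_y = float(np.sqrt(np.sum((np.arange(L) - mu_y) ** 2 * py)))

    p_sum = np.bincount((i + j).ravel(), weights=p.ravel(), minlength=2 * L - 1)
    p_diff = np.bincount(np.abs(i - j).ravel(), weights=p.ravel(), minlength=L)
    k_sum = np.arange(p_sum.size)
    k_diff = np.arange(p_diff.size)

    if sigma_x > 0 and sigma_y > 0:
        correlation = float(
            (np.sum(i * j * p) - mu_x * mu_y) / (sigma_x * sigma_y)
        )
    else:
        correlation = 0.0
    mu = 0.5 * (mu_x + mu_y)
    sum_average = float(np.sum(k_sum * p_sum))
    diff_mean = float(np.sum(k_diff * p_diff))

    return {
        "energy": float(np.sum(p**2)),
        "contrast": float(np.sum((i - j) ** 2 * p)),
        "correlation": correlation,
        "entropy": _entropy_bits(p),
        "variance": float(np.sum(0.5 * ((i - mu) ** 2 + (j - mu) ** 2) * p)),
        "sum_average": sum_average,
        "sum_variance": float(np.sum((k_sum - sum_average) ** 2 * p_sum)),
        "homogeneity": float(np.sum(p / (1.0 + (i - j) ** 2))),
        "difference_variance": float(np.sum((k_diff - diff_mean) ** 2 * p_diff)),
        "sum_entropy": _entropy_bits(p_sum),
        "difference_entropy": _entropy_bits(p_diff),
        "cluster_shade": float(np.sum((i + j - mu_x - mu_y) ** 3 * p)),
        "cluster_prominence": float(np.sum((i + j - mu_x - mu_y) ** 4 * p)),
        "max_probability": float(p.max()),
    }


def region_feature_vector(
    region: "Region | np.ndarray",
    mask: np.ndarray | None = None,
    levels: int = 16,
    d: int = 1,
    symmetric: bool = False,
) -> np.ndarray:
    """The 70-feature texture descriptor of one region.

    quantize -> 4 directional co-occurrence matrices (mask-restricted)
    -> mean matrix as fifth direction -> normalize each -> 14 statistics
    each.  Order: all 14 statistics for 0, then 45, 90, 135, then mean
    (see :func:`feature_names`).

    Accepts either a :class:`~calculoscope.morphology.Region` or a raw
    gray patch plus optional mask.  With ``symmetric=True`` every pair is
    also counted in reverse order, which makes the full vector exactly
    equivariant under 90-degree rotations (the ordered default is exactly
    equivariant in the four directional blocks, while four nonlinear
    statistics of the mean matrix shift marginally).
    """
    if isinstance(region, Region):
        patch, m = region.patch, region.mask
    else:
        patch = np.asarray(region)
        m = mask
    q = quantize_gray(patch, levels=levels, mask=m)
    mats = [
        glcm(q, theta, d=d, levels=levels, mask=m, symmetric=symmetric)
        for theta in DIRECTIONS
    ]
    mats.append(mean_glcm(mats))
    out = np.empty(14 * 5)
    for k, mat in enumerate(mats):
        feats = haralick_features(normalize_glcm(mat))
        out[14 * k : 14 * (k + 1)] = [feats[name] for name in FEATURE_NAMES]
    return out
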