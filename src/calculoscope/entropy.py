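"""Local-entropy transform, Otsu threshold selection and binarization.

The first stage of the recognition pipeline turns a color histology image
into a lumen-candidate binary mask.  The key observation is textural:
prostatic gland lumina are near-homogeneous while the fibromuscular stroma
(nuclei, connective-tissue fibres) fluctuates strongly, so a sliding-window
entropy of the *normalized gray values*,

    H = -sum_ij p_ij log2 p_ij,   p_ij = f(i,j) / sum_ij f(i,j),

computed over each w x w window separates the two tissue classes.  Note
that this is NOT the entropy of the gray-level histogram: for a constant
window the normalized gray values are a uniform distribution over the
w^2 pixels, so H attains its maximum log2(w^2) exactly, and textured
windows fall below that ceiling.  Homogeneous lumina are therefore the
*high*-entropy side of the transform.

Otsu's method then picks the cut through the entropy image that maximizes
the between-class variance g = w0*(mu0-mu)^2 + w1*(mu1-mu)^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .exceptions import ContractViolationError, DegenerateInputError

__all__ = [
    "OtsuResult",
    "gray_value_entropy",
    "local_entropy",
    "channel_entropy_compose",
    "otsu_threshold",
    "binarize",
]

_COMPOSE_MODES = ("mean", "min", "max")


def gray_value_entropy(values: np.ndarray) -> float:
    """Entropy (bits) of gray values normalized to a probability distribution.

    ``values`` is any array of strictly positive intensities; it is
    flattened, normalized to sum to one, and -sum(p*log2(p)) is returned.
    This is the per-window quantity that :func:`local_entropy` computes at
    every pixel.

    >>> round(gray_value_entropy(np.array([3.0, 1.0])), 4)
    0.8113
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    if v.size == 0:
        raise ContractViolationError("entropy of an empty window is undefined")
    if not np.all(np.isfinite(v)) or np.any(v <= 0):
        raise ContractViolationError("gray values must be finite and > 0")
    p = v / v.sum()
    return float(-np.sum(p * np.log2(p)))


def local_entropy(
    image: np.ndarray, window: int = 9, offset: float = 1.0
) -> np.ndarray:
    """Sliding-window gray-value entropy of a 2-D image.

    Parameters
    ----------
    image : 2-D array
        Gray intensities.  ``offset`` (default +1) is added to every pixel
        first so that 8-bit images containing zeros satisfy the positivity
        requirement of the normalized-gray-value entropy.
    window : odd int >= 3
        Side length w of the square neighborhood.  Borders are handled by
        reflection padding.

    Returns
    -------
    2-D float array, same shape as ``image``, every value in
    ``[0, log2(window**2)]``; constant neighborhoods attain the upper
    bound exactly.

    Notes
    -----
    Writing S for the window sum of f and using
    ``H = log2(S) - (1/S) * sum f*log2(f)``, the transform reduces to two
    box filters, which keeps it O(M*N) irrespective of window size.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D gray image, got shape {img.shape}")
    if window % 2 == 0 or window < 3:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    if window > min(img.shape):
        raise ValueError(
            f"window {window} exceeds image extent {min(img.shape)}"
        )
    f = img + offset
    if not np.all(np.isfinite(f)) or np.any(f <= 0):
        raise ContractViolationError(
            "all gray values must be finite and > 0 after offset"
        )
    # Box sums via uniform_filter (reflect padding), rescaled by w^2.
    area = float(window * window)
    s = ndimage.uniform_filter(f, size=window, mode="reflect") * area
    t = ndimage.uniform_filter(f * np.log2(f), size=window, mode="reflect") * area
    h = np.log2(s) - t / s
    # Float round-off can nudge values a hair outside the theoretical range.
    return np.clip(h, 0.0, np.log2(area))


def channel_entropy_compose(
    image: np.ndarray,
    window: int = 9,
    mode: str = "mean",
    offset: float = 1.0,
) -> np.ndarray:
    """Per-channel local entropy of an RGB image, composed pixel-wise.

    Each of the three channels is treated as a gray image and transformed
    with :func:`local_entropy`; the three entropy maps are then combined by
    ``mode`` ("mean", "min" or "max"; default mean).
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) color image, got {img.shape}")
    if mode not in _COMPOSE_MODES:
        raise ValueError(f"mode must be one of {_COMPOSE_MODES}, got {mode!r}")
    maps = np.stack(
        [local_entropy(img[:, :, c], window=window, offset=offset) for c in range(3)]
    )
    if mode == "mean":
        return maps.mean(axis=0)
    if mode == "min":
        return maps.min(axis=0)
    return maps.max(axis=0)


@dataclass(frozen=True)
class OtsuResult:
    """Outcome of between-class-variance threshold selection.

    ``threshold`` is the largest intensity assigned to the low class, so
    the induced partition is ``below = (image <= threshold)``.  ``mu0`` /
    ``mu1`` are exact class means of the pixel values (not bin centers),
    ``omega0`` / ``omega1`` the class probabilities, and ``g`` the attained
    between-class variance omega0*(mu0-mu)^2 + omega1*(mu1-mu)^2.
    """

    threshold: float
    omega0: float
    omega1: float
    mu0: float
    mu1: float
    g: float

    @property
    def mu(self) -> float:
        """Overall mean, omega0*mu0 + omega1*mu1."""
        return self.omega0 * self.mu0 + self.omega1 * self.mu1


def otsu_threshold(image: np.ndarray, n_bins: int = 256) -> OtsuResult:
    """Exhaustive Otsu threshold over ``n_bins`` quantization levels.

    The intensity range is split into ``n_bins`` equal bins, every cut
    between adjacent bins is scored by between-class variance, and the
    maximizer is returned (ties broken toward the lowest threshold).
    Class means are accumulated from the actual pixel values so that the
    two-point closed form g = omega0*omega1*(mu0-mu1)^2 holds exactly.

    Raises
    ------
    DegenerateInputError
        If the image is constant (no valid split exists).
    """
    vals = np.asarray(image, dtype=np.float64).ravel()
    if vals.size == 0:
        raise ValueError("cannot threshold an empty image")
    if not np.all(np.isfinite(vals)):
        raise ValueError("image contains non-finite values")
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    vmin, vmax = float(vals.min()), float(vals.max())
    if vmax == vmin:
        raise DegenerateInputError("constant image: no threshold separates it")

    idx = np.floor((vals - vmin) / (vmax - vmin) * n_bins).astype(np.intp)
    np.clip(idx, 0, n_bins - 1, out=idx)
    counts = np.bincount(idx, minlength=n_bins).astype(np.float64)
    sums = np.bincount(idx, weights=vals, minlength=n_bins)
    # Track the max value per bin so `threshold` is an attained intensity.
    bin_max = np.full(n_bins, -np.inf)
    np.maximum.at(bin_max, idx, vals)

    n = vals.size
    total = sums.sum()
    c0 = np.cumsum(counts)[:-1]  # cut after bin t, t = 0..n_bins-2
    s0 = np.cumsum(sums)[:-1]
    valid = (c0 > 0) & (c0 < n)
    if not np.any(valid):
        raise DegenerateInputError("no cut separates the image into two classes")
    w0 = c0 / n
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = s0 / c0
        mu1 = (total - s0) / (n - c0)
        g = w0 * (1.0 - w0) * (mu0 - mu1) ** 2
    g[~valid] = -np.inf
    t = int(np.argmax(g))  # argmax returns the first (lowest) maximizer
    threshold = float(bin_max[: t + 1].max())
    return OtsuResult(
        threshold=threshold,
        omega0=float(w0[t]),
        omega1=float(1.0 - w0[t]),
        mu0=float(mu0[t]),
        mu1=float(mu1[t]),
        g=float(g[t]),
    )


def binarize(
    image: np.ndarray,
    threshold: "OtsuResult | float",
    polarity: str = "below",
) -> np.ndarray:
    """Threshold an image into a boolean mask.

    ``polarity="below"`` marks pixels with intensity <= threshold,
    ``"above"`` marks the strict complement (> threshold), so the two
    masks are complementary by construction.  On the entropy image the
    homogeneous lumina are the high-entropy side, i.e. ``polarity="above"``.
    """
    t = threshold.threshold if isinstance(threshold, OtsuResult) else float(threshold)
    img = np.asarray(image)
    if polarity == "below":
        return img <= t
    if polarity == "above":
        return img > t
    raise ValueError(f"polarity must be 'below' or 'above', got {polarity!r}")
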