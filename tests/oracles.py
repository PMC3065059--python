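"""Independent brute-force oracles used by the test suite.

These deliberately re-derive each quantity from its definition with naive
loops, staying independent of the vectorized implementations they check.
"""

import numpy as np


def brute_force_glcm(patch, mask, theta, d, levels):
    """Co-occurrence counts by explicit pair enumeration."""
    offsets = {0: (0, d), 45: (-d, d), 90: (-d, 0), 135: (-d, -d)}
    dr, dc = offsets[theta]
    h, w = patch.shape
    counts = np.zeros((levels, levels))
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w and mask[r, c] and mask[r2, c2]:
                counts[patch[r, c], patch[r2, c2]] += 1
    return counts


def brute_force_otsu(values, n_bins):
    """Best between-class variance over every quantized cut, by loops."""
    values = np.asarray(values, dtype=float).ravel()
    vmin, vmax = values.min(), values.max()
    idx = np.minimum(
        np.floor((values - vmin) / (vmax - vmin) * n_bins).astype(int), n_bins - 1
    )
    best_g, best_t = -1.0, None
    for t in range(n_bins - 1):
        low = values[idx <= t]
        high = values[idx > t]
        if low.size == 0 or high.size == 0:
            continue
        w0 = low.size / values.size
        mu0, mu1 = low.mean(), high.mean()
        mu = w0 * mu0 + (1 - w0) * mu1
        g = w0 * (mu0 - mu) ** 2 + (1 - w0) * (mu1 - mu) ** 2
        if g > best_g:
            best_g, best_t = g, t
    return best_g, best_t


def flood_fill_count(mask, connectivity):
    """Connected-component count by explicit stack-based flood fill."""
    mask = np.asarray(mask, dtype=bool)
    if connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    seen = np.zeros_like(mask)
    h, w = mask.shape
    count = 0
    for r in range(h):
        for c in range(w):
            if mask[r, c] and not seen[r, c]:
                count += 1
                stack = [(r, c)]
                seen[r, c] = True
                while stack:
                    rr, cc = stack.pop()
                    for dr, dc in nbrs:
                        r2, c2 = rr + dr, cc + dc
                        if 0 <= r2 < h and 0 <= c2 < w and mask[r2, c2] and not seen[r2, c2]:
                            seen[r2, c2] = True
                            stack.append((r2, c2))
    return count
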