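"""Independent oracles and small image builders shared across tests.

Everything here is deliberately written the slow, obvious way (explicit
loops, closed forms) so it stays independent of the library code it checks.
"""

from __future__ import annotations

import math

import numpy as np

ANGLE_STEPS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def glcm_oracle(image, mask=None, levels=32, angles=(0, 45, 90, 135)):
    """Brute-force GLCM homogeneity/energy/correlation by pair enumeration."""
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    if mask is None:
        mask = np.ones((h, w), dtype=bool)
    vals = image[mask]
    lo, hi = vals.min(), vals.max()
    q = np.zeros((h, w), dtype=int)
    for r in range(h):
        for c in range(w):
            if mask[r, c] and hi > lo:
                q[r, c] = min(int((image[r, c] - lo) / (hi - lo) * levels), levels - 1)

    stats = []
    for angle in angles:
        dr, dc = ANGLE_STEPS[angle]
        counts: dict[tuple[int, int], float] = {}
        for r in range(h):
            for c in range(w):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < h and 0 <= c2 < w and mask[r, c] and mask[r2, c2]:
                    counts[(q[r, c], q[r2, c2])] = counts.get((q[r, c], q[r2, c2]), 0) + 1
                    counts[(q[r2, c2], q[r, c])] = counts.get((q[r2, c2], q[r, c]), 0) + 1
        total = sum(counts.values())
        if total == 0:
            continue
        p = {k: v / total for k, v in counts.items()}
        homog = sum(v / (1 + abs(i - j)) for (i, j), v in p.items())
        energy = sum(v**2 for v in p.values())
        mu = sum(i * v for (i, _), v in p.items())
        var = sum((i - mu) ** 2 * v for (i, _), v in p.items())
        if var <= 0:
            corr = 0.0
        else:
            corr = sum(v * (i - mu) * (j - mu) for (i, j), v in p.items()) / var
        stats.append((homog, energy, corr))
    if not stats:
        return (math.nan, math.nan, math.nan)
    return tuple(float(np.mean([s[k] for s in stats])) for k in range(3))


def make_disk_frame(shape, centers, radii, fg=120.0, bg=200.0):
    """Antialiased disk(s) on a uniform background (float image)."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    alpha = np.zeros((h, w))
    for (cy, cx), r in zip(centers, radii):
        dist = np.hypot(yy - cy, xx - cx)
        alpha = np.maximum(alpha, np.clip(0.5 + (r - dist), 0.0, 1.0))
    return bg * (1.0 - alpha) + fg * alpha


def disk_mask(shape, center, radius):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return np.hypot(yy - center[0], xx - center[1]) <= radius
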