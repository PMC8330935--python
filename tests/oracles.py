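"""Independent brute-force reference implementations used as test oracles.

These deliberately avoid the vectorized code paths of the package: the
threshold oracle evaluates every window with scalar loops, and the
component oracle is a breadth-first flood fill.
"""

import numpy as np


def phansalkar_bruteforce(img: np.ndarray, radius: int, k=0.25, r=0.5, p=2.0, q=10.0) -> np.ndarray:
    """Per-pixel double-loop evaluation of the Phansalkar threshold.

    Window: digital disk (center distance <= radius), mirror padding,
    population standard deviation, offsets visited in row-major order.
    """
    h, w = img.shape
    padded = np.pad(img, radius, mode="reflect")
    offs = [
        (dy, dx)
        for dy in range(-radius, radius + 1)
        for dx in range(-radius, radius + 1)
        if dy * dy + dx * dx <= radius * radius
    ]
    n = float(len(offs))
    out = np.empty_like(img, dtype=np.float64)
    for i in range(h):
        for j in range(w):
            s1 = np.float64(0.0)
            s2 = np.float64(0.0)
            for dy, dx in offs:
                v = padded[radius + i + dy, radius + j + dx]
                s1 = s1 + v
                s2 = s2 + v * v
            mu = s1 / n
            var = s2 / n - mu * mu
            if var < 0.0:
                var = np.float64(0.0)
            sigma = np.sqrt(var)
            out[i, j] = mu * (1.0 + p * np.exp(-q * mu) + k * (sigma / r - 1.0))
    return out


def flood_fill_components(mask: np.ndarray) -> list[set]:
    """8-connected components by breadth-first flood fill; returns pixel sets."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    seen = np.zeros_like(mask)
    comps = []
    for i in range(h):
        for j in range(w):
            if not mask[i, j] or seen[i, j]:
                continue
            queue = [(i, j)]
            seen[i, j] = True
            pixels = set()
            while queue:
                y, x = queue.pop()
                pixels.add((y, x))
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        yy, xx = y + dy, x + dx
                        if 0 <= yy < h and 0 <= xx < w and mask[yy, xx] and not seen[yy, xx]:
                            seen[yy, xx] = True
                            queue.append((yy, xx))
            comps.append(pixels)
    return comps
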