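"""Independent brute-force oracles used by the test suite.

Each oracle re-derives a quantity by the most direct method available
(double loops, enumeration), sharing no code with the implementation paths
it checks.
"""

import math

import numpy as np


def pcf_brute_force(coords, window, r_grid, bandwidth):
    """Double-loop kernel PCF with translation edge correction.

    Evaluates, at every grid radius, the kernel estimator term by term over
    all ordered point pairs.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    area = window.width * window.height
    out = np.zeros(len(r_grid))
    for k, r in enumerate(r_grid):
        total = 0.0
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                dx = coords[i, 0] - coords[j, 0]
                dy = coords[i, 1] - coords[j, 1]
                d = math.hypot(dx, dy)
                u = (r - d) / bandwidth
                if abs(u) >= 1.0 or d == 0.0:
                    continue
                kern = 0.75 / bandwidth * (1.0 - u * u)
                t_area = (window.width - abs(dx)) * (window.height - abs(dy))
                total += kern / (2.0 * math.pi * d * t_area)
        # kernel mass on non-negative distances (boundary renormalisation)
        rho = min(r / bandwidth, 1.0)
        mass = 1.0 - 0.25 * (2.0 - 3.0 * rho + rho**3)
        out[k] = total * area * area / (n * (n - 1)) / mass
    return out


def nn_brute_force(coords):
    """O(n^2) nearest-neighbour distances."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    out = np.empty(n)
    for i in range(n):
        best = math.inf
        for j in range(n):
            if i != j:
                best = min(best, math.hypot(*(coords[i] - coords[j])))
        out[i] = best
    return out


def ztp_mean_enumeration(mu, k_max=100):
    """Zero-truncated Poisson mean by direct pmf enumeration."""
    norm = 1.0 - math.exp(-mu)
    total = 0.0
    for k in range(1, k_max + 1):
        pmf = math.exp(-mu) * mu**k / math.factorial(k)
        total += k * pmf / norm
    return total


def mask_pixel_tally(image_rgb, colour_map):
    """Per-category pixel counts by an explicit per-pixel loop."""
    counts = {}
    h, w = image_rgb.shape[:2]
    for i in range(h):
        for j in range(w):
            rgb = tuple(int(v) for v in image_rgb[i, j])
            key = "#%02x%02x%02x" % rgb
            cat = colour_map.get(key)
            counts[cat] = counts.get(cat, 0) + 1
    return counts
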