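"""Independent brute-force reference implementations used only by tests.

Everything here is deliberately written with explicit Python loops and no
FFTs or vectorized tricks, so it shares no code path with the package and
can serve as an oracle for equivalence checks on small inputs.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def reflect_index(i: int, n: int) -> int:
    """Mirror an out-of-range index the way np.pad(mode='reflect') does."""
    if n == 1:
        return 0
    period = 2 * n - 2
    i = i % period
    if i >= n:
        i = period - i
    return i


def naive_gradient(image: np.ndarray) -> np.ndarray:
    """Per-pixel dI/dx + i*dI/dy: central differences, one-sided at borders."""
    h, w = image.shape
    out = np.zeros((h, w), dtype=complex)
    for y in range(h):
        for x in range(w):
            if 0 < x < w - 1:
                dx = (image[y, x + 1] - image[y, x - 1]) / 2.0
            elif x == 0:
                dx = image[y, 1] - image[y, 0]
            else:
                dx = image[y, w - 1] - image[y, w - 2]
            if 0 < y < h - 1:
                dy = (image[y + 1, x] - image[y - 1, x]) / 2.0
            elif y == 0:
                dy = image[1, x] - image[0, x]
            else:
                dy = image[h - 1, x] - image[h - 2, x]
            out[y, x] = dx + 1j * dy
    return out


def naive_encode(field: np.ndarray, m: int) -> np.ndarray:
    """Mode-m Fourier coefficient r*exp(i*m*theta) of each gradient."""
    h, w = field.shape
    out = np.zeros((h, w), dtype=complex)
    for y in range(h):
        for x in range(w):
            g = field[y, x]
            r = abs(g)
            if r > 0:
                theta = math.atan2(g.imag, g.real)
                out[y, x] = r * complex(math.cos(m * theta), math.sin(m * theta))
    return out


def naive_basis_kernel(
    ring_radius: float, sigma: float, k: int, support_radius: int
) -> np.ndarray:
    """Gaussian-annulus circular harmonic kernel, built pixel by pixel."""
    side = 2 * support_radius + 1
    kernel = np.zeros((side, side), dtype=complex)
    total = 0.0
    for row in range(side):
        for col in range(side):
            u = col - support_radius
            v = row - support_radius
            rho = math.hypot(u, v)
            w = math.exp(-0.5 * ((rho - ring_radius) / sigma) ** 2)
            total += w
            psi = math.atan2(v, u)
            kernel[row, col] = w * complex(math.cos(k * psi), math.sin(k * psi))
    kernel /= total
    if k != 0:
        kernel[support_radius, support_radius] = 0.0
    return kernel


def naive_correlate_conj(fmap: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """out[p] = sum_q conj(kernel[q]) fmap[p+q], reflect border, double loop."""
    h, w = fmap.shape
    r = kernel.shape[0] // 2
    out = np.zeros((h, w), dtype=complex)
    for y in range(h):
        for x in range(w):
            acc = 0j
            for dy in range(-r, r + 1):
                for dx in range(-r, r + 1):
                    kv = kernel[dy + r, dx + r].conjugate()
                    fv = fmap[reflect_index(y + dy, h), reflect_index(x + dx, w)]
                    acc += kv * fv
            out[y, x] = acc
    return out


def naive_descriptor(image: np.ndarray, centre, config, spec) -> np.ndarray:
    """Full loop-based descriptor extraction mirroring the pipeline contract."""
    x, y = centre
    field = naive_gradient(np.asarray(image, dtype=float))
    modes = {m: naive_encode(field, m) for m in range(config.m_max + 1)}
    kernels = {}
    for j, rc in enumerate(config.ring_radii):
        for k in range(config.k_max + 1):
            kernels[(j, k)] = naive_basis_kernel(
                rc, config.ring_sigma, k, config.radius
            )
    raw = {}
    for (j, k, m) in spec.raw_triples:
        raw[(j, k, m)] = naive_correlate_conj(modes[m], kernels[(j, k)])
    values = []
    for (j, k, m) in spec.singles:
        v = raw[(j, k, m)][y, x]
        values.extend([v.real, v.imag])
    for t1, t2 in spec.composites:
        v = raw[t1][y, x] * raw[t2][y, x]
        values.extend([v.real, v.imag])
    for t in spec.magnitudes:
        values.append(abs(raw[t][y, x]))
    return np.asarray(values, dtype=float)


def symmetric_index(i: int, n: int) -> int:
    """Edge-including mirror, the border rule of scipy.ndimage 'reflect'."""
    if i < 0:
        i = -i - 1
    if i >= n:
        i = 2 * n - 1 - i
    return i


def naive_windowed_std(image: np.ndarray, window: int) -> np.ndarray:
    """Per-pixel standard deviation over a window x window mirrored patch."""
    h, w = image.shape
    r = window // 2
    out = np.zeros((h, w))
    for y in range(h):
        for x in range(w):
            vals = [
                image[symmetric_index(y + dy, h), symmetric_index(x + dx, w)]
                for dy in range(-r, r + 1)
                for dx in range(-r, r + 1)
            ]
            out[y, x] = np.std(vals)
    return out


def flood_fill_components(mask: np.ndarray) -> int:
    """Count 8-connected components of a binary mask by explicit flood fill."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    h, w = mask.shape
    count = 0
    for y in range(h):
        for x in range(w):
            if not mask[y, x] or seen[y, x]:
                continue
            count += 1
            stack = [(y, x)]
            seen[y, x] = True
            while stack:
                cy, cx = stack.pop()
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        ny, nx = cy + dy, cx + dx
                        if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and not seen[ny, nx]:
                            seen[ny, nx] = True
                            stack.append((ny, nx))
    return count


def optimal_assignment_counts(detections, truth, radius):
    """Exhaustive best matching: maximize pairs within radius, then minimize
    total distance.  Only feasible for tiny instances."""
    det = np.asarray(detections, dtype=float).reshape(-1, 2)
    tru = np.asarray(truth, dtype=float).reshape(-1, 2)
    nd, nt = len(det), len(tru)
    best_tp = 0
    best_cost = float("inf")
    k = min(nd, nt)
    for size in range(k, -1, -1):
        found = False
        for det_idx in itertools.combinations(range(nd), size):
            for tru_perm in itertools.permutations(range(nt), size):
                dists = [
                    math.hypot(
                        det[i, 0] - tru[j, 0], det[i, 1] - tru[j, 1]
                    )
                    for i, j in zip(det_idx, tru_perm)
                ]
                if all(d <= radius for d in dists):
                    cost = sum(dists)
                    if cost < best_cost:
                        best_cost = cost
                        best_tp = size
                        found = True
        if found:
            break
    tp = best_tp
    return tp, nd - tp, nt - tp
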