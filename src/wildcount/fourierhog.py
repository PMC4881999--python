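"""Rotation-invariant Fourier HOG descriptors.

The classical histogram-of-oriented-gradients descriptor bins gradient
directions into a discrete grid, which ties the descriptor to the object's
orientation.  Here each pixel's gradient ``g = dx + i*dy = r*exp(i*theta)``
is instead treated as a Dirac delta on the circle of orientations and
expanded in a Fourier series, giving per-pixel coefficients

    F_m = r * exp(i*m*theta),      m = 0 .. M_max.

Spatial pooling is done by convolving each coefficient plane with circular
harmonic basis kernels

    U_{j,k}(rho, psi) = w_j(rho) * exp(i*k*psi)

where ``w_j`` is a real ring-shaped (Gaussian annulus) radial profile and
``k`` is the angular wavenumber.  A raw feature ``X_{k,m} = U_{j,k} * F_m``
picks up a phase ``exp(i*alpha*(m - k))`` when the image rotates by
``alpha`` about the evaluation point, so

* a *single* feature with ``m == k`` is rotation invariant, and
* a *product* ``X_{k1,m1} X_{k2,m2}`` with ``m1 - k1 + m2 - k2 == 0`` is
  rotation invariant.

The real-valued descriptor concatenates real and imaginary parts of such
invariant combinations (optionally plus magnitudes ``|X_{k,m}|``, which are
trivially invariant).

Coordinate convention: row-major arrays, origin at the top-left,
``x`` = column index, ``y`` = row index, both 0-based, pixel centres at
integer coordinates.  Angles are measured with ``atan2(y, x)`` in this
frame throughout (image, gradients and kernels all share it), so the
rotation algebra above is self-consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import fftconvolve

from .exceptions import InvalidInputError, InvalidParameterError, InvalidSpecError

__all__ = [
    "FeatureConfig",
    "DescriptorSpec",
    "BasisFunction",
    "FourierHOG",
    "compute_gradient_field",
    "fourier_encode_gradients",
    "make_basis_functions",
    "convolve_features",
    "build_invariant_features",
    "extract_window_descriptor",
    "default_descriptor_spec",
]


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class FeatureConfig:
    """Feature-extraction parameters.

    Parameters
    ----------
    window :
        Side of the (square) descriptor window in pixels.  The kernel
        support radius is ``window // 2``.
    m_max :
        Highest Fourier mode of the gradient-orientation expansion.
    k_max :
        Highest angular wavenumber of the basis kernels.
    n_rings :
        Number of radial profiles; ring centres are evenly spaced on
        ``[0, radius]`` (``{0, s, 2s, ...}`` with ``s = radius/(n_rings-1)``).
    ring_width :
        Std-dev of the Gaussian annuli as a fraction of the ring spacing.
    composite_budget :
        Maximum number of composite (product) invariants retained.
    include_magnitudes :
        Whether to append ``|X_{k,m}|`` entries for every raw feature used.
    """

    window: int = 24
    m_max: int = 4
    k_max: int = 4
    n_rings: int = 4
    ring_width: float = 0.5
    composite_budget: int = 40
    include_magnitudes: bool = False

    def __post_init__(self) -> None:
        if self.window < 3:
            raise InvalidParameterError("window must be >= 3 pixels")
        if self.m_max < 1:
            raise InvalidParameterError("m_max must be >= 1")
        if self.k_max < 0:
            raise InvalidParameterError("k_max must be >= 0")
        if self.n_rings < 1:
            raise InvalidParameterError("n_rings must be >= 1")

    @property
    def radius(self) -> int:
        return self.window // 2

    @property
    def ring_radii(self) -> tuple[float, ...]:
        if self.n_rings == 1:
            return (0.0,)
        s = self.radius / (self.n_rings - 1)
        return tuple(j * s for j in range(self.n_rings))

    @property
    def ring_sigma(self) -> float:
        if self.n_rings == 1:
            return self.ring_width * self.radius
        return self.ring_width * self.radius / (self.n_rings - 1)

    def to_dict(self) -> dict:
        return {
            "window": self.window,
            "m_max": self.m_max,
            "k_max": self.k_max,
            "n_rings": self.n_rings,
            "ring_width": self.ring_width,
            "composite_budget": self.composite_budget,
            "include_magnitudes": self.include_magnitudes,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FeatureConfig":
        return cls(
            window=int(d["window"]),
            m_max=int(d["m_max"]),
            k_max=int(d["k_max"]),
            n_rings=int(d["n_rings"]),
            ring_width=float(d["ring_width"]),
            composite_budget=int(d["composite_budget"]),
            include_magnitudes=bool(d["include_magnitudes"]),
        )


Triple = tuple[int, int, int]  # (j, k, m)


@dataclass(frozen=True)
class DescriptorSpec:
    """Index sets defining which invariant combinations form the descriptor.

    ``singles`` are triples ``(j, k, m)`` with ``m == k`` (each contributes
    its real and imaginary part); ``composites`` are pairs of triples with
    ``m1 - k1 + m2 - k2 == 0`` (real and imaginary part of the product);
    ``magnitudes`` are arbitrary triples contributing ``|X|``.

    Construction rejects any entry that is not rotation invariant: this is
    a correctness guard, not a warning.
    """

    singles: tuple[Triple, ...]
    composites: tuple[tuple[Triple, Triple], ...] = ()
    magnitudes: tuple[Triple, ...] = ()

    def __post_init__(self) -> None:
        for (j, k, m) in self.singles:
            if m != k:
                raise InvalidSpecError(
                    f"single feature (j={j}, k={k}, m={m}) is not rotation "
                    f"invariant: requires m == k"
                )
        for (t1, t2) in self.composites:
            (_, k1, m1), (_, k2, m2) = t1, t2
            s = m1 - k1 + m2 - k2
            if s != 0:
                raise InvalidSpecError(
                    f"composite pair {t1} x {t2} has rotation index sum "
                    f"{s} != 0 and is not rotation invariant"
                )

    def __len__(self) -> int:
        return 2 * len(self.singles) + 2 * len(self.composites) + len(self.magnitudes)

    @property
    def raw_triples(self) -> tuple[Triple, ...]:
        """All distinct (j, k, m) raw feature maps the descriptor needs."""
        needed: set[Triple] = set(self.singles) | set(self.magnitudes)
        for t1, t2 in self.composites:
            needed.add(t1)
            needed.add(t2)
        return tuple(sorted(needed))

    @property
    def entry_names(self) -> tuple[str, ...]:
        names: list[str] = []
        for (j, k, m) in self.singles:
            names.append(f"re[X(j={j},k={k},m={m})]")
            names.append(f"im[X(j={j},k={k},m={m})]")
        for (j1, k1, m1), (j2, k2, m2) in self.composites:
            tag = f"X(j={j1},k={k1},m={m1})*X(j={j2},k={k2},m={m2})"
            names.append(f"re[{tag}]")
            names.append(f"im[{tag}]")
        for (j, k, m) in self.magnitudes:
            names.append(f"abs[X(j={j},k={k},m={m})]")
        return tuple(names)


def default_descriptor_spec(config: FeatureConfig) -> DescriptorSpec:
    """Build the default invariant index sets for a feature configuration.

    Singles: every ``(j, k, k)`` with ``k <= min(k_max, m_max)``.
    Composites: pairs ``X_{k1,m1} X_{k2,m2}`` with opposite nonzero rotation
    index (``m1 - k1 = -(m2 - k2) > 0``), radial indices at most one ring
    apart, ordered by ``(j1, k1, m1, j2, k2, m2)`` and truncated at the
    configured budget.
    """
    kk = min(config.k_max, config.m_max)
    singles = tuple(
        (j, k, k) for j in range(config.n_rings) for k in range(kk + 1)
    )

    feats = [
        (j, k, m)
        for j in range(config.n_rings)
        for k in range(config.k_max + 1)
        for m in range(config.m_max + 1)
    ]
    candidates = []
    for (j1, k1, m1) in feats:
        d = m1 - k1
        if d <= 0:
            continue
        for (j2, k2, m2) in feats:
            if m2 - k2 != -d:
                continue
            if abs(j1 - j2) > 1:
                continue
            candidates.append(((j1, k1, m1), (j2, k2, m2)))
    candidates.sort(key=lambda p: p[0] + p[1])
    composites = tuple(candidates[: config.composite_budget])

    magnitudes: tuple[Triple, ...] = ()
    if config.include_magnitudes:
        seen = set(singles)
        for t1, t2 in composites:
            seen.add(t1)
            seen.add(t2)
        magnitudes = tuple(sorted(seen))
    return DescriptorSpec(singles=singles, composites=composites, magnitudes=magnitudes)


# ---------------------------------------------------------------------------
# gradients and Fourier encoding


def _validate_gray(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise InvalidInputError("expected a 2-d grayscale image")
    if image.shape[0] < 3 or image.shape[1] < 3:
        raise InvalidInputError("image must be at least 3x3 pixels")
    if not np.all(np.isfinite(image)):
        raise InvalidInputError("image contains non-finite intensities")
    return image


def compute_gradient_field(image: np.ndarray) -> np.ndarray:
    """Complex gradient field ``G = dI/dx + i dI/dy``.

    Central differences on the interior, one-sided differences at the
    borders.  Returns a complex array of the same shape as ``image``.
    """
    image = _validate_gray(image)
    dy, dx = np.gradient(image)  # np.gradient: central interior, one-sided edges
    return dx + 1j * dy


def fourier_encode_gradients(field: np.ndarray, m_max: int) -> np.ndarray:
    """Fourier coefficients of the per-pixel gradient-orientation delta.

    For a pixel with gradient ``r*exp(i*theta)`` the mode-``m`` coefficient
    is ``r*exp(i*m*theta)``; mode 0 is the (real) gradient magnitude.
    Returns an array of shape ``(m_max + 1, H, W)``.
    """
    if m_max < 1:
        raise InvalidParameterError("m_max must be >= 1")
    field = np.asarray(field, dtype=complex)
    r = np.abs(field)
    unit = np.zeros_like(field)
    np.divide(field, r, out=unit, where=r > 0)
    stack = np.empty((m_max + 1,) + field.shape, dtype=complex)
    stack[0] = r
    for m in range(1, m_max + 1):
        stack[m] = stack[m - 1] * unit
    return stack


# ---------------------------------------------------------------------------
# basis functions


@dataclass(frozen=True)
class BasisFunction:
    """Circular harmonic kernel ``w_j(rho) * exp(i*k*psi)`` on a square grid."""

    kernel: np.ndarray
    j: int
    k: int
    radius: int
    ring_radius: float
    ring_sigma: float


def make_basis_functions(
    radii: Sequence[float],
    k_max: int,
    support_radius: int,
    sigma: float,
) -> list[BasisFunction]:
    """Build one kernel per (j, k), k = 0 .. k_max.

    ``radii[j]`` is the centre radius of the j-th Gaussian annulus profile
    ``w_j(rho) = exp(-(rho - radii[j])^2 / (2 sigma^2))``, normalised to
    unit total weight over the ``(2*support_radius+1)``-sided square
    support.  The k = 0 kernels are real; kernels with ``k != 0`` sum to
    (numerically) zero over the support because the angular factor
    integrates to zero on every ring.
    """
    if len(radii) == 0:
        raise InvalidParameterError("radii must be non-empty")
    if k_max < 0:
        raise InvalidParameterError("k_max must be >= 0")
    if any(r > support_radius for r in radii):
        raise InvalidParameterError("ring radius exceeds kernel support")
    coords = np.arange(-support_radius, support_radius + 1, dtype=float)
    u, v = np.meshgrid(coords, coords)  # u = x offset (cols), v = y offset (rows)
    rho = np.hypot(u, v)
    psi = np.arctan2(v, u)
    out: list[BasisFunction] = []
    for j, rc in enumerate(radii):
        w = np.exp(-0.5 * ((rho - rc) / sigma) ** 2)
        w /= w.sum()
        for k in range(k_max + 1):
            kernel = w * np.exp(1j * k * psi)
            if k != 0:
                # a circular harmonic with k != 0 vanishes at the origin
                # (the angle is undefined there); atan2(0, 0) would
                # otherwise give the centre pixel full weight and break
                # the exact 90-degree rotation symmetry of the grid
                kernel[support_radius, support_radius] = 0.0
            out.append(
                BasisFunction(
                    kernel=kernel,
                    j=j,
                    k=k,
                    radius=support_radius,
                    ring_radius=float(rc),
                    ring_sigma=float(sigma),
                )
            )
    return out


# ---------------------------------------------------------------------------
# convolution


def _correlate_conj(fmap: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Cross-correlate ``fmap`` with the conjugated kernel, reflect border.

    ``out[p] = sum_q conj(kernel[q]) * fmap[p + q]`` with offsets ``q``
    centred on the kernel midpoint and out-of-image pixels mirror-reflected
    (no edge duplication).  Correlating with the conjugate is what makes a
    raw feature transform as ``exp(i*alpha*(m - k))`` under rotation.
    """
    r = kernel.shape[0] // 2
    padded = np.pad(fmap, r, mode="reflect")
    flipped = np.conj(kernel[::-1, ::-1])
    out = fftconvolve(padded, flipped, mode="same")
    return out[r:-r, r:-r]


def convolve_features(stack: np.ndarray, basis: BasisFunction) -> np.ndarray:
    """Raw Fourier HOG feature maps ``X_{k,m} = U_{j,k} * F_m``.

    ``stack`` may be one coefficient plane (2-d) or the full
    ``(M+1, H, W)`` stack, in which case one map per mode is returned.
    """
    stack = np.asarray(stack, dtype=complex)
    side = basis.kernel.shape[0]
    if stack.shape[-1] < side or stack.shape[-2] < side:
        raise InvalidInputError("basis support exceeds image size")
    if stack.ndim == 2:
        return _correlate_conj(stack, basis.kernel)
    return np.stack([_correlate_conj(plane, basis.kernel) for plane in stack])


# ---------------------------------------------------------------------------
# invariant assembly


def _gather_raw(
    raw: Mapping[Triple, np.ndarray], triple: Triple
) -> np.ndarray:
    try:
        return raw[triple]
    except KeyError as exc:  # pragma: no cover - defensive
        raise InvalidSpecError(f"raw feature map {triple} not provided") from exc


def invariant_maps(
    raw: Mapping[Triple, np.ndarray], spec: DescriptorSpec
) -> np.ndarray:
    """Stack the real invariant planes for a whole image.

    Returns an ``(H, W, D)`` float array whose last axis follows
    ``spec.entry_names``.
    """
    planes: list[np.ndarray] = []
    for t in spec.singles:
        x = _gather_raw(raw, t)
        planes.append(x.real)
        planes.append(x.imag)
    for t1, t2 in spec.composites:
        prod = _gather_raw(raw, t1) * _gather_raw(raw, t2)
        planes.append(prod.real)
        planes.append(prod.imag)
    for t in spec.magnitudes:
        planes.append(np.abs(_gather_raw(raw, t)))
    return np.stack(planes, axis=-1)


def build_invariant_features(
    raw: Mapping[Triple, np.ndarray],
    spec: DescriptorSpec,
    centre: tuple[int, int],
) -> np.ndarray:
    """Real invariant descriptor at one pixel.

    ``raw`` maps ``(j, k, m)`` to the corresponding feature map;
    ``centre`` is an ``(x, y)`` pixel coordinate.  The spec is re-validated
    on construction, so any entry violating the ``m == k`` /
    zero-index-sum conditions has already been rejected.
    """
    x, y = centre
    values: list[float] = []
    for t in spec.singles:
        v = _gather_raw(raw, t)[y, x]
        values.append(v.real)
        values.append(v.imag)
    for t1, t2 in spec.composites:
        v = _gather_raw(raw, t1)[y, x] * _gather_raw(raw, t2)[y, x]
        values.append(v.real)
        values.append(v.imag)
    for t in spec.magnitudes:
        values.append(abs(_gather_raw(raw, t)[y, x]))
    return np.asarray(values, dtype=float)


# ---------------------------------------------------------------------------
# high-level extractor


class FourierHOG:
    """End-to-end extractor: image -> rotation-invariant descriptor planes.

    Builds the basis kernels once; ``feature_maps`` then computes, for a
    whole image, only the raw maps the descriptor spec actually uses.
    """

    def __init__(
        self, config: FeatureConfig | None = None, spec: DescriptorSpec | None = None
    ) -> None:
        self.config = config or FeatureConfig()
        self.spec = spec if spec is not None else default_descriptor_spec(self.config)
        basis_list = make_basis_functions(
            self.config.ring_radii,
            self.config.k_max,
            self.config.radius,
            self.config.ring_sigma,
        )
        self._basis = {(b.j, b.k): b for b in basis_list}

    @property
    def n_features(self) -> int:
        return len(self.spec)

    def basis(self, j: int, k: int) -> BasisFunction:
        return self._basis[(j, k)]

    def raw_feature_maps(self, image: np.ndarray) -> dict[Triple, np.ndarray]:
        image = _validate_gray(image)
        if min(image.shape) < 2 * self.config.radius + 1:
            raise InvalidInputError(
                "image smaller than the descriptor window "
                f"({self.config.window} px)"
            )
        field = compute_gradient_field(image)
        stack = fourier_encode_gradients(field, self.config.m_max)
        raw: dict[Triple, np.ndarray] = {}
        for (j, k, m) in self.spec.raw_triples:
            raw[(j, k, m)] = _correlate_conj(stack[m], self._basis[(j, k)].kernel)
        return raw

    def feature_maps(self, image: np.ndarray) -> np.ndarray:
        """(H, W, D) invariant descriptor planes for every pixel."""
        return invariant_maps(self.raw_feature_maps(image), self.spec)

    def descriptor(self, image: np.ndarray, centre: tuple[int, int]) -> np.ndarray:
        """Descriptor at a single (x, y) pixel of ``image``."""
        image = _validate_gray(image)
        x, y = centre
        if not (0 <= x < image.shape[1] and 0 <= y < image.shape[0]):
            raise InvalidInputError(f"centre {centre} outside image {image.shape}")
        return build_invariant_features(self.raw_feature_maps(image), self.spec, centre)


def extract_window_descriptor(
    image: np.ndarray,
    centre: tuple[int, int],
    config: FeatureConfig | None = None,
    spec: DescriptorSpec | None = None,
) -> np.ndarray:
    """Convenience wrapper: descriptor of ``image`` at ``centre`` (x, y)."""
    return FourierHOG(config, spec).descriptor(image, centre)
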