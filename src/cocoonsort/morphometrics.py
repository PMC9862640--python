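"""Outline morphometrics: radial digitization, generalized Procrustes
alignment, and elliptic Fourier shape descriptors.

A segmented cocoon silhouette is reduced to 180 boundary points sampled at
equal angular increments (one every pi/90 rad) around the region centroid.
Sets of outlines are superimposed by generalized Procrustes analysis (GPA),
removing translation, rotation and isotropic scale, and each aligned outline
is decomposed into elliptic Fourier harmonics: four coefficients
(a_i, b_i for x; c_i, d_i for y) per harmonic, up to the Nyquist order of
half the point count.  The harmonic series is truncated where the average
cumulative harmonic power over a training set reaches 99.999% of the average
total power, and the retained coefficients feed the shape classifier.

Two decompositions are offered.  The default (``method="dft"``) treats the
ordered points as uniform samples of the closed curve and computes the exact
discrete Fourier coefficients, so decompose/reconstruct form an exact
transform pair and harmonic power satisfies Parseval's identity exactly.
``method="chord"`` is the classical formulation that integrates the
piecewise-linear coordinate increments against the cumulative chordal
length; for the near-uniformly spaced outlines produced by the radial
digitizer the two agree to O(N^-2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import AlignmentError, DigitizationError, ValidationError

GPA_TOL = 1e-8
GPA_MAX_ITER = 200
DEFAULT_POWER_FRACTION = 0.99999


# ---------------------------------------------------------------------------
# Outline container and radial digitizer
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Outline:
    """Closed polygon of boundary points in (x, y) pixel coordinates.

    Point i sits on the ray from ``centroid`` at angle 2*pi*i/N; the polygon
    closes from the last point back to the first.
    """

    points: np.ndarray  # (N, 2) float
    centroid: tuple[float, float]

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
            raise ValidationError(f"outline needs (N>=3, 2) points, got {pts.shape}")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return self.points.shape[0]


def digitize_outline(mask: np.ndarray, n_points: int = 180) -> Outline:
    """Sample the region boundary at equal angles around its centroid.

    For each angle theta_i = 2*pi*i/n_points the returned point is the
    outermost crossing of the region boundary along the ray from the
    centroid, located to sub-pixel precision by linear interpolation of the
    mask.  Deeply non-convex silhouettes remain representable because the
    outermost (not first) crossing is taken, but a multi-valued radius is
    collapsed to its largest value.
    """
    mask = np.asarray(mask, dtype=bool)
    if n_points < 3:
        raise ValidationError("n_points must be >= 3")
    if not mask.any():
        raise DigitizationError("empty mask")
    cy, cx = ndimage.center_of_mass(mask)
    iy, ix = int(round(cy)), int(round(cx))
    if not (0 <= iy < mask.shape[0] and 0 <= ix < mask.shape[1]) or not mask[iy, ix]:
        raise DigitizationError("region centroid falls outside the region")

    h, w = mask.shape
    corners = np.array([[0, 0], [0, w - 1], [h - 1, 0], [h - 1, w - 1]], float)
    r_max = float(np.max(np.hypot(corners[:, 0] - cy, corners[:, 1] - cx))) + 1.0
    step = 0.5
    radii = np.arange(0.0, r_max + step, step)
    theta = 2.0 * np.pi * np.arange(n_points) / n_points
    dy = np.sin(theta)[:, None] * radii[None, :]
    dx = np.cos(theta)[:, None] * radii[None, :]
    coords = np.stack([cy + dy, cx + dx])  # (2, n_points, n_radii)
    prof = ndimage.map_coordinates(
        mask.astype(np.float64), coords.reshape(2, -1), order=1, cval=0.0
    ).reshape(n_points, radii.size)

    inside = prof >= 0.5
    if not inside[:, 0].all():
        raise DigitizationError("centroid not interior to the region")
    # outermost inside sample per ray, then linear sub-pixel refinement
    last = inside.shape[1] - 1 - np.argmax(inside[:, ::-1], axis=1)
    rows = np.arange(n_points)
    v0 = prof[rows, last]
    nxt = np.minimum(last + 1, radii.size - 1)
    v1 = prof[rows, nxt]
    frac = np.where(v0 > v1, (v0 - 0.5) / np.where(v0 > v1, v0 - v1, 1.0), 0.0)
    r = radii[last] + frac * step
    pts = np.column_stack([cx + r * np.cos(theta), cy + r * np.sin(theta)])
    return Outline(points=pts, centroid=(float(cx), float(cy)))


# ---------------------------------------------------------------------------
# Generalized Procrustes alignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignedOutlineSet:
    outlines: list[np.ndarray]
    mean_shape: np.ndarray
    residual_ss: float
    n_iterations: int


def _as_points(outline) -> np.ndarray:
    if isinstance(outline, Outline):
        return np.asarray(outline.points, dtype=np.float64)
    pts = np.asarray(outline, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValidationError(f"expected (N, 2) points, got {pts.shape}")
    return pts


def _normalize(pts: np.ndarray, scale: bool) -> np.ndarray:
    pts = pts - pts.mean(axis=0)
    if scale:
        size = np.linalg.norm(pts)
        if size < 1e-12:
            raise AlignmentError("outline has zero spread")
        pts = pts / size
    return pts


def _rotate_onto(pts: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Optimal rotation (no reflection) of centered ``pts`` onto ``target``."""
    u, _, vt = np.linalg.svd(target.T @ pts)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, d]) @ vt
    return pts @ rot.T


def procrustes_align(
    outlines,
    scale: bool = True,
    tol: float = GPA_TOL,
    max_iter: int = GPA_MAX_ITER,
) -> AlignedOutlineSet:
    """Generalized Procrustes superimposition of a set of outlines.

    Translation and rotation are always removed; isotropic scale is removed
    by default (full GPA) because cocoon size is gated by a separate station
    and the shape features should be size-free.  The mean shape is updated
    iteratively until the relative change in residual sum of squares drops
    below ``tol``.
    """
    configs = [_as_points(o) for o in outlines]
    if len(configs) < 2:
        raise ValidationError("GPA needs at least two outlines")
    n = configs[0].shape[0]
    if any(c.shape[0] != n for c in configs):
        raise ValidationError("all outlines must have the same point count")
    configs = [_normalize(c, scale) for c in configs]

    mean = configs[0].copy()
    prev_rss = np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        configs = [_rotate_onto(c, mean) for c in configs]
        mean = np.mean(configs, axis=0)
        mean -= mean.mean(axis=0)
        if scale:
            norm = np.linalg.norm(mean)
            if norm < 1e-12:
                raise AlignmentError("degenerate mean shape")
            mean /= norm
        rss = float(sum(np.sum((c - mean) ** 2) for c in configs))
        if prev_rss - rss < tol * max(prev_rss, 1e-30) and n_iter > 1:
            prev_rss = rss
            break
        prev_rss = rss
    return AlignedOutlineSet(
        outlines=configs, mean_shape=mean, residual_ss=prev_rss, n_iterations=n_iter
    )


def align_to(outline, reference) -> np.ndarray:
    """Superimpose one outline onto a reference (e.g. a stored mean shape)."""
    ref = _normalize(_as_points(reference), scale=True)
    pts = _normalize(_as_points(outline), scale=True)
    return _rotate_onto(pts, ref)


def procrustes_distance(a, b) -> float:
    """Full Procrustes distance between two outlines (translation, scale and
    rotation removed)."""
    pa = _normalize(_as_points(a), scale=True)
    pb = _normalize(_as_points(b), scale=True)
    pb = _rotate_onto(pb, pa)
    return float(np.linalg.norm(pa - pb))


# ---------------------------------------------------------------------------
# Elliptic Fourier analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EFADescriptor:
    """Elliptic Fourier decomposition of a closed outline.

    ``coefficients`` has shape (n_harmonics, 4) ordered (a, b, c, d): cosine
    and sine amplitudes of the x projection, then of the y projection.  The
    harmonic power is (a^2 + b^2 + c^2 + d^2) / 2 per harmonic.  ``a0, c0``
    hold the outline centroid (DC term).
    """

    coefficients: np.ndarray  # (n, 4)
    a0: float
    c0: float
    n_points: int
    method: str = "dft"
    k_truncation: int | None = None

    def __post_init__(self) -> None:
        coeff = np.asarray(self.coefficients, dtype=np.float64)
        if coeff.ndim != 2 or coeff.shape[1] != 4:
            raise ValidationError(f"coefficients must be (n, 4), got {coeff.shape}")
        if coeff.shape[0] > self.n_points // 2:
            raise ValidationError("harmonic count exceeds the Nyquist order")
        if self.k_truncation is not None and not (
            1 <= self.k_truncation <= coeff.shape[0]
        ):
            raise ValidationError("k_truncation out of range")
        object.__setattr__(self, "coefficients", coeff)

    @property
    def n_harmonics(self) -> int:
        return self.coefficients.shape[0]

    @property
    def harmonic_power(self) -> np.ndarray:
        return 0.5 * np.sum(self.coefficients**2, axis=1)

    @property
    def total_power(self) -> float:
        return float(self.harmonic_power.sum())

    def flat_coefficients(self, k: int | None = None) -> np.ndarray:
        """First k harmonics flattened to a 4k feature vector (a1,b1,c1,d1,...)."""
        k = self.n_harmonics if k is None else k
        return self.coefficients[:k].ravel()


def _dft_series(values: np.ndarray, n: int) -> tuple[float, np.ndarray, np.ndarray]:
    """Exact real Fourier series of a uniformly sampled periodic sequence."""
    npts = values.size
    spec = np.fft.rfft(values) / npts
    dc = float(spec[0].real)
    m = np.arange(1, n + 1)
    cos_c = 2.0 * spec[m].real
    sin_c = -2.0 * spec[m].imag
    if n == npts // 2 and npts % 2 == 0:
        cos_c[-1] = spec[npts // 2].real  # Nyquist term appears once
        sin_c[-1] = 0.0
    return dc, cos_c, sin_c


def _chord_series(pts: np.ndarray, n: int) -> tuple[float, float, np.ndarray]:
    """Classical elliptic Fourier coefficients from chord-length increments."""
    d = np.diff(np.vstack([pts, pts[:1]]), axis=0)
    dt = np.hypot(d[:, 0], d[:, 1])
    if np.any(dt == 0):
        keep = dt > 0
        d, dt = d[keep], dt[keep]
    t = np.concatenate([[0.0], np.cumsum(dt)])
    big_t = t[-1]
    phi = 2.0 * np.pi * t / big_t
    harmonics = np.arange(1, n + 1)[:, None]
    dcos = np.cos(harmonics * phi[1:]) - np.cos(harmonics * phi[:-1])
    dsin = np.sin(harmonics * phi[1:]) - np.sin(harmonics * phi[:-1])
    scale = big_t / (2.0 * np.pi**2 * harmonics.ravel() ** 2)
    slopes = d / dt[:, None]
    a = scale * (dcos @ slopes[:, 0])
    c = scale * (dcos @ slopes[:, 1])
    b = scale * (dsin @ slopes[:, 0])
    d_ = scale * (dsin @ slopes[:, 1])
    # DC terms: average of the piecewise-linear curve over one period
    mids = (pts + np.vstack([pts[1:], pts[:1]])) / 2.0
    a0 = float(np.sum(mids[:, 0] * dt) / big_t)
    c0 = float(np.sum(mids[:, 1] * dt) / big_t)
    coeff = np.column_stack([a, b, c, d_])
    return a0, c0, coeff


def efa_decompose(outline, n: int, method: str = "dft") -> EFADescriptor:
    """Decompose a closed outline into n elliptic Fourier harmonics."""
    pts = _as_points(outline)
    npts = pts.shape[0]
    if not 1 <= n <= npts // 2:
        raise ValidationError(
            f"harmonic count {n} outside [1, Nyquist={npts // 2}] for {npts} points"
        )
    if method == "dft":
        a0, ax, bx = _dft_series(pts[:, 0], n)
        c0, cy, dy = _dft_series(pts[:, 1], n)
        coeff = np.column_stack([ax, bx, cy, dy])
    elif method == "chord":
        a0, c0, coeff = _chord_series(pts, n)
    else:
        raise ValidationError(f"unknown EFA method {method!r}")
    return EFADescriptor(coefficients=coeff, a0=a0, c0=c0, n_points=npts, method=method)


def efa_reconstruct(
    desc: EFADescriptor, k: int | None = None, n_points: int | None = None
) -> Outline:
    """Rebuild an outline from the first k harmonics.

    With ``k = n_harmonics`` and ``n_points`` equal to the analyzed point
    count, the DFT decomposition round-trips to the original points at
    machine precision.
    """
    k = desc.n_harmonics if k is None else k
    if not 1 <= k <= desc.n_harmonics:
        raise ValidationError(f"k={k} outside [1, {desc.n_harmonics}]")
    npts = desc.n_points if n_points is None else n_points
    if npts < 3:
        raise ValidationError("n_points must be >= 3")
    t = 2.0 * np.pi * np.arange(npts) / npts
    m = np.arange(1, k + 1)
    cos_mt = np.cos(np.outer(t, m))
    sin_mt = np.sin(np.outer(t, m))
    a, b, c, d = (desc.coefficients[:k, i] for i in range(4))
    x = desc.a0 + cos_mt @ a + sin_mt @ b
    y = desc.c0 + cos_mt @ c + sin_mt @ d
    pts = np.column_stack([x, y])
    return Outline(points=pts, centroid=(desc.a0, desc.c0))


def increment_power(outline) -> float:
    """Total power of the coordinate increment series, Sum(dx^2 + dy^2).

    For the DFT decomposition this equals the Parseval-weighted sum of
    harmonic amplitudes (see :func:`harmonic_increment_power`).
    """
    pts = _as_points(outline)
    d = np.diff(np.vstack([pts, pts[:1]]), axis=0)
    return float(np.sum(d**2))


def harmonic_increment_power(desc: EFADescriptor) -> float:
    """Increment-series power implied by the harmonic amplitudes.

    Differencing a sampled harmonic of order m multiplies its amplitude by
    2 sin(pi m / N); Parseval then gives
    Sum_j (dx_j^2 + dy_j^2) = (N/2) * Sum_m w_m (a_m^2+b_m^2+c_m^2+d_m^2)
    with w_m = 4 sin^2(pi m / N) and the Nyquist term counted at weight 2N.
    """
    npts = desc.n_points
    m = np.arange(1, desc.n_harmonics + 1)
    w = 4.0 * np.sin(np.pi * m / npts) ** 2
    amp2 = np.sum(desc.coefficients**2, axis=1)
    factor = np.full(m.size, npts / 2.0)
    if desc.n_harmonics == npts // 2 and npts % 2 == 0:
        factor[-1] = npts  # Nyquist cosine appears once, not twice
    return float(np.sum(factor * w * amp2))


def truncation_order(
    descriptors, fraction: float = DEFAULT_POWER_FRACTION
) -> int:
    """Smallest k with mean cumulative power >= fraction of mean total power.

    The default keeps 99.999% of the average total harmonic power over the
    training set.
    """
    descs = list(descriptors)
    if not descs:
        raise ValidationError("empty descriptor list")
    if not 0 < fraction <= 1.0:
        raise ValidationError("fraction must be in (0, 1]")
    n = descs[0].n_harmonics
    if any(d.n_harmonics != n for d in descs):
        raise ValidationError("descriptors must share the harmonic count")
    powers = np.stack([d.harmonic_power for d in descs])
    mean_cum = np.cumsum(powers.mean(axis=0))
    total = mean_cum[-1]
    if total <= 0:
        return 1
    k = int(np.searchsorted(mean_cum, fraction * total, side="left")) + 1
    return min(k, n)
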