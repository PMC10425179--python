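"""Grey-level-index (GLI) images and laminar profile extraction.

The GLI quantifies the volume fraction of cell bodies in fixed-size square
measuring fields of a binarized histological section; sampled along traverses
that run perpendicular to the cortical surface it yields depth profiles whose
shape encodes the laminar pattern of a cortical area.  Each profile is
parametrized as a 10-feature vector — the five moments (mean amplitude,
centroid depth, dispersion, skewness, kurtosis) of the profile treated as a
frequency distribution over relative cortical depth, and the same five moments
of its absolute first derivative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates
from shapely.geometry import LineString


@dataclass(frozen=True)
class SectionImage:
    """A 2D grayscale section.

    Parameters
    ----------
    pixels : 2D array of grey values (0-255 for raw sections, 0-100 for GLI).
    resolution : physical size of one pixel in micrometres.
    """

    pixels: np.ndarray
    resolution: float = 1.0

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"pixels must be 2D, got shape {px.shape}")
        if not self.resolution > 0:
            raise ValueError("resolution must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class ContourPair:
    """Outer and inner cortical contours bounding the ribbon to profile.

    Coordinates are (x, y) in pixel units of the image the contours belong to
    (pixel-centre convention, 0-based).  For cytoarchitectonic profiles the
    outer contour follows the layer I/II interface; for receptor profiles it
    follows the pial surface.
    """

    outer: np.ndarray
    inner: np.ndarray

    def __post_init__(self):
        for name in ("outer", "inner"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
                raise ValueError(f"{name} contour must be an (N>=2, 2) array")
            object.__setattr__(self, name, arr)
        out_ls = LineString(self.outer)
        in_ls = LineString(self.inner)
        if not out_ls.is_simple or not in_ls.is_simple:
            raise ValueError("contours must be simple (non-self-intersecting)")
        if out_ls.intersects(in_ls):
            raise ValueError("outer and inner contours must not cross")

    def scale(self, factor: float) -> "ContourPair":
        """Rescale coordinates, e.g. when moving onto a coarser GLI grid."""
        return ContourPair(self.outer * factor, self.inner * factor)


@dataclass(frozen=True)
class Traverse:
    """A straight depth traverse from the outer to the inner contour."""

    start: np.ndarray  # (x, y) on the outer contour
    end: np.ndarray    # (x, y) on the inner contour

    def sample(self, n: int) -> np.ndarray:
        """Return n equidistant (x, y) points from start (depth 0) to end (depth 1)."""
        t = np.linspace(0.0, 1.0, n)[:, None]
        return (1 - t) * np.asarray(self.start, float) + t * np.asarray(self.end, float)

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.asarray(self.end) - np.asarray(self.start)))


@dataclass(frozen=True)
class Profile:
    """GLI (or density) values at equidistant relative depths 0..1."""

    values: np.ndarray
    index: int = 0

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("profile needs at least 2 depth samples")
        object.__setattr__(self, "values", v)


FEATURE_NAMES = (
    "mean", "centroid", "sd", "skewness", "kurtosis",
    "d_mean", "d_centroid", "d_sd", "d_skewness", "d_kurtosis",
)


def gli_from_image(binary_cell_mask: SectionImage, field_size: float) -> SectionImage:
    """Compute a GLI image from a binarized cell-body mask.

    The mask is divided into non-overlapping square measuring fields of side
    ``field_size`` (micrometres); each output cell holds 100 x the fraction of
    cell-body pixels in its field.  Trailing rows/columns that do not fill a
    complete field are dropped.  The returned image's resolution equals the
    field size.
    """
    res = binary_cell_mask.resolution
    f = field_size / res
    if field_size <= 0 or f < 1 - 1e-9:
        raise ValueError("field_size must cover at least one pixel")
    if abs(f - round(f)) > 1e-9:
        raise ValueError("field_size must be a positive multiple of the pixel resolution")
    f = int(round(f))
    px = np.asarray(binary_cell_mask.pixels)
    vals = np.unique(px)
    if not np.all(np.isin(vals, (0, 1))):
        if np.all(np.isin(vals, (0, 255))):
            px = (px > 0).astype(float)
        else:
            raise ValueError("mask must be binary (0/1 or 0/255)")
    px = px.astype(float)
    h, w = px.shape
    if h < f or w < f:
        raise ValueError("image smaller than one measuring field")
    px = px[: (h // f) * f, : (w // f) * f]
    blocks = px.reshape(h // f, f, w // f, f)
    gli = 100.0 * blocks.mean(axis=(1, 3))
    return SectionImage(gli, resolution=field_size)


def _arclength_points(polyline: np.ndarray, fractions: np.ndarray) -> np.ndarray:
    """Points at given normalized arclength fractions along a polyline."""
    seg = np.diff(polyline, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    total = cum[-1]
    if total <= 0:
        raise ValueError("degenerate contour with zero length")
    targets = fractions * total
    x = np.interp(targets, cum, polyline[:, 0])
    y = np.interp(targets, cum, polyline[:, 1])
    return np.column_stack([x, y])


def _segments_cross(a0, a1, b0, b1) -> bool:
    """Proper intersection test for two segments (shared endpoints ignored)."""
    def orient(p, q, r):
        return (q[0] - p[0]) * (r[1] - p[1]) - (q[1] - p[1]) * (r[0] - p[0])

    d1 = orient(b0, b1, a0)
    d2 = orient(b0, b1, a1)
    d3 = orient(a0, a1, b0)
    d4 = orient(a0, a1, b1)
    return ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0))


def build_traverses(contours: ContourPair, n: int) -> list[Traverse]:
    """Construct ``n`` equidistant, mutually non-crossing depth traverses.

    Origins are spaced equally along the outer contour's arclength; each
    origin is matched to the point at the same normalized arclength fraction
    of the inner contour.  For parallel or concentric contour geometry this
    yields traverses perpendicular to the local cortical surface.
    """
    if n < 2:
        raise ValueError("need at least 2 traverses")
    fr = np.linspace(0.0, 1.0, n)
    starts = _arclength_points(contours.outer, fr)
    ends = _arclength_points(contours.inner, fr)
    traverses = [Traverse(s, e) for s, e in zip(starts, ends)]
    # adjacent traverses are the only realistic crossing risk, but check all pairs
    for i in range(n):
        for j in range(i + 1, n):
            if _segments_cross(starts[i], ends[i], starts[j], ends[j]):
                raise ValueError(f"traverses {i} and {j} cross; contour geometry too convoluted")
    return traverses


def sample_profile(gli: SectionImage, traverse: Traverse, n_depth: int = 101,
                   index: int = 0) -> Profile:
    """Sample a depth profile by bilinear interpolation along a traverse."""
    if n_depth < 2:
        raise ValueError("n_depth must be >= 2")
    pts = traverse.sample(n_depth)
    h, w = gli.shape
    x, y = pts[:, 0], pts[:, 1]
    if (x.min() < -0.5 or x.max() > w - 0.5 or y.min() < -0.5 or y.max() > h - 0.5):
        raise ValueError("traverse exits image bounds")
    vals = map_coordinates(gli.pixels.astype(float), [y, x], order=1, mode="nearest")
    return Profile(vals, index=index)


def _distribution_moments(weights: np.ndarray, x: np.ndarray) -> tuple[float, float, float, float]:
    """Centroid, SD, skewness and (non-excess) kurtosis of a frequency
    distribution with nonnegative weights over positions x."""
    total = weights.sum()
    if total <= 0:
        return 0.0, 0.0, 0.0, 0.0
    w = weights / total
    c = float(np.sum(w * x))
    var = float(np.sum(w * (x - c) ** 2))
    sd = float(np.sqrt(var))
    if sd == 0:
        return c, 0.0, 0.0, 0.0
    skew = float(np.sum(w * (x - c) ** 3) / sd ** 3)
    kurt = float(np.sum(w * (x - c) ** 4) / sd ** 4)
    return c, sd, skew, kurt


def featurize(profile: Profile) -> np.ndarray:
    """Parametrize a profile as its canonical 10-feature vector.

    Features 1-5: mean amplitude, then centroid depth, SD, skewness and
    kurtosis of the profile treated as a frequency distribution over relative
    depth 0..1.  Features 6-10: the same five quantities for the absolute
    first derivative of the profile (amplitude change per unit relative
    depth, evaluated at depth-interval midpoints).
    """
    y = profile.values
    if y.size < 3:
        raise ValueError("profile must have at least 3 samples")
    if np.any(y < 0):
        raise ValueError("profile values must be nonnegative")
    if y.sum() <= 0:
        raise ValueError("zero-mass profile: centroid undefined")
    n = y.size
    depth = np.linspace(0.0, 1.0, n)
    mean_amp = float(y.mean())
    c, sd, sk, ku = _distribution_moments(y, depth)

    dy = np.abs(np.diff(y)) * (n - 1)  # per unit relative depth
    mid = 0.5 * (depth[:-1] + depth[1:])
    d_mean = float(dy.mean())
    dc, dsd, dsk, dku = _distribution_moments(dy, mid)
    return np.array([mean_amp, c, sd, sk, ku, d_mean, dc, dsd, dsk, dku])


def featurize_ribbon(profiles: list[Profile]) -> np.ndarray:
    """Stack feature vectors for an ordered ribbon of profiles: (n, 10)."""
    return np.vstack([featurize(p) for p in profiles])


def standardize_features(vectors: np.ndarray) -> np.ndarray:
    """Standardize each feature to mean 0, SD 1 across the set.

    Constant features map to 0 by convention so no coordinate dominates or
    degenerates in subsequent multivariate comparisons.
    """
    arr = np.asarray(vectors, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need at least 2 feature vectors")
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=0)
    out = np.zeros_like(arr)
    nz = sd > 0
    out[:, nz] = (arr[:, nz] - mean[nz]) / sd[nz]
    return out
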