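"""The 15-parameter morphometric panel for single-cell binary images.

The panel quantifies three aspects of microglial shape:

* **complexity** — box-counting fractal dimension, lacunarity, roughness,
  cell perimeter, convex hull perimeter;
* **size** — cell area, convex hull area, bounding-circle diameter,
  maximum span across the hull, mean radius, density;
* **circularity** — cell circularity, hull circularity, span ratio, and
  the coefficient of variation of the hull radius.

Measurement conventions (documented once, used everywhere):

* the fractal dimension is estimated on the *outlined* image, lacunarity
  on the *filled* image (both configurable);
* box counts use the minimum cover over a set of frozen seeded grid
  origins per scale;
* the perimeter is the length of the marching-squares 0.5-level contour
  (sub-pixel, asymptotically unbiased for smooth shapes);
* the convex hull is taken over foreground *pixel corners* (pixels as
  unit squares), which guarantees ``cell_area <= hull_area`` and hence
  ``density <= 1``;
* the minimal enclosing circle uses Welzl's algorithm over hull vertices
  in their deterministic hull order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist
from skimage.measure import find_contours, label

from .image import BinaryCellPair

__all__ = [
    "BoxCountConfig",
    "MorphometricProfile",
    "PARAMETER_GROUPS",
    "box_counts",
    "box_counting_dimension",
    "lacunarity",
    "hull_descriptors",
    "basic_descriptors",
    "perimeter_length",
    "profile_cell",
    "profile_cells",
]

#: panel grouping used for reporting and directional checks
PARAMETER_GROUPS = {
    "complexity": ("fractal_dimension", "lacunarity", "roughness",
                   "cell_perimeter", "hull_perimeter"),
    "size": ("cell_area", "hull_area", "bounding_circle_diameter",
             "max_span", "mean_radius", "density"),
    "circularity": ("cell_circularity", "hull_circularity", "span_ratio",
                    "radius_cv"),
}

_ORIGIN_SEED = 20_240_509  # frozen; grid origins are package constants


@dataclass(frozen=True)
class BoxCountConfig:
    """Frozen settings of the box-counting scan.

    ``scales`` defaults to powers of two from 2 px up to a quarter of the
    smaller image side.  ``n_grid_positions`` grid origins are tried per
    scale (the first is always (0, 0), the rest are frozen seeded
    offsets); the reported count per scale is the minimum over origins
    (a grid-offset minimal cover).  ``aggregate="mean"`` averages instead.
    """

    scales: tuple[int, ...] | None = None
    n_grid_positions: int = 4
    use_outline_for_dimension: bool = True
    aggregate: str = "min"

    def __post_init__(self):
        if self.scales is not None:
            s = tuple(self.scales)
            if len(s) < 2 or any(b <= a for a, b in zip(s, s[1:])) or s[0] < 1:
                raise ValueError("scales must be >=2 strictly increasing box sizes")
        if self.n_grid_positions < 1:
            raise ValueError("need at least one grid position")
        if self.aggregate not in ("min", "mean"):
            raise ValueError("aggregate must be 'min' or 'mean'")

    def resolve_scales(self, shape: tuple[int, int]) -> tuple[int, ...]:
        if self.scales is not None:
            return tuple(self.scales)
        limit = max(min(shape) // 4, 2)
        scales, s = [], 2
        while s <= limit:
            scales.append(s)
            s *= 2
        if len(scales) < 2:
            raise ValueError("image too small for box counting")
        return tuple(scales)

    def origins(self, scale: int) -> list[tuple[int, int]]:
        rng = np.random.default_rng([_ORIGIN_SEED, scale])
        out = [(0, 0)]
        while len(out) < self.n_grid_positions:
            out.append(tuple(int(v) for v in rng.integers(0, scale, size=2)))
        return out


class BoxCountFit(NamedTuple):
    dimension: float
    r_squared: float
    scales: tuple[int, ...]
    counts: tuple[float, ...]


def _grid_box_masses(img: np.ndarray, scale: int, origin: tuple[int, int]) -> np.ndarray:
    """Per-box foreground pixel counts for one grid placement.

    The grid is anchored at ``origin`` (offset into the first box); the
    image is padded with background so partial boxes at every edge are
    counted as boxes.
    """
    oy, ox = origin
    h, w = img.shape
    ph = (-(h + oy)) % scale
    pw = (-(w + ox)) % scale
    padded = np.zeros((h + oy + ph, w + ox + pw), dtype=img.dtype)
    padded[oy:oy + h, ox:ox + w] = img
    H, W = padded.shape
    return padded.reshape(H // scale, scale, W // scale, scale).sum(axis=(1, 3))


def box_counts(
    img: np.ndarray, scale: int, config: BoxCountConfig = BoxCountConfig()
) -> list[int]:
    """Number of occupied boxes at one scale, one value per grid origin."""
    img = np.asarray(img, dtype=bool)
    return [int(np.count_nonzero(_grid_box_masses(img, scale, o)))
            for o in config.origins(scale)]


def box_counting_dimension(
    outlined: np.ndarray, config: BoxCountConfig = BoxCountConfig()
) -> BoxCountFit:
    """Box-counting (Minkowski) dimension of a binary set.

    Least-squares slope of log(box count) against log(box size); the
    count per scale aggregates the frozen grid origins (minimum by
    default).  Returns the dimension (negated slope) with the fit R².

    Raises ``ValueError`` on an empty image or fewer than two usable
    scales.
    """
    img = np.asarray(outlined, dtype=bool)
    if not img.any():
        raise ValueError("empty image")
    scales = config.resolve_scales(img.shape)
    agg = min if config.aggregate == "min" else (lambda v: sum(v) / len(v))
    counts = [float(agg(box_counts(img, s, config))) for s in scales]
    usable = [(s, c) for s, c in zip(scales, counts) if c >= 1]
    if len(usable) < 2:
        raise ValueError("fewer than 2 usable scales")
    x = np.log([s for s, _ in usable])
    y = np.log([c for _, c in usable])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0
    return BoxCountFit(dimension=-float(slope), r_squared=r2,
                       scales=tuple(s for s, _ in usable),
                       counts=tuple(c for _, c in usable))


def lacunarity(
    filled: np.ndarray, config: BoxCountConfig = BoxCountConfig()
) -> float:
    """Mean squared coefficient of variation of per-box mass, (σ/μ)².

    For each scale and grid origin, boxes lying fully inside the frame
    and intersecting the foreground bounding box contribute their pixel
    mass; Λ(scale, origin) = (σ/μ)² over those masses and the result is
    the mean over all scales and origins.  A translation-invariant set
    (e.g. a fully filled frame) scores 0; heterogeneous mass scores
    higher.
    """
    img = np.asarray(filled, dtype=bool)
    if not img.any():
        raise ValueError("empty image")
    rows = np.any(img, axis=1).nonzero()[0]
    cols = np.any(img, axis=0).nonzero()[0]
    r0, r1, c0, c1 = rows[0], rows[-1] + 1, cols[0], cols[-1] + 1
    h, w = img.shape
    values = []
    for scale in config.resolve_scales(img.shape):
        for oy, ox in config.origins(scale):
            # complete boxes only: the first full box starts (-o) mod scale
            sy, sx = (-oy) % scale, (-ox) % scale
            my, mx = (h - sy) // scale, (w - sx) // scale
            if my < 1 or mx < 1:
                continue
            block = img[sy:sy + my * scale, sx:sx + mx * scale]
            masses = block.reshape(my, scale, mx, scale).sum(axis=(1, 3))
            # keep boxes intersecting the foreground bounding box
            i_lo = max(0, (r0 - sy) // scale)
            i_hi = min(my - 1, (r1 - 1 - sy) // scale)
            j_lo = max(0, (c0 - sx) // scale)
            j_hi = min(mx - 1, (c1 - 1 - sx) // scale)
            if i_hi < i_lo or j_hi < j_lo:
                continue
            sub = masses[i_lo:i_hi + 1, j_lo:j_hi + 1].astype(float).ravel()
            mu = sub.mean()
            if mu > 0:
                values.append(float(sub.var()) / (mu * mu))
    if not values:
        raise ValueError("no usable boxes for lacunarity")
    return float(np.mean(values))


# ---------------------------------------------------------------------------
# hull geometry
# ---------------------------------------------------------------------------

def _corner_points(filled: np.ndarray) -> np.ndarray:
    """Corners (x, y) of boundary pixels, treating pixels as unit squares."""
    from .image import outline_of
    ys, xs = np.nonzero(outline_of(filled))
    if len(ys) == 0:
        raise ValueError("empty image")
    corners = np.empty((4 * len(ys), 2), dtype=float)
    for i, (dy, dx) in enumerate(((-0.5, -0.5), (-0.5, 0.5), (0.5, -0.5), (0.5, 0.5))):
        corners[i * len(ys):(i + 1) * len(ys), 0] = xs + dx
        corners[i * len(ys):(i + 1) * len(ys), 1] = ys + dy
    return np.unique(corners, axis=0)


def _welzl_circle(points: np.ndarray) -> tuple[float, float, float]:
    """Minimal enclosing circle (cx, cy, r) by Welzl's algorithm.

    Points are processed in their given (deterministic) order; no
    shuffling, so results are reproducible across runs and platforms.
    """
    pts = [tuple(p) for p in points]

    def circle_two(a, b):
        cx, cy = (a[0] + b[0]) / 2, (a[1] + b[1]) / 2
        r = math.dist(a, b) / 2
        return (cx, cy, r)

    def circle_three(a, b, c):
        ax, ay = a; bx, by = b; cx_, cy_ = c
        d = 2 * (ax * (by - cy_) + bx * (cy_ - ay) + cx_ * (ay - by))
        if abs(d) < 1e-12:
            return None
        ux = ((ax ** 2 + ay ** 2) * (by - cy_) + (bx ** 2 + by ** 2) * (cy_ - ay)
              + (cx_ ** 2 + cy_ ** 2) * (ay - by)) / d
        uy = ((ax ** 2 + ay ** 2) * (cx_ - bx) + (bx ** 2 + by ** 2) * (ax - cx_)
              + (cx_ ** 2 + cy_ ** 2) * (bx - ax)) / d
        return (ux, uy, math.dist((ux, uy), a))

    def inside(circ, p, eps=1e-9):
        return circ is not None and math.dist((circ[0], circ[1]), p) <= circ[2] + eps

    def from_boundary(boundary):
        if not boundary:
            return (0.0, 0.0, 0.0)
        if len(boundary) == 1:
            return (*boundary[0], 0.0)
        if len(boundary) == 2:
            return circle_two(*boundary)
        return circle_three(*boundary)

    # iterative move-to-front Welzl
    def mec(ps, boundary):
        circ = from_boundary(boundary)
        if len(boundary) == 3:
            return circ
        for i, p in enumerate(ps):
            if not inside(circ, p):
                circ = mec(ps[:i], boundary + [p])
        return circ

    import sys
    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10 * len(pts) + 1000))
    try:
        return mec(pts, [])
    finally:
        sys.setrecursionlimit(old)


def hull_descriptors(filled: np.ndarray) -> dict[str, float]:
    """Convex-hull shape descriptors of a filled mask.

    The hull is computed over the corners of boundary pixels (pixels as
    unit squares), so the hull always contains the whole silhouette.
    Returns ``hull_area``, ``hull_perimeter``, ``max_span`` (largest
    pairwise hull-vertex distance), ``bounding_circle_diameter`` (minimal
    enclosing circle of the hull vertices), ``mean_radius`` (mean distance
    from the hull's polygon centroid to its vertices), ``radius_cv``
    (sd/mean of those distances) and ``span_ratio`` = max_span /
    (2 · mean_radius).

    Raises ``ValueError("degenerate hull")`` for collinear input.
    """
    pts = _corner_points(np.asarray(filled, dtype=bool))
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:  # pragma: no cover - corners are never collinear
        raise ValueError("degenerate hull") from exc
    verts = pts[hull.vertices]  # counter-clockwise order
    hull_area = float(hull.volume)   # in 2-D, volume is the area
    hull_perimeter = float(hull.area)  # and area is the perimeter
    max_span = float(pdist(verts).max()) if len(verts) > 1 else 0.0

    cx, cy, r = _welzl_circle(verts)

    # polygon (area) centroid of the hull
    x, y = verts[:, 0], verts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a6 = 3.0 * cross.sum()
    centroid = (float(((x + xn) * cross).sum() / a6),
                float(((y + yn) * cross).sum() / a6))
    radii = np.hypot(verts[:, 0] - centroid[0], verts[:, 1] - centroid[1])
    mean_radius = float(radii.mean())
    radius_cv = float(radii.std(ddof=0) / mean_radius) if mean_radius > 0 else 0.0

    return {
        "hull_area": hull_area,
        "hull_perimeter": hull_perimeter,
        "max_span": max_span,
        "bounding_circle_diameter": 2.0 * r,
        "mean_radius": mean_radius,
        "radius_cv": radius_cv,
        "span_ratio": max_span / (2.0 * mean_radius) if mean_radius > 0 else 0.0,
    }


def perimeter_length(filled: np.ndarray, smooth_sigma: float = 1.0) -> float:
    """Cell perimeter: length of the 0.5-level contour of the smoothed mask.

    The mask is Gaussian-smoothed (``smooth_sigma`` px) before extracting
    the marching-squares 0.5-level contour; sub-pixel interpolation on the
    smoothed field removes the staircase bias of chain-code estimators
    (a raw digital disk otherwise reads ~5% long, pushing its circularity
    down to ~0.89).  With the default sigma the estimator is accurate to
    ~1-2% on disks, squares and crosses.  Structures thinner than ~1.5 px
    fall below the 0.5 level and do not contribute; silhouettes in this
    package use 2-px strokes.
    """
    img = np.asarray(filled, dtype=float)
    padded = np.pad(img, max(1, int(4 * smooth_sigma)))  # closed contours at edges
    if smooth_sigma > 0:
        padded = ndimage.gaussian_filter(padded, sigma=smooth_sigma)
    total = 0.0
    for contour in find_contours(padded, 0.5):
        diffs = np.diff(contour, axis=0)
        total += float(np.hypot(diffs[:, 0], diffs[:, 1]).sum())
    if total == 0.0:
        raise ValueError("zero perimeter")
    return total


def basic_descriptors(pair: BinaryCellPair) -> dict[str, float]:
    """Area, perimeter and the ratio descriptors derived from the hull.

    ``density`` = cell_area / hull_area; ``roughness`` = cell_perimeter /
    hull_perimeter; circularity = 4π·area/perimeter², evaluated for the
    cell mask and for its convex hull.
    """
    hull = hull_descriptors(pair.filled)
    cell_area = float(np.count_nonzero(pair.filled))
    cell_perimeter = perimeter_length(pair.filled)
    return {
        "cell_area": cell_area,
        "cell_perimeter": cell_perimeter,
        "density": cell_area / hull["hull_area"],
        "roughness": cell_perimeter / hull["hull_perimeter"],
        "cell_circularity": 4.0 * math.pi * cell_area / cell_perimeter ** 2,
        "hull_circularity": 4.0 * math.pi * hull["hull_area"]
                            / hull["hull_perimeter"] ** 2,
    }


@dataclass(frozen=True)
class MorphometricProfile:
    """The full 15-parameter panel for one cell, plus QC fields."""

    cell_id: str
    # complexity
    fractal_dimension: float
    lacunarity: float
    roughness: float
    cell_perimeter: float
    hull_perimeter: float
    # size
    cell_area: float
    hull_area: float
    bounding_circle_diameter: float
    max_span: float
    mean_radius: float
    density: float
    # circularity / shape diagnostics
    cell_circularity: float
    hull_circularity: float
    span_ratio: float
    radius_cv: float
    # QC
    fit_r_squared: float = float("nan")
    n_components: int = 1

    PARAMETERS = tuple(p for group in PARAMETER_GROUPS.values() for p in group)

    def as_dict(self) -> dict:
        return asdict(self)


def profile_cell(
    pair: BinaryCellPair, config: BoxCountConfig = BoxCountConfig()
) -> MorphometricProfile:
    """Measure the complete panel on one filled/outlined pair."""
    fd_img = pair.outlined if config.use_outline_for_dimension else pair.filled
    fit = box_counting_dimension(fd_img, config)
    lac = lacunarity(pair.filled, config)
    hull = hull_descriptors(pair.filled)
    basic = basic_descriptors(pair)
    n_comp = label(pair.filled, connectivity=2, return_num=True)[1]
    return MorphometricProfile(
        cell_id=pair.cell_id,
        fractal_dimension=fit.dimension,
        lacunarity=lac,
        roughness=basic["roughness"],
        cell_perimeter=basic["cell_perimeter"],
        hull_perimeter=hull["hull_perimeter"],
        cell_area=basic["cell_area"],
        hull_area=hull["hull_area"],
        bounding_circle_diameter=hull["bounding_circle_diameter"],
        max_span=hull["max_span"],
        mean_radius=hull["mean_radius"],
        density=basic["density"],
        cell_circularity=basic["cell_circularity"],
        hull_circularity=basic["hull_circularity"],
        span_ratio=hull["span_ratio"],
        radius_cv=hull["radius_cv"],
        fit_r_squared=fit.r_squared,
        n_components=n_comp,
    )


def profile_cells(
    pairs: list[BinaryCellPair], config: BoxCountConfig = BoxCountConfig()
) -> pd.DataFrame:
    """Panel for many cells as a DataFrame, one row per cell."""
    rows = [profile_cell(p, config).as_dict() for p in pairs]
    return pd.DataFrame(rows).set_index("cell_id")
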