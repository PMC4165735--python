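"""Speeded-Up Robust Features (SURF) for grayscale range images.

The detector is the Fast-Hessian: box-filter approximations of the
second-order Gaussian derivatives are evaluated through an integral image,
and the (weighted) determinant of the approximated Hessian is maximized
over position and scale.  Scale space is built from the classical SURF
filter-size ladder (9, 15, 21, 27 in the first octave, doubling steps in
later octaves); the per-size response maps are merged into a single sorted
scale stack and candidates are strict 3x3x3 local maxima in that stack,
refined to sub-pixel/sub-scale position by iterated 3D quadratic
interpolation.  Using one global stack (rather than per-octave stacks with
overlapping filter sizes) means an isolated blob yields exactly one
detection instead of near-duplicates in adjacent octaves.

The descriptor is the standard 64-dimensional SURF vector: a 20s x 20s
window oriented along the dominant Haar-response direction (or upright),
split into 4x4 subregions of 5x5 samples, each subregion contributing
(sum dx, sum |dx|, sum dy, sum |dy|) of Gaussian-weighted Haar wavelet
responses, with the final vector L2-normalized.

Everything here is deterministic; there is no randomness in detection,
description or matching.

Image conventions follow the renderer: x right, y down, pixel centers at
half-integer positions; angles are measured with atan2(dy, dx) in this
frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import cdist

from .errors import ContractError, ParameterError, ProtoviewError
from .multiview import ViewImage

__all__ = [
    "SurfParams",
    "InterestPoint",
    "SurfDescriptor",
    "DegenerateDescriptorError",
    "integral_image",
    "box_sum",
    "detect_interest_points",
    "assign_orientation",
    "compute_descriptor",
    "extract_features",
    "match_features",
]

BASE_SCALE = 1.2  # sigma of the 9x9 filter
DXY_WEIGHT = 0.9  # balance weight in det(H) = Dxx*Dyy - (0.9*Dxy)^2


class DegenerateDescriptorError(ProtoviewError):
    """The descriptor window carries no gray-level energy."""


@dataclass(frozen=True)
class SurfParams:
    """Detection/description configuration.

    ``hessian_threshold`` applies to the box-filter determinant on
    intensities in [0, 1]; the 4e-4 default is the classical OpenSURF
    operating point, which suppresses the weak secondary lobes a box-filter
    determinant produces around an isolated blob while retaining gray-level
    structure in rendered range images.
    """

    hessian_threshold: float = 4e-4
    octaves: int = 4
    intervals_per_octave: int = 4
    upright: bool = False


@dataclass(frozen=True)
class InterestPoint:
    """A detected blob: sub-pixel location, SURF scale (sigma), and metadata."""

    x: float
    y: float
    scale: float
    response: float
    laplacian_sign: int
    orientation: float = 0.0


@dataclass(frozen=True)
class SurfDescriptor:
    """64-component local descriptor attached to an interest point."""

    values: np.ndarray
    point: InterestPoint

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (64,):
            raise ValueError("SURF descriptor has 64 components")
        object.__setattr__(self, "values", v)


# ---------------------------------------------------------------------------
# integral image


def integral_image(image: ViewImage | np.ndarray) -> np.ndarray:
    """(H+1, W+1) cumulative-sum table; entry (i, j) sums pixels above-left.

    Any axis-aligned rectangle sum then costs four lookups (:func:`box_sum`).
    """
    pixels = image.pixels if isinstance(image, ViewImage) else np.asarray(image, dtype=float)
    h, w = pixels.shape
    table = np.zeros((h + 1, w + 1))
    np.cumsum(np.cumsum(pixels, axis=0), axis=1, out=table[1:, 1:])
    return table


def box_sum(table: np.ndarray, row: int, col: int, rows: int, cols: int) -> float:
    """Sum of the ``rows x cols`` pixel rectangle with top-left pixel (row, col).

    The rectangle is clipped to the image, matching zero-padding semantics.
    """
    h, w = table.shape[0] - 1, table.shape[1] - 1
    r0 = min(max(row, 0), h)
    c0 = min(max(col, 0), w)
    r1 = min(max(row + rows, 0), h)
    c1 = min(max(col + cols, 0), w)
    if r1 <= r0 or c1 <= c0:
        return 0.0
    return float(table[r1, c1] - table[r0, c1] - table[r1, c0] + table[r0, c0])


def _filter_sizes(octaves: int, intervals: int) -> list[int]:
    """Classical SURF filter-size ladder, deduplicated and sorted."""
    sizes: set[int] = set()
    for o in range(octaves):
        base = 3 * 2 ** (o + 1) + 3       # 9, 15, 27, 51, ...
        step = 6 * 2 ** o                 # 6, 12, 24, 48, ...
        for i in range(intervals):
            sizes.add(base + step * i)
    return sorted(sizes)


def _response_maps(table: np.ndarray, size: int) -> tuple[np.ndarray, np.ndarray] | None:
    """Determinant and trace maps for one box-filter size, full image frame.

    Entries where the filter does not fit are -inf (det) / 0 (trace).
    Returns None when the filter exceeds the image.
    """
    h, w = table.shape[0] - 1, table.shape[1] - 1
    b = (size - 1) // 2
    lobe = size // 3
    n_r, n_c = h - 2 * b, w - 2 * b
    if n_r <= 0 or n_c <= 0:
        return None

    def box(dr: int, dc: int, rows: int, cols: int) -> np.ndarray:
        r0, c0 = b + dr, b + dc
        return (
            table[r0 + rows : r0 + rows + n_r, c0 + cols : c0 + cols + n_c]
            - table[r0 : r0 + n_r, c0 + cols : c0 + cols + n_c]
            - table[r0 + rows : r0 + rows + n_r, c0 : c0 + n_c]
            + table[r0 : r0 + n_r, c0 : c0 + n_c]
        )

    half_lobe = (lobe - 1) // 2
    dyy = box(-b, -(lobe - 1), size, 2 * lobe - 1) - 3.0 * box(
        -half_lobe, -(lobe - 1), lobe, 2 * lobe - 1
    )
    dxx = box(-(lobe - 1), -b, 2 * lobe - 1, size) - 3.0 * box(
        -(lobe - 1), -half_lobe, 2 * lobe - 1, lobe
    )
    dxy = (
        box(-lobe, 1, lobe, lobe)
        + box(1, -lobe, lobe, lobe)
        - box(-lobe, -lobe, lobe, lobe)
        - box(1, 1, lobe, lobe)
    )
    inv_area = 1.0 / (size * size)
    dxx = dxx * inv_area
    dyy = dyy * inv_area
    dxy = dxy * inv_area

    det = np.full((h, w), -np.inf)
    trace = np.zeros((h, w))
    det[b : b + n_r, b : b + n_c] = dxx * dyy - (DXY_WEIGHT * dxy) ** 2
    trace[b : b + n_r, b : b + n_c] = dxx + dyy
    return det, trace


def detect_interest_points(
    table: np.ndarray,
    hessian_threshold: float = SurfParams.hessian_threshold,
    octaves: int = SurfParams.octaves,
    intervals_per_octave: int = SurfParams.intervals_per_octave,
) -> list[InterestPoint]:
    """Fast-Hessian detection on an integral image.

    Candidates are strict 3x3x3 maxima of the determinant stack above
    ``hessian_threshold`` (plateau ties yield no detection); each is
    refined by up to 5 rounds of 3D quadratic interpolation and discarded
    if the refined offset still exceeds 0.5 in any dimension.

    Returned points are sorted by (response descending, y, x).
    """
    if hessian_threshold < 0:
        raise ParameterError("hessian_threshold must be non-negative")
    h, w = table.shape[0] - 1, table.shape[1] - 1
    if min(h, w) < 9:
        raise ContractError("image too small for the 9x9 base filter")

    sizes = [s for s in _filter_sizes(octaves, intervals_per_octave) if s <= min(h, w)]
    if len(sizes) < 3:
        return []
    maps = [_response_maps(table, s) for s in sizes]
    det = np.stack([m[0] for m in maps])      # (S, H, W)
    trace = np.stack([m[1] for m in maps])

    # strict 3x3x3 maxima with a fully valid neighborhood
    footprint = np.ones((3, 3, 3), dtype=bool)
    footprint[1, 1, 1] = False
    neigh_max = ndimage.maximum_filter(det, footprint=footprint, mode="constant", cval=np.inf)
    neigh_min = ndimage.minimum_filter(det, size=3, mode="constant", cval=-np.inf)
    valid_center = neigh_min > -np.inf
    cand = (det > hessian_threshold) & (det > neigh_max) & valid_center
    cand[0] = cand[-1] = False

    points: list[InterestPoint] = []
    s_idx, rows, cols = np.nonzero(cand)
    for s, r, c in zip(s_idx.tolist(), rows.tolist(), cols.tolist()):
        refined = _interpolate_extremum(det, valid_center, s, r, c)
        if refined is None:
            continue
        s_f, y_f, x_f, value, (sb, rb, cb) = refined
        step = (sizes[min(sb + 1, len(sizes) - 1)] - sizes[max(sb - 1, 0)]) / 2.0
        size_f = sizes[sb] + (s_f - sb) * step
        scale = BASE_SCALE * size_f / 9.0
        if not (0 <= x_f < w and 0 <= y_f < h):
            continue
        lap = 1 if trace[sb, rb, cb] >= 0 else -1
        points.append(
            InterestPoint(x=x_f, y=y_f, scale=scale, response=value, laplacian_sign=lap)
        )
    points.sort(key=lambda p: (-p.response, p.y, p.x))
    return points


def _interpolate_extremum(
    det: np.ndarray, valid: np.ndarray, s: int, r: int, c: int
) -> tuple[float, float, float, float, tuple[int, int, int]] | None:
    """Iterated 3D quadratic refinement of a scale-space extremum.

    Returns (s_refined, y_refined, x_refined, interpolated response,
    final integer base) or None when refinement walks off the valid
    region or never settles within half a cell.
    """
    n_s, n_r, n_c = det.shape
    for _ in range(5):
        cube = det[s - 1 : s + 2, r - 1 : r + 2, c - 1 : c + 2]
        ds = (cube[2, 1, 1] - cube[0, 1, 1]) / 2.0
        dy = (cube[1, 2, 1] - cube[1, 0, 1]) / 2.0
        dx = (cube[1, 1, 2] - cube[1, 1, 0]) / 2.0
        dss = cube[2, 1, 1] + cube[0, 1, 1] - 2 * cube[1, 1, 1]
        dyy = cube[1, 2, 1] + cube[1, 0, 1] - 2 * cube[1, 1, 1]
        dxx = cube[1, 1, 2] + cube[1, 1, 0] - 2 * cube[1, 1, 1]
        dsy = (cube[2, 2, 1] - cube[2, 0, 1] - cube[0, 2, 1] + cube[0, 0, 1]) / 4.0
        dsx = (cube[2, 1, 2] - cube[2, 1, 0] - cube[0, 1, 2] + cube[0, 1, 0]) / 4.0
        dyx = (cube[1, 2, 2] - cube[1, 2, 0] - cube[1, 0, 2] + cube[1, 0, 0]) / 4.0
        hess = np.array([[dss, dsy, dsx], [dsy, dyy, dyx], [dsx, dyx, dxx]])
        grad = np.array([ds, dy, dx])
        try:
            offset = -np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            return None
        if np.all(np.abs(offset) <= 0.5):
            value = float(cube[1, 1, 1] + 0.5 * grad @ offset)
            return s + float(offset[0]), r + float(offset[1]), c + float(offset[2]), value, (s, r, c)
        s2 = int(np.clip(s + round(float(offset[0])), 1, n_s - 2))
        r2 = int(np.clip(r + round(float(offset[1])), 1, n_r - 2))
        c2 = int(np.clip(c + round(float(offset[2])), 1, n_c - 2))
        if (s2, r2, c2) == (s, r, c) or not valid[s2, r2, c2]:
            return None
        s, r, c = s2, r2, c2
    return None


# ---------------------------------------------------------------------------
# Haar responses (vectorized over sample arrays)


def _haar_xy(
    table: np.ndarray, ys: np.ndarray, xs: np.ndarray, half: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Haar-x / Haar-y responses of side ``2*half`` at positions (ys, xs).

    Positions are in pixel-index coordinates (pixel centers at
    half-integers); the filter is snapped to the nearest pixel *boundary*
    so its footprint is symmetric about the sample, which makes responses
    over a mirror-symmetric patch exactly antisymmetric.  The third return
    value flags samples whose filter fits inside the image.
    """
    h, w = table.shape[0] - 1, table.shape[1] - 1
    rows = np.rint(np.asarray(ys) + 0.5).astype(int)
    cols = np.rint(np.asarray(xs) + 0.5).astype(int)
    ok = (rows - half >= 0) & (rows + half <= h) & (cols - half >= 0) & (cols + half <= w)
    r = np.clip(rows, half, max(h - half, half))
    c = np.clip(cols, half, max(w - half, half))

    def rect(r0, c0, r1, c1):
        return table[r1, c1] - table[r0, c1] - table[r1, c0] + table[r0, c0]

    right = rect(r - half, c, r + half, c + half)
    left = rect(r - half, c - half, r + half, c)
    down = rect(r, c - half, r + half, c + half)
    up = rect(r - half, c - half, r, c + half)
    return right - left, down - up, ok


def assign_orientation(point: InterestPoint, table: np.ndarray) -> float:
    """Dominant orientation from Haar responses around the point.

    Haar filters of side 4*scale are evaluated on a circular grid of radius
    6*scale (integer steps of scale), Gaussian-weighted with sigma 2*scale;
    the orientation is the direction of the largest response-vector sum
    over a pi/3 window slid in 0.15 rad steps.  Samples whose filter
    leaves the image are skipped; with no valid sample the orientation is 0.
    """
    s = max(int(round(point.scale)), 1)
    ij = np.array([(i, j) for i in range(-5, 6) for j in range(-5, 6) if i * i + j * j < 36])
    ys = point.y + ij[:, 0] * float(s)
    xs = point.x + ij[:, 1] * float(s)
    resx, resy, ok = _haar_xy(table, ys, xs, 2 * s)
    if not ok.any():
        return 0.0
    weight = np.exp(-(ij[:, 0] ** 2 + ij[:, 1] ** 2) / 8.0)  # sigma = 2*scale, steps of scale
    resx = resx * weight
    resy = resy * weight
    resx, resy = resx[ok], resy[ok]
    angles = np.mod(np.arctan2(resy, resx), 2 * math.pi)

    best_norm2 = -1.0
    best_angle = 0.0
    for start in np.arange(0.0, 2 * math.pi, 0.15):
        end = start + math.pi / 3
        in_win = (angles >= start) & (angles < end)
        if end > 2 * math.pi:
            in_win |= angles < end - 2 * math.pi
        if not in_win.any():
            continue
        sx = float(resx[in_win].sum())
        sy = float(resy[in_win].sum())
        norm2 = sx * sx + sy * sy
        if norm2 > best_norm2:
            best_norm2 = norm2
            best_angle = math.atan2(sy, sx)
    return float(np.mod(best_angle, 2 * math.pi))


def compute_descriptor(
    point: InterestPoint, table: np.ndarray, upright: bool = False
) -> SurfDescriptor:
    """64-d SURF descriptor of a point.

    A 20s x 20s window rotated by the point's orientation (identity when
    upright) is sampled on a 20x20 grid at step s; Haar responses of side
    2s are Gaussian-weighted (sigma 3.3s), rotated into the orientation
    frame, and pooled per 4x4 subregion as (sum dx, sum |dx|, sum dy,
    sum |dy|).  Raises ``ContractError`` when the sampling window leaves
    the image and ``DegenerateDescriptorError`` on a zero-energy window.
    """
    s = point.scale
    theta = 0.0 if upright else point.orientation
    co, si = math.cos(theta), math.sin(theta)
    idx = np.arange(-10, 10) + 0.5
    u, v = np.meshgrid(idx * s, idx * s, indexing="ij")  # point-frame offsets
    u, v = u.ravel(), v.ravel()
    gx = point.x + u * co - v * si
    gy = point.y + u * si + v * co
    half = max(int(round(s)), 1)
    rx, ry, ok = _haar_xy(table, gy, gx, half)
    if not ok.all():
        raise ContractError("descriptor window leaves the image")
    g = np.exp(-(u * u + v * v) / (2 * (3.3 * s) ** 2))
    rx = rx * g
    ry = ry * g
    dx = rx * co + ry * si     # responses in the point's frame
    dy = -rx * si + ry * co

    sub_i = (np.arange(-10, 10) + 10) // 5
    su, sv = np.meshgrid(sub_i, sub_i, indexing="ij")
    sub = (su * 4 + sv).ravel()
    values = np.zeros(64)
    for b in range(16):
        m = sub == b
        values[4 * b + 0] = dx[m].sum()
        values[4 * b + 1] = np.abs(dx[m]).sum()
        values[4 * b + 2] = dy[m].sum()
        values[4 * b + 3] = np.abs(dy[m]).sum()
    norm = float(np.linalg.norm(values))
    if norm < 1e-12:
        raise DegenerateDescriptorError("zero-energy descriptor window")
    values /= norm
    return SurfDescriptor(values=values, point=point)


def extract_features(
    image: ViewImage, params: SurfParams = SurfParams()
) -> list[SurfDescriptor]:
    """Detect interest points and describe them; the full per-image pipeline.

    Points whose descriptor window leaves the image, or whose window has no
    gray-level energy, are dropped silently.  The result is deterministically
    ordered by (response descending, y, x).  An empty list is a valid result
    (e.g. for a constant image).
    """
    table = integral_image(image)
    points = detect_interest_points(
        table,
        params.hessian_threshold,
        params.octaves,
        params.intervals_per_octave,
    )
    out: list[SurfDescriptor] = []
    for pt in points:
        if not params.upright:
            pt = replace(pt, orientation=assign_orientation(pt, table))
        try:
            out.append(compute_descriptor(pt, table, upright=params.upright))
        except (ContractError, DegenerateDescriptorError):
            continue
    return out


def match_features(
    a: np.ndarray | list[SurfDescriptor],
    b: np.ndarray | list[SurfDescriptor],
    ratio: float = 0.7,
) -> list[tuple[int, int]]:
    """Ratio-test nearest-neighbor matching from descriptor set a to b.

    Each a-descriptor is paired with its Euclidean nearest neighbor in b if
    the nearest/second-nearest distance ratio is below ``ratio``; when b has
    a single member the test degrades to an absolute cutoff of 0.5.
    One-to-many matches are suppressed by keeping the closest pair per
    b-index.  Returns (a_index, b_index) pairs.
    """
    da = _as_matrix(a)
    db = _as_matrix(b)
    if da.shape[0] == 0 or db.shape[0] == 0:
        raise ContractError("both descriptor collections must be nonempty")
    dist = cdist(da, db)
    candidates: list[tuple[float, int, int]] = []
    if db.shape[0] < 2:
        for i in range(da.shape[0]):
            if dist[i, 0] < 0.5:
                candidates.append((float(dist[i, 0]), i, 0))
    else:
        part = np.argsort(dist, axis=1)[:, :2]
        for i in range(da.shape[0]):
            j1, j2 = int(part[i, 0]), int(part[i, 1])
            d1, d2 = float(dist[i, j1]), float(dist[i, j2])
            if d2 <= 0 or d1 / d2 < ratio:
                candidates.append((d1, i, j1))
    best: dict[int, tuple[float, int]] = {}
    for d1, i, j in candidates:
        if j not in best or d1 < best[j][0]:
            best[j] = (d1, i)
    return sorted((i, j) for j, (_, i) in best.items())


def save_features(
    store: dict[tuple[str, int], list[SurfDescriptor]], path
) -> None:
    """Persist per-view feature sets to an ``.npz`` container.

    One record per feature: x, y, scale, orientation, laplacian sign,
    response and the 64 descriptor values, stored as float64 so the values
    round-trip bit-exactly.
    """
    arrays: dict[str, np.ndarray] = {}
    for (model_id, view_id), descs in store.items():
        key = f"{model_id}|{view_id}"
        meta = np.array(
            [
                [d.point.x, d.point.y, d.point.scale, d.point.orientation,
                 d.point.laplacian_sign, d.point.response]
                for d in descs
            ],
            dtype=float,
        ).reshape(len(descs), 6)
        arrays["meta|" + key] = meta
        arrays["desc|" + key] = _as_matrix(descs) if descs else np.empty((0, 64))
    np.savez(path, **arrays)


def load_features(path) -> dict[tuple[str, int], list[SurfDescriptor]]:
    """Inverse of :func:`save_features`."""
    store: dict[tuple[str, int], list[SurfDescriptor]] = {}
    with np.load(path) as data:
        keys = sorted({k.split("|", 1)[1] for k in data.files})
        for key in keys:
            model_id, view_id = key.rsplit("|", 1)
            meta = data["meta|" + key]
            desc = data["desc|" + key]
            descs = [
                SurfDescriptor(
                    values=desc[i],
                    point=InterestPoint(
                        x=meta[i, 0], y=meta[i, 1], scale=meta[i, 2],
                        orientation=meta[i, 3], laplacian_sign=int(meta[i, 4]),
                        response=meta[i, 5],
                    ),
                )
                for i in range(meta.shape[0])
            ]
            store[(model_id, int(view_id))] = descs
    return store


def _as_matrix(descs: np.ndarray | list[SurfDescriptor]) -> np.ndarray:
    if isinstance(descs, np.ndarray):
        return np.atleast_2d(np.asarray(descs, dtype=float))
    return (
        np.array([d.values for d in descs], dtype=float)
        if descs
        else np.empty((0, 64))
    )
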