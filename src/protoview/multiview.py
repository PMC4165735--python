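"""Fourteen-viewpoint orthographic range-image rendering.

A regular octahedron centered on the model provides the camera directions:
its 6 vertices give the axis-aligned views (right/left, top/bottom,
front/rear along +-x, +-y, +-z) and its 8 face normals give the oblique
views along (+-1,+-1,+-1)/sqrt(3).  From each direction the model is
rendered as a depth-shaded sphere-impostor image: pixel intensity encodes
the distance of the nearest sphere surface from the camera (a range image),
with background exactly 0 and foreground in [0.25, 1] so silhouette edges
always contrast with the background.

Raster convention: row 0 is the image top, x grows rightward, y downward,
pixel centers sit at half-integer coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import ContractError
from .structure_io import ProteinModel, model_extent

__all__ = [
    "ViewSpec",
    "ViewImage",
    "octahedron_viewpoints",
    "render_view",
    "render_all_views",
    "save_png",
    "load_png",
]

DEFAULT_SIZE = 100
DEFAULT_FILL = 0.9
FOREGROUND_FLOOR = 0.25


@dataclass(frozen=True)
class ViewSpec:
    """One camera: looks along ``-direction`` toward the origin.

    ``kind`` is ``"axis"`` for the 6 vertex views and ``"oblique"`` for the
    8 face-normal views.  ``up`` fixes the image roll deterministically.
    """

    view_id: int
    direction: np.ndarray
    up: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        u = np.asarray(self.up, dtype=float)
        if abs(np.linalg.norm(d) - 1) > 1e-12 or abs(np.linalg.norm(u) - 1) > 1e-12:
            raise ValueError("direction and up must be unit vectors")
        if abs(float(d @ u)) > 1e-12:
            raise ValueError("up must be orthogonal to direction")
        object.__setattr__(self, "direction", d)
        object.__setattr__(self, "up", u)

    @property
    def right(self) -> np.ndarray:
        """Image x-axis in world coordinates (up x direction)."""
        return np.cross(self.up, self.direction)


@dataclass(frozen=True)
class ViewImage:
    """A square grayscale range image of one model from one viewpoint."""

    pixels: np.ndarray  # (H, W) float64 in [0, 1]
    view_id: int
    model_id: str

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.shape[0] != px.shape[1]:
            raise ValueError("view image must be square")
        object.__setattr__(self, "pixels", px)

    @property
    def size(self) -> int:
        return self.pixels.shape[0]


def _axis_up(direction: np.ndarray) -> np.ndarray:
    # +z as up except for the +-z cameras, which use +y
    if abs(direction[2]) > 0.5:
        return np.array([0.0, 1.0, 0.0])
    return np.array([0.0, 0.0, 1.0])


def _oblique_up(direction: np.ndarray) -> np.ndarray:
    z = np.array([0.0, 0.0, 1.0])
    u = z - (z @ direction) * direction
    return u / np.linalg.norm(u)


def octahedron_viewpoints() -> list[ViewSpec]:
    """The 14 canonical viewpoints, in a fixed deterministic order.

    Views 1-6 are the +-x, +-y, +-z axis directions; views 7-14 are the
    eight (+-1,+-1,+-1)/sqrt(3) face normals, signs enumerated
    lexicographically.
    """
    views: list[ViewSpec] = []
    axis_dirs = [
        (1, 0, 0), (-1, 0, 0),
        (0, 1, 0), (0, -1, 0),
        (0, 0, 1), (0, 0, -1),
    ]
    for i, d in enumerate(axis_dirs, start=1):
        direction = np.array(d, dtype=float)
        views.append(ViewSpec(i, direction, _axis_up(direction), "axis"))
    vid = 7
    s = 1.0 / math.sqrt(3.0)
    for sx in (-1, 1):
        for sy in (-1, 1):
            for sz in (-1, 1):
                direction = np.array([sx * s, sy * s, sz * s])
                views.append(ViewSpec(vid, direction, _oblique_up(direction), "oblique"))
                vid += 1
    return views


def render_view(
    model: ProteinModel,
    view: ViewSpec,
    size: int = DEFAULT_SIZE,
    fill: float = DEFAULT_FILL,
) -> ViewImage:
    """Orthographically render a normalized model from one viewpoint.

    Atoms are drawn as depth-shaded disks (sphere impostors) with
    z-buffering.  The camera sits on the ``+direction`` side; depth along
    ``direction`` is remapped so the nearest possible surface point of the
    unit bounding sphere maps to intensity 1.0 and the farthest to 0.25.
    Background stays exactly 0.  The unit sphere spans ``fill`` of the
    frame.
    """
    extent = model_extent(model)
    if extent > 1 + 1e-6:
        raise ContractError(
            f"model {model.model_id!r} is not normalized (extent {extent:.4f} > 1); "
            "call normalize_model first"
        )
    d = view.direction
    up = view.up
    right = view.right
    half = size / 2.0
    px_scale = half * fill  # pixels per world unit

    coords = model.coordinates
    u = coords @ right          # image x (world units)
    v = coords @ up             # image "up" (world units)
    depth = coords @ d          # larger = closer to camera
    radii = model.radii

    # atom centers relative to the image center (x right, y down), pixels
    tu = u * px_scale
    tv = -v * px_scale
    cx = half + tu
    cy = half + tv
    rpix = radii * px_scale

    zbuf = np.full((size, size), -np.inf)
    order = np.argsort(depth)   # draw far-to-near; max-zbuffer makes order moot
    for idx in order:
        r = rpix[idx]
        x0 = max(int(math.floor(cx[idx] - r - 0.5)), 0)
        x1 = min(int(math.ceil(cx[idx] + r - 0.5)), size - 1)
        y0 = max(int(math.floor(cy[idx] - r - 0.5)), 0)
        y1 = min(int(math.ceil(cy[idx] + r - 0.5)), size - 1)
        if x1 < x0 or y1 < y0:
            continue
        # offsets formed as (exact half-integer) - t so that mirrored and
        # 90-degree-rotated renders agree bit-for-bit
        xs = np.arange(x0, x1 + 1) + 0.5
        ys = np.arange(y0, y1 + 1) + 0.5
        dx2 = ((xs - half) - tu[idx]) ** 2
        dy2 = ((ys - half) - tv[idx]) ** 2
        rho2 = dy2[:, None] + dx2[None, :]
        mask = rho2 <= r * r
        if not mask.any():
            continue
        # front sphere surface depth, in world units
        zs = depth[idx] + np.sqrt(
            np.maximum(radii[idx] ** 2 - rho2 / (px_scale * px_scale), 0.0)
        )
        tile = zbuf[y0 : y1 + 1, x0 : x1 + 1]
        np.copyto(tile, np.maximum(tile, zs), where=mask)

    pixels = np.zeros((size, size))
    fg = zbuf > -np.inf
    # surface depth of the unit bounding sphere spans [-1, 1]
    pixels[fg] = FOREGROUND_FLOOR + (1 - FOREGROUND_FLOOR) * (zbuf[fg] + 1) / 2.0
    np.clip(pixels, 0.0, 1.0, out=pixels)
    return ViewImage(pixels=pixels, view_id=view.view_id, model_id=model.model_id)


def render_all_views(
    model: ProteinModel,
    size: int = DEFAULT_SIZE,
    fill: float = DEFAULT_FILL,
) -> list[ViewImage]:
    """Render the model from all 14 octahedron viewpoints, ordered by view id."""
    return [render_view(model, view, size=size, fill=fill) for view in octahedron_viewpoints()]


def save_png(image: ViewImage, directory: str | Path) -> Path:
    """Export a view as 8-bit grayscale PNG named ``<model_id>_v<view_id>.png``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"{image.model_id}_v{image.view_id:02d}.png"
    arr = np.rint(image.pixels * 255.0).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)
    return path


def load_png(path: str | Path) -> ViewImage:
    """Load a PNG written by :func:`save_png` back into a [0,1] float image."""
    path = Path(path)
    stem = path.stem
    model_id, _, vid = stem.rpartition("_v")
    arr = np.asarray(Image.open(path).convert("L"), dtype=float) / 255.0
    return ViewImage(pixels=arr, view_id=int(vid), model_id=model_id)
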