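"""Random initial-pressure phantoms for 2D photoacoustic tomography.

The imaging scene is a 10 x 10 mm region of interest discretised on a
128 x 128 grid (pixel pitch 78.125 um).  Ground-truth initial pressure
maps are built from randomly placed convex absorbers (triangles, squares,
rectangles) with random circumradius, peak intensity and rotation, plus an
optional vessel-like phantom made of thin branching random-walk curves.
All fields are dimensionless absorbance maps in [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GRID_SIZE",
    "PIXEL_SIZE_M",
    "PhantomSpec",
    "sample_phantom_spec",
    "polygon_vertices",
    "rasterize",
    "generate_scene",
    "generate_vessel_scene",
]

GRID_SIZE = 128
#: pixel pitch of the 10 mm / 128 grid, in metres
PIXEL_SIZE_M = 10e-3 / GRID_SIZE

RADIUS_RANGE = (5.0, 10.0)
#: aspect ratio range used for rectangles (squares are the aspect-1 case)
RECT_ASPECT_RANGE = (1.5, 3.0)
#: objects per scene when not given explicitly
N_OBJECTS_RANGE = (1, 5)
#: centres are drawn inside this radius (pixels) around the grid centre so
#: that every absorber stays inside the 4 mm transducer ring
CENTER_DISC_RADIUS = 40.0

SHAPE_KINDS = ("triangle", "square", "rectangle")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensity of one convex absorber.

    Parameters
    ----------
    shape_kind : {"triangle", "square", "rectangle"}
    center : (row, col) position of the circumcentre, in grid pixels.
    radius : circumradius in pixels, in [5, 10].
    intensity : peak absorbance, in [0, 1].
    rotation : rotation angle in radians, in [0, 2*pi).
    aspect : width/height ratio for rectangles (1 for the other kinds).
    """

    shape_kind: str
    center: tuple[float, float]
    radius: float
    intensity: float
    rotation: float
    aspect: float = 1.0

    def __post_init__(self) -> None:
        if self.shape_kind not in SHAPE_KINDS:
            raise ValueError(f"unknown shape kind {self.shape_kind!r}")
        if self.radius < 1.0:
            raise ValueError(f"degenerate polygon: radius {self.radius} < 1 px")
        if not RADIUS_RANGE[0] <= self.radius <= RADIUS_RANGE[1]:
            raise ValueError(f"radius {self.radius} outside {RADIUS_RANGE}")
        if not 0.0 <= self.intensity <= 1.0:
            raise ValueError(f"intensity {self.intensity} outside [0, 1]")
        if not 0.0 <= self.rotation < 2.0 * math.pi:
            raise ValueError(f"rotation {self.rotation} outside [0, 2*pi)")
        r, c = self.center
        if not (0 <= r < GRID_SIZE and 0 <= c < GRID_SIZE):
            raise ValueError(f"center {self.center} outside the grid")
        if self.aspect < 1.0:
            raise ValueError("aspect must be >= 1")


def sample_phantom_spec(rng: np.random.Generator) -> PhantomSpec:
    """Draw one absorber spec; kind uniform over the three shapes, radius
    uniform in [5, 10] px, intensity uniform in [0, 1], rotation uniform in
    [0, 2*pi)."""
    kind = SHAPE_KINDS[rng.integers(len(SHAPE_KINDS))]
    # centre constrained to a disc so the absorber stays within the ring
    theta = rng.uniform(0.0, 2.0 * math.pi)
    rho = CENTER_DISC_RADIUS * math.sqrt(rng.uniform())
    center = (
        GRID_SIZE / 2 + rho * math.sin(theta),
        GRID_SIZE / 2 + rho * math.cos(theta),
    )
    radius = rng.uniform(*RADIUS_RANGE)
    intensity = rng.uniform(0.0, 1.0)
    rotation = rng.uniform(0.0, 2.0 * math.pi)
    aspect = rng.uniform(*RECT_ASPECT_RANGE) if kind == "rectangle" else 1.0
    return PhantomSpec(kind, center, radius, intensity, rotation, aspect)


def polygon_vertices(spec: PhantomSpec) -> np.ndarray:
    """Vertices of the absorber polygon, shape (n_vertices, 2) as (row, col),
    counter-clockwise in (col, row) axes."""
    if spec.shape_kind == "triangle":
        angles = spec.rotation + np.deg2rad([90.0, 210.0, 330.0])
        offsets = np.stack(
            [spec.radius * np.sin(angles), spec.radius * np.cos(angles)], axis=1
        )
    else:
        if spec.shape_kind == "square":
            hw = hh = spec.radius / math.sqrt(2.0)
        else:  # rectangle with circumradius preserved
            hw = spec.radius * spec.aspect / math.hypot(1.0, spec.aspect)
            hh = spec.radius / math.hypot(1.0, spec.aspect)
        corners = np.array([[-hh, -hw], [-hh, hw], [hh, hw], [hh, -hw]])
        cos_t, sin_t = math.cos(spec.rotation), math.sin(spec.rotation)
        rot = np.array([[cos_t, -sin_t], [sin_t, cos_t]])  # acts on (row, col)
        offsets = corners @ rot.T
    return np.asarray(spec.center, dtype=float) + offsets


def _points_strictly_inside(points: np.ndarray, vertices: np.ndarray) -> np.ndarray:
    """Vectorised strict point-in-convex-polygon test.

    ``points`` is (M, 2) of (row, col); ``vertices`` (V, 2) ordered
    consistently (either orientation).  A point is inside when it lies
    strictly on the same side of every edge.
    """
    v = np.asarray(vertices, dtype=float)
    edges = np.roll(v, -1, axis=0) - v  # (V, 2)
    rel = points[:, None, :] - v[None, :, :]  # (M, V, 2)
    cross = edges[None, :, 0] * rel[:, :, 1] - edges[None, :, 1] * rel[:, :, 0]
    return np.all(cross > 0, axis=1) | np.all(cross < 0, axis=1)


def rasterize(spec: PhantomSpec, grid_size: int = GRID_SIZE) -> np.ndarray:
    """Rasterise one absorber onto the pixel grid.

    A pixel belongs to the shape when its centre (integer row/col
    coordinate) lies strictly inside the polygon; member pixels carry
    ``spec.intensity``, the rest are 0.
    """
    vertices = polygon_vertices(spec)
    rmin = max(int(np.floor(vertices[:, 0].min())), 0)
    rmax = min(int(np.ceil(vertices[:, 0].max())), grid_size - 1)
    cmin = max(int(np.floor(vertices[:, 1].min())), 0)
    cmax = min(int(np.ceil(vertices[:, 1].max())), grid_size - 1)
    field = np.zeros((grid_size, grid_size), dtype=np.float64)
    if rmin > rmax or cmin > cmax:
        return field
    rows, cols = np.mgrid[rmin : rmax + 1, cmin : cmax + 1]
    pts = np.stack([rows.ravel(), cols.ravel()], axis=1).astype(float)
    inside = _points_strictly_inside(pts, vertices).reshape(rows.shape)
    field[rmin : rmax + 1, cmin : cmax + 1] = inside * spec.intensity
    return field


def generate_scene(
    rng: np.random.Generator,
    n_objects: int | None = None,
    grid_size: int = GRID_SIZE,
) -> np.ndarray:
    """Ground-truth initial pressure: a few random absorbers, additively
    blended and clipped to [0, 1] (overlaps allowed)."""
    if n_objects is None:
        n_objects = int(rng.integers(N_OBJECTS_RANGE[0], N_OBJECTS_RANGE[1] + 1))
    if n_objects < 0:
        raise ValueError("n_objects must be >= 0")
    field = np.zeros((grid_size, grid_size), dtype=np.float64)
    for _ in range(n_objects):
        field += rasterize(sample_phantom_spec(rng), grid_size)
    return np.clip(field, 0.0, 1.0)


def generate_vessel_scene(
    rng: np.random.Generator,
    n_branches: int | None = None,
    grid_size: int = GRID_SIZE,
) -> np.ndarray:
    """Vessel-like phantom: thin (1-3 px) branching random-walk curves with
    intensity in [0.5, 1] on a dark background."""
    if n_branches is None:
        n_branches = int(rng.integers(2, 6))
    field = np.zeros((grid_size, grid_size), dtype=np.float64)
    if n_branches == 0:
        return field
    center = grid_size / 2.0
    # seed points of primary branches near the centre of the ring
    queue = []
    for _ in range(n_branches):
        pos = np.array(
            [
                center + rng.uniform(-15.0, 15.0),
                center + rng.uniform(-15.0, 15.0),
            ]
        )
        heading = rng.uniform(0.0, 2.0 * math.pi)
        queue.append((pos, heading, int(rng.integers(40, 90)), 0))
    max_depth = 2
    while queue:
        pos, heading, steps, depth = queue.pop()
        width = float(rng.integers(1, 4))
        intensity = rng.uniform(0.5, 1.0)
        for _ in range(steps):
            heading += rng.normal(0.0, 0.25)
            pos = pos + np.array([math.sin(heading), math.cos(heading)])
            if not (0 <= pos[0] < grid_size and 0 <= pos[1] < grid_size):
                break
            if math.hypot(pos[0] - center, pos[1] - center) > CENTER_DISC_RADIUS + 8:
                break
            _stamp_disc(field, pos, width / 2.0, intensity)
            if depth < max_depth and rng.uniform() < 0.02:
                fork = heading + rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 1.1)
                queue.append((pos.copy(), fork, int(rng.integers(20, 50)), depth + 1))
    return np.clip(field, 0.0, 1.0)


def _stamp_disc(field: np.ndarray, pos: np.ndarray, radius: float, value: float) -> None:
    """Paint a small disc (max-blend) centred at ``pos`` (row, col)."""
    r0 = max(int(math.floor(pos[0] - radius)), 0)
    r1 = min(int(math.ceil(pos[0] + radius)), field.shape[0] - 1)
    c0 = max(int(math.floor(pos[1] - radius)), 0)
    c1 = min(int(math.ceil(pos[1] + radius)), field.shape[1] - 1)
    if r0 > r1 or c0 > c1:
        return
    rows, cols = np.mgrid[r0 : r1 + 1, c0 : c1 + 1]
    mask = (rows - pos[0]) ** 2 + (cols - pos[1]) ** 2 <= max(radius, 0.5) ** 2
    region = field[r0 : r1 + 1, c0 : c1 + 1]
    region[mask] = np.maximum(region[mask], value)
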