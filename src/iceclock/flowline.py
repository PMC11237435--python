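"""Streamline tracing and per-segment sampling over gridded velocity fields.

A flowline is integrated downstream from a start point (typically on the
grounding line) through a 2-D velocity field, then cut into fixed-length
arc segments.  Each segment carries the quantities the layer model needs:
flow duration, vertical strain rate (from horizontal divergence via
incompressibility) and the basal melt/accretion rate sampled at the
segment midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError, StagnationError

#: Speeds below this (m/yr) are treated as stagnant flow.
STAGNATION_SPEED = 1.0


@dataclass(frozen=True)
class VelocityField:
    """Gridded 2-D velocity field.

    Parameters
    ----------
    x, y : 1-D ascending grid coordinates (m).
    u, v : velocity components (m/yr), shape ``(len(y), len(x))``.
    """

    x: np.ndarray
    y: np.ndarray
    u: np.ndarray
    v: np.ndarray

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        u = np.asarray(self.u, dtype=float)
        v = np.asarray(self.v, dtype=float)
        if np.any(np.diff(x) <= 0) or np.any(np.diff(y) <= 0):
            raise ValueError("grid coordinates must be strictly increasing")
        if u.shape != (y.size, x.size) or v.shape != (y.size, x.size):
            raise ValueError(
                f"component shape {u.shape} does not match grid "
                f"({y.size}, {x.size})"
            )
        if np.isnan(u).any() or np.isnan(v).any():
            raise ValueError("velocity components contain NaN")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "u", u)
        object.__setattr__(self, "v", v)

    def contains(self, point) -> bool:
        px, py = point
        return (self.x[0] <= px <= self.x[-1]) and (self.y[0] <= py <= self.y[-1])


@dataclass(frozen=True)
class ScalarField:
    """Gridded scalar (basal melt/accretion rate, positive = melting) with 1-sigma
    uncertainty on the same grid."""

    x: np.ndarray
    y: np.ndarray
    values: np.ndarray
    sigma: np.ndarray

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        values = np.asarray(self.values, dtype=float)
        sigma = np.asarray(self.sigma, dtype=float)
        if np.any(np.diff(x) <= 0) or np.any(np.diff(y) <= 0):
            raise ValueError("grid coordinates must be strictly increasing")
        if values.shape != (y.size, x.size) or sigma.shape != (y.size, x.size):
            raise ValueError("field shape does not match grid")
        if np.any(sigma < 0):
            raise ValueError("sigma must be non-negative")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "sigma", sigma)


@dataclass(frozen=True)
class FlowPath:
    """Ordered streamline vertices with cumulative arc length."""

    vertices: np.ndarray  # (n, 2)
    arc_length: np.ndarray  # (n,), strictly increasing, starts at 0

    @property
    def length(self) -> float:
        return float(self.arc_length[-1])


@dataclass(frozen=True)
class FlowlineSegment:
    """One arc-length segment of the flowline with midpoint-sampled forcing."""

    index: int  # 1-based along flow
    length: float  # m
    midpoint: tuple  # (x, y) m
    speed: float  # m/yr
    duration: float  # yr, = length / speed
    basal_rate: float  # m/yr, positive = melting
    basal_rate_sigma: float  # m/yr
    strain_rate: float  # 1/yr (vertical)


def _cell_index(coords: np.ndarray, value: float) -> int:
    """Index i such that coords[i] <= value <= coords[i+1]."""
    i = int(np.searchsorted(coords, value, side="right")) - 1
    return min(max(i, 0), coords.size - 2)


def _bilinear(x: np.ndarray, y: np.ndarray, grid: np.ndarray, point) -> float:
    px, py = point
    ix = _cell_index(x, px)
    iy = _cell_index(y, py)
    tx = (px - x[ix]) / (x[ix + 1] - x[ix])
    ty = (py - y[iy]) / (y[iy + 1] - y[iy])
    g00 = grid[iy, ix]
    g01 = grid[iy, ix + 1]
    g10 = grid[iy + 1, ix]
    g11 = grid[iy + 1, ix + 1]
    return float(
        g00 * (1 - tx) * (1 - ty)
        + g01 * tx * (1 - ty)
        + g10 * (1 - tx) * ty
        + g11 * tx * ty
    )


def interpolate_velocity(field: VelocityField, point) -> tuple:
    """Bilinearly sample both velocity components at ``point``.

    Raises
    ------
    DomainError
        If the point lies outside the grid's bounding box.
    """
    if not field.contains(point):
        raise DomainError(f"point {tuple(point)} outside velocity grid domain")
    return (
        _bilinear(field.x, field.y, field.u, point),
        _bilinear(field.x, field.y, field.v, point),
    )


def sample_scalar(field: ScalarField, point) -> tuple:
    """Bilinearly sample (value, sigma) of a scalar field at ``point``."""
    px, py = point
    if not (field.x[0] <= px <= field.x[-1] and field.y[0] <= py <= field.y[-1]):
        raise DomainError(f"point {tuple(point)} outside scalar grid domain")
    return (
        _bilinear(field.x, field.y, field.values, point),
        _bilinear(field.x, field.y, field.sigma, point),
    )


def vertical_strain_rate(field: VelocityField, point) -> float:
    """Vertical strain rate from horizontal divergence by incompressibility.

    Computes ``-(du/dx + dv/dy)`` with central finite differences at the four
    nodes of the grid cell containing ``point`` and interpolates bilinearly
    within the cell (exact for fields linear in x and y).

    Raises
    ------
    DomainError
        If the point is within one grid cell of the domain boundary, where
        central differences are unavailable.
    """
    if not field.contains(point):
        raise DomainError(f"point {tuple(point)} outside velocity grid domain")
    px, py = point
    ix = _cell_index(field.x, px)
    iy = _cell_index(field.y, py)
    nx, ny = field.x.size, field.y.size
    if ix < 1 or ix > nx - 3 or iy < 1 or iy > ny - 3:
        raise DomainError(
            f"point {tuple(point)} too close to grid boundary for "
            "central-difference strain rate"
        )
    div = np.empty((2, 2))
    for a, j in enumerate((iy, iy + 1)):
        for b, i in enumerate((ix, ix + 1)):
            dudx = (field.u[j, i + 1] - field.u[j, i - 1]) / (
                field.x[i + 1] - field.x[i - 1]
            )
            dvdy = (field.v[j + 1, i] - field.v[j - 1, i]) / (
                field.y[j + 1] - field.y[j - 1]
            )
            div[a, b] = dudx + dvdy
    tx = (px - field.x[ix]) / (field.x[ix + 1] - field.x[ix])
    ty = (py - field.y[iy]) / (field.y[iy + 1] - field.y[iy])
    d = (
        div[0, 0] * (1 - tx) * (1 - ty)
        + div[0, 1] * tx * (1 - ty)
        + div[1, 0] * (1 - tx) * ty
        + div[1, 1] * tx * ty
    )
    return -float(d)


def trace_flowline(
    field: VelocityField,
    start,
    step_m: float = 50.0,
    max_length_m: float = 1e6,
) -> FlowPath:
    """Integrate a streamline downstream from ``start``.

    Fixed-step 4th-order Runge-Kutta in arc length (the velocity direction
    field is integrated at unit speed, so each step advances ~``step_m`` m).
    Integration stops at the domain edge, at ``max_length_m``, or when the
    flow stagnates (speed < 1 m/yr).

    Raises
    ------
    DomainError
        If ``start`` is outside the grid.
    StagnationError
        If the flow is already stagnant at ``start``.
    """
    if step_m <= 0:
        raise ValueError("step_m must be positive")
    u0, v0 = interpolate_velocity(field, start)  # raises DomainError if outside
    if np.hypot(u0, v0) < STAGNATION_SPEED:
        raise StagnationError(
            f"speed {np.hypot(u0, v0):.3g} m/yr at start {tuple(start)} is "
            f"below the stagnation threshold ({STAGNATION_SPEED} m/yr)"
        )

    def direction(p):
        u, v = interpolate_velocity(field, p)
        s = np.hypot(u, v)
        if s < STAGNATION_SPEED:
            raise StagnationError(f"stagnant flow at {tuple(p)}")
        return np.array([u / s, v / s])

    pts = [np.asarray(start, dtype=float)]
    lengths = [0.0]
    while lengths[-1] < max_length_m:
        h = min(step_m, max_length_m - lengths[-1])
        p = pts[-1]
        try:
            k1 = direction(p)
            k2 = direction(p + 0.5 * h * k1)
            k3 = direction(p + 0.5 * h * k2)
            k4 = direction(p + h * k3)
        except (DomainError, StagnationError):
            break  # ran off the grid or into stagnant ice: terminate
        nxt = p + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if not field.contains(nxt):
            break
        pts.append(nxt)
        lengths.append(lengths[-1] + float(np.linalg.norm(nxt - p)))
    return FlowPath(np.array(pts), np.array(lengths))


def _point_at_arc_length(path: FlowPath, s: float) -> np.ndarray:
    x = np.interp(s, path.arc_length, path.vertices[:, 0])
    y = np.interp(s, path.arc_length, path.vertices[:, 1])
    return np.array([x, y])


def segment_flowline(
    path: FlowPath,
    field: VelocityField,
    basal: ScalarField,
    seg_len_m: float = 250.0,
) -> list:
    """Cut ``path`` into ``seg_len_m`` arc-length segments and sample forcing.

    Speed, vertical strain rate and basal rate (with sigma) are sampled at
    each segment midpoint; the duration is ``length / speed``.  A trailing
    remainder shorter than ``seg_len_m`` becomes a final truncated segment.

    Raises
    ------
    StagnationError
        If the midpoint speed of any segment falls below the stagnation
        threshold (the message names the segment index).
    """
    if seg_len_m <= 0:
        raise ValueError("seg_len_m must be positive")
    total = path.length
    if total < seg_len_m:
        raise ValueError(
            f"path length {total:.1f} m shorter than segment length {seg_len_m} m"
        )
    bounds = list(np.arange(0.0, total, seg_len_m))
    bounds.append(total)
    # drop a spurious final bound when total is an exact multiple
    if bounds[-1] - bounds[-2] < 1e-9 * seg_len_m:
        bounds.pop()

    segments = []
    for i in range(len(bounds) - 1):
        s0, s1 = bounds[i], bounds[i + 1]
        length = s1 - s0
        mid = _point_at_arc_length(path, 0.5 * (s0 + s1))
        u, v = interpolate_velocity(field, mid)
        speed = float(np.hypot(u, v))
        if speed < STAGNATION_SPEED:
            raise StagnationError(
                f"segment {i + 1}: midpoint speed {speed:.3g} m/yr below "
                f"stagnation threshold"
            )
        ezz = vertical_strain_rate(field, mid)
        ab, sig = sample_scalar(basal, mid)
        segments.append(
            FlowlineSegment(
                index=i + 1,
                length=float(length),
                midpoint=(float(mid[0]), float(mid[1])),
                speed=speed,
                duration=float(length / speed),
                basal_rate=ab,
                basal_rate_sigma=sig,
                strain_rate=ezz,
            )
        )
    return segments
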