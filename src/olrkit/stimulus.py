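"""Spherical dome stimulus geometry.

Random dot fields on the inside of a spherical dome, isotropic in solid
angle; a projector lookup table (LUT) mapping dome coordinates (azimuth,
elevation, in degrees) to projector pixels by per-cell bilinear
interpolation; and horizontal (yaw) dot motion with wrap-around at the
azimuth window edges.

Conventions
-----------
All angles in the public API are degrees.  Azimuth 0 is straight ahead of
the animal, positive to its right; elevation 0 is the horizon, positive
up.  Dot positions denote the *center* of a dot; a displayed dot is a
cluster of 21 partially overlapping component dots arranged in three
concentric rings (see :func:`component_dot_layout`), each of which is fed
through the LUT individually so dots stay round on the curved screen.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .exceptions import ArgumentError, GridFormatError, OutOfRangeError

__all__ = [
    "StimulusWindow",
    "DotField",
    "ProjectionLUT",
    "ComponentDotLayout",
    "DEFAULT_WINDOW",
    "cap_solid_angle",
    "sample_dot_field",
    "dot_count_for_coverage",
    "realized_coverage",
    "advance_dots",
    "animate_dot_field",
    "build_lut",
    "project",
    "component_dot_layout",
    "dot_field_frames_to_csv",
]


@dataclass(frozen=True)
class StimulusWindow:
    """Angular extent of the stimulus on the dome.

    Defaults match a dome stimulus spanning 220 degrees of azimuth and
    elevations from 10 degrees below the animal to 80 degrees above it,
    on a dome of 112 cm inner diameter.
    """

    azi_min: float = -110.0
    azi_max: float = 110.0
    ele_min: float = -10.0
    ele_max: float = 80.0
    dome_diameter_cm: float = 112.0

    def __post_init__(self) -> None:
        if not self.azi_min < self.azi_max:
            raise ArgumentError("azi_min must be < azi_max")
        if not (-90.0 < self.ele_min < self.ele_max < 90.0):
            raise ArgumentError("need -90 < ele_min < ele_max < 90")
        if self.dome_diameter_cm <= 0:
            raise ArgumentError("dome_diameter_cm must be positive")

    @property
    def azi_span(self) -> float:
        return self.azi_max - self.azi_min

    @property
    def solid_angle(self) -> float:
        """Solid angle of the window in steradians.

        For an azimuth band of width ``A`` (radians) between elevations
        ``e0 < e1``:  ``Omega = A * (sin e1 - sin e0)``.
        """
        a = np.deg2rad(self.azi_span)
        return float(a * (np.sin(np.deg2rad(self.ele_max)) - np.sin(np.deg2rad(self.ele_min))))


DEFAULT_WINDOW = StimulusWindow()


def cap_solid_angle(radius_deg: float) -> float:
    """Solid angle of a spherical cap of angular radius ``radius_deg``, in sr.

    ``Omega = 2*pi*(1 - cos r)``; used instead of the planar ``pi r**2``
    approximation (difference < 0.1% at the dot sizes used here, but the
    cap formula is the one consistent with working on the sphere).
    """
    if radius_deg <= 0:
        raise ArgumentError("dot radius must be positive")
    return float(2.0 * np.pi * (1.0 - np.cos(np.deg2rad(radius_deg))))


@dataclass(frozen=True)
class DotField:
    """Dot-center positions for one video frame."""

    azimuths: np.ndarray
    elevations: np.ndarray
    dot_radius: float
    window: StimulusWindow = DEFAULT_WINDOW

    def __post_init__(self) -> None:
        azi = np.asarray(self.azimuths, dtype=float)
        ele = np.asarray(self.elevations, dtype=float)
        object.__setattr__(self, "azimuths", azi)
        object.__setattr__(self, "elevations", ele)
        if azi.shape != ele.shape or azi.ndim != 1:
            raise ArgumentError("azimuths and elevations must be 1-D and equal length")
        if self.dot_radius <= 0:
            raise ArgumentError("dot_radius must be positive")
        w = self.window
        if azi.size:
            if azi.min() < w.azi_min - 1e-9 or azi.max() > w.azi_max + 1e-9:
                raise ArgumentError("azimuths outside the stimulus window")
            if ele.min() < w.ele_min - 1e-9 or ele.max() > w.ele_max + 1e-9:
                raise ArgumentError("elevations outside the stimulus window")

    @property
    def n_dots(self) -> int:
        return int(self.azimuths.size)


def sample_dot_field(
    n_dots: int,
    window: StimulusWindow = DEFAULT_WINDOW,
    dot_radius: float = 1.4,
    rng: np.random.Generator | int | None = None,
) -> DotField:
    """Sample ``n_dots`` dot centers isotropically within ``window``.

    Azimuth is uniform over ``[azi_min, azi_max]``.  Elevation is
    ``arcsin(U)`` with ``U`` uniform over ``[sin(ele_min), sin(ele_max)]``;
    the arcsine compensates for the shrinking circumference of horizontal
    dome cross-sections toward the zenith, so dot density is uniform per
    unit solid angle.
    """
    if n_dots < 0:
        raise ArgumentError("n_dots must be >= 0")
    gen = np.random.default_rng(rng)
    azi = gen.uniform(window.azi_min, window.azi_max, size=n_dots)
    s0, s1 = np.sin(np.deg2rad(window.ele_min)), np.sin(np.deg2rad(window.ele_max))
    ele = np.rad2deg(np.arcsin(gen.uniform(s0, s1, size=n_dots)))
    return DotField(azi, ele, dot_radius, window)


def dot_count_for_coverage(
    dot_radius: float,
    window: StimulusWindow = DEFAULT_WINDOW,
    coverage: float = 0.27,
) -> int:
    """Number of dots so that dots cover ``coverage`` of the window.

    The count is inversely proportional to dot area (spherical-cap solid
    angle), which keeps the covered fraction — and hence the mean
    luminance of the display — constant across dot sizes.
    """
    if not 0.0 <= coverage < 1.0:
        raise ArgumentError("coverage must be in [0, 1)")
    if dot_radius <= 0:
        raise ArgumentError("dot radius must be positive")
    if 2 * dot_radius >= min(window.azi_span, window.ele_max - window.ele_min):
        raise ArgumentError("dot radius too large for the stimulus window")
    return int(round(coverage * window.solid_angle / cap_solid_angle(dot_radius)))


def realized_coverage(n_dots: int, dot_radius: float, window: StimulusWindow = DEFAULT_WINDOW) -> float:
    """Fraction of the window solid angle covered by ``n_dots`` dots (overlap ignored)."""
    return n_dots * cap_solid_angle(dot_radius) / window.solid_angle


def advance_dots(field: DotField, speed: float, direction: str, dt: float) -> DotField:
    """Shift all azimuths by ``speed*dt`` in ``direction``; wrap at the window edges.

    Dots leaving the azimuth window re-enter at the opposite edge, keeping
    the dot count and coverage constant during motion.  Elevations are
    unchanged.  ``direction`` is ``"right"`` (increasing azimuth) or
    ``"left"``.
    """
    if dt <= 0:
        raise ArgumentError("dt must be positive")
    if direction not in ("left", "right"):
        raise ArgumentError(f"direction must be 'left' or 'right', got {direction!r}")
    sign = 1.0 if direction == "right" else -1.0
    w = field.window
    azi = field.azimuths + sign * speed * dt
    azi = w.azi_min + np.mod(azi - w.azi_min, w.azi_span)
    return replace(field, azimuths=azi)


def animate_dot_field(
    field: DotField, speed: float, direction: str, n_frames: int, fps: float = 60.0
) -> Iterator[DotField]:
    """Yield ``n_frames`` successive frames of ``field`` drifting at ``speed`` deg/s."""
    dt = 1.0 / fps
    for _ in range(n_frames):
        yield field
        if speed != 0:
            field = advance_dots(field, speed, direction, dt)


def dot_field_frames_to_csv(frames: Iterable[DotField], path) -> None:
    """Write frames as CSV ``frame,dot_id,azi_deg,ele_deg`` for renderer-agnostic replay."""
    rows = []
    for f_idx, f in enumerate(frames):
        rows.append(
            pd.DataFrame(
                {
                    "frame": f_idx,
                    "dot_id": np.arange(f.n_dots),
                    "azi_deg": f.azimuths,
                    "ele_deg": f.elevations,
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Projection lookup table


class ProjectionLUT:
    """Dome-to-projector lookup table.

    Built from measurements of the dome coordinates (azi, ele) of sample
    dots projected on a rectangular raster of projector pixels (x, y) —
    by default a 20 x 10 raster, 200 nodes.  Queries go in the
    (azi, ele) -> (x, y) direction: the enclosing grid cell is found and
    the forward bilinear map of that cell is inverted (Newton), which is
    exact at the nodes and exact everywhere for affine mappings.
    """

    def __init__(self, x: np.ndarray, y: np.ndarray, azi: np.ndarray, ele: np.ndarray):
        # arrays shaped (n_rows, n_cols); x varies along columns, y along rows
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.azi = np.asarray(azi, dtype=float)
        self.ele = np.asarray(ele, dtype=float)
        if not (self.x.shape == self.y.shape == self.azi.shape == self.ele.shape):
            raise GridFormatError("node arrays must share one (n_rows, n_cols) shape")
        if self.x.ndim != 2 or min(self.x.shape) < 2:
            raise GridFormatError("grid needs at least 2 rows and 2 columns")
        self._validate()

    # -- construction ------------------------------------------------------

    @classmethod
    def from_measurements(cls, measurements) -> "ProjectionLUT":
        """Build from node records ``{x, y, azi, ele}`` (any row order).

        The (x, y) values must form a complete rectangular grid; azi must
        be strictly monotone along x within every row and ele strictly
        monotone along y within every column, otherwise a
        :class:`GridFormatError` is raised.
        """
        df = pd.DataFrame(measurements)
        missing = {"x", "y", "azi", "ele"} - set(df.columns)
        if missing:
            raise GridFormatError(f"measurements lack fields: {sorted(missing)}")
        xs = np.sort(df["x"].unique())
        ys = np.sort(df["y"].unique())
        if len(df) != len(xs) * len(ys):
            raise GridFormatError("measurements do not form a complete rectangular grid")
        df = df.sort_values(["y", "x"])
        shape = (len(ys), len(xs))
        got_x = df["x"].to_numpy().reshape(shape)
        expect_x = np.tile(xs, (len(ys), 1))
        if not np.array_equal(got_x, expect_x):
            raise GridFormatError("duplicate or missing (x, y) grid nodes")
        return cls(
            expect_x,
            np.tile(ys[:, None], (1, len(xs))),
            df["azi"].to_numpy().reshape(shape),
            df["ele"].to_numpy().reshape(shape),
        )

    def _validate(self) -> None:
        dazi = np.diff(self.azi, axis=1)
        dele = np.diff(self.ele, axis=0)
        if not (np.all(dazi > 0) or np.all(dazi < 0)):
            raise GridFormatError("azimuth not monotone along the x grid axis")
        if not (np.all(dele > 0) or np.all(dele < 0)):
            raise GridFormatError("elevation not monotone along the y grid axis")

    @property
    def shape(self) -> tuple[int, int]:
        """(n_cols, n_rows)."""
        return self.x.shape[1], self.x.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.x.size

    # -- IO ----------------------------------------------------------------

    def to_csv(self, path) -> None:
        """Write ``x,y,azi,ele`` rows in row-major grid order."""
        pd.DataFrame(
            {
                "x": self.x.ravel(),
                "y": self.y.ravel(),
                "azi": self.azi.ravel(),
                "ele": self.ele.ravel(),
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ProjectionLUT":
        return cls.from_measurements(pd.read_csv(path))

    # -- projection --------------------------------------------------------

    def project(self, azi, ele) -> tuple[np.ndarray, np.ndarray]:
        """Map dome coordinates (degrees) to projector pixels.

        Raises :class:`OutOfRangeError` for queries outside every grid cell.
        Accepts scalars or arrays; returns float pixel coordinates.
        """
        azi_q = np.atleast_1d(np.asarray(azi, dtype=float))
        ele_q = np.atleast_1d(np.asarray(ele, dtype=float))
        if azi_q.shape != ele_q.shape:
            raise ArgumentError("azi and ele must have the same shape")
        out_x = np.empty(azi_q.shape)
        out_y = np.empty(azi_q.shape)
        for idx in np.ndindex(azi_q.shape):
            out_x[idx], out_y[idx] = self._project_one(azi_q[idx], ele_q[idx])
        if np.isscalar(azi) or np.ndim(azi) == 0:
            return float(out_x[0]), float(out_y[0])
        return out_x, out_y

    def _cells_near(self, a: float, e: float):
        """Candidate cells whose (azi, ele) bounding box contains the query."""
        nr, nc = self.azi.shape
        for i in range(nr - 1):
            for j in range(nc - 1):
                az = self.azi[i : i + 2, j : j + 2]
                el = self.ele[i : i + 2, j : j + 2]
                if az.min() - 1e-9 <= a <= az.max() + 1e-9 and el.min() - 1e-9 <= e <= el.max() + 1e-9:
                    yield i, j

    def _project_one(self, a: float, e: float) -> tuple[float, float]:
        for i, j in self._cells_near(a, e):
            uv = _invert_bilinear(
                self.azi[i : i + 2, j : j + 2], self.ele[i : i + 2, j : j + 2], a, e
            )
            if uv is None:
                continue
            u, v = uv
            x = _bilinear(self.x[i : i + 2, j : j + 2], u, v)
            y = _bilinear(self.y[i : i + 2, j : j + 2], u, v)
            return x, y
        raise OutOfRangeError(f"({a:.3f}, {e:.3f}) deg is outside the calibrated grid")


def _bilinear(corners: np.ndarray, u: float, v: float) -> float:
    """Bilinear interpolation on a 2x2 corner block; u along columns, v along rows."""
    (c00, c01), (c10, c11) = corners
    return (
        c00 * (1 - u) * (1 - v)
        + c01 * u * (1 - v)
        + c10 * (1 - u) * v
        + c11 * u * v
    )


def _invert_bilinear(azi_c: np.ndarray, ele_c: np.ndarray, a: float, e: float, tol: float = 1e-12):
    """Solve the 2x2-cell bilinear system for local coords (u, v) in [0, 1]^2.

    Newton from the cell center; cells of a sane calibration are near-affine
    so convergence is quadratic.  Returns None if the solution falls outside
    the cell (query belongs to a different cell).
    """
    u, v = 0.5, 0.5
    for _ in range(50):
        ra = _bilinear(azi_c, u, v) - a
        re = _bilinear(ele_c, u, v) - e
        if abs(ra) < tol and abs(re) < tol:
            break
        # Jacobian of the bilinear map
        da_du = (azi_c[0, 1] - azi_c[0, 0]) * (1 - v) + (azi_c[1, 1] - azi_c[1, 0]) * v
        da_dv = (azi_c[1, 0] - azi_c[0, 0]) * (1 - u) + (azi_c[1, 1] - azi_c[0, 1]) * u
        de_du = (ele_c[0, 1] - ele_c[0, 0]) * (1 - v) + (ele_c[1, 1] - ele_c[1, 0]) * v
        de_dv = (ele_c[1, 0] - ele_c[0, 0]) * (1 - u) + (ele_c[1, 1] - ele_c[0, 1]) * u
        det = da_du * de_dv - da_dv * de_du
        if det == 0.0:
            return None
        u -= (ra * de_dv - re * da_dv) / det
        v -= (re * da_du - ra * de_du) / det
        if not (-1.0 <= u <= 2.0 and -1.0 <= v <= 2.0):  # diverging: wrong cell
            return None
    eps = 1e-9
    if -eps <= u <= 1 + eps and -eps <= v <= 1 + eps:
        return min(max(u, 0.0), 1.0), min(max(v, 0.0), 1.0)
    return None


def build_lut(node_measurements) -> ProjectionLUT:
    """Build a :class:`ProjectionLUT` from node measurement records."""
    return ProjectionLUT.from_measurements(node_measurements)


def project(lut: ProjectionLUT, azi, ele):
    """Functional wrapper for :meth:`ProjectionLUT.project`."""
    return lut.project(azi, ele)


# ---------------------------------------------------------------------------
# Component dots


@dataclass(frozen=True)
class ComponentDotLayout:
    """Offsets (d_azi, d_ele degrees) of the 21 component dots of one dot."""

    offsets: np.ndarray  # (21, 2)
    dot_radius: float
    ring_sizes: tuple[int, ...] = (6, 7, 8)

    @property
    def count(self) -> int:
        return int(self.offsets.shape[0])

    def ring(self, k: int) -> np.ndarray:
        """Offsets of ring ``k`` (0 = innermost)."""
        start = sum(self.ring_sizes[:k])
        return self.offsets[start : start + self.ring_sizes[k]]


def component_dot_layout(dot_radius: float, edge_margin: float = 0.05) -> ComponentDotLayout:
    """Layout of the 21 component dots that render one stimulus dot.

    Three concentric rings of 6, 7 and 8 dots around the dot center, at
    radii ``r/3``, ``2r/3`` and ``r*(1 - edge_margin)``, each ring with
    evenly spaced angles starting at 0 degrees — a gap-free choice given
    that the component primitives themselves have finite extent.
    Drawing many small overlapping primitives, each individually warped
    through the projection LUT, keeps dots circular on the curved dome
    surface.
    """
    if dot_radius <= 0:
        raise ArgumentError("dot_radius must be positive")
    radii = [dot_radius / 3.0, 2.0 * dot_radius / 3.0, dot_radius * (1.0 - edge_margin)]
    counts = [6, 7, 8]
    offs = []
    for r, n in zip(radii, counts):
        ang = np.deg2rad(np.arange(n) * 360.0 / n)
        offs.append(np.column_stack([r * np.cos(ang), r * np.sin(ang)]))
    return ComponentDotLayout(np.vstack(offs), dot_radius)
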