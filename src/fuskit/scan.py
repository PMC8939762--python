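"""Raster treatment-scan planning and G-code export.

The transducer treats a cylindrical volume by visiting a square lattice of
spots inside a circle at each of several z planes, moving in a serpentine
(boustrophedon) route, dwelling at every spot, and stepping down between
planes.  The default protocol — 4.8 mm circle, 0.3 mm spot and plane
spacing, 6 planes, 0.4 s dwell, 2 mm/s travel — covers a 1.5 mm-tall
cylinder in about eleven and a half minutes.

Spot grids come in three lattice conventions, because a circle-clipped
square lattice is ambiguous about where the lattice sits relative to the
circle centre:

``centered``
    lattice points at (i*s, j*s) including the centre spot;
``half-offset``
    points at ((i+1/2)*s, (j+1/2)*s), no spot at the centre;
``rows-offset``
    rows at j*s with x offset by s/2.

Exported G-code is a minimal RS-274 subset (G21/G90/G0/G1/G4) that a
consumer 3-axis controller executes directly; :func:`parse_gcode` inverts
the export bit-exactly at the declared 3-decimal (mm) precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import GCodeError, InvalidParameterError

__all__ = [
    "ScanPlan",
    "CoverageStats",
    "plane_grid",
    "serpentine_route",
    "route_length",
    "plan_timing",
    "coverage_stats",
    "export_gcode",
    "parse_gcode",
    "laser_offset_transform",
    "build_plan",
]

GRID_CONVENTIONS = ("centered", "half-offset", "rows-offset")


def plane_grid(
    diameter_mm: float, spacing_mm: float, convention: str = "centered"
) -> np.ndarray:
    """Square-lattice spots inside a circle, row-major sorted, shape (N, 2).

    Points are kept when their distance from the circle centre is at most
    the radius (inclusive).  ``spacing > diameter`` degenerates to a
    single centre spot with a warning.
    """
    if diameter_mm <= 0 or spacing_mm <= 0:
        raise InvalidParameterError("diameter and spacing must be positive")
    if convention not in GRID_CONVENTIONS:
        raise InvalidParameterError(
            f"unknown grid convention {convention!r}; choose from {GRID_CONVENTIONS}"
        )
    radius = diameter_mm / 2.0
    if spacing_mm > diameter_mm:
        warnings.warn("spacing exceeds diameter: single-spot plan")
        return np.zeros((1, 2))
    n = int(np.ceil(radius / spacing_mm)) + 1
    idx = np.arange(-n, n + 1, dtype=float)
    if convention == "centered":
        xs = ys = idx * spacing_mm
    elif convention == "half-offset":
        xs = ys = (idx + 0.5) * spacing_mm
    else:  # rows-offset
        xs = (idx + 0.5) * spacing_mm
        ys = idx * spacing_mm
    xx, yy = np.meshgrid(xs, ys)
    keep = xx**2 + yy**2 <= radius**2 + 1e-12
    pts = np.column_stack([xx[keep], yy[keep]])
    # Row-major: by y descending, then x ascending.
    order = np.lexsort((pts[:, 0], -pts[:, 1]))
    return pts[order]


def serpentine_route(spots: np.ndarray) -> np.ndarray:
    """Reorder row-major spots into a serpentine route (alternating x).

    Rows are groups of equal y; every other row is reversed so consecutive
    spots stay adjacent.  Returns the same points, visit-ordered.
    """
    spots = np.asarray(spots, dtype=float)
    if spots.ndim != 2 or spots.shape[1] != 2 or spots.shape[0] == 0:
        raise InvalidParameterError("spots must be a non-empty (N, 2) array")
    ys = spots[:, 1]
    route = []
    flip = False
    for y in np.unique(ys)[::-1]:
        row = spots[ys == y]
        row = row[np.argsort(row[:, 0])]
        route.append(row[::-1] if flip else row)
        flip = not flip
    return np.vstack(route)


def route_length(route: np.ndarray) -> float:
    """Total Euclidean travel along a visit-ordered route, in mm."""
    route = np.asarray(route, dtype=float)
    if route.shape[0] < 2:
        return 0.0
    return float(np.sum(np.linalg.norm(np.diff(route, axis=0), axis=1)))


@dataclass(frozen=True)
class ScanPlan:
    """Complete multi-plane raster plan."""

    circle_diameter_mm: float
    spacing_mm: float
    grid_convention: str
    route: np.ndarray          # (N, 2) visit-ordered spots of one plane
    n_planes: int
    z_spacing_mm: float
    z_start_mm: float = 0.0
    z_order: str = "top-down"  # planes step from z_start by -z_spacing
    dwell_s: float = 0.4
    travel_speed_mm_s: float = 2.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dwell_s < 0 or self.travel_speed_mm_s <= 0:
            raise InvalidParameterError("dwell must be >= 0 and speed > 0")
        if self.n_planes < 1 or self.z_spacing_mm < 0:
            raise InvalidParameterError("need n_planes >= 1 and z_spacing >= 0")
        if self.z_order not in ("top-down", "bottom-up"):
            raise InvalidParameterError("z_order must be top-down or bottom-up")

    @property
    def spots_per_plane(self) -> int:
        return int(self.route.shape[0])

    @property
    def total_spots(self) -> int:
        return self.spots_per_plane * self.n_planes

    def z_planes_mm(self) -> np.ndarray:
        step = -self.z_spacing_mm if self.z_order == "top-down" else self.z_spacing_mm
        return self.z_start_mm + step * np.arange(self.n_planes)

    def route_length_mm(self) -> float:
        return route_length(self.route)

    def to_json(self) -> str:
        import json

        payload = {
            "circle_diameter_mm": self.circle_diameter_mm,
            "spacing_mm": self.spacing_mm,
            "grid_convention": self.grid_convention,
            "route": self.route.tolist(),
            "n_planes": self.n_planes,
            "z_spacing_mm": self.z_spacing_mm,
            "z_start_mm": self.z_start_mm,
            "z_order": self.z_order,
            "dwell_s": self.dwell_s,
            "travel_speed_mm_s": self.travel_speed_mm_s,
            "metadata": self.metadata,
        }
        return json.dumps(payload, indent=2)

    @staticmethod
    def from_json(text: str) -> "ScanPlan":
        import json

        payload = json.loads(text)
        payload["route"] = np.asarray(payload["route"], dtype=float)
        return ScanPlan(**payload)


def build_plan(
    circle_diameter_mm: float = 4.8,
    spacing_mm: float = 0.3,
    n_planes: int = 6,
    z_spacing_mm: float = 0.3,
    dwell_s: float = 0.4,
    travel_speed_mm_s: float = 2.0,
    grid_convention: str = "centered",
    z_start_mm: float = 0.0,
    z_order: str = "top-down",
) -> ScanPlan:
    """Plan the default circular raster protocol."""
    spots = plane_grid(circle_diameter_mm, spacing_mm, grid_convention)
    return ScanPlan(
        circle_diameter_mm=circle_diameter_mm,
        spacing_mm=spacing_mm,
        grid_convention=grid_convention,
        route=serpentine_route(spots),
        n_planes=n_planes,
        z_spacing_mm=z_spacing_mm,
        z_start_mm=z_start_mm,
        z_order=z_order,
        dwell_s=dwell_s,
        travel_speed_mm_s=travel_speed_mm_s,
    )


def plan_timing(plan: ScanPlan, spots_per_plane_override: int | None = None) -> dict:
    """Per-plane and total duration in seconds.

    total = n_planes * (spots * dwell + route_length / speed)
          + (n_planes - 1) * z_spacing / speed.

    ``spots_per_plane_override`` replaces the geometric spot count in the
    dwell term (the protocol's stated count may differ from what a given
    lattice convention reproduces); the route travel time always comes
    from the geometric route.
    """
    n_spots = (
        plan.spots_per_plane
        if spots_per_plane_override is None
        else int(spots_per_plane_override)
    )
    dwell_per_plane = n_spots * plan.dwell_s
    travel_per_plane = plan.route_length_mm() / plan.travel_speed_mm_s
    z_moves = (plan.n_planes - 1) * plan.z_spacing_mm / plan.travel_speed_mm_s
    total = plan.n_planes * (dwell_per_plane + travel_per_plane) + z_moves
    return {
        "dwell_per_plane_s": dwell_per_plane,
        "travel_per_plane_s": travel_per_plane,
        "plane_s": dwell_per_plane + travel_per_plane,
        "z_moves_s": z_moves,
        "total_s": total,
        "total_min": total / 60.0,
    }


@dataclass(frozen=True)
class CoverageStats:
    treated_volume_mm3: float
    scanned_volume_mm3: float
    total_volume_mm3: float
    treated_fraction: float
    scanned_fraction: float
    spot_volume_mm3: float
    conventions: dict


def _union_z_extent(n_planes: int, z_spacing_mm: float, height_mm: float) -> float:
    """Union length of n intervals of length h spaced dz apart."""
    if n_planes == 1:
        return height_mm
    return (n_planes - 1) * min(z_spacing_mm, height_mm) + height_mm


def coverage_stats(
    plan: ScanPlan,
    focal_diameter_um: float = 104.0,
    spot_height_mm: float | None = None,
    total_height_mm: float | None = None,
    cell_mm: float = 0.005,
) -> CoverageStats:
    """Treated / scanned / total volumes and fractions of the plan.

    Spot model: a cylinder of diameter ``focal_diameter_um`` and height
    ``spot_height_mm`` (default: the plane spacing) at every spot.
    Treated volume is the union of spot cylinders; scanned volume adds the
    beam swept along the route between spots.  Since all planes share one
    XY pattern, the unions are computed exactly as (2-D union area) x
    (union of the z intervals), with the 2-D unions rasterized on a
    ``cell_mm`` grid (5 um default).  The reference total volume is the
    plan's circle extruded over the nominal plane span
    (n_planes - 1) * z_spacing by default; treated/scanned volumes are
    counted in full even where spot cylinders poke past the reference
    cylinder, matching protocol summaries that quote nominal heights.
    """
    radius_mm = focal_diameter_um * 1e-3 / 2.0
    if spot_height_mm is None:
        spot_height_mm = plan.z_spacing_mm if plan.n_planes > 1 else 0.3
    if total_height_mm is None:
        # Nominal covered height: first-to-last plane span.
        total_height_mm = (
            (plan.n_planes - 1) * plan.z_spacing_mm
            if plan.n_planes > 1
            else spot_height_mm
        )

    route = plan.route
    if route.shape[0] == 0 or plan.dwell_s < 0:
        raise InvalidParameterError("plan has no spots")

    pad = radius_mm + 2 * cell_mm
    lo = route.min(axis=0) - pad
    hi = route.max(axis=0) + pad
    nx = int(np.ceil((hi[0] - lo[0]) / cell_mm))
    ny = int(np.ceil((hi[1] - lo[1]) / cell_mm))
    xs = lo[0] + (np.arange(nx) + 0.5) * cell_mm
    ys = lo[1] + (np.arange(ny) + 0.5) * cell_mm

    treated = np.zeros((ny, nx), dtype=bool)
    win = int(np.ceil(pad / cell_mm)) + 1
    for x, y in route:
        ix = int((x - lo[0]) / cell_mm)
        iy = int((y - lo[1]) / cell_mm)
        sl_x = slice(max(ix - win, 0), min(ix + win + 1, nx))
        sl_y = slice(max(iy - win, 0), min(iy + win + 1, ny))
        dx = xs[sl_x] - x
        dy = ys[sl_y] - y
        treated[sl_y, sl_x] |= (
            dx[None, :] ** 2 + dy[:, None] ** 2 <= radius_mm**2
        )

    scanned = treated.copy()
    for (x0, y0), (x1, y1) in zip(route[:-1], route[1:]):
        seg = np.array([x1 - x0, y1 - y0])
        seg_len2 = seg @ seg
        if seg_len2 == 0:
            continue
        ix0 = int((min(x0, x1) - radius_mm - lo[0]) / cell_mm)
        ix1 = int((max(x0, x1) + radius_mm - lo[0]) / cell_mm) + 2
        iy0 = int((min(y0, y1) - radius_mm - lo[1]) / cell_mm)
        iy1 = int((max(y0, y1) + radius_mm - lo[1]) / cell_mm) + 2
        sl_x = slice(max(ix0, 0), min(ix1, nx))
        sl_y = slice(max(iy0, 0), min(iy1, ny))
        px = xs[sl_x][None, :] - x0
        py = ys[sl_y][:, None] - y0
        t = np.clip((px * seg[0] + py * seg[1]) / seg_len2, 0.0, 1.0)
        d2 = (px - t * seg[0]) ** 2 + (py - t * seg[1]) ** 2
        scanned[sl_y, sl_x] |= d2 <= radius_mm**2

    cell_area = cell_mm**2
    z_extent = _union_z_extent(plan.n_planes, plan.z_spacing_mm, spot_height_mm)
    treated_vol = treated.sum() * cell_area * z_extent
    scanned_vol = scanned.sum() * cell_area * z_extent
    total_vol = np.pi * (plan.circle_diameter_mm / 2.0) ** 2 * total_height_mm
    spot_vol = np.pi * radius_mm**2 * spot_height_mm
    return CoverageStats(
        treated_volume_mm3=float(treated_vol),
        scanned_volume_mm3=float(scanned_vol),
        total_volume_mm3=float(total_vol),
        treated_fraction=float(treated_vol / total_vol),
        scanned_fraction=float(scanned_vol / total_vol),
        spot_volume_mm3=float(spot_vol),
        conventions={
            "spot_model": f"cylinder d={focal_diameter_um} um, h={spot_height_mm} mm",
            "total_volume": f"cylinder d={plan.circle_diameter_mm} mm, "
                            f"h={total_height_mm} mm",
            "cell_mm": cell_mm,
            "volumes_counted_in_full": True,
        },
    )


def laser_offset_transform(spots: np.ndarray, offset_mm: tuple[float, float]) -> np.ndarray:
    """Rigidly translate spot coordinates by the laser-to-transducer offset."""
    spots = np.asarray(spots, dtype=float)
    return spots + np.asarray(offset_mm, dtype=float)


_COORD_FMT = "{:.3f}"


def export_gcode(plan: ScanPlan, header_comment: str | None = None) -> str:
    """Emit the plan as RS-274 G-code text.

    G21 (mm units), G90 (absolute), G0 rapids to each plane start, G1
    moves at the plan feedrate, G4 P<ms> dwell at every spot.  Coordinates
    are written with 3 decimals (1 um resolution).
    """
    feed = plan.travel_speed_mm_s * 60.0  # mm/min
    lines = []
    if header_comment:
        lines.append(f"; {header_comment}")
    lines.append(f"; circle_diameter_mm={_COORD_FMT.format(plan.circle_diameter_mm)}"
                 f" spacing_mm={_COORD_FMT.format(plan.spacing_mm)}"
                 f" convention={plan.grid_convention} z_order={plan.z_order}")
    lines.append("G21")
    lines.append("G90")
    dwell_ms = int(round(plan.dwell_s * 1000.0))
    for z in plan.z_planes_mm():
        lines.append(f"G0 Z{_COORD_FMT.format(z)}")
        first = True
        for x, y in plan.route:
            word = "G0" if first else "G1"
            feed_word = "" if first else f" F{feed:.1f}"
            lines.append(
                f"{word} X{_COORD_FMT.format(x)} Y{_COORD_FMT.format(y)}{feed_word}"
            )
            lines.append(f"G4 P{dwell_ms}")
            first = False
    return "\n".join(lines) + "\n"


def parse_gcode(text: str) -> ScanPlan:
    """Rebuild a :class:`ScanPlan` from G-code produced by :func:`export_gcode`.

    Rejects unsupported words with their line number.  The round trip is
    exact at the 3-decimal coordinate precision.
    """
    meta: dict = {}
    z_values: list[float] = []
    routes: list[list[tuple[float, float]]] = []
    dwell_ms: int | None = None
    feed: float | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(";"):
            for token in line[1:].split():
                if "=" in token:
                    key, value = token.split("=", 1)
                    meta[key] = value
            continue
        words = line.split()
        cmd = words[0]
        args = {w[0]: w[1:] for w in words[1:]}
        if cmd in ("G21", "G90"):
            continue
        elif cmd == "G0" and "Z" in args and "X" not in args:
            z_values.append(float(args["Z"]))
            routes.append([])
        elif cmd in ("G0", "G1") and "X" in args and "Y" in args:
            if not routes:
                raise GCodeError(f"line {lineno}: XY move before any Z plane")
            routes[-1].append((float(args["X"]), float(args["Y"])))
            if "F" in args:
                feed = float(args["F"])
        elif cmd == "G4" and "P" in args:
            dwell_ms = int(args["P"])
        else:
            raise GCodeError(f"line {lineno}: unsupported G-code word {line!r}")
    if not routes or dwell_ms is None or feed is None:
        raise GCodeError("incomplete program: need planes, dwells and a feedrate")
    route = np.asarray(routes[0], dtype=float)
    for other in routes[1:]:
        if not np.array_equal(np.asarray(other), route):
            raise GCodeError("planes do not share a common route")
    z = np.asarray(z_values)
    z_spacing = float(abs(np.diff(z)).mean()) if z.size > 1 else 0.0
    z_order = "top-down" if (z.size < 2 or z[1] < z[0]) else "bottom-up"
    return ScanPlan(
        circle_diameter_mm=float(meta.get("circle_diameter_mm", "nan")),
        spacing_mm=float(meta.get("spacing_mm", "nan")),
        grid_convention=meta.get("convention", "centered"),
        route=route,
        n_planes=len(z_values),
        z_spacing_mm=z_spacing,
        z_start_mm=float(z[0]),
        z_order=z_order,
        dwell_s=dwell_ms / 1000.0,
        travel_speed_mm_s=feed / 60.0,
        metadata={"parsed": True},
    )
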