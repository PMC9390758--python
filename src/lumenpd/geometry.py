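"""Morphometrics of the residual dissected aorta.

Measurement conventions used throughout the package:

* all lengths in mm, areas in mm^2, volumes in mm^3, times in months,
  growth rates in mm/yr;
* arc positions are measured from the proximal end of the supplied
  centerline;
* cross-sectional planes are placed 20 mm distal to the left subclavian
  artery (LSA) landmark and then every 30 mm, perpendicular to the local
  centerline tangent;
* the per-plane diameter is the maximum Feret (caliper) diameter of the
  combined outer contour (true lumen + false lumen + mural thrombus); a
  short-axis (minimum caliper width) variant is available behind a flag;
* per-plane yearly growth above 2.9 mm/yr is classified as unstable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.spatial import ConvexHull
from shapely.geometry import Polygon

__all__ = [
    "UNSTABLE_GROWTH_THRESHOLD",
    "PLANE_OFFSET_MM",
    "PLANE_SPACING_MM",
    "Centerline",
    "PlaneSet",
    "Station",
    "Tear",
    "DissectionModel",
    "ScanSeries",
    "place_planes",
    "slice_contour",
    "max_diameter",
    "growth_rate",
    "classify_growth",
    "tear_census",
    "lumen_volumes",
    "volume_change",
    "measure_model",
    "tube_mesh",
]

#: yearly growth (mm/yr) above which an aortic segment is labelled unstable
UNSTABLE_GROWTH_THRESHOLD = 2.9

#: first measurement plane sits this far (mm) distal to the LSA landmark
PLANE_OFFSET_MM = 20.0

#: spacing (mm) between consecutive measurement planes
PLANE_SPACING_MM = 30.0


class GeometryError(ValueError):
    """Raised for inconsistent or degenerate geometric input."""


# ---------------------------------------------------------------------------
# centerline and plane placement
# ---------------------------------------------------------------------------


@dataclass
class Centerline:
    """Ordered 3-D polyline through the aortic lumen.

    Parameters
    ----------
    points
        ``(n, 3)`` array of positions in mm, ordered proximal to distal.
    landmark_arc
        Arc position (mm from the first point) of the left subclavian
        artery origin.
    """

    points: np.ndarray
    landmark_arc: float
    arc: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise GeometryError("centerline points must be an (n, 3) array")
        if len(self.points) < 2:
            raise GeometryError("centerline needs at least 2 points")
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(seg <= 0):
            raise GeometryError("centerline arc length must be strictly increasing")
        self.arc = np.concatenate([[0.0], np.cumsum(seg)])
        if not 0.0 <= self.landmark_arc <= self.total_length:
            raise GeometryError(
                f"landmark arc {self.landmark_arc} outside [0, {self.total_length}]"
            )

    @property
    def total_length(self) -> float:
        return float(self.arc[-1])

    def point_at(self, s: float | np.ndarray) -> np.ndarray:
        """Position on the centerline at arc position ``s`` (mm)."""
        s = np.asarray(s, dtype=float)
        return np.stack(
            [np.interp(s, self.arc, self.points[:, i]) for i in range(3)], axis=-1
        )

    def tangent_at(self, s: float | np.ndarray) -> np.ndarray:
        """Unit tangent at arc position ``s`` (per-segment, renormalised)."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        seg_t = np.diff(self.points, axis=0)
        seg_t /= np.linalg.norm(seg_t, axis=1, keepdims=True)
        idx = np.clip(np.searchsorted(self.arc, s, side="right") - 1, 0, len(seg_t) - 1)
        t = seg_t[idx]
        t = t / np.linalg.norm(t, axis=1, keepdims=True)
        return t if t.shape[0] > 1 else t[0]


@dataclass
class PlaneSet:
    """Measurement planes P1..Pn along the centerline."""

    ids: list[str]
    arc_positions: np.ndarray
    normals: np.ndarray

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self):
        return iter(zip(self.ids, self.arc_positions, self.normals))


def place_planes(centerline: Centerline, n_planes: int) -> PlaneSet:
    """Place measurement planes distal to the LSA landmark.

    P1 sits ``PLANE_OFFSET_MM`` beyond the landmark and subsequent planes
    follow at ``PLANE_SPACING_MM`` intervals; normals are the local
    centerline tangents.  Raises :class:`GeometryError` naming the largest
    feasible plane count when the centerline is too short.
    """
    if n_planes < 1:
        raise GeometryError("n_planes must be >= 1")
    available = centerline.total_length - centerline.landmark_arc
    max_n = int(np.floor((available - PLANE_OFFSET_MM) / PLANE_SPACING_MM)) + 1
    if available < PLANE_OFFSET_MM or max_n < n_planes:
        raise GeometryError(
            f"centerline supports at most {max(max_n, 0)} planes "
            f"({available:.1f} mm beyond landmark), requested {n_planes}"
        )
    positions = (
        centerline.landmark_arc
        + PLANE_OFFSET_MM
        + PLANE_SPACING_MM * np.arange(n_planes)
    )
    normals = np.atleast_2d(centerline.tangent_at(positions))
    ids = [f"P{k + 1}" for k in range(n_planes)]
    return PlaneSet(ids=ids, arc_positions=positions, normals=normals)


# ---------------------------------------------------------------------------
# mesh slicing
# ---------------------------------------------------------------------------


def _plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, n)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(n, ref)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    return u, v


def slice_contour(
    mesh, origin: Sequence[float], normal: Sequence[float], tol: float = 1e-6
) -> list[np.ndarray]:
    """Intersect a triangulated surface with a plane.

    Returns a list of closed planar polylines, each an ``(n, 2)`` array in
    an orthonormal in-plane coordinate frame (mm).  An empty list signals
    that the plane misses the mesh entirely.
    """
    import trimesh.intersections

    origin = np.asarray(origin, dtype=float)
    lines = trimesh.intersections.mesh_plane(
        mesh, plane_normal=np.asarray(normal, float), plane_origin=origin
    )
    if len(lines) == 0:
        return []
    u, v = _plane_basis(normal)
    # project the 3-D segment soup into plane coordinates, then stitch
    rel = lines - origin
    seg2 = np.stack([rel @ u, rel @ v], axis=-1)  # (m, 2 endpoints, 2 coords)
    return _stitch_segments(seg2, tol=tol)


def _stitch_segments(segments: np.ndarray, tol: float) -> list[np.ndarray]:
    """Chain unordered 2-D segments into closed loops by endpoint matching."""
    decimals = max(0, int(-np.log10(tol)))
    key = lambda p: tuple(np.round(p, decimals))
    adjacency: dict[tuple, list[int]] = {}
    for i, (a, b) in enumerate(segments):
        adjacency.setdefault(key(a), []).append(i)
        adjacency.setdefault(key(b), []).append(i)
    used = np.zeros(len(segments), dtype=bool)
    loops: list[np.ndarray] = []
    for start in range(len(segments)):
        if used[start]:
            continue
        used[start] = True
        a, b = segments[start]
        chain = [a, b]
        while True:
            tail = chain[-1]
            nxt = None
            for j in adjacency.get(key(tail), []):
                if not used[j]:
                    nxt = j
                    break
            if nxt is None:
                break
            used[nxt] = True
            p, q = segments[nxt]
            chain.append(q if np.allclose(p, tail, atol=10 * tol) else p)
            if np.allclose(chain[-1], chain[0], atol=10 * tol):
                break
        loop = np.asarray(chain)
        if len(loop) >= 4 and np.allclose(loop[0], loop[-1], atol=10 * tol):
            loops.append(loop[:-1])
    return loops


# ---------------------------------------------------------------------------
# diameters and growth
# ---------------------------------------------------------------------------


def _contour_points(contours) -> np.ndarray:
    """Flatten one polygon / an iterable of polygons into an (n, 2) array."""
    if isinstance(contours, Polygon):
        contours = [contours]
    elif isinstance(contours, np.ndarray) and contours.ndim == 2:
        contours = [contours]
    pts = []
    for c in contours:
        if isinstance(c, Polygon):
            pts.append(np.asarray(c.exterior.coords)[:-1])
        else:
            pts.append(np.asarray(c, dtype=float))
    if not pts:
        raise GeometryError("no contours supplied")
    return np.vstack(pts)


def max_diameter(
    contours, method: Literal["feret", "short_axis"] = "feret"
) -> float:
    """Caliper diameter of the combined outer aortic cross-section.

    ``feret`` (default) returns the maximum caliper (Feret) diameter —
    the largest distance between two parallel supporting lines; this
    equals the maximum pairwise vertex distance.  ``short_axis`` returns
    the minimum caliper width of the convex hull (the short-axis reading
    used by some radiology conventions).
    """
    pts = _contour_points(contours)
    if len(pts) < 3:
        raise GeometryError("degenerate contour: fewer than 3 vertices")
    if np.linalg.matrix_rank(pts - pts.mean(axis=0)) < 2:
        raise GeometryError("degenerate contour: collinear vertices")
    hull = ConvexHull(pts)
    hp = pts[hull.vertices]
    if method == "feret":
        d2 = np.sum((hp[:, None, :] - hp[None, :, :]) ** 2, axis=-1)
        return float(np.sqrt(d2.max()))
    if method == "short_axis":
        widths = []
        m = len(hp)
        for i in range(m):
            a, b = hp[i], hp[(i + 1) % m]
            edge = b - a
            edge /= np.linalg.norm(edge)
            n = np.array([-edge[1], edge[0]])
            widths.append(np.abs((hp - a) @ n).max())
        return float(min(widths))
    raise ValueError(f"unknown diameter method {method!r}")


def growth_rate(
    d_prev: float, d_next: float, t_prev: float, t_next: float
) -> float:
    """Equivalent yearly growth (mm/yr) between two scans.

    The monthly rate (diameter change over the scan interval in months)
    is scaled by 12.
    """
    if not t_next > t_prev:
        raise GeometryError(
            f"scan times must increase: t_prev={t_prev}, t_next={t_next}"
        )
    return 12.0 * (d_next - d_prev) / (t_next - t_prev)


def classify_growth(
    rate: float, threshold: float = UNSTABLE_GROWTH_THRESHOLD
) -> Literal["stable", "unstable"]:
    """Label a per-plane yearly growth rate; unstable iff strictly above
    the threshold (default 2.9 mm/yr)."""
    if not np.isfinite(rate):
        raise GeometryError("growth rate must be finite")
    return "unstable" if rate > threshold else "stable"


# ---------------------------------------------------------------------------
# dissection model
# ---------------------------------------------------------------------------


@dataclass
class Station:
    """Cross-sectional state at one arc position.

    ``fl_area`` is the patent (flowing) false-lumen area; ``thrombus_area``
    the clotted false-lumen portion.  ``contour`` optionally holds the
    combined outer cross-section as an ``(n, 2)`` planar polygon (mm).
    """

    arc_mm: float
    tl_area: float
    fl_area: float
    thrombus_area: float = 0.0
    contour: np.ndarray | None = None


@dataclass
class Tear:
    """Communication between true and false lumen through the intimal flap."""

    arc_mm: float
    area_mm2: float
    is_primary: bool = False


@dataclass
class DissectionModel:
    """Parameterised geometry of one scan of a repaired dissection.

    ``outlets`` holds ``(arc position mm, WindkesselOutlet)`` pairs used
    when the model is discretised into a flow network; it may be empty
    for purely morphometric use.
    """

    centerline: Centerline
    stations: list[Station]
    tears: list[Tear]
    inlet_arc: float = 0.0
    outlets: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.stations) < 2:
            raise GeometryError("model needs at least 2 stations")
        arcs = [s.arc_mm for s in self.stations]
        if not np.all(np.diff(arcs) > 0):
            raise GeometryError("stations must be ordered by increasing arc position")
        for s in self.stations:
            if min(s.tl_area, s.fl_area, s.thrombus_area) < 0:
                raise GeometryError("station areas must be non-negative")
            if s.contour is not None and not Polygon(s.contour).is_valid:
                raise GeometryError(
                    f"station at {s.arc_mm} mm has a self-intersecting contour"
                )
        primaries = [t for t in self.tears if t.is_primary]
        if self.tears:
            if len(primaries) != 1:
                raise GeometryError("exactly one primary tear is required")
            if primaries[0].arc_mm > min(t.arc_mm for t in self.tears):
                raise GeometryError("the primary tear must be the most proximal")
            lo, hi = arcs[0], arcs[-1]
            for t in self.tears:
                if not lo <= t.arc_mm <= hi:
                    raise GeometryError(
                        f"tear at {t.arc_mm} mm lies outside the dissected extent"
                    )

    @property
    def station_arcs(self) -> np.ndarray:
        return np.array([s.arc_mm for s in self.stations])


@dataclass
class ScanSeries:
    """One patient's ordered follow-up scans (times in months after surgery)."""

    patient_id: str
    times_months: np.ndarray
    models: list[DissectionModel]

    def __post_init__(self) -> None:
        self.times_months = np.asarray(self.times_months, dtype=float)
        if len(self.models) != len(self.times_months):
            raise GeometryError("one model per scan time required")
        if len(self.models) < 2:
            raise GeometryError("a series needs at least 2 scans")
        if not np.all(np.diff(self.times_months) > 0):
            raise GeometryError("scan times must be strictly increasing")

    @property
    def n_scans(self) -> int:
        return len(self.models)


def tear_census(model: DissectionModel) -> tuple[float, int]:
    """Primary entry tear area (mm^2) and number of re-entry tears.

    Raises if the model carries no tears: a patent false lumen requires at
    least one TL-FL communication.
    """
    if not model.tears:
        raise GeometryError("model has no tears; a patent FL needs >= 1 communication")
    primary = next(t for t in model.tears if t.is_primary)
    return primary.area_mm2, sum(1 for t in model.tears if not t.is_primary)


def lumen_volumes(model: DissectionModel) -> tuple[float, float, float]:
    """Lumen volumes (mm^3) by trapezoidal integration of station areas.

    Returns ``(TL, FL patent, FL thrombus)``; total FL volume is the sum
    of the last two.
    """
    arcs = model.station_arcs
    if len(arcs) < 2:
        raise GeometryError("need >= 2 stations to integrate volumes")
    tl = np.trapezoid([s.tl_area for s in model.stations], arcs)
    fl = np.trapezoid([s.fl_area for s in model.stations], arcs)
    th = np.trapezoid([s.thrombus_area for s in model.stations], arcs)
    return float(tl), float(fl), float(th)


def volume_change(
    model_prev: DissectionModel, model_next: DissectionModel
) -> tuple[float, float]:
    """Percent TL and FL volume change between two consecutive scans.

    FL volume includes thrombus (the clot occupies false-lumen volume even
    though it carries no flow).
    """
    tl0, fl0, th0 = lumen_volumes(model_prev)
    tl1, fl1, th1 = lumen_volumes(model_next)
    if tl0 <= 0 or (fl0 + th0) <= 0:
        raise GeometryError("previous scan has zero lumen volume")
    return (
        100.0 * (tl1 - tl0) / tl0,
        100.0 * ((fl1 + th1) - (fl0 + th0)) / (fl0 + th0),
    )


def measure_model(
    model: DissectionModel,
    planes: PlaneSet,
    method: Literal["feret", "short_axis"] = "feret",
    station_tol_mm: float = 1.0,
) -> dict[str, float]:
    """Per-plane maximum diameter (mm) read from station contours.

    Each plane is matched to the station nearest its arc position (within
    ``station_tol_mm``); the diameter is the caliper diameter of that
    station's combined outer contour.
    """
    arcs = model.station_arcs
    out: dict[str, float] = {}
    for pid, pos, _ in planes:
        i = int(np.argmin(np.abs(arcs - pos)))
        if abs(arcs[i] - pos) > station_tol_mm:
            raise GeometryError(
                f"no station within {station_tol_mm} mm of plane {pid} at {pos} mm"
            )
        st = model.stations[i]
        if st.contour is None:
            raise GeometryError(f"station at {st.arc_mm} mm has no contour")
        out[pid] = max_diameter(st.contour, method=method)
    return out


# ---------------------------------------------------------------------------
# mesh construction (for series exported as STL and for slicing tests)
# ---------------------------------------------------------------------------


def tube_mesh(
    centerline: Centerline,
    arc_positions: Iterable[float],
    radii: Iterable[float],
    sections: int = 64,
):
    """Capped tube surface following the centerline.

    Circular rings of the given radii are swept along the centerline at
    ``arc_positions`` using parallel-transport frames (avoids twist on
    curved centerlines); ends are closed with triangle fans so slices are
    watertight.  Returns a :class:`trimesh.Trimesh` in mm.
    """
    import trimesh

    arc_positions = np.asarray(list(arc_positions), dtype=float)
    radii = np.asarray(list(radii), dtype=float)
    if len(arc_positions) != len(radii) or len(arc_positions) < 2:
        raise GeometryError("need matching arc_positions and radii, >= 2 rings")
    centers = centerline.point_at(arc_positions)
    tangents = np.atleast_2d(centerline.tangent_at(arc_positions))

    # parallel transport of an initial in-plane frame
    u = _plane_basis(tangents[0])[0]
    theta = np.linspace(0, 2 * np.pi, sections, endpoint=False)
    rings = []
    for i in range(len(arc_positions)):
        t = tangents[i]
        u = u - np.dot(u, t) * t
        u /= np.linalg.norm(u)
        v = np.cross(t, u)
        ring = centers[i] + radii[i] * (
            np.outer(np.cos(theta), u) + np.outer(np.sin(theta), v)
        )
        rings.append(ring)
    verts = np.vstack(rings)

    faces = []
    for i in range(len(rings) - 1):
        base0, base1 = i * sections, (i + 1) * sections
        for j in range(sections):
            jn = (j + 1) % sections
            faces.append([base0 + j, base1 + j, base1 + jn])
            faces.append([base0 + j, base1 + jn, base0 + jn])
    # end caps
    c0 = len(verts)
    verts = np.vstack([verts, centers[0], centers[-1]])
    last = (len(rings) - 1) * sections
    for j in range(sections):
        jn = (j + 1) % sections
        faces.append([c0, jn, j])
        faces.append([c0 + 1, last + j, last + jn])
    return trimesh.Trimesh(vertices=verts, faces=np.asarray(faces), process=False)
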