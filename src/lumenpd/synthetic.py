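"""Synthetic longitudinal dissection series with known ground truth.

Real follow-up CTA series for repaired type A dissection are not openly
available, so every downstream stage is exercised on generated data that
emulates the study conditions: 4 patients with 4-5 follow-up scans at
irregular month intervals, 8 or 12 measurement planes, per-plane maximum
pressure differences spanning roughly 0-13 mmHg, growth rates of a few
mm/yr, and a linear PD -> growth law

    growth = a + b * PD + u_patient + eps,
    u ~ N(0, patient_intercept_sd),  eps ~ N(0, noise_sd),

with a patient-level random intercept as the only grouping structure.
The generator records the drawn truth so parameter-recovery tests can
compare the fitted slope against the generating one.

Reproducibility: one global integer seed feeds a ``numpy`` SeedSequence
that is spawned into exactly three child streams, in order: patient
intercepts, PD profiles, growth noise.  Identical config + seed gives
byte-identical output tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import (
    Centerline,
    DissectionModel,
    PLANE_OFFSET_MM,
    PLANE_SPACING_MM,
    ScanSeries,
    Station,
    Tear,
    UNSTABLE_GROWTH_THRESHOLD,
)
from .longitudinal import RECORD_COLUMNS

__all__ = [
    "DEFAULT_SCAN_TIMES",
    "SynthConfig",
    "SynthTruth",
    "generate_record_table",
    "generate_scan_series",
    "nominal_dissection_model",
]

#: follow-up scan times (months after surgery) patterned on the study
#: population: first scans at 4 / 33.5 / 1.5 / 0.5 months, 4-5 scans per
#: patient over roughly 2.5-5 years
DEFAULT_SCAN_TIMES: tuple[tuple[float, ...], ...] = (
    (4.0, 10.5, 16.5, 28.5, 33.5),
    (33.5, 39.0, 47.0, 59.0),
    (1.5, 7.0, 13.5, 20.5, 29.0),
    (0.5, 9.0, 21.5, 33.5),
)


class SynthesisError(ValueError):
    """Raised when a configuration cannot produce a valid series."""


@dataclass
class SynthConfig:
    """Generator settings; defaults emulate the study conditions.

    ``pd_profile`` may fix the per-(patient, interval, plane) pressure
    difference; when ``None`` the PD values are drawn uniformly from
    ``pd_range``.  ``baseline_diameter`` is either a scalar or one value
    per plane.
    """

    n_patients: int = 4
    scan_times: tuple[tuple[float, ...], ...] | None = None
    n_planes: int = 12
    baseline_diameter: float | Sequence[float] = 40.0
    pd_profile: np.ndarray | None = None
    pd_range: tuple[float, float] = (0.0, 13.0)
    growth_intercept: float = 1.0  # a, mm/yr
    growth_slope: float = 0.26  # b, mm/yr per mmHg
    noise_sd: float = 0.8  # mm/yr
    patient_intercept_sd: float = 0.5  # mm/yr
    seed: int = 0
    # geometry-level settings
    tl_fraction: float = 0.45  # TL share of the total lumen area
    station_spacing_mm: float = 10.0
    contour_vertices: int = 64
    primary_tear_areas: tuple[float, ...] = (110.0, 90.0, 150.0, 70.0)
    reentry_counts: tuple[int, ...] = (1, 2, 3, 5)
    reentry_areas: tuple[float, ...] = (20.0, 30.0, 40.0, 60.0)
    thrombosis_extent: tuple[tuple[float, float] | None, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise SynthesisError("need at least 1 patient")
        if self.n_planes not in (8, 12):
            raise SynthesisError("n_planes must be 8 or 12")
        if self.noise_sd < 0 or self.patient_intercept_sd < 0:
            raise SynthesisError("standard deviations must be non-negative")
        if self.scan_times is not None:
            for times in self.scan_times:
                if len(times) < 2 or not np.all(np.diff(times) > 0):
                    raise SynthesisError(
                        f"scan times must be strictly increasing, got {times}"
                    )
        if not 0 < self.tl_fraction < 1:
            raise SynthesisError("tl_fraction must lie in (0, 1)")
        if self.contour_vertices % 2 or self.contour_vertices < 8:
            raise SynthesisError("contour_vertices must be even and >= 8")

    def times_for(self, patient: int) -> np.ndarray:
        if self.scan_times is not None:
            return np.asarray(self.scan_times[patient % len(self.scan_times)], float)
        return np.asarray(DEFAULT_SCAN_TIMES[patient % len(DEFAULT_SCAN_TIMES)], float)

    def baseline_per_plane(self) -> np.ndarray:
        b = np.asarray(self.baseline_diameter, dtype=float)
        if b.ndim == 0:
            # mild proximal-to-distal taper around the requested diameter
            return float(b) - 0.5 * np.linspace(0.0, 6.0, self.n_planes)
        if len(b) != self.n_planes:
            raise SynthesisError("baseline_diameter must be scalar or one per plane")
        return b.copy()


@dataclass
class SynthTruth:
    """Ground truth recorded at generation time."""

    true_slope: float
    true_intercept: float
    patient_intercepts: np.ndarray
    noiseless_growth: pd.DataFrame  # same keys as the record table
    seed: int


def _streams(config: SynthConfig):
    ss = np.random.SeedSequence(config.seed)
    kids = ss.spawn(3)
    return tuple(np.random.default_rng(k) for k in kids)  # (intercepts, pd, noise)


def _draw(config: SynthConfig):
    """All random draws, in the documented stream order."""
    rng_u, rng_pd, rng_eps = _streams(config)
    u = rng_u.normal(0.0, config.patient_intercept_sd, size=config.n_patients)
    pds, epss, times = [], [], []
    for p in range(config.n_patients):
        t = config.times_for(p)
        n_int = len(t) - 1
        if config.pd_profile is not None:
            prof = np.asarray(config.pd_profile, dtype=float)
            pd_p = np.broadcast_to(prof, (n_int, config.n_planes)).copy() \
                if prof.ndim <= 2 else prof[p, :n_int, :].copy()
        else:
            pd_p = rng_pd.uniform(*config.pd_range, size=(n_int, config.n_planes))
        eps_p = rng_eps.normal(0.0, config.noise_sd, size=(n_int, config.n_planes))
        pds.append(pd_p)
        epss.append(eps_p)
        times.append(t)
    return u, pds, epss, times


def _records_from_draws(config, u, pds, epss, times):
    rows, truth_rows = [], []
    for p in range(config.n_patients):
        pid = f"S{p + 1:02d}"
        for j in range(len(times[p]) - 1):
            for k in range(config.n_planes):
                pd_val = pds[p][j, k]
                clean = (
                    config.growth_intercept
                    + config.growth_slope * pd_val
                    + u[p]
                )
                g = clean + epss[p][j, k]
                rows.append(
                    {
                        "patient_id": pid,
                        "scan_index": j + 1,
                        "interval_index": j + 1,
                        "plane_id": f"P{k + 1}",
                        "time_months": times[p][j],
                        "pd_max_mmHg": pd_val,
                        "growth_mm_per_yr": g,
                        "unstable": g > UNSTABLE_GROWTH_THRESHOLD,
                    }
                )
                truth_rows.append(
                    {
                        "patient_id": pid,
                        "interval_index": j + 1,
                        "plane_id": f"P{k + 1}",
                        "noiseless_growth_mm_per_yr": clean,
                    }
                )
    return (
        pd.DataFrame(rows, columns=RECORD_COLUMNS),
        pd.DataFrame(truth_rows),
    )


def generate_record_table(config: SynthConfig) -> tuple[pd.DataFrame, SynthTruth]:
    """Record-level generation: one row per (patient, interval, plane).

    The table follows the growth-record schema consumed by the
    statistics stage; the returned :class:`SynthTruth` carries the drawn
    intercepts and the noiseless growth for each record.
    """
    u, pds, epss, times = _draw(config)
    table, clean = _records_from_draws(config, u, pds, epss, times)
    truth = SynthTruth(
        true_slope=config.growth_slope,
        true_intercept=config.growth_intercept,
        patient_intercepts=u,
        noiseless_growth=clean,
        seed=config.seed,
    )
    return table, truth


# ---------------------------------------------------------------------------
# geometry-level generation
# ---------------------------------------------------------------------------


def _arc_centerline(total_length: float, landmark_arc: float = 10.0) -> Centerline:
    """Gently curved planar centerline of the requested arc length."""
    radius = 600.0  # mm; mild thoracic curvature
    s = np.arange(0.0, total_length + 2.5, 2.5)
    pts = np.column_stack(
        [
            radius * (1.0 - np.cos(s / radius)),
            np.zeros_like(s),
            -radius * np.sin(s / radius),
        ]
    )
    return Centerline(points=pts, landmark_arc=landmark_arc)


def _regular_contour(diameter: float, n_vertices: int) -> np.ndarray:
    """Even regular polygon whose Feret diameter equals ``diameter``."""
    theta = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
    r = diameter / 2.0
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def _model_from_diameters(
    config: SynthConfig,
    patient: int,
    plane_arcs: np.ndarray,
    diam_per_plane: np.ndarray,
    landmark_arc: float,
) -> DissectionModel:
    end_arc = plane_arcs[-1] + PLANE_SPACING_MM
    centerline = _arc_centerline(end_arc + 10.0, landmark_arc)
    station_arcs = np.unique(
        np.concatenate(
            [np.arange(0.0, end_arc + 1e-9, config.station_spacing_mm), plane_arcs]
        )
    )
    diam = np.interp(station_arcs, plane_arcs, diam_per_plane)
    thromb = None
    if config.thrombosis_extent is not None:
        thromb = config.thrombosis_extent[patient % len(config.thrombosis_extent)]
    stations = []
    for arc, d in zip(station_arcs, diam):
        total = np.pi * d**2 / 4.0
        tl = config.tl_fraction * total
        fl = total - tl
        if thromb is not None and thromb[0] <= arc <= thromb[1]:
            st = Station(arc, tl, 0.0, fl, contour=_regular_contour(d, config.contour_vertices))
        else:
            st = Station(arc, tl, fl, 0.0, contour=_regular_contour(d, config.contour_vertices))
        stations.append(st)

    n_re = config.reentry_counts[patient % len(config.reentry_counts)]
    re_area = config.reentry_areas[patient % len(config.reentry_areas)]
    primary_arc = landmark_arc + PLANE_OFFSET_MM / 2.0
    tears = [
        Tear(
            primary_arc,
            config.primary_tear_areas[patient % len(config.primary_tear_areas)],
            is_primary=True,
        )
    ]
    if n_re > 0:
        re_arcs = np.linspace(0.62 * end_arc, 0.95 * end_arc, n_re)
        tears += [Tear(float(a), re_area) for a in re_arcs]
    return DissectionModel(
        centerline=centerline,
        stations=stations,
        tears=tears,
        inlet_arc=0.0,
    )


def generate_scan_series(
    config: SynthConfig,
) -> tuple[list[ScanSeries], pd.DataFrame, SynthTruth]:
    """Geometry-level generation of one series per patient.

    Per-plane total diameters evolve between scans according to the same
    growth law as :func:`generate_record_table` (identical draws for
    identical config + seed), with a fixed TL area fraction, a per-patient
    tear set, and optional thrombosis extent.  Returns the series, the
    matching record table and the ground truth.

    Raises :class:`SynthesisError` if the growth law drives any diameter
    to zero or below.
    """
    u, pds, epss, times = _draw(config)
    table, clean = _records_from_draws(config, u, pds, epss, times)
    landmark_arc = 10.0
    plane_arcs = (
        landmark_arc + PLANE_OFFSET_MM + PLANE_SPACING_MM * np.arange(config.n_planes)
    )
    series: list[ScanSeries] = []
    for p in range(config.n_patients):
        t = times[p]
        diam = config.baseline_per_plane()
        models = [_model_from_diameters(config, p, plane_arcs, diam, landmark_arc)]
        for j in range(len(t) - 1):
            rate = (
                config.growth_intercept
                + config.growth_slope * pds[p][j]
                + u[p]
                + epss[p][j]
            )
            diam = diam + rate * (t[j + 1] - t[j]) / 12.0
            if np.any(diam <= 0):
                raise SynthesisError(
                    f"growth law drove a diameter <= 0 for patient {p + 1}, "
                    f"interval {j + 1}"
                )
            models.append(
                _model_from_diameters(config, p, plane_arcs, diam, landmark_arc)
            )
        series.append(
            ScanSeries(patient_id=f"S{p + 1:02d}", times_months=t, models=models)
        )
    truth = SynthTruth(
        true_slope=config.growth_slope,
        true_intercept=config.growth_intercept,
        patient_intercepts=u,
        noiseless_growth=clean,
        seed=config.seed,
    )
    return series, table, truth


def nominal_dissection_model(
    n_planes: int = 12,
    tl_fraction: float = 0.45,
    primary_tear: tuple[float, float] = (35.0, 70.0),
    reentry_tears: tuple[tuple[float, float], ...] = (
        (270.0, 30.0),
        (310.0, 30.0),
        (350.0, 30.0),
    ),
    thrombosis_extent: tuple[float, float] | None = None,
    baseline_diameter: float = 40.0,
) -> DissectionModel:
    """Nominal dissected thoracic aorta used for solver studies.

    A 40 mm proximal diameter tapering to 34 mm distally, a compressed
    true lumen (45% of the lumen area), a 70 mm^2 primary entry tear
    just distal to the LSA and three 30 mm^2 re-entry tears in the distal
    third — magnitudes in the ranges reported for repaired type A
    dissection.  The false lumen is patent through the distal boundary
    (the dissection continues into the abdominal aorta), so flow networks
    built from this model terminate both lumens in Windkessel outlets.
    Tear positions/areas are keyword-tunable for sensitivity studies
    (e.g. occluding or enlarging the distal tears).
    """
    cfg = SynthConfig(
        n_patients=1,
        n_planes=n_planes,
        baseline_diameter=baseline_diameter,
        tl_fraction=tl_fraction,
        noise_sd=0.0,
        patient_intercept_sd=0.0,
    )
    landmark_arc = 10.0
    plane_arcs = landmark_arc + PLANE_OFFSET_MM + PLANE_SPACING_MM * np.arange(n_planes)
    model = _model_from_diameters(
        cfg, 0, plane_arcs, cfg.baseline_per_plane(), landmark_arc
    )
    arc0, area0 = primary_tear
    tears = [Tear(arc0, area0, is_primary=True)]
    tears += [Tear(a, s) for a, s in reentry_tears]
    stations = model.stations
    if thrombosis_extent is not None:
        lo, hi = thrombosis_extent
        stations = [
            Station(
                s.arc_mm,
                s.tl_area,
                0.0 if lo <= s.arc_mm <= hi else s.fl_area,
                s.fl_area if lo <= s.arc_mm <= hi else 0.0,
                contour=s.contour,
            )
            for s in stations
        ]
    return DissectionModel(
        centerline=model.centerline,
        stations=stations,
        tears=tears,
        inlet_arc=0.0,
    )
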