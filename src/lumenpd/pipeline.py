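"""End-to-end drivers: synthesize -> measure -> simulate -> analyze.

The pipeline mirrors the study workflow: every scan contributes per-plane
diameters, every scan *except the last* of each patient is simulated for
its pressure field (the final scan only closes the last growth interval),
growth/PD records are assembled per (patient, interval, plane), and the
mixed-effects and ROC analyses are fitted on the pooled records.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import geometry as geo
from . import hemodynamics as hemo
from .longitudinal import LmmFit, RocResult, assemble_records, fit_lmm, roc_threshold
from .synthetic import (
    SynthConfig,
    SynthTruth,
    _draw,
    _model_from_diameters,
    _records_from_draws,
    generate_scan_series,
)

__all__ = [
    "SolverSettings",
    "PipelineResult",
    "measure_series",
    "simulate_model_pd",
    "simulate_series",
    "generate_coupled_series",
    "analyze",
    "run_pipeline",
    "write_series",
    "read_series",
]


@dataclass
class SolverSettings:
    """Hemodynamic stage settings (targets, waveform, solver controls).

    ``fl_outlet_split`` is the flow fraction assigned to the distal
    false-lumen Windkessel when the FL is patent at the distal boundary
    (the dissection continues beyond the modeled segment); set it to 0 to
    force a dead-end FL.
    """

    systolic_mmHg: float = 120.0
    diastolic_mmHg: float = 80.0
    period_s: float = 0.857
    cardiac_output_l_min: float = 5.0
    fl_outlet_split: float = 0.4
    dt_steps_per_cycle: int = 1000
    periodicity_tol_mmHg: float = 0.01
    max_cycles: int = 30
    station_merge_mm: float = 5.0
    signed_pd: bool = True

    def inlet(self) -> hemo.FlowWaveform:
        return hemo.FlowWaveform.default_aortic(
            period=self.period_s, cardiac_output_l_min=self.cardiac_output_l_min
        )


@dataclass
class PipelineResult:
    records: pd.DataFrame
    n_dropped: int
    lmm: LmmFit
    roc: RocResult
    measurements: pd.DataFrame
    pd_table: pd.DataFrame


def measure_series(
    series_list: list[geo.ScanSeries],
    n_planes: int,
    method: str = "feret",
) -> pd.DataFrame:
    """Per-plane maximum diameters for every scan of every series."""
    rows = []
    for series in series_list:
        for j, model in enumerate(series.models):
            planes = geo.place_planes(model.centerline, n_planes)
            diam = geo.measure_model(model, planes, method=method)
            for pid, d in diam.items():
                rows.append(
                    {
                        "patient_id": series.patient_id,
                        "scan_index": j + 1,
                        "time_months": series.times_months[j],
                        "plane_id": pid,
                        "diameter_mm": d,
                    }
                )
    return pd.DataFrame(rows)


class _OutletBank:
    """Windkessel calibrations shared across scans (one per split layout)."""

    def __init__(self, settings: SolverSettings):
        self.settings = settings
        self._cache: dict[tuple[float, ...], list[hemo.WindkesselOutlet]] = {}

    def for_splits(self, splits: tuple[float, ...]) -> list[hemo.WindkesselOutlet]:
        if splits not in self._cache:
            self._cache[splits] = hemo.calibrate_windkessel(
                self.settings.systolic_mmHg,
                self.settings.diastolic_mmHg,
                self.settings.inlet(),
                splits=splits,
            )
        return self._cache[splits]

    def outlets_for(self, model: geo.DissectionModel):
        """Distal outlet set: TL always; FL too when patent distally."""
        distal = model.stations[-1]
        split_fl = self.settings.fl_outlet_split
        if distal.fl_area > 0 and split_fl > 0:
            wks = self.for_splits((1.0 - split_fl, split_fl))
            return [
                (distal.arc_mm, wks[0], "TL"),
                (distal.arc_mm, wks[1], "FL"),
            ]
        wks = self.for_splits((1.0,))
        return [(distal.arc_mm, wks[0], "TL")]


def simulate_model_pd(
    model: geo.DissectionModel,
    n_planes: int,
    settings: SolverSettings,
    outlet_bank: _OutletBank | None = None,
) -> dict[str, float]:
    """Simulate one scan and return the per-plane max PD (NaN = no FL)."""
    outlet_bank = outlet_bank or _OutletBank(settings)
    network = hemo.build_network(
        model,
        station_merge=settings.station_merge_mm,
        outlets=outlet_bank.outlets_for(model),
    )
    inlet = settings.inlet()
    result = hemo.simulate(
        network,
        inlet,
        max_cycles=settings.max_cycles,
        dt=inlet.period / settings.dt_steps_per_cycle,
        tol=settings.periodicity_tol_mmHg,
    )
    planes = geo.place_planes(model.centerline, n_planes)
    waves = hemo.plane_pressures(result, planes)
    out: dict[str, float] = {}
    for pid in planes.ids:
        tl, fl = waves[pid]["tl"], waves[pid]["fl"]
        if tl is None or fl is None:
            out[pid] = float("nan")
        else:
            out[pid] = hemo.pd_statistic(tl, fl, signed=settings.signed_pd)[1]
    return out


def simulate_series(
    series_list: list[geo.ScanSeries],
    n_planes: int,
    settings: SolverSettings | None = None,
) -> pd.DataFrame:
    """PD table for all scans except each patient's last.

    The Windkessel outlet is calibrated once for the configured pressure
    targets and inlet waveform, then shared across scans.
    """
    settings = settings or SolverSettings()
    bank = _OutletBank(settings)
    rows = []
    for series in series_list:
        for j, model in enumerate(series.models[:-1]):
            pd_map = simulate_model_pd(model, n_planes, settings, outlet_bank=bank)
            for pid, v in pd_map.items():
                rows.append(
                    {
                        "patient_id": series.patient_id,
                        "scan_index": j + 1,
                        "plane_id": pid,
                        "pd_max_mmHg": v,
                    }
                )
    return pd.DataFrame(rows)


def generate_coupled_series(
    config: SynthConfig,
    settings: SolverSettings | None = None,
) -> tuple[list[geo.ScanSeries], pd.DataFrame, SynthTruth]:
    """Series whose growth is driven by the *simulated* pressure field.

    Instead of an exogenous PD profile, each scan's geometry is run
    through the network solver and the resulting per-plane max PD feeds
    the growth law for the following interval.  The full pipeline applied
    to such a series therefore re-measures exactly the PD values that
    generated the growth (a plane without FL pressure contributes PD = 0
    to the growth law and is later dropped from the record table).
    """
    settings = settings or SolverSettings()
    bank = _OutletBank(settings)
    u, _pds, epss, times = _draw(config)
    landmark_arc = 10.0
    plane_arcs = (
        landmark_arc
        + geo.PLANE_OFFSET_MM
        + geo.PLANE_SPACING_MM * np.arange(config.n_planes)
    )
    series_list: list[geo.ScanSeries] = []
    pds_sim = []
    for p in range(config.n_patients):
        t = times[p]
        diam = config.baseline_per_plane()
        models = [_model_from_diameters(config, p, plane_arcs, diam, landmark_arc)]
        pd_p = np.zeros((len(t) - 1, config.n_planes))
        for j in range(len(t) - 1):
            pd_map = simulate_model_pd(
                models[-1], config.n_planes, settings, outlet_bank=bank
            )
            pd_vec = np.array(
                [pd_map[f"P{k + 1}"] for k in range(config.n_planes)]
            )
            pd_p[j] = np.nan_to_num(pd_vec, nan=0.0)
            rate = (
                config.growth_intercept
                + config.growth_slope * pd_p[j]
                + u[p]
                + epss[p][j]
            )
            diam = diam + rate * (t[j + 1] - t[j]) / 12.0
            models.append(
                _model_from_diameters(config, p, plane_arcs, diam, landmark_arc)
            )
        pds_sim.append(pd_p)
        series_list.append(
            geo.ScanSeries(patient_id=f"S{p + 1:02d}", times_months=t, models=models)
        )
    table, clean = _records_from_draws(config, u, pds_sim, epss, times)
    truth = SynthTruth(
        true_slope=config.growth_slope,
        true_intercept=config.growth_intercept,
        patient_intercepts=u,
        noiseless_growth=clean,
        seed=config.seed,
    )
    return series_list, table, truth


def analyze(
    measurements: pd.DataFrame, pd_table: pd.DataFrame
) -> tuple[pd.DataFrame, int, LmmFit, RocResult]:
    """Assemble records and fit the mixed-effects and ROC analyses."""
    records, n_dropped = assemble_records(measurements, pd_table)
    lmm = fit_lmm(records)
    roc = roc_threshold(records)
    return records, n_dropped, lmm, roc


def run_pipeline(
    config: SynthConfig,
    out_dir: str | Path | None = None,
    settings: SolverSettings | None = None,
    coupled: bool = True,
) -> PipelineResult:
    """Full run: generate, measure, simulate, analyze; optionally persist.

    With ``coupled=True`` (default) growth is driven by simulated PD so
    the statistics stage sees a self-consistent data set; otherwise the
    exogenous PD profile drives growth and the simulated PD plays the
    role of the measured predictor.
    """
    settings = settings or SolverSettings()
    if coupled:
        series_list, _table, _truth = generate_coupled_series(config, settings)
    else:
        series_list, _table, _truth = generate_scan_series(config)
    measurements = measure_series(series_list, config.n_planes)
    pd_table = simulate_series(series_list, config.n_planes, settings)
    records, n_dropped, lmm, roc = analyze(measurements, pd_table)
    result = PipelineResult(records, n_dropped, lmm, roc, measurements, pd_table)
    if out_dir is not None:
        _persist(result, config, settings, Path(out_dir))
    return result


def _persist(
    result: PipelineResult,
    config: SynthConfig,
    settings: SolverSettings,
    out_dir: Path,
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.measurements.to_csv(out_dir / "measurements.csv", index=False)
    result.pd_table.to_csv(out_dir / "pd_table.csv", index=False)
    result.records.to_csv(out_dir / "records.csv", index=False)
    (out_dir / "lmm_fit.json").write_text(json.dumps(result.lmm.to_dict(), indent=2))
    result.roc.to_frame().to_csv(out_dir / "roc_curve.csv", index=False)
    (out_dir / "roc.json").write_text(
        json.dumps(
            {
                "auc": result.roc.auc,
                "cutoff_mmHg": result.roc.cutoff,
                "criterion": result.roc.criterion,
            },
            indent=2,
        )
    )
    fe = result.lmm.fixed_effects
    width = max(len(k) for k in fe)
    lines = ["Solution for fixed effects", "-" * (width + 14)]
    lines += [f"{k:<{width}}  {v:>10.4f}" for k, v in fe.items()]
    (out_dir / "fixed_effects.txt").write_text("\n".join(lines) + "\n")
    cfg = {k: _jsonable(v) for k, v in asdict(config).items()}
    manifest = {
        "config": cfg,
        "solver": asdict(settings),
        "seed": config.seed,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "versions": _versions(),
        "n_records": int(len(result.records)),
        "n_dropped_planes": int(result.n_dropped),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _jsonable(v):
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, tuple):
        return [_jsonable(x) for x in v]
    return v


def _versions() -> dict[str, str]:
    import importlib.metadata as md

    out = {}
    for pkg in ("lumenpd", "numpy", "scipy", "pandas", "statsmodels"):
        try:
            out[pkg] = md.version(pkg)
        except md.PackageNotFoundError:  # pragma: no cover
            out[pkg] = "unknown"
    return out


# ---------------------------------------------------------------------------
# on-disk series format
# ---------------------------------------------------------------------------


def write_series(
    series_list: list[geo.ScanSeries],
    out_dir: str | Path,
    write_meshes: bool = False,
) -> None:
    """Persist series as plain-text files (one directory per patient).

    Layout per patient: ``centerline.csv`` (x, y, z in mm),
    ``series.json`` (scan times, landmark arc), per scan
    ``scan_XX_stations.csv`` (arc, areas, outer diameter) and
    ``scan_XX_tears.csv``.  With ``write_meshes`` the combined outer
    surface of each scan is additionally exported as STL.
    """
    out_dir = Path(out_dir)
    for series in series_list:
        pdir = out_dir / series.patient_id
        pdir.mkdir(parents=True, exist_ok=True)
        cl = series.models[0].centerline
        pd.DataFrame(cl.points, columns=["x_mm", "y_mm", "z_mm"]).to_csv(
            pdir / "centerline.csv", index=False
        )
        meta = {
            "patient_id": series.patient_id,
            "times_months": series.times_months.tolist(),
            "landmark_arc_mm": cl.landmark_arc,
            "n_scans": series.n_scans,
        }
        (pdir / "series.json").write_text(json.dumps(meta, indent=2))
        for j, model in enumerate(series.models):
            rows = []
            for s in model.stations:
                d = geo.max_diameter(s.contour) if s.contour is not None else np.nan
                rows.append(
                    {
                        "arc_mm": s.arc_mm,
                        "tl_area_mm2": s.tl_area,
                        "fl_area_mm2": s.fl_area,
                        "thrombus_area_mm2": s.thrombus_area,
                        "outer_diameter_mm": d,
                    }
                )
            pd.DataFrame(rows).to_csv(
                pdir / f"scan_{j + 1:02d}_stations.csv", index=False
            )
            pd.DataFrame(
                [
                    {
                        "arc_mm": t.arc_mm,
                        "area_mm2": t.area_mm2,
                        "is_primary": t.is_primary,
                    }
                    for t in model.tears
                ]
            ).to_csv(pdir / f"scan_{j + 1:02d}_tears.csv", index=False)
            if write_meshes:
                arcs = model.station_arcs
                radii = [
                    (geo.max_diameter(s.contour) / 2.0)
                    for s in model.stations
                ]
                mesh = geo.tube_mesh(cl, arcs, radii)
                mesh.export(pdir / f"scan_{j + 1:02d}_outer.stl")


def read_series(out_dir: str | Path) -> list[geo.ScanSeries]:
    """Load series written by :func:`write_series`.

    Station contours are rebuilt as regular polygons from the stored
    outer diameter (the synthetic cross-sections are circular).
    """
    from .synthetic import _regular_contour

    out_dir = Path(out_dir)
    series_list = []
    for pdir in sorted(p for p in out_dir.iterdir() if (p / "series.json").exists()):
        meta = json.loads((pdir / "series.json").read_text())
        pts = pd.read_csv(pdir / "centerline.csv").to_numpy()
        cl = geo.Centerline(points=pts, landmark_arc=meta["landmark_arc_mm"])
        models = []
        for j in range(meta["n_scans"]):
            st_df = pd.read_csv(pdir / f"scan_{j + 1:02d}_stations.csv")
            tr_df = pd.read_csv(pdir / f"scan_{j + 1:02d}_tears.csv")
            stations = [
                geo.Station(
                    r.arc_mm,
                    r.tl_area_mm2,
                    r.fl_area_mm2,
                    r.thrombus_area_mm2,
                    contour=_regular_contour(r.outer_diameter_mm, 64)
                    if np.isfinite(r.outer_diameter_mm)
                    else None,
                )
                for r in st_df.itertuples()
            ]
            tears = [
                geo.Tear(r.arc_mm, r.area_mm2, bool(r.is_primary))
                for r in tr_df.itertuples()
            ]
            models.append(
                geo.DissectionModel(
                    centerline=cl, stations=stations, tears=tears, inlet_arc=0.0
                )
            )
        series_list.append(
            geo.ScanSeries(
                patient_id=meta["patient_id"],
                times_months=np.asarray(meta["times_months"]),
                models=models,
            )
        )
    return series_list
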