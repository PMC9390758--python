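"""Reduced-order (0-D) hemodynamics of the dissected aorta.

The dissected thoracic aorta is discretised into two lumped-parameter
chains — one per lumen.  Each inter-station segment carries a Poiseuille
viscous resistance ``R = 8*mu*L/(pi*r_eq**4)`` (with the equivalent
circular radius ``r_eq = sqrt(A/pi)``) and a blood-column inertance
``rho*L/A``.  Intimal tears couple the chains through an orifice law

    dP = R_lin*Q + (rho*K_t / (2*A_t**2)) * Q*|Q|

with a linear term from Poiseuille flow through a flap-thickness channel
and a sharp-edged-orifice quadratic term.  Thrombosed false-lumen
stations carry no flow and are absent from the graph, while the wall is
rigid and blood is incompressible and Newtonian (density 1060 kg/m^3,
viscosity 4 mPa.s by default).

A pulsatile inlet flow drives the network and each outlet terminates in
a 3-element Windkessel (proximal resistance, compliance, distal
resistance) representing the downstream vascular bed.  The system is
integrated implicitly over successive cardiac cycles until the pressure
field is periodic; the true-false lumen pressure difference
``PD = P_TL - P_FL`` is then evaluated at the measurement planes and its
maximum over the converged cycle is the summary statistic.

External units are clinical (mmHg, mL/s, mm); element values are
converted from SI with 1 mmHg = 133.322 Pa fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .geometry import DissectionModel, PlaneSet

__all__ = [
    "MMHG_PA",
    "BloodProperties",
    "WindkesselOutlet",
    "FlowWaveform",
    "NetworkNode",
    "NetworkElement",
    "NetworkModel",
    "SimulationResult",
    "NetworkError",
    "SolverError",
    "build_network",
    "calibrate_windkessel",
    "mirror_network",
    "simulate",
    "plane_pressures",
    "pd_statistic",
    "volume_balance",
]

#: pressure conversion, fixed
MMHG_PA = 133.322

# SI resistance Pa.s/m^3 -> clinical mmHg.s/mL (same factor for inertance)
_R_SI_TO_CLINICAL = 1e-6 / MMHG_PA
# SI quadratic coefficient Pa/(m^3/s)^2 -> mmHg/(mL/s)^2
_Q2_SI_TO_CLINICAL = 1e-12 / MMHG_PA


class NetworkError(ValueError):
    """Raised for an inconsistent network topology or element set."""


class SolverError(RuntimeError):
    """Raised when the periodic solve fails; carries the residual history."""

    def __init__(self, message: str, history: list[float] | None = None):
        super().__init__(message)
        self.history = history or []


@dataclass(frozen=True)
class BloodProperties:
    """Incompressible Newtonian blood."""

    density: float = 1060.0  # kg/m^3
    viscosity: float = 0.004  # Pa.s

    def __post_init__(self) -> None:
        if self.density <= 0 or self.viscosity <= 0:
            raise ValueError("blood density and viscosity must be positive")


@dataclass
class WindkesselOutlet:
    """3-element Windkessel terminal: R1 in series with (C parallel R2).

    Resistances in mmHg.s/mL, compliance in mL/mmHg, pressures in mmHg.
    ``p_distal`` is the reference pressure behind R2 (venous side).
    """

    r_proximal: float
    r_distal: float
    compliance: float
    p_distal: float = 0.0

    def __post_init__(self) -> None:
        if min(self.r_proximal, self.r_distal, self.compliance) <= 0:
            raise ValueError("Windkessel R1, R2 and C must all be positive")

    @property
    def total_resistance(self) -> float:
        return self.r_proximal + self.r_distal


@dataclass
class FlowWaveform:
    """Periodic volumetric inlet flow, sampled uniformly over one cycle.

    ``samples`` are mL/s at times ``linspace(0, period, len(samples))``;
    the first and last samples must agree (periodicity) and the cycle
    mean must be positive (net forward flow).
    """

    period: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.period <= 0:
            raise ValueError("period must be positive")
        if len(self.samples) < 2:
            raise ValueError("need at least 2 samples")
        if abs(self.samples[0] - self.samples[-1]) > 1e-9 * (
            1 + np.abs(self.samples).max()
        ):
            raise ValueError("waveform must be periodic (first sample == last)")
        if self.mean_flow <= 0:
            raise ValueError("mean flow must be positive")

    @property
    def times(self) -> np.ndarray:
        return np.linspace(0.0, self.period, len(self.samples))

    @property
    def mean_flow(self) -> float:
        return float(np.trapezoid(self.samples, self.times) / self.period)

    def at(self, t: float | np.ndarray) -> np.ndarray:
        return np.interp(np.mod(t, self.period), self.times, self.samples)

    @classmethod
    def steady(cls, flow: float, period: float = 1.0, n_samples: int = 11):
        """Constant flow (useful for closed-form checks)."""
        return cls(period=period, samples=np.full(n_samples, float(flow)))

    @classmethod
    def default_aortic(
        cls,
        period: float = 0.857,
        cardiac_output_l_min: float = 5.0,
        systolic_fraction: float = 0.35,
        reverse_fraction: float = 0.10,
        reverse_amplitude: float = 0.10,
        n_samples: int = 1001,
    ):
        """Two-phase aortic inflow shape.

        A systolic half-sine of duration ``systolic_fraction * period``
        followed by a small reverse lobe (valve closure) of duration
        ``reverse_fraction * period`` and amplitude ``reverse_amplitude``
        relative to the systolic peak; zero in diastole.  The peak is set
        so the cycle mean matches the requested cardiac output.
        """
        t = np.linspace(0.0, period, n_samples)
        ts = systolic_fraction * period
        tr = reverse_fraction * period
        mean = cardiac_output_l_min * 1000.0 / 60.0
        peak = mean * period * np.pi / (2.0 * (ts - reverse_amplitude * tr))
        q = np.zeros_like(t)
        sys_mask = t < ts
        q[sys_mask] = peak * np.sin(np.pi * t[sys_mask] / ts)
        rev_mask = (t >= ts) & (t < ts + tr)
        q[rev_mask] = -reverse_amplitude * peak * np.sin(
            np.pi * (t[rev_mask] - ts) / tr
        )
        return cls(period=period, samples=q)


@dataclass(frozen=True)
class NetworkNode:
    lumen: Literal["TL", "FL"]
    arc_mm: float


@dataclass
class NetworkElement:
    """Edge between two nodes.

    ``resistance`` in mmHg.s/mL, ``inertance`` in mmHg.s^2/mL,
    ``quad_coeff`` in mmHg/(mL/s)^2 (orifice term, tears only).
    Positive flow runs from ``node_a`` to ``node_b``.
    """

    node_a: int
    node_b: int
    resistance: float
    inertance: float = 0.0
    quad_coeff: float = 0.0
    kind: Literal["segment", "tear"] = "segment"
    tear_area_mm2: float | None = None

    def __post_init__(self) -> None:
        if self.resistance <= 0:
            raise NetworkError("element resistance must be positive")
        if self.inertance < 0 or self.quad_coeff < 0:
            raise NetworkError("inertance and quad_coeff must be non-negative")


@dataclass
class NetworkModel:
    """Lumped-parameter TL/FL network with Windkessel terminals."""

    nodes: list[NetworkNode]
    elements: list[NetworkElement]
    inlet: int
    outlets: list[tuple[int, WindkesselOutlet]]
    blood: BloodProperties = field(default_factory=BloodProperties)

    def __post_init__(self) -> None:
        n = len(self.nodes)
        if not 0 <= self.inlet < n:
            raise NetworkError("inlet node index out of range")
        if not self.outlets:
            raise NetworkError("at least one Windkessel outlet is required")
        for i, _ in self.outlets:
            if not 0 <= i < n:
                raise NetworkError("outlet node index out of range")
        reach = self._reachable(self.elements)
        if reach != set(range(n)):
            missing = sorted(set(range(n)) - reach)
            raise NetworkError(f"nodes {missing} unreachable from the inlet")
        # false lumen must communicate only through tears
        no_tears = [e for e in self.elements if e.kind != "tear"]
        reach_nt = self._reachable(no_tears)
        fl = {i for i, nd in enumerate(self.nodes) if nd.lumen == "FL"}
        leak = sorted(fl & reach_nt)
        if leak:
            raise NetworkError(
                f"FL nodes {leak} reachable without crossing a tear element"
            )

    def _reachable(self, elements: Sequence[NetworkElement]) -> set[int]:
        adj: dict[int, list[int]] = {}
        for e in elements:
            adj.setdefault(e.node_a, []).append(e.node_b)
            adj.setdefault(e.node_b, []).append(e.node_a)
        seen = {self.inlet}
        stack = [self.inlet]
        while stack:
            i = stack.pop()
            for j in adj.get(i, []):
                if j not in seen:
                    seen.add(j)
                    stack.append(j)
        return seen

    def node_indices(self, lumen: str) -> list[int]:
        return [i for i, nd in enumerate(self.nodes) if nd.lumen == lumen]


@dataclass
class SimulationResult:
    """One converged (periodic) cardiac cycle of the network solution."""

    time: np.ndarray  # (nt+1,) seconds
    node_pressures: np.ndarray  # (n_nodes, nt+1) mmHg
    element_flows: np.ndarray  # (n_elements, nt+1) mL/s
    wk_pressures: np.ndarray  # (n_outlets, nt+1) mmHg
    outlet_flows: np.ndarray  # (n_outlets, nt+1) mL/s
    inlet_flow: np.ndarray  # (nt+1,) mL/s
    convergence: list[float]  # per-cycle max |P(t) - P(t - T)|, mmHg
    converged: bool
    network: NetworkModel


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------


def _segment_rl(
    area_mm2: float, length_mm: float, blood: BloodProperties
) -> tuple[float, float]:
    """Poiseuille resistance and inertance of one segment, clinical units."""
    a = area_mm2 * 1e-6
    l = length_mm * 1e-3
    r_si = 8.0 * np.pi * blood.viscosity * l / a**2  # == 8 mu l / (pi r_eq^4)
    li_si = blood.density * l / a
    return r_si * _R_SI_TO_CLINICAL, li_si * _R_SI_TO_CLINICAL


def _tear_element_values(
    area_mm2: float,
    flap_thickness_mm: float,
    orifice_coefficient: float,
    blood: BloodProperties,
) -> tuple[float, float]:
    """Linear + quadratic coefficients of a tear orifice, clinical units."""
    a = area_mm2 * 1e-6
    l = flap_thickness_mm * 1e-3
    r_lin_si = 8.0 * np.pi * blood.viscosity * l / a**2
    c_si = blood.density * orifice_coefficient / (2.0 * a**2)
    return r_lin_si * _R_SI_TO_CLINICAL, c_si * _Q2_SI_TO_CLINICAL


def build_network(
    model: DissectionModel,
    blood: BloodProperties | None = None,
    station_merge: float = 5.0,
    flap_thickness_mm: float = 2.0,
    orifice_coefficient: float = 1.0,
    tear_attach_max_mm: float = 25.0,
    outlets: list[tuple[float, WindkesselOutlet]] | None = None,
) -> NetworkModel:
    """Discretise a dissection geometry into a TL/FL element network.

    Stations closer than ``station_merge`` mm are merged.  A true-lumen
    node is created at every kept station and a false-lumen node wherever
    the FL is patent; thrombosed FL stations are absent from the graph.
    Tears attach to the nearest TL and patent-FL nodes; a tear whose
    nearest patent FL node is farther than ``tear_attach_max_mm`` (e.g.
    sealed off by thrombus) is treated as occluded and dropped.

    ``outlets`` is a list of ``(arc position mm, WindkesselOutlet)`` or
    ``(arc, WindkesselOutlet, "TL"|"FL")`` entries (TL when unspecified);
    an outlet attaches to its lumen's nearest node.  A distal FL outlet
    represents a dissection extending beyond the modeled segment (the
    false lumen stays patent into the abdominal aorta); omit it for a
    false lumen that dead-ends within the domain.  When ``outlets`` is
    omitted, ``model.outlets`` is used.
    """
    blood = blood or BloodProperties()
    outlets = outlets if outlets is not None else model.outlets
    if not outlets:
        raise NetworkError(
            "no outlets defined: supply (arc, WindkesselOutlet) pairs or set "
            "model.outlets (see calibrate_windkessel)"
        )

    # merge stations, always retaining the first and last
    kept = [0]
    for i in range(1, len(model.stations)):
        if model.stations[i].arc_mm - model.stations[kept[-1]].arc_mm >= station_merge:
            kept.append(i)
    if kept[-1] != len(model.stations) - 1:
        kept.append(len(model.stations) - 1)

    for i in kept:
        if model.stations[i].tl_area <= 0:
            raise NetworkError(
                f"zero TL area at station {model.stations[i].arc_mm} mm"
            )

    nodes: list[NetworkNode] = []
    tl_node_of: dict[int, int] = {}
    fl_node_of: dict[int, int] = {}
    for i in kept:
        tl_node_of[i] = len(nodes)
        nodes.append(NetworkNode("TL", model.stations[i].arc_mm))
    for i in kept:
        if model.stations[i].fl_area > 0:
            fl_node_of[i] = len(nodes)
            nodes.append(NetworkNode("FL", model.stations[i].arc_mm))

    elements: list[NetworkElement] = []
    for i, j in zip(kept[:-1], kept[1:]):
        si, sj = model.stations[i], model.stations[j]
        length = sj.arc_mm - si.arc_mm
        r, li = _segment_rl(0.5 * (si.tl_area + sj.tl_area), length, blood)
        elements.append(NetworkElement(tl_node_of[i], tl_node_of[j], r, li))
    # FL chain: connect consecutive patent stations unless an intervening
    # station (kept or not) is non-patent, which blocks the channel
    for i, j in zip(kept[:-1], kept[1:]):
        if i not in fl_node_of or j not in fl_node_of:
            continue
        between = [
            s for s in model.stations if model.stations[i].arc_mm < s.arc_mm < model.stations[j].arc_mm
        ]
        if any(s.fl_area <= 0 for s in between):
            continue
        si, sj = model.stations[i], model.stations[j]
        length = sj.arc_mm - si.arc_mm
        r, li = _segment_rl(0.5 * (si.fl_area + sj.fl_area), length, blood)
        elements.append(NetworkElement(fl_node_of[i], fl_node_of[j], r, li))

    tl_arcs = np.array([model.stations[i].arc_mm for i in kept])
    fl_items = sorted(fl_node_of.items(), key=lambda kv: model.stations[kv[0]].arc_mm)
    fl_arcs = np.array([model.stations[i].arc_mm for i, _ in fl_items])
    n_patent_tears = 0
    for tear in model.tears:
        if tear.area_mm2 <= 0:
            continue
        if len(fl_arcs) == 0:
            continue
        k_fl = int(np.argmin(np.abs(fl_arcs - tear.arc_mm)))
        if abs(fl_arcs[k_fl] - tear.arc_mm) > tear_attach_max_mm:
            continue  # occluded by thrombus: no patent FL nearby
        k_tl = int(np.argmin(np.abs(tl_arcs - tear.arc_mm)))
        r_lin, c = _tear_element_values(
            tear.area_mm2, flap_thickness_mm, orifice_coefficient, blood
        )
        elements.append(
            NetworkElement(
                tl_node_of[kept[k_tl]],
                fl_items[k_fl][1],
                r_lin,
                0.0,
                c,
                kind="tear",
                tear_area_mm2=tear.area_mm2,
            )
        )
        n_patent_tears += 1
    if fl_node_of and n_patent_tears == 0:
        raise NetworkError(
            "no patent tear connects the lumens; a false lumen without a "
            "communication carries no flow"
        )
    if not fl_node_of:
        raise NetworkError("fully thrombosed false lumen: no FL flow domain")

    inlet = int(np.argmin(np.abs(tl_arcs - model.inlet_arc)))
    wk_list = []
    for entry in outlets:
        arc, wk = entry[0], entry[1]
        lumen = entry[2] if len(entry) > 2 else "TL"
        if lumen == "TL":
            node = tl_node_of[kept[int(np.argmin(np.abs(tl_arcs - arc)))]]
        elif lumen == "FL":
            if len(fl_arcs) == 0:
                raise NetworkError("FL outlet requested but no patent FL nodes")
            node = fl_items[int(np.argmin(np.abs(fl_arcs - arc)))][1]
        else:
            raise NetworkError(f"unknown outlet lumen {lumen!r}")
        wk_list.append((node, wk))
    return NetworkModel(
        nodes=nodes,
        elements=elements,
        inlet=tl_node_of[kept[inlet]],
        outlets=wk_list,
        blood=blood,
    )


# ---------------------------------------------------------------------------
# Windkessel calibration
# ---------------------------------------------------------------------------


def _windkessel_pressure(
    wk: WindkesselOutlet, q: np.ndarray, dt: float, n_cycles: int = 60
) -> np.ndarray:
    """Node pressure of one Windkessel driven by flow ``q`` (one cycle),
    integrated implicitly to the periodic state."""
    q_mean = np.trapezoid(q, dx=dt) / (dt * (len(q) - 1))
    pc = wk.p_distal + q_mean * wk.r_distal
    alpha = 1.0 + dt / (wk.compliance * wk.r_distal)
    pc_hist = np.empty_like(q)
    for _ in range(n_cycles):
        start = pc
        pc_hist[0] = pc
        for j in range(1, len(q)):
            pc = (
                pc
                + dt / wk.compliance * (q[j] + wk.p_distal / wk.r_distal)
            ) / alpha
            pc_hist[j] = pc
        if abs(pc - start) < 1e-7:
            break
    return pc_hist + wk.r_proximal * q


def calibrate_windkessel(
    systolic: float,
    diastolic: float,
    inlet: FlowWaveform,
    splits: Sequence[float] = (1.0,),
    p_reference: float = 0.0,
    r1_fraction: float = 0.056,
    pulse_tol_mmhg: float = 2.0,
    c_bounds: tuple[float, float] = (1e-4, 100.0),
) -> list[WindkesselOutlet]:
    """Windkessel parameters matching target systolic/diastolic pressure.

    The total peripheral resistance of each outlet is fixed by the mean:
    ``R1 + R2 = (MAP - p_reference) / (split * mean flow)`` with
    ``MAP = diastolic + pulse pressure / 3``; ``R1`` is a stated fraction
    of the total (default 5.6%).  Compliance is then found by bisection
    so the pulse pressure of the outlet driven by its flow share matches
    ``systolic - diastolic`` within ``pulse_tol_mmhg``.  Because the MAP
    estimate assumes a fixed waveform shape factor, an outer loop trims
    the total resistance until simulated systolic and diastolic both sit
    within the tolerance.
    """
    if not systolic > diastolic > p_reference:
        raise ValueError("require systolic > diastolic > reference pressure")
    if abs(sum(splits) - 1.0) > 1e-9:
        raise ValueError("outlet flow splits must sum to 1")
    target_pp = systolic - diastolic
    map_ = diastolic + target_pp / 3.0
    dt = inlet.period / 1000.0
    tgrid = np.arange(0.0, inlet.period + dt / 2, dt)
    out: list[WindkesselOutlet] = []
    for split in splits:
        rtot = (map_ - p_reference) / (split * inlet.mean_flow)
        q = split * inlet.at(tgrid)
        for _trim in range(20):
            r1 = r1_fraction * rtot
            r2 = rtot - r1

            def pulse_pressure(c: float) -> float:
                wk = WindkesselOutlet(r1, r2, c, p_reference)
                p = _windkessel_pressure(wk, q, dt)
                return float(p.max() - p.min())

            lo, hi = c_bounds
            f_lo = pulse_pressure(lo) - target_pp
            f_hi = pulse_pressure(hi) - target_pp
            if f_lo < 0 or f_hi > 0:
                raise SolverError(
                    "compliance bisection bracket failed: pulse pressure at "
                    f"C={lo} is {f_lo + target_pp:.2f} mmHg, at C={hi} is "
                    f"{f_hi + target_pp:.2f} mmHg (target {target_pp:.2f})"
                )
            for _ in range(100):
                mid = np.sqrt(lo * hi)  # bisect in log space: C spans decades
                f_mid = pulse_pressure(mid) - target_pp
                if abs(f_mid) < 0.5 * pulse_tol_mmhg:
                    break
                if f_mid > 0:
                    lo = mid
                else:
                    hi = mid
            else:
                raise SolverError(
                    f"compliance bisection did not converge in [{lo}, {hi}]"
                )
            wk = WindkesselOutlet(r1, r2, mid, p_reference)
            p = _windkessel_pressure(wk, q, dt)
            if (
                abs(p.max() - systolic) < pulse_tol_mmhg
                and abs(p.min() - diastolic) < pulse_tol_mmhg
            ):
                break
            rtot += (systolic - float(p.max())) / (split * inlet.mean_flow)
        else:
            raise SolverError(
                "resistance trim loop did not reach the systolic/diastolic "
                f"targets (last {p.max():.2f}/{p.min():.2f} mmHg)"
            )
        out.append(wk)
    return out


# ---------------------------------------------------------------------------
# periodic solver
# ---------------------------------------------------------------------------


def simulate(
    network: NetworkModel,
    inlet: FlowWaveform,
    max_cycles: int = 20,
    dt: float | None = None,
    tol: float = 0.01,
    newton_tol: float = 1e-9,
    max_newton: int = 30,
) -> SimulationResult:
    """Integrate the network to a time-periodic state.

    Implicit-Euler time stepping with a damped-Newton solve of the
    coupled nodal-pressure / element-flow / Windkessel system at every
    step (the tear orifice law is the only nonlinearity).  Cycles repeat
    until the nodal pressure field changes by less than ``tol`` (mmHg)
    between consecutive cycles, up to ``max_cycles``.  The approach to
    the periodic orbit is dominated by the slow Windkessel relaxation
    (time constant R2*C, typically a few cycles), so the capacitor state
    is Aitken-extrapolated at cycle boundaries; convergence is still
    verified on full subsequent cycles.

    Returns the converged cycle; raises :class:`SolverError` with the
    residual history on non-convergence.
    """
    T = inlet.period
    if dt is None:
        dt = T / 1000.0
    if dt > T / 200.0:
        raise ValueError("dt must be at most period/200")
    nt = int(round(T / dt))
    dt = T / nt
    tgrid = np.linspace(0.0, T, nt + 1)
    q_in = inlet.at(tgrid)

    n = len(network.nodes)
    m = len(network.elements)
    k = len(network.outlets)
    a_idx = np.array([e.node_a for e in network.elements], dtype=int)
    b_idx = np.array([e.node_b for e in network.elements], dtype=int)
    R = np.array([e.resistance for e in network.elements])
    L = np.array([e.inertance for e in network.elements])
    cq = np.array([e.quad_coeff for e in network.elements])
    nl = np.nonzero(cq > 0)[0]
    o_node = np.array([i for i, _ in network.outlets], dtype=int)
    r1 = np.array([wk.r_proximal for _, wk in network.outlets])
    r2 = np.array([wk.r_distal for _, wk in network.outlets])
    cwk = np.array([wk.compliance for _, wk in network.outlets])
    pref = np.array([wk.p_distal for _, wk in network.outlets])

    N = n + m + k
    iQ, iC = n, n + m

    # constant part of the Jacobian
    J0 = np.zeros((N, N))
    for e in range(m):
        J0[a_idx[e], iQ + e] -= 1.0  # flow leaves node_a
        J0[b_idx[e], iQ + e] += 1.0
        J0[iQ + e, a_idx[e]] += 1.0
        J0[iQ + e, b_idx[e]] -= 1.0
        J0[iQ + e, iQ + e] = -(R[e] + L[e] / dt)
    for o in range(k):
        J0[o_node[o], o_node[o]] -= 1.0 / r1[o]
        J0[o_node[o], iC + o] += 1.0 / r1[o]
        J0[iC + o, iC + o] = cwk[o] / dt + 1.0 / r1[o] + 1.0 / r2[o]
        J0[iC + o, o_node[o]] -= 1.0 / r1[o]

    # initial state: capacitors at their steady operating point, equal splits
    share = inlet.mean_flow / k
    P = np.full(n, float(np.mean(pref + share * (r1 + r2))))
    Q = np.zeros(m)
    Pc = pref + share * r2

    def residual(P, Q, Pc, qin_t, Q_prev, Pc_prev) -> np.ndarray:
        F = np.zeros(N)
        np.add.at(F, b_idx, Q)
        np.add.at(F, a_idx, -Q)
        F[network.inlet] += qin_t
        q_out = (P[o_node] - Pc) / r1
        np.add.at(F, o_node, -q_out)
        F[iQ : iQ + m] = (
            P[a_idx]
            - P[b_idx]
            - R * Q
            - cq * Q * np.abs(Q)
            - (L / dt) * (Q - Q_prev)
        )
        F[iC:] = (cwk / dt) * (Pc - Pc_prev) - q_out + (Pc - pref) / r2
        return F

    scale = max(1.0, abs(share) * float((r1 + r2).max()))
    p_hist = np.empty((n, nt + 1))
    q_hist = np.empty((m, nt + 1))
    pc_hist = np.empty((k, nt + 1))
    prev_cycle: np.ndarray | None = None
    history: list[float] = []
    converged = False
    pc_starts: list[np.ndarray] = []

    for _cycle in range(max_cycles):
        pc_starts.append(Pc.copy())
        if len(pc_starts) >= 3:
            # Aitken extrapolation of the slow Windkessel relaxation
            d1 = pc_starts[-2] - pc_starts[-3]
            d2 = pc_starts[-1] - pc_starts[-2]
            denom = float(d1 @ d1)
            if denom > 0:
                r = float(d2 @ d1) / denom
                if 1e-3 < r < 0.98:
                    Pc = Pc + d2 * r / (1.0 - r)
                    pc_starts = [Pc.copy()]
                    prev_cycle = None  # re-verify periodicity after the jump
        p_hist[:, 0], q_hist[:, 0], pc_hist[:, 0] = P, Q, Pc
        for j in range(1, nt + 1):
            Q_prev, Pc_prev = Q.copy(), Pc.copy()
            for _it in range(max_newton):
                F = residual(P, Q, Pc, q_in[j], Q_prev, Pc_prev)
                if np.abs(F).max() < newton_tol * scale:
                    break
                J = J0.copy()
                J[iQ + nl, iQ + nl] -= 2.0 * cq[nl] * np.abs(Q[nl])
                delta = np.linalg.solve(J, -F)
                P += delta[:n]
                Q += delta[iQ : iQ + m]
                Pc += delta[iC:]
            else:
                raise SolverError(
                    f"Newton failed at t={tgrid[j]:.4f}s "
                    f"(|F|={np.abs(F).max():.3e})",
                    history,
                )
            p_hist[:, j], q_hist[:, j], pc_hist[:, j] = P, Q, Pc
        if prev_cycle is not None:
            metric = float(np.abs(p_hist - prev_cycle).max())
            history.append(metric)
            if metric < tol:
                converged = True
                break
        prev_cycle = p_hist.copy()
    if not converged:
        raise SolverError(
            f"no periodic state within {max_cycles} cycles "
            f"(last residual {history[-1] if history else float('nan'):.4f} mmHg)",
            history,
        )
    out_flows = (p_hist[o_node, :] - pc_hist) / r1[:, None]
    return SimulationResult(
        time=tgrid,
        node_pressures=p_hist.copy(),
        element_flows=q_hist.copy(),
        wk_pressures=pc_hist.copy(),
        outlet_flows=out_flows,
        inlet_flow=q_in,
        convergence=history,
        converged=True,
        network=network,
    )


def volume_balance(result: SimulationResult) -> tuple[float, float, float]:
    """Cycle-integrated inlet volume, summed outlet volume and their
    relative mismatch (fraction of the inlet volume)."""
    v_in = float(np.trapezoid(result.inlet_flow, result.time))
    v_out = float(np.trapezoid(result.outlet_flows.sum(axis=0), result.time))
    return v_in, v_out, abs(v_out - v_in) / abs(v_in)


# ---------------------------------------------------------------------------
# plane pressures and the PD statistic
# ---------------------------------------------------------------------------


def plane_pressures(
    result: SimulationResult,
    planes: PlaneSet,
    max_gap_mm: float = 45.0,
) -> dict[str, dict[str, np.ndarray | None]]:
    """Per-plane TL and FL pressure waveforms (mmHg).

    The 0-D nodal pressure stands for the lumen's cross-sectional mean;
    planes between nodes are linearly interpolated in arc position.  The
    FL entry is ``None`` where the plane falls outside the patent FL
    extent or inside a thrombosed gap wider than ``max_gap_mm``.
    """
    out: dict[str, dict[str, np.ndarray | None]] = {}
    lum_data = {}
    for lumen in ("TL", "FL"):
        idx = result.network.node_indices(lumen)
        arcs = np.array([result.network.nodes[i].arc_mm for i in idx])
        order = np.argsort(arcs)
        lum_data[lumen] = (
            arcs[order],
            result.node_pressures[np.array(idx, dtype=int)[order], :]
            if idx
            else np.empty((0, len(result.time))),
        )
    for pid, pos, _ in planes:
        entry: dict[str, np.ndarray | None] = {}
        for lumen in ("TL", "FL"):
            arcs, pw = lum_data[lumen]
            if len(arcs) == 0 or pos < arcs[0] - 1e-9 or pos > arcs[-1] + 1e-9:
                entry[lumen.lower()] = None
                continue
            j = int(np.clip(np.searchsorted(arcs, pos), 1, len(arcs) - 1))
            gap = arcs[j] - arcs[j - 1]
            if (
                lumen == "FL"
                and gap > max_gap_mm
                and not (
                    abs(pos - arcs[j]) < 1e-9 or abs(pos - arcs[j - 1]) < 1e-9
                )
            ):
                entry[lumen.lower()] = None  # plane inside a thrombosed gap
                continue
            w = 0.0 if gap == 0 else (pos - arcs[j - 1]) / gap
            entry[lumen.lower()] = (1 - w) * pw[j - 1] + w * pw[j]
        out[pid] = entry
    return out


def mirror_network(
    outlet: WindkesselOutlet, n_chain: int = 12
) -> tuple[NetworkModel, PlaneSet]:
    """Perfectly mirror-symmetric TL/FL network for null-PD verification.

    A shared junction feeds two identical chains (one tagged TL, one FL)
    through identical tear elements; the chains rejoin through identical
    tears at a shared pre-outlet node.  By symmetry the two lumens carry
    identical pressures at matching arc positions, so any computed
    pressure difference is pure solver error.
    """
    arcs = np.linspace(0.0, 330.0, n_chain)
    nodes = [NetworkNode("TL", -10.0)]
    tl: list[int] = []
    fl: list[int] = []
    for arc in arcs:
        tl.append(len(nodes))
        nodes.append(NetworkNode("TL", float(arc)))
    for arc in arcs:
        fl.append(len(nodes))
        nodes.append(NetworkNode("FL", float(arc)))
    out_node = len(nodes)
    nodes.append(NetworkNode("TL", 340.0))

    tear = dict(resistance=1e-4, quad_coeff=3e-4, kind="tear", tear_area_mm2=70.0)
    seg = dict(resistance=5e-4, inertance=1.2e-3)
    elements = [
        NetworkElement(0, tl[0], **tear),
        NetworkElement(0, fl[0], **tear),
    ]
    for a, b in zip(tl[:-1], tl[1:]):
        elements.append(NetworkElement(a, b, **seg))
    for a, b in zip(fl[:-1], fl[1:]):
        elements.append(NetworkElement(a, b, **seg))
    elements.append(NetworkElement(tl[-1], out_node, **tear))
    elements.append(NetworkElement(fl[-1], out_node, **tear))
    net = NetworkModel(
        nodes=nodes, elements=elements, inlet=0, outlets=[(out_node, outlet)]
    )
    plane_arcs = arcs[1:-1].copy()
    planes = PlaneSet(
        ids=[f"P{i + 1}" for i in range(len(plane_arcs))],
        arc_positions=plane_arcs,
        normals=np.tile([0.0, 0.0, -1.0], (len(plane_arcs), 1)),
    )
    return net, planes


def pd_statistic(
    tl_wave: np.ndarray,
    fl_wave: np.ndarray,
    signed: bool = True,
) -> tuple[np.ndarray, float]:
    """TL-FL pressure-difference waveform and its cycle maximum.

    ``PD(t) = P_TL(t) - P_FL(t)``; the summary is the signed maximum over
    the cycle by default (set ``signed=False`` for the maximum absolute
    difference).
    """
    tl = np.asarray(tl_wave, dtype=float)
    fl = np.asarray(fl_wave, dtype=float)
    if tl.shape != fl.shape:
        raise ValueError(
            f"waveforms are on different grids: {tl.shape} vs {fl.shape}"
        )
    pd_wave = tl - fl
    peak = float(pd_wave.max()) if signed else float(np.abs(pd_wave).max())
    return pd_wave, peak
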