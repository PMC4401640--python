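"""Steady Poiseuille flow on a vessel network, wall shear stress, and
flow-direction fields.

The solver treats each perfused segment as a rigid cylindrical tube of mean
radius r and length L carrying laminar Newtonian flow, so its hydraulic
conductance is G = π r⁴ / (8 μ L).  Node pressures solve the Kirchhoff
conservation system with Dirichlet pressures at inlet/outlet nodes; per-
segment flow is Q = G (P_a − P_b), mean velocity v = Q / (π r²) and wall
shear stress τ = 4 μ |Q| / (π r³).

Only the magnitude and orientation of τ and Q feed the downstream polarity
and regression statistics, which is why a 1-D network model (rather than a
full 3-D CFD solve) is used throughout: comparisons are ordinal across
segments, and the pressure scale is an arbitrary boundary-condition choice.

Units: lengths μm, pressure Pa, viscosity Pa·s ⇒ Q in μm³/s, v in μm/s,
τ in Pa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .network import VesselNetwork, warn

#: default plasma-like dynamic viscosity, Pa·s
DEFAULT_VISCOSITY = 3.5e-3
#: default inlet/outlet pressures, Pa (arbitrary scale; only ratios matter)
DEFAULT_INLET_PRESSURE = 60.0
DEFAULT_OUTLET_PRESSURE = 0.0
#: segments with lumen_fraction below this are treated as non-perfused
DEFAULT_LUMEN_CUTOFF = 0.5


class FlowError(ValueError):
    """Raised when the flow problem is ill-posed (no inlet→outlet path,
    zero radius on a perfused segment, missing boundary conditions)."""


@dataclass
class BoundaryConditions:
    """Dirichlet pressure boundary conditions for the network solve."""

    inlet_pressure: dict[int, float]
    outlet_pressure: dict[int, float]
    viscosity: float = DEFAULT_VISCOSITY

    def __post_init__(self) -> None:
        if not self.inlet_pressure or not self.outlet_pressure:
            raise FlowError("need at least one inlet and one outlet")
        if self.viscosity <= 0:
            raise FlowError("viscosity must be > 0")
        if min(self.inlet_pressure.values()) <= max(
            self.outlet_pressure.values()
        ):
            raise FlowError("inlet pressure must exceed outlet pressure")

    @classmethod
    def default_for(cls, net: VesselNetwork,
                    inlet_pressure: float = DEFAULT_INLET_PRESSURE,
                    outlet_pressure: float = DEFAULT_OUTLET_PRESSURE,
                    viscosity: float = DEFAULT_VISCOSITY
                    ) -> "BoundaryConditions":
        """All network inlets at one pressure, all outlets at another."""
        if not net.inlets or not net.outlets:
            raise FlowError("network declares no inlets/outlets")
        return cls(
            inlet_pressure={n: inlet_pressure for n in net.inlets},
            outlet_pressure={n: outlet_pressure for n in net.outlets},
            viscosity=viscosity,
        )


@dataclass
class FlowSolution:
    """Node pressures and per-segment haemodynamic quantities."""

    node_pressure: dict[int, float]
    flow: dict[int, float]  # signed Q w.r.t. (a → b), μm³/s
    velocity: dict[int, float]  # mean |v|, μm/s
    tau: dict[int, float]  # wall shear stress, Pa (≥ 0)
    perfused: dict[int, bool]
    flow_dir: dict[int, np.ndarray] = field(default_factory=dict)
    viscosity: float = DEFAULT_VISCOSITY

    def segment_flow_dir_mean(self, sid: int) -> np.ndarray:
        """Mean oriented unit tangent of a segment (NaN if unperfused)."""
        d = self.flow_dir.get(sid)
        if d is None or np.any(np.isnan(d)):
            return np.array([np.nan, np.nan])
        m = d.mean(axis=0)
        n = np.hypot(*m)
        return m / n if n > 0 else np.array([np.nan, np.nan])

    def to_frame(self, net: VesselNetwork) -> pd.DataFrame:
        rows = []
        for sid in sorted(net.segments):
            d = self.segment_flow_dir_mean(sid)
            rows.append(
                {
                    "segment_id": sid,
                    "Q": self.flow[sid],
                    "v": self.velocity[sid],
                    "tau": self.tau[sid],
                    "dir_x": d[0],
                    "dir_y": d[1],
                    "perfused": self.perfused[sid],
                }
            )
        return pd.DataFrame(rows)


def _polyline_tangents(polyline: np.ndarray) -> np.ndarray:
    """Unit tangent at each polyline vertex (central differences)."""
    diffs = np.gradient(polyline, axis=0)
    norms = np.hypot(*diffs.T)
    norms[norms == 0] = 1.0
    return diffs / norms[:, None]


def solve_flow(net: VesselNetwork, bc: BoundaryConditions | None = None,
               lumen_cutoff: float = DEFAULT_LUMEN_CUTOFF) -> FlowSolution:
    """Solve the Kirchhoff pressure system and derive Q, v, τ, flow_dir.

    Segments with ``lumen_fraction < lumen_cutoff`` are excluded from the
    conductance matrix (non-perfused).  Blind-ended (tip) branches carry
    Q = 0 exactly; connected components without a boundary node are set to
    the outlet pressure with a warning.
    """
    if bc is None:
        bc = BoundaryConditions.default_for(net)
    mu = bc.viscosity
    fixed: dict[int, float] = {}
    fixed.update(bc.outlet_pressure)
    fixed.update(bc.inlet_pressure)
    for nid in fixed:
        if nid not in net.nodes:
            raise FlowError(f"boundary node {nid} not in network")

    included = {
        sid
        for sid, seg in net.segments.items()
        if seg.lumen_fraction >= lumen_cutoff
    }
    for sid in included:
        if net.segments[sid].mean_radius <= 0:
            raise FlowError(f"segment {sid} has zero radius but is perfused")

    # Components of the perfused subgraph with no boundary node are
    # stagnant: flag them before tip-stripping would silently consume them.
    import networkx as nx

    g_inc = nx.Graph()
    for sid in included:
        seg = net.segments[sid]
        g_inc.add_edge(seg.a, seg.b)
    outlet_p = min(bc.outlet_pressure.values())
    pressure: dict[int, float] = {}
    stagnant_segments: set[int] = set()
    for comp in nx.connected_components(g_inc):
        if not (comp & set(fixed)):
            warn(
                f"component of {len(comp)} nodes has no boundary node; "
                "setting pressure to outlet level, Q = 0"
            )
            for n in comp:
                pressure[n] = outlet_p
            for sid in list(included):
                if net.segments[sid].a in comp:
                    stagnant_segments.add(sid)
                    included.discard(sid)

    # Iteratively strip blind-ended branches (degree-1 non-boundary nodes):
    # they cannot carry steady flow, so their Q is exactly zero.
    deg: dict[int, int] = {nid: 0 for nid in net.nodes}
    adj: dict[int, set[int]] = {nid: set() for nid in net.nodes}
    for sid in included:
        seg = net.segments[sid]
        deg[seg.a] += 1
        deg[seg.b] += 1
        adj[seg.a].add(sid)
        adj[seg.b].add(sid)
    active = set(included)
    frontier = [n for n, d in deg.items() if d == 1 and n not in fixed]
    while frontier:
        n = frontier.pop()
        if deg[n] != 1 or n in fixed:
            continue
        (sid,) = [s for s in adj[n] if s in active]
        active.discard(sid)
        seg = net.segments[sid]
        for endpoint in (seg.a, seg.b):
            deg[endpoint] -= 1
            if deg[endpoint] == 1 and endpoint not in fixed:
                frontier.append(endpoint)

    # Conductances of the active core.
    conduct: dict[int, float] = {}
    for sid in active:
        seg = net.segments[sid]
        r, length = seg.mean_radius, seg.length
        conduct[sid] = np.pi * r**4 / (8.0 * mu * length)

    # Connected components of the active core; those without a boundary node
    # are stagnant.
    core_nodes = sorted(
        {net.segments[s].a for s in active}
        | {net.segments[s].b for s in active}
        | set(fixed)
    )
    g = nx.Graph()
    g.add_nodes_from(core_nodes)
    for sid in active:
        seg = net.segments[sid]
        g.add_edge(seg.a, seg.b)
    solvable_nodes: list[int] = []
    inlet_nodes = set(bc.inlet_pressure)
    outlet_nodes = set(bc.outlet_pressure)
    has_path = False
    for comp in nx.connected_components(g):
        if comp & inlet_nodes and comp & outlet_nodes:
            has_path = True
        solvable_nodes.extend(comp)
    if not has_path:
        raise FlowError("no inlet→outlet path in the perfused network")

    solve_set = [n for n in solvable_nodes if n not in fixed]
    index = {n: i for i, n in enumerate(solve_set)}
    n_unknown = len(solve_set)
    rows, cols, vals = [], [], []
    rhs = np.zeros(n_unknown)
    diag = np.zeros(n_unknown)
    for sid in active:
        if sid in stagnant_segments:
            continue
        seg = net.segments[sid]
        gcond = conduct[sid]
        for u, v in ((seg.a, seg.b), (seg.b, seg.a)):
            if u in index:
                i = index[u]
                diag[i] += gcond
                if v in index:
                    rows.append(i)
                    cols.append(index[v])
                    vals.append(-gcond)
                else:
                    rhs[i] += gcond * fixed[v]
    if n_unknown:
        lap = sp.coo_matrix(
            (
                np.concatenate([vals, diag]),
                (
                    np.concatenate([rows, np.arange(n_unknown)]).astype(int),
                    np.concatenate([cols, np.arange(n_unknown)]).astype(int),
                ),
            ),
            shape=(n_unknown, n_unknown),
        ).tocsr()
        sol = spla.spsolve(lap, rhs)
        for n, i in index.items():
            pressure[n] = float(sol[i])
    pressure.update({n: float(p) for n, p in fixed.items()})

    # Any node never touched (isolated boundary-less, or only on excluded
    # segments) gets the outlet pressure.
    for nid in net.nodes:
        pressure.setdefault(nid, outlet_p)

    flow: dict[int, float] = {}
    velocity: dict[int, float] = {}
    perfused: dict[int, bool] = {}
    for sid, seg in net.segments.items():
        if sid in active and sid not in stagnant_segments:
            q = conduct[sid] * (pressure[seg.a] - pressure[seg.b])
        else:
            q = 0.0
        flow[sid] = q
        r = seg.mean_radius
        velocity[sid] = abs(q) / (np.pi * r**2) if r > 0 else 0.0
        perfused[sid] = sid in active and q != 0.0

    sol = FlowSolution(
        node_pressure=pressure,
        flow=flow,
        velocity=velocity,
        tau={sid: 0.0 for sid in net.segments},
        perfused=perfused,
        viscosity=mu,
    )
    return wall_shear(net, sol)


def wall_shear(net: VesselNetwork, flow: FlowSolution) -> FlowSolution:
    """Fill in τ = 4 μ |Q| / (π r³) and oriented per-vertex flow directions.

    The flow direction at each polyline vertex is the centerline tangent,
    flipped where Q < 0; it is NaN-flagged on segments with Q = 0.
    """
    mu = flow.viscosity
    for sid, seg in net.segments.items():
        q = flow.flow[sid]
        r = seg.mean_radius
        flow.tau[sid] = 4.0 * mu * abs(q) / (np.pi * r**3) if r > 0 else 0.0
        tangents = _polyline_tangents(seg.polyline)
        if q > 0:
            flow.flow_dir[sid] = tangents
        elif q < 0:
            flow.flow_dir[sid] = -tangents
        else:
            flow.flow_dir[sid] = np.full_like(tangents, np.nan)
    return flow


def classify_flow(net: VesselNetwork, flow: FlowSolution,
                  low_q: float = 0.25) -> dict[int, str]:
    """Label perfused segments 'low'/'high' by the τ quantile ``low_q``.

    Segments strictly below the quantile are 'low'; ties at the threshold
    (including the all-equal case) are 'high'.  Non-perfused segments are
    not labeled.  Refuses to classify fewer than 4 perfused segments.
    """
    perf = [sid for sid in sorted(net.segments) if flow.perfused[sid]]
    if len(perf) < 4:
        raise FlowError(
            f"classification refused: only {len(perf)} perfused segments"
        )
    taus = np.array([flow.tau[sid] for sid in perf])
    thresh = float(np.quantile(taus, low_q))
    return {
        sid: ("low" if flow.tau[sid] < thresh else "high") for sid in perf
    }


def conservation_residual(net: VesselNetwork, flow: FlowSolution,
                          bc: BoundaryConditions) -> float:
    """Max |Σ signed Q| over interior nodes, relative to max |Q|."""
    acc: dict[int, float] = {nid: 0.0 for nid in net.nodes}
    for sid, seg in net.segments.items():
        q = flow.flow[sid]
        acc[seg.a] -= q
        acc[seg.b] += q
    boundary = set(bc.inlet_pressure) | set(bc.outlet_pressure)
    qmax = max((abs(q) for q in flow.flow.values()), default=0.0)
    if qmax == 0:
        return 0.0
    return max(
        (abs(v) for n, v in acc.items() if n not in boundary), default=0.0
    ) / qmax
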