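"""Synthetic P6-retina generator with known ground truth.

Generates a planar retinal plexus (radial arteries/veins from the optic
center, a jittered polar capillary mesh between them, blind-ended sprouts at
the outer rim), endothelial cells as nucleus+Golgi point pairs whose axial
polarity is drawn relative to the local flow direction, planted regression
profiles at the four morphological stages, and planted apoptosis events with
a configurable colocalization rate.  Everything the detector or the polarity
statistics might recover is recorded in a :class:`GroundTruth` object so each
downstream stage can be tested by planted-parameter recovery.

Default parameters reproduce the scale of a whole P6 mouse retina:
~16,000 endothelial cells, a mean of 78.1 apoptosis events per retina, and
4.82 % of regression profiles colocalized with an apoptotic event.

One master seed drives everything; per-stage substreams are derived by fixed
offsets so stages can be regenerated independently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .flow import BoundaryConditions, FlowSolution, solve_flow
from .network import ImageStack, NetworkLocator, Segment, VesselNetwork, \
    densify_polyline

# substream offsets off the master seed
_SUB_NETWORK, _SUB_CELLS, _SUB_REGRESSION, _SUB_APOPTOSIS = 0, 1, 2, 3

STAGE_SELECTION, STAGE_STENOSIS, STAGE_RETRACTION, STAGE_RESOLUTION = 1, 2, 3, 4


class ConfigurationError(ValueError):
    """Raised for infeasible generator configurations."""


class PreconditionError(RuntimeError):
    """Raised when an operation is called before its inputs exist."""


@dataclass
class PolarityModel:
    """How cell polarity directions are drawn.

    ``vonmises_against_flow`` samples the angle between the polarity vector
    and the local flow direction from a von Mises distribution centered at
    180° with concentration ``kappa`` (kappa=0 reduces to uniform); cells on
    unperfused segments always draw uniformly.  ``magnitude_mean/sd`` set the
    nucleus→Golgi distance in μm (truncated at zero).
    """

    mode: str = "vonmises_against_flow"  # or "uniform"
    kappa: float = 4.0
    magnitude_mean: float = 5.0
    magnitude_sd: float = 1.5

    def validate(self) -> None:
        if self.mode not in ("uniform", "vonmises_against_flow"):
            raise ConfigurationError(f"unknown polarity mode {self.mode!r}")
        if self.kappa < 0:
            raise ConfigurationError("kappa must be ≥ 0")
        if self.magnitude_mean < 0 or self.magnitude_sd < 0:
            raise ConfigurationError("magnitudes must be ≥ 0")


@dataclass
class GenConfig:
    """Generator configuration; defaults are the whole-P6-retina scale."""

    retina_radius: float = 1000.0  # μm
    optic_center: tuple[float, float] = (0.0, 0.0)
    n_arteries: int = 5
    n_veins: int = 5
    capillary_spacing: float = 40.0  # μm
    radius_artery: float = 12.0  # μm
    radius_vein: float = 14.0
    radius_capillary: float = 3.2
    n_cells_target: int = 16000
    polarity_model: PolarityModel = field(default_factory=PolarityModel)
    density_gradient: float = 1.0  # central/peripheral linear density excess
    regression_rate: float = 0.05  # fraction of capillary segments
    stage_mix: tuple[float, float, float, float] = (0.1, 0.3, 0.3, 0.3)
    regression_bias: str = "low_flow"  # or "none"
    apoptosis_total_mean: float = 78.1  # Poisson mean per retina
    coloc_rate: float = 0.0482  # fraction of planted profiles with an event
    coloc_dist: float = 10.0  # μm, one cell-body radius
    capillary_dropout: float = 0.12
    sprout_prob: float = 0.5
    pixel_size: float = 1.0  # μm/px
    seed: int = 0

    def validate(self) -> None:
        for name in ("retina_radius", "capillary_spacing", "radius_artery",
                     "radius_vein", "radius_capillary", "coloc_dist",
                     "pixel_size"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        for name in ("regression_rate", "coloc_rate", "capillary_dropout",
                     "sprout_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if abs(sum(self.stage_mix) - 1.0) > 1e-9:
            raise ConfigurationError("stage_mix must sum to 1")
        if any(f < 0 for f in self.stage_mix):
            raise ConfigurationError("stage_mix fractions must be ≥ 0")
        if self.capillary_spacing >= self.retina_radius:
            raise ConfigurationError(
                "capillary_spacing must be smaller than retina_radius"
            )
        if self.regression_bias not in ("none", "low_flow"):
            raise ConfigurationError(
                f"unknown regression_bias {self.regression_bias!r}"
            )
        self.polarity_model.validate()

    def rng(self, offset: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(offset)])


@dataclass
class GroundTruth:
    """Planted parameters and event lists for recovery testing."""

    regression_stages: dict[int, int] = field(default_factory=dict)
    coloc_segments: list[int] = field(default_factory=list)
    apoptosis: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["x", "y", "coloc"])
    )
    cell_true: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["cell_id", "segment_id", "theta_true_deg"]
        )
    )
    density_gradient: float = 0.0

    def to_dict(self) -> dict:
        return {
            "regression_stages": {
                str(k): int(v) for k, v in sorted(
                    self.regression_stages.items())
            },
            "coloc_segments": [int(s) for s in self.coloc_segments],
            "apoptosis": self.apoptosis.to_dict(orient="list"),
            "cell_true": self.cell_true.to_dict(orient="list"),
            "density_gradient": self.density_gradient,
        }

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def _rot(v: np.ndarray, angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])


def _straight_polyline(p0: np.ndarray, p1: np.ndarray,
                       step: float = 8.0) -> np.ndarray:
    n = max(1, int(np.ceil(np.hypot(*(p1 - p0)) / step)))
    t = np.linspace(0.0, 1.0, n + 1)
    return p0[None, :] + t[:, None] * (p1 - p0)[None, :]


# ---------------------------------------------------------------------------
# network generation


def generate_network(cfg: GenConfig) -> VesselNetwork:
    """Build the radial spoke-and-mesh plexus.

    Arteries and veins alternate as radial spokes from the optic center;
    between them a jittered polar capillary lattice (ring + radial links,
    with angular resolution doubling outward and a random non-bridge
    dropout) forms the mesh; the outermost ring plus blind sprouts form the
    sprouting front.  Each artery ends in exactly one inlet node and each
    vein in one outlet node at the optic disc.
    """
    cfg.validate()
    if cfg.n_arteries < 1 or cfg.n_veins < 1:
        raise ConfigurationError(
            "need at least one artery and one vein (flow unsolvable)"
        )
    rng = cfg.rng(_SUB_NETWORK)
    center = np.asarray(cfg.optic_center, dtype=float)
    spacing = cfg.capillary_spacing
    n_main = cfg.n_arteries + cfg.n_veins
    # alternate arteries and veins around the disc
    spoke_region: list[str] = []
    na, nv = cfg.n_arteries, cfg.n_veins
    for i in range(n_main):
        if (i % 2 == 0 and na > 0) or nv == 0:
            spoke_region.append("artery")
            na -= 1
        else:
            spoke_region.append("vein")
            nv -= 1

    n_rings = int(np.floor((cfg.retina_radius - 0.75 * spacing) / spacing))
    if n_rings < 2:
        raise ConfigurationError(
            "capillary_spacing too large for retina_radius"
        )

    # angular resolution per ring: multiples of n_main, doubling outward
    ring_m: list[int] = []
    m = n_main
    for k in range(1, n_rings + 1):
        r_k = k * spacing
        while 2 * np.pi * r_k / m > 1.45 * spacing:
            m *= 2
        ring_m.append(m)

    net = VesselNetwork()
    next_node = 0
    node_of: dict[tuple[int, int], int] = {}  # (ring, angular index) -> id

    def add_node(pos: np.ndarray) -> int:
        nonlocal next_node
        nid = next_node
        net.nodes[nid] = np.asarray(pos, dtype=float)
        next_node += 1
        return nid

    for k in range(1, n_rings + 1):
        mk = ring_m[k - 1]
        r_k = k * spacing
        for j in range(mk):
            theta = 2 * np.pi * j / mk
            on_spoke = (j * n_main) % mk == 0
            jr = 0.0 if on_spoke else rng.normal(0.0, 0.05 * spacing)
            jt = 0.0 if on_spoke else rng.normal(0.0, 0.05 * spacing / r_k)
            pos = center + (r_k + jr) * np.array(
                [np.cos(theta + jt), np.sin(theta + jt)]
            )
            node_of[(k, j)] = add_node(pos)

    # ostium (inlet/outlet) nodes close to the optic center
    r_ostium = min(12.0, 0.3 * spacing)
    ostium: dict[int, int] = {}
    for s in range(n_main):
        theta = 2 * np.pi * s / n_main
        pos = center + r_ostium * np.array([np.cos(theta), np.sin(theta)])
        nid = add_node(pos)
        ostium[s] = nid
        if spoke_region[s] == "artery":
            net.inlets.append(nid)
        else:
            net.outlets.append(nid)

    next_seg = 0

    def add_segment(a: int, b: int, radius: float, region: str) -> int:
        nonlocal next_seg
        poly = _straight_polyline(net.nodes[a], net.nodes[b])
        sid = next_seg
        net.segments[sid] = Segment(
            a=a,
            b=b,
            polyline=poly,
            radius_profile=np.full(len(poly), radius),
            region=region,
        )
        next_seg += 1
        return sid

    def spoke_radius(region: str, k: int) -> float:
        root = cfg.radius_artery if region == "artery" else cfg.radius_vein
        t = k / n_rings
        return max(
            1.15 * cfg.radius_capillary, root * (1 - t) + 1.15
            * cfg.radius_capillary * t
        )

    def cap_radius() -> float:
        return cfg.radius_capillary * float(np.exp(rng.normal(0.0, 0.08)))

    # ostium -> ring 1 spoke segments
    for s in range(n_main):
        j1 = s * ring_m[0] // n_main
        add_segment(
            ostium[s], node_of[(1, j1)], spoke_radius(spoke_region[s], 0),
            spoke_region[s]
        )

    radial_capillaries: list[int] = []
    for k in range(1, n_rings):
        mk, mk1 = ring_m[k - 1], ring_m[k]
        stride = mk1 // mk
        for j in range(mk):
            a = node_of[(k, j)]
            b = node_of[(k + 1, j * stride)]
            spoke = (j * n_main) % mk == 0
            if spoke:
                s = j * n_main // mk
                add_segment(a, b, spoke_radius(spoke_region[s], k),
                            spoke_region[s])
            else:
                sid = add_segment(a, b, cap_radius(), "capillary")
                if 1 < k < n_rings - 1:
                    radial_capillaries.append(sid)

    for k in range(1, n_rings + 1):
        mk = ring_m[k - 1]
        region = "sprouting_front" if k == n_rings else "capillary"
        for j in range(mk):
            add_segment(
                node_of[(k, j)], node_of[(k, (j + 1) % mk)], cap_radius(),
                region
            )

    # random dropout of interior radial capillaries, preserving connectivity
    # (never removes a bridge, never drops a node below degree 3)
    g = nx.Graph()
    for sid, seg in net.segments.items():
        g.add_edge(seg.a, seg.b, sid=sid)
    for sid in radial_capillaries:
        if rng.random() >= cfg.capillary_dropout:
            continue
        seg = net.segments[sid]
        if g.degree[seg.a] <= 3 or g.degree[seg.b] <= 3:
            continue
        g.remove_edge(seg.a, seg.b)
        if nx.has_path(g, seg.a, seg.b):
            del net.segments[sid]
        else:
            g.add_edge(seg.a, seg.b, sid=sid)

    # blind-ended sprouts at the outer rim; rim nodes without an inward
    # radial link (fresh angles on a doubled ring) always sprout so no
    # degree-2 node survives
    mk = ring_m[-1]
    stride_last = mk // ring_m[-2] if n_rings >= 2 else 1
    r_outer = n_rings * spacing
    for j in range(mk):
        must = (j % stride_last) != 0
        if not must and rng.random() >= cfg.sprout_prob:
            continue
        base = node_of[(n_rings, j)]
        theta = 2 * np.pi * j / mk + rng.normal(0.0, 0.15 / mk * 2 * np.pi)
        length = 0.35 * spacing * (1.0 + 0.3 * rng.uniform(-1, 1))
        tip_r = min(r_outer + length, cfg.retina_radius - 1.0)
        tip = center + tip_r * np.array([np.cos(theta), np.sin(theta)])
        nid = add_node(tip)
        add_segment(base, nid, 0.9 * cfg.radius_capillary, "sprouting_front")

    net.validate()
    return net


# ---------------------------------------------------------------------------
# regression + apoptosis planting


def plant_regression_and_apoptosis(
    net: VesselNetwork, cfg: GenConfig, flow: FlowSolution | None = None
) -> tuple[VesselNetwork, GroundTruth]:
    """Select capillary segments for regression, stage them, and plant
    apoptosis events.

    Stage effects: stage 1 (selection) is attribute-only (no morphology);
    stage 2 dips the central lumen radius below the stenosis threshold while
    the matrix sleeve keeps its calibre; stage 3 drops lumen_fraction into
    (0, 0.5); stage 4 empties the lumen entirely (cells are never placed
    there).  ``round(coloc_rate × n_planted)`` planted segments receive one
    apoptosis event on their centerline; the remaining Poisson-drawn events
    are placed on the vasculature away from any planted segment.
    """
    cfg.validate()
    rng = cfg.rng(_SUB_REGRESSION)
    out = net.copy()
    truth = GroundTruth(density_gradient=cfg.density_gradient)

    capillaries = sorted(
        sid for sid, s in out.segments.items() if s.region == "capillary"
    )
    n_pick = int(round(cfg.regression_rate * len(capillaries)))
    if n_pick > len(capillaries):
        raise ConfigurationError(
            "regression_rate implies more profiles than capillary segments"
        )
    if n_pick > 0:
        if cfg.regression_bias == "low_flow" and flow is not None:
            taus = np.array([flow.tau[s] for s in capillaries])
            scale = np.median(taus[taus > 0]) if np.any(taus > 0) else 1.0
            w = 1.0 / (taus + 0.05 * scale)
            p = w / w.sum()
        else:
            p = None
        picked = rng.choice(capillaries, size=n_pick, replace=False, p=p)
        picked = [int(s) for s in picked]
        stage_counts = rng.multinomial(n_pick, list(cfg.stage_mix))
        stages = np.repeat([1, 2, 3, 4], stage_counts)
        for sid, stage in zip(picked, stages):
            seg = out.segments[sid]
            seg.stage = int(stage)
            truth.regression_stages[sid] = int(stage)
            if stage == STAGE_STENOSIS:
                seg.matrix_radius_profile = seg.radius_profile.copy()
                n = len(seg.radius_profile)
                lo, hi = n // 3, max(n // 3 + 1, 2 * n // 3)
                seg.radius_profile[lo:hi] *= 0.35
            elif stage == STAGE_RETRACTION:
                seg.matrix_radius_profile = seg.radius_profile.copy()
                seg.lumen_fraction = float(rng.uniform(0.05, 0.45))
            elif stage == STAGE_RESOLUTION:
                seg.matrix_radius_profile = seg.radius_profile.copy()
                seg.lumen_fraction = 0.0
    else:
        picked = []

    # apoptosis events; colocalization is planted over the morphologically
    # detectable profiles (stages 2-4) — stage-1 "selection" has no visible
    # correlate, matching how the measured percentage is formed
    total = int(rng.poisson(cfg.apoptosis_total_mean))
    detectable = [
        s for s in picked if truth.regression_stages[s] >= STAGE_STENOSIS
    ]
    n_coloc = min(
        int(round(cfg.coloc_rate * len(detectable))), len(detectable), total
    )
    coloc_segments = (
        [int(s) for s in rng.choice(detectable, size=n_coloc,
                                    replace=False)]
        if n_coloc
        else []
    )
    truth.coloc_segments = sorted(coloc_segments)
    pts = []
    for sid in coloc_segments:
        seg = out.segments[sid]
        pos = _point_along(seg.polyline, rng.uniform(0.15, 0.85))
        ang = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0, 0.5 * cfg.coloc_dist)
        pts.append((pos[0] + rad * np.cos(ang), pos[1] + rad * np.sin(ang),
                    True))

    locator = (
        NetworkLocator(out, step=3.0, segment_ids=picked) if picked else None
    )
    seg_ids = sorted(out.segments)
    lengths = np.array([out.segments[s].length for s in seg_ids])
    pseg = lengths / lengths.sum()
    n_background = max(0, total - n_coloc)
    for _ in range(n_background):
        for _attempt in range(200):
            sid = int(rng.choice(seg_ids, p=pseg))
            seg = out.segments[sid]
            pos = _point_along(seg.polyline, rng.uniform(0, 1))
            pos = pos + rng.normal(0.0, 1.5, size=2)
            if locator is None or locator.distance(pos) > 1.1 * cfg.coloc_dist:
                pts.append((float(pos[0]), float(pos[1]), False))
                break
        else:
            raise ConfigurationError(
                "could not place a background apoptosis event away from "
                "planted regression segments"
            )
    truth.apoptosis = pd.DataFrame(pts, columns=["x", "y", "coloc"])
    return out, truth


def _point_along(polyline: np.ndarray, frac: float) -> np.ndarray:
    """Point at arc-length fraction ``frac`` along a polyline."""
    seglen = np.hypot(*np.diff(polyline, axis=0).T)
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    target = frac * cum[-1]
    i = int(np.searchsorted(cum, target, side="right") - 1)
    i = min(i, len(seglen) - 1)
    t = (target - cum[i]) / seglen[i] if seglen[i] > 0 else 0.0
    return polyline[i] + t * (polyline[i + 1] - polyline[i])


# ---------------------------------------------------------------------------
# cell generation


def generate_cells(
    net: VesselNetwork, cfg: GenConfig, flow: FlowSolution | None = None
) -> tuple[pd.DataFrame, GroundTruth]:
    """Place nuclei on segment centerlines and Golgi at sampled polarity
    angles; returns the cell table and the ground-truth angles.

    Nucleus linear density rises linearly toward the optic center by a
    factor of ``1 + density_gradient``; the total count equals
    ``n_cells_target`` exactly (one multinomial allocation over segments).
    Cells are never placed on lumen-empty (stage 4) segments, and stage-3
    segments are down-weighted by their residual lumen fraction.
    """
    cfg.validate()
    pm = cfg.polarity_model
    if pm.mode == "vonmises_against_flow" and flow is None:
        raise PreconditionError(
            "vonmises_against_flow polarity requires a solved FlowSolution"
        )
    rng = cfg.rng(_SUB_CELLS)
    center = np.asarray(cfg.optic_center, dtype=float)
    g = cfg.density_gradient
    radius = cfg.retina_radius

    seg_ids = sorted(
        sid for sid, s in net.segments.items() if s.lumen_fraction > 0.0
    )
    if not seg_ids:
        return (
            pd.DataFrame(
                columns=["cell_id", "nucleus_x", "nucleus_y", "golgi_x",
                         "golgi_y", "region"]
            ),
            GroundTruth(density_gradient=g),
        )
    weights = []
    for sid in seg_ids:
        seg = net.segments[sid]
        mid = _point_along(seg.polyline, 0.5)
        d = min(np.hypot(*(mid - center)), radius)
        dens = 1.0 + g * (1.0 - d / radius)
        weights.append(seg.length * seg.lumen_fraction * dens)
    w = np.asarray(weights)
    counts = rng.multinomial(cfg.n_cells_target, w / w.sum())

    rows = []
    true_rows = []
    cell_id = 0
    for sid, cnt in zip(seg_ids, counts):
        if cnt == 0:
            continue
        seg = net.segments[sid]
        tangent_dirs = _tangents(seg.polyline)
        fdirs = flow.flow_dir.get(sid) if flow is not None else None
        for frac in rng.uniform(0.0, 1.0, size=cnt):
            pos = _point_along(seg.polyline, frac)
            vi = _nearest_vertex(seg.polyline, pos)
            lateral = rng.normal(0.0, 1.2)
            normal = np.array([-tangent_dirs[vi][1], tangent_dirs[vi][0]])
            nucleus = pos + lateral * normal
            have_flow = (
                fdirs is not None and not np.any(np.isnan(fdirs[vi]))
            )
            if pm.mode == "vonmises_against_flow" and have_flow:
                delta = float(rng.vonmises(np.pi, pm.kappa))
                pdir = _rot(fdirs[vi], delta)
                theta_true = abs(np.degrees(
                    (delta + np.pi) % (2 * np.pi) - np.pi))
            else:
                ang = float(rng.uniform(-np.pi, np.pi))
                pdir = np.array([np.cos(ang), np.sin(ang)])
                theta_true = np.nan
            mag = (
                pm.magnitude_mean
                if pm.magnitude_sd == 0
                else max(0.0, float(rng.normal(pm.magnitude_mean,
                                               pm.magnitude_sd)))
            )
            golgi = nucleus + mag * pdir
            rows.append(
                {
                    "cell_id": cell_id,
                    "nucleus_x": float(nucleus[0]),
                    "nucleus_y": float(nucleus[1]),
                    "golgi_x": float(golgi[0]),
                    "golgi_y": float(golgi[1]),
                    "region": seg.region,
                }
            )
            true_rows.append(
                {
                    "cell_id": cell_id,
                    "segment_id": sid,
                    "theta_true_deg": theta_true,
                }
            )
            cell_id += 1
    cells = pd.DataFrame(rows)
    truth = GroundTruth(
        cell_true=pd.DataFrame(true_rows), density_gradient=g
    )
    return cells, truth


def _tangents(polyline: np.ndarray) -> np.ndarray:
    d = np.gradient(polyline, axis=0)
    n = np.hypot(*d.T)
    n[n == 0] = 1.0
    return d / n[:, None]


def _nearest_vertex(polyline: np.ndarray, p: np.ndarray) -> int:
    return int(np.argmin(np.hypot(*(polyline - p).T)))


# ---------------------------------------------------------------------------
# rendering


def render_masks(
    net: VesselNetwork,
    cells: pd.DataFrame | None,
    cfg: GenConfig,
    apoptosis: pd.DataFrame | None = None,
    fov: float | None = None,
) -> ImageStack:
    """Rasterize the world to binary channels: lumen, matrix, nuclei,
    golgi, caspase.

    The lumen is drawn as per-vertex disks of local radius along each
    segment's lumenized portion (measured from the ``a`` end); the matrix
    channel covers every matrix-positive segment at its sleeve calibre.
    Point channels are small disks.  ``fov`` is the half-extent in μm
    (default: retina_radius plus a margin); a field of view smaller than
    the network bounding box is a configuration error.
    """
    from skimage.draw import disk

    ps = cfg.pixel_size
    center = np.asarray(cfg.optic_center, dtype=float)
    half = fov if fov is not None else cfg.retina_radius + 4.0 * ps
    lo, hi = net.bounding_box()
    pad = max(cfg.radius_artery, cfg.radius_vein)
    if np.any(lo - pad < center - half) or np.any(hi + pad > center + half):
        raise ConfigurationError(
            "field of view smaller than the network bounding box"
        )
    n_px = int(np.ceil(2 * half / ps))
    origin = (center[0] - half, center[1] - half)
    shape = (n_px, n_px)
    channels = {
        name: np.zeros(shape, dtype=bool)
        for name in ("lumen", "matrix", "nuclei", "golgi", "caspase")
    }

    def to_rc(xy: np.ndarray) -> tuple[float, float]:
        return (xy[1] - origin[1]) / ps, (xy[0] - origin[0]) / ps

    def draw_tube(img: np.ndarray, polyline: np.ndarray,
                  radii: np.ndarray, frac: float = 1.0) -> None:
        if frac <= 0:
            return
        dense = densify_polyline(polyline, 0.5 * ps)
        cum = np.concatenate(
            [[0.0], np.cumsum(np.hypot(*np.diff(dense, axis=0).T))]
        )
        limit = frac * cum[-1]
        src_cum = np.concatenate(
            [[0.0], np.cumsum(np.hypot(*np.diff(polyline, axis=0).T))]
        )
        rr = np.interp(cum, src_cum, radii)
        for p, d, r in zip(dense, cum, rr):
            if d > limit + 1e-9:
                break
            row, col = to_rc(p)
            ri, ci = disk((row, col), max(r / ps, 0.8), shape=shape)
            img[ri, ci] = True

    for sid in sorted(net.segments):
        seg = net.segments[sid]
        draw_tube(channels["lumen"], seg.polyline, seg.radius_profile,
                  frac=seg.lumen_fraction)
        if seg.has_matrix:
            mr = (
                seg.matrix_radius_profile
                if seg.matrix_radius_profile is not None
                else seg.radius_profile
            )
            draw_tube(channels["matrix"], seg.polyline, mr)

    def draw_points(img: np.ndarray, xs, ys, radius_um: float) -> None:
        for x, y in zip(xs, ys):
            row, col = to_rc(np.array([x, y]))
            ri, ci = disk((row, col), max(radius_um / ps, 1.0), shape=shape)
            img[ri, ci] = True

    if cells is not None and len(cells):
        draw_points(channels["nuclei"], cells["nucleus_x"],
                    cells["nucleus_y"], 2.0)
        draw_points(channels["golgi"], cells["golgi_x"], cells["golgi_y"],
                    1.5)
    if apoptosis is not None and len(apoptosis):
        draw_points(channels["caspase"], apoptosis["x"], apoptosis["y"], 2.0)
    return ImageStack(channels=channels, pixel_size=ps, origin=origin)


def write_stack(stack: ImageStack, path) -> None:
    """Multi-page TIFF with a JSON channel manifest in the description."""
    import tifffile

    names = sorted(stack.channels)
    data = np.stack([stack.channels[n].astype(np.uint8) for n in names])
    manifest = {
        "channels": names,
        "pixel_size_um": stack.pixel_size,
        "origin_um": list(stack.origin),
    }
    tifffile.imwrite(path, data, description=json.dumps(manifest))


def read_stack(path) -> ImageStack:
    import tifffile

    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        manifest = json.loads(tf.pages[0].description)
    channels = {
        name: data[i].astype(bool)
        for i, name in enumerate(manifest["channels"])
    }
    return ImageStack(
        channels=channels,
        pixel_size=float(manifest["pixel_size_um"]),
        origin=tuple(manifest["origin_um"]),
    )


# ---------------------------------------------------------------------------
# whole-world convenience


@dataclass
class World:
    """One synthetic retina: network before/after planting, both flow
    solutions, the cell table, and the ground truth."""

    cfg: GenConfig
    net_pre: VesselNetwork  # before regression planting
    net: VesselNetwork  # with planted regression morphology
    flow_pre: FlowSolution
    flow: FlowSolution  # on the planted network (regressed segs unperfused)
    cells: pd.DataFrame
    truth: GroundTruth


def simulate_world(cfg: GenConfig,
                   bc: BoundaryConditions | None = None) -> World:
    """Generate network → solve flow → plant regression → re-solve →
    place cells."""
    net_pre = generate_network(cfg)
    bc = bc if bc is not None else BoundaryConditions.default_for(net_pre)
    flow_pre = solve_flow(net_pre, bc)
    net, truth = plant_regression_and_apoptosis(net_pre, cfg, flow_pre)
    flow_post = solve_flow(net, bc)
    cells, cell_truth = generate_cells(net, cfg, flow_post)
    truth.cell_true = cell_truth.cell_true
    return World(
        cfg=cfg,
        net_pre=net_pre,
        net=net,
        flow_pre=flow_pre,
        flow=flow_post,
        cells=cells,
        truth=truth,
    )
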