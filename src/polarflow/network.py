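"""Vessel-network data model and JSON read/write layer.

The network is a planar spatial graph: nodes are branchpoints/endpoints with
2-D positions in micrometres, segments are radius-bearing centerline polylines
between two nodes.  Every downstream stage (flow solve, polarity statistics,
radial profiling, regression detection) consumes this structure, so its
invariants are enforced aggressively on construction and on load.

Coordinates are physical micrometres (x right, y down); rasters use 0-based
row-major pixel indices with ``pixel_size`` as the conversion factor.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

SCHEMA_VERSION = 1

#: segment region labels
REGIONS = ("artery", "vein", "capillary", "sprouting_front")


class NetworkSchemaError(ValueError):
    """Raised when a network JSON document violates the schema."""


class EmptyInputError(ValueError):
    """Raised when an operation receives an empty mask or skeleton."""


def _polyline_length(polyline: np.ndarray) -> float:
    return float(np.sum(np.hypot(*np.diff(polyline, axis=0).T)))


@dataclass
class Segment:
    """A vessel segment: centerline polyline with a radius profile.

    ``lumen_fraction`` is the fraction of the centerline covered by patent
    (ICAM2-like) lumen; ``has_matrix`` flags a continuous (Col.IV-like)
    basement-membrane sleeve.  ``matrix_radius_profile`` holds the sleeve
    radius where it differs from the lumen radius (stenosed or regressed
    segments keep their original sleeve calibre).
    """

    a: int
    b: int
    polyline: np.ndarray  # (n, 2) float64, μm
    radius_profile: np.ndarray  # (n,) float64, μm
    region: str = "capillary"
    lumen_fraction: float = 1.0
    has_matrix: bool = True
    stage: int | None = None
    matrix_radius_profile: np.ndarray | None = None
    #: junction-adjacent samples excluded per end in mean_radius (used by
    #: the extraction stage, where distance-map radii inflate at nodes)
    radius_trim: int = 0

    def __post_init__(self) -> None:
        self.polyline = np.asarray(self.polyline, dtype=float)
        self.radius_profile = np.asarray(self.radius_profile, dtype=float)
        if self.polyline.ndim != 2 or self.polyline.shape[1] != 2:
            raise ValueError("polyline must be an (n, 2) array")
        if self.radius_profile.shape[0] != self.polyline.shape[0]:
            raise ValueError("radius_profile must match polyline vertex count")
        if self.polyline.shape[0] < 2:
            raise ValueError("polyline needs at least 2 vertices")
        if not 0.0 <= self.lumen_fraction <= 1.0:
            raise ValueError("lumen_fraction must lie in [0, 1]")
        if self.matrix_radius_profile is not None:
            self.matrix_radius_profile = np.asarray(
                self.matrix_radius_profile, dtype=float
            )

    @property
    def length(self) -> float:
        """Arc length of the centerline in μm."""
        return _polyline_length(self.polyline)

    @property
    def mean_radius(self) -> float:
        """Arithmetic mean of the radius profile in μm, excluding
        ``radius_trim`` junction-adjacent samples at each end when the
        profile is long enough."""
        prof = self.radius_profile
        t = self.radius_trim
        if t > 0 and len(prof) > 2 * t + 1:
            prof = prof[t:-t]
        return float(np.mean(prof))

    def copy(self) -> "Segment":
        return replace(
            self,
            polyline=self.polyline.copy(),
            radius_profile=self.radius_profile.copy(),
            matrix_radius_profile=(
                None
                if self.matrix_radius_profile is None
                else self.matrix_radius_profile.copy()
            ),
        )


@dataclass
class VesselNetwork:
    """Spatial graph of nodes and radius-bearing vessel segments."""

    nodes: dict[int, np.ndarray] = field(default_factory=dict)
    segments: dict[int, Segment] = field(default_factory=dict)
    inlets: list[int] = field(default_factory=list)
    outlets: list[int] = field(default_factory=list)

    def validate(self) -> None:
        for sid, seg in self.segments.items():
            if seg.a not in self.nodes or seg.b not in self.nodes:
                raise NetworkSchemaError(
                    f"segment {sid} references unknown node"
                )
            if seg.length <= 0:
                raise NetworkSchemaError(f"segment {sid} has zero length")
            for end, node in ((0, seg.a), (-1, seg.b)):
                if not np.allclose(
                    seg.polyline[end], self.nodes[node], atol=1e-6
                ):
                    raise NetworkSchemaError(
                        f"segment {sid} polyline endpoint does not coincide "
                        f"with node {node}"
                    )
        for nid in list(self.inlets) + list(self.outlets):
            if nid not in self.nodes:
                raise NetworkSchemaError(f"boundary node {nid} unknown")

    def to_graph(self) -> nx.MultiGraph:
        """NetworkX view; edge key is the segment id."""
        g = nx.MultiGraph()
        for nid, pos in self.nodes.items():
            g.add_node(nid, pos=pos)
        for sid, seg in self.segments.items():
            g.add_edge(seg.a, seg.b, key=sid, segment=seg)
        return g

    def node_degrees(self) -> dict[int, int]:
        deg: dict[int, int] = {nid: 0 for nid in self.nodes}
        for seg in self.segments.values():
            deg[seg.a] += 1
            deg[seg.b] += 1
        return deg

    def branchpoints(self) -> list[int]:
        """Nodes with degree ≥ 3."""
        return [n for n, d in self.node_degrees().items() if d >= 3]

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        pts = np.concatenate(
            [seg.polyline for seg in self.segments.values()]
            or [np.zeros((0, 2))]
        )
        if len(pts) == 0:
            z = np.zeros(2)
            return z, z
        return pts.min(axis=0), pts.max(axis=0)

    def total_vascularized_area(self) -> float:
        """Σ L·2r over segments: projected lumen area proxy in μm²."""
        return float(
            sum(s.length * 2.0 * s.mean_radius for s in self.segments.values())
        )

    def copy(self) -> "VesselNetwork":
        return VesselNetwork(
            nodes={nid: p.copy() for nid, p in self.nodes.items()},
            segments={sid: s.copy() for sid, s in self.segments.items()},
            inlets=list(self.inlets),
            outlets=list(self.outlets),
        )


@dataclass
class ImageStack:
    """Named 2-D rasters sharing one shape and pixel size.

    ``origin`` is the physical (x, y) μm coordinate of pixel (row=0, col=0).
    """

    channels: dict[str, np.ndarray]
    pixel_size: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError("all channels must share one shape")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def to_pixel(self, xy: np.ndarray) -> np.ndarray:
        """Physical μm → fractional (row, col)."""
        xy = np.atleast_2d(xy)
        col = (xy[:, 0] - self.origin[0]) / self.pixel_size
        row = (xy[:, 1] - self.origin[1]) / self.pixel_size
        return np.column_stack([row, col])


# ---------------------------------------------------------------------------
# JSON serialization


def network_to_dict(net: VesselNetwork) -> dict:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "nodes": [
            {"id": int(nid), "x": float(p[0]), "y": float(p[1])}
            for nid, p in sorted(net.nodes.items())
        ],
        "segments": [],
        "inlets": [int(n) for n in net.inlets],
        "outlets": [int(n) for n in net.outlets],
    }
    for sid, seg in sorted(net.segments.items()):
        rec = {
            "id": int(sid),
            "a": int(seg.a),
            "b": int(seg.b),
            "polyline": [[float(x), float(y)] for x, y in seg.polyline],
            "radius_profile": [float(r) for r in seg.radius_profile],
            "region": seg.region,
            "lumen_fraction": float(seg.lumen_fraction),
            "has_matrix": bool(seg.has_matrix),
        }
        if seg.stage is not None:
            rec["stage"] = int(seg.stage)
        if seg.radius_trim:
            rec["radius_trim"] = int(seg.radius_trim)
        if seg.matrix_radius_profile is not None:
            rec["matrix_radius_profile"] = [
                float(r) for r in seg.matrix_radius_profile
            ]
        doc["segments"].append(rec)
    return doc


def network_from_dict(doc: dict) -> VesselNetwork:
    if not isinstance(doc, dict) or "nodes" not in doc:
        raise NetworkSchemaError("document missing 'nodes'")
    if "segments" not in doc:
        raise NetworkSchemaError("document missing 'segments'")
    net = VesselNetwork()
    for rec in doc["nodes"]:
        for key in ("id", "x", "y"):
            if key not in rec:
                raise NetworkSchemaError(f"node record missing '{key}': {rec}")
        net.nodes[int(rec["id"])] = np.array(
            [float(rec["x"]), float(rec["y"])]
        )
    for rec in doc["segments"]:
        sid = rec.get("id")
        for key in ("id", "a", "b", "polyline", "radius_profile"):
            if key not in rec:
                raise NetworkSchemaError(
                    f"segment {sid!r} missing field '{key}'"
                )
        net.segments[int(sid)] = Segment(
            a=int(rec["a"]),
            b=int(rec["b"]),
            polyline=np.asarray(rec["polyline"], dtype=float),
            radius_profile=np.asarray(rec["radius_profile"], dtype=float),
            region=rec.get("region", "capillary"),
            lumen_fraction=float(rec.get("lumen_fraction", 1.0)),
            has_matrix=bool(rec.get("has_matrix", True)),
            stage=(None if rec.get("stage") is None else int(rec["stage"])),
            radius_trim=int(rec.get("radius_trim", 0)),
            matrix_radius_profile=(
                None
                if rec.get("matrix_radius_profile") is None
                else np.asarray(rec["matrix_radius_profile"], dtype=float)
            ),
        )
    net.inlets = [int(n) for n in doc.get("inlets", [])]
    net.outlets = [int(n) for n in doc.get("outlets", [])]
    net.validate()
    return net


def write_network(net: VesselNetwork, path) -> None:
    with open(path, "w") as fh:
        json.dump(network_to_dict(net), fh, indent=1)


def read_network(path) -> VesselNetwork:
    with open(path) as fh:
        doc = json.load(fh)
    return network_from_dict(doc)


def networks_equal(a: VesselNetwork, b: VesselNetwork, rtol=1e-9) -> bool:
    """Field-by-field equality up to float round-tripping."""
    if set(a.nodes) != set(b.nodes) or set(a.segments) != set(b.segments):
        return False
    if a.inlets != b.inlets or a.outlets != b.outlets:
        return False
    for nid in a.nodes:
        if not np.allclose(a.nodes[nid], b.nodes[nid], rtol=rtol, atol=1e-12):
            return False
    for sid in a.segments:
        sa, sb = a.segments[sid], b.segments[sid]
        if (sa.a, sa.b, sa.region, sa.has_matrix, sa.stage,
                sa.radius_trim) != (
            sb.a,
            sb.b,
            sb.region,
            sb.has_matrix,
            sb.stage,
            sb.radius_trim,
        ):
            return False
        if not math.isclose(
            sa.lumen_fraction, sb.lumen_fraction, rel_tol=rtol, abs_tol=1e-12
        ):
            return False
        if sa.polyline.shape != sb.polyline.shape or not np.allclose(
            sa.polyline, sb.polyline, rtol=rtol, atol=1e-12
        ):
            return False
        if not np.allclose(
            sa.radius_profile, sb.radius_profile, rtol=rtol, atol=1e-12
        ):
            return False
    return True


# ---------------------------------------------------------------------------
# geometry helpers shared by several stages


def densify_polyline(polyline: np.ndarray, step: float) -> np.ndarray:
    """Resample a polyline at ≤ ``step`` μm spacing (endpoints kept)."""
    pts = [polyline[0]]
    for p0, p1 in zip(polyline[:-1], polyline[1:]):
        d = float(np.hypot(*(p1 - p0)))
        n = max(1, int(np.ceil(d / step)))
        for i in range(1, n + 1):
            pts.append(p0 + (p1 - p0) * (i / n))
    return np.asarray(pts)


def point_segment_distance(p: np.ndarray, polyline: np.ndarray) -> float:
    """Exact distance from a point to a polyline."""
    p = np.asarray(p, dtype=float)
    a = polyline[:-1]
    b = polyline[1:]
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    denom[denom == 0] = 1.0
    t = np.clip(np.einsum("ij,ij->i", p - a, ab) / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return float(np.min(np.hypot(*(proj - p).T)))


class NetworkLocator:
    """KD-tree index over densified segment centerlines.

    Supports nearest-segment queries (cell→segment assignment) and
    distance-to-set queries (apoptosis colocalization).  Ties between
    equidistant segments break toward the lower segment id.
    """

    def __init__(self, net: VesselNetwork, step: float = 2.0,
                 segment_ids=None):
        from scipy.spatial import cKDTree

        self.net = net
        ids = sorted(segment_ids) if segment_ids is not None else sorted(
            net.segments
        )
        pts = []
        owners = []
        vidx = []
        for sid in ids:
            dense = densify_polyline(net.segments[sid].polyline, step)
            pts.append(dense)
            owners.extend([sid] * len(dense))
            vidx.extend(range(len(dense)))
        if not pts:
            self.tree = None
            return
        self.points = np.concatenate(pts)
        self.owners = np.asarray(owners)
        self.tree = cKDTree(self.points)
        self.step = step

    def nearest_segment(self, p: np.ndarray, k: int = 12
                        ) -> tuple[int, float]:
        """(segment_id, exact distance) of the nearest centerline."""
        if self.tree is None:
            raise EmptyInputError("locator built over an empty network")
        k = min(k, len(self.points))
        _, idx = self.tree.query(p, k=k)
        idx = np.atleast_1d(idx)
        cands = sorted(set(int(self.owners[i]) for i in idx))
        best_sid, best_d = -1, np.inf
        for sid in cands:
            d = point_segment_distance(p, self.net.segments[sid].polyline)
            if d < best_d - 1e-9:
                best_sid, best_d = sid, d
        return best_sid, best_d

    def distance(self, p: np.ndarray) -> float:
        sid, d = self.nearest_segment(p)
        return d


def warn(msg: str) -> None:
    warnings.warn(msg, stacklevel=2)
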