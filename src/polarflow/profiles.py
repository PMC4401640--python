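"""Radial profiling from the optic nerve and marker-density reports.

Bins every quantity by distance from the optic center: vascularized area
(Σ L·2r over segment arc, apportioned exactly by arc length across bins),
nucleus counts and densities, branchpoint (degree ≥ 3 node) counts and
densities, length-weighted mean wall shear stress, and regression-profile
counts.  Area comes from the graph (so profiles work on graph-only input);
a raster-mask pixel count is available as the alternative area convention.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .flow import FlowSolution
from .network import ImageStack, VesselNetwork, densify_polyline, warn

DEFAULT_BIN_WIDTH = 100.0  # μm
_STEP = 2.0  # μm arc discretization for exact bin apportioning


def _segment_steps(net: VesselNetwork):
    """Yield (segment_id, midpoint, step_length, local_radius) pieces."""
    for sid in sorted(net.segments):
        seg = net.segments[sid]
        dense = densify_polyline(seg.polyline, _STEP)
        cum = np.concatenate(
            [[0.0], np.cumsum(np.hypot(*np.diff(dense, axis=0).T))]
        )
        src = np.concatenate(
            [[0.0], np.cumsum(np.hypot(*np.diff(seg.polyline, axis=0).T))]
        )
        mids = 0.5 * (dense[:-1] + dense[1:])
        lens = np.diff(cum)
        mid_arc = 0.5 * (cum[:-1] + cum[1:])
        radii = np.interp(mid_arc, src, seg.radius_profile)
        yield sid, mids, lens, radii


def radial_profile(
    net: VesselNetwork,
    cells: pd.DataFrame | None,
    flow: FlowSolution | None,
    profiles=None,
    optic_center: tuple[float, float] = (0.0, 0.0),
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> pd.DataFrame:
    """Radial profile of vascular, cellular and haemodynamic quantities.

    One row per distance bin: vascularized area (μm²), nucleus count and
    density, branchpoint count and density, length-weighted mean τ over
    perfused arc, and regression-profile count and density.  Bins with zero
    area get NaN densities (never a division by zero).
    """
    center = np.asarray(optic_center, dtype=float)
    lo, hi = net.bounding_box()
    if np.any(center < lo) or np.any(center > hi):
        warn("optic_center lies outside the network bounding box")
    dmax = 0.0
    pieces = []
    for sid, mids, lens, radii in _segment_steps(net):
        d = np.hypot(*(mids - center).T)
        dmax = max(dmax, float(d.max()))
        pieces.append((sid, d, lens, radii))
    n_bins = max(1, int(np.ceil(dmax / bin_width)))
    edges = np.arange(0.0, (n_bins + 1) * bin_width, bin_width)

    area = np.zeros(n_bins)
    arc = np.zeros(n_bins)
    tau_wsum = np.zeros(n_bins)
    tau_weight = np.zeros(n_bins)
    for sid, d, lens, radii in pieces:
        idx = np.clip((d // bin_width).astype(int), 0, n_bins - 1)
        np.add.at(area, idx, lens * 2.0 * radii)
        np.add.at(arc, idx, lens)
        if flow is not None and flow.perfused.get(sid, False):
            np.add.at(tau_wsum, idx, lens * flow.tau[sid])
            np.add.at(tau_weight, idx, lens)

    n_nuclei = np.zeros(n_bins, dtype=int)
    if cells is not None and len(cells):
        d = np.hypot(
            cells["nucleus_x"].to_numpy() - center[0],
            cells["nucleus_y"].to_numpy() - center[1],
        )
        idx = np.clip((d // bin_width).astype(int), 0, n_bins - 1)
        np.add.at(n_nuclei, idx, 1)

    n_branch = np.zeros(n_bins, dtype=int)
    for nid in net.branchpoints():
        d = float(np.hypot(*(net.nodes[nid] - center)))
        n_branch[min(int(d // bin_width), n_bins - 1)] += 1

    n_reg = np.zeros(n_bins, dtype=int)
    if profiles:
        for p in profiles:
            sid = p.segment_id if hasattr(p, "segment_id") else int(p)
            seg = net.segments[sid]
            mid = seg.polyline[len(seg.polyline) // 2]
            d = float(np.hypot(*(mid - center)))
            n_reg[min(int(d // bin_width), n_bins - 1)] += 1

    with np.errstate(invalid="ignore", divide="ignore"):
        cell_density = np.where(area > 0, n_nuclei / area, np.nan)
        branch_density = np.where(area > 0, n_branch / area, np.nan)
        reg_density = np.where(area > 0, n_reg / area, np.nan)
        mean_tau = np.where(tau_weight > 0, tau_wsum / tau_weight, np.nan)
    return pd.DataFrame(
        {
            "bin_lo": edges[:-1],
            "bin_hi": edges[1:],
            "vascularized_area_um2": area,
            "arc_length_um": arc,
            "n_nuclei": n_nuclei,
            "cell_density_per_um2": cell_density,
            "n_branchpoints": n_branch,
            "branchpoint_density_per_um2": branch_density,
            "mean_tau_pa": mean_tau,
            "tau_arc_length_um": tau_weight,
            "n_regression": n_reg,
            "regression_density_per_um2": reg_density,
        }
    )


def vascularized_area(net: VesselNetwork,
                      stack: ImageStack | None = None,
                      source: str = "graph") -> float:
    """Vascularized area in μm²: graph convention Σ L·2r (default) or the
    raster-mask pixel count of the lumen∪matrix channels."""
    if source == "graph":
        return net.total_vascularized_area()
    if source == "mask":
        if stack is None:
            raise ValueError("mask area convention needs an ImageStack")
        m = np.zeros(stack.shape, dtype=bool)
        for name in ("lumen", "matrix"):
            if name in stack.channels:
                m |= stack.channels[name].astype(bool)
        return float(m.sum()) * stack.pixel_size**2
    raise ValueError(f"unknown area source {source!r}")


def marker_density(
    events: pd.DataFrame,
    vascularized_area_um2: float,
    nuclei: pd.DataFrame | None = None,
    match_dist: float = 5.0,
    markers: list[str] | None = None,
) -> dict:
    """Per-marker counts, densities per 100 μm² of vascularized tissue,
    and (for nuclear markers, given a nucleus table) the fraction of
    Erg-like nuclei positive for the marker (nearest-nucleus match within
    ``match_dist`` μm)."""
    if vascularized_area_um2 <= 0:
        raise ValueError("vascularized area must be > 0")
    out: dict[str, dict] = {}
    for name in markers or []:
        out[name] = {
            "total_events": 0,
            "per_100um2": 0.0,
            "fraction_nuclei_positive": 0.0,
        }
    if events is None or len(events) == 0:
        return out
    work = events.copy()
    if "marker" not in work.columns:
        work["marker"] = "event"
    tree = None
    n_nuclei = 0
    if nuclei is not None and len(nuclei):
        pts = nuclei[["nucleus_x", "nucleus_y"]].to_numpy(dtype=float)
        tree = cKDTree(pts)
        n_nuclei = len(pts)
    for marker, sub in work.groupby("marker"):
        rec = {
            "total_events": int(len(sub)),
            "per_100um2": 100.0 * len(sub) / vascularized_area_um2,
        }
        if tree is not None:
            d, idx = tree.query(sub[["x", "y"]].to_numpy(dtype=float))
            matched = set(np.asarray(idx)[np.asarray(d) <= match_dist])
            rec["fraction_nuclei_positive"] = (
                len(matched) / n_nuclei if n_nuclei else 0.0
            )
        out[str(marker)] = rec
    return out
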