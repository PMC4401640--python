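"""Regression-profile detection, staging and apoptosis colocalization.

A regression profile is an empty (or emptying) basement-membrane sleeve: a
segment positive for matrix (Col.IV-like) whose lumen is deficient — either
broken (lumen_fraction below the continuity threshold) or focally stenosed
(minimum radius well below the segment's median).  Detected profiles are
staged by the four-step regression sequence; stage 1 ("selection") precedes
any morphology and is therefore not detectable in a static frame — staging
starts at stage 2.

Stage rules (mutually exclusive, checked in order):
  4 (resolution)  lumen_fraction = 0 and no resident endothelial cells;
  3 (retraction)  lumen_fraction < disconnect threshold;
  2 (stenosis)    remaining profiles: lumen largely continuous but with a
                  radius dip or a minor discontinuity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .flow import FlowSolution, classify_flow
from .network import VesselNetwork, point_segment_distance

DEFAULT_CONTINUITY_THRESHOLD = 0.95
DEFAULT_DISCONNECT_THRESHOLD = 0.5
DEFAULT_STENOSIS_RATIO = 0.5
DEFAULT_COLOC_DIST = 10.0  # μm


class DetectionError(RuntimeError):
    """Raised when detection preconditions are not met."""


@dataclass
class RegressionProfile:
    """A detected matrix-positive, lumen-deficient segment."""

    segment_id: int
    stage: int  # 2, 3 or 4
    lumen_fraction: float
    radius_ratio: float  # min/median of the radius profile
    resident_cells: int
    coloc_apoptosis: bool | None = None
    dist_to_apoptosis: float | None = None


def resident_cell_counts(cells: pd.DataFrame | None,
                         net: VesselNetwork,
                         end_exclusion: float = 4.0) -> dict[int, int]:
    """Cells per segment from an assigned cell table (segment_id column).

    A cell counts as resident only when its nucleus projects onto the
    segment interior, more than ``end_exclusion`` μm from either endpoint:
    nuclei sitting at a shared branchpoint are ambiguous between the
    segments meeting there and would otherwise contaminate empty sleeves.
    """
    counts = {sid: 0 for sid in net.segments}
    if cells is None or "segment_id" not in getattr(cells, "columns", ()):
        return counts
    assigned = cells[cells["segment_id"] >= 0]
    for _, row in assigned.iterrows():
        sid = int(row["segment_id"])
        if sid not in counts:
            continue
        seg = net.segments[sid]
        arc = _projected_arc_position(
            np.array([row["nucleus_x"], row["nucleus_y"]]), seg.polyline
        )
        if end_exclusion < arc < seg.length - end_exclusion:
            counts[sid] += 1
    return counts


def _projected_arc_position(p: np.ndarray, polyline: np.ndarray) -> float:
    """Arc-length position of the closest point on a polyline to ``p``."""
    best_d, best_arc = np.inf, 0.0
    arc0 = 0.0
    for a, b in zip(polyline[:-1], polyline[1:]):
        ab = b - a
        ll = float(np.dot(ab, ab))
        t = float(np.clip(np.dot(p - a, ab) / ll, 0.0, 1.0)) if ll else 0.0
        proj = a + t * ab
        d = float(np.hypot(*(proj - p)))
        step = float(np.hypot(*ab))
        if d < best_d:
            best_d, best_arc = d, arc0 + t * step
        arc0 += step
    return best_arc


def detect_profiles(
    net: VesselNetwork,
    cell_counts: dict[int, int] | None = None,
    continuity_threshold: float = DEFAULT_CONTINUITY_THRESHOLD,
    disconnect_threshold: float = DEFAULT_DISCONNECT_THRESHOLD,
    stenosis_ratio: float = DEFAULT_STENOSIS_RATIO,
) -> list[RegressionProfile]:
    """Detect and stage regression profiles.

    A segment is a profile iff it has matrix AND (lumen_fraction below the
    continuity threshold OR a stenosis dip: min radius < stenosis_ratio ×
    median radius).  ``cell_counts`` gives resident endothelial cells per
    segment (needed to call stage 4); without it every lumen-empty segment
    is treated as cell-free.
    """
    if not net.segments:
        raise DetectionError("cannot detect profiles on an empty network")
    counts = cell_counts if cell_counts is not None else {}
    out: list[RegressionProfile] = []
    for sid in sorted(net.segments):
        seg = net.segments[sid]
        prof = seg.radius_profile
        med = float(np.median(prof))
        ratio = float(np.min(prof) / med) if med > 0 else 1.0
        dip = ratio < stenosis_ratio
        lf = seg.lumen_fraction
        if not seg.has_matrix:
            continue
        if not (lf < continuity_threshold or dip):
            continue
        resident = int(counts.get(sid, 0))
        if lf == 0.0 and resident == 0:
            stage = 4
        elif lf < disconnect_threshold:
            stage = 3
        else:
            stage = 2
        out.append(
            RegressionProfile(
                segment_id=sid,
                stage=stage,
                lumen_fraction=lf,
                radius_ratio=ratio,
                resident_cells=resident,
            )
        )
    return out


def colocalize_apoptosis(
    profiles: list[RegressionProfile],
    apoptosis_points: np.ndarray | pd.DataFrame,
    net: VesselNetwork,
    coloc_dist: float = DEFAULT_COLOC_DIST,
) -> dict:
    """Flag profiles with an apoptotic event within ``coloc_dist`` of their
    centerline; return the colocalization percentage and its complement.

    With zero profiles the percentage is undefined (None), not 0.
    """
    if isinstance(apoptosis_points, pd.DataFrame):
        pts = apoptosis_points[["x", "y"]].to_numpy(dtype=float)
    else:
        pts = np.atleast_2d(np.asarray(apoptosis_points, dtype=float))
        if pts.size == 0:
            pts = np.zeros((0, 2))
    n_pos = 0
    for prof in profiles:
        poly = net.segments[prof.segment_id].polyline
        if len(pts):
            d = min(point_segment_distance(p, poly) for p in pts)
        else:
            d = np.inf
        prof.dist_to_apoptosis = float(d) if np.isfinite(d) else None
        prof.coloc_apoptosis = bool(d <= coloc_dist)
        n_pos += prof.coloc_apoptosis
    if not profiles:
        return {
            "n_profiles": 0,
            "n_colocalized": 0,
            "coloc_percent": None,
            "non_coloc_percent": None,
        }
    pct = 100.0 * n_pos / len(profiles)
    return {
        "n_profiles": len(profiles),
        "n_colocalized": int(n_pos),
        "coloc_percent": pct,
        "non_coloc_percent": 100.0 - pct,
    }


def regression_counts(profiles: list[RegressionProfile],
                      net: VesselNetwork) -> dict:
    """Profile count normalized per 100 μm² of vascularized area."""
    area = net.total_vascularized_area()
    if area <= 0:
        raise ValueError("vascularized area is zero")
    return {
        "n_profiles": len(profiles),
        "vascularized_area_um2": area,
        "per_100um2": 100.0 * len(profiles) / area,
    }


def low_flow_association(
    profiles: list[RegressionProfile],
    net: VesselNetwork,
    flow: FlowSolution,
    low_q: float = 0.25,
    n_perm: int = 10000,
    seed: int = 0,
) -> dict:
    """2×2 association of profile status × low/high shear class.

    ``flow`` must be solved on the pre-regression network (the planted
    segments are unperfused afterwards, which would make the association
    circular).  Returns the contingency table, the Haldane–Anscombe-
    corrected odds ratio when any cell is empty, and a seeded permutation
    p-value (profile labels shuffled over classified segments).
    """
    labels = classify_flow(net, flow, low_q=low_q)
    profile_ids = {p.segment_id for p in profiles}
    sids = sorted(labels)
    is_low = np.array([labels[s] == "low" for s in sids])
    is_prof = np.array([s in profile_ids for s in sids])
    a = int(np.sum(is_prof & is_low))  # profile, low
    b = int(np.sum(is_prof & ~is_low))  # profile, high
    c = int(np.sum(~is_prof & is_low))
    d = int(np.sum(~is_prof & ~is_low))
    table = {"profile_low": a, "profile_high": b, "other_low": c,
             "other_high": d}
    corrected = any(v == 0 for v in (a, b, c, d))
    margins_ok = (a + b) > 0 and (c + d) > 0 and (a + c) > 0 and (b + d) > 0
    if not margins_ok and not corrected:
        odds = None
    else:
        aa, bb, cc, dd = (
            (a + 0.5, b + 0.5, c + 0.5, d + 0.5) if corrected
            else (a, b, c, d)
        )
        odds = (aa * dd) / (bb * cc)
    direction = None
    if odds is not None:
        direction = "low-flow enriched" if odds > 1 else (
            "high-flow enriched" if odds < 1 else "none")

    rng = np.random.default_rng([int(seed), 23])
    n_prof = int(is_prof.sum())
    p_value = None
    if 0 < n_prof < len(sids):
        obs = a
        n = len(sids)
        sims = np.empty(n_perm, dtype=int)
        for i in range(n_perm):
            pick = rng.choice(n, size=n_prof, replace=False)
            sims[i] = int(np.sum(is_low[pick]))
        p_lo = (np.sum(sims <= obs) + 1) / (n_perm + 1)
        p_hi = (np.sum(sims >= obs) + 1) / (n_perm + 1)
        p_value = float(min(1.0, 2.0 * min(p_lo, p_hi)))
    return {
        "table": table,
        "odds_ratio": odds,
        "haldane_anscombe_corrected": corrected,
        "direction": direction,
        "perm_p": p_value,
        "n_perm": n_perm,
    }
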