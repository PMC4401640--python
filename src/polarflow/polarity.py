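"""Endothelial nucleus→Golgi axial polarity vs. local flow.

Each cell's axial polarity is the 2-D vector p from the nucleus center of
mass to its Golgi.  Relating p to the oriented flow direction of the cell's
vessel segment gives the angle-to-flow θ ∈ [0°, 180°], the signed "scalar
product" s = |p|·cos θ (negative = polarized against flow; s carries length
units, μm, because it is a projection of p, not a true dot product with the
shear vector), and the against-flow indicator θ ∈ [135°, 180°] (the
180°±45° window; the 135° boundary counts as against-flow).

Statistics: per-region against-flow fractions, circular means, |p|
summaries and 15° histograms; sign-stratified OLS of s against wall shear
stress τ; axis projections; and permutation comparisons of polarity between
low/high-shear and regression-adjacent/non-adjacent cell groups.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import linregress

from .flow import FlowSolution, classify_flow
from .network import NetworkLocator, VesselNetwork

DEFAULT_MAX_PAIR_DIST = 10.0  # μm
DEFAULT_MAX_ASSIGN_DIST = 15.0  # μm
AGAINST_FLOW_WINDOW = (135.0, 180.0)  # closed interval, degrees
DEFAULT_ADJACENCY_DIST = 20.0  # μm
THETA_BIN_WIDTH = 15.0  # degrees → 12 bins over [0, 180]


def pair_points(nuclei: np.ndarray, golgis: np.ndarray,
                max_pair_dist: float = DEFAULT_MAX_PAIR_DIST) -> pd.DataFrame:
    """Greedy globally-nearest one-to-one nucleus↔Golgi matching.

    Candidate pairs are processed in order of increasing distance; pairs
    farther than ``max_pair_dist`` are rejected.  Unpaired nuclei are kept
    with an undefined polarity vector (``paired`` = False).
    """
    nuclei = np.atleast_2d(np.asarray(nuclei, dtype=float)) if len(
        nuclei) else np.zeros((0, 2))
    golgis = np.atleast_2d(np.asarray(golgis, dtype=float)) if len(
        golgis) else np.zeros((0, 2))
    pairs: list[tuple[float, int, int]] = []
    if len(nuclei) and len(golgis):
        tree = cKDTree(golgis)
        hits = tree.query_ball_point(nuclei, r=max_pair_dist)
        for i, js in enumerate(hits):
            for j in js:
                d = float(np.hypot(*(nuclei[i] - golgis[j])))
                pairs.append((d, i, j))
        pairs.sort()
    taken_n: set[int] = set()
    taken_g: set[int] = set()
    match: dict[int, int] = {}
    for d, i, j in pairs:
        if i in taken_n or j in taken_g:
            continue
        taken_n.add(i)
        taken_g.add(j)
        match[i] = j
    rows = []
    for i, nuc in enumerate(nuclei):
        if i in match:
            gol = golgis[match[i]]
            p = gol - nuc
            rows.append(
                dict(cell_id=i, nucleus_x=nuc[0], nucleus_y=nuc[1],
                     golgi_x=gol[0], golgi_y=gol[1], px=p[0], py=p[1],
                     p_mag=float(np.hypot(*p)), paired=True)
            )
        else:
            rows.append(
                dict(cell_id=i, nucleus_x=nuc[0], nucleus_y=nuc[1],
                     golgi_x=np.nan, golgi_y=np.nan, px=np.nan, py=np.nan,
                     p_mag=np.nan, paired=False)
            )
    return pd.DataFrame(
        rows,
        columns=["cell_id", "nucleus_x", "nucleus_y", "golgi_x", "golgi_y",
                 "px", "py", "p_mag", "paired"],
    )


def cells_from_table(cells: pd.DataFrame) -> pd.DataFrame:
    """Derive p, |p| from a generator-style cell table (already paired)."""
    out = cells.copy()
    out["px"] = out["golgi_x"] - out["nucleus_x"]
    out["py"] = out["golgi_y"] - out["nucleus_y"]
    out["p_mag"] = np.hypot(out["px"], out["py"])
    out["paired"] = True
    return out


def assign_to_segments(cells: pd.DataFrame, net: VesselNetwork,
                       max_assign_dist: float = DEFAULT_MAX_ASSIGN_DIST
                       ) -> pd.DataFrame:
    """Assign each cell to the nearest segment centerline.

    Cells farther than ``max_assign_dist`` stay unassigned (segment_id -1)
    and are excluded from flow statistics; ties between equidistant
    segments break toward the lower segment id.  The region label is
    copied from the assigned segment.
    """
    out = cells.copy()
    locator = NetworkLocator(net, step=2.0)
    sids, dists, regions = [], [], []
    for _, row in out.iterrows():
        p = np.array([row["nucleus_x"], row["nucleus_y"]])
        sid, d = locator.nearest_segment(p)
        if d > max_assign_dist:
            sids.append(-1)
            dists.append(d)
            regions.append(None)
        else:
            sids.append(sid)
            dists.append(d)
            regions.append(net.segments[sid].region)
    out["segment_id"] = sids
    out["distance_to_segment"] = dists
    out["region"] = regions
    return out


def angle_and_scalar(cells: pd.DataFrame, net: VesselNetwork,
                     flow: FlowSolution) -> pd.DataFrame:
    """θ (degrees, [0, 180]) between p and the local flow direction, and
    s = |p|·cos θ.

    The flow direction is taken at the nearest polyline vertex of the
    assigned segment, so curved segments are handled.  Cells that are
    unassigned, on non-perfused segments, or with |p| = 0 get NaN.
    """
    thetas, scalars, against = [], [], []
    for _, row in cells.iterrows():
        sid = int(row.get("segment_id", -1))
        p = np.array([row["px"], row["py"]])
        if sid < 0 or not np.isfinite(p).all() or not flow.perfused.get(
                sid, False):
            thetas.append(np.nan)
            scalars.append(np.nan)
            against.append(False)
            continue
        mag = float(np.hypot(*p))
        if mag == 0.0:
            thetas.append(np.nan)
            scalars.append(np.nan)
            against.append(False)
            continue
        seg = net.segments[sid]
        nucleus = np.array([row["nucleus_x"], row["nucleus_y"]])
        vi = int(np.argmin(np.hypot(*(seg.polyline - nucleus).T)))
        fdir = flow.flow_dir[sid][vi]
        cosang = float(np.dot(p, fdir)) / mag
        cosang = min(1.0, max(-1.0, cosang))
        theta = float(np.degrees(np.arccos(cosang)))
        thetas.append(theta)
        scalars.append(mag * cosang)
        against.append(
            AGAINST_FLOW_WINDOW[0] <= theta <= AGAINST_FLOW_WINDOW[1]
        )
    out = cells.copy()
    out["theta_deg"] = thetas
    out["scalar_product"] = scalars
    out["against_flow"] = against
    return out


def _circular_stats(theta_deg: np.ndarray) -> tuple[float, float]:
    """(circular mean in degrees, resultant length) of a sample."""
    rad = np.radians(theta_deg)
    z = np.exp(1j * rad).mean()
    return float(np.degrees(np.angle(z)) % 360.0), float(np.abs(z))


def region_stats(cells: pd.DataFrame) -> dict:
    """Per-region and pooled polarity statistics.

    Returns, per region: n cells with defined θ, mean |p|, circular mean
    and resultant length of θ, the against-flow fraction (θ ∈ [135°, 180°])
    and a 12×15° histogram of θ.
    """
    results: dict[str, dict] = {}
    groups = [("all", cells)]
    if "region" in cells.columns:
        for region, sub in cells.groupby("region", dropna=True):
            groups.append((str(region), sub))
    edges = np.arange(0.0, 180.0 + THETA_BIN_WIDTH, THETA_BIN_WIDTH)
    for name, sub in groups:
        theta = sub["theta_deg"].to_numpy(dtype=float)
        defined = theta[np.isfinite(theta)]
        pmag = sub["p_mag"].to_numpy(dtype=float)
        pmag = pmag[np.isfinite(pmag)]
        if len(defined) == 0:
            results[name] = {
                "n": 0,
                "mean_p_mag": float(np.mean(pmag)) if len(pmag) else None,
                "circ_mean_deg": None,
                "resultant_length": None,
                "against_flow_fraction": None,
                "theta_hist": None,
                "theta_bin_edges": edges.tolist(),
            }
            continue
        cmean, rlen = _circular_stats(defined)
        frac = float(
            np.mean(
                (defined >= AGAINST_FLOW_WINDOW[0])
                & (defined <= AGAINST_FLOW_WINDOW[1])
            )
        )
        hist, _ = np.histogram(defined, bins=edges)
        results[name] = {
            "n": int(len(defined)),
            "mean_p_mag": float(np.mean(pmag)) if len(pmag) else None,
            "circ_mean_deg": cmean,
            "resultant_length": rlen,
            "against_flow_fraction": frac,
            "theta_hist": hist.tolist(),
            "theta_bin_edges": edges.tolist(),
        }
    return results


def against_flow_summary(cell_tables: list[pd.DataFrame]) -> dict:
    """Against-flow fraction across replicates, both ways the percentage
    can be formed: pooling all cells, or averaging per-replicate
    fractions."""
    fracs, total_against, total_n = [], 0, 0
    for cells in cell_tables:
        theta = cells["theta_deg"].to_numpy(dtype=float)
        defined = np.isfinite(theta)
        n = int(defined.sum())
        if n == 0:
            continue
        against = int(cells.loc[defined, "against_flow"].sum())
        fracs.append(against / n)
        total_against += against
        total_n += n
    return {
        "per_cell_pooled": (total_against / total_n) if total_n else None,
        "per_replicate_mean": float(np.mean(fracs)) if fracs else None,
    }


def shear_regressions(cells: pd.DataFrame, flow: FlowSolution,
                      by_region: bool = True) -> dict:
    """Sign-stratified OLS of s against the segment's wall shear stress.

    Fits s = gradient·τ + intercept separately on the s > 0 (with-flow) and
    s < 0 (against-flow) strata, and pooled; reports gradient (μm/Pa),
    Pearson R and n.  Strata with < 3 cells or zero τ variance are skipped
    with a warning.
    """
    work = cells.copy()
    work["tau"] = [
        flow.tau.get(int(s), np.nan) if s >= 0 else np.nan
        for s in work["segment_id"]
    ]
    work = work[np.isfinite(work["scalar_product"])
                & np.isfinite(work["tau"])]
    groups = [("all", work)]
    if by_region and "region" in work.columns:
        groups += [(str(r), g) for r, g in work.groupby("region")]
    results: dict[str, dict] = {}
    for name, sub in groups:
        strata = {
            "positive": sub[sub["scalar_product"] > 0],
            "negative": sub[sub["scalar_product"] < 0],
            "all": sub,
        }
        res: dict[str, dict | None] = {}
        for sname, stratum in strata.items():
            if len(stratum) < 3:
                warnings.warn(
                    f"stratum {name}/{sname} has {len(stratum)} cells; "
                    "skipped"
                )
                res[sname] = None
                continue
            tau = stratum["tau"].to_numpy()
            if np.ptp(tau) == 0:
                warnings.warn(
                    f"stratum {name}/{sname} has constant τ; skipped"
                )
                res[sname] = None
                continue
            fit = linregress(tau, stratum["scalar_product"].to_numpy())
            res[sname] = {
                "gradient": float(fit.slope),
                "R": float(fit.rvalue),
                "n": int(len(stratum)),
            }
        results[name] = res
    return results


def axis_projection(cells: pd.DataFrame, axis: np.ndarray) -> dict:
    """Signed projection of p on a reference axis and the dorsal/ventral
    split (projection > 0 vs < 0; exact zeros counted separately)."""
    axis = np.asarray(axis, dtype=float)
    norm = float(np.hypot(*axis))
    if not np.isclose(norm, 1.0):
        warnings.warn("axis is not unit length; normalizing")
        axis = axis / norm
    p = cells[["px", "py"]].to_numpy(dtype=float)
    ok = np.isfinite(p).all(axis=1)
    proj = np.full(len(cells), np.nan)
    proj[ok] = p[ok] @ axis
    defined = proj[np.isfinite(proj)]
    n = len(defined)
    return {
        "projection": proj,
        "n": n,
        "dorsal_fraction": float(np.mean(defined > 0)) if n else None,
        "ventral_fraction": float(np.mean(defined < 0)) if n else None,
        "zero_count": int(np.sum(defined == 0)),
    }


def _perm_pvalue(x: np.ndarray, y: np.ndarray, stat, rng: np.random.Generator,
                 n_perm: int) -> tuple[float, float]:
    """Two-sided permutation p-value for stat(x) − stat(y)."""
    obs = stat(x) - stat(y)
    pooled = np.concatenate([x, y])
    nx = len(x)
    count = 0
    chunk = max(1, int(2_000_000 // max(len(pooled), 1)))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        block = rng.permuted(np.tile(pooled, (m, 1)), axis=1)
        d = stat(block[:, :nx], axis=1) - stat(block[:, nx:], axis=1)
        count += int(np.sum(np.abs(d) >= abs(obs) - 1e-12))
        done += m
    return float(obs), (count + 1) / (n_perm + 1)


def misalignment_near_regression(
    cells: pd.DataFrame,
    net: VesselNetwork,
    flow: FlowSolution,
    profiles,
    adjacency_dist: float = DEFAULT_ADJACENCY_DIST,
    n_perm: int = 10000,
    seed: int = 0,
) -> dict:
    """Compare |p| and the against-flow fraction between cells on low- vs
    high-shear segments, and between cells adjacent vs non-adjacent to
    regression profiles (seeded permutation tests; empty groups skip the
    comparison with a warning)."""
    rng = np.random.default_rng([int(seed), 17])
    labels = classify_flow(net, flow)
    work = cells[cells["segment_id"] >= 0].copy()
    work["shear_class"] = [
        labels.get(int(s)) for s in work["segment_id"]
    ]

    profile_ids = sorted(
        p.segment_id if hasattr(p, "segment_id") else int(p)
        for p in profiles
    )
    if profile_ids:
        locator = NetworkLocator(net, step=3.0, segment_ids=profile_ids)
        adj = np.array(
            [
                locator.distance(
                    np.array([row["nucleus_x"], row["nucleus_y"]])
                ) <= adjacency_dist
                for _, row in work.iterrows()
            ]
        )
    else:
        adj = np.zeros(len(work), dtype=bool)
    work["adjacent"] = adj

    out: dict[str, dict | None] = {}

    def compare(name: str, g1: pd.DataFrame, g2: pd.DataFrame,
                label1: str, label2: str) -> None:
        if len(g1) == 0 or len(g2) == 0:
            warnings.warn(f"comparison {name}: empty group; skipped")
            out[name] = None
            return
        res: dict = {"n_" + label1: len(g1), "n_" + label2: len(g2)}
        x = g1["p_mag"].to_numpy(dtype=float)
        y = g2["p_mag"].to_numpy(dtype=float)
        x, y = x[np.isfinite(x)], y[np.isfinite(y)]
        if len(x) and len(y):
            obs, p = _perm_pvalue(x, y, np.median, rng, n_perm)
            res["p_mag_median_" + label1] = float(np.median(x))
            res["p_mag_median_" + label2] = float(np.median(y))
            res["p_mag_direction"] = (
                f"{label1} < {label2}" if obs < 0 else f"{label1} > {label2}"
                if obs > 0 else "equal"
            )
            res["p_mag_perm_p"] = p
        xt = g1.loc[np.isfinite(g1["theta_deg"]), "against_flow"].to_numpy(
            dtype=float)
        yt = g2.loc[np.isfinite(g2["theta_deg"]), "against_flow"].to_numpy(
            dtype=float)
        if len(xt) and len(yt):
            obs, p = _perm_pvalue(xt, yt, np.mean, rng, n_perm)
            res["against_fraction_" + label1] = float(np.mean(xt))
            res["against_fraction_" + label2] = float(np.mean(yt))
            res["against_direction"] = (
                f"{label1} < {label2}" if obs < 0 else f"{label1} > {label2}"
                if obs > 0 else "equal"
            )
            res["against_perm_p"] = p
        out[name] = res

    compare(
        "low_vs_high_shear",
        work[work["shear_class"] == "low"],
        work[work["shear_class"] == "high"],
        "low",
        "high",
    )
    compare(
        "adjacent_vs_distant",
        work[work["adjacent"]],
        work[~work["adjacent"]],
        "adjacent",
        "distant",
    )
    return out
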