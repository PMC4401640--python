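"""Axial polarity: pairing, assignment, angles, statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linear_sum_assignment

import polarflow as pf
from polarflow.flow import FlowSolution
from polarflow.netgen import GenConfig, PolarityModel
from polarflow.network import point_segment_distance
from polarflow.polarity import (
    angle_and_scalar,
    assign_to_segments,
    axis_projection,
    cells_from_table,
    misalignment_near_regression,
    pair_points,
    region_stats,
    shear_regressions,
)

from conftest import SMALL_CFG_KW


# ---------------------------------------------------------------------------
# pairing


def test_pair_points_3_4_5():
    table = pair_points(np.array([[0.0, 0.0]]), np.array([[3.0, 4.0]]))
    assert table.loc[0, "px"] == 3.0
    assert table.loc[0, "py"] == 4.0
    assert table.loc[0, "p_mag"] == 5.0


def test_pair_points_coincident_golgi_zero_vector():
    table = pair_points(np.array([[1.0, 1.0]]), np.array([[1.0, 1.0]]))
    assert table.loc[0, "p_mag"] == 0.0


def test_pair_points_crossing_matches_optimal_assignment():
    nuclei = np.array([[0.0, 0.0], [4.0, 0.0]])
    golgis = np.array([[3.0, 0.0], [1.0, 0.0]])
    table = pair_points(nuclei, golgis)
    cost = np.linalg.norm(nuclei[:, None] - golgis[None, :], axis=2)
    ri, ci = linear_sum_assignment(cost)
    for i, j in zip(ri, ci):
        assert table.loc[i, "golgi_x"] == golgis[j, 0]


def test_pair_points_respects_max_distance_and_empties():
    table = pair_points(np.array([[0.0, 0.0]]), np.array([[50.0, 0.0]]),
                        max_pair_dist=10.0)
    assert not table.loc[0, "paired"]
    assert len(pair_points(np.zeros((0, 2)), np.zeros((0, 2)))) == 0


# ---------------------------------------------------------------------------
# segment assignment


def test_assign_nucleus_on_centerline(small_world):
    net = small_world.net
    sid0 = sorted(net.segments)[5]
    vertex = net.segments[sid0].polyline[1]
    cells = pd.DataFrame(
        {"nucleus_x": [vertex[0]], "nucleus_y": [vertex[1]],
         "golgi_x": [vertex[0] + 1], "golgi_y": [vertex[1]]}
    )
    cells = assign_to_segments(cells_from_table(cells), net)
    assert cells.loc[0, "distance_to_segment"] == pytest.approx(0.0, abs=1e-9)


def test_assign_matches_exhaustive_search(small_world):
    net = small_world.net
    rng = np.random.default_rng(5)
    lo, hi = net.bounding_box()
    pts = rng.uniform(lo, hi, size=(60, 2))
    cells = pd.DataFrame(
        {"nucleus_x": pts[:, 0], "nucleus_y": pts[:, 1],
         "golgi_x": pts[:, 0], "golgi_y": pts[:, 1]}
    )
    out = assign_to_segments(cells_from_table(cells), net,
                             max_assign_dist=np.inf)
    for i, p in enumerate(pts):
        dists = {
            sid: point_segment_distance(p, seg.polyline)
            for sid, seg in net.segments.items()
        }
        best = min(dists.values())
        expected = min(s for s, d in dists.items() if d <= best + 1e-9)
        assert out.loc[i, "segment_id"] == expected
        assert out.loc[i, "distance_to_segment"] == pytest.approx(best)


def test_assignment_tie_breaks_to_lower_id():
    from polarflow.network import Segment, VesselNetwork

    net = VesselNetwork()
    net.nodes = {
        0: np.array([0.0, 0.0]), 1: np.array([100.0, 0.0]),
        2: np.array([0.0, 10.0]), 3: np.array([100.0, 10.0]),
    }
    net.segments[4] = Segment(
        0, 1, np.array([[0.0, 0.0], [100.0, 0.0]]), np.full(2, 3.0))
    net.segments[7] = Segment(
        2, 3, np.array([[0.0, 10.0], [100.0, 10.0]]), np.full(2, 3.0))
    cells = cells_from_table(pd.DataFrame(
        {"nucleus_x": [50.0], "nucleus_y": [5.0],
         "golgi_x": [51.0], "golgi_y": [5.0]}
    ))
    out = assign_to_segments(cells, net)
    assert out.loc[0, "segment_id"] == 4


# ---------------------------------------------------------------------------
# angles and scalar products


def _stub_flow(net, tau=None):
    """FlowSolution with rightward unit flow on every segment."""
    sol = FlowSolution(
        node_pressure={}, flow={}, velocity={}, tau={}, perfused={},
    )
    for sid, seg in net.segments.items():
        sol.flow[sid] = 1.0
        sol.velocity[sid] = 1.0
        sol.tau[sid] = 1.0 if tau is None else tau[sid]
        sol.perfused[sid] = True
        n = len(seg.polyline)
        sol.flow_dir[sid] = np.tile([1.0, 0.0], (n, 1))
    return sol


def _one_tube_cells(px, py):
    from conftest import make_tube

    net = make_tube(r=4.0, length=100.0)
    cells = cells_from_table(pd.DataFrame(
        {"nucleus_x": [50.0], "nucleus_y": [0.0],
         "golgi_x": [50.0 + px], "golgi_y": [py]}
    ))
    cells["segment_id"] = 0
    cells["region"] = "capillary"
    return net, cells


@pytest.mark.parametrize(
    "px,py,theta,s",
    [
        (-6.0, 0.0, 180.0, -6.0),  # antiparallel to flow
        (0.0, 5.0, 90.0, 0.0),  # perpendicular
        (4.0, 0.0, 0.0, 4.0),  # with flow
    ],
)
def test_angle_and_scalar_sign_convention(px, py, theta, s):
    net, cells = _one_tube_cells(px, py)
    out = angle_and_scalar(cells, net, _stub_flow(net))
    assert out.loc[0, "theta_deg"] == pytest.approx(theta, abs=1e-9)
    assert out.loc[0, "scalar_product"] == pytest.approx(s, abs=1e-9)


def test_angle_45_degrees_hand_trigonometry():
    # p = (1,0) against flow direction (√2/2, √2/2): θ = 45°, s = cos45
    net, cells = _one_tube_cells(1.0, 0.0)
    sol = _stub_flow(net)
    r2 = np.sqrt(2) / 2
    sol.flow_dir[0] = np.tile([r2, r2], (2, 1))
    out = angle_and_scalar(cells, net, sol)
    assert out.loc[0, "theta_deg"] == pytest.approx(45.0, abs=1e-9)
    assert out.loc[0, "scalar_product"] == pytest.approx(r2, abs=1e-9)


def test_zero_vector_theta_undefined():
    net, cells = _one_tube_cells(0.0, 0.0)
    out = angle_and_scalar(cells, net, _stub_flow(net))
    assert np.isnan(out.loc[0, "theta_deg"])


def test_scalar_product_bounds(small_world_analyzed):
    _, cells = small_world_analyzed
    ok = np.isfinite(cells["theta_deg"])
    s = cells.loc[ok, "scalar_product"].to_numpy()
    p = cells.loc[ok, "p_mag"].to_numpy()
    th = cells.loc[ok, "theta_deg"].to_numpy()
    assert np.all(s <= p + 1e-9)
    assert np.all(s >= -p - 1e-9)
    at_min = np.abs(s + p) < 1e-9
    assert np.all(np.abs(th[at_min & (p > 1e-9)] - 180.0) < 1e-6)
    against = cells.loc[ok, "against_flow"].to_numpy()
    assert np.array_equal(against, (th >= 135.0) & (th <= 180.0))


# ---------------------------------------------------------------------------
# region statistics


def test_region_stats_all_against():
    cells = pd.DataFrame(
        {"theta_deg": [180.0] * 5, "p_mag": [5.0] * 5,
         "against_flow": [True] * 5}
    )
    st = region_stats(cells)["all"]
    assert st["against_flow_fraction"] == 1.0
    assert st["resultant_length"] == pytest.approx(1.0)


def test_region_stats_half_against():
    cells = pd.DataFrame(
        {"theta_deg": [170.0, 10.0], "p_mag": [5.0, 5.0],
         "against_flow": [True, False]}
    )
    assert region_stats(cells)["all"]["against_flow_fraction"] == 0.5


def test_region_stats_empty_region_nulls():
    cells = pd.DataFrame(
        {"theta_deg": [np.nan], "p_mag": [2.0], "against_flow": [False],
         "region": ["sprouting_front"]}
    )
    st = region_stats(cells)["sprouting_front"]
    assert st["n"] == 0
    assert st["against_flow_fraction"] is None


def test_uniform_null_gives_quarter_against():
    kw = {k: v for k, v in SMALL_CFG_KW.items() if k != "n_cells_target"}
    cfg = GenConfig(seed=21, n_cells_target=5000,
                    polarity_model=PolarityModel(kappa=0.0), **kw)
    w = pf.simulate_world(cfg)
    cells = cells_from_table(w.cells)
    cells = assign_to_segments(cells, w.net)
    cells = angle_and_scalar(cells, w.net, w.flow)
    frac = region_stats(cells)["all"]["against_flow_fraction"]
    assert frac == pytest.approx(0.25, abs=0.02)


def test_histogram_counts_sum_to_n(small_world_analyzed):
    _, cells = small_world_analyzed
    st = region_stats(cells)
    for rec in st.values():
        if rec["n"]:
            assert sum(rec["theta_hist"]) == rec["n"]


# ---------------------------------------------------------------------------
# shear regressions


def _regression_cells(gradient, noise, n, seed=0):
    rng = np.random.default_rng(seed)
    tau = rng.uniform(0.1, 4.0, n)
    s = gradient * tau + (rng.normal(0, noise, n) if noise else 0.0)
    cells = pd.DataFrame(
        {"segment_id": np.arange(n), "scalar_product": s,
         "p_mag": np.abs(s), "region": "capillary"}
    )
    sol = FlowSolution(node_pressure={}, flow={}, velocity={},
                       tau={i: float(t) for i, t in enumerate(tau)},
                       perfused={i: True for i in range(n)})
    return cells, sol


def test_noiseless_line_recovered_exactly():
    cells, sol = _regression_cells(-0.5, 0.0, 50)
    res = shear_regressions(cells, sol, by_region=False)["all"]
    assert res["negative"]["gradient"] == pytest.approx(-0.5, rel=1e-9)
    assert res["negative"]["R"] == pytest.approx(-1.0, abs=1e-9)


def test_constant_tau_stratum_skipped():
    cells, sol = _regression_cells(-0.5, 0.0, 10)
    for k in sol.tau:
        sol.tau[k] = 2.0
    with pytest.warns(UserWarning, match="constant"):
        res = shear_regressions(cells, sol, by_region=False)["all"]
    assert res["negative"] is None


def test_small_stratum_skipped():
    cells, sol = _regression_cells(0.5, 0.0, 2)
    with pytest.warns(UserWarning):
        res = shear_regressions(cells, sol, by_region=False)["all"]
    assert res["negative"] is None


def test_noisy_gradient_recovered():
    cells, sol = _regression_cells(-0.4, 0.1, 500, seed=3)
    res = shear_regressions(cells, sol, by_region=False)["all"]
    assert res["negative"]["gradient"] == pytest.approx(-0.4, abs=0.03)


# ---------------------------------------------------------------------------
# axis projection


def test_axis_projection_examples():
    cells = pd.DataFrame({"px": [0.0, 3.0], "py": [-5.0, 0.0]})
    res = axis_projection(cells, np.array([0.0, -1.0]))
    assert res["projection"][0] == pytest.approx(5.0)
    assert res["projection"][1] == pytest.approx(0.0)
    assert res["zero_count"] == 1
    with pytest.warns(UserWarning, match="normaliz"):
        axis_projection(cells, np.array([0.0, -2.0]))


def test_axis_projection_mixture_recovery():
    rng = np.random.default_rng(8)
    n = 400
    dorsal = rng.random(n) < 0.7
    py = np.where(dorsal, -np.abs(rng.normal(3, 1, n)),
                  np.abs(rng.normal(3, 1, n)))
    cells = pd.DataFrame({"px": rng.normal(0, 1, n), "py": py})
    res = axis_projection(cells, np.array([0.0, -1.0]))
    assert res["dorsal_fraction"] == pytest.approx(0.70, abs=0.05)


# ---------------------------------------------------------------------------
# frame invariance


def test_rotation_leaves_angles_invariant():
    kw = dict(SMALL_CFG_KW)
    kw["n_cells_target"] = 400
    cfg = GenConfig(seed=14, **kw)
    w = pf.simulate_world(cfg)
    cells = cells_from_table(w.cells)
    cells = assign_to_segments(cells, w.net)
    cells = angle_and_scalar(cells, w.net, w.flow)

    ang = 0.37
    c, s = np.cos(ang), np.sin(ang)
    R = np.array([[c, -s], [s, c]])
    rot = w.net.copy()
    for nid in rot.nodes:
        rot.nodes[nid] = R @ rot.nodes[nid]
    for seg in rot.segments.values():
        seg.polyline = seg.polyline @ R.T
    sol = pf.solve_flow(rot, pf.BoundaryConditions.default_for(rot))
    rcells = w.cells.copy()
    nxy = rcells[["nucleus_x", "nucleus_y"]].to_numpy() @ R.T
    gxy = rcells[["golgi_x", "golgi_y"]].to_numpy() @ R.T
    rcells[["nucleus_x", "nucleus_y"]] = nxy
    rcells[["golgi_x", "golgi_y"]] = gxy
    rcells = cells_from_table(rcells)
    rcells = assign_to_segments(rcells, rot)
    rcells = angle_and_scalar(rcells, rot, sol)
    both = np.isfinite(cells["theta_deg"]) & np.isfinite(rcells["theta_deg"])
    assert both.mean() > 0.9
    np.testing.assert_allclose(
        cells.loc[both, "theta_deg"], rcells.loc[both, "theta_deg"],
        atol=1e-6,
    )
    np.testing.assert_allclose(
        cells.loc[both, "scalar_product"],
        rcells.loc[both, "scalar_product"], atol=1e-6,
    )


# ---------------------------------------------------------------------------
# misalignment comparisons


def test_misalignment_detects_planted_low_shear_effect(small_world):
    w = small_world
    labels = pf.classify_flow(w.net, w.flow)
    rng = np.random.default_rng(2)
    rows = []
    for i, (sid, lab) in enumerate(sorted(labels.items())):
        seg = w.net.segments[sid]
        mid = seg.polyline[len(seg.polyline) // 2]
        mag = 2.0 if lab == "low" else 6.0
        ang = rng.uniform(0, 2 * np.pi)
        rows.append(
            {"cell_id": i, "nucleus_x": mid[0], "nucleus_y": mid[1],
             "golgi_x": mid[0] + mag * np.cos(ang),
             "golgi_y": mid[1] + mag * np.sin(ang)}
        )
    cells = cells_from_table(pd.DataFrame(rows))
    cells = assign_to_segments(cells, w.net)
    cells = angle_and_scalar(cells, w.net, w.flow)
    profiles = pf.detect_profiles(w.net)
    res = misalignment_near_regression(
        cells, w.net, w.flow, profiles, n_perm=500, seed=1
    )
    r = res["low_vs_high_shear"]
    assert r["p_mag_direction"] == "low < high"
    assert r["p_mag_perm_p"] < 0.01


def test_misalignment_single_group_skipped(small_world):
    w = small_world
    cells = cells_from_table(w.cells.head(5).copy())
    cells = assign_to_segments(cells, w.net)
    cells = angle_and_scalar(cells, w.net, w.flow)
    with pytest.warns(UserWarning, match="empty group"):
        res = misalignment_near_regression(
            cells, w.net, w.flow, [], n_perm=50, seed=1
        )
    assert res["adjacent_vs_distant"] is None
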