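"""Synthetic retina generator: topology, determinism, planted truth."""

import itertools
import json

import networkx as nx
import numpy as np
import pytest
from scipy import stats

import polarflow as pf
from polarflow.netgen import GenConfig, PolarityModel
from polarflow.network import network_to_dict, point_segment_distance

from conftest import ROUNDTRIP_CFG_KW, SMALL_CFG_KW, make_tube


# ---------------------------------------------------------------------------
# network generation


def test_no_arteries_is_configuration_error():
    with pytest.raises(pf.ConfigurationError):
        pf.generate_network(GenConfig(n_arteries=0, seed=1))


def test_spacing_wider_than_retina_is_configuration_error():
    with pytest.raises(pf.ConfigurationError):
        GenConfig(capillary_spacing=1200.0, retina_radius=1000.0).validate()


def test_stage_mix_must_sum_to_one():
    with pytest.raises(pf.ConfigurationError):
        GenConfig(stage_mix=(0.5, 0.5, 0.5, 0.0)).validate()


def test_determinism_byte_identical_json():
    cfg = GenConfig(seed=7, **SMALL_CFG_KW)
    a = json.dumps(network_to_dict(pf.generate_network(cfg)))
    b = json.dumps(network_to_dict(pf.generate_network(cfg)))
    assert a == b


def test_every_nonsprout_segment_on_inlet_outlet_path():
    """Exhaustive simple-path oracle on a tiny plexus: each non-sprout
    segment must lie on at least one inlet→outlet simple path."""
    cfg = GenConfig(seed=2, retina_radius=170.0, capillary_spacing=60.0,
                    n_arteries=2, n_veins=1, capillary_dropout=0.3)
    net = pf.generate_network(cfg)
    g = net.to_graph()
    covered: set = set()
    for s, t in itertools.product(net.inlets, net.outlets):
        for path in nx.all_simple_edge_paths(g, s, t):
            covered.update(k for _, _, k in path)
    non_sprout = {
        sid for sid, seg in net.segments.items()
        if seg.region != "sprouting_front"
    }
    # blind sprouts can never be on a simple through-path
    assert non_sprout <= covered


def test_default_reachability_and_bounds():
    cfg = GenConfig(seed=5, **SMALL_CFG_KW)
    net = pf.generate_network(cfg)
    g = net.to_graph()
    reach_in = set().union(*(nx.node_connected_component(g, i)
                             for i in net.inlets))
    assert set(net.nodes) <= reach_in
    center = np.asarray(cfg.optic_center)
    for seg in net.segments.values():
        d = np.hypot(*(seg.polyline - center).T)
        assert np.all(d <= cfg.retina_radius + 1e-6)


def test_one_inlet_per_artery_one_outlet_per_vein():
    cfg = GenConfig(seed=5, **SMALL_CFG_KW)
    net = pf.generate_network(cfg)
    assert len(net.inlets) == cfg.n_arteries
    assert len(net.outlets) == cfg.n_veins
    deg = net.node_degrees()
    for nid in net.inlets + net.outlets:
        assert deg[nid] == 1


# ---------------------------------------------------------------------------
# cells


def test_cell_count_matches_target_exactly(small_world):
    assert len(small_world.cells) == small_world.cfg.n_cells_target


def test_vonmises_requires_flow(small_world):
    with pytest.raises(pf.PreconditionError):
        pf.generate_cells(small_world.net, small_world.cfg, flow=None)


def test_kappa_zero_angles_uniform():
    cfg = GenConfig(seed=4, n_cells_target=5000,
                    polarity_model=PolarityModel(kappa=0.0),
                    **{k: v for k, v in SMALL_CFG_KW.items()
                       if k != "n_cells_target"})
    w = pf.simulate_world(cfg)
    theta = w.truth.cell_true["theta_true_deg"].dropna().to_numpy()
    assert len(theta) > 4000
    p = stats.kstest(theta, stats.uniform(loc=0, scale=180).cdf).pvalue
    assert p > 0.01


def test_large_kappa_concentrates_against_flow():
    cfg = GenConfig(seed=4, polarity_model=PolarityModel(kappa=50.0),
                    **SMALL_CFG_KW)
    w = pf.simulate_world(cfg)
    theta = w.truth.cell_true["theta_true_deg"].dropna().to_numpy()
    # von Mises(kappa=50) mass within ±45° of the mean exceeds 99.9%
    assert np.mean((theta >= 135.0) & (theta <= 180.0)) > 0.99


def test_zero_magnitude_sd_gives_exact_lengths():
    cfg = GenConfig(
        seed=4,
        polarity_model=PolarityModel(magnitude_mean=5.0, magnitude_sd=0.0),
        **SMALL_CFG_KW,
    )
    w = pf.simulate_world(cfg)
    p = np.hypot(
        w.cells["golgi_x"] - w.cells["nucleus_x"],
        w.cells["golgi_y"] - w.cells["nucleus_y"],
    )
    assert np.allclose(p, 5.0)


def test_density_gradient_recovered():
    cfg = GenConfig(seed=9, density_gradient=1.0, **SMALL_CFG_KW)
    w = pf.simulate_world(cfg)
    d = np.hypot(w.cells["nucleus_x"], w.cells["nucleus_y"])
    inner = np.sum(d < 200.0)
    outer = np.sum(d >= 200.0)
    assert inner > 0 and outer > 0
    # central density excess: inner half-disc should hold clearly more
    # cells per unit vasculature than with a flat planting
    cfg_flat = GenConfig(seed=9, density_gradient=0.0, **SMALL_CFG_KW)
    w_flat = pf.simulate_world(cfg_flat)
    d_flat = np.hypot(w_flat.cells["nucleus_x"], w_flat.cells["nucleus_y"])
    assert inner / len(d) > np.sum(d_flat < 200.0) / len(d_flat) + 0.03


# ---------------------------------------------------------------------------
# regression + apoptosis planting


def test_zero_regression_rate_plants_nothing_and_detects_nothing():
    cfg = GenConfig(seed=6, regression_rate=0.0, **{
        k: v for k, v in SMALL_CFG_KW.items() if k != "regression_rate"})
    w = pf.simulate_world(cfg)
    assert w.truth.regression_stages == {}
    assert pf.detect_profiles(w.net) == []


def test_coloc_saturation_flags_every_detectable_profile():
    kw = dict(SMALL_CFG_KW)
    kw.update(coloc_rate=1.0, apoptosis_total_mean=300.0)
    cfg = GenConfig(seed=6, **kw)
    w = pf.simulate_world(cfg)
    detectable = [s for s, st in w.truth.regression_stages.items()
                  if st >= 2]
    assert len(w.truth.coloc_segments) == len(detectable)
    events = w.truth.apoptosis
    coloc_pts = events[events["coloc"]]
    for sid in w.truth.coloc_segments:
        poly = w.net.segments[sid].polyline
        dmin = min(
            point_segment_distance(np.array([r.x, r.y]), poly)
            for r in coloc_pts.itertuples()
        )
        assert dmin <= cfg.coloc_dist


def test_pure_resolution_mix_empties_all_planted_segments():
    kw = dict(SMALL_CFG_KW)
    kw["stage_mix"] = (0.0, 0.0, 0.0, 1.0)
    cfg = GenConfig(seed=6, **kw)
    w = pf.simulate_world(cfg)
    planted = list(w.truth.regression_stages)
    assert planted
    placed = set(w.truth.cell_true["segment_id"])
    for sid in planted:
        assert w.net.segments[sid].lumen_fraction == 0.0
        assert sid not in placed


def test_apoptosis_points_respect_coloc_distance_rule(small_world):
    """Background (non-coloc) events stay clear of planted segments."""
    truth = small_world.truth
    planted = list(truth.regression_stages)
    if not planted:
        pytest.skip("no planted segments in fixture")
    bg = truth.apoptosis[~truth.apoptosis["coloc"]]
    for row in bg.itertuples():
        dmin = min(
            point_segment_distance(
                np.array([row.x, row.y]),
                small_world.net.segments[s].polyline,
            )
            for s in planted
        )
        assert dmin > small_world.cfg.coloc_dist


# ---------------------------------------------------------------------------
# rendering


def test_rendered_stripe_width_matches_radius():
    net = make_tube(r=4.0, length=120.0)
    cfg = GenConfig(seed=1, retina_radius=150.0, pixel_size=0.5,
                    optic_center=(60.0, 0.0))
    stack = pf.render_masks(net, None, cfg)
    lumen = stack.channels["lumen"]
    col = stack.to_pixel(np.array([[60.0, 0.0]]))[0]
    widths = lumen[:, int(col[1]) - 5:int(col[1]) + 5].sum(axis=0)
    assert abs(widths.max() - 16) <= 2  # 4 μm radius / 0.5 μm px → 16 px


def test_empty_cell_table_renders_blank_nuclei(small_world):
    import pandas as pd

    stack = pf.render_masks(
        small_world.net, pd.DataFrame(
            columns=["nucleus_x", "nucleus_y", "golgi_x", "golgi_y"]),
        small_world.cfg,
    )
    assert not stack.channels["nuclei"].any()
    assert stack.channels["lumen"].any()


def test_stage4_segment_matrix_positive_lumen_negative():
    kw = dict(ROUNDTRIP_CFG_KW)
    kw.update(regression_rate=0.08, stage_mix=(0.0, 0.0, 0.0, 1.0))
    cfg = GenConfig(seed=3, **kw)
    w = pf.simulate_world(cfg)
    stack = pf.render_masks(w.net, None, cfg)
    planted = list(w.truth.regression_stages)
    assert planted
    sid = planted[0]
    poly = w.net.segments[sid].polyline
    rc = stack.to_pixel(poly[1:-1])
    rows, cols = rc[:, 0].astype(int), rc[:, 1].astype(int)
    assert stack.channels["matrix"][rows, cols].all()
    assert not stack.channels["lumen"][rows, cols].any()


def test_fov_smaller_than_network_is_error(small_world):
    with pytest.raises(pf.ConfigurationError):
        pf.render_masks(small_world.net, None, small_world.cfg, fov=100.0)


def test_stack_tiff_roundtrip(tmp_path):
    net = make_tube()
    cfg = GenConfig(seed=1, retina_radius=150.0, pixel_size=1.0,
                    optic_center=(50.0, 0.0))
    stack = pf.render_masks(net, None, cfg)
    path = tmp_path / "stack.tif"
    pf.write_stack(stack, path)
    back = pf.read_stack(path)
    assert set(back.channels) == set(stack.channels)
    assert back.pixel_size == stack.pixel_size
    for name in stack.channels:
        assert np.array_equal(back.channels[name], stack.channels[name])
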