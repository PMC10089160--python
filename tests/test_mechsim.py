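"""Mechanics: contact forces, front profile, growth layer, stability."""

import math

import numpy as np
import pytest
import yaml

from crowdclone import (
    ConfigurationError,
    InstabilityError,
    SimConfig,
    compute_forces,
    front_profile,
    front_speed_fit,
    init_population,
    run,
    step,
)
from crowdclone.mechsim import PopulationState, UNLABELED


def make_state(cfg, cells):
    """Build a state from (x, y, theta, rb) tuples."""
    state = PopulationState(cfg)
    for (x, y, th, rb) in cells:
        state.add_cell(x, y, th, rb, UNLABELED, 0.0)
    return state


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "kwargs",
    [
        dict(box_width=2.0),               # narrower than 4 cells
        dict(sigma=-1.0),
        dict(lambda_depth=0.5),            # thinner than one cell
        dict(label_rate=1.5),
        dict(removal_depth=3.0, lambda_depth=5.0, box_width=20.0),
        dict(bud_rule="sideways"),
        dict(growth_profile=[[0.0, -1.0], [5.0, 1.0]]),
    ],
)
def test_invalid_configs_rejected(kwargs):
    with pytest.raises(ConfigurationError):
        SimConfig(**kwargs)


def test_config_yaml_roundtrip(tmp_path):
    cfg = SimConfig(box_width=12.0, lambda_depth=6.0, label_rate=0.02, seed=9)
    path = tmp_path / "cfg.yaml"
    cfg.to_yaml(path)
    cfg2 = SimConfig.from_yaml(path)
    assert cfg2.to_dict() == cfg.to_dict()


def test_config_yaml_unknown_key_rejected(tmp_path):
    path = tmp_path / "cfg.yaml"
    path.write_text("box_width: 12.0\nwibble: 3\n")
    with pytest.raises(ConfigurationError, match="wibble"):
        SimConfig.from_yaml(path)


def test_default_dt_relaxes_overlaps_gently():
    cfg = SimConfig()
    area_min = math.pi * (cfg.sigma / 2) ** 2
    # displacement per step for a 0.1-sigma overlap stays <= 0.01 sigma
    assert cfg.dt * cfg.spring_constant * 0.1 / (cfg.damping * area_min) \
        <= 0.01 * cfg.sigma + 1e-12


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def test_init_population_row():
    cfg = SimConfig(box_width=20.0)
    state = init_population(cfg)
    assert state.n_live == 20
    np.testing.assert_allclose(
        np.sort(state.x[:20]), np.arange(20) + 0.5
    )
    assert np.all(state.y[:20] == 0.0)
    assert np.all(state.rb[:20] == 0.0)
    assert np.all(state.label[:20] == UNLABELED)
    assert np.all(state.growing[:20])


def test_init_population_jittered_is_overlap_free():
    cfg = SimConfig(box_width=30.0)
    state = init_population(cfg, rng=np.random.default_rng(0))
    # worst-case initial mother-mother overlap stays under sigma/2
    xs = np.sort(state.x[: state.n_live])
    gaps = np.diff(np.concatenate([xs, [xs[0] + cfg.box_width]]))
    assert gaps.min() > 0.5 * cfg.sigma


# ---------------------------------------------------------------------------
# forces
# ---------------------------------------------------------------------------

def test_no_force_without_contact():
    cfg = SimConfig(box_width=20.0)
    state = make_state(cfg, [(5.0, 0.0, 0.0, 0.0), (6.5, 0.0, 0.0, 0.0)])
    fx, fy, tq = compute_forces(state, cfg)
    assert np.all(fx == 0) and np.all(fy == 0) and np.all(tq == 0)


def test_linear_repulsion_magnitude():
    cfg = SimConfig(box_width=20.0)
    overlap = 0.1
    state = make_state(
        cfg, [(5.0, 0.0, 0.0, 0.0), (5.0 + 1.0 - overlap, 0.0, 0.0, 0.0)]
    )
    fx, fy, tq = compute_forces(state, cfg)
    np.testing.assert_allclose(fx[0], -cfg.spring_constant * overlap)
    np.testing.assert_allclose(fx[1], +cfg.spring_constant * overlap)
    np.testing.assert_allclose(fx[0] + fx[1], 0.0, atol=1e-12)
    assert np.allclose(fy, 0) and np.allclose(tq, 0)


def test_symmetric_chain_zero_net_force_on_middle():
    cfg = SimConfig(box_width=20.0)
    state = make_state(
        cfg,
        [(5.0, 0.0, 0.0, 0.0), (5.9, 0.0, 0.0, 0.0), (6.8, 0.0, 0.0, 0.0)],
    )
    fx, fy, tq = compute_forces(state, cfg)
    np.testing.assert_allclose(fx[1], 0.0, atol=1e-10)


def test_minimum_image_across_boundary():
    cfg = SimConfig(box_width=20.0)
    state = make_state(cfg, [(0.2, 0.0, 0.0, 0.0), (19.9, 0.0, 0.0, 0.0)])
    fx, _, _ = compute_forces(state, cfg)
    # distance across the seam is 0.3 < 1: repulsion pushes them apart
    assert fx[0] > 0 and fx[1] < 0


# ---------------------------------------------------------------------------
# front profile
# ---------------------------------------------------------------------------

def test_front_profile_constant_row():
    cfg = SimConfig(box_width=10.0)
    y0 = 3.0
    state = make_state(cfg, [(i + 0.5, y0, math.pi / 2, 0.0) for i in range(10)])
    prof = front_profile(state, cfg)
    assert len(prof.heights) == 10
    assert np.allclose(prof.heights, prof.heights[0])
    # height is the material surface: top edge of the highest disk
    np.testing.assert_allclose(prof.heights, y0 + cfg.sigma / 2)


def test_front_profile_empty_column_interpolation():
    cfg = SimConfig(box_width=10.0)
    cells = [(i + 0.5, 10.0 if i < 5 else 12.0, math.pi / 2, 0.0)
             for i in range(10) if i != 7]
    state = make_state(cfg, cells)
    prof = front_profile(state, cfg)
    # empty column takes the max of its nearest non-empty neighbours
    np.testing.assert_allclose(prof.heights[7], 12.0 + 0.5)


def test_front_profile_matches_bruteforce(rng):
    cfg = SimConfig(box_width=12.0)
    cells = [
        (rng.uniform(0, 12), rng.uniform(0, 8), rng.uniform(0, 2 * np.pi),
         rng.uniform(0, 0.49))
        for _ in range(60)
    ]
    state = make_state(cfg, cells)
    prof = front_profile(state, cfg)
    rm = 0.5
    expected = np.full(12, -np.inf)
    for (x, y, th, rb) in cells:
        tops = [(x % 12, y + rm)]
        if rb > 0:
            tops.append((
                (x + (rm + rb) * np.cos(th)) % 12,
                y + (rm + rb) * np.sin(th) + rb,
            ))
        for (px, py) in tops:
            c = min(int(px // 1.0), 11)
            expected[c] = max(expected[c], py)
    filled = np.isfinite(expected)
    np.testing.assert_allclose(prof.heights[filled], expected[filled])


def test_depth_is_floored_at_zero():
    cfg = SimConfig(box_width=10.0)
    state = make_state(cfg, [(i + 0.5, 0.0, math.pi / 2, 0.3) for i in range(10)])
    prof = front_profile(state, cfg)
    assert prof.depth_of(0.5, 100.0) == 0.0


# ---------------------------------------------------------------------------
# stepping
# ---------------------------------------------------------------------------

def test_isolated_cell_grows_exponentially():
    cfg = SimConfig(box_width=10.0)
    state = make_state(cfg, [(5.0, 0.0, math.pi / 2, 0.1)])
    a0 = 0.25 + 0.1 ** 2
    step(state, cfg, n_steps=1)
    a1 = 0.25 + state.rb[0] ** 2
    np.testing.assert_allclose(a1 / a0, math.exp(cfg.growth_rate * cfg.dt),
                               rtol=1e-12)


def test_no_growth_below_growth_layer():
    cfg = SimConfig(box_width=10.0, lambda_depth=5.0)
    cells = [(i + 0.5, 0.0, math.pi / 2, 0.2) for i in range(10)]
    cells += [(5.0, -2 * 5.0, math.pi / 2, 0.2)]  # depth 2*lambda
    state = make_state(cfg, cells)
    state.growing[:10] = False  # keep the front row static
    rb_before = state.rb[10]
    step(state, cfg, n_steps=50)
    assert state.rb[10] == rb_before


def test_two_body_relaxation_matches_independent_integrator():
    cfg = SimConfig(box_width=20.0)
    x1, x2 = 8.0, 8.8
    state = make_state(cfg, [(x1, 0.0, 0.0, 0.0), (x2, 0.0, 0.0, 0.0)])
    state.growing[:2] = False
    # independent explicit-Euler oracle for two overdamped disks
    ox1, ox2 = x1, x2
    mob = 1.0 / (cfg.damping * math.pi * 0.25)
    nsteps = 400
    dists = []
    for _ in range(nsteps):
        d = ox2 - ox1
        f = cfg.spring_constant * max(1.0 - d, 0.0)
        ox1 -= cfg.dt * f * mob
        ox2 += cfg.dt * f * mob
        dists.append(ox2 - ox1)
    step(state, cfg, n_steps=nsteps)
    got = abs(state.x[1] - state.x[0])
    assert got == pytest.approx(ox2 - ox1, abs=1e-6)
    assert np.all(np.diff(dists) >= -1e-12)  # monotone separation
    assert state.y[0] == 0.0 and np.all(state.theta[:2] == 0.0)


def test_instability_raises_helpful_error():
    cfg = SimConfig(box_width=10.0, dt=0.05)
    with pytest.raises(InstabilityError, match="dt"):
        run(cfg)


# ---------------------------------------------------------------------------
# full runs
# ---------------------------------------------------------------------------

def test_run_is_deterministic():
    cfg = dict(box_width=8.0, lambda_depth=3.0, label_rate=0.2,
               stop_divisions=150, seed=5)
    r1 = run(SimConfig(**cfg))
    r2 = run(SimConfig(**cfg))
    assert r1.n_divisions == r2.n_divisions
    assert len(r1.clones) == len(r2.clones)
    for a, b in zip(r1.clones, r2.clones):
        assert (a.label, a.birth_time, a.birth_delta, a.final_size,
                a.surfing, a.active) == \
               (b.label, b.birth_time, b.birth_delta, b.final_size,
                b.surfing, b.active)
    np.testing.assert_array_equal(
        r1.state.snapshot_arrays()["y"], r2.state.snapshot_arrays()["y"]
    )


def test_cell_conservation(small_run):
    cfg = small_run.config
    initial = int(cfg.box_width // cfg.sigma)
    assert small_run.cells_created == initial + small_run.n_divisions
    ids = np.concatenate([
        small_run.state.cell_id[: small_run.state.n_live],
        np.asarray(small_run.state._frozen["cell_id"]),
    ])
    assert len(np.unique(ids)) == len(ids)


def test_no_labeling_without_label_rate():
    cfg = SimConfig(box_width=8.0, lambda_depth=3.0, label_rate=0.0,
                    stop_divisions=100, seed=1)
    res = run(cfg)
    assert res.clones == []


def test_front_advances_steadily(small_run):
    speed, r2 = front_speed_fit(small_run)
    assert speed > 0
    assert r2 > 0.99


def test_growth_layer_occupancy(small_run):
    """Growing cells per unit front length ~ lambda/sigma^2 (within 20%)."""
    cfg = small_run.config
    state = small_run.state
    prof = front_profile(state, cfg)
    n = state.n_live
    depth = np.array([prof.depth_of(state.x[i], state.y[i]) for i in range(n)])
    per_len = np.sum((depth < cfg.lambda_depth) & state.growing[:n]) \
        / cfg.box_width
    target = cfg.lambda_depth / cfg.sigma ** 2
    assert abs(per_len - target) / target < 0.2


def test_excluded_volume(small_run):
    """99th percentile of pairwise disk overlap < 0.15 sigma in steady state."""
    from scipy.spatial import cKDTree

    cfg = small_run.config
    st = small_run.state
    n = st.n_live
    rm = cfg.sigma / 2
    xs = [st.x[:n]]
    ys = [st.y[:n]]
    rs = [np.full(n, rm)]
    cid = [np.arange(n)]
    hb = st.rb[:n] > 0
    xs.append((st.x[:n] + (rm + st.rb[:n]) * np.cos(st.theta[:n]))[hb]
              % cfg.box_width)
    ys.append((st.y[:n] + (rm + st.rb[:n]) * np.sin(st.theta[:n]))[hb])
    rs.append(st.rb[:n][hb])
    cid.append(np.arange(n)[hb])
    X, Y = np.concatenate(xs), np.concatenate(ys)
    R, C = np.concatenate(rs), np.concatenate(cid)
    pairs = cKDTree(np.c_[X, Y]).query_pairs(1.0, output_type="ndarray")
    i, j = pairs[C[pairs[:, 0]] != C[pairs[:, 1]]].T
    dx = np.abs(X[i] - X[j])
    dx = np.minimum(dx, cfg.box_width - dx)
    ov = R[i] + R[j] - np.hypot(dx, Y[i] - Y[j])
    ov = ov[ov > 0]
    assert np.percentile(ov, 99) < 0.15 * cfg.sigma


def test_snapshot_writer_roundtrip(small_run, tmp_path):
    import pandas as pd

    from crowdclone import write_snapshot

    path = tmp_path / "snap.tsv"
    write_snapshot(small_run, small_run.config, path)
    df = pd.read_csv(path, sep="\t")
    assert list(df.columns) == ["cell_id", "x", "y", "theta", "bud_radius",
                                "clone_label", "growing", "birth_time"]
    assert len(df) == small_run.cells_created
    assert (df["clone_label"] == "unlabeled").sum() > 0
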