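"""Spatial subsampling, spectrum rescaling and mutation-rate estimation."""

import numpy as np
import pandas as pd
import pytest

from crowdclone import (
    EmptySampleWarning,
    LDConfig,
    SampleRegion,
    Spectrum,
    draw_sample,
    estimate_mutation_rate,
    reconstruct_full_spectrum,
    rescale_spectrum,
    simulate_luria_delbruck_replicates,
    spectrum_from_sample,
    unrescale_spectrum,
    write_snapshot,
)


@pytest.fixture()
def three_clone_snapshot():
    """Hand-built snapshot: a flat front row plus three separated clones.

    Front cells sit at y = 20 across x in [0, 30); clone A (3 cells) at
    depth ~5, clone B (2 cells) at depth ~15, clone C (4 cells) at depth
    ~25.  All positions in units of sigma.
    """
    rows = []
    cid = 0
    for i in range(30):
        rows.append((cid, i + 0.5, 20.0, np.pi / 2, 0.0, "unlabeled", 1, 0.0))
        cid += 1
    for dx in range(3):  # clone A, depth 20.5 - 15.0 ~ 5
        rows.append((cid, 5.0 + dx, 15.0, 0.0, 0.0, 1, 0, 0.0))
        cid += 1
    for dx in range(2):  # clone B, depth ~ 15
        rows.append((cid, 15.0 + dx, 5.0, 0.0, 0.0, 2, 0, 0.0))
        cid += 1
    for dx in range(4):  # clone C, depth ~ 25
        rows.append((cid, 25.0 + dx * 0.5, -5.0, 0.0, 0.0, 3, 0, 0.0))
        cid += 1
    return pd.DataFrame(rows, columns=[
        "cell_id", "x", "y", "theta", "bud_radius", "clone_label",
        "growing", "birth_time"])


def test_region_membership_on_fixture(three_clone_snapshot):
    snap = three_clone_snapshot
    # depth measured from the front surface at 20.5
    sub, n = draw_sample(snap, SampleRegion("region", depth_range=(3.0, 8.0)))
    assert set(sub["clone_label"]) == {1}
    assert n == 3
    sub, n = draw_sample(snap, SampleRegion("region", depth_range=(10.0, 20.0)))
    assert set(sub["clone_label"]) == {2}
    sub, n = draw_sample(
        snap, SampleRegion("region", depth_range=(20.0, 30.0),
                           x_range=(24.0, 28.0)))
    assert set(sub["clone_label"]) == {3}
    assert n == 4


def test_region_covering_everything_is_identity(three_clone_snapshot):
    snap = three_clone_snapshot
    sub, n = draw_sample(snap, SampleRegion("region", depth_range=(0.0, 1e6)))
    assert n == len(snap)
    pd.testing.assert_frame_equal(
        sub.drop(columns="depth_from_front").reset_index(drop=True), snap)


def test_empty_region_warns(three_clone_snapshot):
    with pytest.warns(EmptySampleWarning):
        sub, n = draw_sample(
            three_clone_snapshot,
            SampleRegion("region", depth_range=(500.0, 600.0)))
    assert n == 0


def test_random_sampling_is_seeded(three_clone_snapshot):
    reg = SampleRegion("random", fraction=0.5, seed=4)
    s1, _ = draw_sample(three_clone_snapshot, reg)
    s2, _ = draw_sample(three_clone_snapshot, reg)
    pd.testing.assert_frame_equal(s1, s2)


def test_sample_region_validation():
    with pytest.raises(ValueError):
        SampleRegion("random", fraction=0.0)
    with pytest.raises(ValueError):
        SampleRegion("region")
    with pytest.raises(ValueError):
        SampleRegion("region", depth_range=(5.0, 2.0))
    with pytest.raises(ValueError):
        SampleRegion("quadrat", fraction=0.5)


# ---------------------------------------------------------------------------
# rescaling
# ---------------------------------------------------------------------------

def test_rescale_region_arithmetic():
    sp = Spectrum(sizes=np.array([5.0]), n_total=10 ** 6, n_sample=10 ** 3,
                  strategy="region")
    scaled = rescale_spectrum(sp)
    assert scaled.frequencies[0] == pytest.approx(5e-6)
    assert scaled.weight == pytest.approx(1e3)


def test_rescale_random_arithmetic():
    sp = Spectrum(sizes=np.array([2.0]), n_total=10 ** 6, n_sample=10 ** 3,
                  strategy="random")
    scaled = rescale_spectrum(sp)
    assert scaled.sizes[0] == pytest.approx(2000.0)
    assert scaled.frequencies[0] == pytest.approx(2000 / 10 ** 6)
    assert scaled.weight == pytest.approx(1.0)


def test_rescale_whole_population_is_identity():
    sp = Spectrum(sizes=np.array([3.0, 7.0]), n_total=100, n_sample=100,
                  strategy="region")
    scaled = rescale_spectrum(sp)
    np.testing.assert_array_equal(scaled.sizes, sp.sizes)
    assert scaled.weight == 1.0


def test_rescale_roundtrip():
    for strategy, n_sample in [("region", 50), ("random", 50)]:
        sp = Spectrum(sizes=np.array([1.0, 2.0, 4.0]), n_total=1000,
                      n_sample=n_sample, strategy=strategy)
        back = unrescale_spectrum(rescale_spectrum(sp))
        np.testing.assert_allclose(back.sizes, sp.sizes)
        assert back.weight == pytest.approx(sp.weight)


# ---------------------------------------------------------------------------
# reconstruction
# ---------------------------------------------------------------------------

def test_reconstruct_single_spectrum_identity():
    sp = rescale_spectrum(Spectrum(sizes=np.array([1.0, 2.0, 8.0]),
                                   n_total=100, strategy="whole"))
    merged = reconstruct_full_spectrum([sp])
    got = merged.cumulative_count_at_freq(np.array([0.01, 0.02, 0.08]))
    np.testing.assert_allclose(got, [3, 2, 1])


def test_reconstruct_orders_and_checks_compatibility():
    a = rescale_spectrum(Spectrum(sizes=np.array([1.0, 2.0]), n_total=1000,
                                  n_sample=100, strategy="region"))
    b = rescale_spectrum(Spectrum(sizes=np.array([5.0]), n_total=1000,
                                  n_sample=500, strategy="random"))
    merged = reconstruct_full_spectrum([a, b])
    f = merged.curve["frequency"].to_numpy()
    assert np.all(np.diff(f) >= 0)
    with pytest.raises(ValueError, match="n_total"):
        reconstruct_full_spectrum([
            a, Spectrum(sizes=np.array([2.0]), n_total=99, strategy="whole"),
        ])


def test_sampling_never_invents_labels(small_run, tmp_path):
    path = tmp_path / "snap.tsv"
    write_snapshot(small_run, small_run.config, path)
    snap = pd.read_csv(path, sep="\t")
    true_counts = snap[snap["clone_label"] != "unlabeled"][
        "clone_label"].value_counts()
    sub, n = draw_sample(snap, SampleRegion("random", fraction=0.3, seed=9))
    sub_counts = sub[sub["clone_label"] != "unlabeled"][
        "clone_label"].value_counts()
    for lab, cnt in sub_counts.items():
        assert lab in true_counts.index
        assert cnt <= true_counts[lab]


def test_deep_region_contiguity_audit(small_run, tmp_path):
    """Clones fully inside a deep-bulk region are recovered at full size."""
    path = tmp_path / "snap.tsv"
    write_snapshot(small_run, small_run.config, path)
    snap = pd.read_csv(path, sep="\t")
    lam = small_run.config.lambda_depth
    region = SampleRegion("region", depth_range=(lam, 1e9))
    sub, _ = draw_sample(snap, region)
    in_region = set(sub["cell_id"])
    labelled = snap[snap["clone_label"] != "unlabeled"]
    ok = total = 0
    for lab, grp in labelled.groupby("clone_label"):
        if set(grp["cell_id"]) <= in_region:
            total += 1
            nsub = (sub["clone_label"] == lab).sum()
            ok += int(nsub == len(grp))
    assert total >= 5
    assert ok / total >= 0.9


# ---------------------------------------------------------------------------
# mutation-rate estimation
# ---------------------------------------------------------------------------

def test_mutation_rate_recovery_from_deterministic_ld():
    mu, reps = 1e-3, 30
    cfg = LDConfig(n_initial=16, n_final=2 ** 20, mu=mu,
                   mode="deterministic", seed=11)
    sizes = np.concatenate(simulate_luria_delbruck_replicates(cfg, reps))
    sp = Spectrum(sizes=sizes, n_total=cfg.realized_n_final * reps,
                  strategy="whole")
    mu_hat, stderr = estimate_mutation_rate(
        sp, model="well-mixed", fit_range=(8, 2 ** 14))
    assert mu_hat == pytest.approx(mu, rel=0.05)
    assert stderr < mu_hat


def test_mutation_rate_empty_range_errors():
    sp = Spectrum(sizes=np.array([1.0, 1.0]), n_total=100, strategy="whole")
    with pytest.raises(ValueError):
        estimate_mutation_rate(sp, model="crowding", fit_range=(5, 50))
    with pytest.raises(ValueError):
        estimate_mutation_rate(sp, model="banana")
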