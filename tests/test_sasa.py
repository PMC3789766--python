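"""Shrake-Rupley SASA, dSASA series, event segmentation, site calling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ligandcloud.errors import ConfigurationError
from ligandcloud.sasa import (
    DeltaSasaSeries,
    SasaParams,
    binding_percentage,
    call_sites,
    delta_sasa,
    segment_events,
    shrake_rupley_sasa,
    sphere_points,
)

from conftest import bead_topology, make_trajectory


def mc_sasa_oracle(coords, radii, probe=1.4, n_points=200_000, seed=0):
    """Dense Monte-Carlo surface sampling, independent of the spiral grid."""
    rng = np.random.default_rng(seed)
    expanded = radii + probe
    areas = np.empty(len(coords))
    for k, (c, r) in enumerate(zip(coords, expanded)):
        pts = rng.normal(size=(n_points, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        test = c + r * pts
        exposed = np.ones(n_points, dtype=bool)
        for j, (cj, rj) in enumerate(zip(coords, expanded)):
            if j == k:
                continue
            exposed &= np.sum((test - cj) ** 2, axis=1) >= rj * rj
        areas[k] = 4 * np.pi * r * r * exposed.mean()
    return areas


def test_isolated_sphere_closed_form():
    area = shrake_rupley_sasa(np.zeros((1, 3)), np.array([1.9]))
    assert area[0] == pytest.approx(4 * np.pi * 3.3 ** 2, rel=1e-12)


def test_two_distant_atoms_unoccluded():
    coords = np.array([[0.0, 0.0, 0.0], [100.0, 0.0, 0.0]])
    areas = shrake_rupley_sasa(coords, np.array([1.9, 1.9]))
    assert np.allclose(areas, 4 * np.pi * 3.3 ** 2)


def test_cluster_agrees_with_monte_carlo_oracle():
    coords = np.array([[0.0, 0.0, 0.0], [3.0, 0.5, 0.0], [1.5, 2.5, 1.0]])
    radii = np.array([1.9, 1.7, 1.5])
    ours = shrake_rupley_sasa(coords, radii, params=SasaParams(n_sphere_points=2048))
    oracle = mc_sasa_oracle(coords, radii)
    assert np.all(np.abs(ours - oracle) / oracle < 0.01)


def test_sasa_monotone_under_added_occluder():
    rng = np.random.default_rng(3)
    coords = rng.uniform(0, 6, size=(6, 3))
    radii = np.full(6, 1.8)
    small = shrake_rupley_sasa(coords, radii, subset=np.arange(5))
    big = shrake_rupley_sasa(coords, radii, subset=np.arange(6))
    assert np.all(big[:5] <= small + 1e-9)


def test_sasa_converges_with_point_count():
    rng = np.random.default_rng(7)
    coords = rng.uniform(0, 8, size=(10, 3))
    radii = rng.uniform(1.4, 2.0, size=10)
    a1 = shrake_rupley_sasa(coords, radii, params=SasaParams(n_sphere_points=1024))
    a2 = shrake_rupley_sasa(coords, radii, params=SasaParams(n_sphere_points=2048))
    scale = 4 * np.pi * (radii + 1.4) ** 2
    assert np.all(np.abs(a1 - a2) / scale < 0.02)


def test_sphere_points_are_unit_and_spread():
    pts = sphere_points(256)
    assert np.allclose(np.linalg.norm(pts, axis=1), 1.0)
    assert np.linalg.norm(pts.mean(axis=0)) < 0.02


def test_params_validation():
    with pytest.raises(ValueError):
        SasaParams(n_sphere_points=8)
    with pytest.raises(ValueError):
        SasaParams(probe_radius=-1.0)


# ---------------------------------------------------------------------------
# dSASA
# ---------------------------------------------------------------------------

def _two_bead_traj(lig_pos):
    topo = bead_topology(3) + bead_topology(1, role="ligand", start=4)
    coords = np.array([[0.0, 0.0, 0.0], [10.0, 0.0, 0.0], [20.0, 0.0, 0.0],
                       list(lig_pos)])
    return make_trajectory([coords], topo)


def test_distant_ligand_gives_zero_dsasa():
    traj = _two_bead_traj((100.0, 0.0, 0.0))
    series = delta_sasa(traj)
    assert np.all(series.values == 0.0)


def test_adjacent_ligand_buries_only_its_residue():
    traj = _two_bead_traj((0.0, 3.0, 0.0))       # touching residue 1 only
    series = delta_sasa(traj)
    vals = series.values[0]
    assert vals[0] > 0.0
    assert vals[1] == 0.0 and vals[2] == 0.0
    # cross-check the buried area against the Monte-Carlo oracle
    coords = traj.frames[0].coordinates
    radii = traj.radii()
    apo = mc_sasa_oracle(coords[:3], radii[:3])
    holo = mc_sasa_oracle(coords, radii)
    assert vals[0] == pytest.approx(apo[0] - holo[0], rel=0.02)


def test_dsasa_requires_ligand():
    traj = make_trajectory([np.zeros((3, 3)) + np.arange(3)[:, None] * 10],
                           bead_topology(3))
    with pytest.raises(ConfigurationError):
        delta_sasa(traj)


def test_dsasa_nonnegative_on_simulation(sticky_site_run):
    _, _, traj = sticky_site_run
    sub = make_trajectory([traj.frames[i].coordinates for i in range(0, 100, 10)],
                          traj.topology)
    series = delta_sasa(sub)
    assert np.all(series.values >= 0.0)


# ---------------------------------------------------------------------------
# Event segmentation and percentages
# ---------------------------------------------------------------------------

def _series(mask_matrix, spacing=20.0):
    """Boolean mask -> DeltaSasaSeries with values 20 (above) or 0."""
    mask = np.asarray(mask_matrix, dtype=bool)
    values = np.where(mask, 20.0, 0.0)
    n_frames, n_res = values.shape
    return DeltaSasaSeries(values, np.arange(1, n_res + 1),
                           np.arange(n_frames) * spacing, spacing)


def test_long_run_retained_short_run_discarded():
    series = _series(np.ones((1000, 1)))
    events = segment_events(series)              # 1000 * 20 ps = 20 ns
    assert len(events) == 1 and events[0].duration == pytest.approx(20.0)

    series = _series(np.ones((400, 1)))          # 8 ns: under the 10 ns floor
    assert segment_events(series) == []


def test_alternating_frames_produce_no_events():
    mask = (np.arange(200) % 2 == 0)[:, None]
    assert segment_events(_series(mask)) == []


def test_min_duration_below_spacing_warns():
    with pytest.warns(UserWarning):
        segment_events(_series(np.ones((5, 1))), min_duration=0.001)


def test_percentage_from_retained_and_discarded_events():
    series = _series(np.ones((1000, 1)))
    events = segment_events(series)
    pct = binding_percentage(events, 1000, series.residue_ids)
    assert pct.loc[1] == pytest.approx(100.0)

    series = _series(np.ones((400, 1)))
    pct = binding_percentage(segment_events(series), 400, series.residue_ids)
    assert pct.loc[1] == 0.0


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.lists(st.booleans(), min_size=1, max_size=120),
       st.integers(min_value=1, max_value=10))
def test_segmentation_equals_mask_oracle(mask, min_frames):
    """Events + percentage equal brute-force run-length filtering."""
    mask = np.array(mask, dtype=bool)
    spacing = 20.0
    min_duration = min_frames * spacing / 1000.0
    series = _series(mask[:, None], spacing)
    events = segment_events(series, min_duration=min_duration)

    # oracle: per-frame boolean with runs < min_frames zeroed
    kept = np.zeros(len(mask), dtype=bool)
    i = 0
    while i < len(mask):
        if mask[i]:
            j = i
            while j < len(mask) and mask[j]:
                j += 1
            if j - i >= min_frames:
                kept[i:j] = True
            i = j
        else:
            i += 1
    pct = binding_percentage(events, len(mask), series.residue_ids)
    assert pct.loc[1] == pytest.approx(100.0 * kept.mean())
    assert sum(e.n_frames for e in events) == kept.sum()


# ---------------------------------------------------------------------------
# Site calling
# ---------------------------------------------------------------------------

def test_call_sites_rules():
    assert call_sites({r: 0.0 for r in range(1, 20)}) == []

    pct = {5: 40.0, 6: 35.0, 7: 50.0, 12: 20.0}
    sites = call_sites(pct, min_pct=15.0, max_gap=1)
    assert [(s.start, s.end) for s in sites] == [(5, 7), (12, 12)]
    assert sites[0].rank == 1 and sites[0].mean_percentage > sites[1].mean_percentage

    # max_gap 0 splits a range broken by one sub-threshold residue
    pct = {5: 40.0, 6: 5.0, 7: 50.0}
    sites = call_sites(pct, min_pct=15.0, max_gap=0)
    assert [(s.start, s.end) for s in sites] == [(7, 7), (5, 5)]
    sites = call_sites(pct, min_pct=15.0, max_gap=1)
    assert [(s.start, s.end) for s in sites] == [(5, 7)]
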