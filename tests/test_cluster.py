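"""Kabsch superposition, pairwise RMSD, Daura clustering, ligand clouds."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ligandcloud.cluster import (
    cluster_population_report,
    daura_cluster,
    kabsch_superpose,
    ligand_cloud,
    pairwise_rmsd_matrix,
)
from ligandcloud.errors import ConfigurationError, DegenerateGeometryError
from ligandcloud.synth import ConformerMixtureSpec, sample_conformer_mixture

from conftest import bead_topology, make_trajectory


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def quaternion_rmsd_oracle(x, y):
    """Independent quaternion-eigenvalue formulation of optimal RMSD."""
    x = x - x.mean(axis=0)
    y = y - y.mean(axis=0)
    m = x.T @ y
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = np.linalg.eigvalsh(k)[-1]
    msd = (np.sum(x ** 2) + np.sum(y ** 2) - 2 * lam) / len(x)
    return np.sqrt(max(msd, 0.0))


# ---------------------------------------------------------------------------
# Kabsch
# ---------------------------------------------------------------------------

def test_rigid_motion_gives_zero_rmsd():
    rng = np.random.default_rng(0)
    x = rng.normal(size=(12, 3))
    y = x @ random_rotation(rng).T + np.array([5.0, -3.0, 2.0])
    res = kabsch_superpose(x, y)
    assert res.rmsd < 1e-8
    assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)
    assert np.allclose(res.apply(x), y, atol=1e-8)


def test_mirror_image_keeps_proper_rotation():
    rng = np.random.default_rng(1)
    x = rng.normal(size=(10, 3))
    y = x.copy()
    y[:, 0] *= -1.0                      # reflection
    res = kabsch_superpose(x, y)
    assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)
    assert res.rmsd > 0.1


def test_rmsd_matches_quaternion_oracle():
    rng = np.random.default_rng(2)
    for _ in range(5):
        x = rng.normal(size=(10, 3))
        y = rng.normal(size=(10, 3))
        assert kabsch_superpose(x, y).rmsd == pytest.approx(
            quaternion_rmsd_oracle(x, y), abs=1e-8)


def test_degenerate_subsets_rejected():
    line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
    with pytest.raises(DegenerateGeometryError):
        kabsch_superpose(line, line)
    with pytest.raises(DegenerateGeometryError):
        kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


# ---------------------------------------------------------------------------
# Pairwise matrix
# ---------------------------------------------------------------------------

def _mixture_traj(n_frames=40, seed=3, weights=(0.6, 0.4), noise=0.5, gap=20.0):
    rng = np.random.default_rng(seed)
    t1 = rng.normal(size=(10, 3)) * 3.0
    t2 = t1 + np.array([gap, 0.0, 0.0]) * 0  # same centroid, reshaped below
    t2 = rng.normal(size=(10, 3)) * 3.0 + np.array([0.0, 0.0, gap])
    spec = ConformerMixtureSpec([t1, t2], list(weights), noise_sigma=noise, seed=seed)
    return sample_conformer_mixture(spec, n_frames)


def test_identical_frames_zero_matrix():
    coords = np.random.default_rng(4).normal(size=(6, 3))
    traj = make_trajectory([coords, coords, coords], bead_topology(6))
    m = pairwise_rmsd_matrix(traj)
    assert np.allclose(m, 0.0, atol=1e-8)


def test_matrix_matches_elementwise_kabsch():
    traj = _mixture_traj(n_frames=5)
    m = pairwise_rmsd_matrix(traj)
    assert np.allclose(m, m.T, atol=1e-9)
    coords = traj.coords()
    for i in range(5):
        for j in range(5):
            expected = 0.0 if i == j else kabsch_superpose(coords[i], coords[j]).rmsd
            assert m[i, j] == pytest.approx(expected, abs=1e-8)


def test_matrix_invariant_under_rigid_motion():
    traj = _mixture_traj(n_frames=8)
    m1 = pairwise_rmsd_matrix(traj)
    rng = np.random.default_rng(5)
    rot = random_rotation(rng)
    moved = [fr.coordinates @ rot.T + np.array([10.0, -4.0, 7.0])
             for fr in traj.frames]
    traj2 = make_trajectory(moved, traj.topology)
    m2 = pairwise_rmsd_matrix(traj2)
    assert np.allclose(m1, m2, atol=1e-8)


# ---------------------------------------------------------------------------
# Daura clustering
# ---------------------------------------------------------------------------

def daura_oracle(rmsd, cutoff):
    """Exhaustive re-scan greedy clustering, recomputed from scratch."""
    n = len(rmsd)
    remaining = set(range(n))
    assignment = [-1] * n
    reps = []
    cid = 0
    while remaining:
        best, best_nb = None, None
        for i in sorted(remaining):
            nb = {j for j in remaining if rmsd[i][j] <= cutoff}
            if best_nb is None or len(nb) > len(best_nb):
                best, best_nb = i, nb
        for j in best_nb:
            assignment[j] = cid
        remaining -= best_nb
        reps.append(best)
        cid += 1
    return assignment, reps


def test_all_zero_rmsd_single_cluster():
    cs = daura_cluster(np.zeros((7, 7)))
    assert cs.n_clusters == 1
    assert cs.populations[0] == pytest.approx(1.0)
    assert cs.representatives[0] == 0


def test_empty_matrix_rejected():
    with pytest.raises(ValueError):
        daura_cluster(np.empty((0, 0)))


def test_two_template_populations_recovered():
    traj = _mixture_traj(n_frames=1000, noise=0.5)
    m = pairwise_rmsd_matrix(traj)
    cs = daura_cluster(m, cutoff=2.0)
    assert cs.n_clusters == 2
    assert abs(cs.populations[0] - 0.6) < 0.03
    assert abs(cs.populations[1] - 0.4) < 0.03


@settings(deadline=None, derandomize=True, max_examples=40)
@given(st.integers(min_value=2, max_value=25), st.integers(min_value=0, max_value=10_000))
def test_daura_matches_exhaustive_oracle(n, seed):
    rng = np.random.default_rng(seed)
    d = rng.uniform(0, 4, size=(n, n))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    cs = daura_cluster(d, cutoff=2.0)
    assignment, reps = daura_oracle(d.tolist(), 2.0)
    assert list(cs.assignment) == assignment
    assert list(cs.representatives) == reps
    sizes = np.bincount(cs.assignment)
    assert np.all(np.diff(sizes[np.argsort(-sizes)]) <= 0)
    assert cs.populations.sum() == pytest.approx(1.0, abs=1e-9)


# ---------------------------------------------------------------------------
# Ligand clouds
# ---------------------------------------------------------------------------

def _traj_with_ligand():
    rng = np.random.default_rng(6)
    pep = rng.normal(size=(8, 3)) * 3.0
    topo = bead_topology(8) + bead_topology(2, role="ligand", start=9)
    frames = []
    for k in range(6):
        lig = np.array([[10.0 + k, 0.0, 0.0], [12.0 + k, 0.0, 0.0]])
        frames.append(np.vstack([pep, lig]))
    return make_trajectory(frames, topo)


def test_cloud_point_is_ligand_center_of_mass():
    traj = _traj_with_ligand()
    m = pairwise_rmsd_matrix(traj)
    cs = daura_cluster(m, cutoff=2.0)
    cloud = ligand_cloud(traj, cs)
    assert cs.n_clusters == 1
    pts = cloud.points[0]
    assert len(pts) == traj.n_frames           # one point per member frame
    # peptide is identical in every frame, so the transform is identity and
    # the cloud point is the mid-point of the two equal-mass beads
    assert np.allclose(pts[0], [11.0, 0.0, 0.0], atol=1e-8)
    assert np.allclose(pts[-1], [16.0, 0.0, 0.0], atol=1e-8)


def test_cloud_requires_ligand():
    traj = make_trajectory([np.random.default_rng(7).normal(size=(5, 3))] * 2,
                           bead_topology(5))
    m = pairwise_rmsd_matrix(traj)
    with pytest.raises(ConfigurationError):
        ligand_cloud(traj, daura_cluster(m))


# ---------------------------------------------------------------------------
# Population report
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("pops,expected", [
    ([14.3, 13.9, 13.7, 10.4, 7.5, 6.9, 5.4, 5.2], 77),   # bound ensemble
    ([10.5, 8.6, 7.8, 6.4, 6.1, 4.5, 3.5, 3.0], 50),      # free ensemble
])
def test_cumulative_top8_population(pops, expected):
    table, cumulative = cluster_population_report(pops, top_k=8)
    assert cumulative == expected
    assert list(table["population_pct"]) == sorted(pops, reverse=True)


def test_single_cluster_reports_100():
    _, cumulative = cluster_population_report([1.0], top_k=8)
    assert cumulative == 100


def test_holo_ensemble_clusters_tighter_than_apo():
    """Ligand-stabilised (lower-noise) ensembles concentrate population."""
    rng = np.random.default_rng(11)
    templates = [rng.normal(size=(10, 3)) * 4.0 + np.array([0, 0, 30.0 * k])
                 for k in range(12)]
    apo_w = np.full(12, 1 / 12)
    holo_w = np.array([0.3, 0.2, 0.15, 0.1, 0.08, 0.05, 0.04, 0.03,
                       0.02, 0.015, 0.01, 0.005])
    holo_w /= holo_w.sum()
    out = {}
    for name, w in (("apo", apo_w), ("holo", holo_w)):
        spec = ConformerMixtureSpec(templates, w, noise_sigma=0.4, seed=13)
        traj = sample_conformer_mixture(spec, 400)
        cs = daura_cluster(pairwise_rmsd_matrix(traj), cutoff=2.0)
        _, out[name] = cluster_population_report(cs, top_k=8)
    assert out["holo"] > out["apo"]
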