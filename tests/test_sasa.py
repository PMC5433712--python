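"""Shrake-Rupley correctness: analytic spheres, invariances, oracles."""

import numpy as np
import pytest

from haloadapt.sasa import compute_sasa, reference_areas, sphere_points, surface_composition
from haloadapt.structure_io import annotate, flatten
from haloadapt.synth import gen_scatter_structure
from tests.conftest import carbon_structure

R_EXP = 1.70 + 1.4  # expanded radius of a carbon atom at water probe
SPHERE = 4 * np.pi * R_EXP ** 2


def two_sphere_analytic(d: float) -> float:
    """Total exposed area of two equal spheres of radius R_EXP at distance d."""
    if d >= 2 * R_EXP:
        return 2 * SPHERE
    h = R_EXP - d / 2
    return 2 * (SPHERE - 2 * np.pi * R_EXP * h)


def test_sphere_points_basics():
    one = sphere_points(1)
    assert one.shape == (1, 3)
    for n in (1, 100, 960):
        pts = sphere_points(n)
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)
    assert np.linalg.norm(sphere_points(100).mean(axis=0)) < 0.05


def test_single_sphere_within_one_percent():
    res = compute_sasa(carbon_structure([(0, 0, 0)]))
    assert abs(res.total - SPHERE) / SPHERE < 0.01


def test_two_spheres_analytic_within_two_percent():
    for d in (2.0, 3.1, 4.5, 6.0):
        res = compute_sasa(carbon_structure([(0, 0, 0), (d, 0, 0)]))
        exact = two_sphere_analytic(d)
        assert abs(res.total - exact) / exact < 0.02, f"d={d}"


def test_disjoint_spheres_additive():
    res = compute_sasa(carbon_structure([(0, 0, 0), (100, 0, 0)]))
    assert res.total == pytest.approx(2 * SPHERE, rel=1e-9)


def test_translation_invariance_exact(rng):
    pos = rng.uniform(0, 8, size=(6, 3))
    base = compute_sasa(carbon_structure(pos)).total
    moved = pos + np.array([123.0, -45.0, 67.0])
    assert compute_sasa(carbon_structure(moved)).total == pytest.approx(base, rel=1e-6)


def test_rotation_invariance_within_quadrature_error(rng):
    # the sphere point set is fixed in space, so rotating the molecule
    # re-samples the occlusion pattern: totals agree to quadrature accuracy,
    # not exactly
    pos = rng.uniform(0, 8, size=(6, 3))
    base = compute_sasa(carbon_structure(pos)).total
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    moved = pos @ q.T
    assert compute_sasa(carbon_structure(moved)).total == pytest.approx(base, rel=0.01)


def test_burying_monotonicity(rng):
    """Adding an atom never increases any existing atom's exposed area."""
    pos = rng.uniform(0, 6, size=(5, 3))
    before = compute_sasa(carbon_structure(pos)).per_atom
    added = np.vstack([pos, rng.uniform(0, 6, size=(1, 3))])
    after = compute_sasa(carbon_structure(added)).per_atom[:5]
    assert np.all(after <= before + 1e-9)


def _monte_carlo_area(positions, n_samples, seed):
    """Independent oracle: rejection sampling of points on expanded spheres."""
    rng = np.random.default_rng(seed)
    positions = np.asarray(positions, dtype=float)
    total = 0.0
    for i, center in enumerate(positions):
        v = rng.normal(size=(n_samples, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        pts = center + R_EXP * v
        inside = np.zeros(n_samples, dtype=bool)
        for j, other in enumerate(positions):
            if j == i:
                continue
            inside |= np.linalg.norm(pts - other, axis=1) < R_EXP
        total += (~inside).mean() * SPHERE
    return total


def test_monte_carlo_oracle_on_random_clusters(rng):
    for trial in range(10):
        pos = rng.uniform(0, 6, size=(5, 3))
        ours = compute_sasa(carbon_structure(pos)).total
        mc = _monte_carlo_area(pos, 40_000, seed=trial)
        assert abs(ours - mc) / mc < 0.02


def test_against_biotite_shrake_rupley(rng):
    """Cross-check against an independent implementation on a random cluster."""
    import biotite.structure as bst

    pos = rng.uniform(0, 10, size=(8, 3))
    arr = bst.AtomArray(len(pos))
    arr.coord = pos.astype(np.float32)
    arr.element = np.array(["C"] * len(pos))
    arr.atom_name = np.array(["CB"] * len(pos))
    arr.res_name = np.array(["ALA"] * len(pos))
    arr.res_id = np.arange(1, len(pos) + 1)
    arr.chain_id = np.array(["A"] * len(pos))
    ref = bst.sasa(arr, probe_radius=1.4, point_number=960,
                   vdw_radii="Single").sum()
    ours = compute_sasa(carbon_structure(pos)).total
    assert abs(ours - ref) / ref < 0.02


def test_surface_composition_partition_and_planted_split():
    s, truth = gen_scatter_structure({"A": 3, "D": 7}, seed=0)
    annotate(s)
    res = compute_sasa(s)
    comp = surface_composition(s, res)
    assert sum(comp.by_bucket.values()) == pytest.approx(100.0, abs=0.01)
    # 3 of 10 equal-area residues are hydrophobic-set (Ala): 30/70 split
    assert comp.by_bucket["hydrophobic"] == pytest.approx(30.0, abs=0.1)
    assert comp.by_bucket["D"] == pytest.approx(70.0, abs=0.1)
    # generator's analytic per-residue areas match the computed ones
    for key, area in res.per_residue.items():
        assert area == pytest.approx(truth["sphere_area"], rel=0.01)


def test_lysine_only_structure_is_all_K():
    s, _ = gen_scatter_structure({"K": 4}, seed=1)
    annotate(s)
    comp = surface_composition(s, compute_sasa(s))
    assert comp.by_bucket["K"] == pytest.approx(100.0, abs=1e-9)


def test_zero_area_raises():
    s, _ = gen_scatter_structure({"A": 1}, seed=0)
    annotate(s)
    res = compute_sasa(s)
    res.total = 0.0
    with pytest.raises(ValueError):
        surface_composition(s, res)


def test_reference_areas_cover_standard_residues():
    ref = reference_areas()
    assert len(ref) == 20
    assert all(v > 0 for v in ref.values())
    # tryptophan exposes more surface than glycine in an extended tripeptide
    assert ref["TRP"] > ref["GLY"]
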