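import numpy as np
import pytest

from porescan.geometry import RigidTransform, rotation_about_axis
from porescan.labeling import assign_labels, resolve
from porescan.superposition import (
    ChiralityError,
    SuperpositionError,
    default_fit_labels,
    kabsch,
    orient_template,
    rmsd_by_segment,
    superpose,
)
from porescan.synthetic import PoreSpec, build_pore


def rotation_grid_oracle(P, Q, step_deg=10.0):
    """Brute-force oracle: best RMSD over a rotation grid x centroid match."""
    P = P - P.mean(axis=0)
    Q0 = Q - Q.mean(axis=0)
    best = np.inf
    angles = np.deg2rad(np.arange(0.0, 360.0, step_deg))
    for a in angles:
        Ra = rotation_about_axis([1, 0, 0], np.degrees(a))
        for b in angles:
            Rb = rotation_about_axis([0, 1, 0], np.degrees(b))
            for c in angles:
                Rc = rotation_about_axis([0, 0, 1], np.degrees(c))
                R = Rc @ Rb @ Ra
                rmsd = np.sqrt(np.mean(np.sum((P @ R.T - Q0) ** 2, axis=1)))
                best = min(best, rmsd)
    return best


def test_kabsch_beats_rotation_grid_oracle():
    rng = np.random.default_rng(11)
    for _ in range(3):
        P = rng.normal(size=(8, 3)) * 3.0
        R = rotation_about_axis(rng.normal(size=3), rng.uniform(0, 360))
        Q = P @ R.T + rng.normal(size=(8, 3)) * 0.4 + [2.0, -1.0, 3.0]
        _, rmsd = kabsch(P, Q)
        oracle = rotation_grid_oracle(P, Q, step_deg=10.0)
        assert rmsd <= oracle + 1e-3


def test_kabsch_recovers_exact_rigid_motion():
    rng = np.random.default_rng(5)
    P = rng.normal(size=(12, 3)) * 4.0
    true = RigidTransform(rotation_about_axis([1, 0, 0], 90.0), np.array([5.0, 5.0, 5.0]))
    Q = true.apply(P)
    tr, rmsd = kabsch(P, Q)
    assert rmsd < 1e-10
    assert np.allclose(tr.rotation, true.rotation, atol=1e-10)
    assert np.allclose(tr.translation, true.translation, atol=1e-10)


def test_kabsch_rejects_mirrored_points():
    rng = np.random.default_rng(7)
    P = rng.normal(size=(10, 3)) * 3.0
    Q = P.copy()
    Q[:, 0] *= -1.0  # reflection
    with pytest.raises(ChiralityError):
        kabsch(P, Q)


def test_kabsch_needs_three_atoms():
    with pytest.raises(SuperpositionError):
        kabsch(np.zeros((2, 3)), np.ones((2, 3)))


def test_orient_template_conventions(fresh_alpha_labeled):
    ls, _ = fresh_alpha_labeled
    ls, _ = orient_template(ls)
    # pore axis is z: filter-region quadruple centroids sit on x=y=0
    anchor3 = resolve(ls, "3p52", "CA").xyz
    assert abs(anchor3[1]) < 1e-6  # repeat-III tyrosine in xOz plane
    assert anchor3[0] > 0
    # +z extracellular: filter above the inner-helix bundle
    inner_z = np.mean([resolve(ls, f"{r}i30", "CA").xyz[2] for r in (1, 2, 3, 4)])
    assert anchor3[2] > inner_z


def test_orient_template_is_idempotent(fresh_alpha_labeled):
    ls, _ = fresh_alpha_labeled
    orient_template(ls)
    _, second = orient_template(ls)
    assert np.abs(second.rotation - np.eye(3)).max() < 1e-6
    assert np.abs(second.translation).max() < 1e-6


def test_superpose_identity_gives_zero_rmsd(oriented_template, fresh_alpha_labeled):
    ls, _ = fresh_alpha_labeled
    res = superpose(ls, oriented_template)
    assert res.fit_rmsd < 1e-9
    assert res.n_atoms_used == 40  # p38-p47 x 4 repeats


def test_superpose_frame_independence(oriented_template):
    """fit_rmsd does not depend on the query's starting pose."""
    rmsds = []
    rng = np.random.default_rng(3)
    for _ in range(3):
        pore, truth = build_pore(PoreSpec())
        ls = assign_labels(pore, truth.segment_map)
        t = RigidTransform(
            rotation_about_axis(rng.normal(size=3), rng.uniform(0, 360)),
            rng.normal(size=3) * 10,
        )
        ls.structure.transform(t)
        rmsds.append(superpose(ls, oriented_template).fit_rmsd)
    assert np.ptp(rmsds) < 1e-6


def test_superpose_noisy_rmsd_matches_expectation(oriented_template):
    """Gaussian Cα noise (σ per coordinate) leaves a fit RMSD near √3·σ."""
    sigma = 0.5
    rng = np.random.default_rng(42)
    rmsds = []
    for _ in range(5):
        pore, truth = build_pore(PoreSpec())
        ls = assign_labels(pore, truth.segment_map)
        for lab in default_fit_labels():
            res = ls.residue_of.get(lab)
            if res is not None:
                res.atoms["CA"].xyz = res.atoms["CA"].xyz + rng.normal(0, sigma, 3)
        rmsds.append(superpose(ls, oriented_template).fit_rmsd)
    expected = np.sqrt(3) * sigma
    mean = float(np.mean(rmsds))
    assert 0.6 * expected < mean < 1.05 * expected  # least-squares shrinkage < ideal


def test_rmsd_by_segment_consistency(oriented_template, fresh_alpha_labeled):
    ls, _ = fresh_alpha_labeled
    res = superpose(ls, oriented_template)
    seg = rmsd_by_segment(ls, oriented_template, default_fit_labels())
    assert abs(seg - res.fit_rmsd) < 1e-9


def test_translated_helix_rmsd_is_exact_offset(oriented_template):
    pore, truth = build_pore(PoreSpec())
    ls = assign_labels(pore, truth.segment_map)
    superpose(ls, oriented_template)
    # translate repeat-2 inner helix by 2 Å along x, no refit
    for lab, res in ls.residue_of.items():
        if lab.repeat == 2 and lab.segment == "i":
            for a in res.atoms.values():
                a.xyz = a.xyz + np.array([2.0, 0.0, 0.0])
    labels = [f"2i{k}" for k in range(1, 36)]
    assert abs(rmsd_by_segment(ls, oriented_template, labels) - 2.0) < 1e-9


def test_gate_perturbation_inflates_inner_not_p1_rmsd(oriented_template):
    """Moving gate-region residues leaves the P1 fit untouched."""
    pore, truth = build_pore(PoreSpec())
    ls = assign_labels(pore, truth.segment_map)
    rng = np.random.default_rng(0)
    for lab, res in ls.residue_of.items():
        if lab.segment == "i" and lab.index >= 25:
            for a in res.atoms.values():
                a.xyz = a.xyz + rng.normal(0, 2.0, 3)
    res = superpose(ls, oriented_template)
    inner_c = np.mean(
        [res.per_segment_rmsd[f"{r}i"] for r in (1, 2, 3, 4)]
    )
    assert res.fit_rmsd < 0.5
    assert inner_c > 2 * res.fit_rmsd


def test_superpose_c4_symmetry_of_pore(oriented_template):
    pore, truth = build_pore(PoreSpec())
    ls = assign_labels(pore, truth.segment_map)
    rot = RigidTransform(rotation_about_axis([0, 0, 1], 90.0), np.zeros(3))
    ls.structure.transform(rot)
    res = superpose(ls, oriented_template)
    # the same labels pair with different (rotated) coordinates, yet the
    # optimal fit recovers the 90-degree rotation exactly
    assert res.fit_rmsd < 1e-6
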