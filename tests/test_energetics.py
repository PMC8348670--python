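import numpy as np
import pytest

from porescan.energetics import (
    COULOMB_K,
    ChargeTable,
    ChargedAtomSet,
    EnergeticsError,
    NonbondedParams,
    PinRestraint,
    assign_charges,
    pair_energy,
    partition_by_residue,
    pin_energy,
    refine_pose,
)
from porescan.labeling import assign_labels
from porescan.superposition import orient_template
from porescan.synthetic import IonSpec, LigandSpec, PoreSpec, build_pore

POINT = NonbondedParams(rstar={"Q": 1.0}, eps={"Q": 0.0})


def charges_at(positions, qs):
    return ChargedAtomSet(np.atleast_2d(np.array(positions, float)),
                          ["Q"] * len(qs), np.array(qs, float))


def test_coulomb_closed_form_at_3p32_angstrom():
    a = charges_at([[0, 0, 0]], [1.0])
    b = charges_at([[3.32, 0, 0]], [1.0])
    _, coul = pair_energy(a, b, POINT)
    assert abs(coul - COULOMB_K / (2 * 3.32**2)) < 1e-12
    assert abs(coul - 15.06) < 0.01  # hand evaluation


def test_coulomb_inverse_square_law():
    a = charges_at([[0, 0, 0]], [1.0])
    for r in (2.0, 4.0, 5.5):
        c1 = pair_energy(a, charges_at([[r, 0, 0]], [1.0]), POINT)[1]
        c2 = pair_energy(a, charges_at([[2 * r, 0, 0]], [1.0]), POINT)[1]
        assert abs(c2 - c1 / 4.0) < 1e-12


def test_vdw_minimum_at_rmin_equals_minus_eps():
    params = NonbondedParams(rstar={"C": 1.908}, eps={"C": 0.086})
    a = ChargedAtomSet(np.array([[0.0, 0.0, 0.0]]), ["C"], np.zeros(1))
    b = ChargedAtomSet(np.array([[2 * 1.908, 0.0, 0.0]]), ["C"], np.zeros(1))
    vdw, _ = pair_energy(a, b, params)
    assert abs(vdw + 0.086) < 1e-12


def test_pair_energy_matches_naive_double_loop():
    rng = np.random.default_rng(9)
    params = NonbondedParams.default()
    elements = ["C", "N", "O", "S"]
    na, nb = 18, 25
    ea = [elements[i % 4] for i in range(na)]
    eb = [elements[(i + 1) % 4] for i in range(nb)]
    A = ChargedAtomSet(rng.uniform(-6, 6, (na, 3)), ea, rng.uniform(-0.5, 0.5, na))
    # keep the sets apart to avoid clashes
    B = ChargedAtomSet(rng.uniform(-6, 6, (nb, 3)) + [15, 0, 0], eb,
                       rng.uniform(-0.5, 0.5, nb))
    vdw, coul = pair_energy(A, B, params, cutoff=12.0)
    # independent brute-force oracle
    ref_vdw = ref_coul = 0.0
    for i in range(na):
        for j in range(nb):
            r = float(np.linalg.norm(A.coords[i] - B.coords[j]))
            if r > 12.0:
                continue
            ri, ei = params.of(A.elements[i])
            rj, ej = params.of(B.elements[j])
            rmin, eps = ri + rj, np.sqrt(ei * ej)
            ref_vdw += eps * ((rmin / r) ** 12 - 2 * (rmin / r) ** 6)
            ref_coul += COULOMB_K * A.charges[i] * B.charges[j] / (2 * r * r)
    assert abs(vdw - ref_vdw) < 1e-9
    assert abs(coul - ref_coul) < 1e-9


def test_clash_below_half_angstrom_is_error():
    a = charges_at([[0, 0, 0]], [1.0])
    b = charges_at([[0.3, 0, 0]], [1.0])
    with pytest.raises(EnergeticsError, match="overlap"):
        pair_energy(a, b, POINT)


def test_charge_table_net_charge_invariant():
    with pytest.raises(EnergeticsError, match="formal charge"):
        ChargeTable(residues={"BAD": {"formal_charge": 1.0, "atoms": {"N1": 0.5}}})
    table = ChargeTable.default()
    assert sum(table.residues["LIG"]["atoms"].values()) == pytest.approx(1.0)


def test_assign_charges_and_fallback(charged_pore_labeled):
    ls, truth = charged_pore_labeled
    table = ChargeTable.default()
    lig = assign_charges(ls.structure.het_residues("LIG"), table)
    assert lig.net_charge == pytest.approx(1.0)
    ions = assign_charges(ls.structure.ion_residues(), table)
    assert ions.net_charge == pytest.approx(2.0)  # two K+
    protein = assign_charges(ls.structure.chain_residues("A"), table)
    assert protein.net_charge == pytest.approx(0.0)  # neutral fallback


def test_missing_charge_entry_is_named_error(charged_pore_labeled):
    ls, _ = charged_pore_labeled
    table = ChargeTable(residues={"LIG": {"formal_charge": 1.0, "atoms": {"XX": 1.0}}})
    with pytest.raises(EnergeticsError, match="N1"):
        assign_charges(ls.structure.het_residues("LIG"), table)


def test_partition_additivity_and_c4_symmetry():
    spec = PoreSpec(ligand=LigandSpec(atoms=[("N1", "N", (0.0, 0.0, -6.0), 1.0)]))
    pore, truth = build_pore(spec)
    ls = assign_labels(pore, truth.segment_map)
    orient_template(ls)
    charges = ChargeTable.default(use_backbone_dipole=True)
    part = partition_by_residue(ls, "LIG", charges=charges)
    assert abs(part.table["total"].sum() - part.grand_total) < 1e-9
    # C4 symmetry: the four copies of each labelled position contribute equally
    for idx in (15, 18):
        rows = part.table[part.table["label"].isin([f"{r}i{idx}" for r in (1, 2, 3, 4)])]
        assert len(rows) == 4
        assert np.ptp(rows["total"].values) < 1e-6
    # attractive-share convention: attractive percents sum to 100
    att = part.table.loc[part.table["total"] < 0, "percent"].sum()
    assert abs(att - 100.0) < 0.1


def test_partition_single_contributor_is_total():
    spec = PoreSpec(
        ligand=LigandSpec(atoms=[("N1", "N", (0.0, 0.0, -4.0), 1.0)]),
        ions=[IonSpec("K", -3.0, "S5", 1.0)],
    )
    pore, truth = build_pore(spec)
    ls = assign_labels(pore, truth.segment_map)
    orient_template(ls)
    # neutral protein (no dipoles): only the ion interacts electrostatically
    charges = ChargeTable.default(use_backbone_dipole=False)
    part = partition_by_residue(ls, "LIG", charges=charges, cutoff=6.0)
    ion_row = part.table[part.table["resname"] == "K"]
    assert len(ion_row) == 1
    assert ion_row["coulomb"].iloc[0] == pytest.approx(part.coulomb_total)
    assert ion_row["coulomb"].iloc[0] > 0  # cation-cation repulsion


def test_pin_flat_bottom_and_worked_values():
    pin = PinRestraint(reference=np.zeros((1, 3)))
    assert pin_energy(np.array([[0.8, 0, 0]]), pin) == 0.0
    assert pin_energy(np.array([[2.0, 0, 0]]), pin) == pytest.approx(10.0)
    # continuity at the boundary
    eps = 1e-7
    assert pin_energy(np.array([[1.0 + eps, 0, 0]]), pin) < 1e-10
    linear = PinRestraint(reference=np.zeros((1, 3)), form="linear")
    assert pin_energy(np.array([[2.0, 0, 0]]), linear) == pytest.approx(10.0)
    assert pin_energy(np.array([[3.0, 0, 0]]), linear) == pytest.approx(20.0)


def test_refine_pose_monotone_and_deterministic(charged_pore_labeled):
    ls, _ = charged_pore_labeled
    charges = ChargeTable.default(use_backbone_dipole=True)
    env = assign_charges(
        [r for r in ls.structure.residues if not r.het], charges
    )
    lig = assign_charges(ls.structure.het_residues("LIG"), charges)
    r1 = refine_pose(lig, env, n_steps=60, seed=12)
    r2 = refine_pose(lig, env, n_steps=60, seed=12)
    assert r1.trace == r2.trace  # determinism
    assert r1.energy <= r1.initial_energy
    assert all(a >= b for a, b in zip(r1.trace, r1.trace[1:]))  # non-increasing


def test_refine_pose_recovers_constructed_minimum():
    """A cation displaced 2 Å from its pinned reference position returns
    to within 0.3 Å of the constructed minimum (the pin basin centre is
    the unique objective minimum when the environment is out of range)."""
    env = ChargedAtomSet(np.array([[100.0, 0.0, 0.0]]), ["O"], np.array([-1.0]))
    target = np.array([[0.0, 0.0, -4.0]])
    lig = ChargedAtomSet(target + np.array([[2.0, 0.0, 0.0]]), ["N"], np.array([1.0]))
    pins = PinRestraint(reference=target, flat_bottom=0.05, coefficient=10.0)
    res = refine_pose(lig, env, pins=pins, n_steps=300, seed=4)
    assert np.linalg.norm(res.coords[0] - target[0]) < 0.3
    assert res.pins_satisfied


def test_refine_pose_at_minimum_keeps_energy():
    """Starting exactly at the objective minimum, refinement changes nothing."""
    env = ChargedAtomSet(np.array([[100.0, 0.0, 0.0]]), ["O"], np.array([-1.0]))
    target = np.array([[0.0, 0.0, 0.0]])
    lig = ChargedAtomSet(target.copy(), ["N"], np.array([1.0]))
    pins = PinRestraint(reference=target, flat_bottom=0.0, coefficient=10.0)
    res = refine_pose(lig, env, pins=pins, n_steps=80, seed=0)
    assert res.initial_energy == pytest.approx(0.0, abs=1e-12)
    assert res.energy == pytest.approx(0.0, abs=1e-12)
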