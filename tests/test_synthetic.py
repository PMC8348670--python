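import json

import numpy as np
import pytest

from porescan.geometry import fit_line
from porescan.labeling import assign_labels, load_segment_map
from porescan.structure_io import read_structure
from porescan.synthetic import (
    ALPHA_PHI_PSI,
    HelixSpec,
    IonSpec,
    LigandSpec,
    PoreSpec,
    build_helix,
    build_pore,
    fixture_suite,
)


def helix_rise_and_turn(st):
    ca = np.array([r.atoms["CA"].xyz for r in st.residues])
    centroid, axis = fit_line(ca)
    proj = (ca - centroid) @ axis
    rise = abs(float(np.mean(np.diff(proj))))
    perp = ca - centroid - np.outer(proj, axis)
    e1 = perp[0] / np.linalg.norm(perp[0])
    e2 = np.cross(axis, e1)
    ang = np.unwrap(np.arctan2(perp @ e2, perp @ e1))
    res_per_turn = 360.0 / abs(float(np.degrees(np.mean(np.diff(ang)))))
    return rise, res_per_turn


def test_alpha_helix_geometry():
    st = build_helix(HelixSpec(sequence="A" * 20))
    rise, turn = helix_rise_and_turn(st)
    assert abs(rise - 1.50) < 0.1
    assert abs(turn - 3.6) < 0.1
    ca = np.array([r.atoms["CA"].xyz for r in st.residues])
    end_to_end = np.linalg.norm(ca[-1] - ca[0])
    assert abs(end_to_end - 19 * 1.5) / (19 * 1.5) < 0.08


def test_pi_stretch_is_more_compressed_than_alpha():
    from porescan.synthetic import PI_PHI_PSI, PI_TAU

    st = build_helix(
        HelixSpec(sequence="A" * 20, phi_psi=[(*PI_PHI_PSI, PI_TAU)] * 20)
    )
    rise, turn = helix_rise_and_turn(st)
    alpha_rise, _ = helix_rise_and_turn(build_helix(HelixSpec(sequence="A" * 20)))
    assert rise < alpha_rise
    assert 1.0 < rise < 1.4
    assert turn > 4.0  # wider than the 3.6-residue alpha turn


def test_single_residue_helix_atom_content():
    st = build_helix(HelixSpec(sequence="A"))
    atoms = st.residues[0].atoms
    assert set(atoms) == {"N", "CA", "C", "O", "CB"}
    gly = build_helix(HelixSpec(sequence="G"))
    assert set(gly.residues[0].atoms) == {"N", "CA", "C", "O"}


def test_self_clashing_dihedrals_rejected():
    with pytest.raises(ValueError, match="self-clash"):
        build_helix(HelixSpec(sequence="A" * 12, phi_psi=[(0.0, 0.0)] * 12))


def test_bulge_outside_sequence_rejected():
    with pytest.raises(ValueError, match="outside"):
        build_helix(HelixSpec(sequence="A" * 10, bulge_position=10))


def test_pore_c4_symmetry_before_noise(alpha_pore):
    pore, _ = alpha_pore
    from porescan.geometry import rotation_about_axis

    rot = rotation_about_axis([0, 0, 1], -90.0)
    coords = {}
    for r in pore.residues:
        coords[(r.chain, r.seqid)] = r.atoms["CA"].xyz
    chains = "ABCD"
    for (chain, seqid), xyz in coords.items():
        nxt = chains[(chains.index(chain) + 1) % 4]
        assert np.allclose(rot @ xyz, coords[(nxt, seqid)], atol=1e-9)


def test_ground_truth_records_bulge(alpha_pore):
    _, truth = alpha_pore
    assert truth.bulges == {}
    inner = [HelixSpec(), HelixSpec(bulge_position=15), HelixSpec(), HelixSpec()]
    _, t2 = build_pore(PoreSpec(inner=inner))
    assert t2.bulges == {"2i": 15}


def test_noise_requires_seed():
    with pytest.raises(ValueError, match="seed"):
        build_pore(PoreSpec(noise_sigma=0.3))


def test_noisy_build_is_deterministic():
    a, _ = build_pore(PoreSpec(noise_sigma=0.3, seed=5))
    b, _ = build_pore(PoreSpec(noise_sigma=0.3, seed=5))
    deltas = [
        np.abs(x.xyz - y.xyz).max()
        for (_, x), (_, y) in zip(a.all_atoms(), b.all_atoms())
    ]
    assert max(deltas) == 0.0


def test_fixture_suite_contents_and_determinism(tmp_path):
    m1 = fixture_suite(tmp_path / "a", seed=17)
    m2 = fixture_suite(tmp_path / "b", seed=17)
    assert len(m1["structures"]) >= 12
    # manifest bulge positions consistent with file names
    for s in m1["structures"]:
        if s["name"].startswith("bulge_i"):
            b = int(s["name"].split("_i")[1].split("_")[0])
            assert s["bulges"] == {"2i": b}
    # byte-identical regeneration
    for f in sorted((tmp_path / "a").iterdir()):
        assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()


def test_every_fixture_loads_and_labels_completely(tmp_path):
    fixture_suite(tmp_path / "fx", seed=17)
    manifest = json.loads((tmp_path / "fx" / "manifest.json").read_text())
    for s in manifest["structures"]:
        st = read_structure(tmp_path / "fx" / f"{s['name']}.pdb")
        m = load_segment_map(tmp_path / "fx" / f"{s['name']}.map.json")
        ls = assign_labels(st, m)
        assert ls.report["unmapped_polymer"] == 0
        assert ls.report["mapped"] == 4 * (17 + 35)


def test_ligand_and_ion_ground_truth():
    spec = PoreSpec(
        ligand=LigandSpec(),
        ions=[IonSpec("K", 16.0, "S2", 1.0), IonSpec("CA", -2.0, "S5", 2.0)],
    )
    pore, truth = build_pore(spec)
    assert truth.ligand_region == "central_cavity"
    assert truth.ion_sites == {"S2": 16.0, "S5": -2.0}
    assert truth.ligand_charges == {"N1": 1.0}
    assert len(pore.ion_residues()) == 2
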