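import math

import numpy as np
import pytest

from porescan.geometry import RigidTransform, rotation_about_axis
from porescan.labeling import assign_labels
from porescan.pore_geometry import (
    AtomSelector,
    GeometryError,
    classify_ligand_region,
    cross_distance,
    map_ion_sites,
    select_atom,
)
from porescan.superposition import orient_template, superpose
from porescan.synthetic import IonSpec, LigandSpec, PoreSpec, build_pore


def _oriented(spec):
    pore, truth = build_pore(spec)
    ls = assign_labels(pore, truth.segment_map)
    orient_template(ls)
    return ls, truth


def test_selector_parsing_and_resolution(charged_pore_labeled):
    ls, _ = charged_pore_labeled
    atom = select_atom(ls, "ligand:LIG:N1")
    assert atom.element == "N"
    ca = select_atom(ls, "label:2p48:O")
    assert ca.element == "O"
    k1 = select_atom(ls, "ion:K:1")
    k2 = select_atom(ls, "ion:K:2")
    assert k1.xyz[2] > k2.xyz[2]  # z-ordered from extracellular side
    with pytest.raises(GeometryError):
        AtomSelector.parse("nonsense")
    with pytest.raises(GeometryError):
        select_atom(ls, "ion:K:9")


def test_cross_distance_same_atom_is_zero(charged_pore_labeled):
    ls, _ = charged_pore_labeled
    rec = cross_distance((ls, "ligand:LIG:N1"), (ls, "ligand:LIG:N1"))
    assert rec["distance_A"] == 0.0


def test_cross_distance_constructed_axial_separation():
    spec = PoreSpec(
        ligand=LigandSpec(
            atoms=[("N1", "N", (0.0, 0.0, -2.0), 1.0), ("N2", "N", (0.0, 0.0, -6.0), 0.0)]
        )
    )
    ls, _ = _oriented(spec)
    rec = cross_distance((ls, "ligand:LIG:N1"), (ls, "ligand:LIG:N2"))
    assert abs(rec["distance_A"] - 4.0) < 1e-9


def test_cross_distance_invariant_under_common_rigid_motion(charged_pore_labeled):
    ls, _ = charged_pore_labeled
    d0 = cross_distance((ls, "ligand:LIG:N1"), (ls, "ion:K:1"))["distance_A"]
    moved = ls.copy()
    t = RigidTransform(rotation_about_axis([1, 2, 3], 77.0), np.array([4.0, -2.0, 9.0]))
    moved.structure.transform(t)
    d1 = cross_distance((moved, "ligand:LIG:N1"), (moved, "ion:K:1"))["distance_A"]
    assert abs(d0 - d1) < 1e-6


def test_cross_distance_requires_common_frame(fresh_alpha_labeled, charged_pore_labeled):
    unaligned, _ = fresh_alpha_labeled
    ls, _ = charged_pore_labeled
    with pytest.raises(GeometryError, match="frame"):
        cross_distance((unaligned, "label:2p48:O"), (ls, "ligand:LIG:N1"))


def test_ion_sites_labeled_in_z_order():
    spec = PoreSpec(
        ions=[IonSpec("K", 16.0, "S2"), IonSpec("K", 12.5, "S3"), IonSpec("K", -2.0, "S5")]
    )
    ls, truth = _oriented(spec)
    sites = map_ion_sites(ls, site_labels=list(truth.ion_sites))
    assert list(sites.sites) == ["S2", "S3", "S5"]
    auto = map_ion_sites(ls)
    assert list(auto.sites) == ["S1", "S2", "S3"]
    assert auto.z_of("S1") > auto.z_of("S2") > auto.z_of("S3")


def test_degenerate_ion_ordering_is_error():
    spec = PoreSpec(ions=[IonSpec("K", 5.0, "A"), IonSpec("NA", 5.0, "B")])
    ls, _ = _oriented(spec)
    with pytest.raises(GeometryError, match="degenerate"):
        map_ion_sites(ls)


def test_no_ions_yields_empty_map_with_warning(oriented_template):
    with pytest.warns(UserWarning, match="no axial ions"):
        sites = map_ion_sites(oriented_template)
    assert sites.sites == {}


def test_axial_ligand_is_fully_central_cavity():
    ls, _ = _oriented(PoreSpec(ligand=LigandSpec(atoms=[("N1", "N", (0, 0, -4.0), 1.0)])))
    call = classify_ligand_region(ls, "LIG")
    assert call.fractions == {"central_cavity": 1.0}


def test_peripheral_ligand_lands_in_a_fenestration():
    az = math.radians(-135.0)
    ls, _ = _oriented(
        PoreSpec(
            ligand=LigandSpec(
                atoms=[("C1", "C", (11 * math.cos(az), 11 * math.sin(az), 0.0), 0.0)]
            )
        )
    )
    call = classify_ligand_region(ls, "LIG")
    assert call.majority.startswith("fenestration(")


def test_spanning_ligand_fractions_partition_unity():
    az = math.radians(-135.0)
    ls, _ = _oriented(
        PoreSpec(
            ligand=LigandSpec(
                atoms=[
                    ("N1", "N", (0.0, 0.0, -4.0), 1.0),
                    ("C9", "C", (11 * math.cos(az), 11 * math.sin(az), 0.0), 0.0),
                ]
            )
        )
    )
    call = classify_ligand_region(ls, "LIG")
    assert abs(sum(call.fractions.values()) - 1.0) < 1e-12
    assert len(call.fractions) == 2
    assert all(v > 0 for v in call.fractions.values())


def test_c4_rotation_permutes_fenestrations():
    az = math.radians(-135.0)
    ls, _ = _oriented(
        PoreSpec(
            ligand=LigandSpec(
                atoms=[("C1", "C", (11 * math.cos(az), 11 * math.sin(az), 0.0), 0.0)]
            )
        )
    )
    first = classify_ligand_region(ls, "LIG").majority
    lig = ls.structure.het_residues("LIG")[0]
    rot = RigidTransform(rotation_about_axis([0, 0, 1], -90.0), np.zeros(3))
    for a in lig.atoms.values():
        a.xyz = rot.apply(a.xyz)
    second = classify_ligand_region(ls, "LIG").majority
    n1 = int(first.split("(")[1].split("/")[0])
    n2 = int(second.split("(")[1].split("/")[0])
    assert (n1 % 4) + 1 == n2


def test_missing_ligand_is_error(oriented_template):
    with pytest.raises(GeometryError, match="absent"):
        classify_ligand_region(oriented_template, "XYZ")
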