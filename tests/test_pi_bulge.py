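import numpy as np
import pytest

from conftest import make_bulged
from porescan.geometry import RigidTransform
from porescan.pi_bulge import (
    HelixProfile,
    ProfileError,
    axis_distance_profile,
    cb_azimuth,
    cluster_cb_orientations,
    combine_calls,
    detect_bulge_hbond,
    detect_bulge_register,
    deviation_profile,
)
from porescan.superposition import superpose


def test_identical_structures_give_zero_deviation_profile(oriented_template, fresh_alpha_labeled):
    ls, _ = fresh_alpha_labeled
    superpose(ls, oriented_template)
    prof = deviation_profile(ls, oriented_template, "2i")
    assert prof.values.max() < 1e-9
    assert prof.kind == "deviation_from_template"


def test_uniform_translation_gives_constant_profile(oriented_template, fresh_alpha_labeled):
    ls, _ = fresh_alpha_labeled
    superpose(ls, oriented_template)
    t = RigidTransform(np.eye(3), np.array([1.0, 0.0, 0.0]))
    for res in ls.residue_of.values():
        for a in res.atoms.values():
            a.xyz = t.apply(a.xyz)
    prof = deviation_profile(ls, oriented_template, "2i")
    assert np.allclose(prof.values, 1.0, atol=1e-9)


def test_bulge_inflates_downstream_deviation(oriented_template):
    ls, truth = make_bulged(15)
    superpose(ls, oriented_template)
    prof = deviation_profile(ls, oriented_template, "2i")
    up = prof.values[prof.positions < 13]
    down = prof.values[prof.positions > 17]
    assert down.mean() > 2 * max(up.mean(), 0.5)


def test_axis_profile_requires_oriented_frame(fresh_alpha_labeled):
    ls, _ = fresh_alpha_labeled  # built frame but flag not set
    with pytest.raises(ProfileError, match="oriented"):
        axis_distance_profile(ls, "2i")


def test_axis_profile_period_is_helical(oriented_template):
    from porescan.experiments import axis_profile_period

    assert 3.4 <= axis_profile_period(oriented_template) <= 3.8


def test_constant_profile_for_axial_pseudo_helix():
    prof = HelixProfile(np.arange(1, 11), np.full(10, 8.0), "distance_from_axis")
    assert np.allclose(prof.values, 8.0)
    ref = HelixProfile(np.arange(1, 11), np.full(10, 8.0), "distance_from_axis")
    call = detect_bulge_register(prof, ref)
    assert not call.present


def test_register_scan_identical_profiles_no_call(oriented_template, fresh_alpha_labeled):
    ls, _ = fresh_alpha_labeled
    superpose(ls, oriented_template)
    qa = axis_distance_profile(ls, "2i")
    ra = axis_distance_profile(oriented_template, "2i")
    assert not detect_bulge_register(qa, ra).present
    assert not detect_bulge_register(deviation_profile(ls, oriented_template, "2i")).present


@pytest.mark.parametrize("b", [12, 15, 18, 21])
def test_register_scan_localizes_noiseless_bulges(oriented_template, b):
    ls, truth = make_bulged(b)
    superpose(ls, oriented_template)
    call = detect_bulge_register(deviation_profile(ls, oriented_template, "2i"))
    assert call.present
    assert abs(call.position - b) <= 1
    axis_call = detect_bulge_register(
        axis_distance_profile(ls, "2i"), axis_distance_profile(oriented_template, "2i")
    )
    assert axis_call.present
    assert abs(axis_call.position - b) <= 1


@pytest.mark.parametrize("b", [12, 15, 18, 21])
def test_hbond_detector_localizes_noiseless_bulges(oriented_template, b):
    ls, _ = make_bulged(b)
    superpose(ls, oriented_template)
    call = detect_bulge_hbond(ls, "2i")
    assert call.present
    assert abs(call.position - b) <= 1


def test_ideal_alpha_helix_has_no_pi_register_bonds(oriented_template):
    call = detect_bulge_hbond(oriented_template, "1i")
    assert not call.present
    assert all(v == "alpha" for v in call.evidence["registers"].values())


def test_bulged_helix_shows_pi_register_run(oriented_template):
    ls, _ = make_bulged(16)
    superpose(ls, oriented_template)
    call = detect_bulge_hbond(ls, "2i")
    assert call.evidence["pi_runs"], "expected at least one i->i+5 register run"


def test_methods_agree_on_all_noiseless_fixtures(oriented_template):
    for b in range(12, 22):
        ls, _ = make_bulged(b)
        superpose(ls, oriented_template)
        reg = detect_bulge_register(deviation_profile(ls, oriented_template, "2i"))
        hb = detect_bulge_hbond(ls, "2i")
        assert reg.present and hb.present
        assert abs(reg.position - hb.position) <= 1


def test_consensus_confidence_monotone_in_agreement(oriented_template):
    ls, _ = make_bulged(15)
    superpose(ls, oriented_template)
    reg = detect_bulge_register(deviation_profile(ls, oriented_template, "2i"))
    hb = detect_bulge_hbond(ls, "2i")
    both = combine_calls([reg, hb])
    from dataclasses import replace

    degraded = replace(hb, present=False, position=None)
    one = combine_calls([reg, degraded])
    assert both.present
    assert both.confidence >= one.confidence


def test_cb_azimuth_conventions(oriented_template):
    o = cb_azimuth(oriented_template, "1i20")
    assert -180.0 <= o.azimuth < 180.0
    # C4 copies differ by exactly 90 degrees
    az = [cb_azimuth(oriented_template, f"{r}i20").azimuth for r in (1, 2, 3, 4)]
    gaps = sorted((a - b) % 360 for a, b in zip(az, az[1:]))
    for g in gaps:
        assert min(g % 90, 90 - g % 90) < 1e-6


def test_cb_azimuth_glycine_is_error(oriented_template):
    with pytest.raises(ProfileError, match="CB"):
        cb_azimuth(oriented_template, "1p51")  # filter glycine


def test_cb_orientation_clusters_separate_bulged_from_regular(oriented_template):
    regular = [cb_azimuth(oriented_template, f"{r}i20") for r in (1, 2, 3, 4)]
    bulged = []
    for b in (14, 15, 16):
        ls, _ = make_bulged(b)
        superpose(ls, oriented_template)
        bulged.append(cb_azimuth(ls, "2i20"))
    result = cluster_cb_orientations(regular + bulged, seed=0)
    assert result["separation_deg"] > 60.0
    labels = result["labels"]
    assert len(set(labels[:4])) == 1 and len(set(labels[4:])) == 1
    assert labels[0] != labels[4]


def test_short_profiles_rejected():
    short = HelixProfile(np.arange(1, 6), np.ones(5), "distance_from_axis")
    with pytest.raises(ProfileError):
        detect_bulge_register(short, short)
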