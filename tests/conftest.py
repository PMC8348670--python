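import pytest

from porescan.labeling import assign_labels
from porescan.superposition import orient_template
from porescan.synthetic import HelixSpec, IonSpec, LigandSpec, PoreSpec, build_pore


@pytest.fixture(scope="session")
def alpha_pore():
    """α-only C4 pore with ground truth (built frame)."""
    return build_pore(PoreSpec())


@pytest.fixture(scope="session")
def oriented_template():
    """Labelled α-only pore in the canonical oriented frame."""
    pore, truth = build_pore(PoreSpec())
    ls = assign_labels(pore, truth.segment_map)
    orient_template(ls)
    return ls


@pytest.fixture()
def fresh_alpha_labeled():
    pore, truth = build_pore(PoreSpec())
    return assign_labels(pore, truth.segment_map), truth


def make_bulged(b, sigma=0.0, seed=None):
    inner = [HelixSpec(), HelixSpec(bulge_position=b), HelixSpec(), HelixSpec()]
    pore, truth = build_pore(PoreSpec(inner=inner, noise_sigma=sigma, seed=seed))
    return assign_labels(pore, truth.segment_map), truth


@pytest.fixture(scope="session")
def charged_pore_labeled():
    spec = PoreSpec(
        ligand=LigandSpec(atoms=[("N1", "N", (0.0, 0.0, -4.0), 1.0)]),
        ions=[IonSpec("K", 16.0, "S2", 1.0), IonSpec("K", 12.5, "S3", 1.0)],
    )
    pore, truth = build_pore(spec)
    ls = assign_labels(pore, truth.segment_map)
    orient_template(ls)
    return ls, truth
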