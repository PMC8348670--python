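"""Idealized labelled pore structures with machine-readable ground truth.

The generator emulates, at reduced realism, the conserved pore-module
architecture of P-loop channels: a C4-symmetric bundle of four inner
helices (gate-forming, pore-lining), four short P1 helices whose
C-termini point at the cavity (the "focus" of the P-helix dipoles), and a
short selectivity-filter strand carrying the fingerprint tyrosine anchor.
Optional extras: an axial cationic ligand with assigned charges, axial
monovalent/divalent ions at declared sites, and Gaussian coordinate noise.

Helices are built residue-by-residue from standard internal coordinates
(NeRF-style chain extension); backbone geometry constants are ordinary
peptide values, and a π-helix bulge is modelled as a 5-residue stretch of
π dihedrals centred on the requested position — five π residues occupy
roughly the axial span of four α residues, which is what shifts every
downstream side chain by one position, the structural signature the
detectors look for.

Every generated pore is accompanied by a :class:`GroundTruth` record
(segment map, true bulge positions, true ligand region, true ion sites,
noise seed) so that each pipeline stage can be scored without downloads.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist, pdist

from .geometry import fit_line, place_atom, rotation_about_axis, unit
from .labeling import SegmentEntry, SegmentMap
from .structure_io import Atom, Residue, Structure, write_structure

__all__ = [
    "HelixSpec",
    "LigandSpec",
    "IonSpec",
    "PoreSpec",
    "GroundTruth",
    "build_helix",
    "build_pore",
    "fixture_suite",
    "ALPHA_PHI_PSI",
    "PI_PHI_PSI",
]

# standard helix dihedrals (degrees)
ALPHA_PHI_PSI = (-57.0, -47.0)
#: π-stretch dihedrals.  Chosen (together with the widened N-Cα-C angle
#: below) so that five π residues span the rise and twist of four α
#: residues — the geometric content of a single-residue π-bulge insertion —
#: while forming i→i+5 (not i→i+4) backbone hydrogen bonds.
PI_PHI_PSI = (-48.0, -80.0)
#: N-Cα-C angle for π residues; real π helices widen tau well above the
#: standard 111.2°.
PI_TAU = 117.0

# backbone internal coordinates (Å / degrees): ordinary peptide geometry
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.229
ANGLE_C_N_CA = 121.7
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_CA_C_O = 120.5
OMEGA = 180.0

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

#: default sequences; specific residues at landmark positions (I at i15,
#: F at i18, N at i20 — the conserved ligand-sensing / asparagine positions)
DEFAULT_INNER_SEQ = "AAAAAAAAAAAAAAIAAFANAAAAAAAAAAAAAAA"  # i1..i35
DEFAULT_P1_SEQ = "AAAAAAAAAAA"  # p37..p47
FILTER_SEQ = "TTVGYG"  # p48..p53; tyrosine anchor at p52


@dataclass
class HelixSpec:
    """One helix: sequence plus per-residue backbone dihedrals.

    ``bulge_position`` is the 1-based label index on which a π-stretch of
    ``bulge_length`` residues is centred (the ground-truth bulge position).
    """

    sequence: str = DEFAULT_INNER_SEQ
    phi_psi: list[tuple[float, float]] | None = None
    bulge_position: int | None = None
    bulge_length: int = 5

    def dihedrals(self) -> list[tuple[float, float, float]]:
        """Per-residue (φ, ψ, τ) with τ the N-Cα-C angle."""
        n = len(self.sequence)
        if self.phi_psi is not None:
            if len(self.phi_psi) != n:
                raise ValueError("sequence length must equal dihedral list length")
            dihed = [tuple(d) for d in self.phi_psi]
        else:
            dihed = [ALPHA_PHI_PSI] * n
        if self.bulge_position is not None:
            half = self.bulge_length // 2
            lo = self.bulge_position - half
            hi = lo + self.bulge_length - 1
            if lo < 1 or hi > n:
                raise ValueError(
                    f"π-stretch {lo}..{hi} falls outside the 1..{n} sequence"
                )
            for k in range(lo, hi + 1):
                dihed[k - 1] = PI_PHI_PSI
        out = []
        for d in dihed:
            if len(d) == 3:
                out.append(tuple(d))
            else:
                tau = PI_TAU if tuple(d) == PI_PHI_PSI else ANGLE_N_CA_C
                out.append((d[0], d[1], tau))
        return out


# Cβ from N, CA, C by the standard tetrahedral construction
_CB_COEFF = (-0.58273431, 0.56802827, -0.54067466)


def _place_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    b = ca - n
    cc = c - ca
    a = np.cross(b, cc)
    return _CB_COEFF[0] * a + _CB_COEFF[1] * b + _CB_COEFF[2] * cc + ca


def build_helix(
    spec: HelixSpec, chain: str = "A", first_resseq: int = 1
) -> Structure:
    """Build backbone + Cβ coordinates for one helix from internal coordinates.

    The α-helical default geometry yields a rise of ~1.5 Å per residue and
    ~3.6 residues per turn; π dihedrals give a more compressed, wider helix.
    Raises if the requested dihedrals bring non-bonded backbone atoms closer
    than 1.5 Å (self-clash: non-physical input).
    """
    seq = spec.sequence.upper()
    for ch in seq:
        if ch not in ONE_TO_THREE:
            raise ValueError(f"unknown one-letter residue code {ch!r}")
    dihed = spec.dihedrals()
    n_res = len(seq)

    N = np.zeros((n_res, 3))
    CA = np.zeros((n_res, 3))
    C = np.zeros((n_res, 3))
    # seed residue in a local frame
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (BOND_N_CA, 0.0, 0.0)
    th = np.deg2rad(dihed[0][2])
    C[0] = CA[0] + BOND_CA_C * np.array([-np.cos(th), np.sin(th), 0.0])
    for i in range(1, n_res):
        psi_prev = dihed[i - 1][1]
        N[i] = place_atom(N[i - 1], CA[i - 1], C[i - 1], BOND_C_N, ANGLE_CA_C_N, psi_prev)
        CA[i] = place_atom(CA[i - 1], C[i - 1], N[i], BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        C[i] = place_atom(C[i - 1], N[i], CA[i], BOND_CA_C, dihed[i][2], dihed[i][0])

    st = Structure()
    for i, one in enumerate(seq):
        res = Residue(chain=chain, seqid=first_resseq + i, icode="",
                      name=ONE_TO_THREE[one], het=False)
        res.atoms["N"] = Atom("N", "N", N[i].copy())
        res.atoms["CA"] = Atom("CA", "C", CA[i].copy())
        res.atoms["C"] = Atom("C", "C", C[i].copy())
        # carbonyl O in the peptide plane, anti to the next N
        o = place_atom(N[i], CA[i], C[i], BOND_C_O, ANGLE_CA_C_O, dihed[i][1] + 180.0)
        res.atoms["O"] = Atom("O", "O", o)
        if one != "G":
            res.atoms["CB"] = Atom("CB", "C", _place_cb(N[i], CA[i], C[i]))
        st.add_residue(res)

    # self-clash check on backbone atoms of non-adjacent residues
    bb = np.array([a.xyz for r in st.residues for a in r.atoms.values()])
    owner = np.array([i for i, r in enumerate(st.residues) for _ in r.atoms])
    d = cdist(bb, bb)
    sep = np.abs(owner[:, None] - owner[None, :])
    close = (d < 1.5) & (sep >= 2)
    if np.any(close):
        raise ValueError("non-physical dihedrals: backbone self-clash < 1.5 Å")
    return st


def _helix_ca(st: Structure) -> np.ndarray:
    return np.array([r.atoms["CA"].xyz for r in st.residues])


def _orient_fragment(
    st: Structure, direction: np.ndarray, anchor: np.ndarray, n_fit: int | None = None
) -> None:
    """Rotate a fragment so its Cα axis (residue 1 -> N) points along
    ``direction`` and translate its first Cα to ``anchor``.

    ``n_fit`` restricts the axis fit to the first n residues — used to
    anchor a π-bulged helix by its regular N-terminal part, so the
    perturbation propagates downstream (as it does in real structures).
    """
    ca_all = _helix_ca(st)
    ca = ca_all if n_fit is None else ca_all[: max(2, n_fit)]
    _, axis = fit_line(ca)
    if np.dot(ca[-1] - ca[0], axis) < 0:
        axis = -axis
    target = unit(np.asarray(direction, dtype=float))
    v = np.cross(axis, target)
    s = np.linalg.norm(v)
    c = np.dot(axis, target)
    if s < 1e-12:
        rot = np.eye(3) if c > 0 else rotation_about_axis(
            _any_perpendicular(axis), 180.0
        )
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)
    for r in st.residues:
        for a in r.atoms.values():
            a.xyz = rot @ a.xyz
    shift = np.asarray(anchor, dtype=float) - st.residues[0].atoms["CA"].xyz
    for r in st.residues:
        for a in r.atoms.values():
            a.xyz = a.xyz + shift


def _any_perpendicular(v: np.ndarray) -> np.ndarray:
    w = np.array([1.0, 0.0, 0.0]) if abs(v[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    return unit(np.cross(v, w))


def _build_filter_column(
    chain: str, first_resseq: int, radius: float, base_z: float, rise: float = 1.5
) -> Structure:
    """Stylized selectivity-filter strand (TTVGYG): a compact vertical
    residue stack at ``radius`` from the pore axis, backbone carbonyls
    pointing at the axis (as the real filter's ion-coordinating carbonyls
    do) and Cβ pointing outward.

    The filter is an orientation/region anchor, not a substrate for
    backbone diagnostics, so a stylized column is preferred over a NeRF
    chain: it keeps the four symmetry mates compact and clash-free.
    """
    st = Structure()
    for k, one in enumerate(FILTER_SEQ):
        ca = np.array([radius, 0.0, base_z + rise * k])
        res = Residue(chain=chain, seqid=first_resseq + k, icode="",
                      name=ONE_TO_THREE[one], het=False)
        res.atoms["N"] = Atom("N", "N", ca + np.array([-0.45, 0.35, -1.15]))
        res.atoms["CA"] = Atom("CA", "C", ca)
        res.atoms["C"] = Atom("C", "C", ca + np.array([-0.45, -0.35, 1.15]))
        res.atoms["O"] = Atom("O", "O", ca + np.array([-1.55, -0.45, 1.35]))
        if one != "G":
            res.atoms["CB"] = Atom("CB", "C", ca + np.array([1.45, 0.15, 0.35]))
        st.add_residue(res)
    return st


@dataclass
class LigandSpec:
    """Rigid point-charge ligand: atom name, element, xyz (pore frame), charge."""

    resname: str = "LIG"
    atoms: list[tuple[str, str, tuple[float, float, float], float]] = field(
        default_factory=lambda: [("N1", "N", (0.0, 0.0, -2.0), 1.0)]
    )

    @property
    def net_charge(self) -> float:
        return sum(a[3] for a in self.atoms)


@dataclass
class IonSpec:
    element: str = "K"
    z: float = 8.0
    site: str = "S4"
    charge: float = 1.0


@dataclass
class PoreSpec:
    """Full pore: four-fold symmetric bundle + optional ligand/ions/noise.

    C4 placement is exact before noise; ``seed`` is mandatory when
    ``noise_sigma`` > 0.  Default dimensions put the inner-helix bundle at
    11 Å from the axis with a slight outward splay of the gate ends
    (open-gate bundle), P1 helices tilted with their C-termini pointing at
    the cavity, and the filter column at 4 Å radius above the cavity.
    """

    inner: HelixSpec | list[HelixSpec] = field(default_factory=HelixSpec)
    p1: HelixSpec = field(default_factory=lambda: HelixSpec(sequence=DEFAULT_P1_SEQ))
    bundle_radius: float = 11.0
    p1_cterm_radius: float = 6.5  # where the P1 C-terminal axis end sits
    p1_cterm_z: float = 15.5
    p1_elevation: float = 60.0  # P1 axis angle below horizontal, deg
    filter_radius: float = 4.0
    p1_azimuth: float = -40.0  # P1 of repeat n sits between inner helices n, n+1
    filter_azimuth: float = -15.0  # filter column leans toward its own P1
    helix_tilt: float = 6.0  # outward splay of the gate-side helix ends, deg
    inner_top_z: float = 16.0
    filter_base_z: float = 10.0
    ligand: LigandSpec | None = None
    ions: list[IonSpec] = field(default_factory=list)
    noise_sigma: float = 0.0
    seed: int | None = None

    def inner_specs(self) -> list[HelixSpec]:
        if isinstance(self.inner, HelixSpec):
            return [self.inner] * 4
        if len(self.inner) != 4:
            raise ValueError("inner must be one HelixSpec or a list of four")
        return list(self.inner)


@dataclass
class GroundTruth:
    segment_map: SegmentMap
    bulges: dict[str, int]  # e.g. {"2i": 15}
    ligand_region: str | None
    ion_sites: dict[str, float]  # site label -> z
    ligand_charges: dict[str, float]
    noise_sigma: float
    seed: int | None

    def to_json(self) -> dict:
        return {
            "segment_map": self.segment_map.to_json(),
            "bulges": self.bulges,
            "ligand_region": self.ligand_region,
            "ion_sites": self.ion_sites,
            "ligand_charges": self.ligand_charges,
            "noise_sigma": self.noise_sigma,
            "seed": self.seed,
        }


CHAINS = "ABCD"
P_FIRST_INDEX = 37  # P1 helix starts at p37; filter TTVGYG is p48..p53
GYG_ANCHOR_INDEX = 52  # the fingerprint filter tyrosine label index


def build_pore(spec: PoreSpec) -> tuple[Structure, GroundTruth]:
    """Assemble the four-fold pore and emit its ground truth.

    Repeats I–IV sit at azimuths 0°, −90°, −180°, −270° (clockwise viewed
    from the extracellular side, +z), each repeat one chain (A–D).
    """
    if spec.noise_sigma > 0 and spec.seed is None:
        raise ValueError("seed is mandatory when noise_sigma > 0")
    inner_specs = spec.inner_specs()
    p_len = len(spec.p1.sequence) + len(FILTER_SEQ)

    pore = Structure(accession="synthetic-pore")
    entries: list[SegmentEntry] = []
    bulges: dict[str, int] = {}

    # --- repeat 1 fragments, then rotate into place ---
    for repeat in range(1, 5):
        chain = CHAINS[repeat - 1]
        rot = rotation_about_axis([0, 0, 1], -90.0 * (repeat - 1))

        hspec = inner_specs[repeat - 1]
        inner = build_helix(hspec, chain=chain, first_resseq=101)
        # inner helix: N-term extracellular (top), index increases downward;
        # a bulged helix is anchored by its regular N-terminal stretch
        n_fit = None
        if hspec.bulge_position is not None:
            n_fit = hspec.bulge_position - hspec.bulge_length // 2 - 1
        _orient_fragment(inner, direction=[0, 0, -1],
                         anchor=[spec.bundle_radius, 0.0, spec.inner_top_z],
                         n_fit=n_fit)
        if spec.helix_tilt:
            # tilt about the tangential axis through the helix top; positive
            # angles splay the gate-side ends outward (open-gate bundle)
            top = inner.residues[0].atoms["CA"].xyz.copy()
            tilt = rotation_about_axis([0, 1, 0], -spec.helix_tilt)
            for r in inner.residues:
                for a in r.atoms.values():
                    a.xyz = tilt @ (a.xyz - top) + top
        if hspec.bulge_position is not None:
            bulges[f"{repeat}i"] = hspec.bulge_position

        p1 = build_helix(spec.p1, chain=chain, first_resseq=P_FIRST_INDEX)
        # P1 runs down-and-inward; its C-terminal end is the "focus" point
        # over the cavity.  Anchor the *last* Cα and walk back up the axis.
        elev = np.deg2rad(spec.p1_elevation)
        p1_dir = np.array([-np.cos(elev), 0.0, -np.sin(elev)])
        p1_len = np.linalg.norm(
            _helix_ca(p1)[-1] - _helix_ca(p1)[0]
        )
        p1_start = (
            np.array([spec.p1_cterm_radius, 0.0, spec.p1_cterm_z]) - p1_len * p1_dir
        )
        _orient_fragment(p1, direction=p1_dir, anchor=p1_start)
        p1_rot = rotation_about_axis([0, 0, 1], spec.p1_azimuth)
        for r in p1.residues:
            for a in r.atoms.values():
                a.xyz = p1_rot @ a.xyz

        filt = _build_filter_column(
            chain=chain,
            first_resseq=P_FIRST_INDEX + len(spec.p1.sequence),
            radius=spec.filter_radius,
            base_z=spec.filter_base_z,
        )
        f_rot = rotation_about_axis([0, 0, 1], spec.filter_azimuth)
        for r in filt.residues:
            for a in r.atoms.values():
                a.xyz = f_rot @ a.xyz

        for fragment in (p1, filt, inner):
            for r in fragment.residues:
                for a in r.atoms.values():
                    a.xyz = rot @ a.xyz
                pore.add_residue(r)

        entries.append(SegmentEntry(repeat, "p", chain, P_FIRST_INDEX,
                                    P_FIRST_INDEX, p_len))
        entries.append(SegmentEntry(repeat, "i", chain, 101, 1,
                                    len(hspec.sequence)))

    # inter-helix clash check before noise
    coords = np.array([a.xyz for _, a in pore.all_atoms()])
    chain_of = np.array([ord(r.chain) for r, _ in pore.all_atoms()])
    d = cdist(coords, coords)
    inter = chain_of[:, None] != chain_of[None, :]
    if np.any((d < 2.0) & inter):
        raise ValueError("inter-helix clash < 2 Å before noise; widen the bundle")

    # --- ligand ---
    ligand_charges: dict[str, float] = {}
    if spec.ligand is not None:
        res = Residue(chain="X", seqid=1, icode="", name=spec.ligand.resname, het=True)
        for name, element, xyz, q in spec.ligand.atoms:
            res.atoms[name] = Atom(name, element, np.array(xyz, dtype=float), het=True)
            ligand_charges[name] = q
        pore.add_residue(res)

    # --- ions ---
    ion_sites: dict[str, float] = {}
    for k, ion in enumerate(spec.ions):
        res = Residue(chain="I", seqid=k + 1, icode="",
                      name=ion.element.upper(), het=True)
        res.atoms[ion.element.upper()] = Atom(
            ion.element.upper(), ion.element.upper(),
            np.array([0.0, 0.0, ion.z]), het=True,
        )
        pore.add_residue(res)
        if ion.site in ion_sites:
            raise ValueError(f"duplicate ion site label {ion.site}")
        ion_sites[ion.site] = ion.z

    # --- noise (coordinates only; ground truth untouched) ---
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        for _, a in pore.all_atoms():
            a.xyz = a.xyz + rng.normal(0.0, spec.noise_sigma, 3)

    seg_map = SegmentMap(channel="synthetic-pore", entries=entries)
    truth = GroundTruth(
        segment_map=seg_map,
        bulges=bulges,
        ligand_region="central_cavity" if spec.ligand is not None else None,
        ion_sites=ion_sites,
        ligand_charges=ligand_charges,
        noise_sigma=spec.noise_sigma,
        seed=spec.seed,
    )
    return pore, truth


def fixture_suite(out_dir: str | Path, seed: int = 17) -> dict:
    """Write the canonical synthetic test set and its manifest.

    Contents: an α-only pore, single-bulge pores with the bulge at i12…i21
    in repeat 2, noisy replicas (σ = 0.3 Å), a charged-ligand pore and an
    ion-laden pore.  Re-running with the same seed reproduces the files
    byte for byte.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": seed, "structures": []}

    def emit(name: str, spec: PoreSpec) -> None:
        st, truth = build_pore(spec)
        write_structure(st, out_dir / f"{name}.pdb")
        truth.segment_map.save(out_dir / f"{name}.map.json")
        (out_dir / f"{name}.truth.json").write_text(
            json.dumps(truth.to_json(), indent=1) + "\n"
        )
        manifest["structures"].append(
            {"name": name, "bulges": truth.bulges, "sigma": spec.noise_sigma}
        )

    emit("alpha_only", PoreSpec())
    for b in range(12, 22):
        inner = [HelixSpec(), HelixSpec(bulge_position=b), HelixSpec(), HelixSpec()]
        emit(f"bulge_i{b}", PoreSpec(inner=inner))
    for k, b in enumerate((14, 17, 20)):
        inner = [HelixSpec(), HelixSpec(bulge_position=b), HelixSpec(), HelixSpec()]
        emit(f"bulge_i{b}_noisy", PoreSpec(inner=inner, noise_sigma=0.3, seed=seed + k))
    emit("charged_ligand", PoreSpec(ligand=LigandSpec()))
    emit(
        "ion_laden",
        PoreSpec(ions=[IonSpec("K", 16.0, "S2"), IonSpec("K", 12.0, "S4"),
                       IonSpec("K", -2.0, "S5")]),
    )

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
    return manifest
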