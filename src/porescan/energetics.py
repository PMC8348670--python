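"""Ligand–channel non-bonded energetics with a distance-dependent dielectric.

The scoring model is a 6-12 van der Waals term plus a Coulomb term with the
dielectric ε = 2r, so electrostatics fall off as 1/r²:

    E_vdw  = Σ_ij ε*_ij [ (R*_ij / r_ij)^12 − 2 (R*_ij / r_ij)^6 ]
    E_coul = Σ_ij 332.064 q_i q_j / (2 r_ij²)        [kcal/mol, r in Å, q in e]

with Lorentz–Berthelot combination (R*_ij = R*_i + R*_j as Rmin halves;
ε*_ij geometric mean).  Only *intermolecular* terms are computed
(ligand↔protein, ligand↔ion, ligand↔lipid), so no bonded exclusions are
needed.  Hydrogens, when present, are ignored.

A reduced bundled per-element parameter set stands in for full force-field
atom typing: the analysis products are energy *trends* and per-residue
*shares* of the interaction energy, not absolute binding free energies.
User-supplied parameter and charge tables override the bundled ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .geometry import rotation_about_axis
from .labeling import LabeledStructure
from .structure_io import Residue

__all__ = [
    "NonbondedParams",
    "ChargeTable",
    "EnergyPartition",
    "PinRestraint",
    "EnergeticsError",
    "pair_energy",
    "partition_by_residue",
    "pin_energy",
    "assign_charges",
    "refine_pose",
]

COULOMB_K = 332.064  # kcal·Å/(mol·e²)
DEFAULT_CUTOFF = 12.0  # Å
CLASH_DISTANCE = 0.5  # Å; below this the point-charge model is meaningless


class EnergeticsError(ValueError):
    pass


def _load_data(name: str) -> dict:
    with resources.files("porescan.data").joinpath(name).open() as fh:
        return json.load(fh)


@dataclass
class NonbondedParams:
    """Per-element van der Waals parameters (R* = Rmin/2 in Å, ε* kcal/mol)."""

    rstar: dict[str, float]
    eps: dict[str, float]
    coulomb_k: float = COULOMB_K

    @classmethod
    def default(cls) -> "NonbondedParams":
        doc = _load_data("nonbonded.json")
        return cls(
            rstar={el: v["rstar"] for el, v in doc["elements"].items()},
            eps={el: v["eps"] for el, v in doc["elements"].items()},
            coulomb_k=doc.get("coulomb_constant", COULOMB_K),
        )

    @classmethod
    def load(cls, path: str | Path) -> "NonbondedParams":
        doc = json.loads(Path(path).read_text())
        return cls(
            rstar={el: v["rstar"] for el, v in doc["elements"].items()},
            eps={el: v["eps"] for el, v in doc["elements"].items()},
            coulomb_k=doc.get("coulomb_constant", COULOMB_K),
        )

    def of(self, element: str) -> tuple[float, float]:
        el = element.upper()
        if el not in self.rstar:
            raise EnergeticsError(f"no van der Waals parameters for element {el!r}")
        if self.rstar[el] <= 0 or self.eps[el] < 0:
            raise EnergeticsError(f"invalid parameters for element {el!r}")
        return self.rstar[el], self.eps[el]


@dataclass
class ChargeTable:
    """Partial charges keyed by (residue name, atom name) with fallbacks.

    Residue entries must sum to their declared formal charge (±10⁻³).
    ``backbone_dipole`` optionally assigns reduced amide/carbonyl charges
    to protein residues without their own entry.
    """

    residues: dict[str, dict] = field(default_factory=dict)
    element_fallback: dict[str, float] = field(default_factory=lambda: {"default": 0.0})
    backbone_dipole: dict[str, float] | None = None
    use_backbone_dipole: bool = False

    def __post_init__(self) -> None:
        for name, entry in self.residues.items():
            total = sum(entry["atoms"].values())
            if abs(total - entry["formal_charge"]) > 1e-3:
                raise EnergeticsError(
                    f"residue {name!r}: atom charges sum to {total}, declared "
                    f"formal charge {entry['formal_charge']}"
                )

    @classmethod
    def default(cls, use_backbone_dipole: bool = False) -> "ChargeTable":
        doc = _load_data("charges.json")
        return cls(
            residues=doc["residues"],
            element_fallback=doc.get("element_fallback", {"default": 0.0}),
            backbone_dipole=doc.get("backbone_dipole"),
            use_backbone_dipole=use_backbone_dipole,
        )

    @classmethod
    def load(cls, path: str | Path, use_backbone_dipole: bool = False) -> "ChargeTable":
        doc = json.loads(Path(path).read_text())
        return cls(
            residues=doc["residues"],
            element_fallback=doc.get("element_fallback", {"default": 0.0}),
            backbone_dipole=doc.get("backbone_dipole"),
            use_backbone_dipole=use_backbone_dipole,
        )

    def charge_of(self, residue: Residue, atom_name: str) -> float:
        entry = self.residues.get(residue.name)
        if entry is not None:
            if atom_name in entry["atoms"]:
                return float(entry["atoms"][atom_name])
            raise EnergeticsError(
                f"atom {atom_name!r} of residue {residue.name!r} missing from its "
                "charge entry"
            )
        if self.use_backbone_dipole and self.backbone_dipole is not None and not residue.het:
            if atom_name in self.backbone_dipole:
                return float(self.backbone_dipole[atom_name])
        element = residue.atoms[atom_name].element.upper()
        if element in self.element_fallback:
            return float(self.element_fallback[element])
        if "default" in self.element_fallback:
            return float(self.element_fallback["default"])
        raise EnergeticsError(
            f"no charge for atom {atom_name!r} of {residue.name!r} and no fallback"
        )


@dataclass
class ChargedAtomSet:
    """Coordinates, elements and charges ready for pair_energy."""

    coords: np.ndarray  # (n, 3)
    elements: list[str]
    charges: np.ndarray  # (n,)
    names: list[str] = field(default_factory=list)

    @property
    def net_charge(self) -> float:
        return float(self.charges.sum())


def assign_charges(
    residues: list[Residue] | Residue,
    table: ChargeTable,
    skip_hydrogens: bool = True,
) -> ChargedAtomSet:
    """Attach charges (and vdW element keys) to the atoms of residues."""
    if isinstance(residues, Residue):
        residues = [residues]
    coords, elements, charges, names = [], [], [], []
    for res in residues:
        for name, atom in res.atoms.items():
            if skip_hydrogens and atom.element.upper() == "H":
                continue
            coords.append(atom.xyz)
            elements.append(atom.element.upper())
            charges.append(table.charge_of(res, name))
            names.append(f"{res.chain}/{res.name}{res.seqid}/{name}")
    if not coords:
        raise EnergeticsError("no atoms to charge")
    return ChargedAtomSet(np.array(coords), elements, np.array(charges), names)


def pair_energy(
    a: ChargedAtomSet,
    b: ChargedAtomSet,
    params: NonbondedParams | None = None,
    cutoff: float = DEFAULT_CUTOFF,
) -> tuple[float, float]:
    """Intermolecular (vdW, Coulomb) energy between two disjoint atom sets.

    Pairs beyond ``cutoff`` are excluded; a pair closer than 0.5 Å is an
    error (steric clash beyond the validity of the point model).
    Returns energies in kcal/mol.
    """
    if params is None:
        params = NonbondedParams.default()
    r = cdist(a.coords, b.coords)
    if np.any(r < CLASH_DISTANCE):
        i, j = np.unravel_index(int(np.argmin(r)), r.shape)
        na = a.names[i] if a.names else f"atom {i}"
        nb = b.names[j] if b.names else f"atom {j}"
        raise EnergeticsError(
            f"atoms {na} and {nb} overlap (r = {r[i, j]:.3f} Å < {CLASH_DISTANCE})"
        )
    mask = r <= cutoff
    if not mask.any():
        return 0.0, 0.0
    ra = np.array([params.of(el)[0] for el in a.elements])
    rb = np.array([params.of(el)[0] for el in b.elements])
    ea = np.array([params.of(el)[1] for el in a.elements])
    eb = np.array([params.of(el)[1] for el in b.elements])
    rmin = ra[:, None] + rb[None, :]
    epsm = np.sqrt(ea[:, None] * eb[None, :])
    with np.errstate(divide="ignore"):
        x6 = np.where(mask, (rmin / np.where(mask, r, 1.0)) ** 6, 0.0)
    vdw = float(np.sum(epsm * (x6**2 - 2.0 * x6) * mask))
    qq = a.charges[:, None] * b.charges[None, :]
    coul = float(
        np.sum(np.where(mask, params.coulomb_k * qq / (2.0 * r**2 + 1e-300), 0.0))
    )
    return vdw, coul


@dataclass
class EnergyPartition:
    """Per-residue decomposition of a ligand's interaction energy."""

    table: pd.DataFrame  # columns: label, chain, resnum, resname, vdw, coulomb, total, percent
    ligand: str
    vdw_total: float
    coulomb_total: float

    @property
    def grand_total(self) -> float:
        return self.vdw_total + self.coulomb_total

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.table.to_csv(path, index=False, float_format="%.6f")
        return path


def partition_by_residue(
    ls: LabeledStructure,
    ligand: str,
    params: NonbondedParams | None = None,
    charges: ChargeTable | None = None,
    cutoff: float = DEFAULT_CUTOFF,
    include_het: bool = True,
) -> EnergyPartition:
    """Decompose the ligand's non-bonded energy residue by residue.

    Each row is pair_energy(ligand, that residue); the grand totals are
    the sums of the rows (exact additivity by construction, identical
    summation order).  Residues without universal labels are reported
    under their chain/residue number, never dropped.  ``percent`` follows
    the attractive-share convention: each residue's total over the sum of
    all attractive (negative) residue totals, × 100 — so attractive
    residues' percents are positive and sum to 100, repulsive residues
    carry negative percents.
    """
    if params is None:
        params = NonbondedParams.default()
    if charges is None:
        charges = ChargeTable.default()
    lig_residues = ls.structure.het_residues(ligand)
    if not lig_residues:
        raise EnergeticsError(f"ligand {ligand!r} absent from structure")
    lig = assign_charges(lig_residues, charges)
    lig_keys = {r.key for r in lig_residues}

    rows = []
    for res in ls.structure.residues:
        if res.key in lig_keys:
            continue
        if res.het and not include_het:
            continue
        other = assign_charges(res, charges)
        # quick reject: residue entirely beyond cutoff
        if cdist(lig.coords, other.coords).min() > cutoff:
            vdw = coul = 0.0
        else:
            vdw, coul = pair_energy(lig, other, params, cutoff)
        lab = ls.label_of.get(res.key)
        rows.append(
            {
                "label": str(lab) if lab is not None else "",
                "chain": res.chain,
                "resnum": res.seqid,
                "resname": res.name,
                "vdw": vdw,
                "coulomb": coul,
                "total": vdw + coul,
            }
        )
    df = pd.DataFrame(rows)
    attractive = -df.loc[df["total"] < 0, "total"].sum()
    if attractive > 0:
        df["percent"] = -df["total"] / attractive * 100.0
    else:
        df["percent"] = 0.0
    df = df.sort_values("total").reset_index(drop=True)
    return EnergyPartition(
        table=df,
        ligand=ligand,
        vdw_total=float(df["vdw"].sum()),
        coulomb_total=float(df["coulomb"].sum()),
    )


@dataclass
class PinRestraint:
    """Flat-bottom penalty holding atoms near reference coordinates.

    Zero inside the flat bottom; beyond it a parabolic penalty
    k·(d − w)² with the printed restraint constant k = 10 (per Å beyond
    the 1 Å flat bottom).  A linear form 10·(d − w) is selectable.
    """

    reference: np.ndarray  # (n, 3)
    flat_bottom: float = 1.0  # Å
    coefficient: float = 10.0  # kcal/mol per Å (or Å²) beyond the flat bottom
    form: str = "parabolic"  # or "linear"

    def __post_init__(self) -> None:
        self.reference = np.atleast_2d(np.asarray(self.reference, dtype=float))
        if self.form not in ("parabolic", "linear"):
            raise EnergeticsError(f"unknown pin form {self.form!r}")


def pin_energy(current: np.ndarray, restraint: PinRestraint) -> float:
    """Total pin energy of atoms at ``current`` versus their references.

    Continuous at the flat-bottom boundary (zero from both sides).
    """
    cur = np.atleast_2d(np.asarray(current, dtype=float))
    if cur.shape != restraint.reference.shape:
        raise EnergeticsError("current coordinates do not match pin references")
    d = np.linalg.norm(cur - restraint.reference, axis=1)
    excess = np.clip(d - restraint.flat_bottom, 0.0, None)
    if restraint.form == "parabolic":
        return float(restraint.coefficient * np.sum(excess**2))
    return float(restraint.coefficient * np.sum(excess))


@dataclass
class RefineResult:
    translation: np.ndarray
    rotation_angles: np.ndarray  # degrees about x, y, z (applied in order)
    coords: np.ndarray
    energy: float
    initial_energy: float
    trace: list[float]
    pins_satisfied: bool


def _pose_coords(base: np.ndarray, x: np.ndarray) -> np.ndarray:
    centre = base.mean(axis=0)
    R = (
        rotation_about_axis([0, 0, 1], x[5])
        @ rotation_about_axis([0, 1, 0], x[4])
        @ rotation_about_axis([1, 0, 0], x[3])
    )
    return (base - centre) @ R.T + centre + x[:3]


def refine_pose(
    ligand: ChargedAtomSet,
    environment: ChargedAtomSet,
    params: NonbondedParams | None = None,
    pins: PinRestraint | None = None,
    n_steps: int = 200,
    seed: int = 0,
    step_translation: float = 0.3,  # Å
    step_rotation: float = 8.0,  # degrees
    local_every: int = 25,
    cutoff: float = DEFAULT_CUTOFF,
) -> RefineResult:
    """Rigid-body pose refinement by seeded stochastic descent.

    Random 6-dof perturbations (Gaussian steps in translation and in the
    three rotation angles) are accepted only when they lower the
    objective — pair_energy(ligand, environment) plus the pin energy — so
    the accepted-energy trace is non-increasing and the final energy never
    exceeds the initial one.  Every ``local_every`` accepted or rejected
    steps a Nelder–Mead polish from the current pose is attempted.
    Deterministic for a given seed.
    """
    from scipy.optimize import minimize

    if params is None:
        params = NonbondedParams.default()
    base = ligand.coords.copy()

    def objective(x: np.ndarray) -> float:
        coords = _pose_coords(base, x)
        posed = ChargedAtomSet(coords, ligand.elements, ligand.charges, ligand.names)
        try:
            vdw, coul = pair_energy(posed, environment, params, cutoff)
        except EnergeticsError:
            return np.inf  # clash: reject
        e = vdw + coul
        if pins is not None:
            e += pin_energy(coords, pins)
        return e

    x = np.zeros(6)
    e = objective(x)
    if not np.isfinite(e):
        raise EnergeticsError("non-finite objective at the starting pose")
    trace = [e]
    rng = np.random.default_rng(seed)
    scale = np.array([step_translation] * 3 + [step_rotation] * 3)
    for step in range(1, n_steps + 1):
        cand = x + rng.normal(0.0, 1.0, 6) * scale
        e_cand = objective(cand)
        if e_cand <= e:
            x, e = cand, e_cand
            trace.append(e)
        if step % local_every == 0:
            res = minimize(
                objective, x, method="Nelder-Mead",
                options={"maxiter": 120, "xatol": 1e-3, "fatol": 1e-6},
            )
            if np.isfinite(res.fun) and res.fun <= e:
                x, e = res.x, float(res.fun)
                trace.append(e)
    coords = _pose_coords(base, x)
    pins_ok = True
    if pins is not None:
        d = np.linalg.norm(coords - pins.reference, axis=1)
        pins_ok = bool(np.all(d <= pins.flat_bottom + 1.0))
        if not pins_ok:
            import warnings

            warnings.warn(
                "refined pose leaves some pinned atoms more than 1 Å beyond "
                "the flat bottom",
                stacklevel=2,
            )
    return RefineResult(
        translation=x[:3].copy(),
        rotation_angles=x[3:].copy(),
        coords=coords,
        energy=float(e),
        initial_energy=float(trace[0]),
        trace=trace,
        pins_satisfied=pins_ok,
    )
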