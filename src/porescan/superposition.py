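"""Template orientation and rigid superposition in the common pore frame.

The reference template is first put into a fixed frame: the pore axis (the
C4 pseudo-symmetry axis of the selectivity-filter region) coincides with
z, +z points extracellular, the repeat-III filter-tyrosine Cα lies in the
xOz plane with x > 0.  Every query structure is then rigidly superposed
onto the oriented template by a least-squares (Kabsch) fit of Cα atoms
sharing the same universal labels — by default the four P1 helices,
positions p38–p47, the most 3D-conserved element of P-loop channels.

Pairing is by identical universal label only; there is no sequence-based
rescue.  All RMSDs are in Å over Cα atoms unless stated otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import RigidTransform, fit_line, rotation_about_axis, unit
from .labeling import LabeledStructure, ResidueLabel, labels_in_range, parse_label

__all__ = [
    "AlignmentResult",
    "SuperpositionError",
    "ChiralityError",
    "kabsch",
    "orient_template",
    "superpose",
    "rmsd_by_segment",
    "default_fit_labels",
]

#: Default fit set: P1-helix positions p38-p47 in all four repeats.
DEFAULT_FIT_RANGE = (38, 47)

#: Default label of the fingerprint selectivity-filter tyrosine (GYG motif).
DEFAULT_GYG_INDEX = 52


class SuperpositionError(ValueError):
    pass


class ChiralityError(SuperpositionError):
    """The optimal orthogonal map is a reflection: mirrored coordinates."""


def default_fit_labels(
    start: int = DEFAULT_FIT_RANGE[0], stop: int = DEFAULT_FIT_RANGE[1]
) -> list[ResidueLabel]:
    return labels_in_range("p", start, stop)


@dataclass
class AlignmentResult:
    transform: RigidTransform
    fit_rmsd: float
    per_segment_rmsd: dict[str, float]
    n_atoms_used: int
    labels_used: list[str] = field(default_factory=list)

    def to_json(self) -> dict:
        return {
            "transform": self.transform.to_json(),
            "fit_rmsd": self.fit_rmsd,
            "per_segment_rmsd": self.per_segment_rmsd,
            "n_atoms_used": self.n_atoms_used,
            "labels_used": self.labels_used,
        }


def kabsch(moving: np.ndarray, target: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares rigid transform mapping ``moving`` onto ``target``.

    Closed-form solution via SVD of the covariance matrix.  Raises
    :class:`ChiralityError` if a genuine reflection would be required
    (the degenerate near-planar case is corrected silently, as is
    conventional).  Returns ``(transform, rmsd)``.
    """
    P = np.asarray(moving, dtype=float)
    Q = np.asarray(target, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise SuperpositionError("point sets must be matching (n, 3) arrays")
    n = P.shape[0]
    if n < 3:
        raise SuperpositionError(f"need at least 3 paired atoms, got {n}")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    if d < 0:
        # a true reflection is only "required" when the point set is
        # genuinely 3-dimensional; near-planar sets are fixed up silently
        if S[-1] > 1e-6 * S[0]:
            raise ChiralityError(
                "optimal superposition requires a reflection; the query "
                "coordinates appear to be mirrored"
            )
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    transform = RigidTransform(R, t)
    rmsd = float(np.sqrt(np.mean(np.sum((transform.apply(P) - Q) ** 2, axis=1))))
    return transform, rmsd


def _ca_of(ls: LabeledStructure, label: ResidueLabel, atom: str) -> np.ndarray | None:
    res = ls.residue_of.get(label)
    if res is None or atom not in res.atoms:
        return None
    return res.atoms[atom].xyz


def orient_template(
    ls: LabeledStructure,
    gyg_index: int = DEFAULT_GYG_INDEX,
    window: int = 2,
) -> tuple[LabeledStructure, RigidTransform]:
    """Put a labelled template into the canonical pore frame, in place.

    The pore axis is the best-fit line through the centroids of symmetric
    Cα quadruples of the filter region (label indices ``gyg_index ± window``
    present in all four repeats); it is mapped onto z with +z extracellular
    (filter above the inner-helix bundle).  The structure is then rotated
    about z so the repeat-III filter-tyrosine Cα has y = 0, x > 0, and
    translated so the filter-tyrosine quadruple centroid is the origin.

    Returns the same (mutated) structure and the transform applied.
    Applying the operation twice gives the identity to numerical precision.
    """
    anchors: dict[int, np.ndarray] = {}
    for r in (1, 2, 3, 4):
        xyz = _ca_of(ls, ResidueLabel(r, "p", gyg_index), "CA")
        if xyz is None:
            raise SuperpositionError(
                f"filter anchor {r}p{gyg_index} (CA) unresolvable; "
                "all four filter tyrosines are required"
            )
        anchors[r] = xyz

    centroids = []
    for idx in range(gyg_index - window, gyg_index + window + 1):
        quad = [_ca_of(ls, ResidueLabel(r, "p", idx), "CA") for r in (1, 2, 3, 4)]
        if all(q is not None for q in quad):
            centroids.append(np.mean(quad, axis=0))
    if len(centroids) < 2:
        raise SuperpositionError(
            "fewer than two complete filter-region quadruples; cannot fit pore axis"
        )
    _, axis = fit_line(np.array(centroids))

    # +z extracellular: the filter sits above the inner-helix bundle
    inner_cas = [
        res.atoms["CA"].xyz
        for lab, res in ls.residue_of.items()
        if lab.segment == "i" and "CA" in res.atoms
    ]
    ref_down = np.mean(inner_cas, axis=0) if inner_cas else np.zeros(3)
    filter_centroid = np.mean(list(anchors.values()), axis=0)
    if np.dot(filter_centroid - ref_down, axis) < 0:
        axis = -axis

    # rotation taking axis -> z
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    s = np.linalg.norm(v)
    c = float(np.dot(axis, z))
    if s < 1e-12:
        R1 = np.eye(3) if c > 0 else rotation_about_axis([1, 0, 0], 180.0)
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R1 = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)

    centroid = filter_centroid
    a3 = R1 @ (anchors[3] - centroid)
    phi = np.degrees(np.arctan2(a3[1], a3[0]))
    R2 = rotation_about_axis(z, -phi)
    R = R2 @ R1
    t = -R @ centroid
    transform = RigidTransform(R, t)
    ls.structure.transform(transform)
    ls.oriented = True
    return ls, transform


def superpose(
    query: LabeledStructure,
    template: LabeledStructure,
    fit_labels: list[ResidueLabel | str] | None = None,
    atom: str = "CA",
    min_pair_fraction: float = 0.8,
    apply: bool = True,
) -> AlignmentResult:
    """Kabsch-superpose a query onto the template over shared labels.

    Labels resolvable in both structures (with the named atom) are paired;
    if fewer than ``min_pair_fraction`` of the requested labels pair, a
    warning is issued; fewer than 3 pairs is an error.  With ``apply``
    the query coordinates are transformed in place and the query inherits
    the template's frame flag.
    """
    if fit_labels is None:
        fit_labels = default_fit_labels()
    labels = [parse_label(l) if isinstance(l, str) else l for l in fit_labels]
    pairs = []
    used: list[str] = []
    for lab in labels:
        q = _ca_of(query, lab, atom)
        t = _ca_of(template, lab, atom)
        if q is not None and t is not None:
            pairs.append((q, t))
            used.append(str(lab))
    if len(pairs) < 3:
        raise SuperpositionError(
            f"only {len(pairs)} of {len(labels)} fit labels pair in both structures"
        )
    if len(pairs) < min_pair_fraction * len(labels):
        warnings.warn(
            f"only {len(pairs)}/{len(labels)} fit labels paired "
            f"(< {min_pair_fraction:.0%}); alignment may be unreliable",
            stacklevel=2,
        )
    P = np.array([p for p, _ in pairs])
    Q = np.array([q for _, q in pairs])
    transform, fit_rmsd = kabsch(P, Q)

    if apply:
        query.structure.transform(transform)
        query.oriented = template.oriented

    # per-segment RMSD in the common frame (no refitting)
    per_segment: dict[str, float] = {}
    groups: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {}
    for lab in sorted(set(query.residue_of) & set(template.residue_of)):
        q = _ca_of(query, lab, atom)
        t = _ca_of(template, lab, atom)
        if q is None or t is None:
            continue
        if not apply:
            q = transform.apply(q)
        groups.setdefault(f"{lab.repeat}{lab.segment}", []).append((q, t))
    for key, pts in sorted(groups.items()):
        qq = np.array([p for p, _ in pts])
        tt = np.array([t for _, t in pts])
        per_segment[key] = float(np.sqrt(np.mean(np.sum((qq - tt) ** 2, axis=1))))

    return AlignmentResult(
        transform=transform,
        fit_rmsd=fit_rmsd,
        per_segment_rmsd=per_segment,
        n_atoms_used=len(pairs),
        labels_used=used,
    )


def rmsd_by_segment(
    query: LabeledStructure,
    template: LabeledStructure,
    selection: list[ResidueLabel | str],
    atom: str = "CA",
) -> float:
    """RMSD over paired Cα of a label selection, in the current frames.

    No refitting is performed: both structures are assumed to already sit
    in the common template frame.
    """
    labels = [parse_label(l) if isinstance(l, str) else l for l in selection]
    diffs = []
    for lab in labels:
        q = _ca_of(query, lab, atom)
        t = _ca_of(template, lab, atom)
        if q is not None and t is not None:
            diffs.append(q - t)
    if not diffs:
        raise SuperpositionError("empty pairing for the requested selection")
    d = np.array(diffs)
    return float(np.sqrt(np.mean(np.sum(d**2, axis=1))))
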