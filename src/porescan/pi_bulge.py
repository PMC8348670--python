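"""π-bulge detection in pore-lining inner helices.

A π-bulge (a one-residue insertion producing a short stretch of π-helix,
i→i+5 backbone hydrogen bonds) rotates and shifts every residue
downstream of it by roughly one helical position.  Three independent
diagnostics are implemented:

* **register scan** over the per-position deviation profile from a
  regular-α reference: downstream of a bulge, position k of the query
  matches position k−1 of the reference better than its own, so a split
  point with a one-position shift drops the mean deviation sharply;
* **axis-distance phase**: the same register scan applied to the helical
  oscillation of Cα distance from the pore axis (maxima/minima shift one
  position downstream of the bulge);
* **hydrogen-bond register**: the direct structural definition — backbone
  carbonyl O(i) accepted by amide N(i+5) (π) instead of N(i+4) (α),
  classified by an N···O distance criterion.

Each detector returns a :class:`BulgeCall`; calls can be combined, with
confidence increasing in the number of agreeing methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .labeling import LabeledStructure, ResidueLabel, parse_label

__all__ = [
    "HelixProfile",
    "BulgeCall",
    "CbOrientation",
    "deviation_profile",
    "axis_distance_profile",
    "detect_bulge_register",
    "detect_bulge_hbond",
    "cb_azimuth",
    "cluster_cb_orientations",
    "combine_calls",
]

#: Relative-improvement threshold for the register scan: a one-position
#: shift must reduce the profile mismatch by at least this fraction.
DEFAULT_THETA = 0.3

#: Hydrogen-bond distance criterion (N···O), Å, for per-donor register
#: classification.
HBOND_CUTOFF = 3.5

#: Distances are clipped here when building the α−π margin profile, so a
#: single fully broken bond cannot dominate the matched filter.
HBOND_DMAX = 4.5

#: Matched-filter template for the H-bond margin profile of a
#: single-residue π-bulge: expected elevation of (d_{i+4} − d_{i+5}) above
#: the α baseline at donor offsets (position − bulge position), calibrated
#: on ideal helix geometry.
HBOND_TEMPLATE_OFFSETS = np.arange(-1, 6)
HBOND_TEMPLATE_WEIGHTS = np.array([0.5, 0.7, 0.7, 1.8, 1.8, 1.5, 0.7])

#: Matched-filter presence threshold (normalised score, Å).
HBOND_SCORE_THRESHOLD = 0.45

MIN_OVERLAP = 8


class ProfileError(ValueError):
    pass


@dataclass
class HelixProfile:
    """Per-position scalar series along one labelled helix."""

    positions: np.ndarray  # strictly increasing label indices
    values: np.ndarray  # Å, >= 0
    kind: str  # "deviation_from_template" | "distance_from_axis"
    helix: str = ""  # e.g. "2i"
    skipped: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.shape != self.values.shape:
            raise ProfileError("positions and values must have equal length")
        if len(self.positions) and np.any(np.diff(self.positions) <= 0):
            raise ProfileError("positions must be strictly increasing")
        if np.any(self.values < 0):
            raise ProfileError("profile values must be non-negative")

    def value_at(self, position: int) -> float | None:
        hits = np.nonzero(self.positions == position)[0]
        return float(self.values[hits[0]]) if hits.size else None

    def to_rows(self) -> list[tuple[int, float]]:
        return list(zip(self.positions.tolist(), self.values.tolist()))


@dataclass
class BulgeCall:
    helix: str
    present: bool
    position: int | None
    position_range: tuple[int, int] | None
    confidence: float
    method: str
    evidence: dict = field(default_factory=dict)

    def to_json(self) -> dict:
        return {
            "helix": self.helix,
            "present": self.present,
            "position": self.position,
            "position_range": self.position_range,
            "confidence": round(self.confidence, 4),
            "method": self.method,
            "evidence": self.evidence,
        }


@dataclass
class CbOrientation:
    label: str
    azimuth: float  # deg, absolute, in [-180, 180)
    relative_azimuth: float  # deg from the outward radial direction
    radial_component: float  # signed, outward positive


def _helix_labels(ls: LabeledStructure, helix: str | tuple[int, str]) -> list[ResidueLabel]:
    if isinstance(helix, tuple):
        repeat, segment = helix
    else:
        repeat, segment = int(helix[0]), helix[1]
    labs = ls.labels(repeat=repeat, segment=segment)
    if not labs:
        raise ProfileError(f"helix {repeat}{segment} has no labelled residues")
    return labs


def deviation_profile(
    query: LabeledStructure, template: LabeledStructure, helix: str | tuple[int, str]
) -> HelixProfile:
    """|Cα_query(ik) − Cα_template(ik)| per shared position, common frame.

    Positions missing a Cα in either structure are skipped and recorded.
    """
    q_labs = _helix_labels(query, helix)
    t_labs = set(_helix_labels(template, helix))
    positions, values, skipped = [], [], []
    for lab in q_labs:
        if lab not in t_labs:
            skipped.append(lab.index)
            continue
        rq = query.residue_of[lab]
        rt = template.residue_of[lab]
        if "CA" not in rq.atoms or "CA" not in rt.atoms:
            skipped.append(lab.index)
            continue
        positions.append(lab.index)
        values.append(float(np.linalg.norm(rq.atoms["CA"].xyz - rt.atoms["CA"].xyz)))
    helix_id = f"{q_labs[0].repeat}{q_labs[0].segment}"
    return HelixProfile(np.array(positions), np.array(values),
                        "deviation_from_template", helix_id, skipped)


def axis_distance_profile(
    ls: LabeledStructure, helix: str | tuple[int, str]
) -> HelixProfile:
    """Cα distance from the pore axis (√(x²+y²)) per position.

    Requires the structure to be in the oriented frame (pore axis = z).
    """
    if not ls.oriented:
        raise ProfileError(
            "structure is not in the oriented frame; run orient_template/superpose first"
        )
    labs = _helix_labels(ls, helix)
    positions, values, skipped = [], [], []
    for lab in labs:
        res = ls.residue_of[lab]
        if "CA" not in res.atoms:
            skipped.append(lab.index)
            continue
        x, y, _ = res.atoms["CA"].xyz
        positions.append(lab.index)
        values.append(float(np.hypot(x, y)))
    helix_id = f"{labs[0].repeat}{labs[0].segment}"
    return HelixProfile(np.array(positions), np.array(values),
                        "distance_from_axis", helix_id, skipped)


def _moving_average(values: np.ndarray, w: int) -> np.ndarray:
    if w < 1:
        return values.copy()
    pad = np.pad(values, w, mode="edge")
    kernel = np.ones(2 * w + 1) / (2 * w + 1)
    return np.convolve(pad, kernel, mode="same")[w : -w]


def _detect_register_axis(
    profile_query: HelixProfile,
    profile_ref: HelixProfile,
    theta: float,
    min_overlap: int,
    detrend_window: int = 3,
) -> BulgeCall:
    """Split scan on the detrended helical oscillation of two axis-distance
    profiles: score(j) = mean |q(k) − r(k)| for k < j plus
    mean |q(k) − r(k−1)| for k ≥ j.  Profiles are detrended (moving-average
    subtraction over roughly one helical turn) so the phase of the
    oscillation, not the slow radial drift, carries the decision."""
    common = np.intersect1d(profile_query.positions, profile_ref.positions)
    if common.size < min_overlap:
        raise ProfileError(f"profile overlap {common.size} < required {min_overlap}")
    qv = profile_query.values - _moving_average(profile_query.values, detrend_window)
    rv = profile_ref.values - _moving_average(profile_ref.values, detrend_window)
    q = {int(p): v for p, v in zip(profile_query.positions, qv)}
    r = {int(p): v for p, v in zip(profile_ref.positions, rv)}

    score_noshift = float(np.mean([abs(q[int(p)] - r[int(p)]) for p in common]))
    candidates = []
    for j_idx in range(2, common.size - 1):  # >= 2 positions in each arm
        j = int(common[j_idx])
        up = [abs(q[int(p)] - r[int(p)]) for p in common[:j_idx]]
        down = [
            abs(q[int(p)] - r[int(p) - 1]) for p in common[j_idx:] if int(p) - 1 in r
        ]
        if len(down) < 2:
            continue
        candidates.append((float(np.mean(up)) + float(np.mean(down)), j))
    if not candidates:
        raise ProfileError("no valid split candidates in the overlap")

    best_score, best_j = min(candidates)
    improvement = 1.0 - best_score / score_noshift if score_noshift > 0 else 0.0
    present = bool(best_score < (1.0 - theta) * score_noshift)
    if present:
        # near-ties between adjacent splits are common; report the centroid
        # of the near-minimal plateau
        thr = best_score + 0.05 * max(score_noshift - best_score, 1e-12)
        plateau = [j for s, j in candidates if s <= thr]
        position = int(round(float(np.mean(plateau))))
    else:
        position = None
    return BulgeCall(
        helix=profile_query.helix,
        present=present,
        position=position,
        position_range=(position - 1, position + 1) if present else None,
        confidence=float(np.clip(improvement, 0.0, 1.0)) if present else 0.0,
        method="register_scan",
        evidence={
            "score_no_shift": round(score_noshift, 4),
            "best_split": best_j,
            "best_score": round(best_score, 4),
            "improvement": round(improvement, 4),
            "theta": theta,
            "profile_kind": profile_query.kind,
        },
    )


def _detect_register_deviation(
    profile_query: HelixProfile,
    profile_ref: HelixProfile | None,
    min_overlap: int,
    smooth_window: int = 2,
    ratio: float = 2.0,
    margin: float = 0.8,
) -> BulgeCall:
    """Change-point detection on a deviation-from-template profile.

    Downstream of a bulge the per-position deviation jumps from the noise
    floor to the inter-position distance scale; the bulge position is read
    off the half-maximum crossing of the smoothed ramp (linear
    interpolation between positions).  ``profile_ref``, when given, is a
    baseline deviation profile (e.g. of a known-regular query) subtracted
    point-wise first.
    """
    if len(profile_query.positions) < min_overlap:
        raise ProfileError("deviation profile too short")
    P = profile_query.positions.astype(float)
    v = profile_query.values.copy()
    if profile_ref is not None:
        ref = {int(p): val for p, val in zip(profile_ref.positions, profile_ref.values)}
        v = np.clip(
            np.array([val - ref.get(int(p), 0.0) for p, val in zip(P, v)]), 0.0, None
        )
    vs = _moving_average(v, smooth_window)

    best = (-np.inf, None)
    for i in range(2, len(vs) - 2):
        t = vs[i:].mean() - vs[:i].mean()
        if t > best[0]:
            best = (t, i)
    jump, i0 = best
    up, down = vs[:i0], vs[i0:]
    present = bool(down.mean() > ratio * up.mean() + margin)
    position = None
    if present:
        thr = (float(np.median(up)) + float(np.median(down))) / 2.0
        for i in range(len(vs) - 1):
            if vs[i] <= thr < vs[i + 1]:
                frac = (thr - vs[i]) / (vs[i + 1] - vs[i])
                position = int(round(P[i] + frac))
                break
        if position is None:
            position = int(P[i0])
    confidence = float(np.clip(jump / (down.mean() + 1e-12), 0.0, 1.0)) if present else 0.0
    return BulgeCall(
        helix=profile_query.helix,
        present=present,
        position=position,
        position_range=(position - 1, position + 1) if present else None,
        confidence=confidence,
        method="register_scan",
        evidence={
            "upstream_mean": round(float(up.mean()), 4),
            "downstream_mean": round(float(down.mean()), 4),
            "jump": round(float(jump), 4),
            "profile_kind": profile_query.kind,
        },
    )


def detect_bulge_register(
    profile_query: HelixProfile,
    profile_ref: HelixProfile | None = None,
    theta: float = DEFAULT_THETA,
    min_overlap: int = MIN_OVERLAP,
) -> BulgeCall:
    """Register scan: does a one-position shift explain the query profile?

    Dispatches on profile kind.  For axis-distance profiles (both
    profiles required) every candidate split j is scored as the mean
    in-register deviation upstream plus the mean one-position-shifted
    deviation downstream, on detrended oscillations; a bulge is called
    when the best split improves on the no-shift score by more than
    ``theta``.  For deviation-from-template profiles the downstream jump
    itself is the signal and the bulge position is the half-maximum
    crossing of the ramp.
    """
    if profile_query.kind == "distance_from_axis":
        if profile_ref is None:
            raise ProfileError("axis-distance register scan needs a reference profile")
        return _detect_register_axis(profile_query, profile_ref, theta, min_overlap)
    return _detect_register_deviation(profile_query, profile_ref, min_overlap)


def detect_bulge_hbond(
    ls: LabeledStructure,
    helix: str | tuple[int, str],
    cutoff: float = HBOND_CUTOFF,
    score_threshold: float = HBOND_SCORE_THRESHOLD,
) -> BulgeCall:
    """Backbone H-bond register test: α (O(i)←N(i+4)) vs π (O(i)←N(i+5)).

    Each donor amide N(k) is classified by comparing its distances to the
    two candidate acceptors O(k−4) and O(k−5): the per-donor register (the
    nearer acceptor within ``cutoff``) is reported as evidence, and the
    margin profile m(k) = d(k−4) − d(k−5) (distances clipped at
    ``HBOND_DMAX``) is correlated against the matched-filter template of a
    single-residue π-bulge.  A bulge is called where the normalised
    correlation exceeds ``score_threshold`` — far more robust to
    coordinate noise than per-donor votes.  Positions with missing
    backbone atoms are skipped and recorded.
    """
    labs = _helix_labels(ls, helix)
    index_of = {lab.index: lab for lab in labs}
    helix_id = f"{labs[0].repeat}{labs[0].segment}"
    margins: dict[int, float] = {}
    registers: dict[int, str] = {}
    skipped: list[int] = []
    for lab in labs:
        donor = ls.residue_of[lab]
        if "N" not in donor.atoms:
            skipped.append(lab.index)
            continue
        n_xyz = donor.atoms["N"].xyz
        d: dict[int, float] = {}
        for shift in (4, 5):
            acc_lab = index_of.get(lab.index - shift)
            if acc_lab is None:
                continue
            acceptor = ls.residue_of[acc_lab]
            if "O" not in acceptor.atoms:
                skipped.append(acc_lab.index)
                continue
            d[shift] = float(np.linalg.norm(n_xyz - acceptor.atoms["O"].xyz))
        if 4 in d and 5 in d:
            margins[lab.index] = min(d[4], HBOND_DMAX) - min(d[5], HBOND_DMAX)
        within = {s: v for s, v in d.items() if v <= cutoff}
        if within:
            registers[lab.index] = "alpha" if min(within, key=within.get) == 4 else "pi"

    if len(margins) < MIN_OVERLAP:
        raise ProfileError("too few donors with complete backbone for H-bond scan")

    baseline = float(np.median(list(margins.values())))
    full_w2 = float(np.sum(HBOND_TEMPLATE_WEIGHTS**2))
    best_score, best_b = -np.inf, None
    ks = sorted(margins)
    for b in range(ks[0] - int(HBOND_TEMPLATE_OFFSETS.min()),
                   ks[-1] - int(HBOND_TEMPLATE_OFFSETS.max()) + 1):
        s = w2 = 0.0
        for off, w in zip(HBOND_TEMPLATE_OFFSETS, HBOND_TEMPLATE_WEIGHTS):
            k = b + int(off)
            if k in margins:
                s += w * (margins[k] - baseline)
                w2 += w * w
        if w2 < 0.7 * full_w2:  # too much of the template falls off the helix
            continue
        score = s / w2
        if score > best_score:
            best_score, best_b = score, b

    present = bool(best_score > score_threshold)
    position = best_b if present else None
    pi_donors = sorted(k for k, v in registers.items() if v == "pi")
    runs: list[list[int]] = []
    for k in pi_donors:
        if runs and k == runs[-1][-1] + 1:
            runs[-1].append(k)
        else:
            runs.append([k])
    return BulgeCall(
        helix=helix_id,
        present=present,
        position=position,
        position_range=(position - 1, position + 1) if present else None,
        confidence=float(np.clip(best_score, 0.0, 1.0)) if present else 0.0,
        method="hbond_register",
        evidence={
            "registers": {str(k): v for k, v in sorted(registers.items())},
            "pi_runs": runs,
            "matched_filter_score": round(float(best_score), 4),
            "skipped": sorted(set(skipped)),
            "cutoff": cutoff,
        },
    )


def combine_calls(calls: list[BulgeCall], tolerance: int = 1) -> BulgeCall:
    """Merge per-method calls into a consensus.

    Present if a majority of methods agree a bulge exists and their
    positions agree within ``tolerance``; confidence is monotone in the
    number of agreeing methods.
    """
    if not calls:
        raise ValueError("no calls to combine")
    helix = calls[0].helix
    positive = [c for c in calls if c.present and c.position is not None]
    n = len(calls)
    if not positive:
        return BulgeCall(helix, False, None, None, 0.0, "consensus",
                         {"methods": [c.method for c in calls], "n_agree": 0})
    center = int(round(float(np.median([c.position for c in positive]))))
    agreeing = [c for c in positive if abs(c.position - center) <= tolerance]
    present = len(agreeing) * 2 > n or len(agreeing) == n
    conf = (len(agreeing) / n) * float(np.mean([c.confidence for c in agreeing]))
    position = int(round(float(np.mean([c.position for c in agreeing]))))
    return BulgeCall(
        helix,
        present,
        position if present else None,
        (position - tolerance, position + tolerance) if present else None,
        conf if present else 0.0,
        "consensus",
        {"methods": [c.method for c in calls], "n_agree": len(agreeing)},
    )


def cb_azimuth(ls: LabeledStructure, label: ResidueLabel | str) -> CbOrientation:
    """Orientation of the Cα→Cβ bond about the pore axis.

    ``azimuth`` is the absolute angle of the xy-projected Cα→Cβ vector;
    ``relative_azimuth`` measures it from the outward radial direction at
    the Cα (C4-invariant, used for clustering); ``radial_component`` is
    the outward projection (positive = Cβ points away from the pore axis).
    Glycine (no Cβ) is an explicit error.
    """
    if not ls.oriented:
        raise ProfileError("structure is not in the oriented frame")
    if isinstance(label, str):
        label = parse_label(label)
    res = ls.residue_of.get(label)
    if res is None:
        raise ProfileError(f"label {label} not assigned")
    if res.name == "GLY" or "CB" not in res.atoms:
        raise ProfileError(
            f"residue {label} ({res.name}) has no CB atom; azimuth undefined"
        )
    ca = res.atoms["CA"].xyz
    cb = res.atoms["CB"].xyz
    v = (cb - ca)[:2]
    if np.linalg.norm(ca[:2]) < 1e-9:
        raise ProfileError(f"CA of {label} lies on the pore axis; radial undefined")
    radial = ca[:2] / np.linalg.norm(ca[:2])
    azimuth = float(np.degrees(np.arctan2(v[1], v[0])))
    ca_az = float(np.degrees(np.arctan2(radial[1], radial[0])))
    rel = (azimuth - ca_az + 180.0) % 360.0 - 180.0
    if azimuth >= 180.0:
        azimuth -= 360.0
    return CbOrientation(
        label=str(label),
        azimuth=azimuth,
        relative_azimuth=float(rel),
        radial_component=float(np.dot(v, radial)),
    )


def cluster_cb_orientations(
    orientations: list[CbOrientation], seed: int = 0
) -> dict:
    """2-means split of Cα→Cβ orientations on the unit circle.

    Clusters the C4-invariant relative azimuths (as unit vectors, so the
    circular topology is respected).  Returns cluster assignments, the two
    mean angles and their angular separation in degrees.
    """
    from sklearn.cluster import KMeans

    if len(orientations) < 2:
        raise ValueError("need at least two orientations to cluster")
    ang = np.deg2rad([o.relative_azimuth for o in orientations])
    X = np.column_stack([np.cos(ang), np.sin(ang)])
    km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(X)
    means = []
    for k in (0, 1):
        members = X[km.labels_ == k]
        m = members.mean(axis=0)
        means.append(float(np.degrees(np.arctan2(m[1], m[0]))))
    sep = abs((means[0] - means[1] + 180.0) % 360.0 - 180.0)
    return {
        "labels": km.labels_.tolist(),
        "cluster_mean_azimuth": means,
        "separation_deg": float(sep),
    }
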