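# Methods

`porescan` implements a comparative-structure analysis of P-loop channel
pore domains: a shared residue-labelling scheme, a convention-fixed
superposition of all structures into one pore frame, quantitative
detection of π-helix bulges in the pore-lining inner helices, annotated
geometry in the common frame, and a per-residue decomposition of
ligand–channel non-bonded interaction energy. Every stage is exercised
end-to-end on synthetically generated idealized pores whose ground truth
is known by construction.

## Universal residue labels

Structures of different channel families share the pore-module fold but
not author numbering. A label `<repeat><segment><index>` (repeat 1–4 for
subunits/repeats I–IV arranged clockwise viewed from the extracellular
side; segment `o` outer helix, `p` P-loop, `i` inner helix; index = the
residue's position within the segment) names structurally homologous
residues across channels. Labels come from explicit, human-curated
*segment maps* (JSON), never from automatic alignment: an entry maps
`length` consecutive polymer residues of a chain, starting at an author
residue number, onto consecutive label indices. Counting polymer residues
rather than author numbers makes ranges robust to numbering gaps;
insertion codes are distinct residues.

Index anchoring follows the selectivity-filter fingerprint: in potassium
channels the GYG tyrosine carries **p52** (hence the filter threonines sit
at p48/p49 and the P1 helix occupies p37–p47), and the inner-helix
gating-hinge glycine of KcsA-like channels sits at **i14** (so KcsA
I100 = i15, F103 = i18). Bundled maps for the Kv1.2/Kv2.1 template and
KcsA use these anchors.

## Common pore frame and superposition

The reference template is oriented so that the pore axis — the best-fit
line through the centroids of symmetric Cα quadruples of the filter
region (label indices p50–p53 by default) — coincides with z, +z points
extracellular (filter above the gate), the repeat-III filter-tyrosine Cα
lies in the xOz plane with x > 0, and the filter-tyrosine quadruple
centroid is the origin. Orientation is idempotent to numerical precision.

Queries are rigidly superposed onto the oriented template by a
closed-form least-squares (Kabsch, SVD) fit of Cα atoms paired purely by
identical universal label; the default fit set is the four P1 helices,
positions **p38–p47** (the most 3D-conserved element of the fold). A
reported range of p37–p48 exists in the literature for the same fit; the
range is a config option, p38–p47 being the default. If fewer than 80% of
requested labels pair, a warning is issued; fewer than 3 is an error. A
genuinely required reflection (mirrored coordinates, smallest singular
value > 10⁻⁶ of the largest) raises a chirality error; the near-planar
degenerate case is corrected silently as is conventional. Optimality is
cross-checked in the tests against a brute-force 10°-step rotation-grid
oracle.

## π-bulge detection

A π-bulge — a single-residue insertion producing a short stretch of
i→i+5 backbone hydrogen bonds — retards every downstream residue by
roughly one helical position. Three independent diagnostics are
implemented; all report a position on the inner-helix label scale.

**Deviation register scan.** The per-position deviation profile
|Cα_query(i_k) − Cα_template(i_k)| is flat at the noise floor upstream of a
bulge and jumps to the inter-position distance scale downstream. The
detector smooths the profile (moving average, window 2), finds the
change point maximizing the upstream/downstream mean difference, calls a
bulge when the downstream mean exceeds twice the upstream mean plus a
0.8 Å margin, and reads the position off the half-maximum crossing of the
ramp (linear interpolation between positions).

**Axis-distance register scan.** The distance of inner-helix Cα from the
pore axis oscillates with the ~3.6-position helical period; downstream of
a bulge the extrema shift one position. Both profiles are detrended
(moving-average subtraction over ≈ one turn) to isolate the oscillation
from the slow radial drift, then every candidate split j is scored as the
mean in-register residual upstream plus the mean one-position-shifted
residual downstream; a bulge is called when the best split improves on
the no-shift score by more than θ = 0.3 (configurable — the threshold is
our operationalization of a visual criterion and is flagged as such in
reports). Near-minimal splits are common, so the reported position is the
centroid of the ≤5%-above-minimum plateau.

**Hydrogen-bond register.** For each donor amide N(k) the distances to
the two candidate acceptors O(k−4) (α) and O(k−5) (π) are measured.
Per-donor registers (nearest acceptor within 3.5 Å) are reported as
evidence; the call itself correlates the margin profile
m(k) = d₄(k) − d₅(k), distances clipped at 4.5 Å, against the fixed
response template of a single-residue bulge (weights calibrated on ideal
helix geometry, stored as module constants). This matched filter keeps
the noiseless behaviour of the naive run-of-π-bonds rule (exact
localization) while remaining reliable under 0.3 Å coordinate noise,
where per-donor votes are at the mercy of ~0.5 Å distance noise against
a 0.2–0.4 Å margin.

A consensus call across methods is present when a majority agree within
±1 position; its confidence is monotone in the number of agreeing
methods. One bulge per helix is assumed (a multi-bulge scan is out of
scope). Side-chain reorientation is quantified by the azimuth of the
projected Cα→Cβ bond about the pore axis; the azimuth relative to the
outward radial direction is C4-invariant and is what the 2-means split
(k-means on unit vectors, so the circular topology is respected)
clusters when comparing bulged and regular helices at the conserved
asparagine position i20.

## Pore geometry in the common frame

Cross-structure distances are plain Euclidean distances between selected
atoms of structures sitting in the common frame; the record carries both
accessions and selectors. Axial ion positions are labelled S1, S2, …
from the extracellular side by z-order (declared labels accepted for
synthetic structures); equal z is a degenerate-ordering error.

Ligand binding regions follow an anchor-derived geometric rule rather
than fixed constants, so it transfers across families: the filter-base
plane is the mean Cα z of p48/p49, the gate plane the mean Cα z of i30,
and the cavity radius R_c is 0.7 × the mean axis distance of the i18 Cα
(the pore-facing surface lies well inside the Cα trace; the factor is
documented and reported with every call). Atoms below the gate plane are
*gate*; inside R_c between the planes, *central cavity*; outside R_c in
that slab, *fenestration n/(n+1)* by the azimuthal sector between
adjacent inner helices; above the filter base, *outer pore*. Per-atom
fractions always sum to 1, and rotating a ligand by 90° about the axis
permutes the fenestration label, as it must under C4 symmetry.

## Energetics

Non-bonded energy is a 6-12 van der Waals term,
ε*_ij[(R*_ij/r)¹² − 2(R*_ij/r)⁶] with R*_ij the sum of per-element
Rmin/2 values and ε*_ij their geometric mean, plus Coulomb with the
distance-dependent dielectric ε = 2r:
E = 332.064·q_iq_j/(2r²) kcal/mol (a 1/r² law). Pairs beyond 12 Å are
excluded; a pair under 0.5 Å is an error. Only intermolecular terms are
computed, so no bonded exclusion bookkeeping exists. Hydrogens are
ignored. The bundled per-element parameter table is a reduced,
consolidated set (documented in `data/nonbonded.json`); a full
force-field atom typing is deliberately out of scope because the analysis
products are energy *trends* and per-residue *shares*, not absolute
binding free energies. Charges come from a JSON table keyed by residue
and atom name, validated against declared formal charges (±10⁻³), with an
optional reduced backbone-dipole assignment (amide/carbonyl partial
charges, net-neutral per residue) and an element fallback.

The per-residue partition row i is pair_energy(ligand, residue i); the
grand totals are the sums of the rows in fixed order, so additivity is
exact. The percent column uses the attractive-share convention: residue
total divided by the sum of all attractive (negative) residue totals,
×100 — attractive residues sum to 100%, repulsive residues carry negative
percents. The convention is configurable in the sense that the raw
columns are always present; published "share of binding" percentages
depend on the convention chosen and on the full force-field stack, so
only signs and ranks are treated as reproducible here.

**Pins.** Experimental coordinates are enforced by flat-bottom
restraints: zero within 1 Å of the reference, then k·(d−1)² with
k = 10 kcal/mol (the printed restraint constant), continuous at the
boundary; a linear form 10·(d−1) is selectable because the printed units
admit both readings.

**Pose refinement** is rigid-body (3 translations + 3 rotations) seeded
stochastic descent on pair energy + pin energy: Gaussian proposals
(0.3 Å / 8° steps) accepted only downhill, with periodic Nelder–Mead
polish. Acceptance strictly downhill makes the accepted-energy trace
non-increasing by construction, and the run is deterministic given its
seed. Side-chain torsions are not refined: the synthetic structures carry
no side chains beyond Cβ, and full flexible refinement belongs to the
internal-coordinate minimization machinery that is out of scope.

## Synthetic pore generator

The generator emulates the conserved pore-module architecture at reduced
realism: four inner helices (35 residues, i1–i35, N-term extracellular)
on an 11 Å bundle radius with a 6° outward splay of the gate ends (an
open-gate bundle), four 11-residue P1 helices whose C-terminal axis ends
point at a focus over the cavity (r = 6.5 Å, z = 15.5 Å, 60° below
horizontal, offset −40° in azimuth so each P1 sits between two inner
helices, which is what creates fenestrations), and a stylized
selectivity-filter column (TTVGYG, p48–p53, Cα at 4 Å radius, carbonyls
pointing at the axis, Cβ outward). Default sequences are poly-Ala with
landmark residues at the conserved positions (I at i15, F at i18, N at
i20). Placement parameters were fixed once to satisfy the generator's
own clash invariant (≥2 Å between chains before noise) across all
fixture bulge positions.

Helices are built by NeRF-style internal-coordinate chain extension with
standard peptide geometry (N–Cα 1.458 Å, Cα–C 1.525 Å, C–N 1.329 Å,
ω = 180°, planar carbonyl, tetrahedral Cβ); the α defaults
(φ,ψ) = (−57°,−47°) yield a 1.56 Å rise and 3.62 residues/turn. A π-bulge
is a 5-residue stretch of (φ,ψ,τ) = (−48°,−80°,117°) centred on the
requested position: these constants were chosen so that five π residues
span the rise *and* twist of four α residues — the geometric content of a
single-residue insertion, which is what shifts every downstream residue
by one position — while forming i→i+5 rather than i→i+4 hydrogen bonds
(the widened N–Cα–C angle matches the known distortion of real
π-helices; the textbook π dihedrals alone reproduce neither property
under ideal covalent geometry). A bulged helix is anchored by its regular
N-terminal part, so the perturbation propagates downstream as in real
structures.

Gaussian coordinate noise (per coordinate, σ in Å) is applied after
assembly, never to the ground truth; a seed is mandatory whenever
σ > 0 and regeneration is byte-identical. Ligands are rigid point-charge
bodies; ions are single atoms at declared axial sites.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: side chains beyond Cβ (so steric drug contacts
and rotamer effects are absent), P2 helices and real P-loop turn
geometry, lipids and detergents, heterogeneous per-repeat architecture of
eukaryotic Nav/Cav channels, experimental-map artefacts (anisotropic
uncertainty, unmodelled density, alternate conformations beyond the
altloc rule), and real bulge irregularity (real π-stretches are not five
identical residues). The detectors' 95%+ recovery under synthetic noise
is therefore a statement about the estimators given the insertion
geometry, not a clinical error rate on cryo-EM models.

## Study conditions and problem sizes

The quantitative conditions used by the tests, the analysis scripts and
`scripts/acceptance.py`: single-bulge pores with the bulge at i12…i21 in
repeat II; noise σ ∈ {0, 0.3} Å per coordinate; α-only negative
controls. Recovery is scored as a present call within ±1 position of
ground truth. The default runs use 10 noiseless cases, 60–80 noisy cases
and 60–80 negative controls per detector, and 5 replicates per noise
level for the superposition benchmark — sizes at which the whole suite
completes in a couple of minutes while leaving the success criteria
(100% noiseless, ≥95% noisy, ≤5% false positives) well resolved.

## Known limitations

Real-structure reproduction requires per-channel segment maps; bundled
maps cover only the Kv1.2/Kv2.1 template and KcsA, anchored on in-text
label assignments — maps for other families must be curated by the user
from an authoritative alignment. Downloading deposited structures needs
network access (`porescan.fetch`); everything else runs fully offline.
The energy model is a reduced scoring function: absolute values and
percentage splits are convention- and parameter-dependent; only signs,
ranks and symmetry relations are treated as robust observables. The
register detectors assume at most one bulge per helix, and the atypical
repeat-II bulge patterns seen in some L-type calcium-channel structures
are a stress case for the single-split model rather than a guaranteed
call.
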