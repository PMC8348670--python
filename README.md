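# porescan

Comparative structural analysis of P-loop channel pore domains.

P-loop channels — potassium, sodium and calcium channels, TRP channels,
ionotropic glutamate receptors — share one pore-module fold: four
inner (S6) helices lining the ion pathway, four P-loops carrying the
selectivity filter, and short P1 helices whose dipoles point into the
central cavity. Hundreds of deposited structures hold drugs, lipids and
permeant ions in this module, but every family has its own residue
numbering and every entry its own orientation, which makes direct
comparison painful. `porescan` gives structural pharmacologists and
channel biophysicists a pipeline that makes such comparisons
quantitative:

* **universal residue labels** `<repeat><segment><index>` (e.g. `2i19`,
  `3p48`) assigned from explicit per-channel segment maps, so homologous
  residues share a name across families;
* **convention-fixed superposition**: the template is oriented with the
  pore axis on z (+z extracellular) and the repeat-III filter tyrosine on
  +x, and each query is Kabsch-fitted on the P1-helix Cα set (labels
  p38–p47 × 4), the most conserved element of the fold;
* **π-bulge detection** in inner helices by three independent
  diagnostics — deviation-profile change point, axis-distance register
  scan, and backbone H-bond register (α: O(i)←N(i+4) vs π: O(i)←N(i+5)) —
  with consensus confidence;
* **pore geometry**: cross-structure atom distances in the common frame,
  z-ordered permeant-ion sites (S1…), and ligand binding-region
  classification (central cavity / fenestration n/n+1 / gate) from
  anchor-derived boundaries;
* **energetics**: per-residue partition of ligand–channel non-bonded
  energy (6-12 vdW + Coulomb with the distance-dependent dielectric
  ε = 2r, so electrostatics fall off as 1/r²), flat-bottom pin
  restraints (zero within 1 Å, 10·(d−1)² kcal/mol beyond), and seeded
  rigid-body pose refinement;
* a **synthetic pore generator** that builds idealized C4 pores from
  internal coordinates — with controllable π-bulges, point-charge
  ligands, axial ions and coordinate noise — carrying machine-readable
  ground truth, so the whole pipeline is testable without downloads.

## Worked example

Build a pore with a π-bulge at i15 of repeat II, align it to an α-only
reference and call the bulge:

```bash
porescan synth --out fixtures --seed 17
porescan pibulge fixtures/bulge_i15.pdb --map fixtures/bulge_i15.map.json \
    --ref fixtures/alpha_only.pdb --ref-map fixtures/alpha_only.map.json --helix 2i
```

prints

```
2i: bulge present at i15 (confidence 0.80)
```

— the register scan and the H-bond classifier both localize the bulge at
exactly the position the generator planted it; the confidence is the
consensus over the agreeing methods. The same library calls are available
in Python:

```python
from porescan.labeling import assign_labels
from porescan.superposition import orient_template, superpose
from porescan.pi_bulge import deviation_profile, detect_bulge_register
from porescan.synthetic import PoreSpec, HelixSpec, build_pore

ref, truth = build_pore(PoreSpec())
template = assign_labels(ref, truth.segment_map)
orient_template(template)

inner = [HelixSpec(), HelixSpec(bulge_position=15), HelixSpec(), HelixSpec()]
pore, gt = build_pore(PoreSpec(inner=inner))
query = assign_labels(pore, gt.segment_map)
superpose(query, template)                      # fit_rmsd = 0.000 Å
call = detect_bulge_register(deviation_profile(query, template, "2i"))
print(call.present, call.position)              # True 15
```

The numbered scripts under `analysis/` run the full study on the
synthetic conditions and write their tables under `results/`:
`01_generate_pores.py` (the fixture set), `02_superposition_benchmark.py`
(P1 fit RMSD vs noise; e.g. mean 0.853 Å at σ = 0.5 Å, below the ideal
√3·σ = 0.87 Å displacement because the fit absorbs part of the noise),
`03_bulge_detection.py` (localization within ±1: 100% noiseless,
≥ 96% at σ = 0.3 Å, 0% false positives on α-only helices) and
`04_ligand_energetics.py` (an axial +1 ligand is attracted by the
filter-turn backbone carbonyls, repelled by a permeant K⁺ at
+1.15 kcal/mol, with exactly equal contributions from the four symmetry
mates of every labelled residue).

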