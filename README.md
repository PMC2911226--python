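# cycloscan

Structural comparison of human cyclophilin PPIase domains and an
in-silico S2-pocket specificity screen: tethered Monte-Carlo docking of
all 400 X-Z-Gly-Pro tetrapeptides against a receptor with flexible
gatekeeper sidechains, scored by a binding-energy estimate plus an
S2-penetration distance metric, and rendered as P3×P2 specificity arrays.

## What it does

- **structures** — PDB/mmCIF reading, global sequence alignment (affine
  gaps, BLOSUM62), Kabsch superposition/RMSD, mapping of every family
  member onto the 16 PPIA-numbered active-site reference positions,
  position-121 CsA-competence labels, and loop-region classification.
- **pockets** — gatekeeper-1/3 gap width, S2-rim formal charge, and the
  three-way surface classification (mixed-neutral / acidic / occluded).
- **screen** — tetrapeptide library generation, template-anchored
  placement of the Gly-Pro dipeptide, harmonic tethers, a documented
  LJ + screened-Coulomb + H-bond + torsion-strain scoring model, and a
  numba-accelerated Metropolis sampler over P2/P3 torsions and
  gatekeeper sidechain chi angles. Energies are on an internal scale;
  only orderings and classes are meaningful.
- **report** — 20×20 P3×P2 specificity arrays, energy-vs-distance
  scatter tables, top-N rankings, chemistry-class summaries.
- **synthdata** — deterministic toy receptors with configurable S2-pocket
  depth, gatekeeper gap and rim chemistry, a Gly-Pro template complex,
  and rigid/noise perturbations, so the whole pipeline is testable
  without downloading any structure.

## CLI

```sh
cycloscan synth --scenario aromatic-S2 --seed 7 --out toy.pdb
cycloscan align --ref ppia.pdb --target nktr.pdb --atoms all --out report.json
cycloscan classify --ref ppia.pdb --target nktr.pdb
cycloscan screen --receptor rec.pdb --ref ppia.pdb --template tmpl.pdb \
    --iterations 200000 --seed 1 --out results.tsv
cycloscan report --results results.tsv --out-dir reports/
```

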