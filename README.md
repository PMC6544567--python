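# structalert

Rule-based structural-consequence analysis of missense variants on protein
3D structures.

A missense variant replaces one amino acid in a protein. Whether that
substitution destabilises the folded structure can often be read directly
from the coordinates: does it break a disulfide bond, bury a charge, clash
sterically, open a cavity, or put the backbone in torsion space the new
residue cannot occupy? `structalert` answers this with a transparent,
explainable pipeline rather than a trained black box:

1. **Model building.** From the wild-type coordinates it builds three
   models that share the input backbone bitwise (the backbone is never
   moved): `WT` (wild-type side chains, minor ±5° chi adjustment), `MUTANT`
   (the substituted side chain grafted from ideal geometry, with every side
   chain within 5 Å stripped and repacked by a deterministic clash-minimising
   chi-grid search), and `WT-CONTROL` (wild-type residue retained but the
   whole zone repacked freely — a control for interactions that are unstable
   under repacking alone, which are then excluded from the comparison).
2. **Feature evaluation.** Seventeen geometric damage rules are evaluated:
   disulfide / side-chain H-bond / salt-bridge loss at relaxed distance
   cutoffs (S–S < 3.3 Å, N–O < 3.9 Å, N–O < 5.0 Å; the extra 1 Å absorbs
   side-chain modelling error), burial-class rules driven by relative
   solvent accessibility (buried = RSA < 9%, Shrake–Rupley SASA over a
   theoretical max-ASA reference), a local MolProbity-style clash score
   (≥ 30 with an increase ≥ 18, atoms within 20 Å of the variant Cα),
   dual-probe grid cavity volume changes (≥ 70 Å³, probes 1.4 / 4.0 Å),
   Kabsch–Sander secondary-structure changes, Ramachandran-class
   incompatibilities, cis-proline and bend-glycine replacements. Sixteen
   rules contribute to the overall verdict; "exposed hydrophobic introduced"
   is evaluated but reported only. A single fired alert marks the variant
   structurally damaging.
3. **Benchmarking.** A statistics layer summarises labelled disease/neutral
   cohorts as TPR = TP/NP, FPR = FP/NN, TPR/FPR, MCC and Wald 95% CIs, with
   one-tailed two-proportion z-tests per feature and Benjamini–Hochberg
   correction; McNemar and one-tailed Mann–Whitney tests are included for
   paired-predictor and distribution-shift comparisons.

A deterministic synthetic-structure generator (ideal helices and paired
strands, engineered disulfide / salt-bridge / H-bond partners, burial cages,
carved cavities, labelled cohorts with planted effects) makes every rule
testable without downloading any coordinates.

## Worked example

Build a small two-segment structure whose cysteines form a 2.08 Å disulfide,
then ask what a Cys→Arg substitution does:

```bash
python -c "
from structalert.structure_io import write_pdb
import structalert.synthetic_fixtures as sf
open('ss_pair.pdb','w').write(write_pdb(sf.disulfide_pair(2.08)))"
structalert analyze --pdb ss_pair.pdb --chain A --variant C3R --out-dir out
```

prints

```
Variant C3R (chain A, structure numbering)
Overall: structurally DAMAGING

[ALERT] disulfide breakage
        mutant_disulfides=[], wt_disulfides=[(('A', 3, ''), ('B', 3, ''), 2.08)]
[  ok ] buried pro introduced
[  ok ] clash
...
```

The wild-type model retains the 2.08 Å S–S bond; the arginine mutant has no
sulfur to bond, so the disulfide-breakage alert fires and the variant is
flagged damaging. `out/` also receives the machine-readable JSON report and
the mutant coordinates (`A_C3R_mutant.pdb`). `structalert batch` analyses a
TSV of variants against one structure, and `structalert benchmark` turns
saved reports plus disease/neutral labels into a per-feature
TPR/FPR/ratio/p/p_adj table.

As a library:

```python
from structalert import VariantSpec, build_models, evaluate
import structalert.synthetic_fixtures as sf

s = sf.buried_core("L")                      # leucine buried in a cage
v = VariantSpec("A", 3, "L", "P")
report = evaluate(build_models(s, v), v)
print(report.fired_features())               # ['buried_pro_introduced']
```

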