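# Methods

This note records the models, numerical choices and limitations behind
`structalert`, at the level of detail a maintainer or a careful user needs.

## The model-triple protocol

Given wild-type coordinates and a substitution, three models are built that
share the input backbone (N, CA, C, O) bitwise; the backbone is never moved.
The *repack zone* is the target residue plus every residue with any heavy
atom within 5 Å of any target heavy atom.

* **MUTANT** — the target's side chain is replaced by the mutant type and
  the whole zone is repacked freely.
* **WT** — wild-type side chains are rebuilt from ideal geometry at their
  native chi angles and refined only within a ±5° window per chi ("minor
  adjustment"); ties prefer the native pose.
* **WT-CONTROL** — the wild-type residue is retained but the zone is
  repacked freely, exactly as in MUTANT. If the control changes the
  target's disulfides, side-chain H-bonds or salt bridges relative to WT,
  the corresponding alert is *excluded by control* for that variant: a
  difference that repacking alone produces cannot be attributed to the
  substitution.

### Side-chain placement engine

Side chains are grafted from ideal residue geometry (the chemical-component
dictionary bundled with biotite, heavy atoms only, superimposed on N/CA/C)
and posed by chi rotation about standard chi1–chi4 axes. The search is a
deterministic grid: joint 15° enumeration over chi1/chi2, sequential 15°
passes for chi3/chi4, then one ±5°/±10° refinement sweep per chi; residues
are packed largest-first with one re-refinement sweep over the zone.
Proline is grafted as a rigid ring.

The objective is the summed van-der-Waals overlap beyond 0.4 Å against all
surrounding atoms, with three chemistry-aware exemptions: Cys SG–SG pairs
in the 1.8–2.5 Å window score a −2.0 bond credit instead of a clash (so
repacking can re-form disulfides, which a pure steric objective would
actively avoid); SG–CB contacts of a disulfide at ≥ 2.6 Å and N···O
contacts at ≥ 2.4 Å (potential hydrogen bonds) are not penalised. A
residue's own backbone is outside its scoring context (1-2/1-3 contacts).
Score ties break towards extended (trans) chis in free mode and towards the
native chis in WT mode, making every placement a pure function of its
input. Placements whose residual overlap exceeds 10 Å are flagged as
steric failures in the diagnostics, never raised.

This engine is a deliberately simple, dependency-free repacker: no rotamer
statistics, no energy model, no backbone relaxation. It is not expected to
reproduce any particular packing program's output; what the pipeline relies
on is only the presence/absence of interactions and coarse steric/volume
changes between models built by *the same* engine.

## Geometric substrates

* **SASA** — Shrake–Rupley sphere sampling with a fixed golden-spiral point
  set (960 points, probe 1.4 Å) on heavy atoms; element vdW radii
  C 1.70 / N 1.55 / O 1.52 / S 1.80 Å (bundled table). Points exactly on a
  neighbour's sphere are credited to the lower-index atom, which makes the
  degenerate co-located-atoms case behave like a single sphere.
* **RSA** — residue SASA over the bundled theoretical max-ASA reference
  (Tien-style values), capped at 100%. *Buried* means RSA < 9% (strict).
  Burial for all burial-gated rules is assessed on WT; the mutant RSA
  enters only the buried/exposed-switch rule (state flip plus |ΔRSA| ≥ 5).
* **Torsions** — standard phi/psi/omega with undefined values at termini
  and chain breaks (peptide C–N > 2.5 Å).
* **Ramachandran classes** — point-in-region lookup on bundled coarse
  polygon tables for four residue classes (general / glycine / proline /
  pre-proline), favored ⊂ allowed, outlier = complement. The polygons are
  this package's own coarse convex basins, not a digitization of any
  published contour set; only the three-way classification contract is
  offered. Because the backbone never moves, the disallowed-phi/psi alert
  fires purely through the residue-class change of the table (e.g. a
  glycine-only conformation inherited by a non-glycine mutant).
* **Secondary structure** — Kabsch–Sander electrostatic H-bond energy
  E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol with the amide
  H placed geometrically (1.0 Å from N, opposite the bisector of C(i−1)–N
  and CA–N); bond iff E < −0.5; proline donates nothing. Pattern rules give
  the 8 classes with priority H > E > B > G > I > T > S > C; bends (S) are
  CA-trace curvature > 70°. Exact agreement with any DSSP release is not
  claimed (π-helix edge rules vary); only class changes between models that
  share a backbone are consumed downstream. With a fixed backbone such
  changes can arise only from proline gain/loss, and at the variant's own
  position specifically through β-bridge donors.
* **Clash score** — heavy-atom pairs overlapping ≥ 0.4 Å per 1000 atoms
  among atoms within 20 Å of the variant Cα. No hydrogens are added;
  to compensate, all intra-residue pairs, adjacent-residue
  backbone–backbone pairs (all within 1-4 connectivity) and disulfide
  SG/CB pairs are excluded. Numerical equivalence with MolProbity's
  hydrogen-aware score is explicitly not claimed; the thresholds (mutant
  ≥ 30 and increase ≥ 18) are interpreted on this package's own score.
* **Cavity volume** — dual-probe grid method (0.6 Å grid, 26-neighbour
  connectivity): bulk solvent is the boundary-connected region where a
  4.0 Å probe centre fits, dilated by the probe radius; candidate void is
  everything outside the vdW volume and the bulk; a void component is a
  cavity only if a 1.4 Å probe fits somewhere inside it (mere packing
  crevices are not cavities), and its volume is its full vdW-free space
  with sub-voxel (2×2×2) supersampling at boundaries to suppress grid
  quantization. Surface pockets count. WT and MUTANT are compared on
  *total* cavity volume (robust to cavity merging/splitting); the alert
  threshold is |Δ| ≥ 70 Å³.

## The 17 rules

Residue classes: hydrophobic A C F I L M V W; hydrophilic D E H K N Q R;
neutral G P S T Y; negative D E; positive H K R. The verdict vocabulary is
`fired / clear / excluded_by_control / not_applicable` — a rule whose
substrate is missing (e.g. phi/psi at a terminus) is reported
not-applicable, never silently clear. The overall damaging flag is the OR
of the 16 used rules. Ten rules (disulfide breakage, buried Pro introduced,
buried hydrophilic/charge introduced, charge switch, disallowed phi/psi,
charge replaced, buried Gly replaced, cis-Pro replaced, Gly in a bend)
depend only on the wild-type structure and are tagged as such in reports.
"Breaks all H-bonds" means the WT target had ≥ 1 side-chain H-bond
(side-chain/side-chain and side-chain/main-chain counted jointly, N–O
distance criterion only, sequence-adjacent main-chain partners excluded)
and the MUTANT target has none; salt-bridge breakage is analogous over
opposite-charge side-chain N–O pairs.

## Sequence-to-structure mapping

Variants given in protein-sequence numbering are mapped onto author
numbering by global alignment of the sequence against the chain's observed
residues (BLOSUM62, gap open −10 / extend −0.5), rejected below 30%
identity (configurable). Modified residues (MSE and friends) map to their
parent amino acid and are flagged. Alternate locations collapse to the
highest-occupancy conformer (ties: 'A', then lexicographic); only the
first MODEL of multi-model files is read.

## Synthetic structures and what they do (and do not) show

The generator builds peptides from ideal internal coordinates by
torsion-driven extension, with side chains at requested chi angles
(default trans). Engineered fixtures place interactions at *exact*
requested geometry: disulfide pairs with proper CB–S–S stereochemistry,
salt-bridge and H-bond partners at requested N–O distances (approach
azimuth and spin chosen by deterministic clearance scans), burial cages of
single-carbon blockers on two Fibonacci shells (radii 5.4/8.8 Å, ≥ 3 Å
spacing — opaque to solvent yet clash-free and outside the repack zone),
carved cubic voids whose wall vdW surfaces sit exactly at the requested
void size, and paired fully extended glycine strands whose exact 2-residue
periodicity sustains a complete H-bond ladder (register constants derived
once by scan and frozen). Gaussian coordinate jitter emulates
homology-model error, optionally sparing the backbone as homology models
largely do.

Labelled cohorts plant per-feature firing: each variant is assigned a
feature round-robin and fires it with the planted probability (seeded);
firing variants use a fixture/substitution verified to trip exactly that
rule, non-firing variants use a benign surface substitution. Passing the
cohort tests therefore shows that the pipeline wiring, the rule logic and
the statistics recover planted ground truth — it does not show calibration
on real proteins, where burial, packing and interaction geometry are far
less clean and the alert rates depend strongly on the cohort composition.

Problem sizes used by the test suite and the acceptance script (synthetic
cohorts of 400 variants over ~18 distinct recipe evaluations, fixtures of
30–250 atoms, 960-point SASA, 0.6 Å cavity grids) were chosen so the whole
analysis reruns from scratch in about a minute on one CPU while still
exercising every kernel against an independent oracle.

## Statistics

TPR = TP/NP, FPR = FP/NN, ratio TPR/FPR (infinite at FPR = 0, excluded from
sorting rather than substituted), MCC from the standard product formula,
and Wald 95% CIs (rate ± 1.96·√(rate(1−rate)/N), clamped to [0, 1] —
matching the printed formula rather than Wilson intervals). Per-feature
significance is a pooled one-tailed two-proportion z-test (H1: TPR > FPR;
degenerate pooled proportions return p = 0.5 by convention), corrected by
Benjamini–Hochberg across the 17 features. McNemar uses the exact binomial
for b + c < 25 and the continuity-corrected chi-square otherwise. The
one-tailed Mann–Whitney U uses the exact null distribution for tie-free
samples up to n = 12 and the tie-corrected normal approximation otherwise.
In the planted-cohort test the 16 simultaneous binomial recovery checks are
Bonferroni-corrected so the family-wise error, not the per-check error, is
5%.

## Known limitations

* The repacker has no rotamer statistics or energetics; side-chain poses in
  crowded real-protein environments will differ from dedicated packers.
* H-bond and salt-bridge detection is distance-only (no angular terms,
  no O–O hydrogen bonds, no pi or metal interactions).
* The clash score and the Ramachandran tables are self-consistent
  surrogates, not reproductions of MolProbity's.
* Cavity volumes depend on the grid convention near surfaces; the bundled
  defaults keep WT/MUTANT comparisons consistent, which is what the alert
  consumes.
* mmCIF input, multi-model ensembles, and interface (protein–protein/DNA/
  ligand) features are out of scope.
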