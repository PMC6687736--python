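# dimerdyn

Desk-scale molecular-dynamics trajectory analysis for two-chain helix-bundle
dimers, motivated by the structural biology of anoctamin-5 (ANO5), the
~100-kDa putative intracellular channel/scramblase whose recessive mutations
cause limb-girdle muscular dystrophy type 2L.  The dimerization interface of
such a protein is held by four central α-helices — two per subunit — and
assessing how mutations perturb that interface requires a chain of standard
trajectory analyses: stability gating, interaction occupancies, secondary
structure, interface solvation energetics, and essential dynamics.

`dimerdyn` implements that chain as a tested library, together with a
synthetic-trajectory generator so every analysis can be validated against
exact planted ground truth, and the companion rare-variant filter cascade
used to triage whole-exome candidates in the same kind of study.

## What it computes

* **Synthetic dimers** (`dimerdyn.synthetic`): C2-symmetric four-helix-bundle
  dimer topologies (ideal α-helix geometry, 1.5 Å rise, ~3.6 residues/turn)
  and seeded stochastic trajectories with a machine-readable ground-truth
  manifest: Gaussian concerted motions along planted orthonormal modes,
  Bernoulli on/off hydrogen bonds and hydrophobic contacts at specified
  occupancies, partial helix unwinding, and an initial drift phase before a
  stable plateau.
* **Stability** (`dimerdyn.stability`): Kabsch superposition, backbone RMSD
  series, detection of a stable window of at least 40 ns (slope/SD rule with
  a block-stationarity guard; never a silent full-range fallback), and
  two-pass iterative average structures.
* **Interaction occupancy** (`dimerdyn.interactions`): a hydrogen bond counts
  in a frame iff donor–acceptor distance ≤ 3.2 Å *and* D–H–A angle ≥ 120°;
  a hydrophobic contact iff the minimum distance between two residues'
  side-chain C/S atoms lies in 3.5–5.5 Å.  Occupancy is the percentage of
  window frames in which the interaction is present.  A census of contacts
  between the four central helices summarizes interface integrity, including
  whether helix A1 reaches both B1 and B2 or only one of them.
* **Secondary structure** (`dimerdyn.secondary_structure`): Kabsch–Sander
  hydrogen-bond energy `E = 0.084·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)·332
  kcal/mol` (bond iff E < −0.5), helix from two consecutive i→i+4 turns,
  strand from bridge rules; per-segment and accumulated helical content
  (SSC).
* **Interface energetics** (`dimerdyn.interface`): Shrake–Rupley SASA on a
  deterministic spiral quadrature; interface area
  (SASA_A + SASA_B − SASA_AB)/2; solvation free-energy gain
  ΔG = −Σ σ(element)·ΔSASA with Eisenberg–McLachlan-style atomic solvation
  parameters; and a Monte-Carlo ΔG p-value comparing the observed interface
  patch against random connected surface patches of equal residue count
  (p < 0.5 ⇒ an interaction-specific hydrophobic interface).
* **Essential dynamics** (`dimerdyn.essential_dynamics`): PCA of Cα
  coordinate fluctuations, globally (PCA-1) and over the central helices
  (PCA-2), with projections, r² between PC1 time series, and mode
  animations; plus PCA of the 6 inter-helix centroid distances pooled across
  systems (PCA-3) for comparing projection clouds.
* **Variant triage** (`dimerdyn.variants`): retain a variant iff its ExAC
  minor-allele frequency is absent or < 3% for LGMD-panel genes (< 1%
  otherwise) *and* at least one of Mutation Taster / PolyPhen2 / PROVEAN /
  SIFT calls it damaging; dbscSNV splice flag iff both ada and rf scores
  exceed 0.6; deterministic prioritization (truncating, then splice-flagged,
  then missense by damaging-call count).  A nine-variant ANO5 worked-example
  table ships with the package (`dimerdyn/data/table3_ano5.tsv`; the
  printed columns are reported values, while the Mutation Taster/PROVEAN
  verdicts and the numeric dbscSNV scores are representative placeholders
  consistent with the qualitative annotations).

## Worked example

The numbered drivers under `analysis/` run the full study on two synthetic
runs — a wild-type-like dimer (strong planted interface bonds at 71.9% and
57.4% occupancy, mild unwinding) and a perturbed dimer (weakened bonds,
40% unwinding):

```
$ python analysis/01_simulate.py
$ python analysis/02_stability.py
wildtype: plateau 65.8 ns starting at 4.1 ns (discarded the equilibration
ramp); plateau RMSD 4.26 +/- 0.29 A
$ python analysis/03_interactions_ssc.py
perturbed: census total 38 (intersubunit 23, A1 balance both); accumulated
SSC 80.4%; strongest interchain H-bond 3-916 at 28.9%
wildtype: census total 41 (intersubunit 26, A1 balance both); accumulated
SSC 83.9%; strongest interchain H-bond 3-916 at 74.7%
$ python analysis/04_interface.py
perturbed: interface 402 A^2, dG -10.4 kcal/mol, p 0.005
wildtype:  interface 443 A^2, dG -11.3 kcal/mol, p 0.0
$ python analysis/05_essential_dynamics.py
perturbed: PC1 explains 81.2% (central helices 81.7%); top eigenvalue 34.05 A^2
wildtype:  PC1 explains 71.1% (central helices 71.8%); top eigenvalue 16.33 A^2
r^2 of PC1 projections perturbed vs wildtype: 0.004
PCA-3: 2 components explain 96.5% of the inter-helix distance variance
$ python analysis/06_variants.py
9/9 variants pass the cascade; 1 splice-flagged (p.His841Asp)
```

Reading the numbers: the wild-type-like run keeps its strongest interchain
hydrogen bond at 74.7% occupancy (a *strong* bond; the planted truth was
71.9%), a denser helix-contact census, higher helical content, a larger and
more favourable interface, and small PC1 amplitudes; the perturbed run
loses the persistent bond (28.9%), unwinds more (lower SSC), and its
central helices move with twice the PC1 amplitude — while the r² ≈ 0
between the two PC1 time series shows the concerted motions follow
different patterns.  Outputs land as CSV/JSON under `results/`.

There is also a CLI (`dimerdyn simulate|analyze|contacts|interface|ed|
variants|report`) wrapping the same functions.

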