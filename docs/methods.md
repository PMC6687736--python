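# Methods

This note documents the models, conventions and numerical choices behind
`dimerdyn`, and what the synthetic test bed does and does not establish
about real trajectories.

## Dimer numbering

A two-chain topology uses a single *dimer numbering*: chain A keeps its
1-based local residue indices; chain-B residue *i* is numbered *i* + 913,
the subunit length of the anoctamin-5 system that motivates the package.
For an ANO5-sized subunit the four central interface helices map as
A1 609–639 ↔ B1 1522–1552 and A2 692–715 ↔ B2 1605–1628.  (Published
helix tables for this system sometimes quote B1 as starting at 1523, which
is off by one against the A2/B2 offset; the uniform +913 rule is adopted
everywhere.)  Ranges are inclusive, coordinates are in Å, angles in
degrees.

## Synthetic trajectory generator

The generator is a *statistical* emulator, not a physical simulator: no
force field, thermostat, solvent or membrane.  The analyses under test are
statistical properties of frame stacks, so the test bed plants exactly the
statistical structure those analyses are supposed to measure, with exact
per-frame draw logs.  Frames are stamped at a nominal save interval
(2 ps by default, matching common production settings, so 40 ns ↔ 20,000
frames); fixtures and the analysis study use a scaled 100 ps interval to
keep run sizes desk-scale, and every ns↔frame conversion is taken from the
trajectory metadata, never hard-coded.

* **Geometry.** Ideal α-helices are built residue-by-residue by NeRF
  (natural extension reference frame) placement with Engh–Huber-like bond
  geometry and φ/ψ = (−57°, −47°), giving a rise of ≈1.5 Å/residue and
  ≈3.6 residues/turn.  A monomer is helix–loop–helix; the four helices sit
  on the corners of a square (default side 10 Å) with antiparallel
  neighbours, and chain B is chain A rotated by the C2 operator, exact to
  machine precision.  Spacing below twice the backbone helix radius raises
  an overlap error (side chains are allowed to interdigitate).  The default
  helix sequence cycles Leu-Ala-Ser-Ala, placing hydrogen-bond
  donors/acceptors (Ser OG–HG) and hydrophobic side chains (Leu) on every
  helix.  Loops are glycines strung between helix termini; amide hydrogens
  are placed on every residue with a predecessor.
* **Concerted modes.** Planted modes are built from per-helix rigid
  translations of the Cα atoms (interface breathing along x; an
  intra-chain scissor along y), projected off the 6-dimensional rigid-body
  subspace and orthonormalized.  Mode displacements extend rigidly over
  each residue's atoms, so planted motion never distorts helix internal
  geometry — DSSP labels and backbone hydrogen bonds stay clean under
  arbitrary mode amplitudes.  Default variances are 4 and 1 Ų.  Frame
  amplitudes are i.i.d. Normal(0, σ²).
* **Planted interactions.** Each planted hydrogen bond re-places the
  acceptor-side atoms per frame: formed geometry D–A = 2.9 Å with a D–H–A
  angle of 165°, broken geometry D–A = 4.5 Å (outside the 3.2 Å
  criterion); placement is along the donor's outward direction so no other
  atom of either residue interferes with the criterion.  Only side-chain
  acceptors may be planted (displacing a backbone O would corrupt the
  secondary-structure assignment).  Hydrophobic contacts move one
  designated side-chain atom to 4.5 Å (formed, inside the 3.5–5.5 Å band)
  or 8.0 Å (broken) from its partner, outward from the partner residue.
  Formed/broken states are independent Bernoulli draws at the planted
  occupancy, logged per frame.
* **Unwinding.** An unwound segment (default: a 4-residue central turn of
  helix A1) is replaced, in a Bernoulli-drawn fraction of frames, by an
  extended strand (φ = ψ = 180°) rebuilt from the segment's first-residue
  backbone frame.  This removes the i→i+4 hydrogen bonds through the
  segment, so DSSP calls it non-helical exactly in the drawn frames.
* **Drift.** The drift phase displaces chain B along +x with a quadratic
  decay over the drift frames (fast early relaxation, small slow tail),
  yielding a monotone RMSD ramp against frame 0 followed by a plateau.
  The default amplitude is 8 Å.  A linear decay was tried first and
  rejected: its long uniform tail cannot be separated from a noisy plateau
  by any local stationarity statistic, whereas a quadratic tail decays
  below the fluctuation noise well before the plateau begins.
* **Reproducibility.** All draws come from one `numpy` Generator seeded by
  the manifest; identical seed + manifest yields bit-identical frames.

What passing tests on this generator show: the estimators count, average,
decompose and rank exactly what they claim to, at the stated thresholds,
with correct statistical calibration.  What they do not show: robustness
to force-field artifacts, solvent noise, correlated (non-i.i.d.) bond
dynamics, conformational transitions between basins, or imperfect
experimental structures.  Real-data conclusions still require the usual
convergence diagnostics.

## Stability gating

All downstream statistics are computed over a *stable window* of at least
40 ns.  How stability is judged is rarely reported in application papers;
the rule here is explicit: a candidate window qualifies when (i) the
least-squares slope of its RMSD series is within `slope_tol`
(default 0.01 Å/ns), (ii) its SD is within `sd_tol` (default 0.5 Å), and
(iii) every tenth of the window is itself stationary — block SD within
`sd_tol` and block mean within `sd_tol` of the window mean.  The block
guard exists because a long plateau dilutes a localized equilibration ramp
out of the global statistics; with it, detected windows contain at most a
sub-block sliver of ramp whose deviations are comparable to the noise.
Among qualifying windows the longest wins, ties broken toward the latest
start.  No qualifying window raises an error — never a silent full-range
fallback.  `sd_tol` should be set a small multiple (2–3×) above the
plateau's stationary RMSD spread; the analysis study uses 0.5 Å for its
runs (stationary spread ≈ 0.25–0.3 Å, dominated by the planted
unwinding's bimodal geometry), and the pipeline default is 0.8 Å for the
default 30% unwinding condition.  "Backbone" means N, Cα, C, O.  Average
structures use a two-pass iterative mean (fit to the first frame, average,
re-fit to that mean, re-average).

## Interaction occupancies

Hydrogen bond: D–A ≤ 3.2 Å and D–H–A ≥ 120°, with donors/acceptors from
per-residue chemistry templates; polar hydrogens are placed by idealized
geometry when a structure lacks them (amide H 1.01 Å from N on the
bisector opposite Cα and the preceding C).  Atom-level bonds aggregate to
residue pairs by the *maximum* occupancy over atom pairs (the
union-of-frames alternative would count a pair present when any of its
atom pairs is; it is noted but not the default, since residue tables in
the field report the dominant atom pair).  Hydrophobic contact: minimum
distance over the two residues' side-chain C and S atoms within
3.5–5.5 Å, for *all* residues, not only canonically hydrophobic ones —
contacts through the aliphatic stems of polar residues (e.g. lysine) are
real and counted.  Intra-residue and sequence-adjacent (|Δindex| ≤ 1
within a chain) pairs are excluded.  The census threshold defaults to 10%
occupancy.  Strength vocabulary: strong ≥ 50%, medium 20–50%, periodic
below 20%.

## Secondary structure

Kabsch–Sander energy with the standard 0.084·332 coupling and the −0.5
kcal/mol cutoff; helix (H) from two consecutive i→i+4 turns, strand (E)
from parallel/antiparallel bridge rules, else coil.  Only H matters for
the SSC figures; whether 3₁₀/π subtypes should count as helical is left
out (strict H only).  SSC of a segment is the percentage of residue-frames
labelled H over the window; the accumulated average pools the
residue-frames of all four central helices, i.e. a residue-frame-weighted
mean.  Chains shorter than 5 residues are all-coil, not an error.

## Interface energetics

The module estimates the quantities printed by interface-analysis services
(whose exact internals are not public), so its absolute numbers are
estimator-specific; the tested claims are the geometric and statistical
contracts (analytic sphere areas, zero interface for separated chains, C2
symmetry, additivity, null calibration of the p-value).

* SASA: Shrake–Rupley with a deterministic golden-spiral point set
  (default 256 points/atom; 960 gives the analytic single-sphere area to
  1e-6 relative), Bondi radii (C 1.70, N 1.55, O 1.52, S 1.80, H 1.20 Å),
  probe 1.4 Å.  Orientation dependence of the quadrature is ≈1% at 256
  points — rigid-motion invariance holds to that tolerance.
* Interfacing atom: SASA decreases on complexation; interfacing residue:
  at least one interfacing atom.  Interface area =
  (SASA_A + SASA_B − SASA_AB)/2.
* ΔG = −Σ σ·ΔSASA over buried area with atomic solvation parameters
  σ(C) = +16, σ(S) = +21, σ(N) = σ(O) = −6 cal/(mol·Ų)
  (Eisenberg–McLachlan-style; hydrogens carry no independent term).  The
  table is a module constant and can be overridden.
* ΔG p-value: grow `n_samples` random connected patches of N(res) surface
  residues (surface = per-residue SASA ≥ 1 Ų in the isolated chain;
  adjacency = Cα–Cα within 6 Å); p is the fraction of patches whose
  hypothetical ΔG — burying the patch's whole exposed surface, the same
  σ·area accounting applied to the observed interfacing residues — is more
  favourable than observed.  The observed interface is scored with the
  same hypothetical accounting rather than the complexation ΔG, otherwise
  the two scales are incommensurable and p degenerates to 0 or 1.  Ties
  are broken by a fair coin so the null distribution stays uniform.
  Fixed seed ⇒ bit-identical p.

## Essential dynamics

Cartesian PCA (schemes 1 and 2) subsamples the window uniformly to 2,500
frames, superposes each frame onto the two-pass iterative mean *over the
analysis selection itself* (removing rigid-body motion relative to the
analyzed atoms), builds the 3N covariance and eigendecomposes it.  No mass
weighting — the decomposition is of coordinate fluctuations.  Eigenvector
sign is fixed by making the largest-magnitude component positive, so runs
are comparable and tests deterministic.  r² between PC1 series squares the
Pearson correlation after linear-interpolation resampling to a common
length; it is sign-invariant because eigenvector sign is arbitrary.
Zero-variance series yield an undefined flag (None), never NaN
propagation.

The distance scheme (PCA-3) measures the 6 pairwise Cα-centroid distances
between the four central helices every 50th frame, pools frames across
systems, mean-centers jointly (no z-scoring: the features share units and
comparable scales, and standardizing would re-weight exactly the
amplitude differences the comparison is after) and keeps 2 components.
Per-system clouds are summarized by centroid position and dispersion
(trace of the projection covariance).

In the demonstration study the top PCA mode of the perturbed run is the
planted unwinding itself — partial helix melting appears as the dominant
"concerted motion", roughly doubling the PC1 amplitude relative to the
wild-type-like run while the PC1 time courses decorrelate (r² ≈ 0).
Planted-Gaussian-mode recovery (eigenvalues within sampling error of 4
and 1 Ų, subspace overlap > 0.99) is verified on drift- and unwinding-free
runs, where those modes are the only variance source.

## Variant triage

Frequency clause: MAF < 3% for genes on the LGMD panel, < 1% otherwise;
an absent MAF (not catalogued, including "0" entries) passes.
Pathogenicity clause: at least one damaging verdict among the configured
predictors — default Mutation Taster, PolyPhen2, PROVEAN and SIFT (the
four-tool set; the narrower three-tool variant is a configuration away).
dbscSNV: both ada and rf strictly > 0.6.  Ranking is a deterministic
stand-in for phenotype-ontology prioritizers, which are out of scope:
truncating (nonsense/frameshift) first, then splice-flagged, then missense
by damaging-call count, ties by gene and genomic position.  ACMG codes are
carried as labels only.  The packaged worked-example table contains the
nine reported ANO5 variants with their published frequencies, PolyPhen2/
SIFT annotations and ACMG codes; Mutation Taster and PROVEAN cells are
left absent (their per-variant verdicts are not published) and the
His841Asp dbscSNV scores are representative values (0.78/0.72) consistent
with the published "both > 0.6" statement.

## Problem sizes

The default bundle has 14-residue helices and 4-residue loops (64
residues, 446 atoms per dimer).  The analysis study simulates 700 frames
at a 100 ps save interval (≈70 ns), detects ≥40 ns windows, and runs PCA
on up to 2,500 window frames; occupancy validation uses 20 seeded runs of
500–2,000 frames; the p-value null calibration uses 200 replicates of 100
patches.  These sizes make every statistical interval in the tests sharp
enough to detect real estimator errors while the whole study runs in
minutes on one CPU.

## Known limitations

* The interface estimator reproduces the *form* of service-style interface
  reports, not any service's exact numbers; solvation parameters are a
  single published-style table.
* The DSSP implementation covers H/E/C only (no 3₁₀/π subtyping, no
  torsion-only fallback).
* The stable-window rule is one defensible formalization of "RMSD has
  plateaued"; tolerance defaults travel with the study conditions and must
  be re-examined for data with different noise scales.
* Residue chemistry templates cover Gly/Ala/Val/Leu/Ser/Cys/Met — enough
  for the synthetic systems; unknown residues parse but are excluded from
  chemistry tables with a warning.
* The PCA-3 frame pooling assumes systems share the same four-helix
  definition; nothing aligns heterogeneous helix sets.
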