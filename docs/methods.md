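# Methods

This note records the models, parameter choices and numerical decisions
behind `glp1qsar`, and what the test suite does and does not establish
about real data.

## Potency dataset and the methylation decomposition

Potencies follow the molar convention pEC50 = 9 − log₁₀(EC50[nM]). The
packaged tables carry, per peptide, the 11 residue tokens (closed
vocabulary, validated at load), the cAMP EC50 in nM with a
right-censoring flag for out-of-range (> 1000 nM) measurements, Emax,
and — where one is tabulated — a pEC50. Where both an EC50 and a
tabulated pEC50 exist they can disagree by several tenths of a log unit
(separate assay campaigns with different concentration ranges); the
tabulated pEC50 is treated as authoritative for all downstream analysis,
including for censored peptides that nevertheless carry a pEC50.
Conversions from EC50 are exact and round-trip to 1e−12 relative.

The Cα-methylation decomposition takes the Aib-scan/Ala-scan pair at
each position, subtracts the two pEC50s, and removes the reference
constant obtained from the position-6 parent pair (0.97 log units for
this dataset). Arithmetic is unrounded internally; two-decimal rounding
is display-only. Because the source tables themselves were rounded
before differencing, two positions (1 and 9) disagree with the tabulated
differences by one last-digit unit; the tests therefore compare at
±0.01.

The 31-member regression training set cannot be reconstructed exactly
from the published tables (the exclusion markers are not visible in the
source). The packaged `in_training_31` flag includes all 21 scan
analogs, the three parents, and the seven mono-substituted Phe6 analogs
(2-Br, 2-Cl, 2-CF₃, 2-CH₃, 2-NO₂, 2-CN, 3-CF₃); the one-shot-assayed
2,6-difluoro analog is excluded as not re-validated. This flag controls
only which rows enter demonstration fits and splits; no numerical claim
depends on the exact membership.

Potency profiling bins analogs by fold-loss versus their series parent
into decade classes (≤3×, 3–30×, 30–300×, >300×, censored); the binning
is scale-invariant by construction.

## Interface descriptors

The descriptor layer is a documented surrogate energy model: the
original study computed these quantities with a proprietary modeling
engine whose internal functional forms are unpublished, so absolute
values are not comparable — only consistency across peptides matters,
and the regression re-fits all weights. Everything below is
deterministic and parameterized in `EnergyModelParams` (one JSON-able
dataclass).

**Annotation.** Complexes are read from PDB text (Biopython), bonds are
inferred geometrically (distance below covalent-radii sum + 0.45 Å), and
atoms are classed as polar/apolar hydrogens, apolar carbons, polar
heavies, or members of formally charged groups. Aromatic rings and
charge groups come from a residue template table (canonical amino acids
plus Aib, biphenylalanine, ring-substituted and Cα-methylated
phenylalanines, and the minimal toy residues used by the generator);
templates are user-extensible at run time. Rings must be planar to
0.3 Å. Halogens (F, Cl, Br) are supported because the series' defining
Phe6 modifications carry them.

**Contact detectors** (all brute-force over cross-interface candidates):

| kind | criterion | energy scale |
|---|---|---|
| hydrogen bond | d(H···A) ≤ 2.5 Å and ∠D–H···A ≥ 120°; heavy-atom fallback d(D···A) ≤ 3.5 Å when the structure has no hydrogens | 12 kJ/mol |
| hydrophobic | apolar C···C ≤ 5.0 Å | 2 kJ/mol |
| cation-π | cation center to ring centroid ≤ 6.0 Å, ≤ 45° off the ring normal | 8 kJ/mol |
| π-π | stacked: ≤ 5.5 Å and ≤ 30°; T-shaped: ≤ 7.0 Å and 60–90° | 6 kJ/mol |
| ion-ion | opposite-sign group centers ≤ 6.0 Å | 10 kJ/mol |

Each contact's energy is the (negative) scale times smooth distance- and
angle-ramps in [0, 1], capped at zero. To keep the five channels
orthogonal, aromatic-ring members and formally charged atoms are
excluded from the hydrophobic pair set, and ionized-group atoms from the
hydrogen-bond sets: ring stacking and salt bridges are scored once, in
their own channels, not re-counted as carbon contacts or polar bonds.
The total count and total energy are exact sums of the five channels.

**Binding-energy terms.** Every B\* term is complex minus frozen parts.
Potential terms use Coulomb (solute dielectric 1, k = 1389.35
kJ·Å/mol) and 6–12 Lennard-Jones sums with Lorentz–Berthelot combining
and a smooth 10→12 Å switch; with frozen coordinates the three-way
difference is algebraically the cross-interface pair sum, which is how
it is evaluated (no catastrophic cancellation of intramolecular terms).
Polar solvation is generalized-Born with the molecular-surface radii
(polar H 0.32 Å, other H 1.017, C 1.8, O 1.344, N 1.14, S 2.0; ε_out
= 78), exact in the single-ion Born limit; the off-diagonal screening
terms carry the same 10→12 Å switch so that a complex whose parts lie
beyond the cutoff decomposes to exactly zero binding terms. Nonpolar
solvation is SASA-proportional: −0.06 kJ/mol/Å² on total SASA
(solute–solvent van der Waals) and +0.03 kJ/mol/Å² on apolar SASA
(hydrophobic). Partial charges are a fixed template (polar H +0.40,
N −0.40, O −0.50, S −0.15, polar C +0.45; unit formal charges spread
over ionized groups) — deliberately coarse, declared, and constant
across peptides.

**SASA.** Shrake–Rupley numeric integration over a 256-point golden
spiral (deterministic; doubling the density moves totals by well under
1%). A fixed global point set is not exactly rotation-invariant, so all
SASA-dependent descriptors are evaluated in a canonical molecular frame:
principal axes of the coordinate covariance with signs fixed by the
third (then fifth) projection moments, right-handed. The frame depends
only on the point-cloud geometry, making descriptors invariant under
rigid-body transforms and atom reordering to ~1e−12; frozen parts reuse
the complex's frame, preserving exact separability. Structures with
exactly degenerate principal moments (perfectly symmetric point clouds)
would have an ill-conditioned frame; real and generated complexes are
generic.

**Packing / model-quality surrogates.** Pack3D is the negated
distance-weighted count of non-bonded heavy-atom contacts within 6 Å
(weight 1 − d/6); Pack1D is the negated count of non-bonded heavy-atom
contacts within 4.5 Å that are sequence-local (same chain, residue
separation ≤ 2) or cross-chain; MQ = 0.1·(contact density) − 0.5·(clash
count), with clashes defined as non-bonded heavy pairs under 2.4 Å. The
affine MQ form is additive over non-interacting parts, so all Bind\*
scores vanish exactly for separated complexes.

## Regression engine

OLS is solved by least squares on the design matrix with explicit
rank checking (collinear columns are named in the error). Conventions,
also embedded in every report:

* AIC = n·ln(RSS/n) + 2k with k counting the intercept and the slopes
  (not the error variance); AICc = AIC + 2k(k+1)/(n−k−1).
* Q² = 1 − PRESS/TSS with TSS about the full-sample mean; PRESS uses
  the hat-matrix identity (verified against explicit n refits).
* VIF_j = 1/(1 − R_j²) from auxiliary regressions.
* Stepwise: forward inclusion of the smallest partial-F p-value ≤ α
  (default α = 0.05; a published 0.5 variant is inconsistent with the
  reported one/two-term models and is not the default), then backward
  elimination of any term whose p-value exceeds α. Ties break on
  canonical descriptor-name order, making the result independent of
  candidate-list order.
* Y-randomization permutes the response (seeded) and refits the fixed
  selected term set — it asks whether *this* model's fit could arise by
  chance, not whether a fresh selection would find one;
  cRp² = √R²·√(R² − mean R²_rand), clipped at zero.

A known property of stepwise selection, visible in the simulations: at
per-term α = 0.05 over 26 candidates the forward step examines the
minimum of ~24 null p-values, so at least one spurious term is admitted
in roughly 1 − 0.95²⁴ ≈ 70% of runs even when the true terms are found.
This inflation is inherent to the procedure, and is exactly why the
validation ladder (bounded R²_adj window, AICc ranking, physical
interpretability of terms) exists downstream of the raw selection.

Model selection offers both published protocols: the bounded protocol
labels candidates underfit/pass/overfit against an R²_adj window
(defaults 0.37 — the single-term binding-energy reference fit — and
0.62 — the agreement between two independent experimental assays, which
a computational model should not beat) with significance, VIF and Q²
gates; the algorithmic protocol walks candidates in ascending AICc and
returns the first that passes a physical-interpretability flag.

## Splits and external prediction

All splits sort ascending by pEC50 with ties broken by id, so they are
deterministic and input-order independent. Alternating: odd sorted
positions train (16/15 for n = 31), giving potency-matched sides — each
test member sits exactly one adjacent gap above its matched training
partner. Every-fifth: the fifth member of each full group of five tests
(25/6 for n = 31); trailing partial groups train. Potency-ranked: the
least potent round-half-away-from-zero(f·n) train and the most potent
remainder test, an extrapolation stress test. External predictions
report R²_pred = 1 − SSE/SS(about the training mean) — negative when
worse than the constant training-mean predictor, which is why a
squared-correlation definition is not used — RMSE_pred, best-fit and
through-origin slopes of predicted versus observed, and the mean shift.

## Synthetic data: what it emulates and what it does not

`gen_descriptor_table` defaults mirror the study conditions: n = 31
rows, the 26 canonical descriptor names, two true terms with weights
(0.8, 0.6) on unit-variance predictors and noise σ = √(2/3), giving a
population R² of 0.6 — the regime of the real fit. Collinearity is
induced by a Cholesky mix of a user-specified correlation structure;
infeasible (non-positive-definite) requests are rejected, not repaired.
`gen_toy_complex` realizes each requested interaction with a minimal
atom group at explicit geometry, enforcing a ≥10% margin on every
detector threshold, with planted sites 25 Å apart and decoy atoms far
outside all cutoffs. `gen_scan_dataset` builds parent/Ala/Aib records
with additive per-position effects plus a constant methylation effect
and wires the pairs exactly like the real tables.

Passing tests on these generators establish the *statistical and
geometric machinery*: detector criteria, formula identities, invariances,
selection and validation behavior at the study's sample size. They do
not establish that the surrogate energy model ranks real peptide
complexes as the original engine did, nor that a model trained on real
descriptors extrapolates — the potency-ranked split exists precisely to
probe that failure mode on real data.

## Problem sizes used in the checks

Simulation-based checks run at the study scale (n = 31, p = 26) with
200 seeds for selection-rate estimates, 100 seeds for null rates and
best-subset comparisons, and 200 Y-randomization trials for null-mean
checks; toy complexes stay under ~100 atoms, where the brute-force
detectors and 256-point SASA are exact enough for all stated tolerances.
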