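# Methods

## The problem

The package models the antiproliferative activity of 102 ring-substituted
1-hydroxynaphthalene-2-carboxanilides against two human colon-carcinoma
lines — HCT116 with wild-type p53 (`HCT116+/+`) and with the TP53 gene
deleted (`HCT116-/-`) — and normal human dermal fibroblasts (NHDF).
Activities are IC50 values in µM; entries printed as ">25" are
right-censored at the assay ceiling and entries never measured are missing.
The modeling goal is descriptive 3D-QSAR: which spatial regions around the
shared scaffold raise or lower potency, and which molecules the models
systematically refuse to train on.

## Activity data

`datasets` parses the packaged CSV (one row per compound, three cell-line
columns plus the printed ± uncertainties). Modeling uses
pIC50 = −log10(IC50·10⁻⁶). Censored values are clamped to the 25 µM ceiling
with the censor flag retained (default policy) or excluded; clamping keeps
the full 102-row ensemble that the resampling design assumes. The ±
uncertainties are stored but never propagated — activities enter the models
as point values. "Micromolar activity" means IC50 < 10 µM on HCT116+/+.

Structures are rebuilt from the scaffold plus substituent codes
("2-Cl-3,5-CF3" → Cl at the anilide 2-position, CF3 at 3 and 5); allowed
groups are OCH3, CH3, F, Cl, Br, CF3, NO2. SMILES are canonicalized with
RDKit.

## Structures and alignment

Each compound gets a single low-energy conformer: seeded ETKDG
distance-geometry embedding followed by MMFF94 relaxation (RDKit). Partial
charges are plain Gasteiger charges; the Hückel π-refinement of the
original Gasteiger-Hückel scheme is proprietary, and the plain scheme
reproduces the sign pattern that the electrostatic analysis depends on.

All molecules share a 14-atom core — naphthalene C1…C8a, the phenolic O,
and the amide C/O/N — located by SMARTS matching and ordered canonically
(C1 bears the OH, C2 the carboxamide). Alignment is least-squares
rigid-body superposition (Kabsch SVD) of the mapped core onto the template,
compound 1; the transform is applied to all atoms, so internal geometry is
preserved exactly. RMSD is reported over the 14 core atoms.

## CoMFA fields

A regular lattice at 2.0 Å spacing is grown to cover every aligned
molecule's van der Waals envelope plus a 4.0 Å margin. At each point, for a
probe atom (sp³ C at +1 e by default; C at 0 and H at +1 available):

* steric: Lennard-Jones 6–12, E = Σ ε_ij[(R_ij/r)¹² − 2(R_ij/r)⁶] with
  Tripos-like radii/well depths and geometric-mean combination;
* electrostatic: Coulomb with a distance-dependent dielectric ε(r) = r,
  E = Σ 332.06 q_p q_i / r².

Both are truncated at +30 kcal/mol; the electrostatic term is clipped
symmetrically at −30 (the reference procedure states only the upper cut;
the symmetric floor keeps the matrix conditioned). Columns with energy
variance below 2.0 kcal²/mol² (sample variance, ddof = 1) are discarded.
Exact commercial force-field energies are not reproducible, so field-level
checks are property-based (caps, decay, probe-charge linearity), not
value-matching.

## CoMSA descriptors

The vdW surface of each molecule is sampled quasi-uniformly (Fibonacci
spirals per atom sphere, default 5 points/Å², interior points culled) and
annotated with the Coulomb potential Σ 332.06 q_i/r. A square Kohonen map
(20×20 or 30×30) is trained on the xyz coordinates of the template surface
— compound 8c, the most active analog. Training is online SOM with
exponentially decaying learning rate (0.5 → 0.01) and Gaussian neighborhood
(radius side/2 → 0.5) over 10 epochs, fully seeded. Projection assigns each
surface point to its best-matching neuron only if it lies within the
winning distance md ∈ [0.2, 2.0] Å; each neuron's descriptor entry is the
mean potential of its accepted points, 0 where no point lands (both
aggregation and fill are configurable; the original workflow does not state
them). The result is a fixed 400- or 900-element vector per molecule.

## PLS, validation statistics

PLS1 by NIPALS deflation on centered data; field matrices are not
unit-scaled (CoMFA convention), general descriptor matrices may be.
Statistics:

* q²cv = 1 − Σ(obs−pred)²/Σ(obs−mean(obs))² over m leave-one-out refits,
  with mean(obs) taken over all m objects (the printed formula, implemented
  literally rather than per-fold);
* SDEP = √(Σ(pred−obs)²/n);
* q²test, SDEP on strictly held-out rows.

Model complexity A is the smallest component count attaining the maximal
q²cv. The reference workflow's SAMPLS shortcut is replaced by exact LOO
refits — the statistic is identical, only slower. The implementation is
cross-checked in the tests against scikit-learn's PLSRegression (full
coefficient agreement) and against fold-by-fold least-squares enumeration.

## IVE-PLS

Column stability is |mean(b_j)|/std(b_j) over the coefficient vectors of
the LOO submodels (the resampling behind the ratio is not named in the
reference; LOO matches the surrounding machinery and is reused from the
q²cv pass at no extra cost). The elimination loop removes exactly one
lowest-stability column per step (ties → lowest index), refits, and records
q²cv; the retained subset is the one at the q²cv-maximal step. Degenerate
0/0 stability is defined as 0; nonzero mean with zero spread as +∞.

## Stochastic model validation

The ensemble is repeatedly split 2:1 (68/34 at n = 102) uniformly at
random; per draw the component count is re-selected on the training block,
and q²cv/SDEP plus held-out q²test/SDEP are recorded. "Best" models pass
q²cv ≥ 0.6 and q²test > 0 (a strict-> variant of the first threshold is a
flag). Per-molecule test-set frequency over the best models flags compounds
the good models push out of training. Deterministic splits for
benchmarking: activity-ranked systematic thirds and maximin Kennard-Stone
on the 1-D activity values. The reference run used 10⁶ samplings; the
default desk scale is 10⁴ and the test suite uses 2,000 — the loop is
identical, only the count differs.

## Pharmacophore maps

IVE-selected columns are tallied across resamplings, normalized to [0, 1]
by the maximal count, thresholded at 0.8, and reduced to the top 20% by
weight for display. Each surviving column is classified by the sign of its
mean regression coefficient crossed with the sign of the mean Gasteiger
charge of template atoms within 3 Å of the column's spatial anchor (grid
point, or SOM-neuron codebook position; the 3 Å neighborhood is this
package's definition — the reference does not give one). Maps export as
PDB pseudo-atoms (occupancy = weight, B-factor = class code).

## Chemical-space PCA

Columns with SD < 10⁻⁴ or any missing entry are dropped; the matrix is
centered and by default standardized before PCA (scikit-learn, full SVD).
The original analysis ran on 4,885 Dragon descriptors (2,916 after
preprocessing) and 13 Sybyl parameters; those pools are commercial, so the
package ships an open RDKit block (counts, MW, TPSA, estimated logP, Ro5
terms, …) to exercise the same machinery. The original variance figures
(70.72% at 4 PCs, 79.47% at 2 PCs) are therefore context, not targets.

## DNA-binding spectra

DNA concentration from Beer–Lambert with ε(260 nm) = 6600 M⁻¹cm⁻¹; purity
passes iff A260/A280 > 1.8 (strict). Binding metrics locate the band
maximum of the free and bound spectra inside a search window (default
330–450 nm, the long-wavelength band of the reported dual maxima) and
report hypochromism H% = 100(A_free − A_bound)/A_free with each spectrum
read at its own maximum, Δε =
(A_free − A_bound)/(c·l), and the shift λmax,bound − λmax,free (positive =
red). A flat or edge-maximal window raises an error rather than guessing.

## Synthetic generators

* Latent regression: X holds `n_informative` columns driven by a
  rank-`rank` score matrix (each informative column rescaled to unit
  variance so effect sizes are commensurate with the iid-normal noise
  columns), and a linear response with Gaussian noise σ. Ground truth
  (informative ids, true b) is returned. In the noiseless limit every
  downstream stage recovers it exactly.
* Censored activities: lognormal IC50 draws (log-scale SD 1.0) with the
  location set so the exceedance probability of the 25 µM ceiling equals
  the requested censoring fraction; at fraction 0 the distribution anchors
  at the measured table's ~1.5 µM median and above-ceiling draws are
  rejected.
* Spectra: Gaussian bands on a 1 nm grid over 200–500 nm; the bound band is
  the free band scaled by (1 − H/100) and shifted, plus optional iid noise.

What the generators do not emulate: real descriptor collinearity structure,
heteroscedastic assay error, and the discreteness of substituent space — so
green recovery tests certify the algorithms, not field performance on new
chemistry.

## Problem sizes and numerical choices

The test suite runs IVE recovery at n = 60 with 10 informative + 90 noise
columns over 20 seeds (rank 10, A = 8: with a lower-rank informative block
the ten columns are mutually collinear and full recovery is not
identifiable), and SMV properties at 2,000 samplings of a 102×50 matrix.
The acceptance script models the real 102-compound table end to end
(CoMFA ~300 post-filter columns, 30×30 CoMSA block) with 500 SMV samplings.
Tie-breaks are always toward the lowest column index or smallest A;
all randomness flows from explicit seeds (NumPy PCG64). LOO q² is
undefined for a constant response and raises; PLS component counts are
clamped to the effective rank with a warning.

## Known limitations

* Absolute field energies depend on the LJ parameter table and Gasteiger
  charges; only relative/structural conclusions are meaningful.
* The 14-atom core ordering is canonical within this package; equivalence
  with the original trial alignment holds only up to core numbering.
* One conformer per molecule; no conformational ensembles or docking.
* Censoring is handled by clamping, not by survival-style likelihoods.
* The full-set q²cv on the packaged data (~0.35–0.40 with this open stack)
  sits below the ~0.5 of the commercial-descriptor original; the SMV
  best-model filter (0.6/0) accordingly passes few or no desk-scale
  samples on the real data.
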