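# Methods

This note records the models, conventions and deliberate design choices
behind each module, what the synthetic generators do and do not emulate,
and the package's known limitations.

## Activity curation and pIC50

Raw bioassay records carry an IC50 in nM and a relational qualifier
(`eq`, `gt`, `lt`). Curation produces one row per compound:

- exact duplicates collapse to their median (mean of the central pair for
  even counts);
- qualified records survive only when the inequality pins the compound's
  1000 nM activity class — `> x` with x ≥ 1000 nM (inactive) or `< x` with
  x ≤ 1000 nM (active). A bound such as "> 500 nM" is class-ambiguous and
  is dropped. Surviving qualified records contribute their bound as the
  working IC50; when a compound has both exact and qualified records the
  exact median wins and a `class_consistent` flag records whether all
  survivors agree on the class. This is the only reading of the qualifier
  convention under which it acts as a filter; the operation is idempotent.
- non-positive IC50 values are rejected with a logged reason, never
  silently.

pIC50 = −log₁₀(IC50 in mol/L); 1000 nM ↦ 6.0. The 6.0 threshold is also
the default active/inactive boundary for the classification AUC. (Note
that pIC50 ≥ 6 corresponds to IC50 ≤ 1 µM, not 1 nM.)

## Splits, folds, feature selection

Test size is ⌈n·fraction⌉ with a minimum of 1, so 103 compounds at 10 %
give the conventional 92/11 split. Fold sizes differ by at most one; all
assignments are seeded `numpy.random.default_rng` permutations.

CFS scores a subset S of fingerprint bits by
M(S) = k·r̄_cf / √(k + k(k−1)·r̄_ff), with r̄_cf the mean absolute Pearson
correlation between member bits and activity and r̄_ff the mean absolute
pairwise correlation among members. Pearson against a binary bit is the
point-biserial correlation; a symmetric-uncertainty variant is explicitly
not implemented, because Pearson is the original CFS formulation for
numeric targets and keeps the exhaustive-enumeration oracle trivial.
The search is best-first from the empty set with a priority queue over
subsets, terminating after 5 consecutive expansions that fail to improve
the incumbent (configurable). Zero-variance columns are excluded before
the search. On ≤ 12-feature problems the search empirically attains the
exhaustive optimum; no such guarantee exists in general.

Feature selection defaults to the training set only; selecting on the
full set before splitting leaks test information into the model.

## Validation statistics and decision rules

All statistics are direct sums over paired observed/predicted values, as
defined in the QSAR-validation literature: Q²/R², RTO slopes k, k′ and
coefficients R₀² (observed-side denominator), R′₀² (predicted-side
denominator Σ(Ŷ−Ŷ̄)² — the printed-formula variant, not the observed-side
variant some papers use), CCC, Q²F1/Q²F2/Q²F3, r²m/r′²m/r̄²m and MAE.
Q²F2 equals R² once the external mean is used in both, and is reported
for CV-kind prediction sets with the whole-set mean (there is no external
set in that case). Q²F1 and Q²F3 need the training-set mean, size and sum
of squares, which the harness records on every prediction set.

Near-perfect fits can make R² − R₀² numerically negative; r²m then uses
the absolute value under the square root and the report is flagged. The
Golbraikh–Tropsha rule evaluates Q² > 0.5, R² > 0.6, the RTO ratio
criterion (either variant < 0.1), the slope window (either of k, k′ in
[0.85, 1.15]) and |R₀²−R′₀²| < 0.3; a non-positive R² fails the ratio
criteria explicitly instead of dividing by zero. The Chirico–Gramatica
rule requires CCC ≥ 0.85, each Q²Fn ≥ 0.70 and r̄²m ≥ 0.65, with missing
Q²F values counted as failures rather than skipped.

ROC AUC is computed by the Mann–Whitney midrank formulation, exact under
ties, never by trapezoidal integration of an ROC curve.

## Modelling harness

Learners are consumed through a two-method `fit`/`predict` interface.
Adapters map the six conventional algorithm names (rf, svm, rbf,
adaboost, mlp, knn) to scikit-learn estimators with library defaults —
"rbf" resolves to kernel ridge with an RBF kernel, the closest analog of
a classic RBF network. The test suite exercises the harness only with
trivial reference models (mean, ordinary least squares, one-nearest-
neighbour), so its correctness does not depend on any learner's
internals. Model ranking sorts by descending cross-validated Q², breaks
ties by ascending MAE, then alphabetically.

## Screening analytics

Score tables carry an explicit direction per protocol (`lower_better`
for docking energies); every ranked operation orients scores so larger
is better, and ranking ties are broken lexicographically by compound id
for determinism. EF(x) = (actives in the top ⌈x·N⌉ / ⌈x·N⌉) ÷ (A/N),
the most common enrichment-factor definition; EF(1) is identically 1.
Consensus scoring standardises each protocol over the screened set,
negates lower-better z-scores, and sums — invariant by construction
under positive affine transforms of any protocol's raw scores.
Cognate-pose RMSD deliberately applies **no** superposition (both poses
share the receptor frame) and no graph-symmetry correction; symmetric
ligands can therefore report inflated RMSDs, a documented limitation.

## Negative design

Exclusion logic is a local rule engine: substructure alerts (the RDKit
PAINS catalogue, families A/B/C, enabled by default), property windows
(defaults MW 100–600, cLogP −3–6, HBD ≤ 5, HBA ≤ 10, rotatable bonds
≤ 11 — a standard drug-likeness profile, fully config-driven),
annotation thresholds (pScore ≥ 300 fails, inclusive) and annotation
flags (aggregator). Aggregation and promiscuity are consumed as imported
annotations, not predicted: the published predictors are web services
whose models are not redistributable, and what matters downstream is the
decision logic. Verdicts are independent per compound; a rule that cannot
be evaluated (unparsable SMILES, missing annotation) yields
`not_evaluable`, which fails the compound only in strict mode, and the
compound is never silently dropped.

## Trajectory analytics

Superposition is the Kabsch algorithm (SVD with determinant correction,
proper rotations only). RMSD series fit each frame to **frame 0** on the
protein backbone by default — deviation relative to the initial
structure — and measure over a possibly different selection (ligand,
binding site). RMSF and PCA instead superpose onto the iterated mean
structure (two passes), which removes global rotation and translation
before measuring internal fluctuation. Rg is mass-weighted by default;
PCA covariance is plain Cartesian (mass-weighting off).

Hydrogen bonds use the donor-heavy-atom···acceptor distance (≤ 3.0 Å
default) and the D–H···A angle (≥ 135°), both inclusive at the cutoff;
hydrogens must be explicit, there is no hydrogen inference anywhere in
the package. The 3.0 Å magnitude is consistent with a heavy-atom
distance; whether published cutoffs mean D···A or H···A varies by tool,
so this convention is documented rather than inferred. Occupancy is the
percentage of frames satisfying both criteria; bonds under the 20 %
occupancy cutoff are excluded from the headline table but kept in the
full listing, and average distances are computed over satisfying frames
only.

The binding site is defined as protein residues with any heavy atom
within 5.0 Å (inclusive) of any ligand heavy atom in frame 0, reported
as those residues' backbone atoms by default; this is a plain geometric
convention standing in for pocket-detection services.

The free-energy landscape is the standard Boltzmann inversion of the 2-D
frame histogram over PC1/PC2: G = −k_B·T·ln(n/n_max), k_B·T ≈ 0.596
kcal/mol at the 300 K default (a kJ/mol switch is provided). The
occupied minimum is exactly 0; empty bins carry the maximum finite G
plus an offset and are flagged rather than interpolated. Basins are
counted as occupied local minima whose 8-neighbour rim sits at least a
configurable depth (default 0.5 kcal/mol) above them — on pure-noise
projections this counts many shallow minima, which is the honest answer
for an unstructured landscape.

## Synthetic generators

The generators produce data with the statistical structure each stage
assumes, not realistic chemistry — fingerprints are abstract Bernoulli
bit vectors, no SMILES or 3-D conformers are generated.

- **Fingerprint datasets**: uninformative bits are Bernoulli(p) with p
  drawn once per bit from U(0.05, 0.5), mimicking sparse real
  fingerprints and exercising variance handling in feature selection.
  The planted signal Σwⱼ·bitⱼ is affinely rescaled so the *noiseless*
  signal spans the activity range exactly (default pIC50 4.398–7.721,
  the span of the curated kinase set the generator emulates); Gaussian
  noise (default sd 0.3 pIC50 units) is added after rescaling so its
  units are preserved. Defaults are 103 compounds × 1024 bits with 10
  unit-weight informative bits. The real data's noise level and
  bit–activity structure are unknown; these are conventions chosen to be
  realistic for a curated single-target IC50 set (assay replicate scatter
  of ~0.2–0.4 log units), not estimates.
- **Score sets**: Gaussian per class with a stored direction convention;
  the closed-form AUC Φ(Δ/√(σₐ²+σᵢ²)) provides an analytic target.
- **Trajectories**: frame = rigid_motion ∘ (reference + isotropic
  Gaussian noise). Rotation is applied about the template centroid,
  which keeps Rg invariant by construction. Scheduled hydrogen bonds
  place the acceptor on the donor→hydrogen ray at 2.8 Å (angle 180°,
  conforming) in exactly round(fraction·F) seeded-random frames and at
  5.0 Å otherwise, so scheduled occupancies are exact by construction.

What passing tests on these generators shows: the *analytics* are
correct — formulas, search, decision logic, geometry. What it does not
show: performance on real chemistry (correlated fingerprint bits,
non-linear structure–activity relationships, anharmonic trajectory
dynamics, solvent effects). The generators have no fingerprint bit
correlations beyond chance, no activity cliffs, and harmonic, memoryless
dynamics.

## Problem sizes and numerics

The test suite and the acceptance script run at desk scale, chosen so
every stochastic check has comfortable statistical margin: QSAR runs use
500 compounds × 1024 bits (10 planted bits, noise 0.3), screening runs
2000–4000 compounds per table, trajectory checks use 100–5000 frames on
peptide-sized systems. Metric computations are validated to 1e-10
against direct-summation oracles; PCA trace conservation to 1e-8
relative; FEL bin ratios are exact by construction. Degenerate inputs
(zero observed variance, single-class labels, zero-variance protocols,
collinear fit selections, empty selections) raise explicit errors rather
than returning NaN.

## Interfaces

The package is a library: the importable API plus the narrative scripts
in `examples/` are the interface, and `scripts/acceptance.py` re-runs
the whole pipeline. File adapters cover fingerprint CSV + JSON metadata,
score CSV + direction sidecar, and single/multi-model PDB via biotite;
binary trajectory formats (DCD/XTC) are out of scope — convert to
multi-model PDB upstream.

## Known limitations

- No docking, shape matching, MD propagation, MM/GBSA energetics or
  toxicity prediction — those stages produce this package's *inputs*.
- Heavy-atom pose RMSD without symmetry correction.
- CFS best-first search is a heuristic; optimality is verified only at
  small feature counts.
- The printed exact duplicate-median rule assumes a single assay type;
  mixed-assay heterogeneity is the caller's problem.
- PDB coordinates carry 10⁻³ Å precision; round-trips through PDB are
  only that accurate.
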