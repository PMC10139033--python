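# funnelscreen

Analytics for a multi-stage virtual-screening funnel against a protein
target: from raw bioassay records to a validated QSAR model, from docking
score tables to an enriched, consensus-ranked and negative-design-filtered
hit list, and from MD trajectories to binding-stability evidence.

The package is aimed at computational chemists who run screening campaigns
and want the *decision machinery* — validation statistics, enrichment
analytics, filtering rules, trajectory metrics — as tested, reusable code
rather than as ad-hoc scripts. Docking engines, shape matching and MD
propagation are deliberately out of scope: scores arrive as tables,
trajectories as coordinates.

## What it computes

**QSAR curation and modelling** (`dataprep`, `qsarharness`)

- IC50 curation: duplicate collapse to the median, inequality-qualified
  records kept only when they pin the 1000 nM activity class,
  pIC50 = −log₁₀ IC50 [M].
- Correlation-based feature selection (CFS) over fingerprint bits with a
  best-first subset search maximising
  M(S) = k·r̄_cf / √(k + k(k−1)·r̄_ff).
- Seeded 90:10 splits and k-fold assignments; a model-agnostic
  cross-validation harness over any `fit`/`predict` regressor.

**External-validation statistics** (`valmetrics`)

Every standard acceptance statistic computed from paired (Y, Ŷ):
Q²/R² = 1 − Σ(Y−Ŷ)²/Σ(Y−Ȳ)², the regression-through-origin slopes
k = ΣYŶ/ΣŶ² and k′ = ΣYŶ/ΣY² with their coefficients R₀², R′₀²,
Lin's concordance correlation coefficient (CCC), the external functions
Q²F1/Q²F2/Q²F3, the r²m family, MAE, and a threshold-classification ROC
AUC — plus the Golbraikh–Tropsha rule (Q² > 0.5, R² > 0.6, RTO ratios
< 0.1, slopes in [0.85, 1.15], |R₀²−R′₀²| < 0.3) and the
Chirico–Gramatica rule (CCC ≥ 0.85, Q²Fn ≥ 0.70, r̄²m ≥ 0.65).

**Screening analytics** (`screenfunnel`)

ROC AUC with score-direction handling, enrichment factor EF(x%),
Z-normalised consensus scoring, benchmark score thresholds, top-N ranking
with deterministic tie-breaks, hit-list intersections with Venn sizes, and
cognate-pose RMSD (no superposition, 2 Å pass rule).

**Negative design** (`negdesign`)

A local rule engine over screening hits: PAINS substructure alerts (RDKit
catalogue, families A/B/C), configurable physicochemical windows
(MW, cLogP, HBD, HBA, rotatable bonds), promiscuity exclusion
(pScore ≥ 300) and aggregator flags consumed as annotations.

**Trajectory stability** (`trajstab`)

Kabsch superposition, RMSD time series (backbone / ligand / binding site),
radius of gyration, per-atom and per-residue RMSF, geometric hydrogen-bond
occupancy (3.0 Å donor···acceptor, 135° D–H···A, 20 % occupancy cutoff,
inclusive), Cartesian PCA with global-motion removal, and a free-energy
landscape G = −k_B·T·ln(n/n_max) over PC1/PC2.

**Synthetic data** (`synthio`)

Seeded generators that emulate each stage's inputs: fingerprint datasets
with a planted linear bit–activity signal spanning pIC50 4.398–7.721,
two-Gaussian active/inactive score sets with a closed-form AUC, and
trajectories with Gaussian per-atom fluctuation, rigid-body motion and
exactly scheduled hydrogen-bond geometry.

## Worked example

```bash
python examples/qsar_validation.py
```

prints

```
CFS selected 10 bits (10/10 planted), merit 0.735
10-fold CV:  Q2 = 0.7488  MAE = 0.246 pIC50 units
external:    R2 = 0.8469  CCC = 0.9153  QF1/2/3 = 0.847/0.847/0.793  rm2_bar = 0.733
Golbraikh-Tropsha: PASS; Chirico-Gramatica: PASS
active/inactive AUC at pIC50 >= 6: 0.986
```

Feature selection recovered all ten planted fingerprint bits; the
cross-validated Q² of 0.75 sits at the ceiling set by the generator's
noise; the external statistics clear both acceptance rules, so the model
would be accepted for screening. The other scripts in `examples/` walk
through activity curation, the screening funnel (AUC/EF/consensus/
threshold/intersection), negative design, and trajectory stability in the
same style.

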