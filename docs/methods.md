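# Methods

## Scope and model form

The package implements linear (ordinary-least-squares) 2D-QSAR for a
series of benzisoxazole IP6K1 inhibitors whose activities are expressed
as pIC50 = −log10(IC50/10⁶) with IC50 in micromolar, i.e. molar pIC50.
The modeled equation is a five-term MLR on raw, unscaled descriptor
values; the printed intercept (5.125) and integer-count descriptors only
make sense on raw scales, so no autoscaling is applied to the regression
itself.  Standardized coefficients (b·sd(x)/sd(y)) are computed solely
for descriptor-importance ranking.

## Structure standardization

Input SMILES are canonicalized once at load time: RDKit cleanup
(includes aromatic perception), largest-organic-fragment salt stripping
(fragments compared by heavy-atom count, ties resolved toward higher
molecular weight), then charge neutralization.  The operation is
idempotent; quaternary ammonium centers, which have no removable proton,
legitimately stay charged.  Descriptor computation is performed on the
hydrogen-explicit graph of the standardized parent.

## Descriptors

All five interpretable descriptors are graph invariants; the test suite
checks invariance under 100 random atom renumberings per fixture
molecule, and all pair counts against a naive all-pairs enumeration over
networkx BFS distances that shares no code with the production path.

- **F04[C-C]**: unordered heavy-atom pairs of carbons at shortest-path
  distance 4; fragments are mutually unreachable (distance ∞).
- **H-047**: hydrogens attached to sp³ carbons bearing exactly one
  heteroatom (non-C, non-H) or to sp²/aromatic carbons bearing none.
  The class superscript counts attached heteroatoms; aromatic carbons
  are treated as sp², never sp³.  Halogens count as heteroatoms, which
  is why chloromethane contributes 3.
- **nRCONHR**: distinct R–C(=O)–N(H)–R′ groups whose carbonyl
  substituent R and nitrogen substituent R′ are both non-aromatic
  carbons; N-aryl amides and primary amides are excluded.
- **CMC-50**: 1 iff ALOGP ∈ [1.3, 4.1], AMR ∈ [70, 110], MW ∈
  [230, 390] and nAT ∈ [30, 55], all intervals closed ("between x and
  y" read inclusively, the conventional reading of the qualifying
  ranges); else 0.  nAT counts all atoms including hydrogens; MW uses
  standard atomic weights.
- **CATS2D_lag_TT**: pharmacophore-pair counts.  Typing per heavy atom:
  donor = O/N with ≥1 H; acceptor = any O, or uncharged/anionic
  non-amide N; positive = formally positive atom or basic aliphatic
  amine N (not adjacent to carbonyl, not bonded to an aromatic atom);
  negative = formally negative atom or acidic hydroxyl O
  (carboxylic/sulfonic/phosphonic); lipophilic = Cl/Br/I or carbon with
  only C/H neighbors.  Amide N is excluded from the acceptor class but
  its N–H still grants donor status.  Counts are raw unordered pairs,
  one count per pair; lag 0 counts atoms carrying both types at once.
  Halogens other than Cl/Br/I and sulfur are left untyped — the
  original scheme is ambiguous there, and the typing table is a single
  function that is easy to extend.

**ALOGP/AMR parameterization.**  The atom-contribution logP and molar
refractivity are computed with the Wildman–Crippen atom-classification
system as implemented in RDKit.  The CMC-50 qualifying ranges were
historically calibrated against the earlier Ghose–Crippen/Viswanadhan
parameter set used by commercial descriptor software, so borderline
molecules can flip the binary flag between parameterizations.  This is
the known residual-divergence risk when comparing against descriptor
tables exported from other tools; for such comparisons the import path
(`descriptor_matrix(..., imported=...)`) accepts externally computed
columns, which are provenance-tagged "imported" and never recomputed.
Atoms matching no contribution class are flagged, contribute zero, and
raise a warning.

## Data splitting

The training/test split is systematic on activity rank: sort by pIC50
descending and assign ranks start, start+every, … (defaults 2 and 5,
1-based) to the test set — 29 train / 7 test for 36 compounds.  Ties in
pIC50 are broken by compound id so the split is invariant under input
row order; the original series contains no ties, so this choice is
inert there but makes the operation deterministic everywhere.

## Feature selection

**SFS** adds descriptors greedily.  Candidates are ranked by one of four
scoring functions — R², negative MAE, negative mean Poisson deviance,
negative mean gamma deviance (scikit-learn metrics, all oriented
higher-is-better) — either on the training fit or by 5-fold
cross-validation (seeded shuffled folds; the fold seed is recorded in
the selection report).  The top candidate is retained only if it
improves the model's Q²_LOO by at least 5% (relative by default,
`new ≥ 1.05·old`; an absolute mode is available — "improves by at least
5%" is most naturally relative, and with a non-positive baseline any
strict improvement is accepted).  Growth stops at `max_features`
(default 5) and is additionally capped by the 1:5
observations-per-variable rule.  The increment rule is applied during
growth; applying it only after reaching the cap is possible by setting
the threshold to zero and post-filtering the trace.

**GA** searches subsets of fixed cardinality (5, matching the fixed-size
published models) with tournament selection (size 2), one-point
crossover on the sorted gene lists with duplicate repair, per-gene
bit-swap mutation, and elitism; fitness is Q²_LOO of the OLS fit.
Before the search, columns with variance < 1e-4 are dropped and one of
each pair with |r| > 0.99 removed.  Defaults: population 100,
generations 100, crossover 0.8, mutation 0.05 — conventional GA-MLR
settings, exposed in `GAConfig`; runs are deterministic per seed, the
best individual ever seen is returned, and a population that stays
degenerate for 10 generations triggers an early stop with a notice.

## Validation battery

- Q²_LOO uses the closed-form PRESS residual e/(1−h); points with
  leverage 1 fall back to an explicit refit.  Equality with the
  refit-loop oracle is asserted to 1e-9 on random problems.
- Q²_LMO: 5 random groups, 20 runs (the convention used for the
  leave-many-out statistic elsewhere in this workflow), averaged.
- External: Q²_F1 (reference = training mean), Q²_F2 (test mean),
  RMSEP, test MAE.  The reported MAE in the training block is the
  training-set MAE; the test-set MAE is reported separately.
- r_m² metrics in Roy's original (unscaled) formulation: r_m² =
  r²(1−√(r²−r0²)) with r0² from the through-origin regression of
  predicted on observed, the reverse variant swapping the roles, and
  Δr_m² their absolute difference; a slightly negative radicand is
  clamped to zero with a notice.
- Y-randomization: 100 seeded response permutations by default
  (configurable), cR_p² = R·√(R² − mean R_r²).
- Collinearity: full cross-correlation matrix, max |r|, and VIF_j =
  1/(1−R_j²) from regressing each descriptor on the others with
  intercept; perfect collinearity reports VIF = ∞.
- Applicability domain: leverages on the intercept-augmented training
  design (test compounds projected onto it), warning leverage h* =
  3(p+1)/n, standardized residuals scaled by training RMSE for training
  points and RMSEP for test points (conventional Williams-plot
  practice), structural outliers at h > h*, response outliers at
  |standardized residual| > 3.

Q²_LOO ≤ R² is checked empirically across the simulation suite and
reported when violated rather than asserted — it is a strong regularity
of well-posed OLS problems, not a theorem.

## Synthetic data

The generator mirrors the study's shape: 36 compounds, five mixed
count/binary descriptors (Poisson marginals λ = 8, 0.3, 4, 6 for the
pair counts, amide count, H-047 and lipophilic pairs; Bernoulli p = 0.4
for the drug-likeness flag), the published equation's coefficients as
planted truth, and Gaussian noise σ = 0.2 pIC50 units.  These marginals
put simulated activities in the observed 4.5–7.6 window and keep them
strictly positive so the Poisson/gamma deviance scorers are exercised.
What the simulator does **not** emulate: correlation among descriptors
of real congeneric series, heteroscedastic assay error, and the
discrete structure of real molecules behind the descriptor columns —
passing recovery tests therefore demonstrates the statistical machinery,
not descriptor-calculation agreement with any particular commercial
package.  A sparse count column (the amide count) can be all-zero in
rare draws, in which case OLS correctly refuses the rank-deficient
design.

The planted-recovery property uses the exact sampling standard error
(known σ and design) for its 2-SE band, whose coverage is 95.45% by
construction; the estimated-SE version has Student-t coverage ≈94.5% at
these degrees of freedom and would sit just under a 95% acceptance line
by construction, not by defect.  Single-replicate end-to-end checks use
a 3-SE band so the joint test over five coefficients stays at the ~98%
level.

Fixture molecules carry hand-derived expected values (provenance-tagged
"hand", or "oracle" for the two values frozen from the enumeration
routine) and are re-verified at test time against the brute-force
oracle, so a change in typing rules cannot silently drift past the
suite.

## Frozen models

Both published equations ship as immutable `FrozenModel`s with
coefficients at printed precision (the CATS2D_01_LL coefficient is
stored as 0.100, the printed "+0.1").  The all-descriptor equation is
coefficients-only by design: its GETAWAY/WHIM/Burden/autocorrelation
descriptors depend on conformer generation and proprietary
implementations and are accepted only as imported columns — computing
them "approximately" would misrepresent reproducibility.  Predictions
are affine in the descriptor vector (checked numerically) and JSON
round-trips preserve predictions to 1e-12.  When a training descriptor
matrix is attached, predictions carry a leverage-based in/out-of-domain
flag.

## Problem sizes

Analyses and tests run on the study-sized problems they model: 36
compounds, 5–15 descriptor columns, 50-candidate selection pools, 200
recovery replicates, 50 selector replicates, 100-round Y-randomization.
These sizes match the original experiment's scale; nothing is
down-sampled from it.

## Known limitations

- ALOGP/AMR values (hence borderline CMC-50 flags) follow the
  Wildman–Crippen parameterization, not the Ghose–Crippen tables of
  commercial descriptor software; see above.
- CATS typing of sulfur and of halogens beyond Cl/Br/I is left
  undefined, as in the original scheme's published description.
- The GA reproduces the published models' quality envelope, not the
  exact trajectory of any particular GA implementation, whose internals
  are not documented.
- Whether activity ties in the original series (none are visible) were
  broken by compound index or otherwise is unknowable from the printed
  data; the id-based tie-break documented above is this package's
  choice.
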