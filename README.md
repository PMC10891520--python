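# ip6kqsar

2D-QSAR modeling of benzisoxazole inhibitors of inositol hexakisphosphate
kinase 1 (IP6K1), a target for obesity and metabolic dysfunction.  The
package rebuilds the interpretable linear modeling workflow for this
series as a tested, reusable pipeline: graph-based molecular descriptors,
activity-sorted data splitting, descriptor-subset selection for multiple
linear regression, the complete QSAR validation battery, applicability-
domain analysis, and frozen published equations for predicting new
compounds.

## The model

Activities are pIC50 = −log10(IC50 [M]).  The central artifact is the
interpretable five-descriptor MLR equation ("M09"):

```
pIC50 = +0.169 F04[C-C] − 0.447 CMC-50 − 0.378 nRCONHR
        − 0.275 H-047   + 0.100 CATS2D_01_LL + 5.125
```

with, for n_train = 29: R² = 0.857, Q²_LOO = 0.800, MAE = 0.201, and for
the 7 external compounds Q²_F1 = 0.785.  All five descriptors are pure
functions of the 2D molecular graph:

- **F04[C-C]** — carbon pairs at topological (shortest-path) distance 4;
- **CMC-50** — binary Ghose–Viswanadhan–Wendoloski CMC 50% drug-likeness
  index (1 iff ALOGP ∈ [1.3, 4.1], AMR ∈ [70, 110], MW ∈ [230, 390],
  nAT ∈ [30, 55]);
- **nRCONHR** — aliphatic secondary amide count;
- **H-047** — hydrogens on C1(sp³)/C0(sp²) carbons (superscript =
  attached heteroatoms);
- **CATS2D_01_LL** — lipophilic–lipophilic pharmacophore pairs at
  distance 1.

The companion all-descriptor equation ("M15") is shipped as frozen
coefficients only; its conformer/matrix-based descriptors must be
imported from an external descriptor table.

## Worked example

```python
>>> from ip6kqsar import MoleculeGraph, load_m09, standardize_structure
>>> from ip6kqsar.descriptors import compute_descriptor
>>> m09 = load_m09()
>>> g = MoleculeGraph.from_smiles(standardize_structure("c1ccc2oncc2c1"))
>>> x = {n: compute_descriptor(g, n) for n in m09.names}
>>> x
{'F04[C-C]': 1, 'CMC-50': 0, 'nRCONHR': 0, 'H-047': 4, 'CATS2D_01_LL': 4}
>>> m09.predict_one(x)[0]
4.594
```

The 1,2-benzisoxazole core has one C–C pair at distance 4, four
aromatic C0(sp²) hydrogens, four bonded lipophilic–lipophilic pairs, no
aliphatic secondary amide, and falls outside the CMC-50 windows (it is
far smaller than a drug-sized molecule), so the equation predicts
5.125 + 0.169 − 1.100 + 0.400 = 4.594 pIC50 units.  An all-zero
descriptor vector returns exactly the intercept, 5.125.

The same flow is available from the shell:

```
ip6kqsar split compounds.csv split.csv         # activity-sorted 29/7-style split
ip6kqsar descriptors split.csv X.csv           # five interpretable descriptors
ip6kqsar select-ga X.csv split.csv sel.json    # GA subset search (Q2_LOO fitness)
ip6kqsar validate split.csv X.csv report.json  # full validation battery
ip6kqsar predict new.csv pred.csv              # frozen-equation predictions
ip6kqsar run compounds.csv out/                # everything, with a manifest
```

## Analysis scripts

The numbered drivers under `analysis/` rerun the study workflow on
synthetic data with known ground truth (the compound table of the
original series is not redistributed here) and write their tables under
`results/`:

1. `01_fixture_descriptors.py` — descriptor values for the fixture
   molecules, cross-checked against a brute-force enumeration oracle;
2. `02_simulate_dataset.py` — a 36-compound study-shaped dataset with
   the published coefficients planted as truth plus decoy descriptors;
3. `03_split_fit_validate.py` — 29/7 split, OLS refit, validation
   battery, Y-randomization, Williams plot;
4. `04_model_grid.py` — the 4-scorer × {no CV, 5-fold} SFS grid plus the
   GA, scored by the average of Q²_LOO and Q²_F1;
5. `05_frozen_predictions.py` — frozen-equation predictions for the
   fixture molecules.

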