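#!/usr/bin/env python
"""Apply the frozen interpretable equation to the fixture molecules and
to reference descriptor vectors.

The frozen model is the published five-descriptor equation; its
prediction for an all-zero descriptor vector is the intercept, 5.125
pIC50 units.  For each fixture molecule the five descriptors are
computed from the standardized structure and pushed through the
equation.  (The fixture set is small laboratory chemistry, far from the
benzisoxazole training series, so these predictions exercise the
arithmetic and the pipeline, not medicinal-chemistry claims.)

Writes results/frozen_predictions.csv.
"""

from pathlib import Path

import pandas as pd

from ip6kqsar.dataset import standardize_structure
from ip6kqsar.descriptors import compute_descriptor
from ip6kqsar.molgraph import MoleculeGraph
from ip6kqsar.registry import load_m09
from ip6kqsar.simulate import make_fixture_set

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main():
    RESULTS.mkdir(exist_ok=True)
    m09 = load_m09()
    zero = {n: 0.0 for n in m09.names}
    intercept_pred, _ = m09.predict_one(zero)
    print(f"all-zero descriptor vector -> {intercept_pred} (the equation's intercept)")

    rows = []
    for f in make_fixture_set():
        g = MoleculeGraph.from_smiles(standardize_structure(f.smiles))
        x = {n: compute_descriptor(g, n) for n in m09.names}
        pred, _ = m09.predict_one(x)
        rows.append({"name": f.name, **x, "pIC50_M09": round(pred, 3)})
    df = pd.DataFrame(rows).set_index("name")
    df.to_csv(RESULTS / "frozen_predictions.csv")
    print(df.to_string())
    print(f"-> {RESULTS / 'frozen_predictions.csv'}")


if __name__ == "__main__":
    main()
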