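#!/usr/bin/env python
"""Run the full model-building grid on the simulated dataset: sequential
forward selection under four scoring functions, each without and with
5-fold cross-validation (eight models), plus the genetic algorithm.

This mirrors the original model-screening experiment in which eight
SFS variants competed against a GA-selected model and the winner was
chosen on the average of internal (Q2_LOO) and external (Q2_F1)
predictivity.  Here the planted truth is known, so the table also
records whether each selector recovered the true descriptor support
from among the decoy columns.

Reads results/sim_dataset.csv; writes results/model_grid.csv.
"""

import json
from pathlib import Path

import pandas as pd

from ip6kqsar.dataset import CompoundRecord, Dataset, activity_sorted_split
from ip6kqsar.selection import SCORERS, GAConfig, SFSConfig, ga_select, sfs_select
from ip6kqsar.validation import q2_loo, external_metrics

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 20240263


def main():
    df = pd.read_csv(RESULTS / "sim_dataset.csv").set_index("id")
    truth = json.loads((RESULTS / "sim_truth.json").read_text())
    ds = Dataset(
        [CompoundRecord(id=i, smiles="C", pic50=float(v)) for i, v in df["pic50"].items()]
    )
    labelled = activity_sorted_split(ds)
    tr = [r.id for r in labelled if r.split == "train"]
    te = [r.id for r in labelled if r.split == "test"]
    X = df.drop(columns=["pic50"])
    y = df["pic50"]
    support = set(truth["support"])

    rows = []

    def record(label, result):
        model = result.model
        q2 = q2_loo(X.loc[tr, model.names], y.loc[tr])
        ext = external_metrics(
            model, X.loc[te, model.names], y.loc[te], float(y.loc[tr].mean())
        )
        rows.append(
            {
                "model": label,
                "n_descriptors": len(result.chosen),
                "Q2_LOO": round(q2, 3),
                "Q2_F1": round(ext["Q2_F1"], 3),
                "average": round(0.5 * (q2 + ext["Q2_F1"]), 3),
                "support_recovered": set(result.chosen) == support,
                "chosen": ";".join(result.chosen),
            }
        )

    i = 0
    for cv in (None, 5):
        for scorer in SCORERS:
            i += 1
            cfg = SFSConfig(scoring=scorer, cv_folds=cv, max_features=5, seed=SEED)
            try:
                record(f"SFS-{scorer}-{'cv5' if cv else 'nocv'}", sfs_select(X.loc[tr], y.loc[tr], cfg))
            except ValueError as exc:
                rows.append({"model": f"SFS-{scorer}-{'cv5' if cv else 'nocv'}", "chosen": f"failed: {exc}"})
    record("GA", ga_select(X.loc[tr], y.loc[tr], GAConfig(n_features=5, seed=SEED)))

    grid = pd.DataFrame(rows)
    grid.to_csv(RESULTS / "model_grid.csv", index=False)
    print(grid.drop(columns=["chosen"]).to_string(index=False))
    best = grid.loc[grid["average"].idxmax()]
    print(
        f"\nbest model by (Q2_LOO + Q2_F1)/2: {best['model']} "
        f"(average {best['average']}, support recovered: {best['support_recovered']})"
    )
    print(f"-> {RESULTS / 'model_grid.csv'}")


if __name__ == "__main__":
    main()
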