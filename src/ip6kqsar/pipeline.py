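"""End-to-end orchestration: standardize -> descriptors -> split ->
select -> validate -> applicability domain -> frozen-model export.

Every stage writes a standalone artifact (CSV/JSON) that downstream
subcommands accept as input, and a manifest records the seed, package
versions and input checksums so a re-run with the same config is
byte-comparable.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .dataset import Dataset, activity_sorted_split
from .descriptors import M09_DESCRIPTORS, descriptor_matrix
from .registry import FrozenModel
from .selection import GAConfig, SFSConfig, ga_select, sfs_select
from .validation import validate_model, williams_ad

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    input_csv: str
    output_dir: str
    descriptors: list[str] = field(default_factory=lambda: list(M09_DESCRIPTORS))
    imported_csv: str | None = None  # external descriptor matrix, if any
    split_every: int = 5
    split_start: int = 2
    selector: str = "ga"  # "sfs" | "ga" | "none" (use the descriptor list as-is)
    sfs: SFSConfig = field(default_factory=SFSConfig)
    ga: GAConfig = field(default_factory=GAConfig)
    y_rand_iterations: int = 100
    lmo_groups: int = 5
    lmo_runs: int = 20
    seed: int = 0


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full workflow; returns the manifest dict."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    in_path = Path(cfg.input_csv)
    if not in_path.exists():
        raise PipelineError("load", f"input file {in_path} does not exist")

    # --- load + standardize -------------------------------------------- #
    try:
        ds = Dataset.from_csv(in_path)
    except Exception as exc:
        raise PipelineError("standardize", str(exc)) from exc

    # --- split ---------------------------------------------------------- #
    ds = activity_sorted_split(ds, every=cfg.split_every, start=cfg.split_start)
    ds.to_csv(out / "dataset_split.csv")

    # --- descriptors ---------------------------------------------------- #
    imported = None
    if cfg.imported_csv:
        imported = pd.read_csv(cfg.imported_csv).set_index("id")
    try:
        dm = descriptor_matrix(ds, cfg.descriptors, imported=imported)
    except KeyError as exc:
        raise PipelineError("descriptors", str(exc)) from exc
    if dm.failed_ids:
        raise PipelineError("descriptors", f"structures failed to parse: {dm.failed_ids}")
    dm.to_csv(out / "descriptor_matrix.csv")

    train = ds.subset("train")
    test = ds.subset("test")
    Xtr = dm.values.loc[train.ids]
    Xte = dm.values.loc[test.ids]
    ytr = train.activities()
    yte = test.activities()

    # --- selection ------------------------------------------------------ #
    if cfg.selector == "sfs":
        sel = sfs_select(Xtr, ytr, cfg.sfs)
    elif cfg.selector == "ga":
        sel = ga_select(Xtr, ytr, cfg.ga)
    elif cfg.selector == "none":
        sel = None
    else:
        raise PipelineError("select", f"unknown selector {cfg.selector!r}")
    chosen = sel.chosen if sel is not None else list(dm.columns)
    if sel is not None:
        (out / "selection.json").write_text(json.dumps(sel.to_dict(), indent=2))

    # --- validation + AD ------------------------------------------------ #
    try:
        model, report = validate_model(
            Xtr[chosen],
            ytr,
            Xte[chosen],
            yte,
            y_rand_iterations=cfg.y_rand_iterations,
            lmo_groups=cfg.lmo_groups,
            lmo_runs=cfg.lmo_runs,
            seed=cfg.seed,
        )
    except Exception as exc:
        raise PipelineError("validate", str(exc)) from exc
    report.to_json(out / "validation_report.json")
    (out / "validation_report.md").write_text(report.to_markdown() + "\n")
    ad = williams_ad(model, Xtr[chosen], ytr, Xte[chosen], yte)
    ad.to_csv(out / "williams.csv")

    # --- frozen-model export -------------------------------------------- #
    frozen = FrozenModel(
        name="fitted",
        model=model,
        provenance=f"fitted by ip6kqsar {__version__} from {in_path.name}, seed {cfg.seed}",
        n_train=len(train),
        stats={"R2": report.R2, "Q2_LOO": report.Q2_LOO},
    )
    frozen.to_json(out / "model.json")

    manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "seed": cfg.seed,
        "selector": cfg.selector,
        "descriptors_requested": cfg.descriptors,
        "descriptors_chosen": chosen,
        "n_train": len(train),
        "n_test": len(test),
        "inputs": {str(in_path): _sha256(in_path)},
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.suffix in (".csv", ".json", ".md") and p.name != "manifest.json"
        },
    }
    if cfg.imported_csv:
        manifest["inputs"][cfg.imported_csv] = _sha256(Path(cfg.imported_csv))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
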