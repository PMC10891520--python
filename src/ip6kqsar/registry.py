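"""Frozen MLR models for IP6K1 inhibition and prediction with AD gating.

Two published equations are shipped ready to use:

``M09`` (interpretable descriptors, all computable from a SMILES)::

    pIC50 = +0.169 F04[C-C] - 0.447 CMC-50 - 0.378 nRCONHR
            - 0.275 H-047   + 0.100 CATS2D_01_LL + 5.125

``M15`` (complex topological/conformer descriptors; values must be
imported from an external descriptor table, they are never computed
here)::

    pIC50 = +0.223 VE3sign_B(s) + 3.079 MATS4m + 10.797 SpMax2_Bh(v)
            - 6.694 G3i + 10.984 R5e+ - 33.064

Coefficients are stored at printed precision and are immutable.  When a
frozen model carries a training descriptor matrix, predictions also get
a leverage-based applicability-domain flag.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

import numpy as np
import pandas as pd

from .validation import MLRModel

__all__ = ["FrozenModel", "load_m09", "load_m15", "predict"]


@dataclass(frozen=True)
class FrozenModel:
    """An immutable MLR model with provenance and optional AD reference."""

    name: str
    model: MLRModel
    provenance: str
    n_train: int | None = None
    stats: Mapping[str, float] = field(default_factory=dict)
    ad_reference: pd.DataFrame | None = None  # training descriptor matrix

    def __post_init__(self):
        if not self.provenance:
            raise ValueError("a provenance string is required")
        object.__setattr__(self, "stats", MappingProxyType(dict(self.stats)))

    @property
    def names(self) -> list[str]:
        return list(self.model.names)

    # ------------------------------------------------------------------ #
    def predict_one(self, x: Mapping[str, float]) -> tuple[float, bool | None]:
        """Predict pIC50 for one descriptor vector.

        Returns ``(prediction, inside_ad)``; the AD flag is None when no
        reference matrix is attached.  Missing descriptors raise with
        their names.
        """
        missing = [n for n in self.model.names if n not in x]
        if missing:
            raise KeyError(f"missing descriptors: {', '.join(missing)}")
        vec = np.array([float(x[n]) for n in self.model.names])
        pred = float(self.model.intercept + vec @ np.asarray(self.model.coefficients))
        inside = None
        if self.ad_reference is not None:
            A = np.column_stack(
                [np.ones(len(self.ad_reference)), self.ad_reference[self.model.names].to_numpy(float)]
            )
            a = np.concatenate([[1.0], vec])
            h = float(a @ np.linalg.solve(A.T @ A, a))
            h_star = 3.0 * (len(self.model.names) + 1) / len(self.ad_reference)
            inside = h <= h_star
        return pred, inside

    def predict_frame(self, X: pd.DataFrame) -> pd.Series:
        return pd.Series(self.model.predict(X), index=X.index, name=f"pIC50_{self.name}")

    # ------------------------------------------------------------------ #
    # serialization
    # ------------------------------------------------------------------ #
    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "name": self.name,
                "descriptors": self.model.names,
                "coefficients": self.model.coefficients,
                "standard_errors": self.model.coefficient_se,
                "intercept": self.model.intercept,
                "intercept_se": self.model.intercept_se,
                "n_train": self.n_train,
                "stats": dict(self.stats),
                "provenance": self.provenance,
            },
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    @classmethod
    def from_json(cls, source) -> "FrozenModel":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            data = json.loads(source)
        else:
            with open(source) as fh:
                data = json.load(fh)
        return cls(
            name=data["name"],
            model=MLRModel(
                names=data["descriptors"],
                coefficients=data["coefficients"],
                coefficient_se=data.get("standard_errors"),
                intercept=data["intercept"],
                intercept_se=data.get("intercept_se"),
            ),
            provenance=data["provenance"],
            n_train=data.get("n_train"),
            stats=data.get("stats", {}),
        )


def load_m09() -> FrozenModel:
    """The interpretable five-descriptor IP6K1 inhibition equation."""
    return FrozenModel(
        name="M09",
        model=MLRModel(
            names=["F04[C-C]", "CMC-50", "nRCONHR", "H-047", "CATS2D_01_LL"],
            coefficients=[0.169, -0.447, -0.378, -0.275, 0.100],
            coefficient_se=[0.028, 0.139, 0.131, 0.029, 0.031],
            intercept=5.125,
            intercept_se=0.485,
        ),
        provenance="published IP6K1 benzisoxazole 2D-QSAR, interpretable-descriptor model",
        n_train=29,
        stats={
            "R2": 0.857,
            "R2_adj": 0.826,
            "Q2_LOO": 0.800,
            "MAE": 0.201,
            "rm2_LOO": 0.724,
            "delta_rm2_LOO": 0.088,
            "Q2_F1": 0.785,
            "Q2_F2": 0.765,
            "RMSEP": 0.309,
            "rm2_test": 0.706,
            "delta_rm2_test": 0.125,
            "cRp2": 0.761,
        },
    )


def load_m15() -> FrozenModel:
    """The all-descriptor equation; its descriptors are import-only."""
    return FrozenModel(
        name="M15",
        model=MLRModel(
            names=["VE3sign_B(s)", "MATS4m", "SpMax2_Bh(v)", "G3i", "R5e+"],
            coefficients=[0.223, 3.079, 10.797, -6.694, 10.984],
            coefficient_se=[0.083, 0.574, 1.593, 1.071, 3.07],
            intercept=-33.064,
            intercept_se=6.179,
        ),
        provenance=(
            "published IP6K1 benzisoxazole 2D-QSAR, all-descriptor model; "
            "coefficients only - descriptor values must be imported"
        ),
        n_train=29,
        stats={
            "R2": 0.890,
            "R2_adj": 0.866,
            "Q2_LOO": 0.839,
            "MAE": 0.181,
            "Q2_F1": 0.870,
            "Q2_F2": 0.858,
            "RMSEP": 0.240,
            "cRp2": 0.794,
        },
    )


def predict(model: FrozenModel, x: Mapping[str, float]) -> tuple[float, bool | None]:
    """Functional alias for :meth:`FrozenModel.predict_one`."""
    return model.predict_one(x)
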