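"""Descriptor-subset selection for MLR: sequential forward selection and
a fixed-cardinality genetic algorithm.

SFS grows the model greedily, ranking candidate descriptors by one of
four scoring functions (R^2, negative MAE, negative mean Poisson
deviance, negative mean gamma deviance), optionally under 5-fold
cross-validation, and retains a candidate only if it improves the
model's Q^2_LOO by at least a configurable increment (5% relative by
default), stopping at ``max_features`` (the 1:5 observations-per-variable
rule caps this at n/5).

The GA searches over descriptor subsets of fixed size with tournament
selection, one-point crossover and bit-swap mutation, using Q^2_LOO of
the OLS fit as fitness, after dropping near-constant columns (variance
< 1e-4) and one of each pair with |r| > 0.99.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import (
    mean_absolute_error,
    mean_gamma_deviance,
    mean_poisson_deviance,
    r2_score,
)
from sklearn.model_selection import KFold

from .validation import MLRModel, fit_ols, q2_loo

__all__ = [
    "SCORERS",
    "score",
    "SFSConfig",
    "GAConfig",
    "SelectionResult",
    "sfs_select",
    "ga_select",
    "prefilter_columns",
]


def score(yobs, ypred, scoring: str) -> float:
    """Evaluate a scoring function; higher is always better.

    ``R2`` = 1 - SSres/SStot; ``NMAE`` = -mean|e|; ``NMPD``/``NMGD`` are
    the negated mean Poisson / gamma deviances (observed and predicted
    values must be strictly positive for those two).
    """
    yo = np.asarray(yobs, dtype=float)
    yp = np.asarray(ypred, dtype=float)
    if len(yo) != len(yp) or len(yo) < 2:
        raise ValueError("need two equal-length vectors of at least 2 points")
    if scoring == "R2":
        if np.allclose(yo, yo[0]):
            raise ValueError("constant observed vector: R2 undefined")
        return float(r2_score(yo, yp))
    if scoring == "NMAE":
        return float(-mean_absolute_error(yo, yp))
    if scoring in ("NMPD", "NMGD"):
        bad = np.flatnonzero((yo <= 0) | (yp <= 0))
        if bad.size:
            raise ValueError(
                f"deviance scorers need positive values; offending rows: {bad.tolist()}"
            )
        fn = mean_poisson_deviance if scoring == "NMPD" else mean_gamma_deviance
        return float(-fn(yo, yp))
    raise ValueError(f"unknown scoring function {scoring!r}")


SCORERS = ("R2", "NMAE", "NMPD", "NMGD")


@dataclass
class SFSConfig:
    scoring: str = "R2"
    cv_folds: int | None = None  # None or 5
    max_features: int = 5
    increment_threshold: float = 0.05
    increment_mode: str = "relative"  # or "absolute"
    seed: int = 0

    def __post_init__(self):
        if self.scoring not in SCORERS:
            raise ValueError(f"scoring must be one of {SCORERS}")
        if self.cv_folds not in (None, 5):
            raise ValueError("cv_folds must be None or 5")
        if self.increment_threshold < 0:
            raise ValueError("increment_threshold must be >= 0")


@dataclass
class GAConfig:
    n_features: int = 5
    population: int = 100
    generations: int = 100
    crossover_rate: float = 0.8
    mutation_rate: float = 0.05
    tournament_size: int = 2
    correlation_cutoff: float = 0.99
    variance_cutoff: float = 1e-4
    stall_generations: int = 10
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.crossover_rate <= 1 and 0 <= self.mutation_rate <= 1):
            raise ValueError("rates must lie in [0, 1]")
        if self.population < 2:
            raise ValueError("population must be >= 2")


@dataclass
class SelectionResult:
    chosen: list[str]
    trace: list[dict]
    model: MLRModel
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "chosen": self.chosen,
            "trace": self.trace,
            "coefficients": dict(zip(self.model.names, self.model.coefficients)),
            "intercept": self.model.intercept,
            "notes": self.notes,
        }


def _subset_score(X: pd.DataFrame, y, cols: list[str], cfg: SFSConfig) -> float:
    yv = np.asarray(y, dtype=float)
    A = X[cols].to_numpy(dtype=float)
    if cfg.cv_folds is None:
        model = fit_ols(X[cols], yv)
        return score(yv, model.predict(X[cols]), cfg.scoring)
    kf = KFold(n_splits=cfg.cv_folds, shuffle=True, random_state=cfg.seed)
    scores = []
    for tr, te in kf.split(A):
        D = np.column_stack([np.ones(len(tr)), A[tr]])
        beta = np.linalg.lstsq(D, yv[tr], rcond=None)[0]
        pred = np.column_stack([np.ones(len(te)), A[te]]) @ beta
        scores.append(score(yv[te], pred, cfg.scoring))
    return float(np.mean(scores))


def _passes_increment(q2_old: float | None, q2_new: float, cfg: SFSConfig) -> bool:
    if q2_old is None:
        return True  # first descriptor: nothing to improve on
    if cfg.increment_mode == "absolute":
        return q2_new >= q2_old + cfg.increment_threshold
    # relative reading of "improves by at least X%"; for a non-positive
    # baseline any strict improvement counts
    if q2_old <= 0:
        return q2_new > q2_old
    return q2_new >= q2_old * (1.0 + cfg.increment_threshold)


def sfs_select(X: pd.DataFrame, y, cfg: SFSConfig) -> SelectionResult:
    """Greedy forward selection with the Q^2_LOO increment rule."""
    pool = list(X.columns)
    if not pool:
        raise ValueError("empty candidate pool")
    if X.isna().any().any():
        raise ValueError("descriptor matrix contains missing values")
    n = len(X)
    max_features = min(cfg.max_features, n // 5) if n >= 5 else cfg.max_features
    chosen: list[str] = []
    trace: list[dict] = []
    notes: list[str] = []
    q2_current: float | None = None
    while len(chosen) < max_features and pool:
        ranked = sorted(
            pool,
            key=lambda c: _subset_score(X, y, chosen + [c], cfg),
            reverse=True,
        )
        best = ranked[0]
        best_score = _subset_score(X, y, chosen + [best], cfg)
        q2_new = q2_loo(X[chosen + [best]], y)
        if not _passes_increment(q2_current, q2_new, cfg):
            notes.append(
                f"stopped: adding {best} raises Q2_LOO {q2_current:.4f} -> "
                f"{q2_new:.4f}, below the increment rule"
            )
            break
        chosen.append(best)
        pool.remove(best)
        q2_current = q2_new
        trace.append({"added": best, "score": best_score, "q2_loo": q2_new})
    if not chosen:
        raise ValueError("no descriptor passed the selection rules")
    return SelectionResult(chosen=chosen, trace=trace, model=fit_ols(X[chosen], y), notes=notes)


# ---------------------------------------------------------------------- #
# genetic algorithm
# ---------------------------------------------------------------------- #
def prefilter_columns(
    X: pd.DataFrame, correlation_cutoff: float = 0.99, variance_cutoff: float = 1e-4
) -> tuple[pd.DataFrame, list[str]]:
    """Drop near-constant columns and one of each highly correlated pair."""
    dropped = []
    keep = []
    for c in X.columns:
        if X[c].to_numpy(dtype=float).var() < variance_cutoff:
            dropped.append(c)
        else:
            keep.append(c)
    Xk = X[keep]
    if len(keep) > 1:
        corr = np.abs(np.corrcoef(Xk.to_numpy(dtype=float), rowvar=False))
        to_drop = set()
        for i in range(len(keep)):
            if keep[i] in to_drop:
                continue
            for j in range(i + 1, len(keep)):
                if corr[i, j] > correlation_cutoff:
                    to_drop.add(keep[j])
        dropped.extend(sorted(to_drop, key=keep.index))
        keep = [c for c in keep if c not in to_drop]
    return X[keep], dropped


def _fitness(X: pd.DataFrame, y, cols: tuple[str, ...]) -> float:
    try:
        return q2_loo(X[list(cols)], y)
    except np.linalg.LinAlgError:
        return -np.inf


def ga_select(X: pd.DataFrame, y, cfg: GAConfig) -> SelectionResult:
    """Fixed-cardinality genetic search maximizing Q^2_LOO.

    Deterministic for a fixed seed; keeps the best individual ever seen
    (elitism), and stops early with a notice if the population is
    identical for ``stall_generations`` consecutive generations.
    """
    Xf, dropped = prefilter_columns(X, cfg.correlation_cutoff, cfg.variance_cutoff)
    pool = list(Xf.columns)
    k = cfg.n_features
    if len(pool) < k:
        raise ValueError(f"pool of {len(pool)} columns cannot fill {k}-feature models")
    rng = np.random.default_rng(cfg.seed)
    notes = [f"prefilter dropped: {dropped}"] if dropped else []

    def _repair(genes: list[str]) -> tuple[str, ...]:
        seen = list(dict.fromkeys(genes))
        while len(seen) < k:
            extra = pool[rng.integers(len(pool))]
            if extra not in seen:
                seen.append(extra)
        return tuple(sorted(seen[:k]))

    cache: dict[tuple[str, ...], float] = {}

    def _fit(ind: tuple[str, ...]) -> float:
        if ind not in cache:
            cache[ind] = _fitness(Xf, y, ind)
        return cache[ind]

    population = [
        tuple(sorted(rng.choice(len(pool), size=k, replace=False)))
        for _ in range(cfg.population)
    ]
    population = [tuple(pool[i] for i in ind) for ind in population]
    best_ind = max(population, key=_fit)
    best_fit = _fit(best_ind)
    trace = [{"generation": 0, "best_q2_loo": best_fit}]
    stall = 0
    for gen in range(1, cfg.generations + 1):
        new_pop = [best_ind]  # elitism
        while len(new_pop) < cfg.population:
            parents = []
            for _ in range(2):
                contenders = [population[rng.integers(len(population))] for _ in range(cfg.tournament_size)]
                parents.append(max(contenders, key=_fit))
            if rng.random() < cfg.crossover_rate:
                cut = int(rng.integers(1, k)) if k > 1 else 0
                child_genes = list(parents[0][:cut]) + list(parents[1][cut:])
            else:
                child_genes = list(parents[0])
            child = list(_repair(child_genes))
            for g in range(k):
                if rng.random() < cfg.mutation_rate:
                    swap = pool[rng.integers(len(pool))]
                    if swap not in child:
                        child[g] = swap
            new_pop.append(_repair(child))
        population = new_pop
        gen_best = max(population, key=_fit)
        if _fit(gen_best) > best_fit:
            best_ind, best_fit = gen_best, _fit(gen_best)
        trace.append({"generation": gen, "best_q2_loo": best_fit})
        if len(set(population)) == 1:
            stall += 1
            if stall >= cfg.stall_generations:
                notes.append(f"early stop at generation {gen}: population degenerate")
                break
        else:
            stall = 0
    return SelectionResult(
        chosen=list(best_ind),
        trace=trace,
        model=fit_ols(Xf[list(best_ind)], y),
        notes=notes,
    )
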