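"""Experimental protocol: repeated random 60/40 splits, a (p, c) grid over
contexts and clusters, and RMSE tables comparing the TSK-LM against the
conventional linguistic model.

Each iteration draws one seeded train/check split that is shared by every
(variant, p, c) cell, and the clustering seed for a cell depends only on
(master seed, iteration, p, c) — not on the variant — so the two variants
are compared on identical granulations (paired comparisons).  Min–max
normalisation is always recomputed from the training split alone and
applied to its check split, so no information leaks from the check data.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .model import train

__all__ = [
    "ExperimentConfig",
    "ResultTable",
    "rmse",
    "split_indices",
    "run_experiment",
    "improvement_pct",
]

log = logging.getLogger(__name__)


def rmse(y, yhat) -> float:
    """Root mean square error between targets and predictions."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size == 0 or y.size != yhat.size:
        raise ValueError("rmse needs two equal-length, non-empty vectors")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def improvement_pct(baseline: float, value: float) -> float:
    """Relative improvement of ``value`` over ``baseline``, in percent."""
    return 100.0 * (baseline - value) / baseline


@dataclass
class ExperimentConfig:
    """Settings of one repeated-split grid experiment."""

    train_fraction: float = 0.6
    iterations: int = 10
    p_grid: Sequence[int] = (2, 3, 4, 5, 6)
    c_grid: Sequence[int] = (2, 3, 4, 5, 6)
    scheme: str = "flexible"
    variants: Sequence[str] = ("tsk_lm", "conventional_lm")
    seed: int = 0
    fuzzifier: float = 2.0
    tol: float = 1e-5
    max_iter: int = 200
    features: Sequence[str] | None = None   # input column subset (None = all)
    target: str = "ee"

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.iterations < 1:
            raise ValueError("need at least one iteration")
        if not self.p_grid or not self.c_grid:
            raise ValueError("p_grid and c_grid must be non-empty")


@dataclass
class ResultTable:
    """Grid results: per-cell means plus the per-iteration values behind them."""

    summary: pd.DataFrame        # variant, p, c, trn_rmse, chk_rmse
    per_iteration: pd.DataFrame  # variant, p, c, iteration, trn_rmse, chk_rmse
    failures: list[str] = field(default_factory=list)

    def best(self, variant: str) -> pd.Series:
        """Best cell of a variant: minimal mean check RMSE."""
        sub = self.summary[self.summary["variant"] == variant].dropna(
            subset=["chk_rmse"]
        )
        if sub.empty:
            raise ValueError(f"no successful cells for variant {variant!r}")
        return sub.loc[sub["chk_rmse"].idxmin()]


def split_indices(n: int, train_fraction: float, rng) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/check index split: |train| = round(f * n)."""
    n_train = int(round(train_fraction * n))
    if not 0 < n_train < n:
        raise ValueError("split leaves one side empty")
    perm = rng.permutation(n)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def _extract(data, config: ExperimentConfig):
    if isinstance(data, pd.DataFrame):
        cols = (
            list(config.features)
            if config.features is not None
            else [c for c in data.columns if c != config.target]
        )
        X = data[cols].to_numpy(dtype=float)
        y = data[config.target].to_numpy(dtype=float)
    else:
        X, y = data
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
    if y.size < 10:
        raise ValueError("need at least 10 rows to run the protocol")
    return X, y


def run_experiment(data, config: ExperimentConfig) -> ResultTable:
    """Run the repeated-split grid experiment.

    ``data`` is a DataFrame containing the target column (default ``ee``)
    or an ``(X, y)`` pair.  Every (variant, p, c) cell is trained on each
    iteration's training split and scored by RMSE on both splits; cell
    means over iterations land in ``summary``.  A failing cell is recorded
    in ``failures`` and reported as NaN; the run continues.
    """
    X, y = _extract(data, config)
    n = y.size
    rows = []
    failures: list[str] = []
    t_start = time.perf_counter()
    for it in range(config.iterations):
        split_rng = np.random.default_rng([config.seed, it])
        tr, ck = split_indices(n, config.train_fraction, split_rng)
        for p in config.p_grid:
            for c in config.c_grid:
                # clustering seed shared by both variants: paired comparison
                cell_seed = [config.seed, it, p, c]
                for variant in config.variants:
                    try:
                        model = train(
                            X[tr], y[tr], p=p, c=c,
                            scheme=config.scheme, variant=variant,
                            m=config.fuzzifier, tol=config.tol,
                            max_iter=config.max_iter, seed=cell_seed,
                        )
                        trn = rmse(y[tr], model.predict_batch(X[tr])[1])
                        chk = rmse(y[ck], model.predict_batch(X[ck])[1])
                    except ValueError as e:
                        failures.append(
                            f"iteration {it}, {variant}, p={p}, c={c}: {e}"
                        )
                        trn = chk = np.nan
                    rows.append(
                        {
                            "variant": variant, "p": p, "c": c,
                            "iteration": it, "trn_rmse": trn, "chk_rmse": chk,
                        }
                    )
        log.info("iteration %d/%d done (%.2fs elapsed)",
                 it + 1, config.iterations, time.perf_counter() - t_start)
    per_iteration = pd.DataFrame(rows)
    summary = (
        per_iteration.groupby(["variant", "p", "c"], as_index=False)[
            ["trn_rmse", "chk_rmse"]
        ]
        .mean()
        .sort_values(["variant", "p", "c"], ignore_index=True)
    )
    return ResultTable(summary=summary, per_iteration=per_iteration, failures=failures)
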