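"""Fivefold cross-validation with environment-stratified Pearson scoring.

Folds partition *lines*, not observations, so a line's records never sit in
train and test simultaneously across environments (this prevents leakage of
the identical genotype through the relationship matrices).  For each fold
the model is refit with the held-out lines' phenotypes masked (whole-kernel
conditioning), predictions are scored by Pearson correlation *within* each
environment, and the per-environment correlations are averaged to the fold
accuracy; the report carries the mean and standard deviation across the
five folds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from ._util import warn
from .inference import ChainConfig, ModelSpec, gibbs_fit, posterior_predict

__all__ = ["FoldPlan", "CVReport", "make_folds", "pearson", "crossvalidate", "permutation_null"]


@dataclass
class FoldPlan:
    """Assignment of every line to one of ``n_folds`` near-equal folds."""

    assignments: dict
    seed: int
    n_folds: int = 5

    def lines_in_fold(self, fold: int) -> list:
        return [l for l, f in self.assignments.items() if f == fold]


@dataclass
class CVReport:
    """Per-fold, per-environment accuracies with across-fold summary.

    ``predictions`` keeps every held-out observation's posterior predictive
    mean next to its phenotype, enabling diagnostics such as permutation
    calibration without refitting.
    """

    per_fold: pd.DataFrame  # columns: fold, env, r, n_test
    fold_r: np.ndarray      # stratified (env-averaged) accuracy per fold
    mean_r: float
    std_r: float
    pooled_r: float
    predictions: pd.DataFrame | None = None  # fold, env, line, y_true, y_pred
    scenario_id: str | None = None
    trait: str | None = None

    def summary(self) -> str:
        return f"{self.mean_r:.3f} ({self.std_r:.3f})"


def permutation_null(
    report: CVReport, n_perms: int = 50, seed: int = 0
) -> np.ndarray:
    """Null distribution of the mean CV accuracy under no association.

    Permutes predictions within every (fold, environment) cell of the
    report and recomputes the stratified mean accuracy; returns one value
    per permutation.
    """
    if report.predictions is None or report.predictions.empty:
        raise ValueError("report carries no predictions")
    rng = np.random.default_rng(seed)
    preds = report.predictions
    out = np.empty(n_perms)
    for b in range(n_perms):
        fold_means = []
        for fold, chunk in preds.groupby("fold"):
            env_rs = []
            for env, cell in chunk.groupby("env"):
                if len(cell) < 3:
                    continue
                shuffled = rng.permutation(cell["y_pred"].to_numpy())
                r = pearson(cell["y_true"].to_numpy(), shuffled)
                if np.isfinite(r):
                    env_rs.append(r)
            if env_rs:
                fold_means.append(np.mean(env_rs))
        out[b] = np.mean(fold_means)
    return out


def make_folds(line_ids: Sequence, seed: int, n_folds: int = 5) -> FoldPlan:
    """Randomly partition lines into near-equal folds (sizes differ <= 1)."""
    line_ids = list(line_ids)
    if len(line_ids) < n_folds:
        raise ValueError(f"need at least {n_folds} lines for {n_folds}-fold CV")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(line_ids))
    assignments = {}
    for pos, idx in enumerate(order):
        assignments[line_ids[idx]] = pos % n_folds + 1
    return FoldPlan(assignments=assignments, seed=seed, n_folds=n_folds)


def pearson(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Pearson correlation r = sum (y-ybar)(yhat-yhatbar) / (||.|| ||.||).

    Returns NaN (with a coded warning) when either side has zero variance.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    ok = np.isfinite(y_true) & np.isfinite(y_pred)
    y_true, y_pred = y_true[ok], y_pred[ok]
    if len(y_true) < 3:
        raise ValueError("need at least 3 paired finite values")
    a = y_true - y_true.mean()
    b = y_pred - y_pred.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        warn("ZERO_VARIANCE_SCORE", "Pearson undefined: zero variance on one side")
        return float("nan")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def crossvalidate(
    model_builder: Callable[[], ModelSpec] | ModelSpec,
    phenotypes: pd.DataFrame,
    trait: str,
    plan: FoldPlan,
    chain: ChainConfig | None = None,
    scenario_id: str | None = None,
) -> CVReport:
    """Line-level K-fold CV of one model on one trait.

    ``phenotypes`` must have columns ``line``, ``env`` and ``trait``, with
    rows aligned one-to-one with the model's observation axis.  The model
    (including kernels and their eigendecompositions, computed lazily on
    first fit) is shared across folds; only the phenotype mask changes.
    """
    model = model_builder() if callable(model_builder) else model_builder
    chain = chain or ChainConfig()
    if len(phenotypes) != model.n_obs:
        raise ValueError("phenotype table does not match model observation axis")
    missing = set(phenotypes["line"]) - set(plan.assignments)
    if missing:
        raise ValueError(f"fold plan does not cover lines: {sorted(missing)[:5]} ...")

    y_full = phenotypes[trait].to_numpy(dtype=float)
    lines = phenotypes["line"].to_numpy()
    envs = phenotypes["env"].to_numpy()
    rows = []
    fold_rs = []
    pred_rows = []
    all_true, all_pred = [], []
    for fold in range(1, plan.n_folds + 1):
        test_lines = set(plan.lines_in_fold(fold))
        test_mask = np.array([l in test_lines for l in lines])
        y_train = y_full.copy()
        y_train[test_mask] = np.nan
        fold_chain = ChainConfig(
            iterations=chain.iterations,
            burn_in=chain.burn_in,
            thinning=chain.thinning,
            seed=int(np.random.SeedSequence(chain.seed, spawn_key=(fold,)).generate_state(1)[0] % (2**31)),
        )
        samples = gibbs_fit(y_train, model, fold_chain)
        pred = posterior_predict(samples, model)
        scored = test_mask & np.isfinite(y_full)
        pred_rows.append(
            pd.DataFrame(
                {
                    "fold": fold,
                    "env": envs[scored],
                    "line": lines[scored],
                    "y_true": y_full[scored],
                    "y_pred": pred[scored],
                }
            )
        )
        env_rs = []
        for env in dict.fromkeys(envs):
            sel = test_mask & (envs == env) & np.isfinite(y_full)
            if sel.sum() < 3:
                continue
            r = pearson(y_full[sel], pred[sel])
            if np.isnan(r):
                warn("CV_CELL_MISSING", f"fold {fold}, env {env}: undefined correlation")
                continue
            rows.append({"fold": fold, "env": env, "r": r, "n_test": int(sel.sum())})
            env_rs.append(r)
            all_true.append(y_full[sel])
            all_pred.append(pred[sel])
        if env_rs:
            fold_rs.append(float(np.mean(env_rs)))
        else:
            warn("CV_FOLD_MISSING", f"fold {fold}: no scorable environment")
    fold_rs = np.asarray(fold_rs)
    pooled = pearson(np.concatenate(all_true), np.concatenate(all_pred)) if all_true else float("nan")
    return CVReport(
        per_fold=pd.DataFrame(rows),
        fold_r=fold_rs,
        mean_r=float(np.mean(fold_rs)) if len(fold_rs) else float("nan"),
        std_r=float(np.std(fold_rs, ddof=1)) if len(fold_rs) > 1 else float("nan"),
        pooled_r=pooled,
        predictions=pd.concat(pred_rows, ignore_index=True) if pred_rows else None,
        scenario_id=scenario_id,
        trait=trait,
    )
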