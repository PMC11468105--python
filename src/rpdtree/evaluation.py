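"""Model assessment: k-fold cross-validated ASE and the sensitivity scan.

The average squared error (ASE) of the tree is assessed by 10-fold
cross-validation: subjects are randomly partitioned into k folds
(sizes differing by at most one), the tree is regrown on each fold's
complement, and the held-out squared errors are pooled over subjects,

    ASE_cv = (1/n) * sum_i (y_i - yhat_{-fold(i)}(x_i))^2.

A per-fold ASE is also reported, since the literature is ambiguous
about pooled vs fold-averaged figures.  Folds are simple random (not
stratified) and fully determined by the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ContractError
from .predictors import PredictorTable
from .tree import Hyperparams, Tree, grow_tree, predict_frame, variable_importance

__all__ = ["CvResult", "kfold_cv_ase", "resubstitution_ase", "sensitivity_scan"]


@dataclass(frozen=True)
class CvResult:
    k: int
    seed: int
    assignment: tuple  # fold index per subject, in input order
    fold_ase: tuple  # per-fold mean squared held-out error
    fold_sizes: tuple
    pooled_ase: float  # mean over all subjects (well-defined with unequal folds)

    @property
    def fold_mean_ase(self) -> float:
        return float(np.mean(self.fold_ase))


def _fold_assignment(n: int, k: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    assignment = np.empty(n, dtype=int)
    assignment[perm] = np.arange(n) % k
    return assignment


def kfold_cv_ase(X, y, hp: Hyperparams, k: int = 10, seed: int = 0) -> CvResult:
    """Cross-validated ASE of the tree on (X, y); reproducible given the seed."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < k:
        raise ContractError(f"need at least k={k} subjects; got {n}")
    df = X.data if isinstance(X, PredictorTable) else X
    assignment = _fold_assignment(n, k, seed)
    sq_err = np.empty(n)
    fold_ase, fold_sizes = [], []
    for fold in range(k):
        held = assignment == fold
        if isinstance(X, PredictorTable):
            train = PredictorTable(df.loc[~held], X.specs)
            test = PredictorTable(df.loc[held], X.specs)
        else:
            train, test = df.loc[~held], df.loc[held]
        tree = grow_tree(train, y[~held], hp)
        pred = predict_frame(tree, test)
        sq = (y[held] - pred) ** 2
        sq_err[held] = sq
        fold_ase.append(float(sq.mean()))
        fold_sizes.append(int(held.sum()))
    return CvResult(
        k=k,
        seed=seed,
        assignment=tuple(int(a) for a in assignment),
        fold_ase=tuple(fold_ase),
        fold_sizes=tuple(fold_sizes),
        pooled_ase=float(sq_err.mean()),
    )


def resubstitution_ase(tree: Tree, X, y) -> float:
    """Mean squared training error; equals sum of leaf SSEs over n."""
    y = np.asarray(y, dtype=float)
    pred = predict_frame(tree, X)
    return float(((y - pred) ** 2).mean())


def sensitivity_scan(
    X, y, presets: dict[str, Hyperparams], k: int = 10, seed: int = 0
) -> dict:
    """Refit and re-assess the tree under each hyperparameter preset.

    Returns, per preset, a structure summary (root variable, depth, leaf
    count), the importance table, resubstitution and CV ASE, plus a
    pairwise structural diff of the split-variable sets.
    """
    if len(presets) < 2:
        raise ContractError("sensitivity scan needs at least two presets")
    report: dict = {"presets": {}, "diff": {}}
    split_sets = {}
    for name, hp in presets.items():
        tree = grow_tree(X, y, hp)
        cv = kfold_cv_ase(X, y, hp, k=k, seed=seed)
        root_var = None if tree.root.is_leaf else tree.root.rule.variable
        imp = variable_importance(tree)
        split_sets[name] = set(tree.split_variables())
        report["presets"][name] = {
            "hyperparams": {
                "maxdepth": hp.maxdepth,
                "minleafsize": hp.minleafsize,
                "minvariance": hp.minvariance,
            },
            "root_variable": root_var,
            "depth": tree.depth,
            "n_leaves": len(tree.leaves()),
            "importance": imp.to_dict("records"),
            "resubstitution_ase": tree.training_ase,
            "cv_ase_pooled": cv.pooled_ase,
            "cv_ase_fold_mean": cv.fold_mean_ase,
        }
    names = list(presets)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            only_a = sorted(split_sets[a] - split_sets[b])
            only_b = sorted(split_sets[b] - split_sets[a])
            report["diff"][f"{a} vs {b}"] = {
                f"only_in_{a}": only_a,
                f"only_in_{b}": only_b,
            }
    return report


def sensitivity_table(report: dict) -> pd.DataFrame:
    """Flat one-row-per-preset view of a sensitivity report."""
    rows = []
    for name, r in report["presets"].items():
        rows.append(
            {
                "preset": name,
                "root_variable": r["root_variable"],
                "depth": r["depth"],
                "n_leaves": r["n_leaves"],
                "resubstitution_ase": r["resubstitution_ase"],
                "cv_ase_pooled": r["cv_ase_pooled"],
            }
        )
    return pd.DataFrame(rows)
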