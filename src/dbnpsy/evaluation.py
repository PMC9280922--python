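"""Predictive evaluation and effect-size reporting.

Cross-validated posterior classification error for each wave-2 node (the
0-1 loss of predicting the node's value as the posterior mode given the
participant's wave-1 values), marginal 2x2 odds ratios with Woolf
confidence intervals and the Haldane-Anscombe correction, and ranked
top-k arc tables for the exploratory progression analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .bn_core import ConstraintSet, DAGStructure, fit_cpts, predict_posterior_mode_many
from .model_averaging import ArcStrengthTable, _as_joint, automatic_threshold
from .nodes import W2, wave_of
from .structure_learning import SearchConfig, hill_climb

# --------------------------------------------------------------------------
# Cross-validated posterior classification error
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CVLossReport:
    """Mean and spread of the per-node 0-1 loss across CV runs."""

    losses: pd.DataFrame  # index: W2 node; columns: mean_loss, sd_loss
    k: int
    runs: int
    seed: int

    def mean_loss(self, node: str) -> float:
        return float(self.losses.loc[node, "mean_loss"])


def cv_classification_loss(
    panel,
    constraints: ConstraintSet,
    config: SearchConfig | None = None,
    k: int = 10,
    runs: int = 10,
    seed: int = 0,
    relearn: bool = True,
    structure: DAGStructure | None = None,
    iss: float = 1.0,
) -> CVLossReport:
    """k-fold cross-validated posterior classification error per wave-2 node.

    Each run shuffles the participants with a seeded permutation and splits
    them into k folds (remainder participants spread one per fold).  For
    each fold the structure is learned on the training portion (or, with
    ``relearn=False``, the supplied ``structure`` is reused), CPTs are
    fitted with Dirichlet smoothing, and every held-out participant's
    wave-2 nodes are predicted as the posterior mode given their wave-1
    values.  The report holds the mean over runs of the per-run loss (the
    unweighted mean over folds) and the standard deviation over runs.
    """
    joint = _as_joint(panel)
    n = len(joint)
    if k < 2:
        raise ValueError(f"need at least 2 folds, got {k}")
    if n < k:
        raise ValueError(f"cohort of {n} cannot be split into {k} folds")
    if not relearn and structure is None:
        raise ValueError("relearn=False requires a fixed structure")
    config = config or SearchConfig()
    w2_nodes = [c for c in joint.columns if wave_of(c) == W2]
    if not w2_nodes:
        raise ValueError("panel has no wave-2 nodes")
    rng = np.random.default_rng(seed)
    run_losses = np.empty((runs, len(w2_nodes)))
    for r in range(runs):
        perm = rng.permutation(n)
        folds = np.array_split(perm, k)
        fold_losses = np.empty((k, len(w2_nodes)))
        for f, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(perm, test_idx, assume_unique=True)
            train = joint.iloc[train_idx]
            test = joint.iloc[test_idx]
            if relearn:
                cfg = replace(config, seed=int(rng.integers(2**31)))
                dag = hill_climb(train, constraints, cfg)
            else:
                dag = structure
            cpts = fit_cpts(dag, train, iss=iss)
            for j, node in enumerate(w2_nodes):
                pred = predict_posterior_mode_many(cpts, node, test)
                actual = test[node].to_numpy()
                fold_losses[f, j] = float(np.mean(pred != actual))
        run_losses[r] = fold_losses.mean(axis=0)
    losses = pd.DataFrame(
        {
            "mean_loss": run_losses.mean(axis=0),
            "sd_loss": run_losses.std(axis=0, ddof=1) if runs > 1 else np.zeros(len(w2_nodes)),
        },
        index=pd.Index(w2_nodes, name="node"),
    )
    return CVLossReport(losses=losses, k=k, runs=runs, seed=seed)


# --------------------------------------------------------------------------
# Marginal 2x2 associations
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class MarginalAssociation:
    """2x2 odds ratio with 95% Woolf confidence interval."""

    parent: str
    child: str
    n11: int
    n10: int
    n01: int
    n00: int
    odds_ratio: float
    ci_low: float
    ci_high: float
    corrected: bool  # Haldane-Anscombe 0.5 added to every cell


def marginal_association(x, y) -> MarginalAssociation:
    """Odds ratio of a wave-1 item on a wave-2 item from the 2x2 table.

    OR = (n11 n00) / (n10 n01); with any empty cell, 0.5 is added to all
    four cells (Haldane-Anscombe) and the result flagged.  The 95% CI is
    ``exp(log OR +- 1.96 * sqrt(sum of reciprocal cells))``.
    """
    xs = np.asarray(x)
    ys = np.asarray(y)
    if xs.shape != ys.shape:
        raise ValueError(f"length mismatch: {xs.shape} vs {ys.shape}")
    if not (np.isin(xs, (0, 1)).all() and np.isin(ys, (0, 1)).all()):
        raise ValueError("columns must be binary")
    n11 = int(np.sum((xs == 1) & (ys == 1)))
    n10 = int(np.sum((xs == 1) & (ys == 0)))
    n01 = int(np.sum((xs == 0) & (ys == 1)))
    n00 = int(np.sum((xs == 0) & (ys == 0)))
    cells = np.array([n11, n10, n01, n00], dtype=float)
    corrected = bool((cells == 0).any())
    if corrected:
        cells = cells + 0.5
    a, b, c, d = cells
    log_or = float(np.log(a * d / (b * c)))
    se = float(np.sqrt((1 / cells).sum()))
    name = getattr(x, "name", None)
    yname = getattr(y, "name", None)
    return MarginalAssociation(
        parent=str(name) if name is not None else "x",
        child=str(yname) if yname is not None else "y",
        n11=n11,
        n10=n10,
        n01=n01,
        n00=n00,
        odds_ratio=float(np.exp(log_or)),
        ci_low=float(np.exp(log_or - 1.96 * se)),
        ci_high=float(np.exp(log_or + 1.96 * se)),
        corrected=corrected,
    )


# --------------------------------------------------------------------------
# Top-k arc ranking
# --------------------------------------------------------------------------


def top_k_arcs(
    table: ArcStrengthTable,
    k: int = 5,
    restrict_children: set[str] | None = None,
) -> pd.DataFrame:
    """The k most certain arcs by bootstrap strength, flagged against the
    automatic threshold.

    Arcs never observed in any bootstrap (strength 0) are not ranked; ties
    break by lexicographic (parent, child) order, so the top-k list is a
    prefix of the top-(k+1) list.  ``restrict_children`` limits the ranking
    to arcs into the given child nodes (e.g. the syndrome indicators).
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    t_auto = automatic_threshold(table)
    df = table.table
    df = df.loc[df["strength"] > 0]
    if restrict_children is not None:
        df = df.loc[df["child"].isin(restrict_children)]
    ranked = df.sort_values(
        ["strength", "parent", "child"], ascending=[False, True, True]
    ).head(k)
    out = ranked.reset_index(drop=True).copy()
    out["above_auto_threshold"] = (out["strength"] >= t_auto) & (t_auto > 0)
    out.attrs["auto_threshold"] = t_auto
    return out
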