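"""Bootstrap arc-strength estimation and consensus-network extraction.

The strength of a candidate arc is the fraction of nonparametric bootstrap
resamples whose learned network contains it.  The averaged ("consensus")
network keeps the arcs whose strength meets a threshold — a fixed a-priori
0.50, or the data-driven significance threshold that minimizes the L1
distance between the empirical strength CDF and an idealized 0/1 step CDF.
Because the temporal blacklist fixes every arc's direction, strength is
simply the directed-arc inclusion frequency; there is no separate
direction-confidence component to estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .bn_core import Arc, ConstraintSet
from .cohort import WavePanel, join_waves
from .nodes import base_of, split_node, wave_of, W2
from .structure_learning import SearchConfig, hill_climb


def _as_joint(panel) -> pd.DataFrame:
    """Accept a joint wave-tagged frame or a (W1, W2) WavePanel pair."""
    if isinstance(panel, pd.DataFrame):
        return panel
    p1, p2 = panel
    if isinstance(p1, WavePanel):
        return join_waves(p1, p2)
    raise TypeError("expected a joint DataFrame or a pair of WavePanels")


@dataclass(frozen=True)
class ArcStrengthTable:
    """Bootstrap inclusion frequency for every candidate arc.

    The table covers the full permitted arc space, zero-strength arcs
    included, so the automatic threshold sees the complete strength
    distribution.
    """

    table: pd.DataFrame  # columns: parent, child, strength
    B: int
    config: SearchConfig
    master_seed: int

    def __post_init__(self) -> None:
        s = self.table["strength"]
        if ((s < 0) | (s > 1)).any():
            raise ValueError("arc strengths must lie in [0, 1]")

    @property
    def strengths(self) -> np.ndarray:
        return self.table["strength"].to_numpy()

    def strength_of(self, arc: Arc) -> float:
        m = (self.table["parent"] == arc[0]) & (self.table["child"] == arc[1])
        if not m.any():
            raise KeyError(f"arc {arc} not in the candidate space")
        return float(self.table.loc[m, "strength"].iloc[0])


def bootstrap_strengths(
    panel,
    constraints: ConstraintSet,
    B: int = 1000,
    config: SearchConfig | None = None,
    master_seed: int = 0,
) -> ArcStrengthTable:
    """Arc strengths from *B* nonparametric bootstrap resamples.

    Each resample draws n participants with replacement (n = cohort size),
    learns a structure by constrained hill climbing, and records its arcs.
    Per-bootstrap RNG streams are spawned from the master seed, so results
    are reproducible and independent of participant row order (rows are
    canonicalized by participant id before resampling).
    """
    joint = _as_joint(panel)
    if len(joint) == 0:
        raise ValueError("cannot bootstrap an empty cohort")
    if B < 1:
        raise ValueError(f"bootstrap count must be >= 1, got {B}")
    config = config or SearchConfig()
    joint = joint.sort_index()
    n = len(joint)
    candidates = sorted(constraints.permitted_arcs(list(joint.columns)))
    counts = {arc: 0 for arc in candidates}
    streams = np.random.SeedSequence(master_seed).spawn(B)
    for ss in streams:
        rng = np.random.default_rng(ss)
        idx = rng.integers(0, n, n)
        sub = joint.iloc[idx]
        cfg = replace(config, seed=int(rng.integers(2**31)))
        dag = hill_climb(sub, constraints, cfg)
        for arc in dag.arcs:
            counts[arc] += 1
    table = pd.DataFrame(
        {
            "parent": [a[0] for a in candidates],
            "child": [a[1] for a in candidates],
            "strength": [counts[a] / B for a in candidates],
        }
    )
    return ArcStrengthTable(table=table, B=B, config=config, master_seed=master_seed)


@dataclass(frozen=True)
class ConsensusNetwork:
    """Arcs meeting the strength threshold, with provenance."""

    arcs: tuple[tuple[str, str, float], ...]  # (parent, child, strength), desc
    threshold: float
    source: str  # "fixed" or "automatic"

    @property
    def arc_set(self) -> frozenset[Arc]:
        return frozenset((p, c) for p, c, _ in self.arcs)

    def strengths(self) -> dict[Arc, float]:
        return {(p, c): s for p, c, s in self.arcs}


def averaged_network(
    table: ArcStrengthTable, threshold: float = 0.50, source: str = "fixed"
) -> ConsensusNetwork:
    """Consensus network at a strength threshold (inclusive).

    An arc is included iff its strength is >= the threshold; at threshold 0
    only arcs actually observed in some bootstrap (strength > 0) qualify.
    An empty consensus is a valid outcome.
    """
    if not 0 <= threshold <= 1:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    df = table.table
    keep = (df["strength"] >= threshold) & (df["strength"] > 0)
    rows = df.loc[keep].sort_values(
        ["strength", "parent", "child"], ascending=[False, True, True]
    )
    arcs = tuple(
        (r.parent, r.child, float(r.strength)) for r in rows.itertuples(index=False)
    )
    return ConsensusNetwork(arcs=arcs, threshold=float(threshold), source=source)


def automatic_threshold(table: ArcStrengthTable) -> float:
    """Data-driven significance threshold on arc strengths.

    Treats the ideal strength vector as 0/1 and picks the cutoff t whose
    induced step CDF (noise arcs at 0, significant arcs at 1) is closest in
    L1 distance to the empirical strength CDF.  Candidate cutoffs are the
    observed strengths plus midpoints between consecutive distinct values;
    among ties the largest candidate is returned, which places the cutoff
    between the noise and signal clusters.
    """
    strengths = np.sort(table.strengths)
    if len(strengths) == 0:
        raise ValueError("strength table is empty")
    uniq = np.unique(strengths)
    if len(uniq) == 1:
        warnings.warn(
            f"all arc strengths identical ({uniq[0]:.3f}); threshold is degenerate",
            stacklevel=2,
        )
        return float(uniq[0])
    mids = (uniq[:-1] + uniq[1:]) / 2
    candidates = np.unique(np.concatenate([uniq, mids]))
    # empirical CDF segments on [0, 1]: breakpoints at the unique strengths
    breaks = np.concatenate([[0.0], uniq, [1.0]])
    widths = np.diff(breaks)
    cdf_vals = np.concatenate([[0.0], np.searchsorted(strengths, uniq, side="right") / len(strengths)])
    best_t, best_l1 = None, np.inf
    for t in candidates:
        a = float(np.mean(strengths <= t))
        l1 = float(np.sum(widths * np.abs(cdf_vals - a)))
        if l1 < best_l1 - 1e-12 or (abs(l1 - best_l1) <= 1e-12 and (best_t is None or t > best_t)):
            best_t, best_l1 = float(t), l1
    return best_t


def classify_arcs(consensus: ConsensusNetwork) -> pd.DataFrame:
    """Label consensus arcs as within-item (persistence) or cross-item.

    An arc is within-item iff parent and child share the same base item id
    across waves; untagged parents are static covariates and always
    classify as cross-item.  Children must be wave-2 nodes.
    """
    rows = []
    for parent, child, strength in consensus.arcs:
        child_base, child_wave = split_node(child)
        if child_wave != W2:
            raise ValueError(f"consensus arc child {child!r} is not a wave-2 node")
        label = "within_item" if base_of(parent) == child_base and wave_of(parent) != W2 else "cross_item"
        rows.append((parent, child, strength, label))
    return pd.DataFrame(rows, columns=["parent", "child", "strength", "class"])
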