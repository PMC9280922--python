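"""End-to-end orchestration of the two temporal-network analyses.

``run_primary_dbn`` reproduces the full-cohort analysis: eligibility
filtering, temporally constrained bootstrap structure learning over all
item nodes, consensus extraction at the fixed 0.50 threshold alongside the
automatic threshold, within-/cross-item arc classification, cross-validated
posterior classification error, and marginal odds ratios for every
consensus arc.  ``run_progression_dbn`` restricts the cohort to
participants free of any subthreshold syndrome at wave 1 and models
progression into the three wave-2 syndrome indicator nodes, always
reporting the top-k most certain arcs (flagged against the automatic
threshold) even when the fixed-threshold consensus is empty.

Every stage draws its randomness from streams spawned off the single
master seed, so identical configurations produce byte-identical reports.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .bn_core import DAGStructure, temporal_constraints_for
from .cohort import (
    SYNDROME_ITEMS,
    WavePanel,
    apply_eligibility,
    build_eligibility_flags,
    default_catalog,
    derive_syndromes,
    join_waves,
    load_cohort,
)
from .evaluation import cv_classification_loss, marginal_association, top_k_arcs
from .model_averaging import (
    automatic_threshold,
    averaged_network,
    bootstrap_strengths,
    classify_arcs,
)
from .nodes import W2, tag
from .structure_learning import SearchConfig
from .synthetic_data import build_scenario, sample_cohort

log = logging.getLogger("dbnpsy")


# --------------------------------------------------------------------------
# Configuration and report schema
# --------------------------------------------------------------------------


class RunConfig(BaseModel):
    """Everything needed to reproduce one analysis run."""

    analysis: Literal["primary_dbn", "progression_dbn"]
    scenario: Optional[str] = None
    scenario_config: dict = Field(default_factory=dict)
    input_path: Optional[str] = None
    cidi_path: Optional[str] = None
    n: int = 664  # simulated cohort size before eligibility filtering
    B: int = 1000
    threshold: float = 0.50
    threshold_mode: Literal["fixed", "auto"] = "fixed"
    restarts: int = 10
    perturbations: int = 10
    cv_k: int = 10
    cv_runs: int = 10
    top_k: int = 5
    progression_w2: Literal["syndromes", "items_and_syndromes"] = "syndromes"
    out_dir: Optional[str] = None
    seed: int = 0

    @model_validator(mode="after")
    def _one_source(self):
        if (self.scenario is None) == (self.input_path is None):
            raise ValueError("supply exactly one of scenario or input_path")
        return self

    def search_config(self, seed: int = 0) -> SearchConfig:
        return SearchConfig(restarts=self.restarts, perturbations=self.perturbations, seed=seed)


class CohortAudit(BaseModel):
    n_input: int
    excluded_incomplete: int
    excluded_cidi: int
    excluded_sts_w1: int
    n_final: int

    @model_validator(mode="after")
    def _sums(self):
        total = (
            self.excluded_incomplete
            + self.excluded_cidi
            + self.excluded_sts_w1
            + self.n_final
        )
        if total != self.n_input:
            raise ValueError(f"filter audit does not sum: {total} != {self.n_input}")
        return self


class ConsensusArc(BaseModel):
    parent: str
    child: str
    strength: float
    strength_pct: str
    arc_class: Literal["within_item", "cross_item"]


class TopArc(BaseModel):
    parent: str
    child: str
    strength: float
    strength_pct: str
    above_auto_threshold: bool


class CVLoss(BaseModel):
    node: str
    mean_loss: float
    sd_loss: float


class MarginalOR(BaseModel):
    parent: str
    child: str
    n11: int
    n10: int
    n01: int
    n00: int
    odds_ratio: float
    ci_low: float
    ci_high: float
    corrected: bool


class AnalysisReport(BaseModel):
    """Validated, serializable record of one analysis run."""

    analysis: str
    version: str
    seed: int
    B: int
    cohort: CohortAudit
    threshold: float
    threshold_source: str
    auto_threshold: float
    consensus_arcs: list[ConsensusArc]
    top_arcs: list[TopArc]
    cv_losses: list[CVLoss]
    marginal_associations: list[MarginalOR]

    def to_json(self) -> str:
        return json.dumps(self.model_dump(), indent=1, sort_keys=True)


# --------------------------------------------------------------------------
# Pipeline
# --------------------------------------------------------------------------


def _pct(s: float) -> str:
    return f"{round(100 * s)}%"


def _subseeds(master: int, k: int) -> list[int]:
    return [int(ss.generate_state(1)[0] % 2**31) for ss in np.random.SeedSequence(master).spawn(k)]


def _load_or_simulate(config: RunConfig, seed_sim: int):
    if config.scenario is not None:
        gt = build_scenario(config.scenario, config.scenario_config)
        p1, p2 = sample_cohort(gt, config.n, seed_sim)
        cidi = None
    else:
        p1, p2 = load_cohort(config.input_path, default_catalog())
        cidi = None
        if config.cidi_path:
            df = pd.read_csv(config.cidi_path, sep=None, engine="python")
            cidi = df.set_index("participant_id")["cidi_diagnosis_w1"]
    return p1, p2, cidi


def _audit(roster: pd.DataFrame) -> CohortAudit:
    reasons = roster["reason"].value_counts()
    return CohortAudit(
        n_input=len(roster),
        excluded_incomplete=int(reasons.get("incomplete", 0)),
        excluded_cidi=int(reasons.get("cidi_diagnosis_w1", 0)),
        excluded_sts_w1=int(reasons.get("sts_at_w1", 0)),
        n_final=int(roster["kept"].sum()),
    )


def _progression_w2_panel(panel_w2: WavePanel, mode: str) -> WavePanel:
    """Wave-2 node set for the progression analysis."""
    cols = set(panel_w2.values.columns)
    if set(SYNDROME_ITEMS) <= cols:
        syn = panel_w2.values[list(SYNDROME_ITEMS)]
    else:
        syn = derive_syndromes(panel_w2)
    if mode == "syndromes":
        values = syn
    else:
        items = panel_w2.values.drop(columns=[c for c in SYNDROME_ITEMS if c in cols])
        values = pd.concat([items, syn], axis=1)
    return WavePanel(values, W2, catalog=None)


def _run(config: RunConfig, mode: str) -> AnalysisReport:
    seed_sim, seed_boot, seed_cv = _subseeds(config.seed, 3)
    p1, p2, cidi = _load_or_simulate(config, seed_sim)
    log.info("loaded cohort: %d at W1, %d at W2", len(p1), len(p2))

    flags = build_eligibility_flags(p1, p2, cidi)
    p1, p2, roster = apply_eligibility(p1, p2, flags, mode=mode)
    audit = _audit(roster)
    log.info("eligibility (%s): %d of %d kept", mode, audit.n_final, audit.n_input)
    if audit.n_final == 0:
        raise ValueError(f"no participants remain after filtering; audit: {audit}")

    if mode == "progression":
        p2 = _progression_w2_panel(p2, config.progression_w2)
    joint = join_waves(p1, p2)
    constraints = temporal_constraints_for(list(joint.columns))

    table = bootstrap_strengths(
        joint, constraints, B=config.B, config=config.search_config(), master_seed=seed_boot
    )
    t_auto = automatic_threshold(table)
    threshold = t_auto if config.threshold_mode == "auto" else config.threshold
    consensus = averaged_network(table, threshold, source=config.threshold_mode)
    classified = classify_arcs(consensus)
    log.info("consensus at %.2f: %d arcs (auto threshold %.3f)", threshold, len(classified), t_auto)

    syndrome_children = {tag(s, W2) for s in SYNDROME_ITEMS}
    restrict = syndrome_children if mode == "progression" and config.progression_w2 != "syndromes" else None
    top = top_k_arcs(table, k=config.top_k, restrict_children=restrict)

    cv = cv_classification_loss(
        joint, constraints, config.search_config(), k=config.cv_k, runs=config.cv_runs, seed=seed_cv
    )
    margs = [
        marginal_association(joint[p], joint[c]) for p, c, _ in consensus.arcs
    ]

    report = AnalysisReport(
        analysis=config.analysis,
        version=__version__,
        seed=config.seed,
        B=config.B,
        cohort=audit,
        threshold=float(threshold),
        threshold_source=config.threshold_mode,
        auto_threshold=float(t_auto),
        consensus_arcs=[
            ConsensusArc(
                parent=r["parent"], child=r["child"], strength=float(r["strength"]),
                strength_pct=_pct(r["strength"]), arc_class=r["class"],
            )
            for r in classified.to_dict("records")
        ],
        top_arcs=[
            TopArc(
                parent=r.parent, child=r.child, strength=float(r.strength),
                strength_pct=_pct(r.strength),
                above_auto_threshold=bool(r.above_auto_threshold),
            )
            for r in top.itertuples(index=False)
        ],
        cv_losses=[
            CVLoss(node=str(node), mean_loss=float(row["mean_loss"]), sd_loss=float(row["sd_loss"]))
            for node, row in cv.losses.iterrows()
        ],
        marginal_associations=[
            MarginalOR(
                parent=m.parent, child=m.child, n11=m.n11, n10=m.n10, n01=m.n01,
                n00=m.n00, odds_ratio=m.odds_ratio, ci_low=m.ci_low,
                ci_high=m.ci_high, corrected=m.corrected,
            )
            for m in margs
        ],
    )
    if config.out_dir:
        _write_outputs(config, report, table, consensus, roster, list(joint.columns))
    return report


def run_primary_dbn(config: RunConfig) -> AnalysisReport:
    """Full-cohort temporal network over all item nodes."""
    if config.analysis != "primary_dbn":
        raise ValueError("config.analysis must be 'primary_dbn'")
    return _run(config, mode="primary")


def run_progression_dbn(config: RunConfig) -> AnalysisReport:
    """Progression analysis into the wave-2 subthreshold-syndrome nodes."""
    if config.analysis != "progression_dbn":
        raise ValueError("config.analysis must be 'progression_dbn'")
    return _run(config, mode="progression")


def run(config: RunConfig) -> AnalysisReport:
    if config.analysis == "primary_dbn":
        return run_primary_dbn(config)
    return run_progression_dbn(config)


# --------------------------------------------------------------------------
# Artifact writing
# --------------------------------------------------------------------------


def _write_outputs(config, report, table, consensus, roster, nodes) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(report.to_json())

    df = table.table.copy()
    included = consensus.arc_set
    df["included"] = [
        int((p, c) in included) for p, c in zip(df["parent"], df["child"])
    ]
    classes = []
    for p, c in zip(df["parent"], df["child"]):
        from .nodes import base_of, split_node
        classes.append("within_item" if base_of(p) == split_node(c)[0] else "cross_item")
    df["class"] = classes
    df.sort_values(["strength", "parent", "child"], ascending=[False, True, True]).to_csv(
        out / "arcs.tsv", sep="\t", index=False
    )

    dag = DAGStructure.from_arcs(nodes, consensus.arc_set)
    (out / "consensus.dot").write_text(dag.to_dot(consensus.strengths()))

    pd.DataFrame([l.model_dump() for l in report.cv_losses]).to_csv(
        out / "cv_losses.tsv", sep="\t", index=False
    )
    roster.to_csv(out / "eligibility.tsv", sep="\t", index=False)
    log.info("artifacts written to %s", out)
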