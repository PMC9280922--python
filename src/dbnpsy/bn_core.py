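"""Discrete Bayesian-network primitives.

Wave-tagged DAGs, the two-slice temporal constraint set, decomposable BIC
scoring of node families, Dirichlet-smoothed conditional probability tables
and posterior-mode prediction.  Scoring uses natural logarithms and the
larger-is-better convention: the family score is the multinomial
log-likelihood minus ``(d / 2) * log N`` with ``d = (r - 1) * q`` free
parameters (``r`` child states, ``q`` parent configurations).  Parent
configurations never observed in the data contribute zero log-likelihood
but still count toward ``q``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import xlogy

from .nodes import STATIC, W1, W2, wave_of

# --------------------------------------------------------------------------
# Graph structures
# --------------------------------------------------------------------------

Arc = tuple[str, str]


@dataclass(frozen=True)
class DAGStructure:
    """A directed acyclic graph over wave-tagged nodes."""

    nodes: tuple[str, ...]
    arcs: frozenset[Arc]

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise ValueError("duplicate node names")
        for p, c in self.arcs:
            if p not in node_set or c not in node_set:
                raise ValueError(f"arc ({p!r}, {c!r}) references unknown node")
            if p == c:
                raise ValueError(f"self-loop on {p!r}")
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.arcs)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("graph contains a cycle")

    @classmethod
    def from_arcs(cls, nodes: Iterable[str], arcs: Iterable[Arc]) -> "DAGStructure":
        return cls(tuple(nodes), frozenset(tuple(a) for a in arcs))

    def parents(self, node: str) -> tuple[str, ...]:
        return tuple(sorted(p for p, c in self.arcs if c == node))

    def sorted_arcs(self) -> list[Arc]:
        return sorted(self.arcs)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("parent\tchild\n")
            for p, c in self.sorted_arcs():
                fh.write(f"{p}\t{c}\n")

    @classmethod
    def from_tsv(cls, path, nodes: Iterable[str]) -> "DAGStructure":
        df = pd.read_csv(path, sep="\t")
        return cls.from_arcs(nodes, zip(df["parent"], df["child"]))

    def to_dot(self, strengths: Mapping[Arc, float] | None = None) -> str:
        """Graphviz DOT export; arc strengths map to pen width and a % label."""
        lines = ["digraph dbn {", "  rankdir=LR;"]
        for n in self.nodes:
            lines.append(f'  "{n}";')
        for p, c in self.sorted_arcs():
            if strengths is not None and (p, c) in strengths:
                s = strengths[(p, c)]
                lines.append(
                    f'  "{p}" -> "{c}" [label="{round(100 * s)}%", penwidth={1 + 4 * s:.2f}];'
                )
            else:
                lines.append(f'  "{p}" -> "{c}";')
        lines.append("}")
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class ConstraintSet:
    """Forbidden and forced arcs for structure search."""

    blacklist: frozenset[Arc]
    whitelist: frozenset[Arc] = frozenset()

    def __post_init__(self) -> None:
        clash = self.blacklist & self.whitelist
        if clash:
            raise ValueError(f"arcs both blacklisted and whitelisted: {sorted(clash)}")

    def permitted_arcs(self, nodes: Sequence[str]) -> list[Arc]:
        """All ordered pairs over *nodes* not blocked by the blacklist."""
        return [
            (p, c)
            for p in nodes
            for c in nodes
            if p != c and (p, c) not in self.blacklist
        ]


def temporal_constraints(
    w1_nodes: Iterable[str],
    w2_nodes: Iterable[str],
    static_nodes: Iterable[str] = (),
) -> ConstraintSet:
    """Two-slice temporal blacklist: only wave-1 (or static) -> wave-2 arcs.

    Blocks arcs within wave 1, within wave 2, backward from wave 2, and any
    arc into a wave-1 or static node, leaving exactly the forward candidate
    space ``(W1 u static) x W2``.
    """
    w1 = tuple(w1_nodes)
    w2 = tuple(w2_nodes)
    static = tuple(static_nodes)
    groups = [set(w1), set(w2), set(static)]
    for i in range(3):
        for j in range(i + 1, 3):
            overlap = groups[i] & groups[j]
            if overlap:
                raise ValueError(f"node sets overlap: {sorted(overlap)}")
    sources = w1 + static
    allowed = {(p, c) for p in sources for c in w2}
    everything = w1 + w2 + static
    blacklist = frozenset(
        (p, c)
        for p in everything
        for c in everything
        if p != c and (p, c) not in allowed
    )
    return ConstraintSet(blacklist=blacklist)


def temporal_constraints_for(columns: Sequence[str]) -> ConstraintSet:
    """Temporal constraints inferred from wave tags of joint-frame columns."""
    w1 = [c for c in columns if wave_of(c) == W1]
    w2 = [c for c in columns if wave_of(c) == W2]
    static = [c for c in columns if wave_of(c) == STATIC]
    return temporal_constraints(w1, w2, static)


# --------------------------------------------------------------------------
# Family scoring
# --------------------------------------------------------------------------


def _as_matrix(panel: pd.DataFrame, cols: Sequence[str]) -> np.ndarray:
    return panel[list(cols)].to_numpy(dtype=np.int64)


def _family_counts(
    child_vals: np.ndarray, parent_vals: np.ndarray, r: int
) -> np.ndarray:
    """Counts n_jk over parent configurations j and child states k.

    Parent configurations are encoded little-endian in the given parent
    order; shape of the result is (q, r) with q = r ** n_parents (binary
    parents assumed to share cardinality r).
    """
    s = parent_vals.shape[1]
    q = r**s
    if s:
        weights = r ** np.arange(s, dtype=np.int64)
        idx = parent_vals @ weights
    else:
        idx = np.zeros(len(child_vals), dtype=np.int64)
    flat = idx * r + child_vals
    return np.bincount(flat, minlength=q * r).reshape(q, r)


def _counts_loglik(counts: np.ndarray) -> float:
    nj = counts.sum(axis=1)
    return float(xlogy(counts, counts).sum() - xlogy(nj, nj).sum())


def family_loglik(node: str, parents: Sequence[str], panel: pd.DataFrame, r: int = 2) -> float:
    """Maximized multinomial log-likelihood of one node family.

    Sum over parent configurations j and child states k of
    ``n_jk * log(n_jk / n_j)`` with the convention ``0 * log 0 = 0``.
    """
    if node in parents:
        raise ValueError(f"node {node!r} listed among its own parents")
    vals = _as_matrix(panel, [node, *parents])
    if vals.size and (vals.min() < 0 or vals.max() >= r):
        raise ValueError(f"values outside 0..{r - 1} in family of {node!r}")
    counts = _family_counts(vals[:, 0], vals[:, 1:], r)
    return _counts_loglik(counts)


def family_penalty(n_parents: int, n_rows: int, r: int = 2) -> float:
    """BIC complexity term ``(d / 2) * log N`` for one family."""
    d = (r - 1) * r**n_parents
    return 0.5 * d * np.log(n_rows)


def family_bic(node: str, parents: Sequence[str], panel: pd.DataFrame, r: int = 2) -> float:
    """Penalized family score (natural log, larger is better)."""
    return family_loglik(node, parents, panel, r) - family_penalty(len(parents), len(panel), r)


def network_score(dag: DAGStructure, panel: pd.DataFrame, r: int = 2) -> float:
    """Decomposable BIC of a DAG: the sum of its family scores."""
    missing = [n for n in dag.nodes if n not in panel.columns]
    if missing:
        raise ValueError(f"dag nodes missing from panel: {missing}")
    return sum(family_bic(n, dag.parents(n), panel, r) for n in dag.nodes)


# --------------------------------------------------------------------------
# Conditional probability tables
# --------------------------------------------------------------------------


@dataclass
class NodeCPT:
    node: str
    parents: tuple[str, ...]
    table: np.ndarray  # (q, r), rows are parent configs little-endian

    def row_index(self, evidence: Mapping[str, int]) -> int:
        idx = 0
        for k, p in enumerate(self.parents):
            if p not in evidence:
                raise KeyError(f"missing value for parent {p!r} of {self.node!r}")
            idx += int(evidence[p]) << k
        return idx


@dataclass
class CPTSet:
    """Smoothed conditional probability tables for every node of a DAG."""

    cpts: dict[str, NodeCPT]
    iss: float = 1.0

    def __getitem__(self, node: str) -> NodeCPT:
        return self.cpts[node]

    def to_json(self, path) -> None:
        payload = {
            "iss": self.iss,
            "nodes": {
                n: {"parents": list(c.parents), "table": c.table.tolist()}
                for n, c in self.cpts.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "CPTSet":
        with open(path) as fh:
            payload = json.load(fh)
        cpts = {
            n: NodeCPT(n, tuple(entry["parents"]), np.asarray(entry["table"], dtype=float))
            for n, entry in payload["nodes"].items()
        }
        return cls(cpts=cpts, iss=float(payload["iss"]))


def fit_cpts(dag: DAGStructure, panel: pd.DataFrame, iss: float = 1.0, r: int = 2) -> CPTSet:
    """Dirichlet-posterior-mean CPTs with imaginary sample size *iss*.

    Each cell is ``(n_jk + iss / (r q)) / (n_j + iss / q)``: the prior mass
    is spread uniformly over the whole table, so unseen parent
    configurations fall back to the uniform distribution and every
    probability is strictly inside (0, 1).
    """
    if iss <= 0:
        raise ValueError(f"imaginary sample size must be positive, got {iss}")
    cpts = {}
    for node in dag.nodes:
        parents = dag.parents(node)
        vals = _as_matrix(panel, [node, *parents])
        counts = _family_counts(vals[:, 0], vals[:, 1:], r).astype(float)
        q = counts.shape[0]
        table = (counts + iss / (r * q)) / (counts.sum(axis=1, keepdims=True) + iss / q)
        cpts[node] = NodeCPT(node, parents, table)
    return CPTSet(cpts=cpts, iss=iss)


def predict_posterior_mode(
    cpts: CPTSet, node: str, evidence: Mapping[str, int]
) -> tuple[int, float]:
    """Posterior-mode prediction of *node* given its parents' values.

    Returns the most probable state and its probability; exact ties break
    toward state 0.
    """
    cpt = cpts[node]
    row = cpt.table[cpt.row_index(evidence)]
    best = int(np.argmax(row))  # first state attaining the max: ties go to 0
    return best, float(row[best])


def predict_posterior_mode_many(
    cpts: CPTSet, node: str, panel: pd.DataFrame
) -> np.ndarray:
    """Vectorized posterior-mode prediction for every row of *panel*."""
    cpt = cpts[node]
    if cpt.parents:
        pv = _as_matrix(panel, cpt.parents)
        weights = 1 << np.arange(pv.shape[1], dtype=np.int64)
        idx = pv @ weights
    else:
        idx = np.zeros(len(panel), dtype=np.int64)
    rows = cpt.table[idx]
    # argmax with ties toward the lowest state: argmax returns the first max
    return rows.argmax(axis=1)
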