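"""Score-based structure search over the temporally constrained arc space.

Hill climbing from the empty graph over single-arc additions and deletions
(arc reversal is never legal under the two-slice temporal blacklist),
followed by random-restart rounds that perturb the incumbent best network
and re-ascend.  Because the temporal constraints admit only wave-1/static
parents of wave-2 children, every candidate graph is acyclic by
construction and the BIC decomposes over wave-2 families; the search
exploits this with per-family score caching and vectorized evaluation of
all single-parent additions for a child in one pass.  An exhaustive
enumeration oracle is provided for small candidate spaces.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import xlogy

from .bn_core import Arc, ConstraintSet, DAGStructure

_LN = np.log


@dataclass(frozen=True)
class SearchConfig:
    """Hill-climbing knobs (defaults follow the study protocol)."""

    restarts: int = 10
    perturbations: int = 10
    seed: int = 0
    score: str = "bic"
    tol: float = 1e-10

    def __post_init__(self) -> None:
        if self.restarts < 0 or self.perturbations < 0:
            raise ValueError("restarts and perturbations must be nonnegative")
        if self.tol <= 0:
            raise ValueError("improvement tolerance must be positive")
        if self.score != "bic":
            raise ValueError(f"unknown score {self.score!r}; only 'bic' is available")


class _ConstrainedSearch:
    """Shared machinery: family scores and moves over the candidate space."""

    def __init__(self, panel: pd.DataFrame, constraints: ConstraintSet):
        self.names = list(panel.columns)
        self.col = {n: i for i, n in enumerate(self.names)}
        X = panel.to_numpy()
        if X.size and not np.isin(X, (0, 1)).all():
            raise ValueError("panel must be binary for structure search")
        self.X = np.ascontiguousarray(X, dtype=np.int64)
        self.n = len(panel)
        self.log_n = float(_LN(self.n)) if self.n else 0.0
        self.candidates: list[Arc] = sorted(constraints.permitted_arcs(self.names))
        for p, c in constraints.whitelist:
            if (p, c) in constraints.blacklist:  # already rejected upstream; belt and braces
                raise ValueError(f"whitelisted arc {(p, c)} is blacklisted")
            if (p, c) not in self.candidates:
                raise ValueError(f"whitelisted arc {(p, c)} outside the node set")
        self.whitelist = frozenset(constraints.whitelist)
        self.children: list[str] = sorted({c for _, c in self.candidates})
        self.allowed: dict[str, list[str]] = {
            c: sorted(p for p, ch in self.candidates if ch == c) for c in self.children
        }
        self._ll_cache: dict[tuple[int, tuple[int, ...]], float] = {}

    # -- family scores ---------------------------------------------------

    def _config_index(self, S: tuple[int, ...]) -> np.ndarray:
        if not S:
            return np.zeros(self.n, dtype=np.int64)
        weights = 1 << np.arange(len(S), dtype=np.int64)
        return self.X[:, list(S)] @ weights

    def _ll(self, ci: int, S: tuple[int, ...]) -> float:
        key = (ci, S)
        cached = self._ll_cache.get(key)
        if cached is not None:
            return cached
        q = 1 << len(S)
        flat = self._config_index(S) * 2 + self.X[:, ci]
        counts = np.bincount(flat, minlength=2 * q).reshape(q, 2)
        nj = counts.sum(axis=1)
        ll = float(xlogy(counts, counts).sum() - xlogy(nj, nj).sum())
        self._ll_cache[key] = ll
        return ll

    def _bic(self, ci: int, S: tuple[int, ...]) -> float:
        return self._ll(ci, S) - 0.5 * (1 << len(S)) * self.log_n

    def _add_gains(self, ci: int, S: tuple[int, ...], P: list[int]) -> np.ndarray:
        """BIC gain of adding each parent in P to the family (ci | S)."""
        if not P:
            return np.empty(0)
        s = len(S)
        q = 1 << s
        base = self._config_index(S) * 4 + self.X[:, ci]
        M = base[:, None] + 2 * self.X[:, P]
        M += np.arange(len(P), dtype=np.int64) * (4 * q)
        cnt = np.bincount(M.ravel(), minlength=len(P) * 4 * q).reshape(len(P), q, 2, 2)
        nj = cnt.sum(axis=3)
        ll_new = xlogy(cnt, cnt).sum(axis=(1, 2, 3)) - xlogy(nj, nj).sum(axis=(1, 2))
        return ll_new - self._ll(ci, S) - 0.5 * q * self.log_n


class _HillClimber(_ConstrainedSearch):
    def __init__(self, panel, constraints, config: SearchConfig):
        super().__init__(panel, constraints)
        self.config = config
        # parent sets as sorted tuples of column indices, keyed by child name
        self.state: dict[str, tuple[int, ...]] = {c: () for c in self.children}
        for p, c in sorted(self.whitelist):
            self.state[c] = tuple(sorted(self.state[c] + (self.col[p],)))
        self._best_move: dict[str, tuple[float, str, str] | None] = {}
        self._dirty = set(self.children)

    def _score(self) -> float:
        return sum(self._bic(self.col[c], S) for c, S in self.state.items())

    def _moves_for(self, child: str) -> tuple[float, str, str] | None:
        """Best (gain, parent, action) for one child, ties to the smaller parent."""
        ci = self.col[child]
        S = self.state[child]
        in_S = set(S)
        adds = [self.col[p] for p in self.allowed[child] if self.col[p] not in in_S]
        best: tuple[float, str, str] | None = None
        gains = self._add_gains(ci, S, adds)
        for g, pi in zip(gains, adds):
            cand = (float(g), self.names[pi], "add")
            if best is None or cand[0] > best[0] or (cand[0] == best[0] and cand[1] < best[1]):
                best = cand
        bic_cur = self._bic(ci, S)
        for pi in S:
            if (self.names[pi], child) in self.whitelist:
                continue  # forced arcs are not removable
            rest = tuple(x for x in S if x != pi)
            g = self._bic(ci, rest) - bic_cur
            cand = (float(g), self.names[pi], "del")
            if best is None or cand[0] > best[0] or (cand[0] == best[0] and cand[1] < best[1]):
                best = cand
        return best

    def _ascend(self) -> None:
        tol = self.config.tol
        while True:
            for c in sorted(self._dirty):
                self._best_move[c] = self._moves_for(c)
            self._dirty.clear()
            pick: tuple[float, str, str, str] | None = None  # gain, parent, child, action
            for c in self.children:
                m = self._best_move.get(c)
                if m is None or m[0] <= tol:
                    continue
                cand = (m[0], m[1], c, m[2])
                if (
                    pick is None
                    or cand[0] > pick[0]
                    or (cand[0] == pick[0] and (cand[1], cand[2]) < (pick[1], pick[2]))
                ):
                    pick = cand
            if pick is None:
                return
            _, parent, child, action = pick
            pi = self.col[parent]
            S = self.state[child]
            if action == "add":
                self.state[child] = tuple(sorted(S + (pi,)))
            else:
                self.state[child] = tuple(x for x in S if x != pi)
            self._dirty.add(child)

    def _set_state(self, snapshot: dict[str, tuple[int, ...]]) -> None:
        for c, S in snapshot.items():
            if self.state[c] != S:
                self.state[c] = S
                self._dirty.add(c)

    def run(self) -> DAGStructure:
        rng = np.random.default_rng(self.config.seed)
        self._ascend()
        best_state = dict(self.state)
        best_score = self._score()
        for _ in range(self.config.restarts):
            self._set_state(best_state)
            for _ in range(self.config.perturbations):
                if not self.candidates:
                    break
                p, c = self.candidates[int(rng.integers(len(self.candidates)))]
                if (p, c) in self.whitelist:
                    continue
                pi = self.col[p]
                S = self.state[c]
                if pi in S:
                    self.state[c] = tuple(x for x in S if x != pi)
                else:
                    self.state[c] = tuple(sorted(S + (pi,)))
                self._dirty.add(c)
            self._ascend()
            score = self._score()
            if score > best_score + self.config.tol:
                best_state = dict(self.state)
                best_score = score
        arcs = {
            (self.names[pi], c) for c, S in best_state.items() for pi in S
        }
        return DAGStructure.from_arcs(self.names, arcs)


def hill_climb(
    panel: pd.DataFrame,
    constraints: ConstraintSet,
    config: SearchConfig | None = None,
) -> DAGStructure:
    """Greedy BIC ascent with random restarts over the constrained space.

    Starts from the empty graph (plus any whitelisted arcs), repeatedly
    applies the best single-arc addition or deletion whose score gain
    exceeds the tolerance, then runs ``restarts`` rounds of
    ``perturbations`` random arc toggles on the incumbent best followed by
    re-ascent, returning the highest-scoring structure seen.  Deterministic
    for a fixed seed; equal-gain moves break ties by lexicographic
    (parent, child) order.
    """
    config = config or SearchConfig()
    return _HillClimber(panel, constraints, config).run()


#: enumeration cap for the oracle, in candidate arcs (2**20 graphs)
EXHAUSTIVE_MAX_ARCS = 20


def exhaustive_best(
    panel: pd.DataFrame,
    constraints: ConstraintSet,
    max_arcs: int = EXHAUSTIVE_MAX_ARCS,
) -> DAGStructure:
    """Exact maximum-BIC structure by enumerating the candidate arc space.

    Every subset of the permitted wave-1 -> wave-2 arc space is acyclic, so
    the global optimum is found by enumerating parent sets per child (the
    BIC decomposes over families; the per-child maxima jointly maximize the
    network score over all ``2**|candidates|`` arc subsets).  Ties prefer
    fewer arcs, then lexicographic arc order.
    """
    search = _ConstrainedSearch(panel, constraints)
    n_cand = len(search.candidates)
    if n_cand > max_arcs:
        raise ValueError(
            f"candidate space of {n_cand} arcs exceeds the enumeration cap "
            f"({max_arcs}); use hill_climb instead"
        )
    arcs: set[Arc] = set()
    for child in search.children:
        ci = search.col[child]
        forced = sorted(p for p, c in search.whitelist if c == child)
        free = [p for p in search.allowed[child] if p not in forced]
        best_S: tuple[str, ...] | None = None
        best_score = -np.inf
        for size in range(len(free) + 1):
            for combo in itertools.combinations(free, size):
                S = tuple(sorted(forced + list(combo)))
                score = search._bic(ci, tuple(search.col[p] for p in S))
                if score > best_score:  # first-seen wins ties: smallest size, lex order
                    best_score = score
                    best_S = S
        for p in best_S or ():
            arcs.add((p, child))
    return DAGStructure.from_arcs(search.names, arcs)
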