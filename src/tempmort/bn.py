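"""Discrete Bayesian networks: simulated-annealing structure search, CPT
estimation and exact inference by enumeration.

A Bayesian network is a pair ``(G, P)``: a directed acyclic graph ``G`` over
discrete variables plus one conditional probability table (CPT) per node, so
that the joint distribution factorizes as ``P(x) = prod_i P(x_i | pa(x_i))``.
Here the networks are small (at most ~11 nodes with 2-3 states each), which
makes exact enumeration the honest inference engine: every marginal and
posterior in this module is a literal sum over full joint assignments.

Structure learning maximizes the (decomposable) BIC score with a
simulated-annealing walk over single-edge moves; parameters are multinomial
maximum-likelihood estimates with optional Laplace smoothing, the sensible
default when only a couple of dozen training rows are available.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "Dag",
    "Cpt",
    "BnModel",
    "SaSchedule",
    "bic_score",
    "sa_search",
    "fit_cpts",
    "joint_probability",
    "marginal_cpt",
    "predict",
    "sample",
    "markov_equivalent",
]


class Dag:
    """Directed acyclic graph over named discrete variables.

    Parameters
    ----------
    states
        Mapping from node name to its ordered list of state labels. The
        order matters: it fixes CPT row/column layout and the tie-break
        order of :func:`predict`.
    edges
        Iterable of ``(parent, child)`` pairs; must leave the graph acyclic.
    """

    def __init__(self, states: dict[str, list[str]], edges=()):
        self.states = {n: list(s) for n, s in states.items()}
        for n, s in self.states.items():
            if len(s) < 1:
                raise ValueError(f"node {n!r} has zero states")
            if len(set(s)) != len(s):
                raise ValueError(f"node {n!r} has duplicate state labels")
        self._g = nx.DiGraph()
        self._g.add_nodes_from(self.states)
        for u, v in edges:
            self.add_edge(u, v)

    # -- basic queries -------------------------------------------------
    @property
    def nodes(self) -> list[str]:
        return list(self.states)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return sorted(self._g.edges)

    def cardinality(self, node: str) -> int:
        return len(self.states[node])

    def parents(self, node: str) -> tuple[str, ...]:
        """Parents in canonical (name-sorted) order."""
        return tuple(sorted(self._g.predecessors(node)))

    def has_edge(self, u: str, v: str) -> bool:
        return self._g.has_edge(u, v)

    def topological_order(self) -> list[str]:
        return list(nx.topological_sort(self._g))

    def copy(self) -> "Dag":
        return Dag(self.states, self._g.edges)

    # -- mutation (acyclicity-preserving) ------------------------------
    def can_add(self, u: str, v: str) -> bool:
        if u == v or self._g.has_edge(u, v) or self._g.has_edge(v, u):
            return False
        return not nx.has_path(self._g, v, u)

    def can_reverse(self, u: str, v: str) -> bool:
        if not self._g.has_edge(u, v):
            return False
        self._g.remove_edge(u, v)
        ok = not nx.has_path(self._g, u, v)
        self._g.add_edge(u, v)
        return ok

    def add_edge(self, u: str, v: str) -> None:
        if u not in self.states or v not in self.states:
            raise KeyError(f"unknown node in edge ({u!r}, {v!r})")
        if not self.can_add(u, v):
            raise ValueError(f"edge ({u!r}, {v!r}) would create a cycle or duplicate")
        self._g.add_edge(u, v)

    def remove_edge(self, u: str, v: str) -> None:
        self._g.remove_edge(u, v)

    def reverse_edge(self, u: str, v: str) -> None:
        if not self.can_reverse(u, v):
            raise ValueError(f"reversing ({u!r}, {v!r}) would create a cycle")
        self._g.remove_edge(u, v)
        self._g.add_edge(v, u)


@dataclass
class Cpt:
    """Conditional probability table ``P(child | parents)``.

    ``table`` has shape ``(q, r)`` where ``r`` is the child's cardinality and
    ``q`` the number of parent configurations. Rows are laid out in
    parent-state-major order over the canonical (name-sorted) parent tuple:
    the first parent's state index varies slowest. Every row sums to 1.
    """

    child: str
    parents: tuple[str, ...]
    table: np.ndarray

    def __post_init__(self):
        self.table = np.asarray(self.table, dtype=float)
        if self.table.ndim != 2:
            raise ValueError("CPT table must be 2-D (parent-config x child-state)")
        rows = self.table.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-9):
            bad = int(np.argmax(np.abs(rows - 1.0)))
            raise ValueError(
                f"CPT for {self.child!r}: row {bad} sums to {rows[bad]:.12f}, not 1"
            )
        if (self.table < -1e-12).any() or (self.table > 1 + 1e-12).any():
            raise ValueError(f"CPT for {self.child!r}: entries outside [0, 1]")


@dataclass
class BnModel:
    """The pair (DAG, CPT set); one CPT per node, parents consistent."""

    dag: Dag
    cpts: dict[str, Cpt]

    def __post_init__(self):
        if set(self.cpts) != set(self.dag.nodes):
            raise ValueError("need exactly one CPT per DAG node")
        for node, cpt in self.cpts.items():
            if cpt.parents != self.dag.parents(node):
                raise ValueError(
                    f"CPT parents {cpt.parents} != DAG parents for {node!r}"
                )
            q = int(np.prod([self.dag.cardinality(p) for p in cpt.parents])) if cpt.parents else 1
            if cpt.table.shape != (q, self.dag.cardinality(node)):
                raise ValueError(f"CPT for {node!r} has shape {cpt.table.shape}, expected ({q}, {self.dag.cardinality(node)})")

    # -- serialization -------------------------------------------------
    def to_json(self) -> str:
        obj = {
            "nodes": {n: self.dag.states[n] for n in self.dag.nodes},
            "edges": self.dag.edges,
            "cpts": {
                n: {"parents": list(c.parents), "table": c.table.tolist()}
                for n, c in self.cpts.items()
            },
        }
        return json.dumps(obj, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "BnModel":
        obj = json.loads(text)
        dag = Dag(obj["nodes"], [tuple(e) for e in obj["edges"]])
        cpts = {
            n: Cpt(n, tuple(c["parents"]), np.array(c["table"]))
            for n, c in obj["cpts"].items()
        }
        return cls(dag, cpts)

    def to_dot(self) -> str:
        lines = ["digraph bn {"]
        for n in self.dag.nodes:
            lines.append(f'  "{n}";')
        for u, v in self.dag.edges:
            lines.append(f'  "{u}" -> "{v}";')
        lines.append("}")
        return "\n".join(lines)


@dataclass(frozen=True)
class SaSchedule:
    """Simulated-annealing schedule (geometric cooling).

    Defaults converge reliably on the ≤11-node problems this package
    targets; ``max_iter`` caps the walk before the stop temperature is
    reached.
    """

    initial_temp: float = 1.0
    cooling: float = 0.995
    moves_per_temp: int = 50
    stop_temp: float = 1e-3
    max_iter: int = 20_000
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.cooling < 1.0):
            raise ValueError("cooling factor must be in (0, 1)")
        if not (self.initial_temp > self.stop_temp > 0.0):
            raise ValueError("need initial_temp > stop_temp > 0")


# ---------------------------------------------------------------------------
# scoring


class _CodedData:
    """Integer-coded view of a discrete table, with state lists per column."""

    def __init__(self, data: pd.DataFrame, states: dict[str, list[str]] | None = None):
        if data.isna().any().any():
            raise ValueError("discrete table contains missing cells")
        self.n = len(data)
        self.states: dict[str, list[str]] = {}
        self.codes: dict[str, np.ndarray] = {}
        for col in data.columns:
            vals = data[col]
            if states is not None and col in states:
                levels = list(states[col])
            elif isinstance(vals.dtype, pd.CategoricalDtype):
                levels = list(vals.cat.categories)
            else:
                levels = sorted(vals.astype(str).unique())
            lookup = {s: i for i, s in enumerate(levels)}
            try:
                codes = vals.astype(str).map(lookup).to_numpy()
            except KeyError as e:  # pragma: no cover - map returns NaN instead
                raise ValueError(f"state {e} not in levels for {col!r}")
            if pd.isna(codes).any():
                raise ValueError(f"column {col!r} contains states outside its level set")
            self.states[col] = levels
            self.codes[col] = codes.astype(np.int64)

    def cardinality(self, col: str) -> int:
        return len(self.states[col])


def _family_score(coded: _CodedData, child: str, parents: tuple[str, ...]) -> float:
    """BIC contribution of one node: multinomial loglik at MLE minus
    (log n)/2 per free parameter, with (r-1)*q free parameters."""
    n = coded.n
    r = coded.cardinality(child)
    q = 1
    idx = np.zeros(n, dtype=np.int64)
    for p in parents:
        idx = idx * coded.cardinality(p) + coded.codes[p]
        q *= coded.cardinality(p)
    flat = idx * r + coded.codes[child]
    counts = np.bincount(flat, minlength=q * r).reshape(q, r)
    row_tot = counts.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = counts * (np.log(counts) - np.log(row_tot)[:, None])
    loglik = float(np.nansum(np.where(counts > 0, ll, 0.0)))
    params = (r - 1) * q
    return loglik - 0.5 * math.log(n) * params


def bic_score(dag: Dag, data: pd.DataFrame, _coded: _CodedData | None = None,
              _cache: dict | None = None) -> float:
    """BIC of a DAG on a fully observed discrete table (larger is better).

    Decomposable: the score is a sum of per-family terms, so edge-local
    moves only touch the affected children's terms.
    """
    coded = _coded if _coded is not None else _CodedData(data, dag.states)
    if coded.n == 0:
        raise ValueError("empty data table")
    total = 0.0
    for node in dag.nodes:
        key = (node, dag.parents(node))
        if _cache is not None and key in _cache:
            total += _cache[key]
            continue
        s = _family_score(coded, node, key[1])
        if _cache is not None:
            _cache[key] = s
        total += s
    return total


# ---------------------------------------------------------------------------
# structure search


def _draw_legal_move(dag: Dag, rng: np.random.Generator, nodes: list[str],
                     blacklist: frozenset, whitelist: frozenset):
    """Uniform draw over legal single-edge moves by rejection sampling.

    Drawing uniformly from the candidate space (ordered pair x move type
    implied by edge presence) and rejecting illegal candidates yields a
    uniform draw over the legal moves. Falls back to exhaustive enumeration
    if rejection stalls; returns None when no legal move exists.
    """
    k = len(nodes)
    for _ in range(200):
        i, j = rng.integers(0, k, size=2)
        if i == j:
            continue
        u, v = nodes[i], nodes[j]
        if dag.has_edge(u, v):
            # existing edge: delete or reverse, coin flip
            if rng.random() < 0.5:
                if (u, v) not in whitelist:
                    return ("delete", u, v)
            else:
                if (u, v) not in whitelist and (v, u) not in blacklist and dag.can_reverse(u, v):
                    return ("reverse", u, v)
        else:
            if (u, v) not in blacklist and dag.can_add(u, v):
                return ("add", u, v)
        # illegal candidate: redraw
    # exhaustive fallback (rare: very constrained graphs)
    legal = []
    for u, v in itertools.permutations(nodes, 2):
        if dag.has_edge(u, v):
            if (u, v) not in whitelist:
                legal.append(("delete", u, v))
                if (v, u) not in blacklist and dag.can_reverse(u, v):
                    legal.append(("reverse", u, v))
        elif (u, v) not in blacklist and dag.can_add(u, v):
            legal.append(("add", u, v))
    if not legal:
        return None
    return legal[rng.integers(0, len(legal))]


def _apply_move(dag: Dag, move) -> None:
    kind, u, v = move
    if kind == "add":
        dag.add_edge(u, v)
    elif kind == "delete":
        dag.remove_edge(u, v)
    else:
        dag.reverse_edge(u, v)


def _undo_move(dag: Dag, move) -> None:
    kind, u, v = move
    if kind == "add":
        dag.remove_edge(u, v)
    elif kind == "delete":
        dag.add_edge(u, v)
    else:
        dag.reverse_edge(v, u)


def sa_search(data: pd.DataFrame, schedule: SaSchedule = SaSchedule(),
              whitelist=(), blacklist=(), states: dict[str, list[str]] | None = None,
              init: Dag | None = None) -> Dag:
    """Learn a DAG by simulated annealing over single-edge moves.

    Moves are edge add / delete / reverse drawn uniformly among the legal
    (acyclicity-preserving, list-respecting) moves. A better candidate is
    always accepted; a worse one with probability ``exp(dScore / T)``. The
    best-scoring DAG ever visited is returned, so the result can never score
    below the initial (by default empty, plus whitelist) graph.

    Parameters
    ----------
    whitelist
        Edges forced to be present throughout the search.
    blacklist
        Edges never allowed.
    states
        Optional explicit state order per variable (else inferred from data).
    """
    if data.shape[1] < 2:
        raise ValueError("need at least 2 variables to learn a structure")
    coded = _CodedData(data, states)
    whitelist = frozenset(tuple(e) for e in whitelist)
    blacklist = frozenset(tuple(e) for e in blacklist)
    if whitelist & blacklist:
        raise ValueError("an edge cannot be both whitelisted and blacklisted")

    dag = init.copy() if init is not None else Dag(coded.states, whitelist)
    for u, v in whitelist:
        if not dag.has_edge(u, v):
            dag.add_edge(u, v)
    nodes = dag.nodes
    rng = np.random.default_rng(schedule.seed)
    cache: dict = {}
    current = _score_all(dag, coded, cache)
    best, best_dag = current, dag.copy()

    temp = schedule.initial_temp
    it = 0
    since_cool = 0
    while temp >= schedule.stop_temp and it < schedule.max_iter:
        move = _draw_legal_move(dag, rng, nodes, blacklist, whitelist)
        if move is None:
            break
        kind, u, v = move
        affected = (v,) if kind in ("add", "delete") else (u, v)
        old_terms = sum(_cached_family(coded, cache, n, dag.parents(n)) for n in affected)
        _apply_move(dag, move)
        new_terms = sum(_cached_family(coded, cache, n, dag.parents(n)) for n in affected)
        delta = new_terms - old_terms
        if delta >= 0 or rng.random() < math.exp(delta / temp):
            current += delta
            if current > best:
                best, best_dag = current, dag.copy()
        else:
            _undo_move(dag, move)
        it += 1
        since_cool += 1
        if since_cool >= schedule.moves_per_temp:
            temp *= schedule.cooling
            since_cool = 0
    return best_dag


def _cached_family(coded: _CodedData, cache: dict, node: str, parents: tuple) -> float:
    key = (node, parents)
    if key not in cache:
        cache[key] = _family_score(coded, node, parents)
    return cache[key]


def _score_all(dag: Dag, coded: _CodedData, cache: dict) -> float:
    return sum(_cached_family(coded, cache, n, dag.parents(n)) for n in dag.nodes)


# ---------------------------------------------------------------------------
# parameters and inference


def fit_cpts(dag: Dag, data: pd.DataFrame, smoothing: float = 1.0) -> BnModel:
    """Estimate one CPT per node from a fully observed table.

    ``P(x_i = s | pa = c) = (N(s, c) + smoothing) / (N(c) + smoothing * r_i)``:
    ``smoothing=0`` gives the multinomial MLE, the default 1 is Laplace's
    rule. Parent configurations never seen in the data get a uniform row.
    """
    if smoothing < 0:
        raise ValueError("smoothing pseudo-count must be >= 0")
    coded = _CodedData(data, dag.states)
    cpts = {}
    for node in dag.nodes:
        parents = dag.parents(node)
        r = dag.cardinality(node)
        q = int(np.prod([dag.cardinality(p) for p in parents])) if parents else 1
        idx = np.zeros(coded.n, dtype=np.int64)
        for p in parents:
            idx = idx * dag.cardinality(p) + coded.codes[p]
        flat = idx * r + coded.codes[node]
        counts = np.bincount(flat, minlength=q * r).reshape(q, r).astype(float)
        row_tot = counts.sum(axis=1, keepdims=True)
        table = np.empty_like(counts)
        seen = row_tot[:, 0] > 0
        if smoothing > 0:
            table = (counts + smoothing) / (row_tot + smoothing * r)
        else:
            table[seen] = counts[seen] / row_tot[seen]
        table[~seen] = 1.0 / r
        cpts[node] = Cpt(node, parents, table)
    return BnModel(dag, cpts)


def _parent_config_index(dag: Dag, parents: tuple[str, ...], assignment: dict) -> int:
    idx = 0
    for p in parents:
        idx = idx * dag.cardinality(p) + dag.states[p].index(assignment[p])
    return idx


def joint_probability(model: BnModel, assignment: dict[str, str]) -> float:
    """P(full assignment) = product of CPT lookups (node-order invariant)."""
    missing = set(model.dag.nodes) - set(assignment)
    if missing:
        raise KeyError(f"assignment missing nodes: {sorted(missing)}")
    p = 1.0
    for node in model.dag.nodes:
        cpt = model.cpts[node]
        row = _parent_config_index(model.dag, cpt.parents, assignment)
        p *= cpt.table[row, model.dag.states[node].index(assignment[node])]
    return p


def _enumerate_assignments(dag: Dag, fixed: dict[str, str] | None = None):
    fixed = fixed or {}
    free = [n for n in dag.nodes if n not in fixed]
    for combo in itertools.product(*(dag.states[n] for n in free)):
        a = dict(fixed)
        a.update(zip(free, combo))
        yield a


def marginal_cpt(model: BnModel, target: str, factor: str) -> pd.DataFrame:
    """P(target | factor) marginalizing every other variable out of the joint.

    Computed by exact enumeration; feasible for the small networks this
    package handles. Rows (one per factor state) sum to 1; a factor state
    with zero probability under the model yields a NaN row.
    """
    if target == factor:
        raise ValueError("target and factor must be distinct nodes")
    t_states = model.dag.states[target]
    f_states = model.dag.states[factor]
    table = np.zeros((len(f_states), len(t_states)))
    for a in _enumerate_assignments(model.dag):
        p = joint_probability(model, a)
        table[f_states.index(a[factor]), t_states.index(a[target])] += p
    rows = table.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        table = np.where(rows > 0, table / rows, np.nan)
    return pd.DataFrame(table, index=pd.Index(f_states, name=factor),
                        columns=pd.Index(t_states, name=target))


def predict(model: BnModel, target: str, evidence: dict[str, str]) -> tuple[str, pd.Series]:
    """Posterior of ``target`` given evidence, by enumeration; argmax state.

    Ties go to the earliest state in the target's state order — risk nodes
    list ``low_risk`` first, so ties resolve conservatively to low risk.
    """
    for node, state in evidence.items():
        if state not in model.dag.states[node]:
            raise ValueError(f"{state!r} is not a state of {node!r}")
    if target in evidence:
        raise ValueError("target cannot appear in the evidence")
    t_states = model.dag.states[target]
    mass = np.zeros(len(t_states))
    for i, ts in enumerate(t_states):
        fixed = dict(evidence)
        fixed[target] = ts
        mass[i] = sum(joint_probability(model, a)
                      for a in _enumerate_assignments(model.dag, fixed))
    total = mass.sum()
    if total <= 0:
        raise ValueError("evidence has zero probability under the model")
    posterior = pd.Series(mass / total, index=t_states, name=target)
    best = float(posterior.max())
    winner = next(s for s in t_states if posterior[s] >= best - 1e-12)
    return winner, posterior


def sample(model: BnModel, n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Ancestral sampling: n i.i.d. rows from the network's joint."""
    order = model.dag.topological_order()
    out: dict[str, np.ndarray] = {}
    codes: dict[str, np.ndarray] = {}
    for node in order:
        cpt = model.cpts[node]
        r = model.dag.cardinality(node)
        if not cpt.parents:
            idx = np.zeros(n, dtype=np.int64)
        else:
            idx = np.zeros(n, dtype=np.int64)
            for p in cpt.parents:
                idx = idx * model.dag.cardinality(p) + codes[p]
        u = rng.random(n)
        cum = np.cumsum(cpt.table, axis=1)
        codes[node] = (u[:, None] > cum[idx]).sum(axis=1).astype(np.int64)
        states = np.array(model.dag.states[node], dtype=object)
        out[node] = states[codes[node]]
    return pd.DataFrame({n_: out[n_] for n_ in model.dag.nodes})


# ---------------------------------------------------------------------------
# structure comparison


def _v_structures(dag: Dag) -> set[tuple[str, str, str]]:
    vs = set()
    for c in dag.nodes:
        ps = dag.parents(c)
        for a, b in itertools.combinations(ps, 2):
            if not dag.has_edge(a, b) and not dag.has_edge(b, a):
                vs.add((min(a, b), c, max(a, b)))
    return vs


def markov_equivalent(d1: Dag, d2: Dag) -> bool:
    """Same skeleton and same v-structures (colliders with unmarried parents)."""
    sk1 = {frozenset(e) for e in d1.edges}
    sk2 = {frozenset(e) for e in d2.edges}
    return sk1 == sk2 and _v_structures(d1) == _v_structures(d2)
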