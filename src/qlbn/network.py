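"""Discrete Bayesian networks with exact inference by enumeration.

The central object is :class:`BayesNet`, a directed acyclic graph of
finitely-valued variables, each carrying a conditional probability table
(CPT).  Inference is performed by full enumeration of the hidden variables:
for a binary query variable *Q* with evidence *e*, the posterior is

    p(q | e) = alpha * sum_i p(q, e, x_i),      alpha = 1 / p(e),

where the sum runs over every joint configuration ``x_i`` of the variables
that are neither queried nor observed.  The per-configuration joint terms
are exposed through :class:`JointDecomposition` because the interference
machinery in :mod:`qlbn.waves` assigns one phase per hidden configuration.

Networks are serialised in a small JSON dialect::

    {"variables": [{"name": ..., "states": [...]}, ...],
     "tables": [{"child": ..., "parents": [...],
                 "rows": [{"given": {parent: state, ...},
                           "dist": {state: prob, ...}}, ...]}]}
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx

from .errors import (
    CyclicGraphError,
    DuplicateTableError,
    ImpossibleEvidenceError,
    MissingTableError,
    NetworkValidationError,
    RowSumError,
    UnsupportedQueryError,
)

#: validation tolerance for CPT row sums
ROW_SUM_TOL = 1e-9
#: tolerance for internal probability comparisons
PROB_TOL = 1e-12


@dataclass(frozen=True)
class VariableSpec:
    """A named discrete variable with an ordered list of at least two states."""

    name: str
    states: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.states) < 2:
            raise NetworkValidationError(
                f"variable {self.name!r} needs at least two states, got {len(self.states)}"
            )
        if len(set(self.states)) != len(self.states):
            raise NetworkValidationError(f"variable {self.name!r} has duplicate state labels")


@dataclass(frozen=True)
class ConditionalTable:
    """CPT of one child variable: a distribution over its states per parent combination.

    ``rows`` maps a tuple of parent states (ordered as ``parents``) to a
    tuple of probabilities ordered as the child's state list.
    """

    child: str
    parents: tuple[str, ...]
    rows: Mapping[tuple[str, ...], tuple[float, ...]]

    def distribution(self, parent_states: tuple[str, ...]) -> tuple[float, ...]:
        return self.rows[parent_states]


@dataclass(frozen=True)
class EvidenceMap:
    """Observed variable -> state assignments; the query variable must not appear."""

    assignments: Mapping[str, str] = field(default_factory=dict)

    def __contains__(self, name: str) -> bool:
        return name in self.assignments

    def items(self):
        return self.assignments.items()


@dataclass(frozen=True)
class JointDecomposition:
    """Per-hidden-configuration joint terms p(outcome, e, x_i) for one query outcome.

    ``terms`` is ordered by the deterministic lexicographic enumeration of
    hidden configurations (variable declaration order, then state
    declaration order), so term index *i* is a stable phase index.
    ``evidence_mass`` is p(e), the sum of terms over *both* query outcomes.
    """

    query_variable: str
    query_outcome: str
    hidden_variables: tuple[str, ...]
    terms: tuple[tuple[tuple[str, ...], float], ...]
    evidence_mass: float

    @property
    def m(self) -> int:
        """Number of hidden configurations (the M of the interference normalisation)."""
        return len(self.terms)

    @property
    def term_values(self) -> tuple[float, ...]:
        return tuple(t for _, t in self.terms)


class BayesNet:
    """A validated discrete Bayesian network."""

    def __init__(self, variables: Sequence[VariableSpec], tables: Sequence[ConditionalTable]):
        self.variables = tuple(variables)
        self._var_index = {v.name: v for v in self.variables}
        if len(self._var_index) != len(self.variables):
            raise NetworkValidationError("duplicate variable names")
        self.tables: dict[str, ConditionalTable] = {}
        for t in tables:
            if t.child in self.tables:
                raise DuplicateTableError(f"two tables for variable {t.child!r}")
            self.tables[t.child] = t
        self._validate()

    # -- validation -----------------------------------------------------

    def _validate(self) -> None:
        for v in self.variables:
            if v.name not in self.tables:
                raise MissingTableError(f"no conditional table for variable {v.name!r}")
        for name in self.tables:
            if name not in self._var_index:
                raise NetworkValidationError(f"table for undeclared variable {name!r}")

        g = nx.DiGraph()
        g.add_nodes_from(self._var_index)
        for t in self.tables.values():
            for p in t.parents:
                if p not in self._var_index:
                    raise NetworkValidationError(
                        f"table for {t.child!r} references unknown parent {p!r}"
                    )
                g.add_edge(p, t.child)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise CyclicGraphError(f"conditional tables induce a cycle: {cycle}")
        self.graph = g

        for t in self.tables.values():
            child = self._var_index[t.child]
            expected = set(
                itertools.product(*(self._var_index[p].states for p in t.parents))
            )
            got = set(t.rows)
            if got != expected:
                missing = expected - got
                extra = got - expected
                raise NetworkValidationError(
                    f"table for {t.child!r}: missing parent rows {sorted(missing)}, "
                    f"unexpected rows {sorted(extra)}"
                )
            for combo, dist in t.rows.items():
                if len(dist) != len(child.states):
                    raise NetworkValidationError(
                        f"table for {t.child!r}, row {combo}: expected "
                        f"{len(child.states)} probabilities, got {len(dist)}"
                    )
                if any(p < -PROB_TOL or p > 1 + PROB_TOL for p in dist):
                    raise RowSumError(
                        f"table for {t.child!r}, row {combo}: entry outside [0, 1]"
                    )
                s = sum(dist)
                if abs(s - 1.0) > ROW_SUM_TOL:
                    raise RowSumError(
                        f"table for {t.child!r}, row {combo}: probabilities sum to {s!r}"
                    )

    # -- accessors ------------------------------------------------------

    def variable(self, name: str) -> VariableSpec:
        try:
            return self._var_index[name]
        except KeyError:
            raise NetworkValidationError(f"unknown variable {name!r}") from None

    @property
    def variable_names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables)

    # -- serialisation --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "variables": [
                {"name": v.name, "states": list(v.states)} for v in self.variables
            ],
            "tables": [
                {
                    "child": t.child,
                    "parents": list(t.parents),
                    "rows": [
                        {
                            "given": dict(zip(t.parents, combo)),
                            "dist": dict(
                                zip(self._var_index[t.child].states, dist)
                            ),
                        }
                        for combo, dist in sorted(t.rows.items())
                    ],
                }
                for t in (self.tables[v.name] for v in self.variables)
            ],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def build_network(spec: Mapping) -> BayesNet:
    """Construct and validate a :class:`BayesNet` from the JSON dialect.

    Raises a specific :class:`~qlbn.errors.NetworkValidationError` subclass
    for each kind of violation (cycle, missing/duplicate table, bad row sum).
    """
    try:
        variables = [
            VariableSpec(v["name"], tuple(v["states"])) for v in spec["variables"]
        ]
    except (KeyError, TypeError) as exc:
        raise NetworkValidationError(f"malformed variables section: {exc}") from exc
    var_index = {v.name: v for v in variables}

    tables = []
    for t in spec.get("tables", []):
        try:
            child = t["child"]
            parents = tuple(t["parents"])
            raw_rows = t["rows"]
        except (KeyError, TypeError) as exc:
            raise NetworkValidationError(f"malformed table entry: {exc}") from exc
        if child not in var_index:
            raise NetworkValidationError(f"table for undeclared variable {child!r}")
        child_states = var_index[child].states
        rows = {}
        for row in raw_rows:
            given = row["given"]
            combo = tuple(given[p] for p in parents)
            dist = row["dist"]
            try:
                rows[combo] = tuple(float(dist[s]) for s in child_states)
            except KeyError as exc:
                raise NetworkValidationError(
                    f"table for {child!r}: row {combo} lacks a probability for state {exc}"
                ) from exc
        tables.append(ConditionalTable(child, parents, rows))
    return BayesNet(variables, tables)


def load_network(path) -> BayesNet:
    """Read a network from a JSON file in the dialect above."""
    with open(path) as fh:
        return build_network(json.load(fh))


def joint_probability(net: BayesNet, assignment: Mapping[str, str]) -> float:
    """Chain-rule joint probability of a complete state assignment.

    The joint factorises as the product of one CPT entry per variable,
    each conditioned on the assigned states of its parents.
    """
    missing = [v.name for v in net.variables if v.name not in assignment]
    if missing:
        raise NetworkValidationError(f"assignment does not cover variables {missing}")
    prob = 1.0
    for var in net.variables:
        table = net.tables[var.name]
        combo = tuple(assignment[p] for p in table.parents)
        dist = table.distribution(combo)
        state = assignment[var.name]
        try:
            idx = var.states.index(state)
        except ValueError:
            raise NetworkValidationError(
                f"{state!r} is not a state of variable {var.name!r}"
            ) from None
        prob *= dist[idx]
    return prob


def hidden_configurations(
    net: BayesNet, query: str, evidence: EvidenceMap
) -> tuple[tuple[str, ...], list[tuple[str, ...]]]:
    """Hidden variables and their joint configurations in deterministic order.

    Order is lexicographic in (variable declaration order, state declaration
    order), which makes phase indices reproducible across runs.
    """
    hidden = tuple(
        v.name for v in net.variables if v.name != query and v.name not in evidence
    )
    configs = list(itertools.product(*(net.variable(h).states for h in hidden)))
    return hidden, configs


def decompose_query(
    net: BayesNet, query: str, outcome: str, evidence: EvidenceMap | None = None
) -> JointDecomposition:
    """Enumerate the joint terms p(outcome, e, x_i) over hidden configurations.

    The query variable must be binary; hidden and evidence variables may
    have any arity.  Zero-probability configurations are retained as terms
    so that the configuration count M (and the 2/(M-1) interference
    normalisation downstream) reflects the full enumeration.
    """
    evidence = evidence or EvidenceMap()
    qvar = net.variable(query)
    if len(qvar.states) != 2:
        raise UnsupportedQueryError(
            f"query variable {query!r} has {len(qvar.states)} states; only binary queries are supported"
        )
    if query in evidence:
        raise NetworkValidationError(f"query variable {query!r} appears in the evidence")
    if outcome not in qvar.states:
        raise NetworkValidationError(f"{outcome!r} is not a state of {query!r}")
    for name, state in evidence.items():
        if state not in net.variable(name).states:
            raise NetworkValidationError(f"{state!r} is not a state of {name!r}")

    hidden, configs = hidden_configurations(net, query, evidence)

    def terms_for(out: str) -> list[tuple[tuple[str, ...], float]]:
        result = []
        for config in configs:
            assignment = dict(evidence.items())
            assignment[query] = out
            assignment.update(zip(hidden, config))
            result.append((config, joint_probability(net, assignment)))
        return result

    this_terms = terms_for(outcome)
    other = next(s for s in qvar.states if s != outcome)
    mass = sum(t for _, t in this_terms) + sum(t for _, t in terms_for(other))
    return JointDecomposition(
        query_variable=query,
        query_outcome=outcome,
        hidden_variables=hidden,
        terms=tuple(this_terms),
        evidence_mass=mass,
    )


def classical_posterior(d_yes: JointDecomposition, d_no: JointDecomposition) -> float:
    """Classical posterior p(outcome | e) = (sum of joint terms) / p(e).

    ``d_yes`` and ``d_no`` must decompose complementary outcomes of the same
    query under the same evidence; the returned value and its counterpart
    sum to one.
    """
    if d_yes.query_variable != d_no.query_variable or d_yes.query_outcome == d_no.query_outcome:
        raise NetworkValidationError(
            "decompositions must cover complementary outcomes of one query"
        )
    if d_yes.evidence_mass <= PROB_TOL:
        raise ImpossibleEvidenceError(
            f"evidence has probability {d_yes.evidence_mass}; posterior undefined"
        )
    return sum(d_yes.term_values) / d_yes.evidence_mass
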