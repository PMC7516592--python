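"""Replication of the disjunction-effect experiment tables.

The package bundles the published response frequencies of two families of
experiments as CSV fixtures:

* **Prisoner's Dilemma** -- probability of defecting given the opponent's
  known choice (defect / cooperate), plus the observed probability of
  defecting when the opponent's choice is unknown;
* **Two-Stage Gamble** -- probability of playing a second gamble given a
  known win / loss on the first, plus the observed probability when the
  first outcome is unknown.

In both families the observed unknown-condition probability falls outside
the classical total-probability mixture -- the disjunction effect.  Each
row is encoded as a two-node network X -> Y with a uniform prior on the
unknown condition X, and the law of maximum uncertainty plus the
quarter-law baseline are recomputed for every row.

The *Average* row of each table follows the source convention: its
classical value is the mean of the per-row classical values (not the
classical value of the averaged conditionals), and its wave is built with
the base pre-rounded to the two printed decimals.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import numpy as np
import pandas as pd

from .errors import InvalidProbabilityError
from .network import BayesNet, ConditionalTable, VariableSpec
from .uncertainty import (
    MaxPrediction,
    WaveInterval,
    predict_from_waves,
    predict_max_uncertainty,
    quarter_law,
    with_base,
)
from .network import EvidenceMap, decompose_query
from .waves import build_wave

logger = logging.getLogger(__name__)

CSV_COLUMNS = [
    "label",
    "cond_given_first",
    "cond_given_not_first",
    "observed_sub",
    "classical_printed",
    "sample_size",
    "modelled_outcome",
]

#: fixture names bundled with the package
PRISONERS_DILEMMA = "prisoners_dilemma"
TWO_STAGE_GAMBLE = "two_stage_gamble"


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero at ``ndigits`` decimals (table convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ExperimentRecord:
    """One experiment row: conditional response rates and the observed rate.

    ``cond_given_first`` is p(o | x) and ``cond_given_not_first`` is
    p(o | not-x), where o is ``modelled_outcome`` (defection for the
    Prisoner's Dilemma, playing for the Two-Stage Gamble) and x the
    favourable known condition.  ``observed_sub`` is the reported
    unknown-condition response rate; it is data for comparison only and
    never feeds the prediction.
    """

    label: str
    cond_given_first: float
    cond_given_not_first: float
    observed_sub: float
    classical_printed: float
    sample_size: int
    modelled_outcome: str

    def __post_init__(self) -> None:
        for name in ("cond_given_first", "cond_given_not_first", "observed_sub", "classical_printed"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidProbabilityError(f"{self.label}: {name}={v} outside [0, 1]")
        if self.sample_size <= 0:
            raise InvalidProbabilityError(f"{self.label}: sample_size must be positive")
        if self.modelled_outcome not in ("y", "not_y"):
            raise InvalidProbabilityError(
                f"{self.label}: modelled_outcome must be 'y' or 'not_y'"
            )

    @property
    def is_average(self) -> bool:
        return "average" in self.label.lower()


@dataclass(frozen=True)
class ReplicationRow:
    """Recomputed table row: interval, prediction, classical and baselines."""

    label: str
    interval: WaveInterval
    pq: float
    classical: float
    observed: float
    pdt: float
    principle: str
    sample_size: int


def load_experiments(path) -> list[ExperimentRecord]:
    """Read experiment records from a CSV file with the bundled header."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        warnings.warn(f"experiment file {path} is empty", stacklevel=2)
        return []
    if df.empty:
        warnings.warn(f"experiment file {path} has no rows", stacklevel=2)
        return []
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise InvalidProbabilityError(f"experiment CSV lacks columns {sorted(missing)}")
    return [
        ExperimentRecord(
            label=str(row.label),
            cond_given_first=float(row.cond_given_first),
            cond_given_not_first=float(row.cond_given_not_first),
            observed_sub=float(row.observed_sub),
            classical_printed=float(row.classical_printed),
            sample_size=int(row.sample_size),
            modelled_outcome=str(row.modelled_outcome),
        )
        for row in df.itertuples(index=False)
    ]


def write_experiments(records, path) -> None:
    """Write records back to CSV (inverse of :func:`load_experiments`)."""
    pd.DataFrame(
        [
            {c: getattr(r, c if c != "label" else "label") for c in CSV_COLUMNS}
            for r in records
        ],
        columns=CSV_COLUMNS,
    ).to_csv(path, index=False)


def bundled_experiments(name: str) -> list[ExperimentRecord]:
    """Load one of the bundled fixtures (:data:`PRISONERS_DILEMMA` or
    :data:`TWO_STAGE_GAMBLE`)."""
    ref = resources.files("qlbn.data").joinpath(f"{name}.csv")
    with resources.as_file(ref) as path:
        return load_experiments(path)


def encode_record(r: ExperimentRecord) -> BayesNet:
    """Encode a row as the two-node network X -> Y with uniform prior.

    The unknown condition X ('x' / 'not_x') gets p(x) = 0.5, modelling the
    no-information experimental condition; the response Y ('y' / 'not_y')
    is conditioned on X via the row's response rates for the modelled
    outcome.
    """
    p1, p2 = r.cond_given_first, r.cond_given_not_first
    if r.modelled_outcome == "y":
        rows = {("x",): (p1, 1.0 - p1), ("not_x",): (p2, 1.0 - p2)}
    else:
        rows = {("x",): (1.0 - p1, p1), ("not_x",): (1.0 - p2, p2)}
    return BayesNet(
        [VariableSpec("X", ("x", "not_x")), VariableSpec("Y", ("y", "not_y"))],
        [
            ConditionalTable("X", (), {(): (0.5, 0.5)}),
            ConditionalTable("Y", ("X",), rows),
        ],
    )


def _predict_record(r: ExperimentRecord, classical_override: float | None = None) -> MaxPrediction:
    """Run the maximum-uncertainty pipeline for one record.

    ``classical_override`` replaces the wave bases with a pre-rounded
    classical value for the modelled outcome (the Average-row convention).
    """
    net = encode_record(r)
    if classical_override is None:
        return predict_max_uncertainty(net, "Y")
    d_yes = decompose_query(net, "Y", "y", EvidenceMap())
    d_no = decompose_query(net, "Y", "not_y", EvidenceMap())
    w_yes, w_no = build_wave(d_yes), build_wave(d_no)
    b = round_half_away(classical_override, 2)
    if r.modelled_outcome == "y":
        w_yes, w_no = with_base(w_yes, b), with_base(w_no, 1.0 - b)
    else:
        w_no, w_yes = with_base(w_no, b), with_base(w_yes, 1.0 - b)
    return predict_from_waves(w_yes, w_no)


def classical_value(r: ExperimentRecord) -> float:
    """Classical total probability of the modelled outcome under uniform prior."""
    return 0.5 * r.cond_given_first + 0.5 * r.cond_given_not_first


def replicate_tables(records: list[ExperimentRecord]) -> list[ReplicationRow]:
    """Recompute interval, pq, classical and quarter-law columns per row.

    Average rows get their classical value as the mean of the other rows'
    classical values, and their waves are built on that value pre-rounded
    to two decimals.
    """
    plain = [r for r in records if not r.is_average]
    rows = []
    for r in records:
        if r.is_average and plain:
            classical = float(np.mean([classical_value(p) for p in plain]))
            pred = _predict_record(r, classical_override=classical)
        else:
            classical = classical_value(r)
            pred = _predict_record(r)
        o = r.modelled_outcome
        rows.append(
            ReplicationRow(
                label=r.label,
                interval=pred.intervals[o],
                pq=pred.pq[o],
                classical=classical,
                observed=r.observed_sub,
                pdt=quarter_law(classical).value,
                principle=pred.principle,
                sample_size=r.sample_size,
            )
        )
    return rows


def replication_frame(rows: list[ReplicationRow], ndigits: int | None = None) -> pd.DataFrame:
    """Tabulate replication rows; optional half-away rounding for display."""
    def fmt(x: float) -> float:
        return round_half_away(x, ndigits) if ndigits is not None else x

    return pd.DataFrame(
        {
            "label": [r.label for r in rows],
            "interval_lo": [fmt(r.interval.lo) for r in rows],
            "interval_hi": [fmt(r.interval.hi) for r in rows],
            "observed": [r.observed for r in rows],
            "pq": [fmt(r.pq) for r in rows],
            "classical": [fmt(r.classical) for r in rows],
            "pdt": [fmt(r.pdt) for r in rows],
            "principle": [r.principle for r in rows],
        }
    )


def random_network(
    seed: int,
    n_vars: int = 4,
    max_parents: int = 2,
    doubly_stochastic: bool = False,
) -> BayesNet:
    """Seeded random binary network for property testing.

    Variables ``v0..v{n-1}`` each pick up to ``max_parents`` parents among
    their predecessors (guaranteeing acyclicity) with CPT entries drawn
    uniformly.  The same seed yields an identical network.  In
    ``doubly_stochastic`` mode the structure is the chain v0 -> v1 -> ...
    and every CPT is doubly stochastic (row o given parent state flips to
    1-o for the other parent state), which forces dominance case 3 between
    the two outcome waves of any query.
    """
    if n_vars < 2:
        raise ValueError("need at least two variables")
    rng = np.random.default_rng(seed)
    states = ("t", "f")
    variables = [VariableSpec(f"v{i}", states) for i in range(n_vars)]
    tables = []
    for i in range(n_vars):
        if doubly_stochastic:
            parents = (f"v{i-1}",) if i > 0 else ()
        else:
            k = int(rng.integers(0, min(i, max_parents) + 1))
            idx = sorted(rng.choice(i, size=k, replace=False)) if k else []
            parents = tuple(f"v{j}" for j in idx)
        rows = {}
        if doubly_stochastic and parents:
            a = float(rng.uniform())
            rows[("t",)] = (a, 1.0 - a)
            rows[("f",)] = (1.0 - a, a)
        else:
            for combo in itertools.product(states, repeat=len(parents)):
                p = float(rng.uniform())
                rows[combo] = (p, 1.0 - p)
        tables.append(ConditionalTable(f"v{i}", parents, rows))
    return BayesNet(variables, tables)
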