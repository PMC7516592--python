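"""The law of balance: phase constraints that cancel interference.

Two complementary outcome waves are *balanced* when their interference
terms cancel pair by pair:

    c^y_ij cos(d^y_ij) = - c^not-y_ij cos(d^not-y_ij)

for each hidden-configuration pair (i, j), with d the phase difference
theta_i - theta_j.  Balanced waves sum to one, so each wave is a genuine
probability without any Bayes renormalisation.

For each pair the ratio r = c^y_ij / c^not-y_ij classifies which wave
dominates:

* case 1 (r < 1): the not-y wave dominates; any phase of the y wave admits
  a balancing counterpart d_not = arccos(-r cos d).
* case 2 (r > 1): the y wave dominates; the roles mirror.
* case 3 (r = 1): neither dominates -- doubly stochastic conditional
  tables; d_not = d +- pi and the induced transform is unitary-like.

The dominated wave's phase is free; the dominating wave's cosine is
confined to [-1/r, 1/r].  With M configurations there are M(M-1)/2 such
sub-equations, each solvable independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import InfeasiblePhaseError, MismatchedWaveError
from .waves import PhaseVector, WaveSpec, evaluate_wave

#: tolerance below which a coefficient ratio counts as exactly one (case 3)
CASE3_TOL = 1e-12
#: coefficients below this are treated as exactly zero (degenerate pair)
DEGENERATE_TOL = 1e-300

CASE_FIRST_DOMINATED = 1
CASE_SECOND_DOMINATED = 2
CASE_NONE_DOMINATES = 3


@dataclass(frozen=True)
class DominancePair:
    """Dominance classification of one interference pair.

    ``ratio`` is c_first / c_second (``inf`` when c_second is zero);
    ``case`` is 1 if the second wave dominates (ratio < 1), 2 if the first
    dominates (ratio > 1), 3 at equality.  ``degenerate`` marks pairs where
    both coefficients vanish: they contribute no interference and impose no
    phase constraint.
    """

    pair: tuple[int, int]
    c_first: float
    c_second: float
    ratio: float
    case: int
    degenerate: bool = False


@dataclass(frozen=True)
class BalanceSystem:
    """All M(M-1)/2 pairwise balance sub-equations between two waves."""

    m: int
    pairs: dict[tuple[int, int], DominancePair]

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def global_case(self) -> int | None:
        """Single dominance label; defined only for M = 2 (one pair)."""
        if self.m == 2:
            return self.pairs[(0, 1)].case
        return None


def classify_pair(c_first: float, c_second: float, pair: tuple[int, int] = (0, 1)) -> DominancePair:
    """Classify a coefficient pair into dominance case 1, 2 or 3.

    Symmetric: swapping the arguments swaps cases 1 and 2 and inverts the
    ratio.  Two zero coefficients yield a degenerate pair (flagged, case 3
    by convention, no constraint).
    """
    if c_first < 0 or c_second < 0:
        raise ValueError("interference coefficients are non-negative")
    if c_first <= DEGENERATE_TOL and c_second <= DEGENERATE_TOL:
        return DominancePair(pair, c_first, c_second, 1.0, CASE_NONE_DOMINATES, degenerate=True)
    ratio = math.inf if c_second <= DEGENERATE_TOL else c_first / c_second
    if abs(ratio - 1.0) <= CASE3_TOL:
        case = CASE_NONE_DOMINATES
    elif ratio < 1.0:
        case = CASE_FIRST_DOMINATED
    else:
        case = CASE_SECOND_DOMINATED
    return DominancePair(pair, c_first, c_second, ratio, case)


def balanced_counterpart_phase(delta: float, pair: DominancePair) -> float:
    """Phase difference of the dominating wave that balances the dominated one.

    For case 1, ``delta`` is the (free) phase difference of the first wave
    and the returned value is the second wave's difference
    arccos(-r cos delta); case 2 mirrors with 1/r; case 3 returns
    arccos(-cos delta) = the pi-shifted phase.  Raises
    :class:`~qlbn.errors.InfeasiblePhaseError` when no balancing phase
    exists (arccos argument outside [-1, 1]) -- the caller must constrain
    the dominating wave instead.
    """
    if pair.degenerate:
        raise InfeasiblePhaseError("degenerate pair imposes no phase constraint")
    if pair.case == CASE_FIRST_DOMINATED:
        r = pair.ratio
    elif pair.case == CASE_SECOND_DOMINATED:
        r = 1.0 / pair.ratio
    else:
        r = 1.0
    arg = -r * math.cos(delta)
    if abs(arg) > 1.0 + 1e-12:
        raise InfeasiblePhaseError(
            f"arccos argument {arg} outside [-1, 1]; phase {delta} cannot be balanced"
        )
    return math.acos(max(-1.0, min(1.0, arg)))


def build_balance_system(w_first: WaveSpec, w_second: WaveSpec) -> BalanceSystem:
    """Classify every interference pair between two complementary waves."""
    if w_first.m != w_second.m:
        raise MismatchedWaveError(
            f"waves have different configuration counts {w_first.m} vs {w_second.m}"
        )
    if w_first.m < 2:
        raise MismatchedWaveError("a balance system needs at least two configurations")
    pairs = {
        ij: classify_pair(w_first.coeffs[ij], w_second.coeffs[ij], ij)
        for ij in sorted(w_first.coeffs)
    }
    return BalanceSystem(m=w_first.m, pairs=pairs)


def balance_residual(
    w_first: WaveSpec,
    phases_first: PhaseVector | tuple[float, ...],
    w_second: WaveSpec,
    phases_second: PhaseVector | tuple[float, ...],
) -> float:
    """Signed interference imbalance between the two waves.

    Zero iff the waves are balanced, in which case they sum to one:
    evaluate_wave(w_first) + evaluate_wave(w_second) = base_1 + base_2 +
    residual = 1 + 0 (with evidence-conditioned terms).
    """
    if w_first.m != w_second.m:
        raise MismatchedWaveError("mismatched configuration counts")
    pf = phases_first.phases if isinstance(phases_first, PhaseVector) else tuple(phases_first)
    ps = phases_second.phases if isinstance(phases_second, PhaseVector) else tuple(phases_second)
    total = 0.0
    for (i, j), c in w_first.coeffs.items():
        total += w_first.norm_factor * c * math.cos(pf[i] - pf[j])
    for (i, j), c in w_second.coeffs.items():
        total += w_second.norm_factor * c * math.cos(ps[i] - ps[j])
    return total


def balanced_pair_waves(
    w_first: WaveSpec, w_second: WaveSpec, delta: float
) -> tuple[float, float]:
    """Evaluate both M = 2 waves at a balanced phase assignment.

    ``delta`` is the phase difference of the dominated wave; the
    counterpart's difference follows from the balance sub-equation.
    Returns (value_first, value_second); the pair sums to one.
    """
    if w_first.m != 2 or w_second.m != 2:
        raise MismatchedWaveError("balanced pair evaluation is defined for M = 2")
    system = build_balance_system(w_first, w_second)
    dom = system.pairs[(0, 1)]
    if dom.case == CASE_SECOND_DOMINATED:
        d_second = delta
        d_first = balanced_counterpart_phase(delta, dom)
    else:
        d_first = delta
        d_second = balanced_counterpart_phase(delta, dom)
    v1 = evaluate_wave(w_first, (d_first, 0.0))
    v2 = evaluate_wave(w_second, (d_second, 0.0))
    return v1, v2
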