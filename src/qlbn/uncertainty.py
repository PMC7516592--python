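"""The law of maximum uncertainty: interval bounds and the pq prediction.

A balanced probability wave can only move within an attainable interval
around its classical base.  For M = 2 the interval has the closed form

    I = [base - h, base + h],        h = 2 sqrt(t_1 t_2)

(the full positive interference of the dominated wave; dominance
feasibility caps h at the counterpart's amplitude when the wave itself
dominates).  For M >= 3 the interval is found by deterministic numeric
optimisation of the wave over gauge-fixed phase differences, with the
cosine of any pair in which the wave dominates clamped to the feasible
band [-1/r, 1/r].

The prediction rule then dispatches on interval overlap:

* **entropy principle** (disjoint intervals): each wave takes the endpoint
  of its interval nearest the uniform distribution 0.5 -- the value of
  largest entropy that loses no wave information.
* **mirror principle** (overlapping intervals): the larger-base outcome
  takes the *full positive interference amplitude of the smaller wave*
  (approximately the smaller classical probability, by the AM-GM
  inequality), mirroring the probability values; the smaller-base outcome
  takes the complement.

A fixed-interference baseline (the "quarter law" of quantum prospect
decision theory, interference term 0.25) is provided for comparison.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .errors import MismatchedWaveError, PrincipleDispatchError, UnsupportedQueryError
from .network import BayesNet, EvidenceMap, classical_posterior, decompose_query
from .balance import BalanceSystem, build_balance_system
from .waves import WaveSpec, build_wave

ENTROPY = "entropy"
MIRROR = "mirror"

#: bases closer than this are treated as tied (forcing the mirror-form rule)
BASE_TIE_TOL = 1e-12


@dataclass(frozen=True)
class WaveInterval:
    """Attainable range [lo, hi] of a balanced probability wave."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (-1e-12 <= self.lo <= self.hi <= 1 + 1e-12):
            raise ValueError(f"invalid interval [{self.lo}, {self.hi}]")

    @property
    def width(self) -> float:
        return self.hi - self.lo

    def nearest_to_half(self) -> float:
        """The endpoint of largest binary entropy (closest to 0.5)."""
        if abs(self.hi - 0.5) <= abs(self.lo - 0.5):
            return self.hi
        return self.lo

    def mirror(self) -> "WaveInterval":
        return WaveInterval(1.0 - self.hi, 1.0 - self.lo)


@dataclass(frozen=True)
class MaxPrediction:
    """Outcome of the law of maximum uncertainty for one binary query."""

    pq: dict[str, float]
    principle: str
    intervals: dict[str, WaveInterval]
    classical: dict[str, float]
    dominance: BalanceSystem
    complementarity_defect: float = 0.0

    def pq_for(self, outcome: str) -> float:
        return self.pq[outcome]


@dataclass(frozen=True)
class QuarterPrediction:
    """Fixed-interference baseline: classical probability minus 0.25."""

    value: float


def binary_entropy(p: float) -> float:
    """Shannon entropy of a Bernoulli(p) distribution in bits."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability {p} outside [0, 1]")
    h = 0.0
    for q in (p, 1.0 - p):
        if q > 0.0:
            h -= q * math.log2(q)
    return h


def quarter_law(classical: float) -> QuarterPrediction:
    """Attenuate a classical total probability by the fixed 0.25 interference term."""
    if not 0.0 <= classical <= 1.0:
        raise ValueError(f"probability {classical} outside [0, 1]")
    return QuarterPrediction(min(1.0, max(0.0, classical - 0.25)))


def intervals_overlap(a: WaveInterval, b: WaveInterval) -> bool:
    """True iff the closed intervals intersect (shared endpoints count)."""
    return a.lo <= b.hi and b.lo <= a.hi


# ---------------------------------------------------------------------------
# interval computation
# ---------------------------------------------------------------------------


def _pair_clamps(w: WaveSpec, counterpart: WaveSpec, system: BalanceSystem) -> dict:
    """Feasible |cos| bound per pair for wave ``w`` under the balance system.

    Where ``w`` dominates a pair (its coefficient is larger), the
    counterpart can only cancel |cos| up to the coefficient ratio's
    inverse; where ``w`` is dominated its phase is free.  A pair whose own
    coefficient vanishes contributes nothing; a pair whose *counterpart*
    coefficient vanishes (but not its own) can only be balanced at zero
    interference.
    """
    first_is_w = True
    # the system is built as (w_first, w_second); detect which slot w holds
    some = next(iter(system.pairs.values()))
    if not math.isclose(w.coeffs[some.pair], some.c_first, rel_tol=0, abs_tol=1e-15):
        first_is_w = False
    clamps = {}
    for ij, dom in system.pairs.items():
        if dom.degenerate:
            clamps[ij] = 0.0
            continue
        c_own = dom.c_first if first_is_w else dom.c_second
        c_other = dom.c_second if first_is_w else dom.c_first
        if c_own <= 0.0:
            clamps[ij] = 0.0
        elif c_other <= 0.0:
            clamps[ij] = 0.0  # nothing can cancel this pair's interference
        else:
            clamps[ij] = min(1.0, c_other / c_own)
    return clamps


def _clamped_interference(w: WaveSpec, clamps: dict, thetas: np.ndarray) -> np.ndarray:
    """Interference of ``w`` at gauge-fixed phases, cosines clamped per pair.

    ``thetas`` has shape (..., M-1); theta_M = 0 by gauge.
    """
    full = np.concatenate([thetas, np.zeros(thetas.shape[:-1] + (1,))], axis=-1)
    total = np.zeros(thetas.shape[:-1])
    for (i, j), c in w.coeffs.items():
        k = clamps[(i, j)]
        cos = np.cos(full[..., i] - full[..., j])
        total += c * np.clip(cos, -k, k)
    return w.norm_factor * total


def _numeric_extrema(
    w: WaveSpec, clamps: dict, grid_points: int = 64
) -> tuple[float, float]:
    """Deterministic min/max of the clamped wave over its free phases.

    Coarse grid over [0, 2 pi)^{M-1} followed by Nelder-Mead refinement
    from the best grid point; no randomness.
    """
    free = w.m - 1
    # keep the grid under ~2^21 evaluations for high M
    pts = grid_points if grid_points**free <= 2**21 else max(8, int((2**21) ** (1 / free)))
    axes = [np.linspace(0.0, 2 * math.pi, pts, endpoint=False)] * free
    mesh = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    vals = _clamped_interference(w, clamps, mesh)

    def refine(x0: np.ndarray, sign: float) -> float:
        obj = lambda th: sign * _clamped_interference(w, clamps, np.asarray(th))
        res = minimize(
            obj, x0, method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-13, "maxiter": 4000},
        )
        return sign * res.fun

    flat = vals.reshape(-1)
    coords = mesh.reshape(-1, free)
    i_lo = int(np.argmin(flat))
    i_hi = int(np.argmax(flat))
    lo = min(float(flat[i_lo]), refine(coords[i_lo], +1.0))
    hi = max(float(flat[i_hi]), refine(coords[i_hi], -1.0))
    return w.base + lo, w.base + hi


def wave_interval(
    w: WaveSpec,
    counterpart: WaveSpec,
    system: BalanceSystem | None = None,
    grid_points: int = 64,
) -> WaveInterval:
    """Attainable interval of a balanced probability wave.

    The smaller-base wave of the pair is the free one: its interval is
    computed directly (closed form for M = 2, constrained numeric
    optimisation for M >= 3).  The larger-base wave's interval is the
    mirror [1 - hi, 1 - lo] of the smaller's, as forced by the balance
    condition that the two waves sum to one.
    """
    if w.m != counterpart.m:
        raise MismatchedWaveError("waves have different configuration counts")
    if system is None:
        system = build_balance_system(w, counterpart)
    small, large = (w, counterpart) if w.base <= counterpart.base else (counterpart, w)

    if small.m == 1:
        lo = hi = small.base
    elif small.m == 2:
        # feasibility caps the half-width at the dominated amplitude
        h = min(small.max_interference, large.max_interference)
        lo, hi = small.base - h, small.base + h
    else:
        clamps = _pair_clamps(small, large, build_balance_system(small, large))
        lo, hi = _numeric_extrema(small, clamps, grid_points)

    small_iv = WaveInterval(max(0.0, lo), min(1.0, hi))
    return small_iv if w is small else small_iv.mirror()


# ---------------------------------------------------------------------------
# prediction principles
# ---------------------------------------------------------------------------


def _order_by_base(w_a: WaveSpec, w_b: WaveSpec) -> tuple[WaveSpec, WaveSpec]:
    """(smaller, larger) by base; stable on ties (the caller's order stands)."""
    if w_b.base < w_a.base - BASE_TIE_TOL:
        return w_b, w_a
    return w_a, w_b


def entropy_principle(
    w_small: WaveSpec, w_large: WaveSpec, grid_points: int = 64
) -> MaxPrediction:
    """Prediction for disjoint intervals: maximise entropy within each interval.

    Each wave takes the endpoint of its interval nearest 0.5.  For M = 2
    the two choices are exact complements; for M >= 3 the residual
    complementarity defect is recorded.
    """
    w_small, w_large = _order_by_base(w_small, w_large)
    system = build_balance_system(w_small, w_large)
    i_small = wave_interval(w_small, w_large, system, grid_points)
    i_large = i_small.mirror()
    if intervals_overlap(i_small, i_large):
        raise PrincipleDispatchError("entropy principle requires disjoint intervals")
    pq_small = i_small.nearest_to_half()
    if w_small.m == 2:
        pq_large = 1.0 - pq_small
    else:
        pq_large = i_large.nearest_to_half()
    return MaxPrediction(
        pq={w_small.outcome: pq_small, w_large.outcome: pq_large},
        principle=ENTROPY,
        intervals={w_small.outcome: i_small, w_large.outcome: i_large},
        classical={w_small.outcome: w_small.base, w_large.outcome: w_large.base},
        dominance=system,
        complementarity_defect=pq_small + pq_large - 1.0,
    )


def mirror_principle(
    w_small: WaveSpec, w_large: WaveSpec, grid_points: int = 64
) -> MaxPrediction:
    """Prediction for overlapping intervals: mirror the probability values.

    The larger-base outcome takes the smaller wave's full positive
    interference amplitude (2 sqrt(t_1 t_2) for M = 2; the numerically
    attained maximum interference for M >= 3 -- an extrapolation, as
    overlapping intervals with three or more configurations have no
    worked reference case).  The smaller-base outcome takes the complement.
    """
    w_small, w_large = _order_by_base(w_small, w_large)
    system = build_balance_system(w_small, w_large)
    i_small = wave_interval(w_small, w_large, system, grid_points)
    i_large = i_small.mirror()
    if not intervals_overlap(i_small, i_large):
        raise PrincipleDispatchError("mirror principle requires overlapping intervals")
    # attained positive interference of the smaller wave
    pq_large = i_small.hi - w_small.base
    pq_small = 1.0 - pq_large
    return MaxPrediction(
        pq={w_small.outcome: pq_small, w_large.outcome: pq_large},
        principle=MIRROR,
        intervals={w_small.outcome: i_small, w_large.outcome: i_large},
        classical={w_small.outcome: w_small.base, w_large.outcome: w_large.base},
        dominance=system,
        complementarity_defect=0.0,
    )


def predict_from_waves(
    w_yes: WaveSpec, w_no: WaveSpec, grid_points: int = 64
) -> MaxPrediction:
    """Dispatch to the entropy or mirror principle from two outcome waves.

    Equal bases centre both intervals on 0.5, which always overlap, so a
    tie dispatches to the mirror rule with the first-named outcome in the
    'larger' slot: it receives the counterpart's interference amplitude,
    the explicit prescription for the equal-distribution case.
    """
    if abs(w_yes.base - w_no.base) <= BASE_TIE_TOL:
        w_small, w_large = w_no, w_yes
    else:
        w_small, w_large = _order_by_base(w_yes, w_no)
    system = build_balance_system(w_small, w_large)
    i_small = wave_interval(w_small, w_large, system, grid_points)
    if intervals_overlap(i_small, i_small.mirror()):
        return mirror_principle(w_small, w_large, grid_points)
    return entropy_principle(w_small, w_large, grid_points)


def predict_max_uncertainty(
    net: BayesNet,
    query: str,
    evidence: EvidenceMap | None = None,
    grid_points: int = 64,
) -> MaxPrediction:
    """Full pipeline: decompose, build waves, balance, intervals, dispatch.

    Deterministic; the classical posteriors are recorded alongside the
    prediction.  With no interference (deterministic tables, or M = 1) the
    intervals degenerate to points and the prediction equals the classical
    posterior.
    """
    evidence = evidence or EvidenceMap()
    qvar = net.variable(query)
    if len(qvar.states) != 2:
        raise UnsupportedQueryError(
            f"query variable {query!r} has {len(qvar.states)} states; only binary queries are supported"
        )
    out_yes, out_no = qvar.states
    d_yes = decompose_query(net, query, out_yes, evidence)
    d_no = decompose_query(net, query, out_no, evidence)
    # validates evidence mass and complementarity
    classical_posterior(d_yes, d_no)
    w_yes = build_wave(d_yes)
    w_no = build_wave(d_no)
    if w_yes.m == 1:
        iv_yes = WaveInterval(w_yes.base, w_yes.base)
        iv_no = WaveInterval(w_no.base, w_no.base)
        return MaxPrediction(
            pq={out_yes: w_yes.base, out_no: w_no.base},
            principle=ENTROPY,
            intervals={out_yes: iv_yes, out_no: iv_no},
            classical={out_yes: w_yes.base, out_no: w_no.base},
            dominance=BalanceSystem(m=1, pairs={}),
        )
    return predict_from_waves(w_yes, w_no, grid_points)


def with_base(w: WaveSpec, base: float) -> WaveSpec:
    """Copy of a wave with its base replaced (interference untouched).

    Used by the replication layer's pre-rounded mode, where the classical
    base of an averaged experiment row is rounded to the printed two
    decimals before wave construction.
    """
    return dataclasses.replace(w, base=base)
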