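"""Intensity and probability waves over hidden configurations.

Each hidden configuration x_i contributes a complex amplitude of magnitude
sqrt(t_i), where t_i = p(outcome, e, x_i) / p(e) is the evidence-conditioned
joint term.  Summing amplitudes and taking the squared magnitude yields an
intensity wave

    I(outcome, theta_1..theta_M)
        = sum_i t_i  +  nf * sum_{i<j} sqrt(t_i t_j) cos(theta_i - theta_j)

with interference normalisation nf = 2/(M-1) (for M = 2 this is 2, the
plain two-slit form).  An intensity wave is non-negative but may exceed 1;
it only becomes a *probability* wave once the law of balance
(:mod:`qlbn.balance`) constrains the phases of the two complementary
outcome waves so their interference cancels.

Working with conditioned terms t_i (rather than raw joints) means a
balanced wave *is* a posterior directly: at orthogonal phases the wave
collapses to the classical posterior p(outcome | e).
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass

import numpy as np

from .errors import ImpossibleEvidenceError, InvalidProbabilityError, MismatchedWaveError
from .network import PROB_TOL, JointDecomposition


@dataclass(frozen=True)
class ComplexAmplitude:
    """A probability amplitude sqrt(p) * e^{i*theta}."""

    magnitude: float
    phase: float

    @property
    def value(self) -> complex:
        return cmath.rect(self.magnitude, self.phase)

    @property
    def probability(self) -> float:
        """Squared magnitude; the Born-rule probability of the amplitude."""
        return self.magnitude**2


@dataclass(frozen=True)
class PhaseVector:
    """Phases theta_1..theta_M, one per hidden configuration.

    Only differences theta_i - theta_j enter any wave, so the gauge
    convention theta_M = 0 is used during optimisation.
    """

    phases: tuple[float, ...]

    def __len__(self) -> int:
        return len(self.phases)

    @classmethod
    def zeros(cls, m: int) -> "PhaseVector":
        return cls((0.0,) * m)

    @classmethod
    def orthogonal(cls, m: int) -> "PhaseVector":
        """Phases with all pairwise differences +-pi/2 do not exist for M > 2;
        instead use the collapse convention: evaluate with every cosine zeroed
        via :func:`evaluate_wave`'s ``collapse`` argument for M > 2, or this
        vector (0, pi/2) for M = 2."""
        if m != 2:
            raise MismatchedWaveError("orthogonal phase pair is only defined for M = 2")
        return cls((math.pi / 2, 0.0))


@dataclass(frozen=True)
class WaveSpec:
    """Base probability plus pairwise interference coefficients.

    ``base`` is the classical total probability sum_i t_i; ``coeffs`` maps
    index pairs (i, j), i < j, to c_ij = sqrt(t_i t_j); ``norm_factor`` is
    2/(M-1).  The arithmetic-geometric mean inequality bounds each
    coefficient: c_ij <= (t_i + t_j)/2, hence the full wave never exceeds
    2 * base.
    """

    outcome: str
    terms: tuple[float, ...]
    base: float
    coeffs: dict[tuple[int, int], float]
    m: int
    norm_factor: float

    def pair_amplitude(self, i: int, j: int) -> float:
        """Full interference amplitude of one pair, nf * c_ij."""
        return self.norm_factor * self.coeffs[(i, j)]

    @property
    def max_interference(self) -> float:
        """Largest attainable interference, all cosines at +1."""
        return self.norm_factor * sum(self.coeffs.values())


def amplitude_from_probability(p: float, theta: float) -> ComplexAmplitude:
    """Encode a probability as an amplitude sqrt(p) e^{i theta}."""
    if not 0.0 <= p <= 1.0:
        raise InvalidProbabilityError(f"probability {p} outside [0, 1]")
    return ComplexAmplitude(math.sqrt(p), theta)


def build_wave(d: JointDecomposition) -> WaveSpec:
    """Build the wave of one query outcome from its joint decomposition.

    Terms are conditioned on the evidence (t_i = p(outcome, e, x_i)/p(e)),
    so the base equals the classical posterior.  With M = 1 the wave is
    degenerate: no interference, norm_factor 0.
    """
    if d.evidence_mass <= PROB_TOL:
        raise ImpossibleEvidenceError("cannot build a wave on zero evidence mass")
    t = tuple(v / d.evidence_mass for v in d.term_values)
    m = len(t)
    coeffs = {
        (i, j): math.sqrt(t[i] * t[j]) for i in range(m) for j in range(i + 1, m)
    }
    norm = 2.0 / (m - 1) if m >= 2 else 0.0
    return WaveSpec(
        outcome=d.query_outcome,
        terms=t,
        base=sum(t),
        coeffs=coeffs,
        m=m,
        norm_factor=norm,
    )


def evaluate_wave(w: WaveSpec, phases: PhaseVector | tuple[float, ...]) -> float:
    """Evaluate the intensity wave at a phase vector.

    Returns base + nf * sum_{i<j} c_ij cos(theta_i - theta_j).  Always
    non-negative; may exceed 1 for unbalanced phases.
    """
    th = phases.phases if isinstance(phases, PhaseVector) else tuple(phases)
    if len(th) != w.m:
        raise MismatchedWaveError(f"expected {w.m} phases, got {len(th)}")
    interference = sum(
        c * math.cos(th[i] - th[j]) for (i, j), c in w.coeffs.items()
    )
    return w.base + w.norm_factor * interference


def sample_wave(w: WaveSpec, n: int = 256) -> np.ndarray:
    """Sample an M = 2 wave over a uniform phase-difference grid.

    Returns an (n, 2) array of (phase difference, intensity) rows spanning
    [-2 pi, 2 pi]; used for plotting interference curves.
    """
    if w.m != 2:
        raise MismatchedWaveError("wave sampling is defined for M = 2 only")
    grid = np.linspace(-2 * math.pi, 2 * math.pi, n)
    c = w.pair_amplitude(0, 1)
    return np.column_stack([grid, w.base + c * np.cos(grid)])


def bayes_normalize(i_yes: float, i_no: float) -> tuple[float, float]:
    """Convert a pair of intensities into probabilities by their ratio.

    This is the normalisation the law of balance makes redundant: balanced
    waves already sum to one, so dividing by the total leaves them
    unchanged; skewed intensity waves are forced to sum to one here.
    """
    if i_yes < 0 or i_no < 0:
        raise InvalidProbabilityError("intensities must be non-negative")
    total = i_yes + i_no
    if total <= 0:
        raise InvalidProbabilityError("cannot normalise two zero intensities")
    return i_yes / total, i_no / total
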