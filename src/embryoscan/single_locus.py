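"""Deterministic single-locus viability selection in a large random-mating population.

Let ``q`` be the frequency of the carrier (focal) allele *a* and the genotype
fitnesses be ``w_AA``, ``w_Aa``, ``w_aa``. One discrete generation of random
mating followed by viability selection gives

    q' = q * (q * w_aa + (1 - q) * w_Aa) / w_bar,
    w_bar = q^2 w_aa + 2 q (1 - q) w_Aa + (1 - q)^2 w_AA.

Two parameterizations cover the cases of interest here:

* pure recessive selection, ``w = (1, 1, 1 - s)``: a recessive lethal
  (``s = 1``) declines along the classic hyperbola ``q_t = q0 / (1 + t q0)``;
* overdominance, ``w = (1 - s1, 1, 1 - s2)``: the heterozygote is fittest and
  the interior equilibrium is ``q_eq = s1 / (s1 + s2)``.

These provide the drift-free reference expectations for how fast an
embryonic (semi-)lethal haplotype should decline, and at what frequency it
can be *maintained* when carriers enjoy a postnatal advantage. Prenatal and
postnatal selection acting on the same genotype compose multiplicatively
into a single per-generation fitness (see :meth:`SelectionModel.compose`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class SelectionModel:
    """Genotype fitnesses (w_AA, w_Aa, w_aa): non-carrier hom, het, carrier hom."""

    w_AA: float
    w_Aa: float
    w_aa: float

    def __post_init__(self):
        ws = (self.w_AA, self.w_Aa, self.w_aa)
        if any(w < 0 for w in ws):
            raise ValueError("fitnesses must be >= 0")
        if all(w == 0 for w in ws):
            raise ValueError("at least one fitness must be positive")

    @classmethod
    def neutral(cls) -> "SelectionModel":
        return cls(1.0, 1.0, 1.0)

    @classmethod
    def recessive(cls, s: float) -> "SelectionModel":
        """Selection s against the carrier homozygote only: w = (1, 1, 1-s)."""
        if not (0 <= s <= 1):
            raise ValueError("s must be in [0, 1]")
        return cls(1.0, 1.0, 1.0 - s)

    @classmethod
    def overdominant(cls, s1: float, s2: float) -> "SelectionModel":
        """Heterozygote advantage: w = (1-s1, 1, 1-s2)."""
        return cls(1.0 - s1, 1.0, 1.0 - s2)

    @classmethod
    def compose(cls, prenatal, postnatal) -> "SelectionModel":
        """Per-genotype product of prenatal survival and relative postnatal fitness.

        Collapses, e.g., embryonic semi-lethality of the homozygote plus a
        heterozygote postnatal survival advantage into one viability model.
        """
        return cls(*(a * b for a, b in zip(prenatal, postnatal)))


@dataclass(frozen=True)
class Trajectory:
    """Deterministic allele-frequency path; ``frequency[t]`` is q after t generations."""

    generations: np.ndarray
    frequency: np.ndarray


def next_generation(q: float, model: SelectionModel) -> float:
    """One step of the deterministic selection recursion (q = carrier-allele frequency)."""
    if not (0 <= q <= 1):
        raise ValueError("q must be in [0, 1]")
    p = 1.0 - q
    w_bar = q * q * model.w_aa + 2 * p * q * model.w_Aa + p * p * model.w_AA
    if w_bar == 0:
        raise ZeroDivisionError("mean fitness is zero at this frequency")
    return q * (q * model.w_aa + p * model.w_Aa) / w_bar


def trajectory(q0: float, model: SelectionModel, T: int) -> Trajectory:
    """Iterate the recursion T generations from q0 (length T+1 including q0)."""
    if T < 0:
        raise ValueError("T must be >= 0")
    qs = np.empty(T + 1)
    qs[0] = q0
    for t in range(T):
        qs[t + 1] = next_generation(qs[t], model)
    return Trajectory(generations=np.arange(T + 1), frequency=qs)


def overdominance_equilibrium(s1: float, s2: float) -> float:
    """Interior equilibrium q_eq = s1 / (s1 + s2) of the carrier allele.

    ``s1`` is the selection against the non-carrier homozygote (the
    heterozygote advantage over AA) and ``s2`` the selection against the
    carrier homozygote (e.g. embryonic mortality).
    """
    if not (0 < s1 <= 1) or not (0 < s2 <= 1):
        raise ValueError("s1 and s2 must be in (0, 1]")
    return s1 / (s1 + s2)
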