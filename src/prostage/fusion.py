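"""Dempster-Shafer evidence algebra on the two-class frame {OCD, NOCD}.

Each feature classifier's pair of output scores becomes a basic probability
assignment (mass function) with focal sets {OCD}, {NOCD} and the whole frame
Theta.  The score shortfall 1 - (p_OCD + p_NOCD) is treated as unassigned
belief and placed on Theta (total ignorance), keeping the empty set at mass
zero as the theory requires.  Masses may be discounted for source
unreliability, are combined by Dempster's rule, and yield Bel/Pls evidential
intervals and a final OCD/NOCD decision.
"""

from __future__ import annotations

from dataclasses import dataclass

from .data import Label

__all__ = [
    "MassFunction",
    "EvidentialInterval",
    "FusionResult",
    "TotalConflictError",
    "VACUOUS",
    "mass_from_outputs",
    "discount",
    "combine",
    "combine_all",
    "evidential_interval",
    "decide",
    "fuse_outputs",
]

_TOL = 1e-9


class TotalConflictError(ValueError):
    """Dempster's rule is undefined when the sources conflict completely."""


@dataclass(frozen=True)
class MassFunction:
    """Basic probability assignment over {OCD, NOCD}.

    ``m_theta`` is the mass committed to the whole frame (ignorance); the
    empty set carries no mass by construction.  The three masses are
    nonnegative and sum to 1 within 1e-9.
    """

    m_ocd: float
    m_nocd: float
    m_theta: float

    def __post_init__(self) -> None:
        for name, v in (("m_ocd", self.m_ocd), ("m_nocd", self.m_nocd), ("m_theta", self.m_theta)):
            if not -_TOL <= v <= 1 + _TOL:
                raise ValueError(f"{name}={v} outside [0, 1]")
        total = self.m_ocd + self.m_nocd + self.m_theta
        if abs(total - 1.0) > _TOL:
            raise ValueError(f"masses sum to {total}, expected 1")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.m_ocd, self.m_nocd, self.m_theta)


#: Total ignorance: all mass on the frame; the identity of Dempster's rule.
VACUOUS = MassFunction(0.0, 0.0, 1.0)


@dataclass(frozen=True)
class EvidentialInterval:
    """[Bel(H), Pls(H)] — lower and upper support for a hypothesis."""

    bel: float
    pls: float

    def __post_init__(self) -> None:
        if not (-_TOL <= self.bel <= self.pls + _TOL and self.pls <= 1 + _TOL):
            raise ValueError(f"invalid evidential interval [{self.bel}, {self.pls}]")


@dataclass(frozen=True)
class FusionResult:
    """Outcome of combining an ordered list of mass functions."""

    combined: MassFunction
    conflict: float  # conflict of the final pairwise step
    conflict_trace: tuple[float, ...]  # conflict at every fold step, in order
    interval_ocd: EvidentialInterval
    interval_nocd: EvidentialInterval
    decision: Label


def mass_from_outputs(p_ocd: float, p_nocd: float) -> MassFunction:
    """Turn a classifier's (p_OCD, p_NOCD) score pair into a mass function.

    If the scores sum to at most 1 the shortfall becomes ignorance mass on
    Theta.  If they sum to more than 1 (two confident logistic units) they
    are renormalised onto the singletons with no ignorance — a guard for
    score pairs the theory itself does not anticipate.
    """
    if not (0.0 <= p_ocd <= 1.0 and 0.0 <= p_nocd <= 1.0):
        raise ValueError(f"scores must be in [0, 1], got ({p_ocd}, {p_nocd})")
    s = p_ocd + p_nocd
    if s <= 1.0:
        return MassFunction(p_ocd, p_nocd, 1.0 - s)
    return MassFunction(p_ocd / s, p_nocd / s, 0.0)


def discount(m: MassFunction, r: float) -> MassFunction:
    """Discount a source by unreliability ``r`` in [0, 1].

    Singleton masses shrink by (1 - r); the removed mass joins the frame.
    r=0 trusts the source fully (identity); r=1 yields the vacuous mass.
    """
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"discount rate must be in [0, 1], got {r}")
    keep = 1.0 - r
    return MassFunction(
        keep * m.m_ocd,
        keep * m.m_nocd,
        1.0 - keep * (m.m_ocd + m.m_nocd),
    )


def combine(m1: MassFunction, m2: MassFunction) -> tuple[MassFunction, float]:
    """Dempster's rule of combination on the two-class frame.

    The conflict ``p`` is the product mass on disjoint singleton pairs; the
    remaining products are normalised by 1 - p.  Raises
    :class:`TotalConflictError` at p = 1.
    """
    p = m1.m_ocd * m2.m_nocd + m1.m_nocd * m2.m_ocd
    if p >= 1.0 - 1e-15:
        raise TotalConflictError(f"total conflict (p={p}) between sources")
    k = 1.0 - p
    ocd = (m1.m_ocd * m2.m_ocd + m1.m_ocd * m2.m_theta + m1.m_theta * m2.m_ocd) / k
    nocd = (m1.m_nocd * m2.m_nocd + m1.m_nocd * m2.m_theta + m1.m_theta * m2.m_nocd) / k
    theta = (m1.m_theta * m2.m_theta) / k
    # renormalise away float drift so downstream validation never trips
    total = ocd + nocd + theta
    return MassFunction(ocd / total, nocd / total, theta / total), p


def combine_all(masses: list[MassFunction] | tuple[MassFunction, ...]) -> FusionResult:
    """Left-fold Dempster combination over an ordered source list.

    The reported ``conflict`` is that of the final pairwise step;
    ``conflict_trace`` lists every step's conflict.  Dempster's rule is
    commutative and associative, so the combined mass is order-invariant.
    """
    masses = list(masses)
    if not masses:
        raise ValueError("combine_all requires at least one mass function")
    acc = masses[0]
    trace: list[float] = []
    for step, m in enumerate(masses[1:], start=1):
        try:
            acc, p = combine(acc, m)
        except TotalConflictError as exc:
            raise TotalConflictError(f"total conflict at fold step {step}: {exc}") from exc
        trace.append(p)
    return FusionResult(
        combined=acc,
        conflict=trace[-1] if trace else 0.0,
        conflict_trace=tuple(trace),
        interval_ocd=evidential_interval(acc, Label.OCD),
        interval_nocd=evidential_interval(acc, Label.NOCD),
        decision=decide(acc),
    )


def evidential_interval(m: MassFunction, hypothesis: Label) -> EvidentialInterval:
    """[Bel(H), Pls(H)] with Pls(H) = 1 - Bel(not H)."""
    if hypothesis == Label.OCD:
        return EvidentialInterval(bel=m.m_ocd, pls=m.m_ocd + m.m_theta)
    return EvidentialInterval(bel=m.m_nocd, pls=m.m_nocd + m.m_theta)


def decide(m: MassFunction) -> Label:
    """The hypothesis with the higher singleton mass; ties go to OCD.

    OCD is the majority class, so the fixed tie-break is the conservative
    (more prevalent) call and keeps the decision deterministic.
    """
    return Label.NOCD if m.m_nocd > m.m_ocd else Label.OCD


def fuse_outputs(
    outputs: list[tuple[float, float]],
    discounts: list[float] | None = None,
) -> FusionResult:
    """Convenience path from raw classifier score pairs to a fused decision."""
    masses = [mass_from_outputs(p_o, p_n) for p_o, p_n in outputs]
    if discounts is not None:
        if len(discounts) != len(masses):
            raise ValueError("one discount rate per source required")
        masses = [discount(m, r) for m, r in zip(masses, discounts)]
    return combine_all(masses)
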