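"""Independent brute-force oracles used to cross-check the implementation.

These deliberately share no code with the package: the Dempster oracle works
on arbitrary frames via explicit power-set enumeration, and the AUC oracle
enumerates every positive/negative score pair.
"""

from __future__ import annotations

import itertools

from prostage.data import Label
from prostage.fusion import MassFunction

OCD = frozenset({"OCD"})
NOCD = frozenset({"NOCD"})
THETA = frozenset({"OCD", "NOCD"})


def to_powerset(m: MassFunction) -> dict[frozenset, float]:
    return {OCD: m.m_ocd, NOCD: m.m_nocd, THETA: m.m_theta}


def dempster_powerset(
    m1: dict[frozenset, float], m2: dict[frozenset, float]
) -> tuple[dict[frozenset, float], float]:
    """Dempster's rule by enumerating all focal-set pairs of any frame."""
    conflict = 0.0
    raw: dict[frozenset, float] = {}
    for a_set, a in m1.items():
        for b_set, b in m2.items():
            inter = a_set & b_set
            if not inter:
                conflict += a * b
            else:
                raw[inter] = raw.get(inter, 0.0) + a * b
    k = 1.0 - conflict
    if k <= 0:
        raise ZeroDivisionError("total conflict")
    return {s: v / k for s, v in raw.items()}, conflict


def dempster_powerset_nary(masses: list[dict[frozenset, float]]) -> dict[frozenset, float]:
    """n-ary combination by exhaustive product enumeration (no folding)."""
    frames = [list(m.items()) for m in masses]
    conflict = 0.0
    raw: dict[frozenset, float] = {}
    for combo in itertools.product(*frames):
        sets, vals = zip(*combo)
        inter = frozenset.intersection(*sets)
        prod = 1.0
        for v in vals:
            prod *= v
        if not inter:
            conflict += prod
        else:
            raw[inter] = raw.get(inter, 0.0) + prod
    k = 1.0 - conflict
    return {s: v / k for s, v in raw.items()}


def pairwise_auc(scores, labels) -> float:
    """P(score_pos > score_neg) + 0.5 P(tie) over all pos x neg pairs."""
    pos = [s for s, l in zip(scores, labels) if l == Label.NOCD]
    neg = [s for s, l in zip(scores, labels) if l == Label.OCD]
    total = sum(
        1.0 if p > n else (0.5 if p == n else 0.0) for p in pos for n in neg
    )
    return total / (len(pos) * len(neg))


def random_mass(rng) -> MassFunction:
    """A uniformly random valid mass function (Dirichlet via exponentials)."""
    x = -1.0 * __import__("numpy").log(rng.random(3))
    x = x / x.sum()
    return MassFunction(float(x[0]), float(x[1]), float(x[2]))
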