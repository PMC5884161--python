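"""Fuse three classifiers' score pairs by Dempster-Shafer combination.

Each (p_OCD, p_NOCD) pair becomes a mass function: the shortfall from 1 is
unassigned belief on the whole frame.  Dempster's rule multiplies agreeing
evidence, discards conflicting products (the conflict p) and renormalises.
Here two sources lean OCD and one leans NOCD: the fused mass backs OCD
far more strongly than any single source.
"""

from prostage import Label
from prostage.fusion import fuse_outputs

# (p_OCD, p_NOCD) from three per-feature classifiers for one patient
outputs = [(0.80, 0.15), (0.65, 0.25), (0.30, 0.55)]
result = fuse_outputs(outputs)

m = result.combined
print(f"combined mass: m(OCD)={m.m_ocd:.4f}  m(NOCD)={m.m_nocd:.4f}  m(Theta)={m.m_theta:.4f}")
print(f"step conflicts: {[round(p, 4) for p in result.conflict_trace]}")
io, inn = result.interval_ocd, result.interval_nocd
print(f"evidential intervals: OCD [{io.bel:.4f}, {io.pls:.4f}]  NOCD [{inn.bel:.4f}, {inn.pls:.4f}]")
print(f"decision: {result.decision.value}  (higher combined singleton mass wins)")
assert result.decision == Label.OCD
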