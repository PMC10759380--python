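"""Quantitative transitivity assessment on a published-shaped network.

Pooled mean age and female proportion per comparison are compared against
the hemi-arthroplasty vs nonoperative reference with the predefined cutoffs
(5 years, 0.20), Fisher-screened for the gender difference.
"""

from nmaudit import AuditConfig, audit_outcome, fixture_like_paper
from nmaudit.pipeline import transitivity_table

spec = fixture_like_paper("davey", "CS")
report = audit_outcome(spec, AuditConfig())

print(transitivity_table(report).to_string(index=False))
print()
print("flags: 'age' = |pooled-age difference vs reference| > 5 years;")
print("'gender' needs BOTH Fisher significance and a >20-point difference,")
print("so the significant (*) but smaller nailing-vs-plate gap is not flagged.")
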