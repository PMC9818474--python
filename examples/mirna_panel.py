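"""Score the published Patient P miRNA oncopanel, both visits.

The initial visit uses the concentration path (fold changes from copies/μL)
and the label path; the follow-up uses the printed expression labels.
"""

from mwrisk import fold_change, panel_from_labels, panel_risk
from mwrisk.clinical_example import (
    FOLLOWUP_LABELS,
    INITIAL_CONCENTRATIONS,
    INITIAL_LABELS,
)

print("initial visit — fold changes (pathology / norm):")
for marker, (norm, path) in INITIAL_CONCENTRATIONS.items():
    print(f"  {marker:22s} {fold_change(norm, path):5.1f}")

initial = panel_risk(panel_from_labels(INITIAL_LABELS))
followup = panel_risk(panel_from_labels(FOLLOWUP_LABELS))
print(f"\ninitial risk factor:  {initial.risk_sum} -> {initial.category} risk")
print(f"follow-up risk factor: {followup.risk_sum} -> {followup.category} risk")
# Each marker's change in its risk direction maps to 0-3; the sum (risk
# factor) below 5 is low risk. The rise 3 -> 7 over six months tracked the
# patient's progression to confirmed carcinoma.
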