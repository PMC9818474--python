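"""Reproduce the two-visit clinical workflow of the worked example.

Initial visit: MWR below both thresholds but the classifier flags high
risk; the miRNA panel comes back low -> monitor with follow-up.  Six
months later all modalities are high -> referral.
"""

from mwrisk import assess, classify_mwr, panel_from_labels, panel_risk
from mwrisk.clinical_example import (
    FOLLOWUP_LABELS,
    FOLLOWUP_QR,
    INITIAL_LABELS,
    INITIAL_QR,
)

for visit, qr, labels in (
    ("initial visit", INITIAL_QR, INITIAL_LABELS),
    ("6-month follow-up", FOLLOWUP_QR, FOLLOWUP_LABELS),
):
    mwr_class = classify_mwr(*qr)
    panel = panel_risk(panel_from_labels(labels))
    result = assess(mwr_class, classifier_label="high", mirna_category=panel.category)
    print(f"{visit}: Q_max={qr[0]}, R={qr[1]} -> {mwr_class.value}; "
          f"panel risk factor {panel.risk_sum} ({panel.category})")
    print(f"  overall: {result.overall.value}")
    for line in result.rationale:
        print(f"    - {line}")
    print()
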