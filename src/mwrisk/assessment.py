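"""Fusion of MWR classification, risk-classifier output and miRNA category.

The clinical workflow: MWR screening first; a classifier flag or an
ambiguous MWR result triggers the miRNA panel; a high panel or suspected
malignancy escalates to referral.  The decision table below codifies that
narrative; it is configuration, not ground truth, and every rule fired is
recorded in the assessment's rationale trace for auditability.

Overall levels (ordered): benign_monitor < elevated_recommend_mirna <
high_risk_refer; discordant_review flags an MWR-suspicion / low-panel
contradiction for human review rather than ranking it.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .mwr import MwrClass


class Overall(str, enum.Enum):
    BENIGN_MONITOR = "benign_monitor"
    ELEVATED_RECOMMEND_MIRNA = "elevated_recommend_mirna"
    HIGH_RISK_REFER = "high_risk_refer"
    DISCORDANT_REVIEW = "discordant_review"


@dataclass
class Assessment:
    mwr_class: MwrClass
    classifier_label: str | None
    mirna_category: str | None
    overall: Overall
    rationale: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "mwr_class": self.mwr_class.value,
            "classifier_label": self.classifier_label,
            "mirna_category": self.mirna_category,
            "overall": self.overall.value,
            "rationale": self.rationale,
        }


def assess(
    mwr_class: MwrClass | str,
    classifier_label: str | None = None,
    mirna_category: str | None = None,
) -> Assessment:
    """Combine the three modality outputs into one overall assessment.

    The table is total: every (mwr_class, classifier_label, mirna_category)
    triple maps to exactly one overall level, and adding a high miRNA
    category never downgrades the result.
    """
    mwr_class = MwrClass(mwr_class)
    for arg, allowed in ((classifier_label, ("low", "high")), (mirna_category, ("low", "high"))):
        if arg is not None and arg not in allowed:
            raise ValueError(f"expected one of {allowed} or None, got {arg!r}")

    trace: list[str] = [f"MWR classification: {mwr_class.value}"]
    if classifier_label is not None:
        trace.append(f"risk classifier: {classifier_label}")
    if mirna_category is not None:
        trace.append(f"miRNA panel category: {mirna_category}")

    if mwr_class is MwrClass.MALIGNANT_SUSPECTED:
        trace.append(
            "Q_max and R above thresholds indicate a probability of "
            "developing breast cancer of over 85%"
        )
        if mirna_category == "low":
            trace.append("miRNA panel low despite MWR suspicion -> discordant, human review")
            overall = Overall.DISCORDANT_REVIEW
        else:
            trace.append("MWR suspicion not contradicted by panel -> refer")
            overall = Overall.HIGH_RISK_REFER
    elif mwr_class is MwrClass.AMBIGUOUS:
        if mirna_category == "high":
            trace.append("ambiguous MWR escalated by high miRNA panel -> refer")
            overall = Overall.HIGH_RISK_REFER
        else:
            trace.append("ambiguous MWR -> miRNA panel recommended")
            overall = Overall.ELEVATED_RECOMMEND_MIRNA
    else:  # benign
        if classifier_label == "high":
            if mirna_category == "high":
                trace.append("classifier and miRNA panel both high -> refer")
                overall = Overall.HIGH_RISK_REFER
            elif mirna_category == "low":
                trace.append(
                    "classifier high but miRNA panel low -> monitor with "
                    "short-interval follow-up"
                )
                overall = Overall.BENIGN_MONITOR
            else:
                trace.append("classifier high, no panel yet -> miRNA panel recommended")
                overall = Overall.ELEVATED_RECOMMEND_MIRNA
        else:
            if mirna_category == "high":
                trace.append("benign MWR but high miRNA panel -> panel follow-up recommended")
                overall = Overall.ELEVATED_RECOMMEND_MIRNA
            else:
                trace.append("no modality elevated -> routine monitoring")
                overall = Overall.BENIGN_MONITOR

    return Assessment(
        mwr_class=mwr_class,
        classifier_label=classifier_label,
        mirna_category=mirna_category,
        overall=overall,
        rationale=trace,
    )
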