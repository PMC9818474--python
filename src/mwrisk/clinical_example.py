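"""Published worked example: Patient P's two visits.

A 65-year-old patient presenting with nipple discharge: the initial visit
showed a benign-side MWR result (Q_max 1.7, R 1.9, both below threshold)
but a high-risk classifier flag, prompting the miRNA panel (risk factor 3,
low).  At the 6-month follow-up the MWR statistics crossed both thresholds
(Q_max 2.45, R 3.2) and the panel rose to risk factor 7 (high); invasive
carcinoma was confirmed histologically.

These printed values serve as the package's reference inputs for tests and
examples; marker names are kept exactly as published (the canonicaliser
handles their inconsistent prefixes).
"""

from __future__ import annotations

#: (Q_max, R) pairs printed for the two visits, °C
INITIAL_QR: tuple[float, float] = (1.7, 1.9)
FOLLOWUP_QR: tuple[float, float] = (2.45, 3.2)

#: initial-visit panel concentrations, copies/μL: marker -> (norm, pathology)
INITIAL_CONCENTRATIONS: dict[str, tuple[float, float]] = {
    "Hsa-miR-155": (28294, 202238),
    "Hsa-miR-196a-3p": (104809, 324654),
    "Hsa-miR-222-3p": (159928, 88908),
    "Hsa-let-7a-5p": (13327568, 2665531),
    "Micro-196a-2": (1665957, 333191),
    "Hsa-miR-106a-5p": (380633, 76126),
    "Has-miR-21-5p": (22209402, 111047010),
    "Hsa-miR-137": (555235050, 111047010),
}

#: fold changes as printed alongside the concentrations (1-decimal reporting)
INITIAL_FOLD_CHANGES: dict[str, float] = {
    "Hsa-miR-155": 7.1,
    "Hsa-miR-196a-3p": 3.1,
    "Hsa-miR-222-3p": 0.6,
    "Hsa-let-7a-5p": 0.2,
    "Micro-196a-2": 0.2,
    "Hsa-miR-106a-5p": 0.2,
    "Has-miR-21-5p": 5.0,
    "Hsa-miR-137": 0.2,
}

#: initial-visit categorical expression labels (risk factor 3 = 1+1+1, low)
INITIAL_LABELS: dict[str, str] = {
    "Hsa-miR-155": "Norm",
    "Hsa-miR-196a-3p": "Norm",
    "Hsa-miR-222-3p": "Slight increase",
    "Hsa-let-7a-5p": "Slight increase",
    "Micro-196a-2": "Norm",
    "Hsa-miR-106a-5p": "Slight increase",
    "Has-miR-21-5p": "Norm",
    "Hsa-miR-137": "Norm",
}

#: follow-up labels with explicit printed scores (risk factor 7 = 3+3+1, high)
FOLLOWUP_LABELS: dict[str, str] = {
    "Hsa-miR-155": "Norm",
    "Hsa-miR-196a-3p": "Norm",
    "Hsa-miR-222-3p": "Pronounced increase—3",
    "Hsa-let-7a-5p": "Pronounced increase—3",
    "Micro-RNA-196a-2": "Norm",
    "Hsa-miR-106a-5p": "Slight increase—1",
    "Has-miR-21-5p": "Norm",
    "Hsa-miR-137": "Norm",
}
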