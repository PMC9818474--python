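"""Oncopanel scoring: fold changes, direction-aware magnitudes, risk sums."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mwrisk import (
    PANEL,
    MarkerMeasurement,
    RiskDirection,
    canonical_marker_name,
    effective_change,
    fold_change,
    label_to_score,
    panel_from_concentrations,
    panel_from_labels,
    panel_risk,
    score_marker,
)
from mwrisk.clinical_example import (
    FOLLOWUP_LABELS,
    INITIAL_CONCENTRATIONS,
    INITIAL_FOLD_CHANGES,
    INITIAL_LABELS,
)
from mwrisk.mirna import PANEL_BY_NAME


class TestFoldChange:
    @pytest.mark.parametrize("marker", sorted(INITIAL_CONCENTRATIONS))
    def test_published_panel_reproduced_at_one_decimal(self, marker):
        norm, path = INITIAL_CONCENTRATIONS[marker]
        assert fold_change(norm, path) == INITIAL_FOLD_CHANGES[marker]

    def test_identity_fold(self):
        assert fold_change(12345.0, 12345.0) == 1.0

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ValueError):
            fold_change(0.0, 100.0)
        with pytest.raises(ValueError):
            fold_change(100.0, -1.0)

    @given(st.sampled_from([0.2, 0.5, 0.9, 1.0, 1.4, 1.5, 2.0, 3.3, 5.0, 7.1]))
    @settings(deadline=None)
    def test_roundtrip_on_fold_grid(self, f):
        n = 10000.0
        assert fold_change(n, n * f) == pytest.approx(round(f, 1))


class TestEffectiveChange:
    def test_protective_marker_decrease_is_reciprocal(self):
        assert effective_change(0.2, RiskDirection.DOWN_IS_RISK) == pytest.approx(5.0)

    def test_oncogenic_marker_increase_passes_through(self):
        assert effective_change(7.1, RiskDirection.UP_IS_RISK) == pytest.approx(7.1)

    @pytest.mark.parametrize(
        "fold,direction",
        [(0.6, RiskDirection.UP_IS_RISK), (3.0, RiskDirection.DOWN_IS_RISK)],
    )
    def test_change_against_risk_direction_is_neutral(self, fold, direction):
        assert effective_change(fold, direction) == 1.0

    @given(st.floats(min_value=0.01, max_value=100.0))
    @settings(deadline=None)
    def test_magnitude_at_least_one(self, fold):
        for direction in RiskDirection:
            assert effective_change(fold, direction) >= 1.0


class TestScoreMarker:
    @pytest.mark.parametrize(
        "magnitude,score",
        [(1.0, 0), (1.2, 0), (1.5, 1), (1.9, 1), (2.0, 2), (4.9, 2), (5.0, 3), (7.1, 3)],
    )
    def test_half_open_bands(self, magnitude, score):
        assert score_marker(magnitude) == score


class TestLabels:
    @pytest.mark.parametrize(
        "label,score",
        [
            ("Norm", 0),
            ("Slight increase", 1),
            ("Moderate increase", 2),
            ("Pronounced increase—3", 3),
            ("Slight increase—1", 1),
            ("Significant increase", 3),
        ],
    )
    def test_label_vocabulary(self, label, score):
        assert label_to_score(label) == score

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown expression label"):
            label_to_score("elevated a lot")


class TestMarkerNames:
    @pytest.mark.parametrize(
        "raw,canonical",
        [
            ("Hsa-miR-155", "mir-155"),
            ("Has-miR-21-5p", "mir-21-5p"),
            ("Micro-196a-2", "mir-196a-2"),
            ("Micro-RNA-196a-2", "mir-196a-2"),
            ("Hsa-let-7a-5p", "let-7a-5p"),
            ("Hsa-miR-196a-3p", "mir-199a-3p"),  # printed alias of the 199a slot
        ],
    )
    def test_inconsistent_prefixes_canonicalised(self, raw, canonical):
        assert canonical_marker_name(raw) == canonical


class TestPanelRisk:
    def test_initial_visit_panel_sums_to_three_low(self):
        result = panel_risk(panel_from_labels(INITIAL_LABELS))
        assert result.risk_sum == 3
        assert result.category == "low"

    def test_followup_panel_sums_to_seven_high(self):
        result = panel_risk(panel_from_labels(FOLLOWUP_LABELS))
        assert result.risk_sum == 7
        assert result.category == "high"

    def test_all_norm_panel_scores_zero(self):
        labels = {m.name: "Norm" for m in PANEL}
        result = panel_risk(panel_from_labels(labels))
        assert result.risk_sum == 0 and result.category == "low"

    def test_missing_marker_rejected(self):
        labels = {m.name: "Norm" for m in PANEL[:-1]}
        with pytest.raises(ValueError, match="missing markers"):
            panel_risk(panel_from_labels(labels))

    def test_duplicate_marker_rejected(self):
        ms = [MarkerMeasurement(marker=m, label="Norm") for m in PANEL]
        ms.append(MarkerMeasurement(marker=PANEL[0], label="Norm"))
        with pytest.raises(ValueError, match="duplicate"):
            panel_risk(ms)

    def test_risk_sum_monotone_in_single_marker_magnitude(self):
        base = {m.name: (1000.0, 1000.0) for m in PANEL}
        prev = -1
        for path in [1000.0, 1600.0, 2500.0, 6000.0]:  # mir-155 is up_is_risk
            conc = dict(base)
            conc["mir-155"] = (1000.0, path)
            rs = panel_risk(panel_from_concentrations(conc)).risk_sum
            assert rs >= prev
            prev = rs

    def test_label_and_concentration_paths_agree_on_consistent_panels(self):
        # synthetic panel where each concentration pair sits inside a band
        mags = {0: 1.1, 1: 1.7, 2: 3.0, 3: 8.0}
        labels = {0: "Norm", 1: "Slight increase", 2: "Moderate increase", 3: "Pronounced increase"}
        for score, mag in mags.items():
            for m in PANEL:
                fold = mag if m.risk_direction is RiskDirection.UP_IS_RISK else 1.0 / mag
                conc = MarkerMeasurement(
                    marker=m, norm_conc=5000.0, path_conc=5000.0 * fold
                )
                lab = MarkerMeasurement(marker=m, label=labels[score])
                from mwrisk.mirna import score_measurement

                assert score_measurement(conc) == score_measurement(lab) == score
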