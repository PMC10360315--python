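"""Activity normalization, brackets, reconciliation, and concordance metrics."""

from __future__ import annotations

import io
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mldmatrix import (
    ActivityMeasurement,
    Construct,
    SeverityBrackets,
    SeverityClass,
    activity_based_severity,
    diagnostic_metrics,
    finalize_severity,
    parse_activity_table,
    percent_wt_activity,
    predictor_correlation,
)

S, M, m, B, U = (
    SeverityClass.SEVERE,
    SeverityClass.MODERATE,
    SeverityClass.MILD,
    SeverityClass.BENIGN,
    SeverityClass.UNKNOWN,
)


def meas(vid, ratios, construct=Construct.CDS, plate="p1"):
    return ActivityMeasurement(
        variant_id=vid, construct=construct, replicate_ion_ratios=ratios, plate_id=plate
    )


class TestPercentWt:
    def test_wildtype_against_itself_is_exactly_100(self):
        wt = meas("WT", [(0.8, 1.1), (0.9, 1.2), (1.0, 1.0)])
        result = percent_wt_activity(wt, wt)
        assert result.mean_percent_wt == pytest.approx(100.0)

    def test_blank_equal_wells_give_zero(self):
        wt = meas("WT", [(1.0, 1.0)] * 3)
        var = meas("v", [(0.0, 1.0)] * 3)
        assert percent_wt_activity(var, wt).mean_percent_wt == 0.0

    def test_half_activity_and_replicate_sd(self):
        wt = meas("WT", [(1.0, 1.0)] * 3)
        var = meas("v", [(0.4, 1.0), (0.5, 1.0), (0.6, 1.0)])
        result = percent_wt_activity(var, wt)
        assert result.mean_percent_wt == pytest.approx(50.0)
        assert result.sd_percent_wt == pytest.approx(10.0)  # sample sd

    def test_negative_ratios_survive_blank_subtraction(self):
        wt = meas("WT", [(1.0, 1.0)] * 3)
        var = meas("v", [(-0.005, 1.0)] * 3)
        assert percent_wt_activity(var, wt).mean_percent_wt == pytest.approx(-0.5)

    def test_zero_control_replicate_dropped_with_warning(self):
        wt = meas("WT", [(1.0, 1.0)] * 3)
        var = meas("v", [(0.5, 0.0), (0.5, 1.0)])
        with pytest.warns(UserWarning, match="zero control"):
            result = percent_wt_activity(var, wt)
        assert result.n_replicates == 1

    def test_nonpositive_wildtype_reference_is_an_error(self):
        wt = meas("WT", [(-0.1, 1.0)] * 3)
        var = meas("v", [(0.5, 1.0)])
        with pytest.raises(ValueError, match="wild-type"):
            percent_wt_activity(var, wt)

    def test_mismatched_construct_or_plate_rejected(self):
        wt = meas("WT", [(1.0, 1.0)])
        with pytest.raises(ValueError, match="construct"):
            percent_wt_activity(meas("v", [(1.0, 1.0)], construct=Construct.GENOMIC), wt)
        with pytest.raises(ValueError, match="plate"):
            percent_wt_activity(meas("v", [(1.0, 1.0)], plate="p2"), wt)


class TestBrackets:
    @pytest.mark.parametrize(
        "percent,expected",
        [
            (0.037, S),  # p.P428L-like null activity
            (-0.5, S),  # negative = null
            (2.13, M),  # p.R86Q
            (2.0, M),  # boundary: severe bracket is right-open
            (4.32, m),  # p.I181S
            (4.0, m),  # boundary
            (7.86, m),  # p.R86W
            (13.0, m),  # mild bracket closed at the pathogenic threshold
            (13.0 + 1e-9, B),
            (14.69, B),  # p.T393S pseudo-deficiency
        ],
    )
    def test_bracket_assignments(self, percent, expected):
        assert activity_based_severity(percent) is expected

    def test_non_finite_input_is_an_error(self):
        with pytest.raises(ValueError):
            activity_based_severity(math.nan)

    @given(st.floats(-50, 200), st.floats(-50, 200))
    def test_bracket_monotone_in_activity(self, x, y):
        """Higher activity never maps to a more severe class."""
        order = {S: 0, M: 1, m: 2, B: 3}
        lo, hi = sorted((x, y))
        assert order[activity_based_severity(lo)] <= order[activity_based_severity(hi)]

    def test_invalid_bracket_ordering_rejected(self):
        with pytest.raises(ValueError):
            SeverityBrackets(severe_upper=5.0, moderate_upper=4.0)


class TestFinalize:
    @pytest.mark.parametrize(
        "patient,cds,genomic,expected",
        [
            (U, S, None, S),  # only activity evidence
            (U, None, M, M),
            (U, U, U, U),  # all unknown -> unknown, not an error
            (M, S, None, M),  # patient evidence wins over a lone activity call
            (M, B, B, M),  # agreeing activity still concedes to the literature
            (S, M, S, S),  # one activity call matches the patient class
            (B, m, M, m),  # disagreement: ordinally closer to benign wins
            (U, S, B, S),  # no patient anchor: tie broken toward severe
        ],
    )
    def test_reconciliation(self, patient, cds, genomic, expected):
        assert finalize_severity(patient, cds, genomic, overrides={}) is expected

    def test_default_override_pins_p428l_to_moderate(self):
        assert finalize_severity(M, S, None, variant_id="p.P428L") is M
        assert finalize_severity(U, S, None, variant_id="p.P428L") is M


class TestDiagnostics:
    def test_zero_false_positives_give_perfect_specificity_and_infinite_dor(self):
        truth = {"a": "pathogenic", "b": "pathogenic", "c": "benign", "d": "benign"}
        percent = {"a": 0.1, "b": 12.9, "c": 20.0, "d": 99.0}
        out = diagnostic_metrics(truth, percent)
        assert out.specificity == 100.0
        assert math.isinf(out.dor) and math.isinf(out.lr_plus)

    def test_two_by_two_counts_and_ratios(self):
        # TP=3 FP=1 FN=1 TN=3 by construction
        truth = {f"p{i}": "pathogenic" for i in range(4)} | {
            f"b{i}": "benign" for i in range(4)
        }
        percent = {"p0": 1, "p1": 5, "p2": 12, "p3": 50, "b0": 9, "b1": 20, "b2": 30, "b3": 40}
        out = diagnostic_metrics(truth, percent)
        assert (out.tp, out.fp, out.fn, out.tn) == (3, 1, 1, 3)
        assert out.sensitivity == pytest.approx(75.0)
        assert out.specificity == pytest.approx(75.0)
        assert out.dor == pytest.approx(9.0)
        assert out.tp + out.fp + out.fn + out.tn == len(truth)

    def test_all_calls_wrong_gives_zero_sensitivity(self):
        out = diagnostic_metrics(
            {"a": "pathogenic", "b": "benign"}, {"a": 50.0, "b": 1.0}
        )
        assert out.sensitivity == 0.0

    def test_empty_intersection_is_an_error(self):
        with pytest.raises(ValueError):
            diagnostic_metrics({"a": "pathogenic"}, {"b": 1.0})


class TestPredictorCorrelation:
    def test_exact_linear_relationships(self):
        x = {f"v{i}": float(i) for i in range(5)}
        assert predictor_correlation(x, {k: 2 * v + 1 for k, v in x.items()}) == pytest.approx(1.0)
        assert predictor_correlation(x, {k: -v for k, v in x.items()}) == pytest.approx(-1.0)

    def test_matches_independent_numpy_estimate(self):
        rng = np.random.default_rng(11)
        ids = [f"v{i}" for i in range(40)]
        act = rng.uniform(0, 100, 40)
        score = 1 - act / 100 + rng.normal(0, 0.2, 40)
        r = predictor_correlation(dict(zip(ids, act)), dict(zip(ids, score)))
        assert r == pytest.approx(np.corrcoef(act, score)[0, 1])

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            predictor_correlation({"a": 1.0, "b": 2.0}, {"a": 1.0, "b": 2.0})
        flat = {f"v{i}": 5.0 for i in range(4)}
        with pytest.raises(ValueError):
            predictor_correlation(flat, {k: float(i) for i, k in enumerate(flat)})


def test_activity_table_parsing_groups_replicates():
    text = (
        "id\tconstruct\tplate_id\treplicate\tarsa_ion_ratio\tbla_ion_ratio\n"
        "WT\tcds\tp1\t1\t1.0\t1.0\n"
        "WT\tcds\tp1\t2\t1.1\t1.0\n"
        "v1\tcds\tp1\t2\t0.25\t0.9\n"
        "v1\tcds\tp1\t1\t0.2\t1.0\n"
    )
    out = {(mm.variant_id, mm.plate_id): mm for mm in parse_activity_table(io.StringIO(text))}
    v1 = out[("v1", "p1")]
    assert v1.replicate_ion_ratios == [(0.2, 1.0), (0.25, 0.9)]  # replicate order
    assert out[("WT", "p1")].construct is Construct.CDS
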