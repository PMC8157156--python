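"""Cost-weighted evaluation: matrix building, indicators, exact identities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crashsev.evaluation import (
    ConfusionMatrix,
    CostTable,
    EvaluationReport,
    aocc,
    build_confusion,
    compare_models,
    comprehensive_cost,
    cost_errors,
    default_cost_table,
    evaluation_report,
    overall_accuracy,
    pocc,
)

# published reference confusion matrices for a Washington State two-year
# multi-vehicle evaluation set: a mixed-logit and a random-forest predictor
RPL_COUNTS = np.array([[1881, 918, 3], [850, 440, 3], [4, 2, 0]])
RF_COUNTS = np.array([[2408, 419, 1], [909, 306, 1], [0, 0, 0]])


# ---------------------------------------------------------------------------
# confusion matrix


def test_build_confusion_tabulates():
    cm = build_confusion(["PDO", "I"], ["I", "I"])
    assert cm.counts[0, 1] == 1 and cm.counts[1, 1] == 1
    assert cm.counts.sum() == 2


def test_build_confusion_perfect_predictions_diagonal():
    labels = ["PDO"] * 3 + ["I"] * 2 + ["FI"]
    cm = build_confusion(labels, labels)
    assert np.array_equal(cm.counts, np.diag([3, 2, 1]))
    assert overall_accuracy(cm) == 1.0


def test_build_confusion_empty_and_unknown():
    cm = build_confusion([], [])
    assert cm.counts.sum() == 0
    with pytest.raises(ValueError):
        build_confusion(["PDO"], ["X"])
    with pytest.raises(ValueError):
        overall_accuracy(cm)


def test_row_ratios_sum_to_one():
    cm = ConfusionMatrix(counts=RPL_COUNTS)
    r = cm.ratios()
    assert np.allclose(r.sum(axis=1), 1.0)
    assert r[0, 0] == pytest.approx(0.6713, abs=5e-5)  # PDO correct share


def test_overall_accuracy_reference_counts():
    cm = ConfusionMatrix(counts=RPL_COUNTS)
    assert cm.overall_accuracy() == pytest.approx(2321 / 4101, abs=1e-12)
    assert cm.overall_accuracy() == pytest.approx(0.5660, abs=5e-5)


def test_confusion_csv_round_trip(tmp_path):
    cm = ConfusionMatrix(counts=RPL_COUNTS)
    path = tmp_path / "cm.csv"
    cm.to_csv(path)
    back = ConfusionMatrix.read_csv(path)
    assert np.array_equal(back.counts, cm.counts)


# ---------------------------------------------------------------------------
# cost table


def test_comprehensive_cost_sums():
    assert comprehensive_cost(46_132, 97_535) == 143_667
    assert comprehensive_cost(588_738, 3_173_900) == 3_762_638
    assert comprehensive_cost(5.0, 0.0) == 5.0
    with pytest.raises(ValueError):
        comprehensive_cost(-1.0, 0.0)


def test_default_cost_table_values():
    t = default_cost_table()
    assert t.comprehensive == {
        "PDO": 12_456,
        "I": 143_667,
        "FI": 3_762_638,
    }


def test_cost_table_validation_and_scaling():
    with pytest.raises(ValueError):
        CostTable(economic={"PDO": -1, "I": 0, "FI": 0}, qaly={"PDO": 0, "I": 0, "FI": 0})
    t = default_cost_table().scaled(2.0)
    assert t.comprehensive["I"] == 2 * 143_667


# ---------------------------------------------------------------------------
# cost indicators on the reference counts


def test_reference_mixed_logit_costs():
    cm = ConfusionMatrix(counts=RPL_COUNTS)
    costs = default_cost_table()
    assert aocc(cm, costs) == pytest.approx(243_238_971, abs=0.5)
    assert pocc(cm, costs) == pytest.approx(252_030_108, abs=0.5)
    opmae, opape, oprmse = cost_errors(cm, costs)
    assert opape == pytest.approx(0.0361, abs=5e-5)
    assert opmae == pytest.approx(2143.66, abs=0.01)
    assert oprmse == pytest.approx(8_791_137 / math.sqrt(4101), abs=1.0)


def test_reference_random_forest_costs():
    cm = ConfusionMatrix(counts=RF_COUNTS)
    costs = default_cost_table()
    opmae, opape, _ = cost_errors(cm, costs)
    assert opape == pytest.approx(0.2712, abs=5e-5)
    assert int(opmae) == 14_076


def test_diagonal_matrix_equal_costs_and_zero_errors():
    cm = ConfusionMatrix(counts=np.diag([5, 3, 1]))
    costs = default_cost_table()
    assert aocc(cm, costs) == pocc(cm, costs)
    assert cost_errors(cm, costs) == (0.0, 0.0, 0.0)


# ---------------------------------------------------------------------------
# property suite (randomized matrices and cost scales)


counts_strategy = st.lists(
    st.integers(min_value=0, max_value=5000), min_size=9, max_size=9
).filter(lambda c: sum(c[:3]) > 0 or sum(c[3:6]) > 0)

scale_strategy = st.floats(
    min_value=0.01, max_value=100.0, allow_nan=False, allow_infinity=False
)


@settings(deadline=None, max_examples=60)
@given(counts=counts_strategy)
def test_identity_opmae_oprmse_gap(counts):
    """OPMAE*N = OPRMSE*sqrt(N) = |AOCC-POCC| exactly."""
    cm = ConfusionMatrix(counts=np.array(counts).reshape(3, 3))
    costs = default_cost_table()
    gap = abs(aocc(cm, costs) - pocc(cm, costs))
    opmae, _, oprmse = cost_errors(cm, costs)
    assert opmae * cm.n == pytest.approx(gap, rel=1e-12)
    assert oprmse * math.sqrt(cm.n) == pytest.approx(gap, rel=1e-12)


@settings(deadline=None, max_examples=60)
@given(counts=counts_strategy, c=scale_strategy)
def test_opape_scale_invariance(counts, c):
    """Scaling all unit costs by c leaves OPAPE unchanged, scales the rest."""
    cm = ConfusionMatrix(counts=np.array(counts).reshape(3, 3))
    base = default_cost_table()
    scaled = base.scaled(c)
    m0, a0, r0 = cost_errors(cm, base)
    m1, a1, r1 = cost_errors(cm, scaled)
    assert a1 == pytest.approx(a0, rel=1e-9)
    assert m1 == pytest.approx(c * m0, rel=1e-9)
    assert r1 == pytest.approx(c * r0, rel=1e-9)
    assert aocc(cm, scaled) == pytest.approx(c * aocc(cm, base), rel=1e-9)


@settings(deadline=None, max_examples=30)
@given(counts=counts_strategy, data=st.data())
def test_costs_invariant_to_prediction_order(counts, data):
    """AOCC/POCC depend on the matrix only, not the row order of labels."""
    cm = ConfusionMatrix(counts=np.array(counts).reshape(3, 3))
    labels_a, labels_p = [], []
    for i, lvl_a in enumerate(("PDO", "I", "FI")):
        for j, lvl_p in enumerate(("PDO", "I", "FI")):
            k = min(cm.counts[i, j], 20)  # keep lists short
            labels_a += [lvl_a] * k
            labels_p += [lvl_p] * k
    if not labels_a:
        return
    perm = data.draw(st.permutations(range(len(labels_a))))
    cm1 = build_confusion(labels_a, labels_p)
    cm2 = build_confusion(
        [labels_a[i] for i in perm], [labels_p[i] for i in perm]
    )
    costs = default_cost_table()
    assert aocc(cm1, costs) == aocc(cm2, costs)
    assert pocc(cm1, costs) == pocc(cm2, costs)


# ---------------------------------------------------------------------------
# reports


def test_evaluation_report_and_comparison_table():
    costs = default_cost_table()
    rpl = evaluation_report(ConfusionMatrix(counts=RPL_COUNTS), costs, "mixed-logit")
    rf = evaluation_report(ConfusionMatrix(counts=RF_COUNTS), costs, "forest")
    table = compare_models([rpl, rf], paper_style=True)
    assert table.loc["AOCC (USD millions)", "mixed-logit"] == 243
    assert table.loc["POCC (USD millions)", "mixed-logit"] == 252
    assert table.loc["POCC (USD millions)", "forest"] == 153
    assert table.loc["AOCC (USD millions)", "forest"] == 209  # truncated
    assert table.loc["OPMAE (USD)", "mixed-logit"] == 2143
    assert table.loc["OPMAE (USD)", "forest"] == 14_076
    assert table.loc["OPRMSE (thousand USD)", "mixed-logit"] == 137
    assert table.loc["OPRMSE (thousand USD)", "forest"] == 895
    assert table.loc["OPAPE (%)", "mixed-logit"] == 3.61
    assert table.loc["OPAPE (%)", "forest"] == 27.12
    # qualitative ranking: logit better on costs, forest on raw accuracy
    assert rpl.opape < rf.opape
    assert rf.r_overall > rpl.r_overall


def test_identical_reports_identical_columns():
    rep = evaluation_report(ConfusionMatrix(counts=RPL_COUNTS), name="a")
    rep2 = evaluation_report(ConfusionMatrix(counts=RPL_COUNTS), name="b")
    table = compare_models([rep, rep2])
    assert (table["a"] == table["b"]).all()


def test_report_json_round_trip():
    rep = evaluation_report(ConfusionMatrix(counts=RPL_COUNTS), name="m")
    back = EvaluationReport.from_json(rep.to_json())
    assert back.to_dict() == rep.to_dict()
    assert np.array_equal(back.confusion.counts, rep.confusion.counts)
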