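"""Confusion diagnostics, filtering scenarios, and the waterfall overview."""

import math

import numpy as np
import pytest

from tp53proxy import (
    CellLineRecord,
    ConfusionMetrics,
    DomainError,
    Label,
    call_cohort,
    confusion,
    evaluate,
    filter_likely_wt,
    scenario_remove,
    waterfall_data,
    waterfall_plot,
)
CGM097 = "NVP-CGM097"
CFC218 = "NVP-CFC218"


def make_cohort(cells, compound=CGM097):
    """cells: list of (pred, obs) strings."""
    return [
        CellLineRecord(
            cell_line=f"L{i:03d}",
            mutations=[],
            tp53_mrna=200.0,
            cn_ratio=1.0,
            signature_prediction={compound: Label(pred)},
            observed_sensitivity={compound: Label(obs)},
        )
        for i, (pred, obs) in enumerate(cells)
    ]


def tally_oracle(records, compound):
    """Independent literal count-and-divide oracle."""
    pairs = [
        (r.signature_prediction[compound].value, r.observed_sensitivity[compound].value)
        for r in records
    ]
    tp = sum(p == "sensitive" and o == "sensitive" for p, o in pairs)
    fp = sum(p == "sensitive" and o == "insensitive" for p, o in pairs)
    fn = sum(p == "insensitive" and o == "sensitive" for p, o in pairs)
    tn = sum(p == "insensitive" and o == "insensitive" for p, o in pairs)

    def div(a, b):
        return a / b if b else math.nan

    return {
        "tp": tp, "fp": fp, "tn": tn, "fn": fn,
        "sensitivity": div(tp, tp + fn),
        "specificity": div(tn, tn + fp),
        "ppv": div(tp, tp + fp),
        "npv": div(tn, tn + fn),
        "response_rate": div(tp + fn, len(pairs)),
    }


def assert_matches_oracle(m, oracle):
    assert (m.tp, m.fp, m.tn, m.fn) == (oracle["tp"], oracle["fp"], oracle["tn"], oracle["fn"])
    for key in ("sensitivity", "specificity", "ppv", "npv", "response_rate"):
        got, want = getattr(m, key), oracle[key]
        assert (math.isnan(got) and math.isnan(want)) or got == pytest.approx(want)


def test_confusion_on_validation40(validation40):
    m = confusion(validation40, CGM097)
    assert (m.tp, m.fn, m.fp, m.tn) == (24, 3, 11, 2)
    assert m.sensitivity == pytest.approx(24 / 27)
    assert m.specificity == pytest.approx(2 / 13)
    assert m.ppv == pytest.approx(24 / 35)
    assert m.npv == pytest.approx(2 / 5)
    assert m.response_rate == pytest.approx(27 / 40)
    assert m.fractions()["ppv"] == "24/35"


def test_confusion_matches_tally_oracle_over_random_cohorts():
    rng = np.random.default_rng(1)
    labels = ("sensitive", "insensitive")
    for _ in range(200):
        cells = [(labels[rng.integers(2)], labels[rng.integers(2)]) for _ in range(15)]
        records = make_cohort(cells)
        assert_matches_oracle(confusion(records, CGM097), tally_oracle(records, CGM097))


def test_confusion_edge_cases():
    perfect = confusion(make_cohort([("sensitive", "sensitive")] * 3
                                    + [("insensitive", "insensitive")] * 2), CGM097)
    assert (perfect.sensitivity, perfect.specificity, perfect.ppv, perfect.npv) == (1, 1, 1, 1)
    # undefined denominators come back NaN, never an exception
    all_pos = confusion(make_cohort([("sensitive", "sensitive")] * 4), CGM097)
    assert math.isnan(all_pos.specificity) and math.isnan(all_pos.npv)
    with pytest.raises(DomainError):
        confusion([], CGM097)
    missing = make_cohort([("sensitive", "sensitive")])
    missing[0].observed_sensitivity[CGM097] = Label.MISSING
    with pytest.raises(DomainError):
        confusion(missing, CGM097)


def test_count_identities_are_exact():
    rng = np.random.default_rng(3)
    for _ in range(50):
        tp, fp, tn, fn = (int(x) for x in rng.integers(0, 30, size=4))
        m = ConfusionMetrics(tp=tp, fp=fp, tn=tn, fn=fn)
        if tp + fp:
            assert m.exact("ppv") * (tp + fp) == tp
            assert m.ppv == pytest.approx(tp / (tp + fp))
        if tn + fn:
            assert m.exact("npv") * (tn + fn) == tn
        assert m.n == tp + fp + tn + fn


def test_filter_likely_wt_partitions_and_is_pure(validation40, table1_records):
    records = table1_records + validation40
    calls = call_cohort(records)
    snapshot = {r.cell_line: dict(r.signature_prediction) for r in records}
    kept, removed = filter_likely_wt(records, calls)
    assert (len(kept), len(removed)) == (40, 12)
    assert {r.cell_line for r in removed} == {r.cell_line for r in table1_records}
    for r in records:  # the filter never touches a record
        assert r.signature_prediction == snapshot[r.cell_line]
    with pytest.raises(DomainError, match="L999"):
        filter_likely_wt(
            [CellLineRecord("L999", mutations=[], tp53_mrna=1.0)], calls
        )


def test_filter_on_panel113(panel113):
    calls = call_cohort(panel113)
    kept, removed = filter_likely_wt(panel113, calls)
    assert (len(kept), len(removed)) == (84, 29)
    assert confusion(kept, CFC218).response_rate == pytest.approx(43 / 84)
    assert confusion(panel113, CFC218).response_rate == pytest.approx(43 / 113)


def test_scenario_remove_dang(validation40):
    sc = scenario_remove(validation40, ["DAN-G"], "dang_removed", CGM097)
    assert sc.metrics.specificity == pytest.approx(1 / 12)
    assert sc.metrics.npv == pytest.approx(1 / 4)
    assert sc.metrics.n == 39
    # no-op removal leaves the baseline untouched
    base = scenario_remove(validation40, [], "noop", CGM097)
    assert base.metrics == confusion(validation40, CGM097)
    with pytest.raises(DomainError, match="NOPE"):
        scenario_remove(validation40, ["NOPE"], "x", CGM097)


def test_scenario_remove_drops_exactly_that_cell(validation40):
    rng = np.random.default_rng(11)
    base = confusion(validation40, CGM097)
    for _ in range(10):
        victim = validation40[rng.integers(len(validation40))]
        sc = scenario_remove(validation40, [victim.cell_line], "one", CGM097)
        m = sc.metrics
        pred = victim.prediction_for(CGM097) is Label.SENSITIVE
        obs = victim.observation_for(CGM097) is Label.SENSITIVE
        expected = {
            "tp": base.tp - (pred and obs),
            "fp": base.fp - (pred and not obs),
            "fn": base.fn - (not pred and obs),
            "tn": base.tn - (not pred and not obs),
        }
        assert (m.tp, m.fp, m.fn, m.tn) == tuple(expected[k] for k in ("tp", "fp", "fn", "tn"))


def test_removing_true_negative_decreases_specificity():
    cells = [("insensitive", "insensitive")] * 3 + [("sensitive", "insensitive")] * 5
    records = make_cohort(cells)
    base = confusion(records, CGM097)
    sc = scenario_remove(records, ["L000"], "tn_gone", CGM097)
    assert sc.metrics.specificity < base.specificity


def test_evaluate_scenario_ladder(validation40, table1_records):
    records = table1_records + validation40
    calls = call_cohort(records)
    scenarios = {s.label: s for s in evaluate(records, calls, CGM097)}
    assert set(scenarios) == {"all_lines", "likely_wt", "likely_wt_no_borderline"}
    assert scenarios["all_lines"].metrics.n == 52
    wt = scenarios["likely_wt"].metrics
    assert (wt.tp, wt.fn, wt.fp, wt.tn) == (24, 3, 11, 2)
    # DAN-G is the only borderline line in the likely-WT set
    nb = scenarios["likely_wt_no_borderline"]
    assert set(nb.removed_lines) - set(scenarios["likely_wt"].removed_lines) == {"DAN-G"}
    assert nb.metrics.specificity == pytest.approx(1 / 12)
    # policies emit subsets of the ladder
    assert [s.label for s in evaluate(records, calls, CGM097, "keep")] == [
        "all_lines", "likely_wt"]
    assert [s.label for s in evaluate(records, calls, CGM097, "drop")] == [
        "all_lines", "likely_wt_no_borderline"]


def test_borderline_free_cohort_makes_scenarios_coincide(panel113):
    calls = call_cohort(panel113)
    scenarios = {s.label: s for s in evaluate(panel113, calls, CFC218)}
    assert scenarios["likely_wt"].metrics == scenarios["likely_wt_no_borderline"].metrics


def test_filtering_insensitive_inactivated_never_lowers_response_rate():
    """Mechanistic premise: inactivated lines are always observed-insensitive;
    removing them can only raise (or keep) the response rate."""
    from tp53proxy import SyntheticCohortConfig, generate_cohort

    for seed in range(5):
        cfg = SyntheticCohortConfig(n_lines=120, seed=seed)
        records, _ = generate_cohort(cfg)
        calls = call_cohort(records)
        kept, _ = filter_likely_wt(records, calls)
        if kept:
            before = confusion(records, cfg.compound).response_rate
            after = confusion(kept, cfg.compound).response_rate
            assert after >= before - 1e-12


def test_waterfall(tmp_path, validation40):
    calls = call_cohort(validation40)
    df = waterfall_data(validation40, calls, CGM097)
    assert len(df) == 40
    assert (df["predicted"] == "sensitive").sum() == 35
    assert df[df["cell_line"] == "DAN-G"]["borderline"].item()
    # deterministic plot source data
    df2 = waterfall_plot(validation40, calls, CGM097, tmp_path / "wf.png")
    assert (tmp_path / "wf.png").exists()
    assert df.equals(df2)
    one = waterfall_data(validation40[:1], calls[:1], CGM097)
    assert len(one) == 1
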