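import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from caftorlab.config_io import Measurement, round_half_up
from caftorlab.validation_stats import (
    accuracy_precision_tables,
    carryover_check,
    extraction_recovery,
    is_normalized,
    lloq_qualification,
    matrix_effect,
    percent_bias,
    percent_cv,
    selectivity_check,
    stability_percent,
    stability_table,
)
from caftorlab.synthetic_data import (
    MatrixTruth,
    StabilityTruth,
    generate_me_er_experiment,
    generate_stability_series,
)

positive = st.floats(min_value=1e-3, max_value=1e3)


# -- elementary statistics --------------------------------------------------


def test_percent_bias_examples():
    # ten replicates constructed to mean 15.55 against nominal 18 (a high-QC
    # run reading ~13.6% low)
    values = [15.5, 15.6] * 5
    assert np.mean(values) == pytest.approx(15.55)
    assert percent_bias(values, 18.0) == pytest.approx(-13.61, abs=0.005)
    assert percent_bias([8.0, 8.0], 8.0) == 0.0
    assert percent_bias([16.0], 8.0) == pytest.approx(100.0)
    with pytest.raises(ValueError):
        percent_bias([1.0], 0.0)


def test_percent_cv_examples():
    assert percent_cv([8, 8, 8]) == 0.0
    assert percent_cv([1, 2, 3]) == pytest.approx(50.0)  # SD 1, mean 2
    with pytest.raises(ValueError):
        percent_cv([1.0])


@given(st.lists(positive, min_size=2, max_size=20), st.floats(min_value=0.1, max_value=100))
def test_percent_cv_scale_invariant(values, scale):
    if np.mean(values) <= 1e-6:
        return
    assert percent_cv(values) == pytest.approx(percent_cv([v * scale for v in values]), rel=1e-6)


# -- accuracy / precision ---------------------------------------------------


def _qc(analyte, level, nominal, run, values):
    return [
        Measurement(
            analyte=analyte, role=level, run_id=run, replicate=i + 1,
            nominal=nominal, concentration=v,
        )
        for i, v in enumerate(values)
    ]


def test_zero_noise_single_run_is_exact(iva):
    ms = _qc("IVA", "qc_mid", 8.0, "run01", [8.0, 8.0, 8.0])
    intra, inter = accuracy_precision_tables(ms, iva)
    assert intra.scope == "intra" and inter.scope == "inter"
    for s in (intra, inter):
        assert s.percent_bias == 0.0 and s.percent_cv == 0.0 and s.passed


def test_shifted_run_breaks_inter_run_acceptance(iva):
    ms = []
    for r in range(1, 6):
        ms += _qc("IVA", "qc_mid", 8.0, f"run{r:02d}", [8.0, 8.05, 7.95])
    ms += _qc("IVA", "qc_mid", 8.0, "run06", [14.4, 14.4, 14.4])  # +80% run
    intra, inter = accuracy_precision_tables(ms, iva)
    assert not inter.passed  # run means pulled up past 15%
    # worst intra run is the clean-but-shifted one: bias 80%, CV 0
    assert intra.run_id == "run06" and intra.percent_bias == pytest.approx(80.0)


def test_between_run_variance_shows_only_in_inter_scope(iva):
    rng = np.random.default_rng(7)
    ms = []
    for r in range(12):
        shift = rng.normal(0, 0.06)  # ~6% between-run component
        vals = 8.0 * (1 + shift) * (1 + rng.normal(0, 0.002, size=5))
        ms += _qc("IVA", "qc_mid", 8.0, f"run{r:02d}", list(vals))
    intra, inter = accuracy_precision_tables(ms, iva)
    assert inter.percent_cv > intra.percent_cv


def test_missing_run_labels_rejected(iva):
    ms = _qc("IVA", "qc_mid", 8.0, "", [8.0, 8.1])
    with pytest.raises(ValueError, match="run_id"):
        accuracy_precision_tables(ms, iva)


# -- blanks -----------------------------------------------------------------


@pytest.mark.parametrize(
    "blank_frac,is_frac,expected",
    [(0.19, 0.04, True), (0.21, 0.04, False), (0.19, 0.06, False)],
)
def test_selectivity_thresholds(blank_frac, is_frac, expected):
    v = selectivity_check(
        blank_responses=[blank_frac * 10.0] * 3,
        lloq_response=10.0,
        is_response_in_lloq=100.0,
        blank_is_responses=[is_frac * 100.0] * 3,
    )
    assert v.passed is expected


def test_carryover_uses_median_of_triplicate():
    ok = carryover_check([1.0, 1.2, 1.5], lloq_response=10.0, is_response=100.0)
    assert ok.passed
    bad = carryover_check([2.5, 1.8, 2.2], lloq_response=10.0, is_response=100.0)
    assert bad.analyte_fraction == pytest.approx(0.22) and not bad.passed
    is_dirty = carryover_check(
        [1.0, 1.0, 1.0], 10.0, 100.0, blank_is_responses=[7.0, 7.0, 7.0]
    )
    assert not is_dirty.passed


# -- matrix effect / recovery ----------------------------------------------


def test_matrix_effect_and_recovery_ratios():
    me = matrix_effect([(100.0, 96.2)] * 6)
    assert me.mean_percent == pytest.approx(96.2)
    assert me.passed and me.cv_percent == pytest.approx(0.0)
    er = extraction_recovery([(96.2, 96.2 * 0.91)] * 6)
    assert er.mean_percent == pytest.approx(91.0)
    assert er.passed
    assert not matrix_effect([(100.0, 84.9)] * 3).passed
    assert not extraction_recovery([(100.0, 89.9)] * 3).passed


def test_is_normalized():
    assert is_normalized(96.2, 96.2) == pytest.approx(100.0)
    assert is_normalized(96.2, 100.0) == pytest.approx(96.2)
    with pytest.raises(ValueError):
        is_normalized(96.2, 0.0)


def test_me_er_generator_recovery_and_telescoping():
    truth = MatrixTruth(me_factor=0.962, er_factor=0.91, n_lots=6)
    table = generate_me_er_experiment(truth, level=0.3, neat_area=1e5)
    me = matrix_effect(list(zip(table.area_A, table.area_B)))
    er = extraction_recovery(list(zip(table.area_B, table.area_C)))
    assert me.mean_percent == pytest.approx(96.2)
    assert er.mean_percent == pytest.approx(91.0)
    # conservation of ratios: C/A = (B/A)·(C/B)
    for a, b, c in zip(table.area_A, table.area_B, table.area_C):
        assert 100 * c / a == pytest.approx(me.mean_percent * er.mean_percent / 100)


def test_me_lot_to_lot_cv_tracks_noise():
    truth = MatrixTruth(me_factor=1.0, er_factor=1.0, n_lots=400)
    table = generate_me_er_experiment(truth, 0.3, 1e5, seed=11, noise_cv=0.03)
    me = matrix_effect(list(zip(table.area_A, table.area_B)))
    # B/A = me_factor·ε with a single 3% lognormal factor per lot
    assert me.cv_percent == pytest.approx(3.0, rel=0.2)


# -- stability --------------------------------------------------------------


@given(positive)
def test_stability_identity_and_scale_invariance(x):
    assert stability_percent(x, x) == pytest.approx(100.0)
    assert stability_percent(2 * x, x) == pytest.approx(stability_percent(4 * x, 2 * x))


def test_stability_percent_printed_cells():
    assert round_half_up(stability_percent(8.55, 8.56)) == 99.88
    assert round_half_up(stability_percent(6.70, 8.56)) == 78.27


def test_stability_table_reproduces_autosampler_study():
    """The three-level, 0/24h/9-day series for the degrading analyte: all
    24 h cells pass, all day-9 cells fall below the 85% window."""
    rows = []
    data = {"low": (0.330, 0.335, 0.250), "medium": (8.56, 8.55, 6.70), "high": (15.50, 15.70, 11.40)}
    for level, (t0, t1, t9) in data.items():
        for day, v in zip((0, 1, 9), (t0, t1, t9)):
            rows.append(
                dict(analyte="IVA", level=level, condition="autosampler_rt",
                     timepoint_days=day, value=v)
            )
    records = stability_table(pd.DataFrame(rows))
    assert len(records) == 6
    day9 = [r for r in records if r.elapsed_days == 9]
    assert all(not r.passed for r in day9)
    assert sorted(round_half_up(r.stability_percent) for r in day9) == [73.55, 75.76, 78.27]
    day1 = [r for r in records if r.elapsed_days == 1]
    assert all(r.passed for r in day1)


def test_stability_generator_inversion():
    """k chosen to hit the observed day-9 endpoint reproduces it exactly."""
    k = np.log(8.56 / 6.70) / 9.0
    truth = StabilityTruth(k_decay=k, timepoints_days=[0, 9])
    df = generate_stability_series(truth, {"medium": 8.56})
    day9 = df[df.timepoint_days == 9]["value"].iloc[0]
    assert day9 == pytest.approx(6.70, rel=1e-12)
    flat = generate_stability_series(
        StabilityTruth(k_decay=0.0, timepoints_days=[0, 1, 9]), {"low": 0.3}
    )
    recs = stability_table(flat)
    assert all(r.stability_percent == pytest.approx(100.0) for r in recs)


def test_stability_table_requires_time_zero():
    df = pd.DataFrame(
        [dict(analyte="IVA", level="low", condition="c", timepoint_days=9, value=1.0)]
    )
    with pytest.raises(ValueError, match="time-0"):
        stability_table(df)


# -- LLOQ qualification -----------------------------------------------------


def _lloq_reps(values_by_session):
    out = []
    for sid, vals in values_by_session.items():
        out += [
            Measurement(analyte="IVA", role="lloq", run_id=sid, replicate=i + 1,
                        nominal=0.1, concentration=v)
            for i, v in enumerate(vals)
        ]
    return out


def test_lloq_qualification_verdicts():
    exact = _lloq_reps({f"s{i}": [0.1] * 8 for i in range(5)})
    res = lloq_qualification(exact, nominal=0.1)
    assert res.passed and not res.warnings
    # one noisy session sinks the verdict even if the pool squeaks by
    noisy = _lloq_reps(
        {
            "s0": [0.1] * 8,
            "s1": [0.1] * 8,
            "s2": [0.1] * 8,
            "s3": [0.1] * 8,
            "s4": [0.06, 0.14, 0.06, 0.14, 0.06, 0.14, 0.06, 0.14],
        }
    )
    res = lloq_qualification(noisy, nominal=0.1)
    session4 = [s for s in res.per_session if s.run_id == "s4"][0]
    assert session4.percent_cv > 20 and not res.passed
    few = lloq_qualification(_lloq_reps({"s0": [0.11] * 10}), nominal=0.1)
    assert few.warnings and few.passed  # +10% bias within 20%
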