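"""Fold-change sentinels, BH adjustment, the moderated test and DEL calls."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lnckit import (
    ExpressionMatrix,
    adjust_bh,
    call_dels,
    log2fc,
    moderated_test,
    read_del_table,
    tabulate_dels,
    welch_t,
)
from lnckit.expression import design_from_sample_names


def bh_oracle(p):
    """Brute-force BH: min over j >= rank of p_(j) * m / j, capped at 1."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    for rank_idx, i in enumerate(order):
        tail = [p[order[j]] * m / (j + 1) for j in range(rank_idx, m)]
        adj[i] = min(1.0, min(tail))
    return adj


def _expr(values: np.ndarray, transcripts=None) -> ExpressionMatrix:
    samples = [
        f"{c}_{tp}h_r{r}" for c in ("C", "TCDD") for tp in (3, 12, 24)
        for r in (1, 2)
    ]
    values = np.asarray(values, float)
    idx = transcripts or [f"T{i}" for i in range(values.shape[0])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=idx, columns=samples),
        design_from_sample_names(samples),
    )


class TestLog2FC:
    @pytest.mark.parametrize(
        "treated,control,expected",
        [(4, 1, 2.0), (1, 1, 0.0), (0.9, 0, math.inf), (0, 0.9, -math.inf)],
    )
    def test_values_and_sentinels(self, treated, control, expected):
        assert log2fc(treated, control) == expected

    def test_both_silent_gives_no_value(self):
        assert log2fc(0, 0) is None

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            log2fc(-1, 2)


class TestBH:
    def test_hand_computed_example(self):
        assert adjust_bh([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_and_degenerate(self):
        assert adjust_bh([0.2]) == pytest.approx([0.2])
        assert adjust_bh([1.0, 1.0, 1.0]) == pytest.approx([1, 1, 1])

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(9)
        p = rng.random(50)
        assert (adjust_bh(p) >= p - 1e-15).all()

    def test_matches_brute_force_definition(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            p = rng.random(int(rng.integers(1, 40)))
            assert adjust_bh(p) == pytest.approx(bh_oracle(p), abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.5])

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=30,
        )
    )
    def test_property_matches_brute_force(self, p):
        assert adjust_bh(p) == pytest.approx(bh_oracle(p), abs=1e-12)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=30,
        )
    )
    def test_property_order_preserved(self, p):
        """BH never reorders evidence: adjusted values are monotone in the
        raw values."""
        adj = adjust_bh(p)
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestModeratedTest:
    def test_identical_groups_give_p_one(self):
        expr = _expr(np.tile([[5.0] * 12], (3, 1)))
        assert (moderated_test(expr, 3) == 1).all()

    def test_zero_shrinkage_recovers_welch(self):
        rng = np.random.default_rng(31)
        vals = rng.lognormal(1, 0.6, size=(40, 12))
        expr = _expr(vals)
        p = moderated_test(expr, 12, shrink=0.0)
        ctrl = expr.samples_for("control", 12)
        trt = expr.samples_for("treated", 12)
        for tid in expr.values.index:
            a = np.log2(expr.values.loc[tid, trt].to_numpy(float) + 0.1)
            b = np.log2(expr.values.loc[tid, ctrl].to_numpy(float) + 0.1)
            assert p[tid] == pytest.approx(welch_t(a, b).p, abs=1e-12)

    def test_power_on_planted_fold_change(self):
        """log2FC = 3 with sd 0.1 lognormal noise at n = 2 vs 2 is detected
        nearly always thanks to variance shrinkage."""
        rng = np.random.default_rng(41)
        base = 4.0
        n = 200
        vals = np.empty((n, 12))
        for i in range(n):
            means = np.array([base] * 6 + [base * 8] * 2 + [base] * 4)
            vals[i] = means * rng.lognormal(0, 0.1, size=12)
        expr = _expr(vals)
        p = moderated_test(expr, 3)
        assert (p < 0.05).mean() >= 0.95

    def test_sentinel_presence_absence_rule(self):
        vals = np.tile([[2.0] * 12], (4, 1))
        vals[0, 0:2] = 0.0   # silent control at 3 h, treated expressed
        vals[1, 0:2] = 0.0
        vals[1, 6:8] = 0.2   # treated below the floor: inconclusive
        expr = _expr(vals)
        p = moderated_test(expr, 3)
        assert p.iloc[0] == 0.0
        assert p.iloc[1] == 1.0


class TestCallDels:
    def test_small_fold_change_not_called(self):
        vals = np.tile([[4.0] * 12], (2, 1))
        vals[0, 6:12] = 4.0 * 2**0.5  # |log2FC| = 0.5 at every timepoint
        expr = _expr(vals)
        assert call_dels(expr) == []

    def test_treated_only_direction(self, noiseless_dataset):
        ds = noiseless_dataset
        dels = {r.lnc_id: r for r in call_dels(ds.expression)}
        rec = dels["TCONS_LINC_0003"]
        assert rec.treated_only
        assert rec.calls[3].direction == "treated_only"

    def test_planted_dels_recovered(self, noiseless_dataset):
        ds = noiseless_dataset
        lnc_ids = [
            t for t, lab in ds.truth.labels.items()
            if lab == "known_lnc" or lab.startswith("novel")
        ]
        dels = call_dels(ds.expression.subset(lnc_ids))
        called = {
            tp: {r.lnc_id for r in dels if tp in r.calls} for tp in (3, 12, 24)
        }
        assert called == ds.truth.expected_dels

    def test_thresholds_off_returns_every_changed_transcript(self):
        vals = np.tile([[4.0] * 12], (3, 1))
        vals[0, 6:12] *= 1.2   # small but consistent change
        expr = _expr(vals)
        dels = call_dels(expr, alpha=1.0, lfc=0.0)
        assert {r.lnc_id for r in dels} == {"T0"}


class TestTabulate:
    def test_packaged_del_table_tallies(self, table1_path):
        tab = tabulate_dels(read_del_table(table1_path))
        assert tab.n_records == 22
        assert tab.tallies == {3: 15, 12: 4, 24: 7}
        assert tab.n_treated_only == 5
        assert tab.n_down == {3: 0, 12: 0, 24: 2}
        assert tab.n_all_timepoints == 1
        assert tab.finite_fc_max == pytest.approx(3.77)
        assert tab.finite_fc_min == pytest.approx(-1.01)

    def test_round_trip_through_tsv(self, table1_path, tmp_path):
        from lnckit import write_del_table

        dels = read_del_table(table1_path)
        out = tmp_path / "again.tsv"
        write_del_table(dels, out)
        again = read_del_table(out)
        assert [(r.lnc_id, sorted(r.calls)) for r in again] == [
            (r.lnc_id, sorted(r.calls)) for r in dels
        ]

    def test_constant_expression_row_z_scores_are_zero(self, table1_path):
        dels = read_del_table(table1_path)[:2]
        samples = [
            f"{c}_{tp}h_r{r}" for c in ("C", "TCDD") for tp in (3, 12, 24)
            for r in (1, 2)
        ]
        vals = pd.DataFrame(
            [[3.0] * 12, list(range(1, 13))],
            index=[dels[0].lnc_id, dels[1].lnc_id],
            columns=samples,
        )
        expr = ExpressionMatrix(vals, design_from_sample_names(samples))
        tab = tabulate_dels(dels, expr=expr)
        assert tab.constant_rows == [dels[0].lnc_id]
        assert (tab.heatmap_z.loc[dels[0].lnc_id] == 0).all()
        assert tab.heatmap_z.loc[dels[1].lnc_id].std(ddof=0) == pytest.approx(1.0)
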