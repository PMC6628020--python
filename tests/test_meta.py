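import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dtameta import (
    ConfusionTable,
    forest_data,
    pool_log_ratio,
    pool_proportion,
    study_indices,
)

tables_strategy = st.lists(
    st.tuples(
        st.integers(1, 200), st.integers(1, 200),
        st.integers(1, 200), st.integers(1, 200),
    ),
    min_size=2,
    max_size=8,
).map(
    lambda ts: [
        ConfusionTable(tp, fp, fn, tn, study_id=f"s{i}")
        for i, (tp, fp, fn, tn) in enumerate(ts)
    ]
)


class TestStudyIndices:
    def test_hand_arithmetic_on_largest_cohort(self):
        # (92, 1, 6, 49): 98 cases, 50 controls
        s = study_indices(ConfusionTable(92, 1, 6, 49))
        assert s.sens == pytest.approx(92 / 98)
        assert s.spec == pytest.approx(0.98)
        assert s.plr == pytest.approx((92 / 98) / 0.02, rel=1e-12)   # 46.94
        assert s.dor == pytest.approx(92 * 49 / (1 * 6), rel=1e-12)  # 751.33
        assert not s.corrected

    def test_zero_cell_continuity_corrected(self):
        s = study_indices(ConfusionTable(10, 0, 5, 20))
        assert s.corrected
        assert s.sens == pytest.approx(10.5 / 16)
        assert np.isfinite([s.ln_plr, s.ln_nlr, s.ln_dor]).all()
        assert s.var_ln_plr > 0 and s.var_ln_nlr > 0 and s.var_ln_dor > 0

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            study_indices(ConfusionTable(0, 5, 0, 5))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(tables_strategy)
    def test_dor_equals_plr_over_nlr(self, tables):
        for t in tables:
            s = study_indices(t)
            assert s.dor == pytest.approx(s.plr / s.nlr, rel=1e-12)

    def test_continuity_correction_vanishes_for_large_counts(self):
        """The +0.5 correction perturbs the DOR by O(1/n): < 1% at
        1000 per arm."""
        raw = ConfusionTable(900, 100, 100, 900)
        uncorrected = study_indices(raw).dor
        tp, fp, fn, tn = 900.5, 100.5, 100.5, 900.5
        corrected = (tp * tn) / (fp * fn)
        assert abs(corrected - uncorrected) / uncorrected < 0.01


class TestPoolProportion:
    def test_aggregate_sensitivity(self, chga_tables):
        res = pool_proportion(chga_tables, "sens")
        assert res.estimate == pytest.approx(255 / 285)
        assert round(res.estimate, 2) == 0.89

    def test_aggregate_specificity(self, chga_tables):
        res = pool_proportion(chga_tables, "spec")
        assert res.estimate == pytest.approx(201 / 225)
        assert round(res.estimate, 2) == 0.89

    def test_identical_studies_are_homogeneous(self):
        tables = [ConfusionTable(40, 10, 10, 40, study_id=f"s{i}") for i in range(4)]
        res = pool_proportion(tables, "sens")
        assert res.estimate == pytest.approx(0.8)
        assert res.q_stat == pytest.approx(0.0, abs=1e-12)
        assert res.i2 == 0.0

    def test_single_study_passthrough(self):
        res = pool_proportion([ConfusionTable(40, 10, 10, 40)], "sens")
        assert res.df == 0 and res.i2 == 0.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(tables_strategy)
    def test_split_invariance(self, tables):
        """Splitting one study into two with the same total counts leaves
        the aggregate proportion unchanged."""
        t = tables[0]
        if t.tp < 2 or t.fn < 2:
            return
        half_a = ConfusionTable(t.tp // 2, t.fp, t.fn // 2, t.tn, study_id="a")
        half_b = ConfusionTable(
            t.tp - t.tp // 2, t.fp, t.fn - t.fn // 2, t.tn, study_id="b"
        )
        merged = pool_proportion(tables, "sens").estimate
        split = pool_proportion([half_a, half_b] + tables[1:], "sens").estimate
        # numerators and denominators are preserved by the split
        assert split == pytest.approx(merged, rel=1e-12)


class TestPoolLogRatio:
    """Pooling cross-checked against an independent reference: the same five
    tables run through R metafor's rma(yi, vi, method="DL") give pooled DOR
    57.251775 (CI 14.875577-220.345449), tau^2 1.770888, Q 17.099039, and
    pooled PLR 7.456404; those values are frozen here."""

    def test_dor_matches_metafor(self, chga_indices):
        res = pool_log_ratio(chga_indices, "dor", model="random")
        assert res.estimate == pytest.approx(57.251775, abs=1e-4)
        assert res.ci_low == pytest.approx(14.875577, abs=1e-4)
        assert res.ci_high == pytest.approx(220.345449, abs=1e-3)
        assert res.tau2 == pytest.approx(1.770888, abs=1e-5)
        assert res.q_stat == pytest.approx(17.099039, abs=1e-5)

    def test_plr_matches_metafor(self, chga_indices):
        res = pool_log_ratio(chga_indices, "plr", model="random")
        assert res.estimate == pytest.approx(7.456404, abs=1e-4)

    def test_nlr_near_printed_value(self, chga_indices):
        res = pool_log_ratio(chga_indices, "nlr", model="random")
        assert res.estimate == pytest.approx(0.14, abs=0.01)

    def test_identical_tables_pool_to_common_index(self):
        tables = [ConfusionTable(40, 10, 10, 40, study_id=f"s{i}") for i in range(3)]
        idx = [study_indices(t) for t in tables]
        res = pool_log_ratio(idx, "dor", model="random")
        assert res.estimate == pytest.approx(idx[0].dor, rel=1e-10)
        assert res.tau2 == 0.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(tables_strategy, st.sampled_from(["plr", "nlr", "dor"]))
    def test_pooled_within_study_range_and_tau2_nonneg(self, tables, which):
        idx = [study_indices(t) for t in tables]
        for model in ("fixed", "random"):
            res = pool_log_ratio(idx, which, model=model)
            logs = [s.log_index(which)[0] for s in idx]
            assert res.tau2 >= 0.0
            assert min(logs) - 1e-9 <= np.log(res.estimate) <= max(logs) + 1e-9

    def test_equal_variances_homogeneous_gives_fixed_equals_random(self):
        # identical tables: equal variances and Q = 0 <= df
        tables = [ConfusionTable(30, 8, 6, 25, study_id=f"s{i}") for i in range(4)]
        idx = [study_indices(t) for t in tables]
        fixed = pool_log_ratio(idx, "dor", model="fixed")
        random = pool_log_ratio(idx, "dor", model="random")
        assert fixed.estimate == pytest.approx(random.estimate, rel=1e-12)


class TestForestData:
    def test_shape_weights_and_order(self, chga_tables, chga_indices):
        pooled = pool_log_ratio(chga_indices, "dor", model="random")
        df = forest_data(chga_indices, pooled)
        assert len(df) == len(chga_tables) + 1
        assert df["weight"].iloc[:-1].sum() == pytest.approx(1.0, abs=1e-9)
        est = df["estimate"].iloc[:-1].to_numpy()
        assert (est == sorted(est, reverse=True)).all()

    def test_proportion_rows(self, chga_tables, chga_indices):
        pooled = pool_proportion(chga_tables, "sens")
        df = forest_data(chga_indices, pooled)
        assert ((df["ci_low"] <= df["estimate"]) & (df["estimate"] <= df["ci_high"])).all()
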