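"""Gating and marker quantification against generator truth and oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from matuscore import gating, panel
from matuscore.gating import (
    GateParams,
    GatingError,
    analyze_sample,
    expression_pattern,
    gate_lymphocytes,
    mfir,
    percent_positive,
    positivity_threshold,
    select_b_cells,
)


def _events(n, **cols):
    base = {c: np.full(n, 5.0) for c in panel.EVENT_COLUMNS}
    base.update({k: np.asarray(v, dtype=float) for k, v in cols.items()})
    return pd.DataFrame(base)


class TestLymphocyteGate:
    def test_truth_lymphocytes_retained_and_granulocytes_excluded(self, cll_sample):
        _, bundle = cll_sample
        gated = gate_lymphocytes(bundle.stained)
        pop = bundle.truth_stained["population"]
        lym_idx = bundle.stained.index[pop == "lymphocyte"]
        gran_idx = bundle.stained.index[pop == "granulocyte"]
        assert len(gated.index.intersection(lym_idx)) / len(lym_idx) >= 0.95
        assert len(gated.index.intersection(gran_idx)) / max(len(gran_idx), 1) <= 0.05

    def test_pure_debris_gives_empty_gate(self):
        events = _events(500, CD45=np.full(500, 0.5), SSC=np.full(500, 30.0))
        assert gate_lymphocytes(events).empty

    def test_gate_is_idempotent_and_never_mutates(self, cll_sample):
        _, bundle = cll_sample
        before = bundle.stained.copy()
        once = gate_lymphocytes(bundle.stained)
        twice = gate_lymphocytes(once)
        pd.testing.assert_frame_equal(once, twice)
        pd.testing.assert_frame_equal(bundle.stained, before)

    def test_missing_columns_rejected(self):
        with pytest.raises(GatingError, match="SSC"):
            gate_lymphocytes(pd.DataFrame({"CD45": [1.0]}))


class TestBCellSelection:
    def test_b_fraction_recovers_profile_fraction(self, cll_sample):
        profile, bundle = cll_sample
        lym = gate_lymphocytes(bundle.stained)
        iso_lym = gate_lymphocytes(bundle.isotype)
        b = select_b_cells(lym, iso_lym)
        assert 100.0 * len(b) / len(lym) == pytest.approx(
            100.0 * profile.b_cell_fraction, abs=5.0
        )

    def test_isotype_identical_to_sample_retains_half_percent(self, rng):
        vals = rng.lognormal(1.0, 0.5, size=4000)
        table = _events(4000, CD19=vals)
        kept = select_b_cells(table, table)
        assert 100.0 * len(kept) / len(table) == pytest.approx(0.5, abs=0.2)

    def test_all_above_isotype_max_fully_retained(self):
        lym = _events(300, CD19=np.linspace(500, 900, 300))
        iso = _events(300, CD19=np.linspace(1, 10, 300))
        assert len(select_b_cells(lym, iso)) == 300


class TestPositivityThreshold:
    def test_interpolated_order_statistic(self):
        assert positivity_threshold(np.arange(1, 1001)) == pytest.approx(995.5)

    def test_constant_list_returns_constant(self):
        assert positivity_threshold(np.full(250, 7.0)) == 7.0

    def test_too_few_control_values_rejected(self):
        with pytest.raises(GatingError, match="99"):
            positivity_threshold(np.arange(99))


class TestPercentPositive:
    def test_direct_counting_oracle(self, rng):
        iso = rng.uniform(0, 10, size=500)
        cut = positivity_threshold(iso)
        marker = np.concatenate([np.full(60, cut + 5.0), np.full(140, cut - 5.0)])
        assert percent_positive(marker, iso) == pytest.approx(100 * 60 / 200)

    def test_marker_equal_to_isotype_gives_half_percent(self, rng):
        vals = rng.lognormal(1.0, 0.4, size=2000)
        assert percent_positive(vals, vals) == pytest.approx(0.5, abs=0.15)

    def test_all_above_isotype_max_is_100(self, rng):
        iso = rng.uniform(0, 10, size=500)
        assert percent_positive(np.full(50, 100.0), iso) == 100.0

    def test_empty_marker_list_rejected(self, rng):
        with pytest.raises(GatingError):
            percent_positive([], rng.uniform(0, 10, size=500))

    @given(scale=st.floats(0.1, 100.0), shift=st.floats(0.0, 50.0))
    @settings(max_examples=25, deadline=None)
    def test_invariant_under_joint_monotone_rescaling(self, scale, shift):
        rng = np.random.default_rng(77)
        iso = rng.lognormal(1.0, 0.5, size=400)
        marker = rng.lognormal(2.0, 0.5, size=300)
        before = percent_positive(marker, iso)
        after = percent_positive(scale * marker + shift, scale * iso + shift)
        assert before == pytest.approx(after)


class TestMfir:
    def test_identity(self, rng):
        vals = rng.lognormal(1.0, 0.3, size=200)
        assert mfir(vals, vals) == pytest.approx(1.0)

    def test_direct_arithmetic(self):
        assert mfir(np.full(10, 50.0), np.full(10, 2.0)) == pytest.approx(25.0)

    def test_zero_isotype_mean_rejected(self):
        with pytest.raises(GatingError):
            mfir([1.0, 2.0], [0.0, 0.0])

    @given(scale=st.floats(1e-3, 1e3))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, scale):
        rng = np.random.default_rng(5)
        x = rng.lognormal(2.0, 0.4, size=100)
        y = rng.lognormal(1.0, 0.4, size=100)
        assert mfir(scale * x, scale * y) == pytest.approx(mfir(x, y))


class TestExpressionPattern:
    @pytest.mark.parametrize(
        "median,expected",
        [(5.0, "weak"), (50.0, "moderate"), (500.0, "strong"),
         (9.99, "weak"), (10.0, "moderate"), (100.0, "strong")],
    )
    def test_decade_membership(self, median, expected):
        assert expression_pattern(np.full(11, median)) == expected

    def test_no_positive_events_defaults_to_weak(self):
        assert expression_pattern(np.array([])) == "weak"


class TestAnalyzeSample:
    def test_cll_sample_cd200_positive_and_high_mfir(self, cll_sample):
        _, bundle = cll_sample
        res = analyze_sample(bundle.stained, bundle.isotype, sample_id="cll")
        assert res.markers["CD200"].percent_positive >= 30.0
        assert res.markers["CD200"].mfir >= 18.0
        assert res.n_b_cells <= res.n_lymphocytes <= res.n_events

    def test_mcl_sample_cd200_negative(self, mcl_template):
        from matuscore import simulate

        rng = np.random.default_rng(21)
        profile = simulate.sample_patient_profile(mcl_template, rng, "mcl")
        bundle = simulate.generate_events(profile, 10_000, rng)
        res = analyze_sample(bundle.stained, bundle.isotype, sample_id="mcl")
        assert res.markers["CD200"].percent_positive < 30.0

    def test_empty_gate_error_names_sample(self):
        debris = _events(400, CD45=np.full(400, 0.5), SSC=np.full(400, 30.0))
        with pytest.raises(GatingError, match="S042"):
            analyze_sample(debris, debris, sample_id="S042")

    def test_agrees_with_bruteforce_recomputation(self, cll_sample):
        """The vectorised pipeline equals naive per-event loops on a slice."""
        _, bundle = cll_sample
        events = bundle.stained.head(1000).reset_index(drop=True)
        isotype = bundle.isotype.head(1000).reset_index(drop=True)
        params = GateParams()
        res = analyze_sample(events, isotype, params)

        def gate_rows(table):
            keep = []
            for _, row in table.iterrows():
                if row["CD45"] >= params.cd45_min and row["SSC"] <= params.ssc_max:
                    keep.append(row)
            return pd.DataFrame(keep)

        lym = gate_rows(events)
        iso_lym = gate_rows(isotype)
        cut19 = positivity_threshold(iso_lym["CD19"])
        b_rows = lym[lym["CD19"] > cut19]
        assert len(b_rows) == res.n_b_cells
        for marker in ("CD5", "CD200", "sIgM"):
            cut = positivity_threshold(iso_lym[marker])
            n_above = sum(1 for v in b_rows[marker] if v > cut)
            pct = 100.0 * n_above / len(b_rows)
            ratio = b_rows[marker].mean() / iso_lym[marker].mean()
            assert res.markers[marker].percent_positive == pytest.approx(pct)
            assert res.markers[marker].mfir == pytest.approx(ratio)
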