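"""Synthetic cohort generator: templates, profiles, events, cohorts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from matuscore import panel, simulate
from matuscore.simulate import (
    CohortConfig,
    ConfigurationError,
    PointMass,
    ScaledBeta,
    default_case_designs,
    generate_cohort,
    generate_events,
    iter_cohort,
    make_case_template,
    sample_patient_profile,
)


class TestTemplates:
    def test_default_designs_cover_all_diagnoses_with_valid_templates(self):
        designs = default_case_designs()
        assert set(designs) == set(panel.DIAGNOSES)
        for diag, cases in designs.items():
            for tpl in cases:
                assert abs(sum(tpl.mixture_weights.values()) - 1.0) < 1e-9
                for marker in panel.PANEL_MARKERS:
                    lo, hi = tpl.positivity[marker].support()
                    assert 0.0 <= lo <= hi <= 100.0

    def test_cll_templates_keep_cd200_and_cd5_high(self):
        for label in ("CLL-typical", "CLL-atypical"):
            for tpl in default_case_designs()[label]:
                assert tpl.positivity["CD200"].support()[0] >= 50.6
                assert tpl.positivity["CD5"].support()[0] >= 30.0

    def test_mcl_templates_keep_cd200_below_boundary(self):
        for tpl in default_case_designs()["MCL"]:
            assert tpl.positivity["CD200"].support()[1] < 30.0

    def test_empty_support_rejected(self):
        with pytest.raises(ConfigurationError):
            ScaledBeta(50.0, 40.0, 45.0)

    def test_mcl_template_with_high_cd200_rejected(self):
        tpl = make_case_template("MCL", {"CD5"}, "strong", False)
        with pytest.raises(ConfigurationError):
            simulate.DiagnosisTemplate(
                diagnosis_label="MCL",
                positivity={**dict(tpl.positivity), "CD200": ScaledBeta(10, 60, 40)},
                intensity=tpl.intensity,
                cd200_mfir=tpl.cd200_mfir,
                sigm_pattern="strong",
            )


class TestProfileSampling:
    def test_profile_respects_template_supports(self, rng):
        for label, idx in (("CLL-typical", 0), ("CLL-atypical", 0), ("MCL", 0)):
            tpl = default_case_designs()[label][idx]
            for _ in range(25):
                profile = sample_patient_profile(tpl, rng)
                for marker in panel.PANEL_MARKERS:
                    lo, hi = tpl.positivity[marker].support()
                    assert lo <= profile.percent_positive[marker] <= hi

    def test_cll_profile_cd200_and_cd5_above_cutoffs(self, cll_template, rng):
        profile = sample_patient_profile(cll_template, rng)
        assert 50.6 <= profile.percent_positive["CD200"] <= 100.0
        assert profile.percent_positive["CD5"] >= 30.0

    def test_mcl_profile_cd200_below_30(self, mcl_template, rng):
        for _ in range(25):
            assert sample_patient_profile(mcl_template, rng).percent_positive["CD200"] < 30.0

    def test_point_mass_template_yields_constant_profile(self, cll_template, rng):
        tpl = simulate.DiagnosisTemplate(
            diagnosis_label="CLL-typical",
            positivity={
                m: PointMass(97.9 if m == "CD200" else 60.0)
                for m in panel.PANEL_MARKERS
            },
            intensity=cll_template.intensity,
            cd200_mfir=PointMass(59.0),
            sigm_pattern="weak",
        )
        profile = sample_patient_profile(tpl, rng)
        assert profile.percent_positive["CD200"] == 97.9
        assert profile.cd200_mfir_target == 59.0

    def test_same_stream_state_gives_identical_profiles(self, cll_template):
        p1 = sample_patient_profile(cll_template, np.random.default_rng(42))
        p2 = sample_patient_profile(cll_template, np.random.default_rng(42))
        assert p1.percent_positive == p2.percent_positive
        assert p1.positive_mfi == p2.positive_mfi


class TestEventGeneration:
    def test_measured_percent_positive_tracks_target(self, cll_sample):
        """On ground-truth B cells, CD200 percent-positive lands within the
        binomial sampling band (about +/-2 points) of the profile target."""
        profile, bundle = cll_sample
        b_mask = bundle.truth_stained["is_b_cell"].to_numpy()
        vals = bundle.stained.loc[b_mask, "CD200"].to_numpy()
        iso = bundle.isotype.loc[
            bundle.truth_isotype["population"].to_numpy() == "lymphocyte", "CD200"
        ].to_numpy()
        cut = np.percentile(iso, 99.5, method="hazen")
        measured = 100.0 * (vals > cut).mean()
        assert measured == pytest.approx(profile.percent_positive["CD200"], abs=2.0)

    def test_null_marker_indistinguishable_from_isotype(self):
        """A 0%-positive marker's B-cell distribution matches the control."""
        tpl = default_case_designs()["MZL"][0]  # CD5 designed negative
        zero = simulate.DiagnosisTemplate(
            diagnosis_label="MZL",
            positivity={**dict(tpl.positivity), "CD5": PointMass(0.0)},
            intensity=tpl.intensity,
            cd200_mfir=tpl.cd200_mfir,
            sigm_pattern=tpl.sigm_pattern,
        )
        pvals = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            profile = sample_patient_profile(zero, rng, sample_id=f"z{seed}")
            bundle = generate_events(profile, 5000, rng)
            b = bundle.truth_stained["is_b_cell"].to_numpy()
            sample_vals = bundle.stained.loc[b, "CD5"]
            iso_b = bundle.truth_isotype["is_b_cell"].to_numpy()
            iso_vals = bundle.isotype.loc[iso_b, "CD5"]
            pvals.append(stats.mannwhitneyu(sample_vals, iso_vals).pvalue)
        assert all(p > 0.01 for p in pvals)

    def test_same_stream_state_gives_identical_tables(self, cll_template):
        def build():
            rng = np.random.default_rng(3)
            profile = sample_patient_profile(cll_template, rng)
            return generate_events(profile, 2000, rng)

        b1, b2 = build(), build()
        pd.testing.assert_frame_equal(b1.stained, b2.stained)
        pd.testing.assert_frame_equal(b1.isotype, b2.isotype)

    def test_low_yield_warns(self, cll_template, rng):
        profile = sample_patient_profile(cll_template, rng)
        with pytest.warns(UserWarning, match="B-cell yield"):
            generate_events(profile, 120, rng)

    def test_truth_labels_live_outside_event_columns(self, cll_sample):
        _, bundle = cll_sample
        assert list(bundle.stained.columns) == list(panel.EVENT_COLUMNS)
        assert "population" not in bundle.stained.columns


class TestCohort:
    def test_default_composition_counts(self):
        cfg = CohortConfig(events_per_sample=200)
        plan = [s for s in simulate._case_plan(cfg)]
        counts = pd.Series([d for d, _ in plan]).value_counts()
        assert counts["CLL-typical"] == 189
        assert counts["CLL-atypical"] == 10
        assert counts["MCL"] == 20
        assert counts["MZL"] == 17
        assert counts["HCL"] == 8
        assert counts["FL"] == 3
        assert counts["OTHER"] == 5
        assert len(plan) == 252

    def test_generate_cohort_writes_files_and_manifest(self, tmp_path):
        cfg = CohortConfig(
            composition={"CLL-typical": 2, "MCL": 1},
            events_per_sample=1500,
            outdir=tmp_path,
        )
        manifest = generate_cohort(cfg, master_seed=9)
        assert len(manifest) == 3
        assert manifest["sample_id"].is_unique
        for row in manifest.itertuples():
            assert (tmp_path / f"{row.sample_id}.events.csv").exists()
            assert (tmp_path / f"{row.sample_id}.isotype.csv").exists()
            assert (tmp_path / f"{row.sample_id}.truth.csv").exists()

    def test_cohort_regeneration_is_byte_identical(self, tmp_path):
        cfg1 = CohortConfig(
            composition={"CLL-typical": 1, "HCL": 1}, events_per_sample=800,
            outdir=tmp_path / "a",
        )
        cfg2 = CohortConfig(
            composition={"CLL-typical": 1, "HCL": 1}, events_per_sample=800,
            outdir=tmp_path / "b",
        )
        m1 = generate_cohort(cfg1, master_seed=4)
        m2 = generate_cohort(cfg2, master_seed=4)
        for row1, row2 in zip(m1.itertuples(), m2.itertuples()):
            assert (
                open(row1.events_path, "rb").read() == open(row2.events_path, "rb").read()
            )

    def test_single_sample_regenerable_in_isolation(self):
        cfg = CohortConfig(composition={"CLL-typical": 3}, events_per_sample=1000)
        full = {s.sample_id: s for s in iter_cohort(cfg, master_seed=13)}
        # rebuild only sample index 2 from its derived stream
        tpl = default_case_designs()["CLL-typical"][2]
        rng = simulate.sample_rng(13, 2)
        profile = sample_patient_profile(tpl, rng, sample_id="S002")
        bundle = generate_events(profile, 1000, rng)
        pd.testing.assert_frame_equal(bundle.stained, full["S002"].events.stained)

    def test_custom_tiny_composition(self):
        cfg = CohortConfig(composition={"CLL-typical": 2}, events_per_sample=500)
        samples = list(iter_cohort(cfg, master_seed=0))
        assert len(samples) == 2
        assert all(s.diagnosis_label == "CLL-typical" for s in samples)

    def test_zero_samples_empty_manifest(self, tmp_path):
        cfg = CohortConfig(composition={}, events_per_sample=500, outdir=tmp_path)
        manifest = generate_cohort(cfg, master_seed=0)
        assert manifest.empty
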