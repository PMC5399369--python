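"""Synthetic cohort generators: determinism, calibration, ground truth."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pdig import connectome, qc, synthetic
from pdig.atlas import CBGT_REGIONS
from pdig.synthetic import (
    DEFAULT_DC_TARGETS,
    DEFAULT_TRUE_MODEL,
    SnpSpec,
    TrueModelSpec,
)


class TestGenerateSubjects:
    def test_group_counts_and_schema(self):
        df = synthetic.generate_subjects(40, 40, seed=1)
        assert len(df) == 80
        assert (df["group"] == "HC").sum() == 40
        assert (df["group"] == "PD").sum() == 40
        assert df.index.is_unique
        assert df["MDS_UPDRS"].isna().all()
        assert df["GDS"].between(0, 15).all()
        assert df["MoCA"].between(20, 30).all()
        assert df["site"].between(1, 9).all()

    def test_seed_determinism(self):
        a = synthetic.generate_subjects(2, 2, seed=7)
        b = synthetic.generate_subjects(2, 2, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_rejects_tiny_groups(self):
        with pytest.raises(ValueError, match="at least 2"):
            synthetic.generate_subjects(1, 5, seed=0)

    def test_groups_age_matched_across_seeds(self):
        # two-sample t on age should be null in the vast majority of draws
        hits = 0
        for seed in range(100):
            df = synthetic.generate_subjects(40, 40, seed=seed)
            hc = df.loc[df["group"] == "HC", "age"]
            pdg = df.loc[df["group"] == "PD", "age"]
            if stats.ttest_ind(hc, pdg).pvalue > 0.05:
                hits += 1
        assert hits >= 90


class TestGenerateGenotypes:
    def test_monomorphic_target(self):
        subjects = synthetic.generate_subjects(10, 10, seed=0)
        panel = (SnpSpec("m", "g", 1, "T", 0.0),)
        g = synthetic.generate_genotypes(subjects, panel, seed=0)
        assert (g.calls["m"] == 0).all()

    def test_realized_maf_near_target(self):
        subjects = synthetic.generate_subjects(5000, 5000, seed=0)
        panel = (SnpSpec("s", "g", 1, "T", 0.3),)
        g = synthetic.generate_genotypes(subjects, panel, seed=2)
        assert qc.compute_maf(g)["s"] == pytest.approx(0.3, abs=0.01)

    def test_missing_rate_near_target(self):
        subjects = synthetic.generate_subjects(5000, 5000, seed=0)
        panel = (SnpSpec("s", "g", 1, "T", 0.3, missing_rate=0.10),)
        g = synthetic.generate_genotypes(subjects, panel, seed=3)
        rate, _ = qc.compute_missing_rates(g)
        assert rate["s"] == pytest.approx(0.10, abs=0.01)

    def test_hwe_distortion_detected(self):
        subjects = synthetic.generate_subjects(500, 500, seed=0)
        panel = (SnpSpec("v", "g", 1, "T", 0.3, hwe_violation_f=0.9),)
        hits = 0
        for seed in range(20):
            g = synthetic.generate_genotypes(subjects, panel, seed=seed)
            if qc.hwe_exact_pvalue(*g.genotype_counts("v")[:3]) < 1e-6:
                hits += 1
        assert hits == 20

    def test_maf_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="target_maf"):
            SnpSpec("bad", "g", 1, "T", 0.7)

    def test_clean_panel_survives_qc(self):
        # no planted violations -> QC should remove nothing at n = 1,000
        subjects = synthetic.generate_subjects(500, 500, seed=0)
        removed = 0
        for seed in range(20):
            g = synthetic.generate_genotypes(subjects, seed=seed)
            _, report = qc.apply_snp_qc(g)
            removed += len(report.removed)
        assert removed == 0


class TestGenerateStreamlines:
    def test_dc_roundtrip_through_connectome(self, cohort):
        # fiber records must reproduce the drawn DC exactly (to fp noise)
        for sid in list(cohort.subjects.index[:5]):
            c = connectome.build_connectivity(cohort.streamlines, subject_id=sid)
            dc = connectome.degree_centrality(c)
            assert np.allclose(
                dc.to_numpy(), cohort.dc.loc[sid, list(CBGT_REGIONS)].to_numpy(),
                rtol=1e-8,
            )

    def test_pallidum_direction_default_config(self, cohort):
        hc = cohort.subjects["group"] == "HC"
        assert (
            cohort.dc.loc[~hc.to_numpy(), "pallidum"].mean()
            < cohort.dc.loc[hc.to_numpy(), "pallidum"].mean()
        )

    def test_all_four_contrast_directions_across_seeds(self):
        directional = {
            "associative_cortex": 1, "motor_cortex": 1, "thalamus": 1, "pallidum": -1
        }
        ok = 0
        for seed in range(40):
            subjects = synthetic.generate_subjects(40, 40, seed=seed)
            dc = synthetic.sample_dc(subjects, seed=seed)
            hc = (subjects["group"] == "HC").to_numpy()
            diffs = dc[~hc].mean() - dc[hc].mean()
            if all(np.sign(diffs[n]) == s for n, s in directional.items()):
                ok += 1
        assert ok >= 0.95 * 40 - 1  # joint direction fidelity

    def test_single_fiber_smoke_case(self):
        subjects = synthetic.generate_subjects(2, 2, seed=0).iloc[:1]
        sl = synthetic.generate_streamlines(subjects, seed=0, fibers_per_pair=(1, 1))
        c = connectome.build_connectivity(sl, subject_id=subjects.index[0])
        m = c.to_numpy()
        off_diag = m[~np.eye(8, dtype=bool)]
        assert np.isfinite(off_diag).all() and (off_diag > 0).all()

    def test_negative_target_mean_rejected(self):
        subjects = synthetic.generate_subjects(2, 2, seed=0)
        targets = {k: dict(v) for k, v in DEFAULT_DC_TARGETS.items()}
        targets["caudate"] = {"HC": (-0.01, 0.001), "PD": (0.01, 0.001)}
        with pytest.raises(ValueError, match="negative"):
            synthetic.sample_dc(subjects, targets, seed=0)

    def test_determinism(self):
        subjects = synthetic.generate_subjects(3, 3, seed=4)
        a = synthetic.generate_streamlines(subjects, seed=4)
        b = synthetic.generate_streamlines(subjects, seed=4)
        pd.testing.assert_frame_equal(a, b)


class TestGeneratePhenotype:
    def test_noiseless_limit_single_term(self, small_cohort):
        truth = TrueModelSpec(intercept=2.0, coefficients={"GDS": 1.0}, noise_sd=1e-12)
        out = synthetic.generate_phenotype(small_cohort, truth, seed=0)
        expected = 2.0 + out.subjects["GDS"].astype(float)
        assert np.allclose(out.subjects["MDS_UPDRS"], expected, atol=1e-9)

    def test_determinism(self, small_cohort):
        a = synthetic.generate_phenotype(small_cohort, DEFAULT_TRUE_MODEL, seed=5)
        b = synthetic.generate_phenotype(small_cohort, DEFAULT_TRUE_MODEL, seed=5)
        pd.testing.assert_series_equal(a.subjects["MDS_UPDRS"], b.subjects["MDS_UPDRS"])

    def test_unresolvable_term_named(self, small_cohort):
        truth = TrueModelSpec(intercept=0.0, coefficients={"rs_not_there": 1.0}, noise_sd=1.0)
        with pytest.raises(KeyError, match="rs_not_there"):
            synthetic.generate_phenotype(small_cohort, truth, seed=0)

    def test_clipping_reported(self, small_cohort):
        truth = TrueModelSpec(intercept=-50.0, coefficients={"GDS": 0.1}, noise_sd=1.0)
        out = synthetic.generate_phenotype(small_cohort, truth, seed=0)
        assert out.n_clipped == len(out.subjects)
        assert (out.subjects["MDS_UPDRS"] == 0).all()

    def test_interaction_coefficient_recovered_within_3se(self):
        # refit the true model form; planted SNPxSNP interaction must be recovered
        from pdig import modeling

        key = "rs9346876 x rs363611"
        bundle = synthetic.simulate_cohort(n_hc=40, n_pd=40, seed=21, with_streamlines=False)
        data = synthetic.feature_frame(bundle)
        y = data.pop("MDS_UPDRS")
        terms = [
            modeling.Term(tuple(k.split(" x "))) for k in DEFAULT_TRUE_MODEL.coefficients
        ]
        X, mapping = modeling.build_design(data, terms)
        model = modeling.fit_ols(y, X, mapping, terms)
        est, se = model.coefficients[key], model.coef_se[key]
        assert abs(est - DEFAULT_TRUE_MODEL.coefficients[key]) < 3 * se


class TestBundle:
    def test_components_share_subject_index(self, cohort):
        idx = list(cohort.subjects.index)
        assert list(cohort.genotypes.calls.index) == idx
        assert list(cohort.dc.index) == idx
        assert set(cohort.streamlines["subject_id"]) == set(idx)

    def test_full_simulation_deterministic(self):
        a = synthetic.simulate_cohort(n_hc=5, n_pd=5, seed=9)
        b = synthetic.simulate_cohort(n_hc=5, n_pd=5, seed=9)
        pd.testing.assert_frame_equal(a.subjects, b.subjects)
        pd.testing.assert_frame_equal(a.streamlines, b.streamlines)
        assert a.genotypes.equals(b.genotypes)
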