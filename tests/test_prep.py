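"""Morphometry preparation: hemisphere averaging, TIV residualization,
cortical signatures, fixed tertile schemes, dichotomizations and cognition
standardization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import gmpatterns as g
from gmpatterns.prep import TERTILE_SCHEMES, _tiv_residuals
from gmpatterns.rois import ALL_ROIS, CORTICAL_ROIS, SUBCORTICAL_ROIS


def paired_table(n=30, seed=0):
    rng = np.random.default_rng(seed)
    data = {"subject_id": [f"S{i}" for i in range(n)],
            "tiv": rng.normal(1.45e6, 1e5, n)}
    for r in CORTICAL_ROIS:
        base = rng.normal(2.5, 0.2, n)
        data[f"lh_{r}"] = base + rng.normal(0, 0.05, n)
        data[f"rh_{r}"] = base + rng.normal(0, 0.05, n)
    for r in SUBCORTICAL_ROIS:
        base = rng.normal(4000, 300, n)
        data[f"Left-{r}"] = base
        data[f"Right-{r}"] = base + rng.normal(0, 50, n)
    return pd.DataFrame(data)


class TestAverageHemispheres:
    def test_arithmetic_mean_of_sides(self):
        t = pd.DataFrame({"lh_insula": [2.4], "rh_insula": [2.6]})
        assert g.average_hemispheres(t)["insula"].iloc[0] == pytest.approx(2.5)

    def test_idempotent_on_averaged_input(self):
        t = g.average_hemispheres(paired_table())
        pd.testing.assert_frame_equal(g.average_hemispheres(t), t)

    def test_82_hemisphere_columns_collapse_to_41_rois(self):
        out = g.average_hemispheres(paired_table())
        assert sum(c in ALL_ROIS for c in out.columns) == 41

    def test_orphan_column_reported(self):
        t = pd.DataFrame({"lh_insula": [2.4]})
        with pytest.raises(ValueError, match="lh_insula"):
            g.average_hemispheres(t)


class TestTivAdjustment:
    def test_perfect_linear_volume_gives_zero_residuals(self, rng):
        tiv = rng.normal(1.45e6, 1e5, 50)
        y = 120.0 + 0.004 * tiv
        assert np.allclose(_tiv_residuals(y, tiv), 0.0, atol=1e-6)

    def test_orthogonality_and_zero_mean(self, rng):
        tiv = rng.normal(1.45e6, 1e5, 200)
        y = 0.003 * tiv + rng.normal(0, 300, 200)
        r = _tiv_residuals(y, tiv)
        assert abs(r.sum()) < 1e-6 * np.abs(y).sum()
        assert abs(np.corrcoef(r, tiv)[0, 1]) < 1e-8

    def test_matches_normal_equations_oracle(self, rng):
        tiv = rng.normal(1.45e6, 1e5, 150)
        y = 500 + 0.002 * tiv + rng.normal(0, 250, 150)
        X = np.column_stack([np.ones(150), tiv])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.allclose(_tiv_residuals(y, tiv), y - X @ beta, atol=1e-10)

    def test_invariant_to_tiv_unit_rescaling(self, rng):
        tiv = rng.normal(1.45e6, 1e5, 120)
        y = 0.003 * tiv + rng.normal(0, 300, 120)
        r_mm3 = _tiv_residuals(y, tiv)
        r_litre = _tiv_residuals(y, tiv / 1e6)
        assert np.allclose(r_mm3, r_litre, atol=1e-8)

    def test_constant_tiv_degenerate(self):
        with pytest.raises(ValueError, match="constant"):
            _tiv_residuals(np.arange(10.0), np.full(10, 1.4e6))

    def test_missing_tiv_propagates_to_residual(self):
        t = paired_table(n=20)
        t.loc[3, "tiv"] = np.nan
        out = g.adjust_volumes_for_tiv(g.average_hemispheres(t))
        assert np.isnan(out.loc[3, "hippocampus"])
        assert out["hippocampus"].drop(3).notna().all()

    def test_pipeline_order_invariance(self):
        """Average-then-adjust equals adjust-per-hemisphere-then-average
        when both hemispheres share the subject's TIV."""
        t = paired_table(n=40, seed=3)
        a = g.adjust_volumes_for_tiv(g.average_hemispheres(t))
        b = t.copy()
        for r in SUBCORTICAL_ROIS:
            for side in (f"Left-{r}", f"Right-{r}"):
                b[side] = _tiv_residuals(b[side].to_numpy(dtype=float),
                                         b["tiv"].to_numpy(dtype=float))
        b = g.average_hemispheres(b)
        for r in SUBCORTICAL_ROIS:
            assert np.allclose(a[r], b[r], atol=1e-8)


class TestSignatures:
    def test_constant_thickness_field(self):
        t = pd.DataFrame({r: [2.2] for r in CORTICAL_ROIS})
        out = g.compute_signatures(t)
        assert out["ad_signature"].iloc[0] == pytest.approx(2.2)
        assert out["mean_thickness"].iloc[0] == pytest.approx(2.2)

    def test_area_weighted_mean(self):
        t = pd.DataFrame({"entorhinal": [2.0], "inferiortemporal": [3.0],
                          "entorhinal_area": [100.0],
                          "inferiortemporal_area": [300.0]})
        out = g.compute_signatures(t, ad_rois=("entorhinal", "inferiortemporal"))
        assert out["ad_signature"].iloc[0] == pytest.approx(2.75)

    def test_equal_areas_reduce_to_plain_mean(self, rng):
        rois = ("entorhinal", "inferiortemporal", "middletemporal", "fusiform")
        t = pd.DataFrame({r: rng.normal(2.5, 0.2, 10) for r in rois})
        for r in rois:
            t[f"{r}_area"] = 500.0
        out = g.compute_signatures(t)
        assert np.allclose(out["ad_signature"], t[list(rois)].mean(axis=1))


class TestTertiles:
    @pytest.mark.parametrize("scheme,value,label", [
        ("FA", 0.25, "T1"), ("FA", 0.3, "T2"), ("FA", 0.35, "T2"),
        ("FA", 0.4, "T2"), ("FA", 0.45, "T3"),
        ("WMHV", 1.0, "T1"), ("WMHV", 2.7, "T2"), ("WMHV", 5.5, "T2"),
        ("WMHV", 6.0, "T3"),
        ("LDL", 3.0, "T1"), ("LDL", 3.05, "T2"), ("LDL", 3.5, "T2"),
        ("LDL", 3.95, "T2"), ("LDL", 4.0, "T3"),
    ])
    def test_printed_cutpoints(self, scheme, value, label):
        assert g.categorize_tertiles(value, scheme) == label

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError, match="unknown tertile scheme"):
            g.categorize_tertiles(1.0, "HDL")

    def test_missing_value_gives_missing_label(self):
        assert pd.isna(g.categorize_tertiles(np.nan, "FA"))

    @given(st.floats(min_value=-1e6, max_value=1e6,
                     allow_nan=False, allow_infinity=False),
           st.sampled_from(sorted(TERTILE_SCHEMES)))
    def test_every_finite_value_gets_exactly_one_label(self, value, scheme):
        assert g.categorize_tertiles(value, scheme) in {"T1", "T2", "T3"}


class TestRiskIndicators:
    def test_printed_dichotomizations(self):
        cov = pd.DataFrame({
            "bmi": [25.0, 24.9], "alcohol_g_week": [99.0, 100.0],
            "sbp": [139.0, 140.0], "dbp": [85.0, 85.0],
            "antihypertensive": [1.0, 0.0],
            "homocysteine": [13.5, 13.6], "crp": [8.0, 7.9],
            "abeta42": [530.0, 531.0], "ttau": [350.0, 349.0],
            "hdl": [1.1, 1.1], "sex_female": [0.0, 1.0],
        })
        out = g.derive_risk_indicators(cov)
        assert out["overweight"].tolist() == [1.0, 0.0]
        assert out["alcohol_atrisk"].tolist() == [0.0, 1.0]
        assert out["hypertension"].tolist() == [1.0, 1.0]  # treated / BP
        assert out["homocysteine_high"].tolist() == [0.0, 1.0]  # strict >
        assert out["crp_high"].tolist() == [1.0, 0.0]
        assert out["abeta_pos"].tolist() == [1.0, 0.0]
        assert out["ttau_pos"].tolist() == [1.0, 0.0]
        assert out["hdl_low"].tolist() == [0.0, 1.0]  # sex-specific cutoff

    def test_nonpositive_bmi_rejected(self):
        with pytest.raises(ValueError, match="BMI"):
            g.derive_risk_indicators(pd.DataFrame({"bmi": [-1.0]}))

    def test_missing_values_propagate(self):
        out = g.derive_risk_indicators(pd.DataFrame({"crp": [np.nan, 9.0]}))
        assert np.isnan(out["crp_high"].iloc[0])
        assert out["crp_high"].iloc[1] == 1.0


class TestCognition:
    def test_baseline_mean_maps_to_zero(self):
        rngl = np.random.default_rng(1)
        base = pd.DataFrame({d: rngl.normal(10, 2, 50)
                             for d in g.rois.COGNITIVE_DOMAINS})
        z, fz = g.standardize_cognition(base, pd.DataFrame([base.mean()]))
        assert np.allclose(z.mean(), 0, atol=1e-12)
        assert np.allclose(fz.iloc[0], 0, atol=1e-12)

    def test_unit_domain_scores_give_unit_global_composite(self):
        rngl = np.random.default_rng(2)
        base = pd.DataFrame({d: rngl.normal(10, 2, 50)
                             for d in g.rois.COGNITIVE_DOMAINS})
        one_sd_up = base.mean() + base.std(ddof=1)
        _, fz = g.standardize_cognition(base, pd.DataFrame([one_sd_up]))
        assert np.allclose(fz[list(g.rois.COGNITIVE_DOMAINS)].iloc[0], 1.0,
                           atol=1e-12)
        assert fz["global_cognition"].iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_unchanged_scores_give_identical_z(self):
        rngl = np.random.default_rng(3)
        base = pd.DataFrame({d: rngl.normal(5, 1, 30)
                             for d in g.rois.COGNITIVE_DOMAINS})
        bz, fz = g.standardize_cognition(base, base.copy())
        pd.testing.assert_frame_equal(bz, fz)

    def test_zero_sd_names_offending_test(self):
        base = pd.DataFrame({d: np.ones(10) if d == "visuospatial"
                             else np.random.default_rng(0).normal(size=10)
                             for d in g.rois.COGNITIVE_DOMAINS})
        with pytest.raises(ValueError, match="visuospatial"):
            g.standardize_cognition(base)

    def test_global_composite_is_mean_of_domains(self, rng):
        base = pd.DataFrame({d: rng.normal(0, 1, 25)
                             for d in g.rois.COGNITIVE_DOMAINS})
        z, _ = g.standardize_cognition(base)
        assert np.allclose(z["global_cognition"],
                           z[list(g.rois.COGNITIVE_DOMAINS)].mean(axis=1))
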