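"""HbA1c model fitting, interaction-triggered stratification and thresholds."""

import numpy as np
import pandas as pd
import pytest

from cypmeta.association import (  # noqa: I001
    FAMILY_THRESHOLDS,
    ModelSpec,
    apply_thresholds,
    build_design,
    fit_model,
    fit_stratified,
)
from cypmeta.association import test_interaction as decide_interaction
from cypmeta.recovery import (
    PAROXETINE_POOLED,
    CohortDesign,
    simulate_design_cohort,
)


def _null_cohort(n, rng, pm_frac=0.05, im_frac=0.25):
    """Synthetic cohort generated with zero phenotype effects."""
    levels = rng.choice(["NM", "IM", "PM"], size=n,
                        p=[1 - im_frac - pm_frac, im_frac, pm_frac])
    diabetes = rng.random(n) < 0.1
    df = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "cyp2d6_phenotype": levels,
            "diabetes": diabetes,
            "takes_antidiabetic": diabetes & (rng.random(n) < 0.7),
            "takes_cyp2d6_inhibitor": rng.random(n) < 0.06,
            "bmi": rng.normal(28.8, 5.66, n).clip(13),
            "age": rng.uniform(40, 70, n),
            "sex": np.where(rng.random(n) < 0.69, "F", "M"),
            "ancestry": rng.choice(["european", "african"], n, p=[0.95, 0.05]),
        }
    )
    df["hba1c"] = (
        30 + 6.0 * diabetes + 0.3 * df["bmi"] + rng.normal(0, 5, n)
    ).clip(15, 184)
    return df


SPEC = ModelSpec(cohort="test", genes=("CYP2D6",), include_interactions=False)


class TestFitModel:
    def test_null_effects_recovered_near_zero(self, rng):
        df = _null_cohort(5000, rng)
        res = fit_model(df, SPEC)
        for term in ("CYP2D6 IM", "CYP2D6 PM"):
            lo, hi = res.terms.loc[term, ["ci_low", "ci_high"]]
            assert lo < 0 < hi

    def test_matches_closed_form_ols(self, rng):
        """Independent oracle: normal equations computed directly."""
        df = _null_cohort(800, rng)
        res = fit_model(df, SPEC)
        X, _, _ = build_design(df, SPEC)
        beta = np.linalg.solve(
            X.T.to_numpy() @ X.to_numpy(), X.T.to_numpy() @ df["hba1c"].to_numpy()
        )
        np.testing.assert_allclose(
            res.terms["estimate"].to_numpy(), beta, rtol=1e-8
        )

    def test_doubling_residual_sd_doubles_ci_width(self, rng):
        base = simulate_design_cohort(PAROXETINE_POOLED, np.random.default_rng(3))
        spec = PAROXETINE_POOLED.spec()
        res1 = fit_model(base, spec)
        X, _, _ = build_design(base, spec)
        fitted = X.to_numpy() @ np.linalg.lstsq(
            X.to_numpy(), base["hba1c"].to_numpy(), rcond=None
        )[0]
        resid = base["hba1c"].to_numpy() - fitted
        doubled = base.assign(hba1c=fitted + 2 * resid)
        res2 = fit_model(doubled, spec)
        w1 = res1.terms.loc["CYP2D6 PM", "ci_high"] - res1.terms.loc["CYP2D6 PM", "ci_low"]
        w2 = res2.terms.loc["CYP2D6 PM", "ci_high"] - res2.terms.loc["CYP2D6 PM", "ci_low"]
        assert w2 / w1 == pytest.approx(2.0, rel=1e-6)

    def test_shift_equivariance_touches_only_intercept(self, rng):
        df = _null_cohort(500, rng)
        res1 = fit_model(df, SPEC)
        res2 = fit_model(df.assign(hba1c=df["hba1c"] + 7.0), SPEC)
        others = [t for t in res1.terms.index if t != "Intercept"]
        np.testing.assert_allclose(
            res1.terms.loc[others, "estimate"],
            res2.terms.loc[others, "estimate"],
            atol=1e-8,
        )
        assert res2.estimate("Intercept") - res1.estimate("Intercept") == pytest.approx(7.0)

    def test_reported_level_counts(self, rng):
        df = _null_cohort(1000, rng)
        res = fit_model(df, SPEC)
        assert res.terms.loc["CYP2D6 PM", "n"] == (df["cyp2d6_phenotype"] == "PM").sum()
        assert res.nobs == 1000

    def test_rank_deficiency_names_columns(self, rng):
        df = _null_cohort(200, rng)
        df["takes_antidiabetic"] = df["diabetes"]  # exact copy -> collinear
        # either member of the collinear pair may be named as redundant
        with pytest.raises(ValueError, match="diabetes|takes_antidiabetic"):
            fit_model(df, SPEC)

    def test_empty_level_dropped_with_warning(self, rng):
        df = _null_cohort(300, rng)
        df = df[df["cyp2d6_phenotype"] != "PM"]
        with pytest.warns(UserWarning, match="CYP2D6 PM"):
            res = fit_model(df, SPEC)
        assert "CYP2D6 PM" in res.dropped_levels


class TestInteractionAndStratification:
    def test_small_interaction_p_triggers_stratification(self, rng):
        design = CohortDesign(
            label="x",
            phenotype_counts={"NM": 1352, "IM": 430, "PM": 103},
            diabetic_counts={"NM": 135, "IM": 32, "PM": 15},
            coefficients={
                "diabetes": 5.68, "CYP2D6 IM": -0.23, "CYP2D6 PM": -0.46,
                "diabetes:CYP2D6 IM": 3.62, "diabetes:CYP2D6 PM": 11.44,
            },
            adj_r2=0.524,
            include_interactions=True,
        )
        df = simulate_design_cohort(design, np.random.default_rng(0))
        res = fit_model(df, design.spec())
        assert res.pvalue("diabetes:CYP2D6 PM") < 0.05
        assert decide_interaction(res) == "stratify"

    def test_null_interaction_stays_pooled(self, rng):
        df = _null_cohort(3000, rng)
        res = fit_model(df, ModelSpec(cohort="t", genes=("CYP2D6",)))
        ps = [res.pvalue(t) for t in res.interaction_terms]
        if all(p >= 0.05 for p in ps):  # overwhelmingly likely under the null
            assert decide_interaction(res) == "pooled"

    def test_boundary_p_is_pooled(self):
        res_like = fit_model(
            _null_cohort(500, np.random.default_rng(9)),
            ModelSpec(cohort="t", genes=("CYP2D6",)),
        )
        res_like.terms.loc["diabetes:CYP2D6 PM", "p"] = 0.05
        res_like.terms.loc["diabetes:CYP2D6 IM", "p"] = 0.6
        assert decide_interaction(res_like) == "pooled"

    def test_missing_interactions_contract_error(self, rng):
        res = fit_model(_null_cohort(400, rng), SPEC)
        with pytest.raises(ValueError, match="interaction"):
            decide_interaction(res)

    def test_stratified_fits_drop_diabetes_terms(self, rng):
        df = _null_cohort(2000, rng)
        diab, nondiab = fit_stratified(df, ModelSpec(cohort="t", genes=("CYP2D6",)))
        for res in (diab, nondiab):
            assert "diabetes" not in res.terms.index
            assert not res.interaction_terms
        assert diab.nobs + nondiab.nobs == 2000

    def test_stratum_estimates_center_on_null_truth(self):
        rng = np.random.default_rng(77)
        means = []
        for _ in range(60):
            df = _null_cohort(800, rng)
            diab, _ = fit_stratified(df, ModelSpec(cohort="t", genes=("CYP2D6",)))
            means.append(diab.estimate("CYP2D6 IM"))
        assert abs(np.mean(means)) < 3 * np.std(means) / np.sqrt(len(means)) + 0.05


class TestThresholds:
    def test_family_thresholds_exact(self):
        assert FAMILY_THRESHOLDS["grouped"] == (0.025, 0.05)
        assert FAMILY_THRESHOLDS["single_drug"] == (0.05 / 6, 0.1 / 6)

    @pytest.mark.parametrize(
        "p, family, label",
        [
            (7.77e-5, "single_drug", "significant"),
            (0.017, "single_drug", "suggestive"),
            (0.03, "grouped", "suggestive"),
            (0.01, "grouped", "significant"),
            (0.5, "single_drug", "ns"),
        ],
    )
    def test_verdicts(self, p, family, label):
        verdict = apply_thresholds({"term": p}, family)
        assert verdict.labels["term"] == label
        assert verdict.pvalues["term"] == p  # raw p always reported

    def test_significant_implies_suggestive_ordering(self):
        for family, (sig, sugg) in FAMILY_THRESHOLDS.items():
            assert sig < sugg

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="family"):
            apply_thresholds({"t": 0.01}, "everything")
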