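"""Contrast coding, mixed-model fitting, cell means, CI comparison rule."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neommr import stats
from neommr.stats import (
    AucMixedModel,
    CellEstimate,
    ModelSpec,
    build_design,
    ci_exclusion,
    ci_verdict,
    mmr_model_spec,
    negative_ci_check,
    offset_model_spec,
    onset_model_spec,
)


def _mmr_row(**kw):
    row = {
        "subject": "s1", "domain": "speech", "dimension": "durational",
        "deviant": "to_E", "region": "left", "category": "short_e", "value": 0.0,
    }
    row.update(kw)
    return row


class TestContrastCoding:
    def test_mmr_codes(self):
        X = build_design(pd.DataFrame([_mmr_row()]), mmr_model_spec())
        r = X.iloc[0]
        assert (r["domain"], r["dimension"], r["deviant"]) == (-0.5, -0.5, -0.5)
        assert (r["latA"], r["latB"]) == (-0.25, -0.5)

    def test_interaction_is_product(self):
        X = build_design(
            pd.DataFrame([_mmr_row(domain="speech", deviant="from_E")]),
            mmr_model_spec(),
        )
        assert X.iloc[0]["domain:deviant"] == pytest.approx((-0.5) * (+0.5))

    @pytest.mark.parametrize("cat,expected", [
        ("long_e", 1.0), ("nonfocal_e", -0.2), ("focal_a", -0.2), ("short_e", -0.6),
    ])
    def test_duration_codes(self, cat, expected):
        row = {"subject": "s1", "domain": "speech", "category": cat,
               "channel": "CZ", "value": 0.0}
        X = build_design(pd.DataFrame([row]), offset_model_spec())
        assert X.iloc[0]["duration"] == pytest.approx(expected)

    def test_channel_derived_location_codes(self):
        row = {"subject": "s1", "domain": "nonspeech", "category": "focal_a",
               "channel": "F4", "value": 0.0}
        X = build_design(pd.DataFrame([row]), onset_model_spec())
        r = X.iloc[0]
        assert (r["latA"], r["latB"], r["ant"]) == (-0.25, 0.5, 0.5)
        assert r["spectrum"] == -0.5

    def test_contrasts_sum_to_zero_over_balanced_levels(self):
        rows = [
            _mmr_row(domain=d, dimension=dim, deviant=dev, region=reg)
            for d in ("speech", "nonspeech")
            for dim in ("durational", "spectral")
            for dev in ("to_E", "from_E")
            for reg in ("left", "midline", "right")
        ]
        X = build_design(pd.DataFrame(rows), mmr_model_spec())
        sums = X.drop(columns="Intercept").sum(axis=0)
        assert np.allclose(sums, 0.0, atol=1e-12)

    def test_unknown_level_named_in_error(self):
        with pytest.raises(ValueError, match="martian"):
            build_design(pd.DataFrame([_mmr_row(domain="martian")]), mmr_model_spec())

    def test_interaction_without_main_effect_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(terms=("domain:deviant",))


class TestModelFitting:
    @staticmethod
    def _cohort_table(effect=0.0, noise_sd=1e-6, subject_sd=0.0, n=8, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(n):
            u = rng.normal(0, subject_sd)
            for dev, code in (("to_E", -0.5), ("from_E", 0.5)):
                for reg in ("left", "midline", "right"):
                    rows.append(
                        _mmr_row(
                            subject=f"s{s}", deviant=dev, region=reg,
                            value=100.0 + effect * code + u + rng.normal(0, noise_sd),
                        )
                    )
        return pd.DataFrame(rows)

    SPEC = ModelSpec(
        terms=("deviant", "latA", "latB", "deviant:latA", "deviant:latB"),
        random_slopes=("deviant",),
    )

    def test_noise_free_recovers_grand_mean_and_effect(self):
        df = self._cohort_table(effect=40.0)
        res = AucMixedModel(df, self.SPEC).fit()
        assert res.params["Intercept"] == pytest.approx(100.0, rel=0.01)
        # coded -0.5/+0.5, so the coefficient equals the injected difference
        assert res.params["deviant"] == pytest.approx(40.0, rel=0.01)

    def test_pure_noise_fixed_effects_near_zero(self):
        """Monte-Carlo null calibration: with an i.i.d.-noise response the
        fixed effects are statistically indistinguishable from zero."""
        n_big_t = 0
        n_seeds = 60
        for seed in range(n_seeds):
            df = self._cohort_table(effect=0.0, noise_sd=30.0, n=10, seed=seed)
            res = AucMixedModel(df, self.SPEC).fit()
            t = np.abs(res.params.to_numpy() / res.bse.to_numpy())
            n_big_t += int(np.any(t[1:] > 3))  # intercept is genuinely 100
        assert n_big_t / n_seeds <= 0.05 + 0.07  # binomial slack at 60 seeds

    def test_agrees_with_lme4_oracle(self):
        """Independent cross-check: lme4's REML fixed effects on the same
        design match to high precision."""
        df = self._cohort_table(effect=40.0, noise_sd=25.0, subject_sd=30.0,
                                n=12, seed=5)
        res = AucMixedModel(df, self.SPEC).fit()
        X = build_design(df, self.SPEC)
        dat = pd.concat([df[["subject", "value"]], X.drop(columns="Intercept")], axis=1)
        dat.columns = [c.replace(":", "_") for c in dat.columns]
        import tempfile, os

        with tempfile.TemporaryDirectory() as d:
            csv = os.path.join(d, "dat.csv")
            dat.to_csv(csv, index=False)
            rcode = (
                f'd <- read.csv("{csv}"); suppressMessages(library(lme4)); '
                'm <- lmer(value ~ deviant + latA + latB + deviant_latA + deviant_latB'
                ' + (1 + deviant | subject), data=d, REML=TRUE); '
                'cat(paste(fixef(m), collapse=","))'
            )
            out = subprocess.run(
                ["Rscript", "-e", rcode], capture_output=True, text=True, timeout=300
            )
        fe = np.array([float(v) for v in out.stdout.strip().split(",")])
        assert np.allclose(fe, res.params.to_numpy(), rtol=1e-4, atol=1e-6)

    def test_rank_deficient_design_lists_aliased_columns(self):
        df = self._cohort_table(effect=0.0)
        df = df[df.region == "left"]  # latA and latB become constant
        with pytest.raises(ValueError, match="aliased"):
            AucMixedModel(df, self.SPEC)

    def test_needs_two_subjects(self):
        df = self._cohort_table().query("subject == 's0'")
        with pytest.raises(ValueError):
            AucMixedModel(df, self.SPEC)


class TestCellMeans:
    def test_intercept_only_cell_mean(self):
        df = TestModelFitting._cohort_table(effect=0.0, noise_sd=5.0, n=10, seed=2)
        res = AucMixedModel(df, ModelSpec(terms=("deviant",), random_slopes=())).fit()
        est = res.cell_mean(deviant="to_E")
        # prediction = intercept + (-0.5) * deviant coefficient
        expected = res.params["Intercept"] - 0.5 * res.params["deviant"]
        assert est.mean == pytest.approx(expected, abs=1e-9)
        assert est.se > 0

    def test_zero_code_vector_gives_intercept(self):
        df = TestModelFitting._cohort_table(effect=10.0, noise_sd=5.0, n=10, seed=3)
        res = AucMixedModel(df, TestModelFitting.SPEC).fit()
        est = res.cell_mean(deviant="to_E", region="midline")
        est2 = res.cell_mean(deviant="from_E", region="midline")
        # midline latB = 0; averaging the two deviants removes the deviant code
        center = 0.5 * (est.mean + est2.mean)
        assert center == pytest.approx(
            res.params["Intercept"] + 0.5 * res.params["latA"], abs=1e-9
        )

    def test_noise_free_cells_reproduce_injected_targets(self):
        df = TestModelFitting._cohort_table(effect=40.0)
        res = AucMixedModel(df, TestModelFitting.SPEC).fit()
        assert res.cell_mean(deviant="to_E", region="left").mean == pytest.approx(80.0, rel=0.01)
        assert res.cell_mean(deviant="from_E", region="left").mean == pytest.approx(120.0, rel=0.01)

    def test_unknown_cell_level_rejected(self):
        df = TestModelFitting._cohort_table()
        res = AucMixedModel(df, TestModelFitting.SPEC).fit()
        with pytest.raises(ValueError):
            res.cell_mean(deviant="sideways", region="left")


class TestCiRule:
    def test_published_style_worked_examples(self):
        """Cell means with the magnitudes of the left-region speech cells:
        the durational pair is mutually exclusive at 95%, the spectral pair
        only at 90%, and the negative spectral deviant's whole 95% CI lies
        below zero."""
        dur = (CellEstimate(34.9, 16.4), CellEstimate(-54.0, 36.2))
        spec_ = (CellEstimate(-65.6, 32.4), CellEstimate(82.3, 77.7))
        assert ci_verdict(*dur) == "exclusive_95"
        assert ci_verdict(*spec_) == "exclusive_90"
        assert negative_ci_check(spec_[0]) is True

    def test_identical_estimates_never_exclusive(self):
        e = CellEstimate(5.0, 2.0)
        assert ci_verdict(e, CellEstimate(5.0, 2.0)) == "not_exclusive"

    def test_negative_ci_check_edge_cases(self):
        assert negative_ci_check(CellEstimate(0.0, 1.0)) is False
        assert negative_ci_check(CellEstimate(-10.0, 100.0)) is False
        assert negative_ci_check(CellEstimate(-10.0, 1.0)) is True

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        m1=st.floats(-100, 100), m2=st.floats(-100, 100),
        s1=st.floats(0.1, 50), s2=st.floats(0.1, 50),
        shrink=st.floats(0.1, 1.0),
    )
    def test_symmetry_monotonicity_and_nesting(self, m1, m2, s1, s2, shrink):
        a, b = CellEstimate(m1, s1), CellEstimate(m2, s2)
        # symmetric in the arguments
        assert ci_exclusion(a, b, 0.95) == ci_exclusion(b, a, 0.95)
        # 95%-exclusive implies 90%-exclusive
        if ci_exclusion(a, b, 0.95):
            assert ci_exclusion(a, b, 0.90)
        # shrinking both SEs never destroys exclusivity
        if ci_exclusion(a, b, 0.95):
            a2 = CellEstimate(m1, s1 * shrink)
            b2 = CellEstimate(m2, s2 * shrink)
            assert ci_exclusion(a2, b2, 0.95)
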