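"""Survey ingestion: status imputation, stratification, lognormal fitting."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ironburden.parameters import StratumKey
from ironburden.survey_ingest import (
    SurveyRecord,
    absorption_coefficient,
    assign_stratum,
    bootstrap_fit,
    ci_normal_sampler,
    fit_lognormal,
    impute_status,
    prepare_survey,
)


def _rec(age, sex="female", pregnant="no", menopausal="no", iron=10.0):
    return SurveyRecord(
        person_id="p", age=age, sex=sex, pregnant=pregnant,
        menopausal=menopausal, iron_intake=iron,
        red_meat_intake=0.0, red_meat_iron=0.0)


class TestImputation:
    # Worked decision-table set: (input record, expected pregnant,
    # expected menopausal, expected excluded) applied by hand.
    WORKED = [
        (_rec(52, menopausal="unknown"), "no", "yes", False),
        (_rec(45, menopausal="unknown"), "no", "no", False),
        (_rec(30, pregnant="unknown", menopausal="no"), "yes", "no", True),
        (_rec(30, pregnant="unknown", menopausal="yes"), "no", "yes", False),
        (_rec(16, pregnant="unknown"), "no", "no", False),
        (_rec(30, pregnant="yes"), "yes", "no", True),
        (_rec(33, pregnant="unknown", menopausal="unknown"), "no", "no", False),
        (_rec(60, pregnant="unknown", menopausal="unknown"), "no", "yes", False),
        (_rec(40, pregnant="yes", menopausal="yes"), "yes", "yes", True),
        (_rec(25, sex="male", pregnant="unknown", menopausal="unknown"),
         "no", "not_applicable", False),
    ]

    @pytest.mark.parametrize("record,pregnant,menopausal,excluded", WORKED)
    def test_decision_table(self, record, pregnant, menopausal, excluded):
        out = impute_status(record)
        assert out.pregnant == pregnant
        assert out.menopausal == menopausal
        assert out.excluded is excluded

    @given(
        age=st.integers(min_value=3, max_value=74),
        sex=st.sampled_from(["male", "female"]),
        pregnant=st.sampled_from(["yes", "no", "unknown"]),
        menopausal=st.sampled_from(["yes", "no", "unknown"]),
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_idempotent(self, age, sex, pregnant, menopausal):
        first = impute_status(_rec(age, sex=sex, pregnant=pregnant,
                                   menopausal=menopausal))
        assert impute_status(first) == first

    @given(
        age=st.integers(min_value=18, max_value=74),
        pregnant=st.sampled_from(["yes", "no", "unknown"]),
        menopausal=st.sampled_from(["yes", "no", "unknown"]),
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_resolves_every_female_record(self, age, pregnant, menopausal):
        out = impute_status(_rec(age, pregnant=pregnant, menopausal=menopausal))
        assert out.pregnant in ("yes", "no")
        if out.pregnant == "yes":
            # pregnant records leave the study; menopause may stay unresolved
            assert out.excluded
        else:
            assert out.menopausal in ("yes", "no")


class TestAbsorption:
    @pytest.mark.parametrize("age,sex,expected", [
        (3, "male", 0.10), (8, "male", 0.10), (11, "female", 0.10),
        (12, "male", 0.16), (15, "female", 0.16), (17, "female", 0.16),
        (18, "male", 0.16), (70, "male", 0.16),
        (18, "female", 0.18), (35, "female", 0.18), (70, "female", 0.18),
    ])
    def test_coefficients(self, age, sex, expected):
        assert absorption_coefficient(age, sex) == expected

    def test_below_domain(self):
        with pytest.raises(ValueError):
            absorption_coefficient(2, "male")


class TestStratumAssignment:
    @pytest.mark.parametrize("age,sex,menopausal,key", [
        (14, "male", "not_applicable", StratumKey("male", "12-17", "not_applicable")),
        (13, "female", "no", StratumKey("female", "12-14", "premenopausal")),
        (16, "female", "no", StratumKey("female", "15-17", "premenopausal")),
        (20, "female", "yes", StratumKey("female", "18-24", "premenopausal")),
        (40, "female", "yes", StratumKey("female", "25-44", "postmenopausal")),
        (40, "female", "no", StratumKey("female", "25-44", "premenopausal")),
        (70, "female", "no", StratumKey("female", "65-74", "postmenopausal")),
    ])
    def test_mapping(self, age, sex, menopausal, key):
        assert assign_stratum(age, sex, menopausal) == key

    def test_age_outside_domain(self):
        with pytest.raises(ValueError):
            assign_stratum(80, "male")


class TestFitting:
    def test_two_point_closed_form(self):
        meanlog, sdlog = fit_lognormal(np.array([1.0, np.e ** 2]))
        assert meanlog == pytest.approx(1.0)
        assert sdlog == pytest.approx(1.0)

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_lognormal(np.full(4, np.e))

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            fit_lognormal(np.array([1.0, 0.0, 2.0]))

    def test_parameter_recovery(self):
        rng = np.random.default_rng(42)
        draws = rng.lognormal(0.52, 0.37, 10_000)
        meanlog, sdlog = fit_lognormal(draws)
        assert meanlog == pytest.approx(0.52, abs=0.02)
        assert sdlog == pytest.approx(0.37, abs=0.02)

    def test_matches_fitdistrplus(self, tmp_path):
        """Cross-check the MLE against R's fitdistrplus on one sample."""
        rng = np.random.default_rng(7)
        draws = rng.lognormal(0.4, 0.36, 300)
        data = tmp_path / "draws.csv"
        np.savetxt(data, draws)
        script = tmp_path / "fit.R"
        script.write_text(textwrap.dedent(f"""
            library(fitdistrplus)
            x <- scan("{data}")
            f <- fitdist(x, "lnorm")
            cat(sprintf("%.10f %.10f", f$estimate[["meanlog"]],
                        f$estimate[["sdlog"]]))
        """))
        out = subprocess.run(["Rscript", "--vanilla", str(script)],
                             capture_output=True, text=True, check=True)
        r_meanlog, r_sdlog = map(float, out.stdout.split()[-2:])
        meanlog, sdlog = fit_lognormal(draws)
        assert meanlog == pytest.approx(r_meanlog, abs=1e-5)
        assert sdlog == pytest.approx(r_sdlog, abs=1e-4)


class TestBootstrap:
    def test_deterministic_under_seed(self):
        draws = np.random.default_rng(3).lognormal(0.4, 0.36, 500)
        a = bootstrap_fit(draws, B=250, rng=np.random.default_rng(11))
        b = bootstrap_fit(draws, B=250, rng=np.random.default_rng(11))
        np.testing.assert_array_equal(a.replicates, b.replicates)

    def test_single_replicate_degenerate_ci(self):
        draws = np.random.default_rng(3).lognormal(0.4, 0.36, 200)
        f = bootstrap_fit(draws, B=1, rng=np.random.default_rng(0))
        lo, hi = f.meanlog_ci
        assert lo == pytest.approx(hi)

    def test_floor_enforced(self):
        draws = np.random.default_rng(3).lognormal(0.4, 0.36, 10)
        with pytest.raises(ValueError, match="floor"):
            bootstrap_fit(draws, B=100, rng=np.random.default_rng(0),
                          stratum=StratumKey("male", "3-6", "not_applicable"))

    def test_ci_width_shrinks_with_n(self):
        """Percentile CI width should scale roughly like 1/sqrt(n)."""
        rng = np.random.default_rng(5)
        widths = {}
        for n in (500, 2000):
            draws = rng.lognormal(0.0, 0.4, n)
            f = bootstrap_fit(draws, B=400, rng=np.random.default_rng(9))
            lo, hi = f.meanlog_ci
            widths[n] = hi - lo
        ratio = widths[500] / widths[2000]
        assert 1.3 < ratio < 3.1  # sqrt(4) = 2 within sampling slack

    def test_ci_normal_sampler_statistics(self, rng):
        """CI-derived sampler reproduces point and implied sd per parameter."""
        from ironburden.parameters import IntakeModel
        intake = IntakeModel(meanlog=0.52, sdlog=0.37,
                             meanlog_ci=(0.46, 0.58), sdlog_ci=(0.33, 0.42))
        draws = ci_normal_sampler(intake)(rng, 40_000)
        assert draws[:, 0].mean() == pytest.approx(0.52, abs=0.002)
        assert draws[:, 0].std() == pytest.approx((0.58 - 0.46) / 3.92, rel=0.05)
        assert draws[:, 1].mean() == pytest.approx(0.37, abs=0.002)


class TestPrepareSurvey:
    def test_excludes_pregnant_and_attaches_strata(self):
        df = pd.DataFrame({
            "person_id": ["a", "b", "c", "d"],
            "age": [35, 35, 8, 52],
            "sex": ["female", "female", "male", "female"],
            "pregnant": ["yes", "no", "no", "no"],
            "menopausal": ["no", "no", "not_applicable", "unknown"],
            "iron_mg_day": [10.0, 12.0, 8.0, 11.0],
            "red_meat_g_day": [0.0, 20.0, 0.0, 0.0],
            "red_meat_iron_mg_day": [0.0, 0.5, 0.0, 0.0],
        })
        out = prepare_survey(df)
        assert list(out["person_id"]) == ["b", "c", "d"]
        b = out[out.person_id == "b"].iloc[0]
        assert (b.gender, b.age_class, b.status) == ("female", "25-44", "premenopausal")
        assert b.absorbed_mg_day == pytest.approx(12.0 * 0.18)
        c = out[out.person_id == "c"].iloc[0]
        assert c.absorbed_mg_day == pytest.approx(8.0 * 0.10)
        d = out[out.person_id == "d"].iloc[0]  # 52, unknown -> postmenopausal
        assert d.status == "postmenopausal"

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            prepare_survey(pd.DataFrame({"age": [5]}))
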