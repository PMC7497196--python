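"""Standardization, design matrices and response construction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from matalloc import (ModelSpec, build_design, build_standardization,
                      response_efficiency, response_proportion)
from matalloc.config import ConfigurationError, ReferenceProfile
from matalloc.design import design_columns, profile_row


def frame(n=6, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "maternal_age": rng.integers(5, 25, n),
        "afr": rng.integers(4, 12, n),
        "status_prev": (["experienced_bred", "prebreeder_last_year",
                         "first_time_last_year", "experienced_skipped"] * n)[:n],
        "birthdate": rng.integers(10, 45, n),
        "pup_sex": (["F", "M"] * n)[:n],
        "maternal_mass_birth": rng.normal(450, 50, n),
        "pup_mass_birth": rng.normal(29, 4, n),
        "day_birth": rng.integers(1, 5, n),
        "day_mid": rng.integers(15, 26, n),
        "day_late": rng.integers(30, 41, n),
    })


class TestResponses:
    def test_proportion_worked_examples(self):
        assert response_proportion(450.0, 300.0) == pytest.approx(1 / 3)
        assert response_proportion(500.0, 500.0) == 0.0

    def test_proportion_requires_positive_parturition_mass(self):
        with pytest.raises(ValueError):
            response_proportion(0.0, 10.0)

    def test_efficiency_worked_example(self):
        # pup 30 -> 60 kg while the mother drops 450 -> 390 kg
        assert response_efficiency(30, 60, 450, 390, 2, 20) == pytest.approx(0.5)

    @pytest.mark.parametrize("d1, d2", [(1, 16), (4, 25), (2, 20)])
    def test_efficiency_day_offsets_cancel(self, d1, d2):
        assert response_efficiency(30, 60, 450, 390, d1, d2) == \
            pytest.approx(0.5)

    def test_efficiency_zero_loss_flagged_nan(self):
        assert np.isnan(response_efficiency(30, 60, 450, 450, 1, 20))


class TestStandardization:
    def test_three_value_example(self):
        df = frame(3)
        df["maternal_age"] = [1, 2, 3]
        std = build_standardization(df, names=["age"])
        assert std.center("age") == pytest.approx(2.0)
        assert std.scales["age"] == pytest.approx(2.0)  # 2 x SD, SD = 1
        np.testing.assert_allclose(std.standardize("age", [1, 2, 3]),
                                   [-0.5, 0.0, 0.5])

    @given(st.lists(st.floats(min_value=-1e3, max_value=1e3)
                    .map(lambda v: round(v, 4)), min_size=5,
                    max_size=40).filter(lambda v: len(set(v)) > 1))
    @settings(max_examples=50, deadline=None)
    def test_standardized_column_has_mean_zero_sd_half(self, values):
        df = frame(len(values))
        df["maternal_age"] = values
        std = build_standardization(df, names=["age"])
        z = std.standardize("age", values)
        assert np.mean(z) == pytest.approx(0.0, abs=1e-9)
        assert np.std(z, ddof=1) == pytest.approx(0.5, rel=1e-9)

    def test_constant_covariate_error_names_it(self):
        df = frame()
        df["afr"] = 7
        with pytest.raises(ConfigurationError, match="afr"):
            build_standardization(df, names=["afr"])


class TestBuildDesign:
    def test_age_form_columns(self):
        df = frame()
        std = build_standardization(df)
        for form, expected in [("null", []), ("linear", ["age"]),
                               ("quadratic", ["age", "age2"]),
                               ("log", ["ln_age"])]:
            spec = ModelSpec(response="proportion", age_form=form)
            _, labels = build_design(df, spec, std)
            assert [c for c in labels if "age" in c] == expected

    def test_quadratic_is_square_of_standardized_linear(self):
        df = frame(8, seed=3)
        std = build_standardization(df)
        spec = ModelSpec(response="proportion", age_form="quadratic",
                         include_birthdate_quadratic=True)
        x, labels = build_design(df, spec, std)
        np.testing.assert_allclose(x[:, labels.index("age2")],
                                   x[:, labels.index("age")] ** 2)
        np.testing.assert_allclose(x[:, labels.index("birthdate2")],
                                   x[:, labels.index("birthdate")] ** 2)

    def test_log_age_standardizes_log_values(self):
        df = frame(8, seed=4)
        std = build_standardization(df)
        spec = ModelSpec(response="weaning", age_form="log")
        x, labels = build_design(df, spec, std)
        ln = np.log(df["maternal_age"].to_numpy(dtype=float))
        expected = (ln - ln.mean()) / (2 * ln.std(ddof=1))
        np.testing.assert_allclose(x[:, labels.index("ln_age")], expected)

    def test_status_expands_against_experienced_bred_reference(self):
        df = frame()
        std = build_standardization(df)
        spec = ModelSpec(response="proportion", age_form="null")
        x, labels = build_design(df, spec, std)
        ref_rows = df["status_prev"] == "experienced_bred"
        for col in ("status_first_time", "status_prebreeder", "status_skipped"):
            assert np.all(x[ref_rows.to_numpy(), labels.index(col)] == 0)
        assert set(np.unique(x[:, labels.index("status_prebreeder")])) <= {0.0, 1.0}

    def test_reference_row_at_means_is_intercept_only(self):
        df = frame(20, seed=6)
        std = build_standardization(df)
        spec = ModelSpec(response="proportion", age_form="quadratic",
                         include_birthdate_quadratic=True)
        row = profile_row(ReferenceProfile(), spec, std)
        labels = design_columns(spec)
        assert row[labels.index("intercept")] == 1.0
        np.testing.assert_allclose(np.delete(row, labels.index("intercept")),
                                   0.0, atol=1e-12)

    def test_unknown_covariate_rejected(self):
        df = frame()
        std = build_standardization(df)
        spec = ModelSpec(response="proportion", age_form="null",
                         covariates=("maternal_mass", "measurement_days",
                                     "not_a_covariate"))
        with pytest.raises(ConfigurationError, match="not_a_covariate"):
            build_design(df, spec, std)


class TestModelSpecValidation:
    @pytest.mark.parametrize("kwargs", [
        {"response": "weaning", "covariates": ("maternal_mass",)},
        {"response": "proportion", "covariates": ("maternal_mass",)},
        {"response": "efficiency",
         "covariates": ("maternal_mass", "measurement_days")},
        {"response": "proportion", "age_form": "cubic"},
        {"response": "growth"},
    ])
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            ModelSpec(**kwargs)
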