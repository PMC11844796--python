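"""Cohort I/O, imputation, complete-case filtering, z-scores and w-scores."""

import numpy as np
import pandas as pd
import pytest

from ftdpls import (complete_case_filter, impute_group_mean, read_cohort,
                    write_cohort, wscore_adjust, zscore_columns,
                    select_followup_closest_to)
from ftdpls.cohort import SchemaError, inverse_zscore

from conftest import make_toy_cohort


class TestRoundTrip:
    @pytest.mark.parametrize("ext", ["csv", "tsv"])
    def test_write_read_lossless(self, tmp_path, ext):
        cohort = make_toy_cohort(n_per_group=3, seed=1)
        path = tmp_path / f"cohort.{ext}"
        write_cohort(cohort, path, with_schema=True)
        back = read_cohort(path)
        pd.testing.assert_frame_equal(
            cohort.data.reset_index(drop=True), back.data, check_exact=False, rtol=1e-15)

    def test_tsv_and_csv_dialects_identical(self, tmp_path):
        cohort = make_toy_cohort(n_per_group=3, seed=2)
        p_csv, p_tsv = tmp_path / "c.csv", tmp_path / "c.tsv"
        write_cohort(cohort, p_csv)
        write_cohort(cohort, p_tsv)
        a = read_cohort(p_csv, cohort.schema)
        b = read_cohort(p_tsv, cohort.schema)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_duplicate_subject_visit_named(self):
        cohort = make_toy_cohort(n_per_group=3)
        dup = pd.concat([cohort.data, cohort.data.iloc[[0]]], ignore_index=True)
        with pytest.raises(SchemaError, match=dup.iloc[0]["subject_id"]):
            type(cohort)(dup, cohort.cognition_cols, cohort.brain_cols)

    def test_non_numeric_cell_rejected(self, tmp_path):
        cohort = make_toy_cohort(n_per_group=3)
        path = tmp_path / "c.csv"
        write_cohort(cohort, path)
        text = path.read_text().splitlines()
        hdr = text[0].split(",")
        col = cohort.cognition_cols[0]
        j = hdr.index(col)
        row = text[1].split(",")
        row[j] = "not-a-number"
        path.write_text("\n".join([text[0], ",".join(row)] + text[2:]))
        with pytest.raises(SchemaError, match=col):
            read_cohort(path, cohort.schema)

    def test_missing_mandatory_column(self, tmp_path):
        cohort = make_toy_cohort(n_per_group=3)
        path = tmp_path / "c.csv"
        write_cohort(cohort, path)
        schema = dict(cohort.schema)
        schema["brain"] = schema["brain"] + ["region_999"]
        with pytest.raises(SchemaError, match="region_999"):
            read_cohort(path, schema)


class TestImputation:
    def test_forced_arithmetic_group_mean(self):
        cohort = make_toy_cohort(n_per_group=3)
        idx = cohort.data.index[cohort.data["group"] == "bvFTD"]
        cohort.data.loc[idx[0], "education"] = 14.0
        cohort.data.loc[idx[1], "education"] = 16.0
        cohort.data.loc[idx[2], "education"] = np.nan
        out = impute_group_mean(cohort, ["education"])
        assert out.data.loc[idx[2], "education"] == 15.0

    def test_no_missing_is_identity(self):
        cohort = make_toy_cohort(n_per_group=3)
        out = impute_group_mean(cohort, ["education"])
        pd.testing.assert_frame_equal(out.data, cohort.data)

    def test_each_group_uses_own_mean(self):
        cohort = make_toy_cohort(n_per_group=4, seed=3)
        df = cohort.data
        expected = {}
        for g in df["group"].unique():
            idx = df.index[df["group"] == g]
            df.loc[idx[0], "education"] = np.nan
            expected[idx[0]] = df.loc[idx[1:], "education"].mean()  # loop oracle
        out = impute_group_mean(cohort, ["education"])
        for i, want in expected.items():
            assert out.data.loc[i, "education"] == pytest.approx(want)

    def test_group_mean_invariance(self):
        cohort = make_toy_cohort(n_per_group=5, seed=4)
        df = cohort.data
        before = df.groupby("group")["education"].mean()
        df.loc[df.index[2], "education"] = np.nan
        after_missing = df.groupby("group")["education"].mean()
        out = impute_group_mean(cohort, ["education"])
        after = out.data.groupby("group")["education"].mean()
        pd.testing.assert_series_equal(after, after_missing)

    def test_group_without_observations_errors(self):
        cohort = make_toy_cohort(n_per_group=3)
        df = cohort.data
        df.loc[df["group"] == "svPPA", "education"] = np.nan
        with pytest.raises(ValueError, match="svPPA"):
            impute_group_mean(cohort, ["education"])


class TestCompleteCase:
    def test_identity_when_complete(self):
        cohort = make_toy_cohort(n_per_group=3)
        out, report = complete_case_filter(cohort, cohort.cognition_cols)
        assert report.n_removed == 0
        pd.testing.assert_frame_equal(out.data, cohort.data)

    def test_single_missing_row_removed(self):
        cohort = make_toy_cohort(n_per_group=3)
        col = cohort.cognition_cols[1]
        cohort.data.loc[cohort.data.index[4], col] = np.nan
        out, report = complete_case_filter(cohort, cohort.cognition_cols)
        assert report.n_removed == 1
        assert report.removed_per_column == {col: 1}
        assert len(out.data) == len(cohort.data) - 1

    def test_random_mask_matches_row_scan(self, rng):
        cohort = make_toy_cohort(n_per_group=5, seed=5)
        cols = cohort.cognition_cols[:3]
        df = cohort.data
        mask = rng.random((len(df), 3)) < 0.25
        for (i, j) in zip(*np.nonzero(mask)):
            df.iloc[i, df.columns.get_loc(cols[j])] = np.nan
        expected_keep = [i for i in range(len(df))
                         if not df.iloc[i][cols].isna().any()]  # brute-force scan
        out, report = complete_case_filter(cohort, cols)
        got = set(out.data["subject_id"])
        want = set(df.iloc[expected_keep]["subject_id"])
        assert got == want or got == want - {
            s for s in want if s in set(df[df["visit"] == "followup"]["subject_id"])}

    def test_all_rows_missing_errors(self):
        cohort = make_toy_cohort(n_per_group=3)
        cohort.data[cohort.cognition_cols[0]] = np.nan
        with pytest.raises(ValueError, match="relax"):
            complete_case_filter(cohort, cohort.cognition_cols)


class TestZScore:
    def test_self_mode_mean_zero_sd_one(self, rng):
        block = pd.DataFrame(rng.normal(3, 5, (40, 4)), columns=list("abcd"))
        z, stats = zscore_columns(block)
        np.testing.assert_allclose(z.mean(), 0, atol=1e-12)
        np.testing.assert_allclose(z.std(ddof=1), 1, atol=1e-12)
        assert stats.reference == "self"

    def test_hand_computed_3x2(self):
        block = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [10.0, 10.0, 16.0]})
        z, _ = zscore_columns(block)
        np.testing.assert_allclose(z["a"], [-1.0, 0.0, 1.0])
        sd_b = np.std([10, 10, 16], ddof=1)
        np.testing.assert_allclose(z["b"], (np.array([10, 10, 16]) - 12) / sd_b)

    def test_reference_stats_mode(self, rng):
        base = pd.DataFrame(rng.normal(0, 2, (30, 3)), columns=list("xyz"))
        _, stats = zscore_columns(base)
        z_again, _ = zscore_columns(base, stats)
        z_self, _ = zscore_columns(base)
        pd.testing.assert_frame_equal(z_again, z_self)

    def test_inverse_recovers_input(self, rng):
        block = pd.DataFrame(rng.normal(2, 7, (25, 3)), columns=list("pqr"))
        z, stats = zscore_columns(block)
        back = inverse_zscore(z, stats)
        np.testing.assert_allclose(back.to_numpy(), block.to_numpy(), atol=1e-10)

    def test_zero_sd_column_named(self):
        block = pd.DataFrame({"ok": [1.0, 2.0, 3.0], "flat": [4.0, 4.0, 4.0]})
        with pytest.raises(ValueError, match="flat"):
            zscore_columns(block)


def _control_frame(n, rng, beta_age=0.5):
    age = rng.uniform(55, 80, n)
    sex = rng.choice(["M", "F"], n)
    edu = rng.uniform(10, 20, n)
    resid = rng.normal(0, 2.0, n)
    val = 3.0 + beta_age * age + 1.5 * (sex == "M") - 0.2 * edu + resid
    return pd.DataFrame({"age": age, "sex": sex, "education": edu, "v": val})


class TestWScore:
    def test_two_residual_sd_gives_w_of_two(self, rng):
        """A patient constructed exactly at control prediction + 2 residual
        SDs must score w = 2 (forced by the formula)."""
        n = 40
        age = np.linspace(50, 80, n)
        # residuals orthogonal to the design so OLS recovers beta exactly
        r = np.sin(np.arange(n))
        X = np.column_stack([np.ones(n), age])
        r = r - X @ np.linalg.lstsq(X, r, rcond=None)[0]
        controls = pd.DataFrame({"age": age, "v": 2.0 + 0.3 * age + r})
        resid_sd = np.sqrt((r ** 2).sum() / (n - 2))
        patient = pd.DataFrame({"age": [60.0], "v": [2.0 + 0.3 * 60.0 + 2 * resid_sd]})
        w = wscore_adjust(patient, controls, ["v"], covariates=("age",))
        assert w["v"].iloc[0] == pytest.approx(2.0, abs=1e-10)

    def test_control_like_patients_calibrated(self):
        rng = np.random.default_rng(0)
        controls = _control_frame(500, rng)
        patients = _control_frame(500, rng)
        w = wscore_adjust(patients, controls, ["v"])
        assert abs(w["v"].mean()) < 0.1
        assert 0.9 <= w["v"].std(ddof=1) <= 1.1

    def test_affine_covariate_invariance(self, rng):
        controls = _control_frame(80, rng)
        patients = _control_frame(40, rng)
        w_years = wscore_adjust(patients, controls, ["v"])
        c2, p2 = controls.copy(), patients.copy()
        c2["age"] *= 12.0  # age in months
        p2["age"] *= 12.0
        w_months = wscore_adjust(p2, c2, ["v"])
        np.testing.assert_allclose(w_years["v"], w_months["v"], atol=1e-8)

    def test_constant_control_variable_errors(self, rng):
        controls = _control_frame(30, rng)
        controls["v"] = 7.0
        patients = _control_frame(5, rng)
        with pytest.raises(ValueError, match="residual SD|rank"):
            wscore_adjust(patients, controls, ["v"])

    def test_too_few_controls_errors(self, rng):
        controls = _control_frame(4, rng)
        with pytest.raises(ValueError, match="controls"):
            wscore_adjust(_control_frame(5, rng), controls, ["v"])


class TestFollowupSelection:
    def test_keeps_visit_closest_to_one_year(self):
        cohort = make_toy_cohort(n_per_group=2, seed=6)
        df = cohort.data
        sid = df.iloc[0]["subject_id"]
        extra = pd.concat([df.iloc[[0]].assign(visit="followup", years_since_baseline=y)
                           for y in (0.5, 1.1, 2.0)], ignore_index=True)
        cohort2 = type(cohort)(pd.concat([df, extra], ignore_index=True),
                               cohort.cognition_cols, cohort.brain_cols)
        out = select_followup_closest_to(cohort2, 1.0)
        fu = out.data[(out.data["subject_id"] == sid) & (out.data["visit"] == "followup")]
        assert len(fu) == 1 and fu.iloc[0]["years_since_baseline"] == 1.1
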