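import numpy as np
import pandas as pd
import pytest

from atlaskit import (
    ExpressionMatrix,
    SampleMeta,
    expression_flags,
    tissue_medians,
    tmm_factors,
    tpm_normalize,
)


def frame(data, samples=None):
    df = pd.DataFrame(data)
    if samples:
        df.columns = samples
    return df


class TestTpmNormalize:
    def test_hand_arithmetic_two_genes(self):
        counts = frame({"s1": [3, 1]})
        counts.index = ["gA", "gB"]
        tpm = tpm_normalize(counts, {"gA": 1000, "gB": 1000})
        assert tpm["s1"].tolist() == [750_000.0, 250_000.0]

    def test_shorter_gene_gets_proportionally_more_tpm(self):
        counts = pd.DataFrame({"s1": [10, 10]}, index=["short", "long"])
        tpm = tpm_normalize(counts, {"short": 1000, "long": 2000})
        assert tpm.loc["short", "s1"] == pytest.approx(2 * tpm.loc["long", "s1"])

    def test_columns_sum_to_one_million(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(
            rng.integers(0, 500, size=(30, 4)),
            index=[f"g{i}" for i in range(30)],
            columns=list("abcd"),
        )
        lengths = {f"g{i}": float(rng.integers(200, 5000)) for i in range(30)}
        tpm = tpm_normalize(counts, lengths)
        assert np.allclose(tpm.sum(axis=0), 1e6, rtol=1e-6)

    def test_all_zero_sample_stays_zero(self, caplog):
        counts = pd.DataFrame({"ok": [5, 5], "empty": [0, 0]}, index=["a", "b"])
        with caplog.at_level("WARNING"):
            tpm = tpm_normalize(counts, {"a": 1000, "b": 1000})
        assert tpm["empty"].tolist() == [0.0, 0.0]
        assert "empty" in caplog.text

    def test_missing_length_names_the_gene(self):
        counts = pd.DataFrame({"s": [1, 2]}, index=["a", "mystery"])
        with pytest.raises(KeyError, match="mystery"):
            tpm_normalize(counts, {"a": 1000})


class TestTmmFactors:
    def test_identical_samples_give_unit_factors(self):
        counts = pd.DataFrame({"s1": [10, 20, 30], "s2": [10, 20, 30]})
        factors = tmm_factors(counts)
        assert factors["s1"] == pytest.approx(1.0, abs=1e-9)
        assert factors["s2"] == pytest.approx(1.0, abs=1e-9)

    def test_pure_depth_scaling_is_absorbed_by_library_size(self):
        rng = np.random.default_rng(9)
        a = rng.integers(1, 1000, size=200)
        counts = pd.DataFrame({"A": a, "B": 2 * a})
        factors = tmm_factors(counts)
        assert factors["A"] == pytest.approx(1.0, abs=1e-9)
        assert factors["B"] == pytest.approx(1.0, abs=1e-9)

    def test_geometric_mean_is_one(self):
        rng = np.random.default_rng(21)
        counts = pd.DataFrame(
            rng.poisson(rng.lognormal(3, 1, size=150)[:, None] * [1, 2, 0.5, 3]),
            columns=list("wxyz"),
        )
        factors = tmm_factors(counts)
        log_mean = np.mean([np.log(f) for f in factors.values()])
        assert log_mean == pytest.approx(0.0, abs=1e-9)

    def test_matches_reference_trimmed_mean_implementation(self):
        # 100-gene simulation with 10 genes 8-fold up in sample 2; expected
        # factors computed once with the standard R reference implementation
        # (edgeR::calcNormFactors, method="TMM") and frozen here.
        rng = np.random.default_rng(20240817)
        base = rng.lognormal(4.0, 1.0, size=100)
        cols = {}
        for i, lf in enumerate([1.0, 1.3, 0.8, 2.0]):
            mu = base * lf
            if i == 1:
                mu = mu.copy()
                mu[:10] *= 8
            cols[f"s{i + 1}"] = rng.poisson(mu)
        counts = pd.DataFrame(cols)
        expected = {
            "s1": 1.0851606741,
            "s2": 0.7789073149,
            "s3": 1.0930735247,
            "s4": 1.0823576612,
        }
        factors = tmm_factors(counts)
        for sample, value in expected.items():
            assert factors[sample] == pytest.approx(value, abs=1e-6)

    def test_zero_total_sample_raises(self):
        counts = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
        with pytest.raises(ValueError, match="zero total"):
            tmm_factors(counts)


def liver_two_project_setup():
    samples = [
        SampleMeta("s1", "P1", "liver"),
        SampleMeta("s2", "P1", "liver"),
        SampleMeta("s3", "P1", "liver"),
        SampleMeta("s4", "P2", "liver"),
        SampleMeta("s5", "P2", "liver"),
    ]
    tpm = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0, 6.0]],
        index=["g"],
        columns=[s.sample_id for s in samples],
    )
    return tpm, samples


class TestTissueMedians:
    def test_median_of_project_medians(self):
        tpm, samples = liver_two_project_setup()
        profiles = tissue_medians(tpm, samples)
        # project medians 2 and 5 -> tissue median 3.5
        assert profiles["g"].tissue_median["liver"] == pytest.approx(3.5)

    def test_single_project_tissue_equals_project_median(self):
        samples = [SampleMeta(f"s{i}", "P1", "brain") for i in range(3)]
        tpm = pd.DataFrame([[5.0, 1.0, 9.0]], index=["g"],
                           columns=[s.sample_id for s in samples])
        profiles = tissue_medians(tpm, samples)
        assert profiles["g"].tissue_median["brain"] == pytest.approx(5.0)

    def test_single_sample_projects_pass_through(self):
        samples = [SampleMeta("a", "P1", "heart"), SampleMeta("b", "P2", "heart")]
        tpm = pd.DataFrame([[2.0, 10.0]], index=["g"], columns=["a", "b"])
        profiles = tissue_medians(tpm, samples)
        assert profiles["g"].tissue_median["heart"] == pytest.approx(6.0)

    def test_permutation_invariance_within_and_across_projects(self):
        rng = np.random.default_rng(4)
        samples = [
            SampleMeta(f"s{i}", f"P{i % 3}", "liver") for i in range(9)
        ]
        values = rng.lognormal(1, 1, size=9)
        tpm = pd.DataFrame([values], index=["g"],
                           columns=[s.sample_id for s in samples])
        ref = tissue_medians(tpm, samples)["g"].tissue_median["liver"]
        perm = rng.permutation(9)
        tpm_p = tpm.iloc[:, perm]
        samples_p = [samples[i] for i in perm]
        assert tissue_medians(tpm_p, samples_p)["g"].tissue_median[
            "liver"
        ] == pytest.approx(ref)


def flag_setup(reads, tpm_vals, tissue="liver", project="P1"):
    samples = [SampleMeta(f"s{i}", project, tissue) for i in range(len(reads))]
    ids = [s.sample_id for s in samples]
    counts = pd.DataFrame([reads], index=["g"], columns=ids)
    tpm = pd.DataFrame([tpm_vals], index=["g"], columns=ids)
    # neutralize the TMM stage: identical scaled values
    matrix = ExpressionMatrix(samples=samples, tpm=tpm, counts=counts,
                              tmm_scaled=tpm.copy())
    profiles = tissue_medians(tpm, samples)
    return matrix, profiles


class TestExpressionFlags:
    def test_half_of_samples_qualifying_is_expressed(self):
        matrix, profiles = flag_setup(
            reads=[10, 10, 0, 0], tpm_vals=[0.5, 0.5, 0.0, 0.0]
        )
        flags = expression_flags(matrix, profiles)
        assert flags["g"].expressed  # 2/4 = 50% qualifies (inclusive)
        assert flags["g"].supporting == [("liver", "P1")]

    def test_low_medians_fail_condition_one_regardless(self):
        matrix, profiles = flag_setup(
            reads=[100, 100, 100, 100], tpm_vals=[0.05, 0.05, 0.05, 0.05]
        )
        assert not expression_flags(matrix, profiles)["g"].expressed

    def test_high_median_sets_highly_expressed(self):
        matrix, profiles = flag_setup(
            reads=[20, 20, 20, 20], tpm_vals=[1.5, 1.5, 1.5, 1.5]
        )
        flags = expression_flags(matrix, profiles)
        assert flags["g"].expressed and flags["g"].highly_expressed

    def test_expressed_but_not_highly(self):
        matrix, profiles = flag_setup(
            reads=[20, 20, 20, 20], tpm_vals=[0.5, 0.5, 0.5, 0.5]
        )
        flags = expression_flags(matrix, profiles)
        assert flags["g"].expressed and not flags["g"].highly_expressed

    def test_monotone_under_random_count_increments(self):
        rng = np.random.default_rng(13)
        matrix, profiles = flag_setup(
            reads=[10, 10, 0, 0], tpm_vals=[0.5, 0.5, 0.0, 0.0]
        )
        assert expression_flags(matrix, profiles)["g"].expressed
        for _ in range(20):
            bumped_counts = matrix.counts + rng.integers(
                0, 50, size=matrix.counts.shape
            )
            bumped_tpm = matrix.tpm + rng.uniform(0, 2, size=matrix.tpm.shape)
            bumped = ExpressionMatrix(
                samples=matrix.samples, tpm=bumped_tpm, counts=bumped_counts,
                tmm_scaled=bumped_tpm.copy(),
            )
            prof = tissue_medians(bumped_tpm, matrix.samples)
            assert expression_flags(bumped, prof)["g"].expressed

    def test_global_count_scaling_leaves_tpm_and_factors_unchanged(self):
        rng = np.random.default_rng(17)
        counts = pd.DataFrame(
            rng.integers(1, 2000, size=(80, 3)),
            index=[f"g{i}" for i in range(80)], columns=list("abc"),
        )
        lengths = {f"g{i}": 1000.0 for i in range(80)}
        tpm1 = tpm_normalize(counts, lengths)
        tpm2 = tpm_normalize(counts * 7, lengths)
        assert np.allclose(tpm1, tpm2)
        f1 = tmm_factors(counts)
        f2 = tmm_factors(counts * 7)
        for s in counts.columns:
            assert f1[s] == pytest.approx(f2[s], abs=1e-9)
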