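import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit
from skbio.stats.composition import clr as skbio_clr
from skbio.stats.composition import multi_replace as skbio_multi_replace

from microdys._errors import DegenerateInputError
from microdys.dysbiosis_cloud import (
    agreement_correlation,
    aitchison_distance,
    classify_dysbiosis,
    cloud_analysis,
    cloud_statistic,
    clr_transform,
    multiplicative_replacement,
    orthogonal_validation,
    table_to_clr,
)
from microdys.tables_io import CountTable, filter_low_depth


class TestMultiplicativeReplacement:
    def test_no_zeros_identity(self):
        row = np.array([[0.2, 0.3, 0.5]])
        np.testing.assert_allclose(multiplicative_replacement(row, 0.01), row)

    def test_hand_example(self):
        out = multiplicative_replacement(np.array([[0.5, 0.5, 0.0]]), 0.01)
        np.testing.assert_allclose(out, [[0.495, 0.495, 0.01]])

    def test_matches_skbio(self):
        X = np.array([[0.5, 0.5, 0.0], [0.25, 0.25, 0.5]])
        np.testing.assert_allclose(
            multiplicative_replacement(X, 0.01), skbio_multi_replace(X, 0.01)
        )

    def test_all_zero_row_errors(self):
        with pytest.raises(DegenerateInputError):
            multiplicative_replacement(np.array([[0.0, 0.0]]), 0.01)

    def test_delta_too_large_errors(self):
        with pytest.raises(ValueError):
            multiplicative_replacement(np.array([[0.5, 0.5, 0.0]]), 0.6)


class TestClrTransform:
    def test_uniform_row_all_zeros(self):
        np.testing.assert_allclose(clr_transform([[0.25] * 4]), np.zeros((1, 4)), atol=1e-12)

    def test_hand_log_identities(self):
        out = clr_transform(np.array([[1, 3, 9]]) / 13)
        np.testing.assert_allclose(out, [[-math.log(3), 0.0, math.log(3)]], atol=1e-12)

    def test_rows_sum_to_zero_and_match_skbio(self):
        rng = np.random.default_rng(0)
        X = rng.dirichlet(np.ones(6), size=4)
        out = clr_transform(X)
        np.testing.assert_allclose(out.sum(axis=1), 0, atol=1e-9)
        np.testing.assert_allclose(out, skbio_clr(X))

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        st.lists(st.floats(0.01, 100), min_size=2, max_size=8),
        st.floats(0.001, 1000),
    )
    def test_scale_invariance(self, parts, scale):
        x = np.array([parts])
        a = clr_transform(x / x.sum())
        xs = x * scale
        b = clr_transform(xs / xs.sum())
        np.testing.assert_allclose(a, b, atol=1e-8)

    def test_zero_entry_errors(self):
        with pytest.raises(ValueError):
            clr_transform([[0.0, 1.0]])


class TestAitchisonDistance:
    def test_identical_compositions_zero(self):
        clr = clr_transform(np.array([[0.2, 0.3, 0.5], [0.2, 0.3, 0.5]]))
        assert aitchison_distance(clr)["0", "1"] == 0.0

    def test_hand_value(self):
        # [1,3,9] vs [9,3,1]: CLR rows (-ln3, 0, ln3) and (ln3, 0, -ln3)
        clr = clr_transform(np.array([[1, 3, 9], [9, 3, 1]]) / 13)
        assert aitchison_distance(clr)["0", "1"] == pytest.approx(2 * math.sqrt(2) * math.log(3))

    def test_consistent_taxon_permutation_invariant(self):
        rng = np.random.default_rng(1)
        X = rng.dirichlet(np.ones(5), size=2)
        perm = rng.permutation(5)
        d1 = aitchison_distance(clr_transform(X))["0", "1"]
        d2 = aitchison_distance(clr_transform(X[:, perm]))["0", "1"]
        assert d1 == pytest.approx(d2)

    def test_matches_pairwise_log_ratio_formula(self):
        # Independent oracle: d^2 = (1/(2D)) * sum_{i,j} (ln(x_i/x_j) - ln(y_i/y_j))^2
        x = np.array([0.1, 0.3, 0.6])
        y = np.array([0.5, 0.2, 0.3])
        D = 3
        acc = 0.0
        for i in range(D):
            for j in range(D):
                acc += (math.log(x[i] / x[j]) - math.log(y[i] / y[j])) ** 2
        oracle = math.sqrt(acc / (2 * D))
        clr = clr_transform(np.vstack([x, y]))
        assert aitchison_distance(clr)["0", "1"] == pytest.approx(oracle)


class TestCloudStatistic:
    def test_query_identical_to_reference_k1_zero(self):
        ref = pd.DataFrame(np.array([[0.0, 0], [1, 0], [0, 1]]), index=["r1", "r2", "r3"])
        q = pd.DataFrame(np.array([[1.0, 0]]), index=["q"])
        assert cloud_statistic(q, ref, k=1).iloc[0] == 0.0

    def test_collinear_leave_one_out_hand_values(self):
        # three collinear points at 0, 1, 2: pairwise distances {1,1,2}
        ref = pd.DataFrame(np.array([[0.0], [1.0], [2.0]]), index=["a", "b", "c"])
        stats = cloud_statistic(ref, ref, k="all")
        np.testing.assert_allclose(stats.to_numpy(), [1.5, 1.0, 1.5])

    def test_far_outlier_exceeds_all_reference_stats(self):
        rng = np.random.default_rng(2)
        ref = pd.DataFrame(rng.normal(size=(10, 4)), index=[f"r{i}" for i in range(10)])
        q = pd.DataFrame(np.full((1, 4), 50.0), index=["out"])
        ref_stats = cloud_statistic(ref, ref)
        assert cloud_statistic(q, ref).iloc[0] > ref_stats.max()

    def test_k_exceeding_usable_reference_errors(self):
        ref = pd.DataFrame(np.eye(3), index=list("abc"))
        with pytest.raises(ValueError):
            cloud_statistic(ref, ref, k=3)  # leave-one-out leaves only 2

    def test_scale_invariance_of_cloud_stat(self):
        # multiplying a zero-free sample's counts by a constant changes
        # nothing after the compositional transform
        counts = pd.DataFrame(
            {"s1": [10, 20, 30], "s2": [5, 5, 5], "s3": [1, 2, 3], "s4": [8, 1, 1]},
            index=["A", "B", "C"],
        )
        t1 = CountTable(counts)
        scaled = counts.copy()
        scaled["s1"] *= 7
        t2 = CountTable(scaled)
        s1 = cloud_statistic(table_to_clr(t1), table_to_clr(t1))
        s2 = cloud_statistic(table_to_clr(t2), table_to_clr(t2))
        np.testing.assert_allclose(s1.to_numpy(), s2.to_numpy(), atol=1e-10)


class TestClassifyDysbiosis:
    def test_hand_threshold(self):
        ref = pd.Series([1.0, 2, 3, 2, 2], index=list("abcde"))
        queries = pd.Series([3.5, 3.3], index=["x", "y"])
        res = classify_dysbiosis(queries, ref)
        assert res.threshold == pytest.approx(2 + 2 * math.sqrt(0.5))
        assert res.samples.loc["x", "classification"] == "dysbiotic"
        assert res.samples.loc["y", "classification"] == "healthy-like"

    def test_exactly_at_threshold_is_healthy_like(self):
        ref = pd.Series([1.0, 2, 3, 2, 2])
        thr = 2 + 2 * math.sqrt(0.5)
        res = classify_dysbiosis(pd.Series([thr], index=["q"]), ref)
        assert res.samples.loc["q", "classification"] == "healthy-like"

    def test_constant_reference_errors(self):
        with pytest.raises(DegenerateInputError):
            classify_dysbiosis(pd.Series([1.0]), pd.Series([2.0, 2.0, 2.0]))

    def test_di_is_log_of_stat_and_monotone(self):
        ref = pd.Series([1.0, 2, 3, 2, 2])
        stats = pd.Series([0.5, 1.0, 2.0, 4.0])
        res = classify_dysbiosis(stats, ref)
        np.testing.assert_allclose(res.samples["di"], np.log(stats))
        assert res.samples["di"].is_monotonic_increasing


class TestOrthogonalValidation:
    def test_constant_si_errors(self):
        si = pd.Series(0.5, index=[f"s{i}" for i in range(10)])
        with pytest.raises(DegenerateInputError):
            orthogonal_validation(si, si.index[:5])

    def test_extreme_cases_all_labelled_dysbiotic(self):
        rng = np.random.default_rng(3)
        healthy = pd.Series(
            expit(rng.normal(-2, 0.5, 30)), index=[f"h{i}" for i in range(30)]
        )
        cases = pd.Series(0.99, index=[f"c{i}" for i in range(10)])
        si = pd.concat([healthy, cases])
        out = orthogonal_validation(si, healthy.index, seed=0, n_trees=100)
        assert (out["labels"].loc[cases.index] == "dysbiotic").all()
        assert 0 <= out["normality_p"] <= 1

    def test_agrees_with_cloud_on_strong_effect_cohort(self, default_cohort):
        from microdys.differential_power import normalize_counts
        from microdys.symptom_classifier import fit_symptom_index

        table = filter_low_depth(default_cohort.table)
        meta = default_cohort.metadata.loc[table.sample_ids]
        cres = cloud_analysis(table, meta, level="genus")
        norm = normalize_counts(table)
        si = fit_symptom_index(norm, meta["group"], n_trees=200, seed=0)
        out = orthogonal_validation(
            si.si, meta.index[meta["group"] == "healthy"], seed=1, n_trees=200, features=norm
        )
        agree = (out["labels"] == cres.samples["classification"]).mean()
        assert agree > 0.6  # both track the same latent class

        res = agreement_correlation(
            cres.samples["cloud_stat"],
            out["probability_index"],
            cres.samples["classification"],
            out["labels"],
        )
        assert res.pearson_r > 0.5
        assert res.label_concordance == pytest.approx(agree)


class TestAgreementCorrelation:
    def test_linear_function_r_one(self):
        x = pd.Series([1.0, 2, 3, 4], index=list("abcd"))
        res = agreement_correlation(x, 2 * x + 1)
        assert res.pearson_r == pytest.approx(1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(4)
        x = pd.Series(rng.normal(size=500))
        y = pd.Series(rng.normal(size=500))
        assert abs(agreement_correlation(x, y).pearson_r) < 0.15

    def test_constant_input_errors(self):
        x = pd.Series([1.0, 1, 1])
        with pytest.raises(DegenerateInputError):
            agreement_correlation(x, pd.Series([1.0, 2, 3]))


class TestCloudAnalysisEndToEnd:
    def test_null_reference_false_positive_rate_near_2sd_tail(self):
        # On cohorts with no effect, the fraction of reference samples
        # flagged dysbiotic under leave-one-out stays a small tail.
        from microdys.synthetic_cohort import (
            geometric_rank_abundance,
            simulate_dirichlet_multinomial,
        )

        rng = np.random.default_rng(5)
        base = geometric_rank_abundance(40, 0.85)
        rates = []
        for _ in range(50):
            counts = simulate_dirichlet_multinomial(base, 0.02, 20000, 38, rng)
            t = CountTable(
                pd.DataFrame(
                    counts, index=[f"g{i}" for i in range(40)],
                    columns=[f"s{i}" for i in range(38)],
                )
            )
            clr = table_to_clr(t)
            stats = cloud_statistic(clr, clr)
            res = classify_dysbiosis(stats, stats)
            rates.append((res.classification == "dysbiotic").mean())
        assert np.mean(rates) <= 0.05

    def test_recovers_latent_class_on_default_cohort(self, default_cohort):
        table = filter_low_depth(default_cohort.table)
        meta = default_cohort.metadata.loc[table.sample_ids]
        res = cloud_analysis(table, meta, reference_group="healthy", level="genus")
        truth = default_cohort.truth.loc[table.sample_ids, "latent_class"]
        from sklearn.metrics import balanced_accuracy_score

        assert balanced_accuracy_score(truth, res.classification) > 0.8
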