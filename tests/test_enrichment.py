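import numpy as np
import pandas as pd
import pytest
from scipy import stats

from h1ub import synthetic
from h1ub.enrichment import (
    EnrichmentConfig,
    ModeratedAnovaFDR,
    assign_groups,
    impute,
    preprocess,
    s0_anova_fdr,
    zscore_cluster,
)


def design_groups(matrix):
    return [c.rsplit("_", 2)[0] for c in matrix.columns]


@pytest.fixture()
def small_matrix():
    rng = np.random.default_rng(0)
    cols = [f"g{g}_b{b}_t{t}" for g in range(2) for b in range(3) for t in range(2)]
    data = rng.normal(25, 1, size=(20, 12))
    m = pd.DataFrame(data, index=[f"P{i}" for i in range(20)], columns=cols)
    return m


class TestPreprocess:
    def test_flagged_rows_removed(self, small_matrix):
        flags = pd.DataFrame(
            {"contaminant": [True] + [False] * 19}, index=small_matrix.index
        )
        out = preprocess(2**small_matrix, EnrichmentConfig(), flags=flags)
        assert "P0" not in out.index

    def test_insufficient_valid_values_removed(self, small_matrix):
        m = 2**small_matrix.copy()
        m.iloc[0, 0:2] = 0.0  # 4 of 6 valid in condition g0
        m.iloc[0, 6:8] = 0.0  # and 4 of 6 in g1: no condition satisfies 5-of-6
        cfg = EnrichmentConfig(min_valid=5, min_valid_scope="per_group")
        out = preprocess(m, cfg, groups=design_groups(m))
        assert m.index[0] not in out.index

    def test_complete_row_log2_transformed(self, small_matrix):
        m = 2**small_matrix
        out = preprocess(m, EnrichmentConfig(min_valid_scope="total"))
        np.testing.assert_allclose(out.iloc[0], small_matrix.iloc[0])

    def test_zeros_become_missing(self, small_matrix):
        m = 2**small_matrix
        m.iloc[1, 0] = 0.0
        out = preprocess(m, EnrichmentConfig(min_valid_scope="total"))
        assert np.isnan(out.iloc[1, 0])

    def test_all_rows_removed_errors(self, small_matrix):
        m = 0 * small_matrix
        with pytest.raises(ValueError):
            preprocess(m, EnrichmentConfig())


class TestImpute:
    def test_complete_matrix_identity(self, small_matrix):
        out, mask = impute(small_matrix, EnrichmentConfig(seed=1))
        pd.testing.assert_frame_equal(out, small_matrix)
        assert not mask.any().any()

    def test_downshifted_distribution(self):
        rng = np.random.default_rng(2)
        data = pd.DataFrame(rng.normal(25, 2, size=(2000, 10)))
        data[data < data.stack().quantile(0.4)] = np.nan
        observed = data.stack()
        mu, sd = observed.mean(), observed.std()
        out, mask = impute(data, EnrichmentConfig(seed=3))
        imputed = out.to_numpy()[mask.to_numpy()]
        n = imputed.size
        assert n > 5000
        se = 0.3 * sd / np.sqrt(n)
        assert imputed.mean() == pytest.approx(mu - 1.8 * sd, abs=3 * se)
        assert imputed.std() == pytest.approx(0.3 * sd, rel=0.05)

    def test_deterministic_under_seed(self, small_matrix):
        m = small_matrix.copy()
        m.iloc[0, 0] = np.nan
        a, _ = impute(m, EnrichmentConfig(seed=7))
        b, _ = impute(m, EnrichmentConfig(seed=7))
        pd.testing.assert_frame_equal(a, b)

    def test_observed_entries_untouched(self, small_matrix):
        m = small_matrix.copy()
        m.iloc[0, 0] = np.nan
        out, mask = impute(m, EnrichmentConfig(seed=1))
        np.testing.assert_array_equal(
            out.to_numpy()[~mask.to_numpy()], m.to_numpy()[~mask.to_numpy()]
        )

    def test_no_observed_values_errors(self):
        empty = pd.DataFrame(np.full((3, 4), np.nan))
        with pytest.raises(ValueError):
            impute(empty, EnrichmentConfig())


class TestModeratedAnova:
    def test_s0_zero_matches_classical_f_ranking(self, small_matrix):
        groups = np.array(design_groups(small_matrix))
        est = ModeratedAnovaFDR(s0=0.0, n_permutations=10, seed=0).fit(
            small_matrix.to_numpy(), groups
        )
        f_classical = np.array(
            [
                stats.f_oneway(
                    row[groups == "g0"], row[groups == "g1"]
                ).statistic
                for row in small_matrix.to_numpy()
            ]
        )
        got = np.argsort(np.argsort(est.statistic_))
        want = np.argsort(np.argsort(f_classical))
        np.testing.assert_array_equal(got, want)

    def test_constant_row_not_significant(self, small_matrix):
        m = small_matrix.copy()
        m.iloc[0] = 20.0
        est = ModeratedAnovaFDR(s0=2.0, n_permutations=50, seed=0).fit(
            m.to_numpy(), np.array(design_groups(m))
        )
        assert est.statistic_[0] == 0.0
        assert not est.significant_[0]

    def test_global_null_controls_fdr(self):
        # no real effects: the declared-positive rate must stay at or below nominal
        total_positives = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            data = rng.normal(size=(500, 12))
            groups = np.repeat([f"g{i}" for i in range(2)], 6)
            est = ModeratedAnovaFDR(s0=0.5, fdr=0.001, n_permutations=200, seed=seed).fit(
                data, groups
            )
            total_positives += est.significant_.sum()
        # 20 x 500 tests at FDR 0.001 under the global null
        assert total_positives <= 2

    def test_tightening_fdr_never_enlarges_set(self):
        spec = synthetic.SyntheticSpec(seed=11)
        matrix, _ = synthetic.simulate_apms_matrix(spec)
        cfg = EnrichmentConfig(seed=11)
        clean = preprocess(matrix, cfg, groups=design_groups(matrix), log_transform=False)
        filled, _ = impute(clean, cfg)
        groups = design_groups(filled)
        loose = s0_anova_fdr(filled, groups, EnrichmentConfig(seed=11, fdr=0.01))
        tight = s0_anova_fdr(filled, groups, EnrichmentConfig(seed=11, fdr=0.001))
        assert set(tight.significant) <= set(loose.significant)

    def test_degenerate_design_rejected(self, small_matrix):
        with pytest.raises(ValueError):
            ModeratedAnovaFDR().fit(small_matrix.to_numpy(), np.array(["a"] * 12))


class TestZscoreAndGroups:
    @pytest.fixture()
    def planted(self):
        spec = synthetic.SyntheticSpec(seed=5)
        matrix, truth = synthetic.simulate_apms_matrix(spec)
        cfg = EnrichmentConfig(seed=5)
        clean = preprocess(matrix, cfg, groups=design_groups(matrix), log_transform=False)
        filled, _ = impute(clean, cfg)
        result = s0_anova_fdr(filled, design_groups(filled), cfg)
        return filled, truth, result

    def test_z_rows_standardized(self, planted):
        filled, _, result = planted
        sub = filled.loc[result.significant]
        z = sub.sub(sub.mean(axis=1), axis=0).div(sub.std(axis=1, ddof=0), axis=0)
        np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(z.std(axis=1, ddof=0), 1.0, atol=1e-9)

    def test_profiles_have_one_column_per_bait(self, planted):
        filled, _, result = planted
        result = zscore_cluster(filled, result, design_groups(filled))
        assert list(result.z_profiles.columns) == [f"g{i}" for i in range(6)]

    def test_clustering_invariant_to_row_order(self, planted):
        filled, _, result = planted
        a = zscore_cluster(filled, result, design_groups(filled), n_clusters=3)
        perm = filled.sample(frac=1.0, random_state=4)
        from h1ub.enrichment import EnrichmentResult

        result2 = s0_anova_fdr(perm, design_groups(perm), EnrichmentConfig(seed=5))
        b = zscore_cluster(perm, result2, design_groups(perm), n_clusters=3)
        common = a.z_profiles.index.intersection(b.z_profiles.index)
        # cluster partitions agree up to label permutation
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(
            a.cluster_labels.loc[common], b.cluster_labels.loc[common]
        ) == pytest.approx(1.0)

    def test_membership_rule(self):
        from h1ub.enrichment import EnrichmentResult

        result = EnrichmentResult(
            statistic=pd.Series(dtype=float),
            qvalues=pd.Series(dtype=float),
            significant=pd.Index(["P1"]),
        )
        result.z_profiles = pd.DataFrame(
            {"g1": [0.5], "g2": [0.1], "g3": [0.4]}, index=["P1"]
        )
        memberships = assign_groups(result, threshold=0.3)
        assert memberships == {"g1": {"P1"}, "g2": set(), "g3": {"P1"}}

    def test_threshold_above_max_empty(self):
        from h1ub.enrichment import EnrichmentResult

        result = EnrichmentResult(
            statistic=pd.Series(dtype=float),
            qvalues=pd.Series(dtype=float),
            significant=pd.Index(["P1"]),
        )
        result.z_profiles = pd.DataFrame({"g1": [0.5]}, index=["P1"])
        assert assign_groups(result, threshold=0.9) == {"g1": set()}

    def test_planted_targets_recovered_as_members(self, planted):
        filled, truth, result = planted
        result = zscore_cluster(filled, result, design_groups(filled))
        memberships = assign_groups(result, threshold=0.3)
        hits = misses = 0
        for pid, row in truth[truth.label == "enriched"].iterrows():
            if pid not in result.z_profiles.index:
                continue
            targets = {f"g{t}" for t in row.target_groups.split(",")}
            for g in targets:
                if pid in memberships[g]:
                    hits += 1
                else:
                    misses += 1
        assert hits / (hits + misses) > 0.95


class TestFullPipelineRecovery:
    def test_sensitivity_and_fdr_on_planted_effects(self):
        sens, fdr = [], []
        for seed in range(1, 21):
            spec = synthetic.SyntheticSpec(seed=seed)
            matrix, truth = synthetic.simulate_apms_matrix(spec)
            cfg = EnrichmentConfig(seed=seed, n_permutations=200)
            clean = preprocess(matrix, cfg, groups=design_groups(matrix), log_transform=False)
            filled, _ = impute(clean, cfg)
            res = s0_anova_fdr(filled, design_groups(filled), cfg)
            labels = truth["label"]
            tp = (labels.loc[res.significant] == "enriched").sum()
            fp = len(res.significant) - tp
            sens.append(tp / (labels == "enriched").sum())
            fdr.append(fp / max(len(res.significant), 1))
        assert np.mean(sens) >= 0.9
        assert np.mean(fdr) <= 0.001 + 0.002  # binomial slack at ~1000 declared positives
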