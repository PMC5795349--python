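import numpy as np
import pandas as pd
import pytest

from phenomap import quantgen as Q
from phenomap import synth
from phenomap.design import generate_design


def obs(genotypes, values, rows=None, replicates=None):
    d = pd.DataFrame({"genotype": genotypes, "value": values})
    if rows is not None:
        d["row"] = rows
    if replicates is not None:
        d["replicate"] = replicates
    return d


class TestAnovaFixtures:
    def test_separated_groups(self):
        fit = Q.anova_day(obs(list("AABB"), [1, 1, 3, 3]), "genotype_only")
        assert fit.ss_genotype == pytest.approx(4.0)
        assert fit.ss_error == pytest.approx(0.0)

    def test_overlapping_groups_give_half(self):
        fit = Q.anova_day(obs(list("AABB"), [0, 2, 2, 4]), "genotype_only")
        assert fit.ss_genotype == pytest.approx(4.0)
        assert fit.ss_error == pytest.approx(4.0)
        assert Q.heritability(fit, "adjusted") == pytest.approx(0.5)

    def test_constant_response_all_zero(self):
        fit = Q.anova_day(obs(list("AABB"), [2.0] * 4), "genotype_only")
        assert fit.ss_genotype == fit.ss_error == 0.0
        assert np.isnan(Q.heritability(fit, "adjusted"))

    def test_row_effect_separates_adjusted_from_classical(self):
        # rows shift by +10; genotypes differ by 2 within rows; no noise
        d = obs(list("ABAB"), [0, 2, 10, 12], rows=[1, 1, 2, 2])
        adj = Q.anova_day(d, "row+genotype")
        cls = Q.anova_day(d, "genotype_only")
        assert Q.heritability(adj, "adjusted") == pytest.approx(1.0)
        assert Q.heritability(cls, "classical") == pytest.approx(4 / 104)
        assert Q.heritability(cls, "classical") < 1.0

    def test_ss_additivity(self):
        rng = np.random.default_rng(0)
        d = obs(
            list("AABBCC") * 3,
            rng.normal(size=18),
            rows=list(np.repeat([1, 2, 3], 6)),
        )
        fit = Q.anova_day(d, "row+genotype")
        total = ((d["value"] - d["value"].mean()) ** 2).sum()
        assert fit.ss_total == pytest.approx(total)
        assert 0 <= Q.heritability(fit, "adjusted") <= 1


class TestAgainstStatsmodelsTypeI:
    def test_sequential_ss_matches_anova_lm(self):
        sm = pytest.importorskip("statsmodels.api")
        from statsmodels.formula.api import ols

        rng = np.random.default_rng(42)
        n = 60
        d = pd.DataFrame(
            {
                "genotype": rng.choice(list("ABCDE"), size=n),
                "row": rng.choice(["r1", "r2", "r3"], size=n),
                "value": rng.normal(size=n),
            }
        )
        # unbalanced data: sequential ordering matters, so this is a real check
        fit = Q.anova_day(d, "row+genotype")
        tab = sm.stats.anova_lm(
            ols("value ~ C(row) + C(genotype)", data=d).fit(), typ=1
        )
        assert fit.ss_env == pytest.approx(tab.loc["C(row)", "sum_sq"])
        assert fit.ss_genotype == pytest.approx(tab.loc["C(genotype)", "sum_sq"])
        assert fit.ss_error == pytest.approx(tab.loc["Residual", "sum_sq"])


class TestModelValidation:
    def test_unreplicated_genotype_dropped(self):
        d = obs(list("AABBC"), [1, 2, 3, 4, 9], rows=[1, 2, 1, 2, 2])
        fit = Q.anova_day(d, "row+genotype")
        assert fit.n_genotypes == 2
        assert fit.n_dropped == 1

    def test_too_few_genotypes_rejected(self):
        with pytest.raises(ValueError):
            Q.anova_day(obs(list("AAAA"), [1, 2, 3, 4]), "genotype_only")

    def test_aliased_terms_detected(self):
        # row and genotype are the same partition -> genotype adds nothing
        d = obs(list("AABB"), [1, 2, 3, 4], rows=[1, 1, 2, 2])
        with pytest.raises(Q.SingularDesignError, match="genotype"):
            Q.anova_day(d, "row+genotype")

    def test_na_rows_dropped(self):
        d = obs(list("AABB") * 2, [1, 1, 3, 3, np.nan, 1, 3, np.nan])
        fit = Q.anova_day(d, "genotype_only")
        assert fit.n_obs == 6
        assert fit.n_dropped == 2


class TestHeritabilityRecovery:
    def test_mean_ss_ratio_matches_finite_sample_expectation(self):
        """The SS-ratio statistic concentrates near its analytic value.

        For k replicated genotypes with n plants each, E[SS_g] =
        (k-1)(n*s2g + s2e) and E[SS_e] = k(n-1)*s2e for the one-way layout,
        so the ratio of expectations is an independent oracle for the mean
        of the statistic (the ratio-of-means approximation is good because
        both sums concentrate at this size).
        """
        design = generate_design(0)
        cfg = synth.SynthConfig(
            seed=0, genotype_variance=1.0, row_variance=0.0, error_variance=1.0
        )
        day = cfg.n_days - 5
        vals = []
        for rep in range(100):
            panel = synth.simulate_trait_panel(design, cfg, seed=1000 + rep)
            d = panel[(panel["trait"] == "height") & (panel["day"] == day)]
            fit = Q.anova_day(d, "row+genotype")
            vals.append(Q.heritability(fit, "adjusted"))
        k, n = 31, 5  # ZL22 is dropped
        ss_g = (k - 1) * (n * 1.0 + 1.0)
        ss_e = k * (n - 1) * 1.0 - 9  # row term absorbs ~9 df of pure error
        expected = ss_g / (ss_g + ss_e)
        assert np.mean(vals) == pytest.approx(expected, abs=0.05)

    def test_row_variance_lowers_classical_but_not_adjusted(self):
        design = generate_design(0)
        cfg = synth.SynthConfig(
            seed=0, genotype_variance=1.0, row_variance=2.0, error_variance=1.0
        )
        day = cfg.n_days - 5
        adj, cls = [], []
        for rep in range(40):
            panel = synth.simulate_trait_panel(design, cfg, seed=2000 + rep)
            d = panel[(panel["trait"] == "height") & (panel["day"] == day)]
            adj.append(Q.heritability(Q.anova_day(d, "row+genotype"), "adjusted"))
            cls.append(
                Q.heritability(Q.anova_day(d, "genotype_only"), "classical")
            )
        assert np.mean(adj) > np.mean(cls)


class TestErrorHeritability:
    def test_residuals_determined_by_genotype(self):
        d = pd.DataFrame(
            {
                "genotype": list("AABB") * 2,
                "replicate": [1, 1, 1, 1, 2, 2, 2, 2],
                "residual": [1, 1, -1, -1, 1, 1, -1, -1],
            }
        )
        assert Q.error_heritability(d) == pytest.approx(1.0)

    def test_single_replicate_hand_case(self):
        d = pd.DataFrame(
            {
                "genotype": list("AABB"),
                "replicate": [1, 1, 1, 1],
                "residual": [1, 1, -1, -1],
            }
        )
        assert Q.error_heritability(d) == pytest.approx(1.0)

    def test_iid_noise_matches_permutation_null(self):
        rng = np.random.default_rng(0)
        base = pd.DataFrame(
            {
                "genotype": np.repeat([f"g{i}" for i in range(32)], 5),
                "replicate": np.tile(np.arange(1, 6), 32),
            }
        )
        sims = []
        for _ in range(60):
            d = base.copy()
            d["residual"] = rng.normal(size=len(d))
            sims.append(Q.error_heritability(d))
        d = base.copy()
        d["residual"] = rng.normal(size=len(d))
        null = Q.permutation_null(d, n_perm=60, seed=1)
        assert np.mean(sims) == pytest.approx(np.mean(null), abs=0.03)


class TestSmoothing:
    def test_constant_series_preserved(self):
        out = Q.smooth_heritability(np.arange(5), np.full(5, 0.7), 2.0)
        assert np.allclose(out, 0.7)

    def test_vanishing_bandwidth_recovers_raw_series(self):
        days = np.array([1.0, 2.0, 3.0, 4.0])
        hr = np.array([0.2, 0.8, 0.4, 0.6])
        out = Q.smooth_heritability(days, hr, 1e-3)
        assert np.allclose(out, hr)

    def test_kernel_weight_oracle_on_spike(self):
        days = np.array([1.0, 2.0, 3.0])
        hr = np.array([0.0, 1.0, 0.0])
        out = Q.smooth_heritability(days, hr, 1.0)
        w = np.exp(-0.5)
        expected_mid = 1.0 / (1.0 + 2 * w)
        assert out[1] == pytest.approx(expected_mid)
        assert 0.0 < out[1] < 1.0

    def test_output_within_input_range(self):
        rng = np.random.default_rng(2)
        hr = rng.random(10)
        out = Q.smooth_heritability(np.arange(10), hr, 2.0)
        assert out.min() >= hr.min() - 1e-12
        assert out.max() <= hr.max() + 1e-12

    def test_nonpositive_bandwidth_rejected(self):
        with pytest.raises(ValueError):
            Q.smooth_heritability(np.arange(3), np.zeros(3), 0.0)
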