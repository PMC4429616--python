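import itertools

import numpy as np
import pytest

from dcgscan.corr_engine import gene_correlations
from dcgscan.global_diff import (
    fdr_across_datasets,
    hodges_lehmann,
    signed_comparison,
    subsampled_abs_comparison,
    wilcoxon_signed_rank,
)
from dcgscan.io_preprocess import preprocess_dataset
from dcgscan.synthetic_data import SimulationConfig, constant_rho, simulate_dataset


def exact_signed_rank_p(diffs, alternative="two-sided"):
    """Enumerate all 2^n sign assignments of |d| ranks (tie-free input)."""
    d = np.asarray(diffs, dtype=float)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = ranks[d > 0].sum()
    n = d.size
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=n)
    ]
    ws = np.array(ws)
    p_greater = np.mean(ws >= w_obs)
    p_less = np.mean(ws <= w_obs)
    if alternative == "greater":
        return p_greater
    if alternative == "less":
        return p_less
    return min(1.0, 2 * min(p_greater, p_less))


class TestWilcoxonSignedRank:
    def test_identical_pairs(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        est, lo, hi, p = wilcoxon_signed_rank(x, x)
        assert p == 1.0 and est == 0.0

    def test_three_positive_differences_one_tailed(self):
        # all 2^3 = 8 sign assignments; only the observed one reaches W = 6
        est, _, _, p = wilcoxon_signed_rank(np.array([1.0, 2.0, 3.0]), alternative="greater")
        assert p == pytest.approx(1 / 8)
        assert est == pytest.approx(2.0)  # pseudomedian of Walsh averages

    def test_exact_path_matches_enumeration(self):
        rng = np.random.default_rng(4)
        d = rng.normal(0.3, 1.0, size=10)
        _, _, _, p = wilcoxon_signed_rank(d)
        assert p == pytest.approx(exact_signed_rank_p(d), abs=1e-12)

    def test_approx_path_near_exact(self):
        # n = 26 forces the normal approximation; enumeration is 2^26 — use
        # scipy's exact mode as the oracle instead
        import scipy.stats

        rng = np.random.default_rng(5)
        d = rng.normal(0.2, 1.0, size=26)
        _, _, _, p = wilcoxon_signed_rank(d)
        p_exact = scipy.stats.wilcoxon(d, method="exact").pvalue
        assert p == pytest.approx(p_exact, abs=0.01)

    def test_hodges_lehmann_matches_walsh_oracle(self):
        rng = np.random.default_rng(6)
        d = rng.normal(0.5, 1.0, size=15)
        est, _, _ = hodges_lehmann(d)
        walsh = [(d[i] + d[j]) / 2 for i in range(15) for j in range(i, 15)]
        assert est == pytest.approx(np.median(walsh), abs=1e-12)

    def test_selection_path_matches_dense_path(self):
        # n above the dense limit exercises bisection selection
        rng = np.random.default_rng(7)
        d = rng.normal(0.1, 1.0, size=700)
        est, lo, hi = hodges_lehmann(d)
        i, j = np.triu_indices(700)
        walsh = np.sort((d[i] + d[j]) / 2)
        assert est == pytest.approx(np.median(walsh), abs=1e-12)
        assert lo < est < hi

    def test_all_zero_differences(self):
        est, _, _, p = wilcoxon_signed_rank(np.zeros(8))
        assert (est, p) == (0.0, 1.0)


@pytest.fixture(scope="module")
def equal_groups_dataset():
    cfg = SimulationConfig(
        n_genes=80,
        n_tumor=12,
        n_normal=12,
        rho_normal_fn=constant_rho(0.3),
        rho_tumor_fn=constant_rho(0.3),
        cpgs_per_gene_range=(2, 4),
        seed=21,
    )
    ds = simulate_dataset(cfg)
    res = preprocess_dataset(ds.expression, ds.methylation, ds.annotation, ds.groups)
    rec = gene_correlations(res.expression, res.methylation_gene_m, res.groups)
    return res, rec


class TestSubsampledAbsComparison:
    def test_equal_groups_collapse_to_direct_test(self, equal_groups_dataset):
        res, rec = equal_groups_dataset
        out = subsampled_abs_comparison(
            rec, res.expression, res.methylation_gene_m, res.groups, n_reps=50, seed=0
        )
        est, lo, hi, p = wilcoxon_signed_rank(
            np.abs(rec["rho_normal"].to_numpy()), np.abs(rec["rho_tumor"].to_numpy())
        )
        assert out.n_reps == 1
        assert out.p_value == p and out.estimate == est
        assert (out.ci_low, out.ci_high) == (lo, hi)

    def test_deterministic_under_seed(self, preprocessed):
        rec = gene_correlations(
            preprocessed.expression, preprocessed.methylation_gene_m, preprocessed.groups
        )
        kw = dict(n_reps=20, seed=123)
        a = subsampled_abs_comparison(
            rec, preprocessed.expression, preprocessed.methylation_gene_m,
            preprocessed.groups, **kw,
        )
        b = subsampled_abs_comparison(
            rec, preprocessed.expression, preprocessed.methylation_gene_m,
            preprocessed.groups, **kw,
        )
        assert a.p_value == b.p_value and a.estimate == b.estimate

    def test_null_mean_p_not_enriched(self):
        # identical generative correlation in both groups: the mean
        # subsampled p should not pile up near zero
        ps = []
        for seed in range(4):
            cfg = SimulationConfig(
                n_genes=250,
                n_tumor=50,
                n_normal=10,
                rho_normal_fn=constant_rho(0.3),
                rho_tumor_fn=constant_rho(0.3),
                cpgs_per_gene_range=(1, 2),
                seed=100 + seed,
            )
            ds = simulate_dataset(cfg)
            res = preprocess_dataset(ds.expression, ds.methylation, ds.annotation, ds.groups)
            rec = gene_correlations(res.expression, res.methylation_gene_m, res.groups)
            out = subsampled_abs_comparison(
                rec, res.expression, res.methylation_gene_m, res.groups,
                n_reps=50, seed=seed,
            )
            ps.append(out.p_value)
        assert np.mean(ps) > 0.1


class TestSignedComparison:
    def test_shifted_correlations_detected(self, preprocessed):
        rec = gene_correlations(
            preprocessed.expression, preprocessed.methylation_gene_m, preprocessed.groups
        )
        out = signed_comparison(rec, dataset_id="fixture")
        assert 0.0 <= out.p_value <= 1.0
        assert out.mode == "signed" and out.n_reps == 1


class TestBenjaminiHochberg:
    def test_single_p_is_identity(self):
        assert fdr_across_datasets([0.07])[0] == pytest.approx(0.07)

    def test_step_up_by_hand(self):
        q = fdr_across_datasets([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_q_at_least_p_and_monotone(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=40)
        q = fdr_across_datasets(p)
        assert np.all(q >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            fdr_across_datasets([0.5, 1.2])
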