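import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest, norm

from dcgscan.dcg_caller import (
    call_dcgs,
    fisher_corr_diff_test,
    mantel_autocorrelation,
    mantel_by_stratum,
    stouffer_combine,
)


class TestFisherCorrDiffTest:
    def test_equal_correlations(self):
        z, p_two, p_greater = fisher_corr_diff_test(0.4, 30, 0.4, 50)
        assert z == 0.0 and p_two == 1.0 and p_greater == 0.5

    def test_lung_cd40_example(self):
        # published per-group Spearman correlations for CD40 at n = 57/57
        z, p_two, _ = fisher_corr_diff_test(0.25, 57, -0.66, 57)
        se = math.sqrt(2 / 54)
        z_oracle = (math.atanh(0.25) - math.atanh(-0.66)) / se
        assert z == pytest.approx(z_oracle, rel=1e-12)
        assert z == pytest.approx(5.447, abs=0.001)
        assert p_two == pytest.approx(5.13e-8, rel=0.01)

    def test_one_tailed_complement(self):
        _, _, pg = fisher_corr_diff_test(0.3, 40, -0.1, 40)
        _, _, pl = fisher_corr_diff_test(-0.1, 40, 0.3, 40)
        assert pg + pl == pytest.approx(1.0, abs=1e-12)

    def test_type_i_error_calibrated(self):
        # 20,000 null draws at n=50/50, independent standard-normal pairs
        rng = np.random.default_rng(12)
        n, reps = 50, 20000
        x1 = rng.standard_normal((reps, n))
        y1 = rng.standard_normal((reps, n))
        x2 = rng.standard_normal((reps, n))
        y2 = rng.standard_normal((reps, n))

        def rowcorr(a, b):
            a = a - a.mean(1, keepdims=True)
            b = b - b.mean(1, keepdims=True)
            return (a * b).sum(1) / np.sqrt((a * a).sum(1) * (b * b).sum(1))

        r1, r2 = rowcorr(x1, y1), rowcorr(x2, y2)
        se = math.sqrt(2 / (n - 3))
        z = (np.arctanh(r1) - np.arctanh(r2)) / se
        p = 2 * norm.sf(np.abs(z))
        # spot-check the vectorized oracle against the implementation
        z0, p0, _ = fisher_corr_diff_test(r1[0], n, r2[0], n)
        assert p0 == pytest.approx(p[0], rel=1e-9)
        rate = float((p < 0.05).mean())
        assert 0.04 <= rate <= 0.06

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            fisher_corr_diff_test(0.1, 3, 0.2, 50)


class TestStoufferCombine:
    def test_trivial_values(self):
        assert stouffer_combine([0.5, 0.5]) == pytest.approx(0.5, abs=1e-12)
        assert stouffer_combine([0.123]) == 0.123

    def test_two_moderate_p(self):
        # Z = 2 * 1.6449 / sqrt(2) = 2.3263 -> p = 0.0100
        assert stouffer_combine([0.05, 0.05]) == pytest.approx(0.01, abs=2e-4)

    def test_matches_closed_form_oracle(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.01, 0.99, size=7)
        oracle = norm.sf(norm.isf(p).sum() / math.sqrt(p.size))
        assert stouffer_combine(p) == pytest.approx(oracle, rel=1e-12)

    def test_monotone_in_components(self):
        base = [0.3, 0.4, 0.5]
        lower = [0.2, 0.4, 0.5]
        assert stouffer_combine(lower) < stouffer_combine(base)

    def test_boundary_p_clamped(self):
        assert 0.0 < stouffer_combine([0.0, 0.5]) < 1.0
        assert 0.0 < stouffer_combine([1.0, 0.5]) < 1.0


def _single_cpg_records(rho_n, rho_t, n_n=20, n_t=30):
    z = lambda r: math.atanh(r)
    return pd.DataFrame(
        {
            "gene_id": ["g1"],
            "cpg_id": ["c1"],
            "rho_normal": [rho_n],
            "rho_tumor": [rho_t],
            "n_normal": [n_n],
            "n_tumor": [n_t],
            "z_normal": [z(rho_n)],
            "z_tumor": [z(rho_t)],
            "method": ["spearman"],
        }
    )


class TestCallDcgs:
    def test_one_cpg_stouffer_equals_single_corr(self):
        rec = _single_cpg_records(0.5, -0.2)
        single = call_dcgs(rec, mode="single_corr")
        stouf = call_dcgs(rec, mode="stouffer")
        for col in ("p_pos_in_cancer", "p_neg_in_cancer", "p_two_sided", "q_value"):
            assert stouf[col].iloc[0] == pytest.approx(single[col].iloc[0], rel=1e-9)
        assert stouf["direction"].iloc[0] == single["direction"].iloc[0]

    def test_two_sided_is_twice_smaller_tail(self, preprocessed):
        from dcgscan.corr_engine import cpg_correlations

        rec = cpg_correlations(
            preprocessed.expression,
            preprocessed.methylation_m,
            preprocessed.annotation,
            preprocessed.groups,
        )
        out = call_dcgs(rec, mode="stouffer")
        expected = np.minimum(
            1.0, 2.0 * out[["p_pos_in_cancer", "p_neg_in_cancer"]].min(axis=1)
        )
        np.testing.assert_allclose(out["p_two_sided"], expected)
        # single-CpG genes: the two tails are complementary
        ones = out[out["n_cpgs"] == 1]
        if len(ones):
            np.testing.assert_allclose(
                ones["p_pos_in_cancer"] + ones["p_neg_in_cancer"], 1.0, atol=1e-12
            )

    def test_invariant_to_cpg_order(self, preprocessed):
        from dcgscan.corr_engine import cpg_correlations

        rec = cpg_correlations(
            preprocessed.expression,
            preprocessed.methylation_m,
            preprocessed.annotation,
            preprocessed.groups,
        )
        shuffled = rec.sample(frac=1.0, random_state=3).reset_index(drop=True)
        a = call_dcgs(rec, mode="stouffer").set_index("gene_id")
        b = call_dcgs(shuffled, mode="stouffer").set_index("gene_id")
        np.testing.assert_allclose(
            a["p_two_sided"], b.loc[a.index, "p_two_sided"], atol=1e-12
        )

    def test_planted_dcgs_recovered(self, cohort, preprocessed):
        from dcgscan.corr_engine import cpg_correlations

        rec = cpg_correlations(
            preprocessed.expression,
            preprocessed.methylation_m,
            preprocessed.annotation,
            preprocessed.groups,
        )
        out = call_dcgs(rec, mode="stouffer", alpha_fdr=0.05)
        truth = cohort.truth.set_index("gene_id")
        called = set(out.loc[out["is_dcg"], "gene_id"])
        planted = set(truth.index[truth["is_dcg"]])
        # small cohort: just demand good enrichment, not perfect recovery
        assert len(called & planted) >= 0.5 * len(planted)


class TestMantel:
    def test_identical_matrices_maximal(self):
        pos = np.array([10.0, 200.0, 900.0, 5000.0])
        r, p = mantel_autocorrelation(pos, pos, n_perm=199, seed=0)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 200)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(8)
        pos = np.array([100.0, 350.0, 900.0, 1600.0])
        dz = rng.normal(size=4)
        r_obs, p = mantel_autocorrelation(pos, dz, n_perm=20000, seed=1)
        # exhaustive oracle over all 4! = 24 relabelings
        iu = np.triu_indices(4, 1)
        d_pos = np.abs(pos[:, None] - pos[None, :])
        d_z = np.abs(dz[:, None] - dz[None, :])

        def mr(a, b):
            a, b = a - a.mean(), b - b.mean()
            return (a * b).sum() / np.sqrt((a * a).sum() * (b * b).sum())

        rs = [
            mr(d_pos[np.ix_(perm, perm)][iu], d_z[iu])
            for perm in itertools.permutations(range(4))
        ]
        p_exact = np.mean([r >= r_obs - 1e-12 for r in rs])
        # sampling excludes the identity relabeling (it enters via the +1),
        # so the estimates can differ by up to 1/24 plus Monte-Carlo noise
        assert p == pytest.approx(p_exact, abs=0.05)

    def test_statistic_matches_skbio(self):
        from skbio.stats.distance import DistanceMatrix, mantel as skbio_mantel

        rng = np.random.default_rng(3)
        pos = np.sort(rng.uniform(0, 1000, size=8))
        dz = rng.normal(size=8)
        r, _ = mantel_autocorrelation(pos, dz, n_perm=99, seed=0)
        d_pos = DistanceMatrix(np.abs(pos[:, None] - pos[None, :]))
        d_z = DistanceMatrix(np.abs(dz[:, None] - dz[None, :]))
        r_skbio = skbio_mantel(d_pos, d_z, method="pearson", permutations=0)[0]
        assert r == pytest.approx(float(r_skbio), abs=1e-10)

    def test_null_p_roughly_uniform(self):
        rng = np.random.default_rng(5)
        pos = np.array([0.0, 300.0, 700.0, 1500.0, 2600.0])
        ps = []
        for _ in range(100):
            dz = rng.normal(size=5)
            _, p = mantel_autocorrelation(pos, dz, n_perm=119, seed=int(rng.integers(2**31)))
            ps.append(p)
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_stratified_runner_and_fdr(self, preprocessed):
        from dcgscan.corr_engine import cpg_correlations

        rec = cpg_correlations(
            preprocessed.expression,
            preprocessed.methylation_m,
            preprocessed.annotation,
            preprocessed.groups,
        )
        out = mantel_by_stratum(rec, n_perm=99, seed=4)
        assert set(out["stratum"]) <= {"within_200bp", "bp200_1000", "beyond_1000bp"}
        assert ((out["q_value"] >= out["p_value"] - 1e-12) | out["q_value"].isna()).all()
        assert (out["n_cpgs"] >= 3).all()
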