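"""Split-half resampling, empirical p-values and the combined significance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from simcompare import (
    SimilarityMatrix,
    align_scale,
    combined_pc,
    crossvalidate_k,
    empirical_pvalues,
    p_of_k,
    significance_pipeline,
    sim_tree,
    split_half_resample,
)

from conftest import random_symmetric


def noise_frame(rng, d=20, L=40):
    return pd.DataFrame(
        rng.normal(size=(d, L)), index=[f"s{i}" for i in range(d)]
    )


class TestSplitHalfResample:
    def test_halves_disjoint_and_cover(self, rng):
        d1, d2 = noise_frame(rng, 10, 7), noise_frame(rng, 10, 9)
        rs = split_half_resample(d1, d2, n_bs=3, seed=0)
        for rep in rs.replicates:
            assert len(rep.ref_half1) == 3 and len(rep.ref_half2) == 4
            assert not set(rep.ref_half1) & set(rep.ref_half2)
            assert sorted([*rep.ref_half1, *rep.ref_half2]) == list(range(7))

    def test_same_seed_same_feature_sets(self, rng):
        d1, d2 = noise_frame(rng), noise_frame(rng)
        a = split_half_resample(d1, d2, n_bs=4, seed=5)
        b = split_half_resample(d1, d2, n_bs=4, seed=5)
        for ra, rb in zip(a.replicates, b.replicates):
            assert np.array_equal(ra.ref_half1, rb.ref_half1)
            assert np.array_equal(ra.tgt_features, rb.tgt_features)

    def test_features_sampled_uniformly(self, rng):
        d1, d2 = noise_frame(rng, 5, 100), noise_frame(rng, 5, 100)
        rs = split_half_resample(d1, d2, n_bs=200, seed=1)
        counts = np.zeros(100)
        for rep in rs.replicates:
            counts[rep.ref_half1] += 1
        # binomial(200, 1/2): 3 sigma around 100
        sigma = np.sqrt(200 * 0.25)
        assert np.all(np.abs(counts - 100) <= 3.5 * sigma)

    def test_rejects_label_mismatch_and_bad_nbs(self, rng):
        d1 = noise_frame(rng)
        d2 = d1.copy()
        d2.index = [f"x{i}" for i in range(len(d2))]
        with pytest.raises(ValueError, match="labels must match"):
            split_half_resample(d1, d2, n_bs=1)
        with pytest.raises(ValueError, match="n_bs"):
            split_half_resample(d1, d1, n_bs=0)


class TestAlignScale:
    def _pair(self, rng, d=8):
        y = SimilarityMatrix(random_symmetric(rng, d), [f"s{i}" for i in range(d)])
        ref = SimilarityMatrix(
            random_symmetric(rng, d) * 2 + 1, [f"s{i}" for i in range(d)]
        )
        return y, ref

    def test_self_alignment_is_identity(self, rng):
        y, _ = self._pair(rng)
        out = align_scale(y, y)
        assert np.allclose(out.values, y.values, atol=1e-12)

    def test_affine_transform_absorbed(self, rng):
        y, _ = self._pair(rng)
        shifted = SimilarityMatrix(
            2.0 * y.values + 3.0, y.labels, metadata={"allow_negative": True}
        )
        out = align_scale(shifted, y)
        off = ~np.eye(8, dtype=bool)
        assert np.allclose(out.values[off], y.values[off], atol=1e-10)

    def test_moments_match_brute_force(self, rng):
        y, ref = self._pair(rng)
        out = align_scale(y, ref)
        off = ~np.eye(8, dtype=bool)
        assert out.values[off].mean() == pytest.approx(ref.values[off].mean(), abs=1e-10)
        assert out.values[off].std() == pytest.approx(ref.values[off].std(), abs=1e-10)

    def test_degenerate_spread_rejected(self):
        flat = SimilarityMatrix(np.ones((3, 3)), list("abc"))
        ref = SimilarityMatrix(np.eye(3) + 1.0, list("abc"))
        with pytest.raises(ValueError, match="zero off-diagonal spread"):
            align_scale(flat, ref)


class TestEmpiricalPvalues:
    def test_observed_above_all_null(self):
        null = np.arange(199, dtype=float).reshape(199, 1)
        p = empirical_pvalues(null, np.array([500.0]))
        assert p[0] == pytest.approx(1.0 / 200.0)

    def test_observed_below_all_null(self):
        null = np.arange(1, 200, dtype=float).reshape(199, 1)
        p = empirical_pvalues(null, np.array([0.0]))
        assert p[0] == pytest.approx(1.0)

    def test_ties_count_towards_null(self):
        null = np.full((50, 1), 3.0)
        p = empirical_pvalues(null, np.array([3.0]))
        assert p[0] == pytest.approx(1.0)

    def test_paired_observed_per_replicate(self):
        null = np.array([[1.0], [5.0], [2.0]])
        obs = np.array([[2.0], [2.0], [2.0]])
        # null >= obs in replicates 2 and 3
        assert empirical_pvalues(null, obs)[0] == pytest.approx(3.0 / 4.0)

    def test_rejects_empty(self):
        with pytest.raises(ValueError, match="replicate"):
            empirical_pvalues(np.empty((0, 2)), np.zeros(2))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_range_invariant(self, seed):
        rng = np.random.default_rng(seed)
        n_bs = int(rng.integers(1, 40))
        null = rng.normal(size=(n_bs, 6))
        obs = rng.normal(size=6)
        p = empirical_pvalues(null, obs)
        assert np.all(p >= 1.0 / (1 + n_bs) - 1e-12)
        assert np.all(p <= 1.0)


class TestPOfK:
    def test_point_mass_at_five(self):
        p = p_of_k(np.full(30, 5), k_max=8)
        assert p[4] == 1.0 and p[5] == 0.0
        assert p[0] == 1.0  # every k-hat is >= 1

    def test_matches_counting_oracle(self, rng):
        samples = rng.integers(1, 12, size=57)
        p = p_of_k(samples, k_max=12)
        for k in range(1, 13):
            assert p[k - 1] == pytest.approx((samples >= k).mean())
        assert np.all(np.diff(p) <= 0)  # non-increasing in k


class TestCombinedPc:
    def test_structure_certain_passes_through(self):
        assert combined_pc(1.0, 0.005) == pytest.approx(0.005)

    def test_no_structure_saturates(self):
        for pf in (0.0, 0.4, 1.0):
            assert combined_pc(0.0, pf) == pytest.approx(1.0)

    def test_unsurprising_statistic_saturates(self):
        for pk in (0.0, 0.5, 1.0):
            assert combined_pc(pk, 1.0) == pytest.approx(1.0)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError, match="0, 1"):
            combined_pc(1.5, 0.2)


class TestCrossvalidateK:
    def test_pure_noise_selects_low_complexity(self, rng):
        d2 = noise_frame(rng, 40, 200)
        k_hat = crossvalidate_k(d2, n_bs=20, k_max=20, seed=3)
        assert np.median(k_hat) <= 3

    def test_clustered_data_recovers_true_complexity(self):
        _, _, truth = sim_tree.make_pair(
            d=100, k=10, L=500, sigma0=0.005, scenario="null", seed=6
        )
        k_hat = crossvalidate_k(truth["data_target"], n_bs=12, k_max=20, seed=4)
        assert np.median(k_hat) >= 9

    def test_deterministic_given_seed(self, rng):
        d2 = noise_frame(rng, 15, 30)
        a = crossvalidate_k(d2, n_bs=5, k_max=10, seed=9)
        b = crossvalidate_k(d2, n_bs=5, k_max=10, seed=9)
        assert np.array_equal(a, b)


@pytest.fixture(scope="module")
def pair():
    _, _, truth = sim_tree.make_pair(
        d=30, k=5, L=80, sigma0=0.05, scenario="null", seed=21
    )
    return truth["data_reference"], truth["data_target"]


class TestPipeline:
    def test_rejects_zero_replicates(self, pair):
        with pytest.raises(ValueError, match="n_bs"):
            significance_pipeline(*pair, n_bs=0)

    def test_pvalues_within_regularized_range(self, pair):
        res = significance_pipeline(*pair, n_bs=19, k_max=8, seed=0)
        floor = 1.0 / 20.0
        for mat in (res.p_persist, res.p_c):
            v = mat.to_numpy()
            assert v.min() >= floor - 1e-12 and v.max() <= 1.0 + 1e-12
        assert np.all(np.diff(res.p_k) <= 1e-12)

    def test_invariant_to_global_feature_rescaling(self, pair):
        d1, d2 = pair
        res1 = significance_pipeline(d1, d2, n_bs=9, k_max=6, seed=2)
        res2 = significance_pipeline(d1, d2 * 37.0, n_bs=9, k_max=6, seed=2)
        assert np.allclose(
            res1.p_c.to_numpy(), res2.p_c.to_numpy(), atol=1e-10
        )

    def test_reproducible_and_thread_independent(self, pair):
        d1, d2 = pair
        serial = significance_pipeline(d1, d2, n_bs=8, k_max=6, seed=5)
        again = significance_pipeline(d1, d2, n_bs=8, k_max=6, seed=5)
        threaded = significance_pipeline(d1, d2, n_bs=8, k_max=6, seed=5, threads=2)
        assert np.array_equal(serial.p_c.to_numpy(), again.p_c.to_numpy())
        assert np.array_equal(serial.p_c.to_numpy(), threaded.p_c.to_numpy())

    def test_structural_change_recipient_not_less_significant(self):
        y1, y2, truth = sim_tree.make_pair(
            d=60, k=6, L=300, sigma0=0.05, scenario="B", seed=33
        )
        res = significance_pipeline(
            truth["data_reference"], truth["data_target"], n_bs=49, k_max=15, seed=1
        )
        rec = [s for s, c in truth["cluster_of"].items() if c == truth["recipient"]]
        mid = [k for k in res.k_values if 4 <= k <= 12]
        sig = res.p_c < 0.05
        rec_frac = sig.loc[rec, mid].to_numpy().mean()
        oth_frac = sig.drop(index=rec)[mid].to_numpy().mean()
        # power dominates: everything floods towards significance, but the
        # recipient cluster is never the better-predicted side, and its
        # excess persistence carries the discriminating signal
        assert rec_frac >= oth_frac - 1e-12
        from simcompare import excess_persistence, predict_target, svd_scan
        from simcompare.matrix import remove_diagonal

        scan = svd_scan(remove_diagonal(y1), k_max=15)
        cmp_res = predict_target(scan, remove_diagonal(y2))
        assert excess_persistence(cmp_res.persistence, rec).loc[4:12].mean() > 0

    def test_residual_level_pvalues_behind_flag(self, pair):
        d1, d2 = pair
        res = significance_pipeline(
            d1, d2, n_bs=7, k_max=4, seed=3, residual_pvalues=True
        )
        assert res.p_resid.shape == (30, 30, 4)
        assert res.p_resid.min() >= 1.0 / 8.0 - 1e-12
        assert res.p_resid.max() <= 1.0
        # off by default: the d^2 k array is a deliberate memory cost
        lean = significance_pipeline(d1, d2, n_bs=7, k_max=4, seed=3)
        assert lean.p_resid is None

    def test_save_writes_artifacts(self, pair, tmp_path):
        res = significance_pipeline(*pair, n_bs=5, k_max=4, seed=8)
        out = res.save(tmp_path / "sig")
        for name in ("p_persist.csv", "p_combined.csv", "p_k.csv", "manifest.json"):
            assert (out / name).exists()
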