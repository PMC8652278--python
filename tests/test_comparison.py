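"""Target prediction, residual persistence and stability under perturbation."""

import numpy as np
import pandas as pd
import pytest

from simcompare import (
    SimilarityMatrix,
    excess_persistence,
    mixture_scan,
    predict_target,
    svd_scan,
)
from simcompare.model import _sym_eig_sorted

from conftest import random_psd, random_symmetric


def _svd_residual_norm(y1, y2, k):
    """Independent route: project the target onto the top-k eigenspace of y1."""
    lam, vec = _sym_eig_sorted(y1)
    a = vec[:, :k]
    return np.linalg.norm(y2 - a @ (a.T @ y2 @ a) @ a.T, "fro"), lam


class TestPredictTarget:
    @pytest.mark.parametrize("method", ["svd", "mixture"])
    def test_self_prediction_reproduces_fit_residuals(self, rng, method):
        for _ in range(5):
            y = random_symmetric(rng, 9)
            if method == "svd":
                scan = svd_scan(y, k_max=6)
            else:
                scan = mixture_scan(y, k_max=4, restarts=1, seed=0, max_iter=300)
            cmp_res = predict_target(scan, y)
            assert np.allclose(cmp_res.total_loss, scan.fit_loss, atol=1e-7)

    def test_scaled_target_scales_residuals(self, rng):
        y1 = random_symmetric(rng, 8)
        scan = svd_scan(y1, k_max=8)
        a = 3.7
        cmp_res = predict_target(scan, a * y1)
        assert np.allclose(cmp_res.total_loss, a * scan.fit_loss, atol=1e-8)
        # at full rank the scaled target is reproduced exactly
        assert cmp_res.total_loss[-1] == pytest.approx(0.0, abs=1e-8)

    def test_full_complexity_predicts_anything(self, rng):
        y1 = random_symmetric(rng, 7)
        y2 = random_symmetric(rng, 7)
        scan = svd_scan(y1, k_max=7)
        cmp_res = predict_target(scan, y2)
        assert cmp_res.total_loss[-1] == pytest.approx(0.0, abs=1e-8)

    def test_reorders_target_by_label(self, dissimilarity):
        scan = svd_scan(dissimilarity, k_max=5)
        perm = list(reversed(dissimilarity.labels))
        shuffled = dissimilarity.reordered(perm)
        direct = predict_target(scan, dissimilarity)
        via_perm = predict_target(scan, shuffled)
        assert np.allclose(
            direct.persistence.to_numpy(), via_perm.persistence.to_numpy()
        )

    def test_rejects_disjoint_labels(self, rng, dissimilarity):
        scan = svd_scan(dissimilarity, k_max=3)
        other = SimilarityMatrix(
            random_symmetric(rng, 15), [f"x{i}" for i in range(15)]
        )
        with pytest.raises(ValueError, match="label sets differ"):
            predict_target(scan, other)

    def test_total_loss_monotone_for_svd(self, rng):
        y1, y2 = random_symmetric(rng, 10), random_symmetric(rng, 10)
        cmp_res = predict_target(svd_scan(y1), y2)
        assert np.all(np.diff(cmp_res.total_loss) <= 1e-10)

    def test_per_subject_persistence_may_rise_while_total_falls(self, rng):
        # a structurally anomalous subject can have its residual dragged up at
        # intermediate k even though the total always falls
        for seed in range(20):
            r = np.random.default_rng(seed)
            y1, y2 = random_symmetric(r, 12), random_symmetric(r, 12)
            cmp_res = predict_target(svd_scan(y1), y2)
            P = cmp_res.persistence.to_numpy()
            assert np.all(np.diff(cmp_res.total_loss) <= 1e-10)
            if (np.diff(P, axis=1) > 1e-12).any():
                break
        else:  # pragma: no cover
            pytest.fail("no per-subject non-monotonicity found in 20 draws")


class TestPersistence:
    def test_matches_brute_force_double_loop(self, rng):
        y1, y2 = random_symmetric(rng, 8), random_symmetric(rng, 8)
        cmp_res = predict_target(svd_scan(y1, k_max=5), y2)
        for k in cmp_res.k_values:
            resid = cmp_res.residual(k)
            for i in range(8):
                expected = sum(resid[i, j] ** 2 for j in range(8))
                assert cmp_res.persistence.iloc[i, k - 1] == pytest.approx(expected)

    def test_row_sums_equal_squared_total_loss(self, rng):
        y1, y2 = random_symmetric(rng, 9), random_symmetric(rng, 9)
        cmp_res = predict_target(svd_scan(y1, k_max=6), y2)
        sums = cmp_res.persistence.sum(axis=0).to_numpy()
        assert np.allclose(sums, cmp_res.total_loss**2)

    def test_zero_residuals_give_zero_matrix(self, rng):
        y1 = random_symmetric(rng, 6)
        cmp_res = predict_target(svd_scan(y1, k_max=6), y1)
        assert cmp_res.persistence[6].to_numpy() == pytest.approx(
            np.zeros(6), abs=1e-12
        )

    def test_residuals_symmetric_without_diagonal_model(self, rng):
        y1, y2 = random_symmetric(rng, 8), random_symmetric(rng, 8)
        cmp_res = predict_target(svd_scan(y1, k_max=4), y2)
        r = cmp_res.residual(3)
        assert np.allclose(r, r.T, atol=1e-8)


class TestDiagonalModelPrediction:
    def test_target_diagonal_refit_and_persistence_excludes_diagonal(self, rng):
        import pandas as pd

        from simcompare import StructuralModel, euclidean_dissimilarity

        df1 = pd.DataFrame(rng.normal(size=(10, 8)), index=[f"s{i}" for i in range(10)])
        df2 = pd.DataFrame(rng.normal(size=(10, 8)), index=[f"s{i}" for i in range(10)])
        y1, y2 = euclidean_dissimilarity(df1), euclidean_dissimilarity(df2)
        scan = StructuralModel(y1, k_max=3, diagonal_model=True).fit()
        assert scan.diagonal is not None
        cmp_res = predict_target(scan, y2)
        assert cmp_res.D2 is not None and len(cmp_res.D2[3]) == 10
        # persistence counts off-diagonal residuals only: the fitted D2
        # absorbs the self-similarity entirely
        for k in cmp_res.k_values:
            r = cmp_res.residual(k)
            off = r.copy()
            np.fill_diagonal(off, 0.0)
            assert np.allclose(
                cmp_res.persistence[k].to_numpy(), (off**2).sum(axis=1)
            )


class TestExcessPersistence:
    def test_constant_matrix_gives_zero(self):
        P = pd.DataFrame(np.full((6, 4), 2.5), index=list("abcdef"))
        assert np.allclose(excess_persistence(P, ["a", "b"]).to_numpy(), 0.0)

    def test_shifted_group_returns_shift(self):
        P = pd.DataFrame(np.ones((6, 3)), index=list("abcdef"))
        P.loc[["a", "b"]] += 4.0
        assert np.allclose(excess_persistence(P, ["a", "b"]).to_numpy(), 4.0)

    def test_rejects_empty_and_full_groups(self):
        P = pd.DataFrame(np.ones((3, 2)), index=list("abc"))
        with pytest.raises(ValueError, match="empty"):
            excess_persistence(P, [])
        with pytest.raises(ValueError, match="proper subset"):
            excess_persistence(P, ["a", "b", "c"])


class TestGroupResidualSummary:
    def test_singleton_partition_returns_squared_residuals(self, rng):
        y1, y2 = random_symmetric(rng, 5), random_symmetric(rng, 5)
        cmp_res = predict_target(svd_scan(y1, k_max=3), y2)
        part = {l: [l] for l in cmp_res.labels}
        out = cmp_res.group_residual_summary(part)
        for k in cmp_res.k_values:
            assert np.allclose(out[k].to_numpy(), cmp_res.residual(k) ** 2)

    def test_single_group_returns_total(self, rng):
        y1, y2 = random_symmetric(rng, 5), random_symmetric(rng, 5)
        cmp_res = predict_target(svd_scan(y1, k_max=3), y2)
        out = cmp_res.group_residual_summary({"all": cmp_res.labels})
        for j, k in enumerate(cmp_res.k_values):
            assert out[k].iloc[0, 0] == pytest.approx(cmp_res.total_loss[j] ** 2)

    def test_rejects_overlap_and_uncovered(self, rng):
        y1 = random_symmetric(rng, 4)
        cmp_res = predict_target(svd_scan(y1, k_max=2), y1)
        labels = cmp_res.labels
        with pytest.raises(ValueError, match="overlap"):
            cmp_res.group_residual_summary({"g": labels[:3], "h": labels[2:]})
        with pytest.raises(ValueError, match="cover"):
            cmp_res.group_residual_summary({"g": labels[:2]})


class TestStabilityUnderPerturbation:
    """Perturbing reference and target moves the residual norm by a bounded
    amount; trials run at unit Frobenius scale where the additive constants
    of the bounds are meaningful."""

    def _trial(self, rng, eps):
        d = int(rng.integers(6, 16))
        y1 = random_psd(rng, d, unit_norm=True)
        y2 = random_psd(rng, d, unit_norm=True)

        def perturb(y):
            p = rng.normal(size=(d, d))
            p = (p + p.T) / 2.0
            p *= eps / np.linalg.norm(p, "fro") * rng.uniform()
            return y + p

        k = int(rng.integers(1, d))
        return y1, y2, perturb(y1), perturb(y2), k

    def test_perturbation_bounds_hold(self, rng):
        n_target_perturb = n_structure = n_combined = 0
        for t in range(300):
            eps = (1e-3, 1e-2, 1e-1)[t % 3]
            y1, y2, y1p, y2p, k = self._trial(rng, eps)
            r, lam = _svd_residual_norm(y1, y2, k)
            # same structure, perturbed target
            rp_same_a, _ = _svd_residual_norm(y1, y2p, k)
            assert r <= rp_same_a + 2 * eps + 1e-12
            n_target_perturb += 1
            # perturbed structure, same target: bounded via the eigengap
            d = y1.shape[0]
            dk = lam[k - 1] - lam[k] if k < d else np.inf
            r_mixed, _ = _svd_residual_norm(y1p, y2, k)
            if dk > 1e-6:
                assert r <= r_mixed + 2**2.5 * eps / dk + 1e-12
                n_structure += 1
                # combined deviation bound, both matrices perturbed
                rp, lamp = _svd_residual_norm(y1p, y2p, k)
                dkp = lamp[k - 1] - lamp[k] if k < d else np.inf
                if min(dk, dkp) > 1e-6:
                    bound = (2 + 2**2.5 / min(dk, dkp)) * eps
                    assert abs(r - rp) <= bound + 1e-12
                    n_combined += 1
        assert n_target_perturb == 300 and n_structure > 250 and n_combined > 200
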