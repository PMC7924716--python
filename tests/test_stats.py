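import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from morphowarp import (
    DegenerateConfigurationError,
    allometric_regression,
    broken_stick_retain,
    broken_stick_thresholds,
    centroid_size,
    cva,
    gpa_align,
    manova_wilks,
    permutation_test,
    procrustes_anova,
    procrustes_distance,
    shape_pca,
)
from morphowarp.stats import GPAResult
from morphowarp.synthetic import simulate_nested_landmarks


def random_configs(seed, n, k, scale=10.0, noise=1.0):
    rng = np.random.default_rng(seed)
    base = rng.normal(size=(k, 3)) * scale
    return base[None] + rng.normal(size=(n, k, 3)) * noise


# ---------------------------------------------------------------------- #
# Centroid size
# ---------------------------------------------------------------------- #

class TestCentroidSize:
    def test_unit_square_closed_form(self):
        cfg = np.array([[0.5, 0.5, 0], [0.5, -0.5, 0], [-0.5, 0.5, 0], [-0.5, -0.5, 0]])
        assert centroid_size(cfg) == pytest.approx(np.sqrt(2.0))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(c=st.floats(0.01, 100.0), seed=st.integers(0, 10**6))
    def test_scales_linearly(self, c, seed):
        cfg = np.random.default_rng(seed).normal(size=(10, 3))
        assert centroid_size(c * cfg) == pytest.approx(c * centroid_size(cfg))

    def test_matches_brute_force(self, rng):
        cfg = rng.normal(size=(10, 3)) * 5
        cen = cfg.mean(axis=0)
        brute = np.sqrt(sum(np.sum((p - cen) ** 2) for p in cfg))
        assert centroid_size(cfg) == pytest.approx(brute)


# ---------------------------------------------------------------------- #
# GPA
# ---------------------------------------------------------------------- #

class TestGPA:
    def test_single_configuration(self, rng):
        cfg = rng.normal(size=(1, 8, 3)) * 10
        g = gpa_align(cfg)
        assert np.allclose(g.consensus, g.aligned[0])
        assert np.abs(g.aligned[0].mean(axis=0)).max() < 1e-9
        assert np.sqrt((g.aligned[0] ** 2).sum()) == pytest.approx(1.0, abs=1e-9)

    def test_similarity_copies_align_exactly(self, rng):
        A = rng.normal(size=(10, 3)) * 10
        R = Rotation.random(random_state=3).as_matrix()
        B = 2.5 * (A @ R.T) + np.array([1.0, 2.0, 3.0])
        g = gpa_align(np.array([A, B]))
        assert np.linalg.norm(g.aligned[0] - g.aligned[1]) < 1e-9

    def test_unit_size_and_centering_invariants(self):
        X = random_configs(2, 12, 9)
        g = gpa_align(X)
        for a in g.aligned:
            assert np.abs(a.mean(axis=0)).max() < 1e-9
            assert np.sqrt((a**2).sum()) == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(g.consensus, g.aligned.mean(axis=0))

    def test_optimality_against_random_rotations(self, rng):
        X = random_configs(5, 3, 6)
        g = gpa_align(X)
        best = np.sum((g.aligned - g.consensus) ** 2)
        centered = [x - x.mean(axis=0) for x in X]
        scaled = [x / np.sqrt((x**2).sum()) for x in centered]
        for _ in range(1000):
            rots = [Rotation.random(random_state=None).as_matrix() for _ in range(3)]
            trial = np.array([s @ r for s, r in zip(scaled, rots)])
            cons = trial.mean(axis=0)
            assert np.sum((trial - cons) ** 2) >= best - 1e-9

    def test_invariant_to_input_similarity_transform(self):
        X = random_configs(7, 6, 8)
        g1 = gpa_align(X)
        R = Rotation.from_euler("zyx", [11, 23, -5], degrees=True).as_matrix()
        X2 = 3.1 * (X @ R.T) + np.array([4.0, -2.0, 9.0])
        g2 = gpa_align(X2)
        # common orientation fixed by aligning consensus 1 onto consensus 2
        U, _, Vt = np.linalg.svd(g1.consensus.T @ g2.consensus)
        Rc = U @ np.diag([1, 1, np.sign(np.linalg.det(U @ Vt))]) @ Vt
        assert np.abs(g1.aligned @ Rc - g2.aligned).max() < 1e-7

    def test_degenerate_configuration_named(self):
        X = np.zeros((2, 5, 3))
        X[0] = np.random.default_rng(0).normal(size=(5, 3))
        with pytest.raises(DegenerateConfigurationError, match="1"):
            gpa_align(X)


# ---------------------------------------------------------------------- #
# PCA + broken stick
# ---------------------------------------------------------------------- #

class TestShapePCA:
    def test_identical_configs_zero_variance(self):
        X = np.repeat(random_configs(0, 1, 8), 5, axis=0)
        pca = shape_pca(gpa_align(X))
        assert pca.eigenvalues.sum() == pytest.approx(0.0, abs=1e-12)
        assert pca.n_retained_broken_stick == 0

    def test_single_shape_vector_gives_one_component(self, rng):
        base = rng.normal(size=(8, 3)) * 10
        v = rng.normal(size=(8, 3))
        # keep amplitudes small: GPA is nonlinear, so only the tangent-space
        # image of a one-parameter family is exactly one-dimensional
        amts = rng.normal(size=12) * 0.05
        X = np.array([base + a * v for a in amts])
        pca = shape_pca(gpa_align(X))
        assert pca.pct_variance[0] > 99.9
        assert (pca.eigenvalues > 1e-4 * pca.eigenvalues[0]).sum() == 1

    def test_matches_covariance_eigendecomposition(self):
        g = gpa_align(random_configs(3, 15, 7))
        Y = g.flat - g.consensus.reshape(1, -1)
        eig_oracle = np.sort(np.linalg.eigvalsh(Y.T @ Y / (len(Y) - 1)))[::-1]
        pca = shape_pca(g)
        m = min(len(pca.eigenvalues), 10)
        assert np.allclose(pca.eigenvalues[:m], eig_oracle[:m], atol=1e-12)

    def test_eigenvalue_sum_is_total_procrustes_variance(self):
        g = gpa_align(random_configs(4, 10, 6))
        pca = shape_pca(g)
        d2 = np.sum((g.flat - g.consensus.reshape(1, -1)) ** 2)
        assert pca.eigenvalues.sum() == pytest.approx(d2 / (len(g.flat) - 1), rel=1e-9)

    def test_rank_bound(self):
        n, k = 6, 20
        pca = shape_pca(gpa_align(random_configs(8, n, k)))
        nonzero = (pca.eigenvalues > 1e-9 * pca.eigenvalues[0]).sum()
        assert nonzero <= min(n - 1, 3 * k - 7)


class TestBrokenStick:
    def test_p3_closed_form(self):
        assert np.allclose(broken_stick_thresholds(3), [11 / 18, 5 / 18, 2 / 18])

    def test_dominant_spectrum_retains_one(self):
        assert broken_stick_retain(np.array([0.8, 0.15, 0.05])) == 1

    def test_uniform_spectrum_retains_zero(self):
        assert broken_stick_retain(np.array([1.0, 1.0, 1.0])) == 0


# ---------------------------------------------------------------------- #
# Procrustes ANOVA
# ---------------------------------------------------------------------- #

class TestProcrustesANOVA:
    @staticmethod
    def _design(X, n_pop, n_ind, n_rep):
        pops = np.repeat([f"p{i}" for i in range(n_pop)], n_ind * n_rep)
        inds = np.tile(np.repeat([f"i{j}" for j in range(n_ind)], n_rep), n_pop)
        reps = np.tile([f"r{r}" for r in range(n_rep)], n_pop * n_ind)
        return pops, inds, reps

    def test_identical_replicates_zero_error(self):
        X = random_configs(1, 6, 8)
        X = np.repeat(X, 2, axis=0)  # each individual digitized twice, identically
        pops, inds, reps = self._design(X, 2, 3, 2)
        t = procrustes_anova(gpa_align(X), pops, inds, reps)
        err = t[t.effect == "Error"]
        assert float(err.SS.iloc[0]) < 1e-12
        assert float(err.pct_var.iloc[0]) < 1e-6

    def test_all_identical_gives_zero_table_with_dfs(self):
        X = np.repeat(random_configs(2, 1, 8), 12, axis=0)
        pops, inds, reps = self._design(X, 2, 3, 2)
        t = procrustes_anova(gpa_align(X), pops, inds, reps)
        assert (t.SS < 1e-12).all()
        assert (t[t.effect != "Total"].DF > 0).all()

    def test_no_replication_raises(self):
        X = random_configs(3, 6, 8)
        pops, inds, reps = self._design(X, 2, 3, 1)
        with pytest.raises(ValueError, match="replication"):
            procrustes_anova(gpa_align(X), pops, inds, reps)

    def test_percent_variance_and_ss_sum(self):
        X, pops, inds, reps = simulate_nested_landmarks(3, 4, 2, seed=5)
        t = procrustes_anova(gpa_align(X), pops, inds, reps)
        effects = t[t.effect != "Total"]
        total = float(t[t.effect == "Total"].SS.iloc[0])
        assert effects.SS.sum() == pytest.approx(total, rel=1e-9)
        assert effects.pct_var.sum() == pytest.approx(100.0, abs=0.01)

    def test_variance_component_recovery(self):
        """Components 4 : 1 : 0.25 (pop : ind : error) must come back in the
        right order with a significant individual effect in >= 4/5 seeds."""
        eps = 0.02
        good = 0
        for seed in range(1, 6):
            X, pops, inds, reps = simulate_nested_landmarks(
                3, 10, 3, k=10,
                sigma_pop=2 * eps, sigma_ind=1 * eps, sigma_err=0.5 * eps,
                seed=seed,
            )
            t = procrustes_anova(gpa_align(X), pops, inds, reps)
            pv = dict(zip(t.effect, t.pct_var))
            P = dict(zip(t.effect, t.P))
            if (
                pv["Population"] > pv["Individuals"] > pv["Error"]
                and P["Individuals"] < 0.05
            ):
                good += 1
        assert good >= 4


# ---------------------------------------------------------------------- #
# Procrustes distances + permutation tests
# ---------------------------------------------------------------------- #

class TestPermutationTest:
    def test_identical_groups_distance_zero_p_one(self):
        X = np.repeat(random_configs(0, 1, 8), 8, axis=0)
        g = gpa_align(X)
        out = permutation_test(g, ["a"] * 4 + ["b"] * 4, n_perm=99, seed=1)
        assert out.distance.iloc[0] == pytest.approx(0.0, abs=1e-9)
        assert out.p.iloc[0] > 0.9

    def test_complete_separation_hits_p_floor(self, rng):
        base = rng.normal(size=(8, 3)) * 10
        v = rng.normal(size=(8, 3))
        X = np.array(
            [base + 0.01 * rng.normal(size=(8, 3)) for _ in range(10)]
            + [base + 1.0 * v + 0.01 * rng.normal(size=(8, 3)) for _ in range(10)]
        )
        g = gpa_align(X)
        out = permutation_test(g, ["a"] * 10 + ["b"] * 10, n_perm=999, seed=2)
        assert out.p.iloc[0] == pytest.approx(1.0 / 1000.0)

    def test_seeded_runs_reproduce(self):
        X = random_configs(9, 12, 6)
        g = gpa_align(X)
        a = permutation_test(g, ["a"] * 6 + ["b"] * 6, n_perm=200, seed=7)
        b = permutation_test(g, ["a"] * 6 + ["b"] * 6, n_perm=200, seed=7)
        assert a.equals(b)

    def test_distance_symmetricish(self, rng):
        A = rng.normal(size=(9, 3))
        B = rng.normal(size=(9, 3))
        assert procrustes_distance(A, B) == pytest.approx(
            procrustes_distance(B, A), rel=1e-6
        )


# ---------------------------------------------------------------------- #
# Allometry
# ---------------------------------------------------------------------- #

def _gpa_from_flat(Y, cs):
    n = len(Y)
    k = Y.shape[1] // 3
    return GPAResult(Y.reshape(n, k, 3), Y.mean(axis=0).reshape(k, 3),
                     np.asarray(cs, dtype=float), 1)


class TestAllometry:
    def test_size_independent_shape_predicts_nothing(self, rng):
        Y = rng.normal(size=(40, 30))
        cs = 50 + rng.normal(size=40) * 5
        res = allometric_regression(_gpa_from_flat(Y, cs), cs, n_perm=499, seed=3)
        assert res.pct_predicted < 10.0
        assert res.p_value > 0.1

    def test_exactly_linear_shape_predicts_everything(self, rng):
        cs = 50 + rng.normal(size=30) * 5
        v = rng.normal(size=24)
        Y = np.outer(cs, v)
        res = allometric_regression(_gpa_from_flat(Y, cs), cs, n_perm=99, seed=0)
        assert res.pct_predicted == pytest.approx(100.0, abs=1e-6)

    def test_recovers_injected_effect_size(self):
        rng = np.random.default_rng(11)
        n = 40
        cs = 50 + rng.normal(size=n) * 5
        xc = cs - cs.mean()
        v = rng.normal(size=30)
        v /= np.linalg.norm(v)
        noise = rng.normal(size=(n, 30))
        noise -= np.outer(noise @ v, v)
        target = 15.0
        alpha = np.sqrt(
            (target / 100 * (noise**2).sum() / (1 - target / 100)) / (xc**2).sum()
        )
        Y = noise + np.outer(alpha * xc, v)
        res = allometric_regression(_gpa_from_flat(Y, cs), cs, n_perm=499, seed=1)
        assert abs(res.pct_predicted - target) <= 4.0
        assert res.p_value < 0.05

    def test_zero_size_variance_rejected(self, rng):
        Y = rng.normal(size=(10, 12))
        with pytest.raises(ValueError, match="variance"):
            allometric_regression(_gpa_from_flat(Y, np.ones(10)), np.ones(10))


# ---------------------------------------------------------------------- #
# CVA
# ---------------------------------------------------------------------- #

class TestCVA:
    def test_two_groups_single_variate(self, rng):
        X = rng.normal(size=(20, 5))
        X[10:] += 3.0
        res = cva(X, ["a"] * 10 + ["b"] * 10)
        assert res.scores.shape[1] == 1

    def test_identical_means_zero_eigenvalues(self, rng):
        X = rng.normal(size=(30, 4))
        gr = np.repeat(["a", "b", "c"], 10)
        for g in "abc":  # force the group means to coincide exactly
            X[gr == g] -= X[gr == g].mean(axis=0)
        res = cva(X, gr)
        assert res.eigenvalues.max() < 1e-9

    def test_three_group_toy_matches_hand_eigenproblem(self):
        X = np.array(
            [[0.0, 0], [1, 0], [0, 1], [1, 1],
             [4, 0], [5, 0], [4, 1], [5, 1],
             [0, 4], [1, 4], [0, 5], [1, 5]]
        )
        gr = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        res = cva(X, gr)
        # hand computation: W = I/3 (per-axis within SS 1 per group, df 9);
        # B from the three group means about the grand mean, df 2
        mns = np.array([[0.5, 0.5], [4.5, 0.5], [0.5, 4.5]])
        gm = mns.mean(axis=0)
        Bm = 4 * sum(np.outer(m - gm, m - gm) for m in mns) / 2
        from scipy.linalg import eigh

        ev = eigh(Bm, np.eye(2) / 3, eigvals_only=True)[::-1]
        assert np.allclose(res.eigenvalues, ev, rtol=1e-9)

    def test_scores_unit_pooled_within_variance(self, rng):
        X = rng.normal(size=(24, 6))
        X[8:16, 0] += 4
        X[16:, 1] += 4
        gr = np.repeat(["a", "b", "c"], 8)
        res = cva(X, gr)
        pooled = np.zeros(res.scores.shape[1])
        for g in "abc":
            S = res.scores[np.array(gr) == g]
            pooled += ((S - S.mean(axis=0)) ** 2).sum(axis=0)
        assert np.allclose(pooled / (24 - 3), 1.0, atol=1e-9)


# ---------------------------------------------------------------------- #
# Wilks' MANOVA
# ---------------------------------------------------------------------- #

class TestManovaWilks:
    def test_null_groups_lambda_near_one(self, rng):
        Y = rng.normal(size=(45, 3))
        grp = np.repeat(["a", "b", "c"], 15)
        t = manova_wilks(Y, grp)
        row = t[t.effect == "Population"].iloc[0]
        assert row.wilks_lambda > 0.6
        assert row.P > 0.05

    def test_univariate_equals_classical_ancova_f(self, rng):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        y = rng.normal(size=30)
        grp = np.repeat(["a", "b", "c"], 10)
        cov = rng.normal(size=30)
        t = manova_wilks(y, grp, covariate=cov, with_interaction=False)
        d = pd.DataFrame({"y": y, "g": grp, "c": cov})
        fit = smf.ols("y ~ C(g) + c", d).fit()
        a = sm.stats.anova_lm(fit, typ=3)
        assert float(t[t.effect == "Population"].F.iloc[0]) == pytest.approx(
            float(a.loc["C(g)", "F"]), abs=1e-9
        )

    def test_separated_groups_small_lambda(self, rng):
        Y = rng.normal(size=(30, 3))
        grp = np.repeat(["a", "b", "c"], 10)
        Y[10:20, 0] += 8
        Y[20:, 1] += 8
        t = manova_wilks(Y, grp)
        row = t[t.effect == "Population"].iloc[0]
        assert row.wilks_lambda < 0.05
        assert row.P < 0.001

    def test_interaction_toggle(self, rng):
        Y = rng.normal(size=(36, 2))
        grp = np.repeat(["a", "b", "c"], 12)
        cov = rng.normal(size=36)
        with_int = manova_wilks(Y, grp, covariate=cov, with_interaction=True)
        without = manova_wilks(Y, grp, covariate=cov, with_interaction=False)
        assert "Population x CS" in set(with_int.effect)
        assert "Population x CS" not in set(without.effect)
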