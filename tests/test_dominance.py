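"""Dominance analysis: all-subsets R², general dominance weights,
bootstrap CIs and dominance relations, checked against independent
brute-force enumeration."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from alexidom import (
    all_subsets_r2,
    bootstrap_gdw_ci,
    dominance_analysis,
    dominance_relations,
    general_dominance_weights,
    gdw_shares,
)
from alexidom.dominance import SubsetR2Map


def brute_force_gdw(X, y):
    """Independent oracle: per-subset OLS refits via lstsq and a naive
    double loop over predictors and subset sizes."""
    n, p = X.shape
    yc = y - y.mean()
    tss = yc @ yc

    def r2(cols):
        if not cols:
            return 0.0
        Z = np.column_stack([np.ones(n), X[:, list(cols)]])
        resid = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
        return 1.0 - (resid @ resid) / tss

    out = np.zeros(p)
    for j in range(p):
        others = [q for q in range(p) if q != j]
        per_size = []
        for s in range(p):
            incs = [r2(S + (j,)) - r2(S) for S in combinations(others, s)]
            per_size.append(np.mean(incs))
        out[j] = np.mean(per_size)
    return out


def orthonormal_centered(n, p, rng):
    A = rng.normal(size=(n, p))
    A = A - A.mean(axis=0)
    Q, _ = np.linalg.qr(A)
    return Q


class TestAllSubsetsR2:
    def test_single_predictor_bivariate_identity(self, rng):
        x = rng.normal(size=(50, 1))
        y = 0.7 * x[:, 0] + rng.normal(size=50)
        m = all_subsets_r2(x, y)
        assert len(m.r2) == 2
        assert m.r2[0] == 0.0
        assert m.r2[1] == pytest.approx(np.corrcoef(x[:, 0], y)[0, 1] ** 2)

    def test_eight_predictors_256_subsets(self, rng):
        X = rng.normal(size=(60, 8))
        m = all_subsets_r2(X, rng.normal(size=60))
        assert len(m.r2) == 256
        assert m.r2_full == m.r2[255]

    def test_dual_solver_oracle_p3(self, rng):
        X = rng.normal(size=(40, 3))
        y = X @ [1.0, -0.5, 0.2] + rng.normal(size=40)
        m = all_subsets_r2(X, y)
        yc = y - y.mean()
        tss = yc @ yc
        for mask in range(8):
            cols = [j for j in range(3) if mask >> j & 1]
            if cols:
                Z = np.column_stack([np.ones(40), X[:, cols]])
                resid = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
                expected = 1.0 - resid @ resid / tss
            else:
                expected = 0.0
            assert m.r2[mask] == pytest.approx(expected, abs=1e-10)

    def test_monotone_under_inclusion(self, rng):
        X = rng.normal(size=(100, 5))
        y = rng.normal(size=100)
        m = all_subsets_r2(X, y)
        for mask in range(32):
            for j in range(5):
                if not mask >> j & 1:
                    assert m.r2[mask | 1 << j] >= m.r2[mask] - 1e-12

    def test_guards(self, rng):
        with pytest.raises(ValueError, match="p <= 20"):
            all_subsets_r2(rng.normal(size=(50, 21)), rng.normal(size=50))
        X = rng.normal(size=(30, 2))
        X = np.column_stack([X, X[:, 0]])
        with pytest.raises(np.linalg.LinAlgError):
            all_subsets_r2(X, rng.normal(size=30))


class TestGeneralDominanceWeights:
    def test_completeness_identity(self, rng):
        X = rng.normal(size=(80, 6))
        y = X @ rng.normal(size=6) + rng.normal(size=80)
        m = all_subsets_r2(X, y)
        gdw = general_dominance_weights(m)
        assert abs(gdw.sum() - m.r2_full) < 1e-10

    def test_orthogonal_closed_form(self, rng):
        Q = orthonormal_centered(120, 4, rng)
        y = rng.normal(size=120)
        gdw = general_dominance_weights(all_subsets_r2(Q, y))
        r2s = np.array([np.corrcoef(Q[:, j], y)[0, 1] ** 2 for j in range(4)])
        assert np.abs(gdw - r2s).max() < 1e-10

    def test_p2_closed_form(self, rng):
        X = rng.normal(size=(60, 2))
        X[:, 1] += 0.5 * X[:, 0]
        y = X @ [1.0, 0.5] + rng.normal(size=60)
        m = all_subsets_r2(X, y)
        r1, r2_, r12 = m.r2[1], m.r2[2], m.r2[3]
        gdw = general_dominance_weights(m)
        assert gdw[0] == pytest.approx(0.5 * (r1 + r12 - r2_), abs=1e-12)
        assert gdw[1] == pytest.approx(0.5 * (r2_ + r12 - r1), abs=1e-12)

    @pytest.mark.parametrize("p", [2, 3, 4])
    def test_brute_force_oracle(self, p, rng):
        X = rng.normal(size=(50, p)) @ (
            np.eye(p) + 0.4 * rng.normal(size=(p, p)))
        y = X @ rng.normal(size=p) + rng.normal(size=50)
        gdw = general_dominance_weights(all_subsets_r2(X, y))
        assert np.abs(gdw - brute_force_gdw(X, y)).max() < 1e-10

    def test_permutation_equivariance(self, rng):
        X = rng.normal(size=(70, 4))
        y = X @ [1, 0.5, -0.3, 0.1] + rng.normal(size=70)
        gdw = general_dominance_weights(all_subsets_r2(X, y))
        perm = [2, 0, 3, 1]
        gdw_p = general_dominance_weights(all_subsets_r2(X[:, perm], y))
        assert np.abs(gdw_p - gdw[perm]).max() < 1e-12

    def test_incomplete_map_rejected(self):
        with pytest.raises(ValueError):
            general_dominance_weights(
                SubsetR2Map(predictor_names=["a", "b"], r2=np.zeros(3)))

    @settings(deadline=None, max_examples=20)
    @given(st.integers(0, 10_000))
    def test_completeness_identity_property(self, seed):
        r = np.random.default_rng(seed)
        p = int(r.integers(2, 6))
        X = r.normal(size=(40, p))
        y = X @ r.normal(size=p) + r.normal(size=40)
        m = all_subsets_r2(X, y)
        gdw = general_dominance_weights(m)
        assert abs(gdw.sum() - m.r2_full) < 1e-10


class TestShares:
    def test_published_share_anchors(self):
        # printed GDW / R2: .116/.232 = 50.0%, .068/.183 = 37.1%,
        # .029/.232 = 12.5%, .020/.232 = 8.6%
        share, _, _ = gdw_shares(np.array([0.116, 0.029, 0.020]), 0.232)
        assert share[0] * 100 == pytest.approx(50.0, abs=0.1)
        assert share[1] * 100 == pytest.approx(12.5, abs=0.1)
        assert share[2] * 100 == pytest.approx(8.6, abs=0.1)
        share_m, _, _ = gdw_shares(np.array([0.068]), 0.183)
        assert share_m[0] * 100 == pytest.approx(37.1, abs=0.1)

    def test_ranks_and_tie_flag(self):
        share, rank, ties = gdw_shares(np.array([0.1, 0.3, 0.1]), 0.5)
        assert list(rank) == [2, 1, 3]  # tie broken by input order
        assert ties
        share2, rank2, ties2 = gdw_shares(np.array([0.3, 0.2, 0.1]), 0.6)
        assert list(rank2) == [1, 2, 3]
        assert not ties2
        assert share2.sum() == pytest.approx(1.0)

    def test_equal_gdws_all_tied(self):
        share, rank, ties = gdw_shares(np.full(4, 0.05), 0.2)
        assert np.allclose(share, 0.25)
        assert ties

    def test_zero_r2_rejected(self):
        with pytest.raises(ValueError):
            gdw_shares(np.array([0.0]), 0.0)


class TestBootstrap:
    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(60, 3))
        y = X @ [1, 0.5, 0.2] + rng.normal(size=60)
        a = bootstrap_gdw_ci(X, y, B=50, seed=9)
        b = bootstrap_gdw_ci(X, y, B=50, seed=9)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_noise_free_outcome_zero_width(self, rng):
        # single predictor: every resample has R^2 = 1, so the GDW
        # replicates are all identical and the CI has zero width
        x = rng.normal(size=(40, 1))
        y = 2.0 * x[:, 0]
        lo, hi, _ = bootstrap_gdw_ci(x, y, B=30, seed=2)
        assert np.abs(hi - lo).max() < 1e-10
        # with several correlated predictors only the total is pinned:
        # each replicate's GDWs still sum to R^2 = 1 exactly
        X = rng.normal(size=(40, 3))
        y3 = X @ [1.0, -1.0, 0.5]
        lo3, hi3, _ = bootstrap_gdw_ci(X, y3, B=30, seed=2)
        assert lo3.sum() <= 1.0 + 1e-10 and hi3.sum() >= 1.0 - 1e-10

    def test_b_below_two_rejected(self, rng):
        with pytest.raises(ValueError):
            bootstrap_gdw_ci(rng.normal(size=(30, 2)),
                             rng.normal(size=30), B=1)

    def test_coverage_orthogonal_population(self):
        # population GDW for orthogonal unit-variance predictors is
        # b_j^2 / var(y); nominal 95% percentile intervals checked over
        # 200 outer replicates at n = 400, B = 400 (MC SE ~1.5%)
        b = np.array([0.5, 0.3, 0.2])
        pop = b**2 / (b @ b + 1.0)
        rng = np.random.default_rng(424242)
        cover = np.zeros(3)
        outer = 200
        for _ in range(outer):
            X = rng.normal(size=(400, 3))
            y = X @ b + rng.normal(size=400)
            lo, hi, _ = bootstrap_gdw_ci(
                X, y, B=400, seed=int(rng.integers(2**31)))
            cover += (lo <= pop) & (pop <= hi)
        assert ((cover / outer >= 0.91) & (cover / outer <= 0.99)).all()


class TestRelations:
    def test_orthogonal_complete_dominance(self, rng):
        Q = orthonormal_centered(150, 2, rng)
        y = 1.0 * Q[:, 0] + 0.2 * Q[:, 1] + 0.5 * rng.normal(size=150)
        rel = dominance_relations(all_subsets_r2(Q, y))
        row = rel[(rel.dominator == "x1") & (rel.dominated == "x2")].iloc[0]
        assert row.complete and row.conditional and row.general

    def test_exchangeable_predictors_tie(self, rng):
        # stack each row with its column-swapped mirror: x1 and x2 are
        # exactly exchangeable in-sample, so neither can dominate and
        # the GDWs tie exactly
        A = rng.normal(size=(60, 2))
        yhalf = A @ [1.0, 0.4] + rng.normal(size=60)
        X = np.vstack([A, A[:, ::-1]])
        y = np.concatenate([yhalf, yhalf])
        m = all_subsets_r2(X, y)
        rel = dominance_relations(m)
        assert not rel["complete"].any()
        assert not rel["general"].any()
        gdw = general_dominance_weights(m)
        assert gdw[0] == pytest.approx(gdw[1], abs=1e-12)

    def test_brute_force_pairwise_oracle(self, rng):
        X = rng.normal(size=(50, 3))
        y = X @ [1.0, 0.6, 0.1] + rng.normal(size=50)
        m = all_subsets_r2(X, y)
        rel = dominance_relations(m)
        # independent pairwise check from the subset map itself
        for _, row in rel.iterrows():
            i = m.predictor_names.index(row.dominator)
            j = m.predictor_names.index(row.dominated)
            diffs = []
            for mask in range(8):
                if mask >> i & 1 or mask >> j & 1:
                    continue
                diffs.append((m.r2[mask | 1 << i] - m.r2[mask])
                             - (m.r2[mask | 1 << j] - m.r2[mask]))
            expected_complete = all(d >= -1e-12 for d in diffs) and any(
                d > 1e-12 for d in diffs)
            assert row.complete == expected_complete


class TestRecovery:
    def test_dif_strongest_trait_on_default_asd_plus_structure(self):
        """On cohorts with the published ASD+ correlation structure at
        n = 281, DIF should hold the largest GDW among the four trait
        predictors in nearly every replicate."""
        from alexidom import default_group_specs, generate_latent_cohort
        spec = default_group_specs()[0]
        wins = 0
        reps = 50
        for s in range(reps):
            lat = generate_latent_cohort(spec, seed=s)
            sub = lat.copy()
            sub["sex"] = (sub["sex"] == "male").astype(float)
            X = sub[["age", "sex", "piq", "viq", "aq", "dif", "ddf", "eot"]]
            gdw = general_dominance_weights(
                all_subsets_r2(X, sub["bdi"].to_numpy()))
            trait_gdw = gdw[4:]
            wins += trait_gdw.argmax() == 1  # dif
        assert wins / reps >= 0.9
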