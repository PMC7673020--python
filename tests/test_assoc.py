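"""Mixed-model machinery: kinship, compression, REML, scan, loci, PVE."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rilsweep.assoc import (
    AssocConfig,
    KinshipMatrix,
    compress_kinship,
    expand_group_kinship,
    kinship_vanraden,
    marker_pve,
    mlm_scan,
    reml_variance_components,
    significant_hits,
)
from rilsweep.core import trait_table
from rilsweep.simulate import RILSimConfig, TraitSimConfig, simulate_ril_population, \
    simulate_trait

from conftest import make_map, make_matrix


def ols_neglog10p(y, g):
    """Independent per-marker oracle: two-sided t-test from simple OLS."""
    res = stats.linregress(g, y)
    return -np.log10(res.pvalue)


class TestKinship:
    def test_duplicated_lines_share_kinship(self):
        rng = np.random.default_rng(0)
        calls = rng.choice([0, 1, 2], size=(5, 30))
        calls[3] = calls[1]  # lines 1 and 3 identical
        K = kinship_vanraden(make_matrix(calls)).values
        assert K[1, 1] == pytest.approx(K[3, 3], abs=1e-12)
        assert K[1, 3] == pytest.approx(K[1, 1], abs=1e-12)

    def test_hand_computed_three_by_two(self):
        # dosages: lines x markers [[0,2],[1,1],[2,0]]
        # p = (0.5, 0.5); W = dosage - 1; denom = 2*(0.25+0.25) = 1
        # K = W W' / 1 = [[2,0,-2],[0,0,0],[-2,0,2]]
        G = make_matrix([[0, 2], [1, 1], [2, 0]])
        K = kinship_vanraden(G).values
        want = np.array([[2.0, 0.0, -2.0], [0.0, 0.0, 0.0], [-2.0, 0.0, 2.0]])
        assert np.allclose(K, want, atol=1e-12)

    def test_symmetric_psd_on_random_matrices(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            calls = rng.choice([0, 1, 2], size=(12, 40))
            K = kinship_vanraden(make_matrix(calls)).values
            assert np.allclose(K, K.T, atol=1e-12)
            assert np.linalg.eigvalsh(K).min() > -1e-8

    def test_monomorphic_matrix_rejected(self):
        with pytest.raises(ValueError):
            kinship_vanraden(make_matrix(np.ones((4, 5)) * 2))


class TestCompression:
    def test_group_per_line_reproduces_kinship(self):
        rng = np.random.default_rng(2)
        K = kinship_vanraden(make_matrix(rng.choice([0, 1, 2], size=(10, 50))))
        groups, B = compress_kinship(K, 10)
        assert np.array_equal(groups, np.arange(10))
        assert np.array_equal(B, K.values)

    def test_single_group_is_grand_mean(self):
        rng = np.random.default_rng(3)
        K = kinship_vanraden(make_matrix(rng.choice([0, 1, 2], size=(8, 50))))
        groups, B = compress_kinship(K, 1)
        assert B.shape == (1, 1)
        assert B[0, 0] == pytest.approx(K.values.mean())

    def test_recovers_duplicated_line_blocks(self):
        rng = np.random.default_rng(4)
        a = rng.choice([0, 2], size=50)
        b = 2 - a  # maximally dissimilar line
        calls = np.vstack([a] * 4 + [b] * 4)
        K = kinship_vanraden(make_matrix(calls))
        groups, B = compress_kinship(K, 2)
        assert len(set(groups[:4])) == 1 and len(set(groups[4:])) == 1
        assert groups[0] != groups[4]

    def test_invalid_group_count_rejected(self):
        K = KinshipMatrix(["a", "b"], np.eye(2))
        with pytest.raises(ValueError):
            compress_kinship(K, 3)


def _reml_instance(seed, n=50, m=80, h2=0.5):
    rng = np.random.default_rng(seed)
    calls = rng.choice([0, 1, 2], size=(n, m))
    G = make_matrix(calls)
    K = kinship_vanraden(G)
    L = np.linalg.cholesky(K.values + 1e-6 * np.eye(n))
    y = np.sqrt(h2) * (L @ rng.standard_normal(n)) \
        + np.sqrt(1 - h2) * rng.standard_normal(n)
    return y, np.ones((n, 1)), K


class TestREML:
    def test_optimum_beats_dense_grid(self):
        """Optimizer's restricted log-likelihood is never below a dense
        2000-point grid oracle."""
        for seed in range(20):
            y, X, K = _reml_instance(seed)
            vc = reml_variance_components(y, X, K)
            grid = np.linspace(-5, 5, 2000)
            lam, U = np.linalg.eigh(K.values)
            lam = np.clip(lam, 0, None)
            from rilsweep.assoc import _reml_loglik
            _, logdet_xtx = np.linalg.slogdet(X.T @ X)
            best = max(_reml_loglik(g, lam, U.T @ y, U.T @ X, logdet_xtx)
                       for g in grid)
            assert vc.log_likelihood >= best - 1e-6

    def test_delta_matches_grid_argmax(self):
        for seed in range(20):
            y, X, K = _reml_instance(100 + seed)
            vc = reml_variance_components(y, X, K)
            grid = np.linspace(-5, 5, 2001)
            lam, U = np.linalg.eigh(K.values)
            lam = np.clip(lam, 0, None)
            from rilsweep.assoc import _reml_loglik
            _, logdet_xtx = np.linalg.slogdet(X.T @ X)
            ll = [_reml_loglik(g, lam, U.T @ y, U.T @ X, logdet_xtx) for g in grid]
            assert abs(np.log10(vc.delta) - grid[int(np.argmax(ll))]) <= 0.05

    def test_null_heritability_near_zero(self):
        """With no genetic signal the fitted genetic-variance share is small
        in the large majority of replicates.  Kinship comes from simulated
        RIL genotypes: linkage gives the relationship matrix the eigenvalue
        spread that makes heritability identifiable (with an unstructured
        iid-marker kinship the null estimate is far more dispersed)."""
        mp = make_map(n_markers=100, spacing_cM=1.0)
        hits = 0
        for seed in range(100):
            cfg = RILSimConfig(n_lines=150, n_chrom=1, markers_per_chrom=100,
                               seed=seed)
            K = kinship_vanraden(simulate_ril_population(mp, cfg))
            y = np.random.default_rng(3000 + seed).standard_normal(150)
            vc = reml_variance_components(y, np.ones((150, 1)), K)
            h2 = vc.sigma_g2 / (vc.sigma_g2 + vc.sigma_e2)
            hits += h2 < 0.05
        assert hits >= 90

    def test_rank_deficient_covariates_rejected(self):
        y, X, K = _reml_instance(7)
        X2 = np.hstack([X, X])
        with pytest.raises(ValueError):
            reml_variance_components(y, X2, K)

    def test_components_consistent(self):
        y, X, K = _reml_instance(11)
        vc = reml_variance_components(y, X, K)
        assert vc.delta == pytest.approx(vc.sigma_e2 / vc.sigma_g2, rel=1e-9)
        assert np.isfinite(vc.log_likelihood)


def _scan_instance(seed, n=60, m=40):
    rng = np.random.default_rng(seed)
    calls = rng.choice([0, 1, 2], size=(n, m))
    G = make_matrix(calls)
    y = trait_table(G.line_ids, rng.standard_normal(n) + 0.2 * calls[:, 3])
    return G, y


class TestScan:
    def test_identity_kinship_collapses_to_ols(self):
        for seed in range(5):
            G, y = _scan_instance(seed)
            K = KinshipMatrix(list(G.line_ids), np.eye(G.n_lines))
            res = mlm_scan(G, y, K)
            yv = y["value"].to_numpy()
            for j, mid in enumerate(G.marker_ids):
                want = ols_neglog10p(yv, G.calls[:, j].astype(float))
                got = res.loc[res["marker_id"] == mid, "neg_log10_p"].iloc[0]
                assert abs(got - want) < 1e-6

    def test_scaled_identity_kinship_matches_ols(self):
        G, y = _scan_instance(42)
        K = KinshipMatrix(list(G.line_ids), 3.7 * np.eye(G.n_lines))
        res = mlm_scan(G, y, K)
        yv = y["value"].to_numpy()
        want = np.array([ols_neglog10p(yv, G.calls[:, j].astype(float))
                         for j in range(G.n_markers)])
        assert np.max(np.abs(res["neg_log10_p"].to_numpy() - want)) < 1e-6

    def test_no_compression_equals_full_group_count(self):
        G, y = _scan_instance(8)
        K = kinship_vanraden(G)
        res_n = mlm_scan(G, y, K, AssocConfig(n_groups="n"))
        res_g = mlm_scan(G, y, K, AssocConfig(n_groups=G.n_lines))
        assert np.max(np.abs(res_n["p_value"].to_numpy()
                             - res_g["p_value"].to_numpy())) < 1e-10

    def test_marker_permutation_invariance(self):
        G, y = _scan_instance(15)
        K = kinship_vanraden(G)
        res = mlm_scan(G, y, K).set_index("marker_id")
        rng = np.random.default_rng(0)
        perm = rng.permutation(G.n_markers)
        from rilsweep.core import GenotypeMatrix
        Gp = GenotypeMatrix(list(G.line_ids),
                            [G.marker_ids[j] for j in perm], G.calls[:, perm])
        res_p = mlm_scan(Gp, y, K).set_index("marker_id")
        for mid in G.marker_ids:
            assert res.loc[mid, "p_value"] == pytest.approx(
                res_p.loc[mid, "p_value"], rel=1e-12)

    def test_exact_scan_agrees_with_direct_per_marker_reml(self):
        """The vectorized exact path (marker in the fixed effects, delta
        re-profiled per marker on a grid) reproduces the p-values obtained
        by running the scalar REML optimizer marker by marker."""
        from rilsweep.assoc import _emma_delta_grid
        G, y = _scan_instance(55, n=50, m=12)
        K = kinship_vanraden(G)
        res = mlm_scan(G, y, K, AssocConfig(p3d=False))
        yv = y["value"].to_numpy()
        X = np.ones((G.n_lines, 1))
        lam, U = np.linalg.eigh(K.values)
        lam = np.clip(lam, 0, None)
        for j, mid in enumerate(G.marker_ids):
            g = G.calls[:, j].astype(float)
            vcj = reml_variance_components(yv, np.column_stack([X, g]), K)
            # GLS t-test at the per-marker REML delta
            w = 1.0 / np.sqrt(lam + vcj.delta)
            yw, Xw, gw = (U.T @ yv) * w, (U.T @ X) * w[:, None], (U.T @ g) * w
            Q, _ = np.linalg.qr(Xw)
            yr_, gr_ = yw - Q @ (Q.T @ yw), gw - Q @ (Q.T @ gw)
            eff = (gr_ @ yr_) / (gr_ @ gr_)
            rss = yr_ @ yr_ - eff**2 * (gr_ @ gr_)
            t = eff / np.sqrt(rss / (G.n_lines - 2) / (gr_ @ gr_))
            want = 2 * stats.t.sf(abs(t), G.n_lines - 2)
            got = res.set_index("marker_id").loc[mid, "p_value"]
            assert np.log10(got) == pytest.approx(np.log10(want), abs=0.02)

    def test_constant_markers_skipped_with_reason(self):
        G, y = _scan_instance(23)
        G.calls[:, 5] = 2
        K = kinship_vanraden(G)
        res = mlm_scan(G, y, K)
        assert G.marker_ids[5] in res.attrs["skipped"]
        assert G.marker_ids[5] not in set(res["marker_id"])

    def test_misaligned_lines_error_names_offenders(self):
        G, y = _scan_instance(31)
        y = y.iloc[:-1]
        K = kinship_vanraden(G)
        with pytest.raises(ValueError, match=G.line_ids[-1]):
            mlm_scan(G, y, K)


class TestHitsAndPVE:
    def _result(self, pvals, mp):
        return pd.DataFrame({
            "marker_id": mp.marker_ids[: len(pvals)],
            "effect": 1.0, "se": 1.0,
            "p_value": pvals,
            "neg_log10_p": -np.log10(pvals),
            "n_used": 100,
        })

    def test_fixed_threshold_application(self):
        mp = make_map(n_markers=4)
        res = self._result([1e-7, 1e-5, 0.5, 0.9], mp)
        loci = significant_hits(res, mp)
        assert len(loci) == 1 and loci["peak_marker"].iloc[0] == mp.marker_ids[0]

    def test_nearby_hits_merge_into_one_locus(self):
        mp = make_map(n_markers=6, spacing_bp=50_000)  # 50 kb apart
        res = self._result([1e-8, 0.5, 1e-7, 0.5, 0.5, 0.5], mp)
        loci = significant_hits(res, mp)
        assert len(loci) == 1
        assert loci["n_markers"].iloc[0] == 2
        assert loci["peak_marker"].iloc[0] == mp.marker_ids[0]

    def test_distant_hits_stay_separate(self):
        mp = make_map(n_markers=3, spacing_bp=2_000_000)
        res = self._result([1e-8, 0.5, 1e-7], mp)
        loci = significant_hits(res, mp)
        assert len(loci) == 2

    def test_empty_result_empty_loci(self):
        mp = make_map(n_markers=3)
        res = self._result([0.5, 0.6, 0.7], mp)
        assert significant_hits(res, mp).empty

    def test_pve_perfect_and_null(self):
        rng = np.random.default_rng(17)
        g = rng.choice([0.0, 1.0, 2.0], size=219)
        assert marker_pve(trait_table([f"L{i}" for i in range(219)], g), g) \
            == pytest.approx(1.0)
        y = trait_table([f"L{i}" for i in range(219)], rng.standard_normal(219))
        assert marker_pve(y, g) < 0.05

    def test_pve_recovers_simulated_fraction(self):
        mp = make_map(n_markers=50)
        vals = []
        for rep in range(100):
            cfg = RILSimConfig(n_lines=219, n_chrom=1, markers_per_chrom=50,
                               seed=4000 + rep)
            G = simulate_ril_population(mp, cfg)
            y = simulate_trait(G, TraitSimConfig(qtl_marker=mp.marker_ids[25],
                                                 pve_qtl=0.19, seed=5000 + rep))
            vals.append(marker_pve(y, G.dosage()[:, 25]))
        assert np.mean(vals) == pytest.approx(0.19, abs=0.02)

    def test_constant_dosage_rejected(self):
        y = trait_table(["a", "b"], [1.0, 2.0])
        with pytest.raises(ValueError):
            marker_pve(y, np.array([1.0, 1.0]))
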