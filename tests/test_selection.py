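import numpy as np
import pytest

from plsmc.selection import (
    RELIABILITY_SENTINEL,
    SelectionParams,
    mc_reliability,
    permutation_vip_fdr,
    run_selection,
    select_reliability_cutoff,
)
from plsmc.synthetic_data import SimulationConfig, simulate_dataset


class TestPermutationFDR:
    def test_planted_gene_has_max_vip_and_tiny_fdr(self, planted_problem):
        X, y, j = planted_problem
        vip_obs, fdr = permutation_vip_fdr(X, y, A=2, n_perm=200, seed=4)
        assert int(np.argmax(vip_obs)) == j
        assert fdr[j] < 0.05

    def test_zero_permutations_errors(self, planted_problem):
        X, y, _ = planted_problem
        with pytest.raises(ValueError):
            permutation_vip_fdr(X, y, A=1, n_perm=0, seed=0)

    def test_fdr_monotone_in_vip(self, planted_problem):
        X, y, _ = planted_problem
        vip_obs, fdr = permutation_vip_fdr(X, y, A=2, n_perm=100, seed=1)
        order = np.argsort(-vip_obs)
        assert (np.diff(fdr[order]) >= -1e-15).all()
        assert fdr[np.argmax(vip_obs)] == fdr.min()

    def test_deterministic_given_seed(self, planted_problem):
        X, y, _ = planted_problem
        a = permutation_vip_fdr(X, y, A=1, n_perm=50, seed=8)
        b = permutation_vip_fdr(X, y, A=1, n_perm=50, seed=8)
        np.testing.assert_array_equal(a[1], b[1])

    def test_null_calibration_small(self, rng):
        """Pure-noise data: almost no gene should clear fdr < 0.05."""
        fracs = []
        for rep in range(10):
            X = rng.normal(size=(40, 100))
            y = rng.normal(size=40)
            _, fdr = permutation_vip_fdr(X, y, A=2, n_perm=100, seed=rep)
            fracs.append((fdr < 0.05).mean())
        assert np.mean(fracs) <= 0.01

    def test_more_permutations_reduce_fdr_spread(self, planted_problem):
        """Monte-Carlo noise of the fdr estimate shrinks as B grows."""
        X, y, _ = planted_problem
        spread = {}
        for B in (100, 400):
            reps = np.stack([
                permutation_vip_fdr(X, y, A=1, n_perm=B, seed=s)[1]
                for s in range(6)
            ])
            null_genes = reps.mean(axis=0) > 0.05  # excludes the planted gene
            spread[B] = reps.std(axis=0)[null_genes].mean()
        assert spread[400] < spread[100]


class TestMCReliability:
    def test_planted_gene_most_reliable(self, rng):
        hits = 0
        for rep in range(20):
            r = np.random.default_rng(rep)
            n, p = 40, 30
            y = r.uniform(0, 10, n)
            X = r.normal(size=(n, p))
            X[:, 0] = (y - y.mean()) / y.std()
            rel = mc_reliability(X, y, np.arange(p), A=2, n_subsets=40,
                                 fraction=0.5, seed=rep)
            if np.argmax(np.abs(rel)) == 0:
                hits += 1
        assert hits >= 19

    def test_single_subset_errors(self, planted_problem):
        X, y, _ = planted_problem
        with pytest.raises(ValueError, match="n_subsets"):
            mc_reliability(X, y, np.arange(5), A=1, n_subsets=1, seed=0)

    def test_bad_fraction_errors(self, planted_problem):
        X, y, _ = planted_problem
        with pytest.raises(ValueError, match="fraction"):
            mc_reliability(X, y, np.arange(5), A=1, fraction=1.5, seed=0)

    def test_zero_spread_hits_sentinel(self, monkeypatch):
        """Degenerate subsets (identical coefficients) map to the signed
        sentinel so the gene survives any finite cutoff."""
        import plsmc.selection as sel

        class FakeModel:
            b = np.array([2.0, -3.0])

        monkeypatch.setattr(sel, "fit_pls1", lambda *a, **k: FakeModel())
        rel = sel.mc_reliability(np.zeros((20, 2)), np.arange(20.0),
                                 np.arange(2), A=1, n_subsets=5, seed=0)
        np.testing.assert_array_equal(
            rel, [RELIABILITY_SENTINEL, -RELIABILITY_SENTINEL])

    def test_invariant_to_gene_order(self, planted_problem):
        X, y, _ = planted_problem
        idx = np.arange(10)
        rel = mc_reliability(X, y, idx, A=2, n_subsets=30, seed=3)
        perm = np.array([3, 1, 4, 0, 2, 9, 8, 7, 6, 5])
        rel_perm = mc_reliability(X[:, perm], y, idx, A=2, n_subsets=30,
                                  seed=3)
        np.testing.assert_allclose(rel[perm], rel_perm, rtol=1e-10)


class TestReliabilityCutoff:
    def test_cutoff_separates_planted_from_noise(self):
        r = np.random.default_rng(12)
        n, p, k = 60, 200, 5
        y = r.uniform(0, 10, n)
        z = (y - y.mean()) / y.std()
        X = r.normal(size=(n, p))
        for j in range(k):
            X[:, j] = 2.0 * z + r.normal(scale=0.5, size=n)
        idx = np.arange(p)
        rel = mc_reliability(X, y, idx, A=2, n_subsets=40, seed=1)
        cutoff, curve = select_reliability_cutoff(X, y, idx, rel, A=2, seed=2)
        kept = idx[np.abs(rel) > cutoff]
        planted_kept = (kept < k).sum()
        noise_kept = (kept >= k).sum()
        assert planted_kept >= 4
        assert noise_kept <= 0.1 * (p - k)

    def test_all_equal_reliability_warns(self, planted_problem):
        X, y, _ = planted_problem
        rel = np.full(5, 2.0)
        with pytest.warns(UserWarning):
            cutoff, _ = select_reliability_cutoff(X, y, np.arange(5), rel,
                                                  A=1, seed=0)
        assert cutoff == 2.0

    def test_rmsecv_tie_breaks_to_larger_cutoff(self, monkeypatch):
        import plsmc.selection as sel

        monkeypatch.setattr(sel, "rmsecv", lambda *a, **k: 1.0)
        rel = np.array([1.0, 2.0, 3.0, 4.0])
        X = np.random.default_rng(0).normal(size=(16, 4))
        y = np.arange(16.0)
        cutoff, curve = select_reliability_cutoff(
            X, y, np.arange(4), rel, A=1, seed=0, grid_size=4)
        # every cutoff ties at rmsecv=1; the largest feasible wins
        assert cutoff == curve["cutoff"].max()


class TestRunSelection:
    def test_recovers_planted_genes(self):
        cfg = SimulationConfig(n_samples=120, n_genes=300, n_informative=15,
                               seed=5)
        ds, truth = simulate_dataset(cfg)
        res = run_selection(ds, SelectionParams(n_perm=100, n_subsets=30,
                                                seed=2))
        sel = {g for g, s in zip(res.gene_ids, res.selected) if s}
        tp = len(sel & truth.informative_gene_ids)
        assert tp / len(truth.informative_gene_ids) >= 0.8
        assert (len(sel) - tp) / max(len(sel), 1) <= 0.2

    def test_null_study_selects_almost_nothing(self):
        empties = []
        for seed in range(3):
            cfg = SimulationConfig(n_samples=40, n_genes=120, n_informative=0,
                                   seed=seed)
            ds, _ = simulate_dataset(cfg)
            res = run_selection(ds, SelectionParams(n_perm=100, n_subsets=20,
                                                    A_max=4, seed=seed))
            empties.append(int(res.selected.sum()))
        assert all(s <= 0.01 * 120 for s in empties)

    def test_selected_subset_of_candidates(self):
        cfg = SimulationConfig(n_samples=60, n_genes=150, n_informative=8,
                               seed=9)
        ds, _ = simulate_dataset(cfg)
        res = run_selection(ds, SelectionParams(n_perm=60, n_subsets=20,
                                                seed=1))
        assert not (res.selected & ~res.candidate).any()

    def test_deterministic_given_seed(self):
        cfg = SimulationConfig(n_samples=40, n_genes=80, n_informative=5,
                               seed=3)
        ds, _ = simulate_dataset(cfg)
        params = SelectionParams(n_perm=50, n_subsets=15, A_max=4, seed=6)
        a = run_selection(ds, params)
        b = run_selection(ds, params)
        assert a.to_frame().equals(b.to_frame())
        assert a.A_star == b.A_star and a.cutoff == b.cutoff

    def test_paper_order_also_runs(self):
        cfg = SimulationConfig(n_samples=60, n_genes=100, n_informative=8,
                               seed=4)
        ds, truth = simulate_dataset(cfg)
        res = run_selection(ds, SelectionParams(n_perm=60, n_subsets=20,
                                                order="paper", seed=2))
        sel = {g for g, s in zip(res.gene_ids, res.selected) if s}
        assert len(sel & truth.informative_gene_ids) >= 4

    def test_default_parameters_match_reference_settings(self):
        p = SelectionParams()
        assert (p.alpha, p.n_perm, p.n_subsets, p.subset_fraction, p.folds) \
            == (0.05, 1000, 100, 0.5, 4)
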