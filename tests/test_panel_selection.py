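import numpy as np
import pytest

import panelest as pe
from panelest.panel_selection import (FirstFitError, _grad_f,
                                      _group_soft_threshold)
from test_generative_model import make_params


def rates_from(lam, nu, eta, lengths_arr, target=("other", "indel"), K=None):
    G = len(lam)
    params = make_params([0.0], lam, nu, eta)
    cat = pe.GeneCatalog(params.genes, np.asarray(lengths_arr, float))
    spec = pe.BiomarkerSpec("x", target)
    r = pe.normalized_rates(params, cat, spec)
    if K is not None:
        r = r.with_K(K)
    return r, cat, spec, params


class TestNormalizedRates:
    def test_uniform_symmetric_case(self):
        r, *_ = rates_from(np.zeros(3), [0.0, 0.0], np.zeros((3, 2)),
                           [10.0, 10.0, 10.0])
        np.testing.assert_allclose(r.p, 1.0 / 6.0)

    def test_target_mass_is_one_for_any_params(self):
        rng = np.random.default_rng(0)
        lam = rng.normal(size=5)
        eta = np.c_[np.zeros(5), rng.normal(size=5)]
        r, *_ = rates_from(lam, [0.0, rng.normal()], eta,
                           rng.uniform(50, 500, 5))
        assert r.p[:, r.target_mask].sum() == pytest.approx(1.0)

    def test_two_gene_single_group_hand_case(self):
        params = make_params([0.0], [0.0, 0.0], [0.0], np.zeros((2, 1)),
                             groups=("other",))
        cat = pe.GeneCatalog(("g0", "g1"), np.array([1.0, 2.0]))
        r = pe.normalized_rates(params, cat, pe.BiomarkerSpec("x", ("other",)))
        np.testing.assert_allclose(r.p[:, 0], [1 / 3, 2 / 3])

    def test_independent_of_mu(self):
        lam = np.array([0.3, -0.7])
        eta = np.zeros((2, 2))
        pa = make_params([1.0], lam, [0.0, -2.0], eta)
        pb = make_params([-4.0], lam, [0.0, -2.0], eta)
        cat = pe.GeneCatalog(pa.genes, np.array([100.0, 300.0]))
        spec = pe.BiomarkerSpec("x", ("other", "indel"))
        np.testing.assert_allclose(pe.normalized_rates(pa, cat, spec).p,
                                   pe.normalized_rates(pb, cat, spec).p)


class TestBiasPenaltyK:
    def test_mu0_shift_scales_K(self):
        _, cat, spec, params = rates_from(np.zeros(2), [0.0, -1.0],
                                          np.zeros((2, 2)), [100.0, 200.0])
        K1 = pe.bias_penalty_K(params, cat, spec, mu0=0.5)
        K2 = pe.bias_penalty_K(params, cat, spec, mu0=0.5 + np.log(2))
        assert K2 == pytest.approx(2 * K1)

    def test_K_equals_expected_biomarker_at_mu0(self):
        from panelest.prediction import expected_biomarker_mass
        _, cat, spec, params = rates_from([0.2, -0.3], [0.0, -2.0],
                                          np.c_[np.zeros(2), [0.1, 0.0]],
                                          [150.0, 250.0])
        mu0 = 1.3
        K = pe.bias_penalty_K(params, cat, spec, mu0)
        assert K == pytest.approx(
            np.exp(mu0) * expected_biomarker_mass(params, cat, spec))

    def test_infinite_sentinel(self):
        _, cat, spec, params = rates_from(np.zeros(2), [0.0, 0.0],
                                          np.zeros((2, 2)), [1.0, 1.0])
        assert pe.bias_penalty_K(params, cat, spec, np.inf) == np.inf


class TestObjectiveF:
    def test_identity_weights_give_zero(self):
        r, *_ = rates_from(np.array([0.5, -0.5]), [0.0, -1.0],
                           np.zeros((2, 2)), [100.0, 50.0], K=7.0)
        w = pe.WeightMatrix(r.genes, r.groups, r.target_indicator)
        assert pe.objective_f(w, r) == pytest.approx(0.0, abs=1e-12)

    def test_zero_weights_give_one_plus_K(self):
        K = 3.25
        r, *_ = rates_from(np.zeros(3), [0.0, -1.0], np.zeros((3, 2)),
                           [10.0, 20.0, 30.0], K=K)
        w = pe.WeightMatrix(r.genes, r.groups, np.zeros((3, 2)))
        assert pe.objective_f(w, r) == pytest.approx(1.0 + K)

    def test_hand_instance_matches_symbolic(self):
        # 2 genes x 2 groups, target = first group only
        p = np.array([[0.25, 0.10], [0.75, 0.40]])
        r = pe.NormalizedRates(("g0", "g1"), ("other", "indel"), p,
                               np.array([True, False]), K=2.0)
        W = np.array([[0.5, -1.0], [2.0, 0.25]])
        expected = (0.25 * 0.25 + 0.75 * 1.0          # (1-w)^2 on target
                    + 0.10 * 1.0 + 0.40 * 0.0625      # w^2 off target
                    + 2.0 * (1 - (p * W).sum()) ** 2)
        w = pe.WeightMatrix(r.genes, r.groups, W)
        assert pe.objective_f(w, r) == pytest.approx(expected)


def ista_oracle(r, lengths, kappa2, iters=300_000, tol=1e-13):
    """Plain (unaccelerated) proximal gradient, run to a tiny gap."""
    p, t, K = r.p, r.target_indicator, r.K
    L = 2 * p.max() + 2 * K * (p ** 2).sum()
    step = 1.0 / L
    penw = kappa2 * lengths.lengths
    W = np.zeros_like(p)
    prev = np.inf
    for i in range(iters):
        W = _group_soft_threshold(W - step * _grad_f(W, p, t, K), step * penw)
        if i % 200 == 0:
            obj = ((p * (W - t) ** 2).sum() + K * (1 - (p * W).sum()) ** 2
                   + (penw * np.linalg.norm(W, axis=1)).sum())
            if abs(prev - obj) < tol * (1 + abs(obj)):
                break
            prev = obj
    return W, obj


def penalized_objective(W, r, lengths, kappa2):
    p, t, K = r.p, r.target_indicator, r.K
    return float((p * (W - t) ** 2).sum() + K * (1 - (p * W).sum()) ** 2
                 + kappa2 * (lengths.lengths * np.linalg.norm(W, axis=1)).sum())


@pytest.fixture
def five_gene_rates():
    rng = np.random.default_rng(42)
    lam = rng.normal(0, 0.8, 5)
    eta = np.c_[np.zeros(5), rng.normal(0, 0.5, 5)]
    r, cat, spec, params = rates_from(lam, [0.0, -2.5], eta,
                                      rng.uniform(100, 2000, 5), K=5.0)
    return r, cat


class TestFirstFit:
    def test_kappa2_zero_recovers_identity(self, five_gene_rates):
        r, cat = five_gene_rates
        w = pe.first_fit(r, cat, kappa2=0.0, kkt_stop=1e-10, kkt_tol=1e-10)
        np.testing.assert_allclose(w.w, r.target_indicator, atol=1e-6)

    def test_above_full_shrinkage_gives_zero(self, five_gene_rates):
        r, cat = five_gene_rates
        kmax = pe.full_shrinkage_kappa2(r, cat)
        w = pe.first_fit(r, cat, kappa2=kmax * 1.01)
        assert np.all(w.w == 0.0)
        assert len(pe.panel_of(w, cat)) == 0

    @pytest.mark.parametrize("frac", [0.3, 0.05, 0.005])
    def test_matches_ista_oracle(self, five_gene_rates, frac):
        r, cat = five_gene_rates
        kappa2 = frac * pe.full_shrinkage_kappa2(r, cat)
        w = pe.first_fit(r, cat, kappa2)
        _, obj_oracle = ista_oracle(r, cat, kappa2)
        obj = penalized_objective(w.w, r, cat, kappa2)
        assert obj == pytest.approx(obj_oracle, rel=1e-6)

    def test_exclude_rows_exactly_zero_include_unpenalized(self, five_gene_rates):
        r, cat = five_gene_rates
        kappa2 = 0.5 * pe.full_shrinkage_kappa2(r, cat)
        include = pe.Panel.from_genes(("g0",), cat)
        exclude = pe.Panel.from_genes(("g4",), cat)
        w = pe.first_fit(r, cat, kappa2, include=include, exclude=exclude)
        assert np.all(w.w[4] == 0.0)
        assert np.linalg.norm(w.w[0]) > 0  # unpenalized gene stays active

    def test_overlapping_include_exclude_rejected(self, five_gene_rates):
        r, cat = five_gene_rates
        pan = pe.Panel.from_genes(("g1",), cat)
        with pytest.raises(ValueError, match="overlap"):
            pe.first_fit(r, cat, 0.1, include=pan, exclude=pan)

    def test_solution_unique_across_starts(self, five_gene_rates):
        r, cat = five_gene_rates
        kappa2 = 0.05 * pe.full_shrinkage_kappa2(r, cat)
        w1 = pe.first_fit(r, cat, kappa2, kkt_stop=1e-10, kkt_tol=1e-10)
        w2 = pe.first_fit(r, cat, kappa2, init=np.full_like(r.p, 3.0),
                          kkt_stop=1e-10, kkt_tol=1e-10)
        assert np.abs(w1.w - w2.w).max() < 1e-6


class TestPanelOf:
    def test_zero_weights_empty_panel(self, tiny_genes):
        w = pe.WeightMatrix(tiny_genes.genes, ("other", "indel"),
                            np.zeros((3, 2)))
        panel = pe.panel_of(w, tiny_genes)
        assert len(panel) == 0 and panel.total_length == 0.0

    def test_support_lengths_hand_case(self, tiny_genes):
        W = np.array([[1.0, 0.0], [0.0, 0.0], [0.0, -0.5]])
        w = pe.WeightMatrix(tiny_genes.genes, ("other", "indel"), W)
        panel = pe.panel_of(w, tiny_genes)
        assert panel.genes == ("g1", "g3")
        assert panel.total_length == 400.0 == w.group_l0(tiny_genes)


class TestRefit:
    def test_full_panel_reaches_global_minimum(self, five_gene_rates):
        r, cat = five_gene_rates
        panel = pe.Panel.from_genes(r.genes, cat)
        w = pe.refit(r, panel)
        np.testing.assert_allclose(w.w, r.target_indicator, atol=1e-12)
        assert pe.objective_f(w, r) == pytest.approx(0.0, abs=1e-12)

    def test_empty_panel_returns_zero_with_warning(self, five_gene_rates):
        r, _ = five_gene_rates
        with pytest.warns(UserWarning, match="empty panel"):
            w = pe.refit(r, pe.Panel.empty())
        assert np.all(w.w == 0.0)

    def test_matches_grid_search_on_small_support(self):
        # 3 genes x 1 group: brute grid over the support coordinates
        params = make_params([0.0], [0.4, -0.2, 0.0], [0.0],
                             np.zeros((3, 1)), groups=("other",))
        cat = pe.GeneCatalog(params.genes, np.array([50.0, 150.0, 300.0]))
        r = pe.normalized_rates(params, cat,
                                pe.BiomarkerSpec("x", ("other",))).with_K(4.0)
        panel = pe.Panel.from_genes(("g0", "g2"), cat)
        w = pe.refit(r, panel)
        grid = np.linspace(-1, 4, 401)
        best, best_val = None, np.inf
        for a in grid:
            for b in grid:
                W = np.array([[a], [0.0], [b]])
                val = pe.objective_f(pe.WeightMatrix(r.genes, r.groups, W), r)
                if val < best_val:
                    best, best_val = (a, b), val
        assert w.w[0, 0] == pytest.approx(best[0], abs=2e-2)
        assert w.w[2, 0] == pytest.approx(best[1], abs=2e-2)
        assert pe.objective_f(w, r) <= best_val + 1e-9

    def test_kkt_residual_tiny(self, five_gene_rates):
        r, cat = five_gene_rates
        panel = pe.Panel.from_genes(("g0", "g2", "g3"), cat)
        w = pe.refit(r, panel)
        rows = np.array([g in panel for g in r.genes])
        grad = _grad_f(w.w, r.p, r.target_indicator, r.K)
        assert np.abs(grad[rows]).max() < 1e-8

    def test_unbiased_refit_constraint(self, five_gene_rates):
        r, cat = five_gene_rates
        r_inf = pe.NormalizedRates(r.genes, r.groups, r.p, r.target_mask,
                                   np.inf)
        panel = pe.Panel.from_genes(("g1", "g3"), cat)
        w = pe.refit(r_inf, panel)
        assert (r.p * w.w).sum() == pytest.approx(1.0, abs=1e-10)

    def test_refit_never_increases_f(self, five_gene_rates):
        r, cat = five_gene_rates
        kappa2 = 0.05 * pe.full_shrinkage_kappa2(r, cat)
        w_first = pe.first_fit(r, cat, kappa2)
        panel = pe.panel_of(w_first, cat)
        w_refit = pe.refit(r, panel)
        assert pe.objective_f(w_refit, r) <= pe.objective_f(w_first, r) + 1e-12


class TestKappa2ForLength:
    def test_zero_budget_empty_panel_at_largest_kappa2(self, five_gene_rates):
        r, cat = five_gene_rates
        grid = pe.default_kappa2_grid(r, cat, n_grid=12)
        k2, panel, _ = pe.kappa2_for_length(r, cat, L=0.0, grid=grid)
        assert len(panel) == 0
        assert k2 == pytest.approx(grid.max())

    def test_budget_above_exome_gives_near_full_panel(self, five_gene_rates):
        r, cat = five_gene_rates
        grid = pe.default_kappa2_grid(r, cat, n_grid=12)
        k2, panel, _ = pe.kappa2_for_length(r, cat, L=cat.total_length, grid=grid)
        # the budget never binds: the longest panel on the path is chosen,
        # with ties resolved toward the larger (sparser) kappa2
        assert panel.total_length >= 0.9 * cat.total_length
        longer_exists = any(
            pe.panel_of(pe.first_fit(r, cat, kk), cat).total_length
            > panel.total_length for kk in grid[grid < k2])
        assert not longer_exists

    def test_half_budget_is_grid_optimal(self, five_gene_rates):
        r, cat = five_gene_rates
        grid = pe.default_kappa2_grid(r, cat, n_grid=25)
        L = 0.5 * cat.total_length
        k2, panel, _ = pe.kappa2_for_length(r, cat, L=L, grid=grid)
        assert panel.total_length <= L
        # exhaustive check: no grid value yields a longer panel within L
        lengths_on_grid = []
        for kk in sorted(grid)[::-1]:
            w = pe.first_fit(r, cat, kk)
            lengths_on_grid.append(pe.panel_of(w, cat).total_length)
        reported = np.maximum.accumulate(lengths_on_grid)
        best = max(l for l in reported if l <= L)
        assert panel.total_length == pytest.approx(best)

    def test_budget_below_mandatory_panel_rejected(self, five_gene_rates):
        r, cat = five_gene_rates
        include = pe.Panel.from_genes(("g0", "g1"), cat)
        with pytest.raises(ValueError, match="budget"):
            pe.kappa2_for_length(r, cat, L=include.total_length - 1,
                                 include=include)

    def test_augmentation_shrinks_to_mandatory_panel(self, five_gene_rates):
        r, cat = five_gene_rates
        include = pe.Panel.from_genes(("g2",), cat)
        kmax = pe.full_shrinkage_kappa2(r, cat, include)
        grid = np.array([kmax * 10.0, kmax * 5.0])
        k2, panel, _ = pe.kappa2_for_length(
            r, cat, L=cat.total_length, grid=grid, include=include)
        assert set(panel.genes) == {"g2"}


def test_panel_gene_list_round_trip(tmp_path, tiny_genes):
    panel = pe.Panel.from_genes(("g1", "g3"), tiny_genes)
    path = tmp_path / "panel.txt"
    panel.write_gene_list(path)
    back = pe.Panel.read_gene_list(path, tiny_genes)
    assert back.genes == panel.genes and back.total_length == 400.0


def test_panel_bed_output(tmp_path, tiny_genes):
    panel = pe.Panel.from_genes(("g1",), tiny_genes)
    coords = {"g1": ("chr1", 100, 200)}
    path = tmp_path / "panel.bed"
    panel.write_bed(path, coords)
    assert path.read_text() == "chr1\t100\t200\tg1\n"
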