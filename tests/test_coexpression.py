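import numpy as np
import pytest
from scipy import stats

from comodnet.coexpression import (
    build_network,
    choose_beta,
    detect_modules,
    drop_constant_genes,
    module_eigengenes,
    module_trait_correlation,
    pick_soft_threshold,
    scale_free_fit,
)
from comodnet.synthetic import SyntheticSpec, simulate_disease_datasets

from conftest import make_expression, make_groups
from oracles import brute_force_tom


class TestSoftThreshold:
    def test_power_law_connectivity_fits_well(self, rng):
        k = (rng.pareto(2.0, size=2000) + 1) * 3
        assert scale_free_fit(k) >= 0.8

    def test_increasing_frequency_flips_sign(self, rng):
        # frequency grows with k -> positive slope -> negative signed R^2
        k = np.concatenate(
            [np.full(size, kv) for size, kv in zip((10, 20, 40, 80, 160), (1, 2, 4, 8, 16))]
        ) * rng.uniform(0.95, 1.05, 310)
        assert scale_free_fit(k) < 0

    def test_choose_beta_smallest_crossing(self):
        r2s = [0.1, 0.3, 0.5, 0.7, 0.79, 0.81, 0.9]
        assert choose_beta(range(1, 8), r2s, 0.8) == 6

    def test_choose_beta_argmax_fallback(self):
        r2s = [0.1, 0.42, 0.3, 0.2]
        assert choose_beta(range(1, 5), r2s, 0.8) == 2

    def test_scan_matches_direct_per_beta_fit(self, rng):
        expr = make_expression(rng.normal(size=(60, 12)))
        scan = pick_soft_threshold(expr, candidates=(1, 2, 3, 4))
        abscor = np.abs(np.corrcoef(expr.values))
        np.fill_diagonal(abscor, 0.0)
        for beta, r2, mk in zip(scan.candidates, scan.r_squared, scan.mean_connectivity):
            k = (abscor**beta).sum(axis=1)
            assert r2 == pytest.approx(scale_free_fit(k))
            assert mk == pytest.approx(k.mean())
        assert scan.chosen == choose_beta(scan.candidates, scan.r_squared, 0.8)

    def test_independent_genes_connectivity_vanishes(self):
        x = np.array([[1.0, -1.0, 1.0, -1.0], [1.0, 1.0, -1.0, -1.0]])
        expr = make_expression(x)
        for beta in (1, 4, 8):
            net = build_network(expr, beta)
            assert net.connectivity == pytest.approx([0.0, 0.0], abs=1e-12)

    def test_constant_genes_dropped_before_scan(self, rng, caplog):
        vals = rng.normal(size=(40, 10))
        vals[5] = 3.14
        expr = make_expression(vals)
        with caplog.at_level("WARNING"):
            cleaned = drop_constant_genes(expr)
        assert cleaned.n_genes == 39


class TestBuildNetwork:
    def test_zero_correlation_fixture(self):
        x = np.array(
            [
                [1.0, -1.0, 1.0, -1.0],
                [1.0, 1.0, -1.0, -1.0],
                [1.0, -1.0, -1.0, 1.0],
            ]
        )
        net = build_network(make_expression(x), beta=3)
        off = ~np.eye(3, dtype=bool)
        assert np.allclose(net.adjacency[off], 0.0)
        assert np.allclose(net.tom[off], 0.0)
        assert np.allclose(np.diag(net.tom), 1.0)

    def test_duplicated_gene_has_unit_adjacency(self, rng):
        v = rng.normal(size=8)
        x = np.vstack([v, 2 * v + 1, rng.normal(size=8)])
        net = build_network(make_expression(x), beta=7)
        assert net.adjacency[0, 1] == pytest.approx(1.0)

    @pytest.mark.parametrize("n,m,beta", [(10, 8, 2), (20, 12, 6), (30, 9, 4)])
    def test_tom_matches_bruteforce(self, rng, n, m, beta):
        x = rng.normal(size=(n, m))
        net = build_network(make_expression(x), beta)
        np.testing.assert_allclose(net.tom, brute_force_tom(x, beta), atol=1e-10)

    def test_tom_symmetric_in_unit_interval(self, rng):
        net = build_network(make_expression(rng.normal(size=(25, 10))), 6)
        assert np.allclose(net.tom, net.tom.T)
        assert net.tom.min() >= 0.0 and net.tom.max() <= 1.0


class TestDetectModules:
    def test_planted_modules_recovered(self):
        spec = SyntheticSpec(
            n_genes=200,
            module_sizes=(50, 50),
            disease_modules=((0, 1),) * 3,
            within_module_cor=0.8,
            seed=17,
        )
        datasets, truth = simulate_disease_datasets(spec)
        expr = datasets[0][0]
        net = build_network(expr, 6)
        assignment = detect_modules(net, expr, min_module_size=30)
        detected = [set(assignment.module_genes(m)) for m in assignment.module_ids()]
        for m in (0, 1):
            planted = set(truth.module_genes[m])
            best = max((len(planted & d) / len(planted | d) for d in detected), default=0)
            assert best >= 0.6

    def test_min_size_above_gene_count_leaves_all_unassigned(self, rng):
        expr = make_expression(rng.normal(size=(40, 10)))
        net = build_network(expr, 6)
        assignment = detect_modules(net, expr, min_module_size=100)
        assert set(assignment.labels.values()) == {0}

    def test_duplicate_factor_modules_merge(self, rng):
        # two blocks driven by the same latent factor must fuse
        f = rng.standard_normal(16)
        blocks = [
            np.vstack([0.9 * f + 0.2 * rng.standard_normal(16) for _ in range(25)])
            for _ in range(2)
        ]
        noise = rng.standard_normal((30, 16))
        expr = make_expression(np.vstack(blocks + [noise]))
        net = build_network(expr, 6)
        assignment = detect_modules(net, expr, min_module_size=20)
        labels = {assignment.labels[f"g{i}"] for i in range(50)}
        labels.discard(0)
        assert len(labels) == 1

    def test_gene_order_permutation_invariant(self, rng):
        spec = SyntheticSpec(
            n_genes=120,
            module_sizes=(40, 40),
            disease_modules=((0, 1),) * 3,
            within_module_cor=0.7,
            seed=5,
        )
        datasets, _ = simulate_disease_datasets(spec)
        expr = datasets[0][0]
        perm = rng.permutation(expr.n_genes)
        shuffled = make_expression(expr.values[perm])
        shuffled = shuffled.__class__(
            tuple(expr.gene_ids[i] for i in perm), expr.sample_ids, expr.values[perm]
        )
        a1 = detect_modules(build_network(expr, 6), expr, min_module_size=20)
        a2 = detect_modules(build_network(shuffled, 6), shuffled, min_module_size=20)
        part1 = {frozenset(a1.module_genes(m)) for m in a1.module_ids()}
        part2 = {frozenset(a2.module_genes(m)) for m in a2.module_ids()}
        assert part1 == part2


class TestEigengenes:
    def test_rank_one_module_reproduces_profile(self, rng):
        v = rng.normal(size=10)
        expr = make_expression(np.vstack([v, v, v]))
        eig = module_eigengenes(expr, {"g0": 1, "g1": 1, "g2": 1})[1]
        assert abs(np.corrcoef(eig, v)[0, 1]) == pytest.approx(1.0)

    def test_orientation_invariant_to_global_sign_flip(self, rng):
        x = rng.normal(size=(6, 12))
        labels = {f"g{i}": 1 for i in range(6)}
        e1 = module_eigengenes(make_expression(x), labels)[1]
        e2 = module_eigengenes(make_expression(-x), labels)[1]
        np.testing.assert_allclose(e1, -e2, atol=1e-10)
        # orientation rule: mean gene-eigengene correlation non-negative
        z = (x - x.mean(1, keepdims=True)) / x.std(1, keepdims=True)
        cors = [np.corrcoef(z[i], e1)[0, 1] for i in range(6)]
        assert np.mean(cors) >= 0

    def test_factor_module_eigengene_tracks_factor(self):
        rng = np.random.default_rng(17)
        f = rng.standard_normal(20)
        x = np.vstack(
            [np.sqrt(0.64) * f + np.sqrt(0.36) * rng.standard_normal(20) for _ in range(40)]
        )
        expr = make_expression(x)
        eig = module_eigengenes(expr, {f"g{i}": 1 for i in range(40)})[1]
        assert abs(np.corrcoef(eig, f)[0, 1]) >= 0.9


class TestModuleTrait:
    def test_eigengene_equal_to_trait_gives_unit_correlation(self):
        trait = np.array([0.0] * 5 + [1.0] * 5)
        x = np.vstack([trait, trait])
        expr = make_expression(x)
        groups = make_groups(expr, n_case=5)
        res = module_trait_correlation(expr, {"g0": 1, "g1": 1}, groups, method="pearson")
        assert abs(res.trait_r[1]) == pytest.approx(1.0)
        assert res.trait_p[1] < 0.01

    def test_case_shifted_module_has_strongest_trait_link(self):
        spec = SyntheticSpec(
            n_genes=150,
            module_sizes=(40, 40),
            disease_modules=((0, 1),) * 3,
            de_effect=2.0,
            de_fraction=1.0,
            seed=17,
        )
        datasets, truth = simulate_disease_datasets(spec)
        expr, groups = datasets[0]
        labels = {}
        for m in (0, 1):
            for g in truth.module_genes[m]:
                labels[g] = m + 1
        res = module_trait_correlation(expr, labels, groups)
        assert res.method == "spearman"
        assert max(abs(r) for r in res.trait_r.values()) >= 0.5

    def test_gs_and_mm_ranges(self, small_dataset):
        datasets, truth = small_dataset
        expr, groups = datasets[0]
        labels = {g: 1 for g in truth.module_genes[0]}
        res = module_trait_correlation(expr.subset_genes(labels), labels, groups)
        assert all(0 <= v <= 1 for v in res.gene_significance.values())
        assert all(-1 <= v <= 1 for v in res.module_membership.values())
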