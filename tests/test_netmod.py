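"""Coexpression-network operations against brute-force oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from saavkit.core_io import SaavkitError
from saavkit.netmod import (
    ModuleAssignment,
    NetworkConfig,
    UNASSIGNED,
    adjacency,
    cluster_modules,
    correlation_matrix,
    eigen_protein,
    fill_eigen_proteins,
    fit_network,
    module_trait_correlation,
    ora_screen,
    tom,
)
from saavkit.simulate import simulate_module_matrix


def brute_force_tom(a):
    """Triple-sum oracle for the topological overlap matrix."""
    n = a.shape[0]
    k = a.sum(axis=1)
    t = np.zeros_like(a)
    for i in range(n):
        for j in range(n):
            if i == j:
                t[i, j] = 1.0
                continue
            l = sum(a[i, u] * a[u, j] for u in range(n))
            t[i, j] = (l + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return t


def random_adjacency(rng, n):
    a = rng.uniform(0, 1, size=(n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 0.0)
    return a


class TestCorrelation:
    def test_duplicate_and_negated_profiles(self, rng):
        x = rng.normal(size=8)
        df = pd.DataFrame([x, x, -x], index=["a", "b", "c"])
        c = correlation_matrix(df)
        assert c.loc["a", "b"] == pytest.approx(1.0)
        assert c.loc["a", "c"] == pytest.approx(-1.0)

    def test_against_two_pass_formula(self, rng):
        df = pd.DataFrame(rng.normal(size=(10, 8)))
        c = correlation_matrix(df).to_numpy()
        x = df.to_numpy()
        for i in range(10):
            for j in range(10):
                xi, xj = x[i] - x[i].mean(), x[j] - x[j].mean()
                expected = (xi @ xj) / math.sqrt((xi @ xi) * (xj @ xj))
                assert abs(c[i, j] - expected) <= 1e-10

    def test_too_few_samples_errors(self):
        with pytest.raises(SaavkitError, match="at least 3 samples"):
            correlation_matrix(pd.DataFrame([[1, 2], [3, 4]]))

    def test_zero_variance_rows_dropped(self, rng):
        df = pd.DataFrame(rng.normal(size=(4, 6)), index=list("abcd"))
        df.loc["c"] = 1.0
        c = correlation_matrix(df)
        assert list(c.index) == ["a", "b", "d"]


class TestAdjacency:
    def test_conventions(self):
        corr = pd.DataFrame([[1.0, 0.0], [0.0, 1.0]], index=list("ab"), columns=list("ab"))
        signed = adjacency(corr, NetworkConfig(soft_power=2, similarity_convention="signed"))
        assert signed.loc["a", "b"] == pytest.approx(0.25)  # ((1+0)/2)^2
        unsigned = adjacency(corr, NetworkConfig(soft_power=2, similarity_convention="unsigned"))
        assert unsigned.loc["a", "b"] == pytest.approx(0.0)
        literal = adjacency(corr, NetworkConfig(soft_power=2, similarity_convention="literal_paper"))
        assert literal.loc["a", "b"] == pytest.approx(0.25)  # ((1-0)/2)^2

    def test_perfect_correlation_saturates(self):
        corr = pd.DataFrame([[1.0, 1.0], [1.0, 1.0]], index=list("ab"), columns=list("ab"))
        a = adjacency(corr, NetworkConfig(soft_power=7))
        assert a.loc["a", "b"] == pytest.approx(1.0)
        assert a.loc["a", "a"] == 0.0  # diagonal zeroed for connectivity

    def test_matches_scalar_recomputation(self, rng):
        r = np.clip((random_adjacency(rng, 8) * 2 - 1), -1, 1)
        np.fill_diagonal(r, 1.0)
        corr = pd.DataFrame(r)
        config = NetworkConfig(soft_power=6)
        a = adjacency(corr, config).to_numpy()
        for i, j in itertools.product(range(8), repeat=2):
            expected = 0.0 if i == j else ((1 + r[i, j]) / 2) ** 6
            assert abs(a[i, j] - expected) <= 1e-12


class TestTom:
    def test_saturated_graph(self):
        a = np.ones((5, 5)) - np.eye(5)
        t = tom(a)
        off = t[~np.eye(5, dtype=bool)]
        assert np.allclose(off, 1.0)

    def test_empty_graph(self):
        t = tom(np.zeros((4, 4)))
        assert np.allclose(t, np.eye(4))

    def test_triangle_of_halves(self):
        a = np.full((3, 3), 0.5)
        np.fill_diagonal(a, 0.0)
        t = tom(a)
        off = t[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 0.5)

    def test_matches_brute_force_random(self, rng):
        for _ in range(25):
            n = int(rng.integers(2, 16))
            a = random_adjacency(rng, n)
            assert np.allclose(tom(a), brute_force_tom(a), atol=1e-10)

    def test_properties_random(self, rng):
        for _ in range(10):
            a = random_adjacency(rng, 12)
            t = tom(a)
            assert np.allclose(t, t.T)
            assert np.allclose(np.diag(t), 1.0)
            assert t.min() >= 0.0 and t.max() <= 1.0


class TestClusterModules:
    def test_two_planted_blocks(self, rng):
        n = 40
        a = np.zeros((2 * n, 2 * n))
        a[:n, :n] = 0.8
        a[n:, n:] = 0.8
        a += rng.uniform(0, 0.01, size=a.shape)
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0.0)
        names = [f"g{i:03d}" for i in range(2 * n)]
        t = pd.DataFrame(tom(a), index=names, columns=names)
        assignment = cluster_modules(t, NetworkConfig(min_module_size=30))
        labels = [assignment.labels[p] for p in names]
        assert len(assignment.modules) == 2
        assert len(set(labels[:n])) == 1 and len(set(labels[n:])) == 1
        assert labels[0] != labels[-1]

    def test_identical_profiles_single_module(self):
        names = [f"g{i}" for i in range(35)]
        t = pd.DataFrame(np.ones((35, 35)), index=names, columns=names)
        assignment = cluster_modules(t, NetworkConfig(min_module_size=30))
        assert len(assignment.modules) == 1
        assert all(l == "WM1" for l in assignment.labels.values())

    def test_fewer_proteins_than_min_size(self):
        names = [f"g{i}" for i in range(10)]
        t = pd.DataFrame(np.eye(10), index=names, columns=names)
        assignment = cluster_modules(t, NetworkConfig(min_module_size=30))
        assert all(l == UNASSIGNED for l in assignment.labels.values())

    def test_permutation_equivariance(self, rng):
        sim = simulate_module_matrix(
            n_modules=2, module_size=35, n_background=10,
            traits={"M1": 4, "M2": 4}, seed=5,
        )
        _, _, _, t = fit_network(sim.expression, NetworkConfig())
        base = cluster_modules(t, NetworkConfig())
        perm = list(rng.permutation(len(t)))
        tp = t.iloc[perm, perm]
        permuted = cluster_modules(tp, NetworkConfig())
        # same partition of protein names regardless of row order
        def partition(a):
            groups = {}
            for p, l in a.labels.items():
                groups.setdefault(l, set()).add(p)
            return {frozenset(v) for k, v in groups.items() if k != UNASSIGNED}
        assert partition(base) == partition(permuted)


class TestEigenProtein:
    def test_single_member(self):
        adj = pd.DataFrame([[0.0]], index=["a"], columns=["a"])
        assert eigen_protein(["a"], adj) == "a"

    def test_star_hub(self):
        names = list("abcde")
        a = np.zeros((5, 5))
        a[0, 1:] = a[1:, 0] = 0.9
        adj = pd.DataFrame(a, index=names, columns=names)
        assert eigen_protein(names, adj) == "a"

    def test_matches_exhaustive_scan(self, rng):
        names = [f"g{i}" for i in range(12)]
        a = random_adjacency(rng, 12)
        adj = pd.DataFrame(a, index=names, columns=names)
        best, best_k = None, -1.0
        for i, name in enumerate(names):
            k = sum(a[i, j] for j in range(12) if j != i)
            if k > best_k:
                best, best_k = name, k
        assert eigen_protein(names, adj) == best


class TestModuleTraitCorrelation:
    def test_profile_equals_indicator(self):
        r, p = module_trait_correlation([0, 0, 1, 1], [0, 0, 1, 1])
        assert r == pytest.approx(1.0)

    def test_hand_computed_point_biserial(self):
        r, p = module_trait_correlation([1, 2, 3, 4], [0, 0, 1, 1])
        assert r == pytest.approx(0.894, abs=1e-3)
        t = r * math.sqrt(2 / (1 - r**2))
        from scipy import stats

        assert p == pytest.approx(2 * stats.t.sf(t, 2), abs=1e-12)

    def test_permutation_invariance(self, rng):
        x = rng.normal(size=10)
        y = (rng.random(10) < 0.5).astype(int)
        y[:2] = [0, 1]  # non-constant
        perm = rng.permutation(10)
        assert module_trait_correlation(x, y) == pytest.approx(
            module_trait_correlation(x[perm], y[perm])
        )

    def test_constant_trait_errors(self):
        with pytest.raises(SaavkitError, match="constant"):
            module_trait_correlation([1, 2, 3, 4], [1, 1, 1, 1])


def assignment_with(modules):
    labels = {}
    for name, members in modules.items():
        for p in members:
            labels[p] = name
    a = ModuleAssignment(labels=labels)
    a.modules = {k: sorted(v) for k, v in modules.items()}
    return a


class TestOraScreen:
    def test_zero_overlap_p_is_one(self):
        universe = {f"u{i}" for i in range(20)}
        module = {f"u{i}" for i in range(5)}
        group = {f"u{i}" for i in range(10, 14)}
        res = ora_screen(assignment_with({"WM1": module}), {"g": group}, universe)
        assert res.table["p"].iloc[0] == pytest.approx(1.0)

    def test_exact_enumeration_example(self):
        # universe 10, module 5, group 4, overlap 4 -> 6/252
        universe = {f"u{i}" for i in range(10)}
        group = {f"u{i}" for i in range(4)}
        module = {f"u{i}" for i in range(5)}
        res = ora_screen(assignment_with({"WM1": module}), {"g": group}, universe)
        assert res.table["p"].iloc[0] == pytest.approx(6 / 252, abs=1e-12)

    def test_group_outside_universe_errors(self):
        with pytest.raises(SaavkitError, match="not a subset"):
            ora_screen(assignment_with({"WM1": {"a"}}), {"g": {"zz"}}, {"a", "b"})

    def test_bh_q_monotone_and_bounded(self, rng):
        universe = {f"u{i}" for i in range(40)}
        elems = sorted(universe)
        modules = {
            f"WM{k + 1}": set(rng.choice(elems, size=10, replace=False)) for k in range(5)
        }
        groups = {
            f"g{k}": set(rng.choice(elems, size=8, replace=False)) for k in range(3)
        }
        res = ora_screen(assignment_with(modules), groups, universe)
        table = res.table.sort_values("p")
        assert (table["q"].to_numpy() >= table["p"].to_numpy() - 1e-15).all()
        assert table["q"].is_monotonic_increasing
        assert ((table["q"] >= 0) & (table["q"] <= 1)).all()
        assert (table["overlap"] <= table[["module_size", "group_size"]].min(axis=1)).all()


def test_parameter_recovery_planted_modules():
    """Planted 3-block matrix: module labels recovered, enriched module ranked first."""
    from sklearn.metrics import adjusted_rand_score

    sim = simulate_module_matrix(n_modules=3, module_size=40, within_r=0.8, seed=11)
    assignment, _, adj, _ = fit_network(sim.expression, NetworkConfig())
    fill_eigen_proteins(assignment, adj)
    true = [sim.labels[p] for p in sim.expression.index]
    pred = [assignment.labels[p] for p in sim.expression.index]
    assert adjusted_rand_score(true, pred) >= 0.8
    res = ora_screen(
        assignment,
        {"unique_M1": sim.planted_unique["M1"]},
        set(sim.expression.index),
    )
    top = res.ranked_modules[0]
    planted_members = {p for p, l in sim.labels.items() if l == sim.enriched_module}
    overlap = len(set(assignment.modules[top]) & planted_members)
    assert overlap >= 0.8 * len(planted_members)
    assert res.screened[top]
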