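"""Exact co-presence testing, network construction, and module detection."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import adjusted_rand_score

import cwpsoil as cw
from cwpsoil import network


def exact_tail(N: int, n_a: int, n_b: int, j: int) -> Fraction:
    """Rational-arithmetic hypergeometric upper tail (independent oracle)."""
    total = math.comb(N, n_b)
    acc = Fraction(0)
    for jj in range(j, min(n_a, n_b) + 1):
        acc += Fraction(math.comb(n_a, jj) * math.comb(N - n_a, n_b - jj), total)
    return acc


class TestCopresencePvalue:
    def test_closed_form_full_overlap(self):
        # C(5,5) C(5,0) / C(10,5) = 1/252
        assert cw.copresence_pvalue(10, 5, 5, 5) == pytest.approx(1 / 252)

    def test_identical_presence_five_of_twenty(self):
        assert cw.copresence_pvalue(20, 5, 5, 5) == pytest.approx(1 / math.comb(20, 5))

    def test_saturated_taxon_never_significant(self):
        # n_a = N forces j_obs = n_b and p = 1
        assert cw.copresence_pvalue(30, 30, 12, 12) == pytest.approx(1.0)

    def test_feasible_minimum_gives_full_tail(self):
        assert cw.copresence_pvalue(10, 7, 6, 3) == pytest.approx(1.0)

    def test_infeasible_j_rejected(self):
        with pytest.raises(ValueError):
            cw.copresence_pvalue(10, 3, 3, 4)
        with pytest.raises(ValueError):
            cw.copresence_pvalue(10, 7, 6, 2)

    @given(
        st.integers(2, 25).flatmap(
            lambda N: st.tuples(
                st.just(N), st.integers(0, N), st.integers(0, N)
            )
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_rational_oracle_and_monotone(self, case):
        N, n_a, n_b = case
        j_min, j_max = max(0, n_a + n_b - N), min(n_a, n_b)
        prev = None
        for j in range(j_min, j_max + 1):
            p = cw.copresence_pvalue(N, n_a, n_b, j)
            assert p == pytest.approx(float(exact_tail(N, n_a, n_b, j)), rel=1e-10)
            if prev is not None:
                assert p <= prev + 1e-12  # tail nonincreasing in j
            prev = p

    def test_symmetry(self):
        assert cw.copresence_pvalue(40, 12, 25, 9) == pytest.approx(
            cw.copresence_pvalue(40, 25, 12, 9), rel=1e-12
        )


def _presence(rows: dict[str, list[int]]) -> pd.DataFrame:
    df = pd.DataFrame(rows).T
    df.columns = [f"s{i}" for i in range(df.shape[1])]
    return df


class TestBuildNetwork:
    def test_disjoint_taxa_no_edge(self):
        pres = _presence({"a": [1, 1, 0, 0, 0, 0], "b": [0, 0, 1, 1, 0, 0]})
        net = cw.build_network(pres)
        assert net.n_edges == 0

    def test_identical_presence_strong_edge(self):
        base = [1] * 5 + [0] * 15
        pres = _presence({"a": base, "b": base})
        net = cw.build_network(pres, alpha=0.05)
        assert net.n_edges == 1
        assert net.edges.iloc[0]["p_value"] == pytest.approx(1 / math.comb(20, 5))

    def test_matches_brute_force_over_all_pairs(self):
        """4-taxon, 8-site toy: edge set equals explicit enumeration."""
        rng = np.random.default_rng(3)
        pres = pd.DataFrame(
            rng.integers(0, 2, size=(4, 8)),
            index=list("abcd"), columns=[f"s{i}" for i in range(8)],
        )
        alpha = 0.3
        net = cw.build_network(pres, alpha=alpha)
        got = {tuple(sorted((r.taxon_a, r.taxon_b))) for r in net.edges.itertuples()}
        expected = set()
        mat = pres.to_numpy()
        prev = mat.sum(axis=1)
        informative = [i for i in range(4) if 0 < prev[i] < 8]
        for i in informative:
            for j in informative:
                if i >= j:
                    continue
                j_obs = int((mat[i] * mat[j]).sum())
                p = float(exact_tail(8, int(prev[i]), int(prev[j]), j_obs))
                if p < alpha:
                    expected.add(tuple(sorted((pres.index[i], pres.index[j]))))
        assert got == expected

    def test_site_permutation_invariance(self):
        rng = np.random.default_rng(4)
        pres = pd.DataFrame(
            rng.integers(0, 2, size=(6, 12)),
            index=[f"t{i}" for i in range(6)],
            columns=[f"s{i}" for i in range(12)],
        )
        net_a = cw.build_network(pres)
        net_b = cw.build_network(pres[rng.permutation(pres.columns)])
        key = lambda n: {tuple(sorted((r.taxon_a, r.taxon_b))) for r in n.edges.itertuples()}
        assert key(net_a) == key(net_b)

    def test_full_prevalence_taxon_isolated_but_retained(self):
        pres = _presence({"a": [1] * 8, "b": [1, 1, 1, 1, 0, 0, 0, 0],
                          "c": [1, 1, 1, 1, 0, 0, 0, 0]})
        net = cw.build_network(pres)
        assert "a" in net.nodes and "a" in net.skipped
        assert {tuple(sorted((r.taxon_a, r.taxon_b))) for r in net.edges.itertuples()} == {
            ("b", "c")
        }


class TestModules:
    def _two_cliques(self):
        nodes = [f"n{i}" for i in range(8)]
        edges = []
        for grp in (nodes[:4], nodes[4:]):
            for i in range(4):
                for j in range(i + 1, 4):
                    edges.append((grp[i], grp[j]))
        edges.append((nodes[0], nodes[4]))  # bridge
        return nodes, edges

    def _net_from_edges(self, nodes, edges):
        rows = [[a, b, 4, 4, 4, 0.01] for a, b in edges]
        return network.CooccurrenceNetwork(
            nodes=nodes,
            edges=pd.DataFrame(rows, columns=network.EDGE_COLUMNS),
        )

    def test_two_cliques_recovered_with_positive_modularity(self):
        nodes, edges = self._two_cliques()
        net = cw.detect_modules(self._net_from_edges(nodes, edges), steps=4, seed=0)
        groups = {}
        for t, m in net.membership.items():
            groups.setdefault(m, set()).add(t)
        assert sorted(map(len, groups.values())) == [4, 4]
        assert set(nodes[:4]) in groups.values()
        assert net.modularity > 0.3
        # exhaustive max-modularity partition agrees
        best_q, best_part = network.modularity_brute_force(nodes, edges)
        best_groups: dict[int, set] = {}
        for t, m in best_part.items():
            best_groups.setdefault(m, set()).add(t)
        assert set(map(frozenset, groups.values())) == set(
            map(frozenset, best_groups.values())
        )

    def test_single_clique_single_module(self):
        nodes = list("abcd")
        edges = [(a, b) for i, a in enumerate(nodes) for b in nodes[i + 1:]]
        net = cw.detect_modules(self._net_from_edges(nodes, edges), seed=0)
        assert len(set(net.membership.values())) == 1

    def test_empty_edge_set_all_singletons(self):
        net = cw.detect_modules(self._net_from_edges(list("abc"), []), seed=0)
        assert sorted(net.membership.values()) == [1, 2, 3]
        assert net.modularity == 0.0

    def test_main_module_flagging(self):
        nodes, edges = self._two_cliques()
        net = cw.detect_modules(self._net_from_edges(nodes + ["iso"], edges), seed=0)
        flagged = cw.main_modules(net, min_size=4)
        assert len(flagged.main_modules) == 2
        all_main = cw.main_modules(net, min_size=1)
        assert len(all_main.main_modules) == len(set(net.membership.values()))

    def test_planted_modules_recovered_from_synthetic_counts(self, desk_data):
        sites = desk_data["sites"]
        truth = desk_data["truth"]
        rare, _ = cw.rarefy(desk_data["counts"]["bacteria"], 12000, seed=1)
        rel = cw.relative_abundance(rare)
        pres = cw.presence_matrix(rare)
        core = cw.select_core(rel, pres, sites)
        net = cw.detect_modules(cw.build_network(pres.loc[core.taxa]), seed=0)
        planted = truth.module_membership["bacteria"]
        common = [t for t in net.membership if t in planted]
        ari = adjusted_rand_score(
            [planted[t] for t in common], [net.membership[t] for t in common]
        )
        assert ari >= 0.7
        n_main = len(cw.main_modules(net, min_size=5).main_modules)
        assert n_main == 2
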