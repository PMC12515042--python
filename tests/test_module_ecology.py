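"""Within-population standardization, module abundance, completeness, letters."""

import numpy as np
import pandas as pd
import pytest

import cwpsoil as cw


class TestZscore:
    def test_worked_row(self):
        x = pd.DataFrame([[2.0, 4.0, 6.0]], index=["p1"], columns=list("abc"))
        z = cw.zscore_rows(x)
        assert z.loc["p1"].tolist() == pytest.approx([-1.0, 0.0, 1.0])

    def test_constant_row_zero_with_warning(self):
        x = pd.DataFrame([[5.0, 5.0, 5.0]], index=["p1"], columns=list("abc"))
        with pytest.warns(UserWarning, match="constant"):
            z = cw.zscore_rows(x)
        assert (z.loc["p1"] == 0).all()

    def test_rows_standardized(self):
        rng = np.random.default_rng(0)
        x = pd.DataFrame(rng.random((10, 50)))
        z = cw.zscore_rows(x)
        assert np.allclose(z.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(z.std(axis=1, ddof=1), 1, atol=1e-12)

    def test_per_taxon_variant_standardizes_columns(self):
        rng = np.random.default_rng(1)
        x = pd.DataFrame(rng.random((10, 5)))
        z = cw.zscore_rows(x, per_taxon=True)
        assert np.allclose(z.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(z.std(axis=0, ddof=1), 1, atol=1e-12)

    def test_single_taxon_rejected(self):
        with pytest.raises(ValueError):
            cw.zscore_rows(pd.DataFrame([[1.0]]))


class TestModuleAbundance:
    def test_all_taxa_single_module_is_zero(self):
        rng = np.random.default_rng(2)
        z = cw.zscore_rows(pd.DataFrame(rng.random((6, 8)), columns=list("abcdefgh")))
        out = cw.module_abundance(z, {t: 1 for t in z.columns})
        assert np.allclose(out["module_1"], 0, atol=1e-12)

    def test_singleton_module_equals_column(self):
        rng = np.random.default_rng(3)
        z = cw.zscore_rows(pd.DataFrame(rng.random((4, 3)), columns=list("abc")))
        out = cw.module_abundance(z, {"a": 1, "b": 1, "c": 2})
        assert np.allclose(out["module_2"], z["c"])

    def test_hand_computed_two_modules(self):
        z = pd.DataFrame(
            [[-1.0, 0.0, 1.0], [1.0, 0.0, -1.0]],
            index=["p1", "p2"], columns=list("abc"),
        )
        out = cw.module_abundance(z, {"a": 1, "b": 1, "c": 2})
        assert out.loc["p1", "module_1"] == pytest.approx(-0.5)
        assert out.loc["p2", "module_1"] == pytest.approx(0.5)
        assert out.loc["p1", "module_2"] == pytest.approx(1.0)

    def test_size_weighted_module_means_sum_to_zero(self):
        """Partition of all standardized taxa: sum_m |m| * mean_z = 0 per site."""
        rng = np.random.default_rng(4)
        z = cw.zscore_rows(pd.DataFrame(rng.random((5, 9)),
                                        columns=[f"t{i}" for i in range(9)]))
        membership = {f"t{i}": (i % 3) + 1 for i in range(9)}
        out = cw.module_abundance(z, membership)
        sizes = pd.Series(membership).value_counts()
        weighted = sum(out[f"module_{m}"] * sizes[m] for m in (1, 2, 3))
        assert np.allclose(weighted, 0, atol=1e-10)


class TestCompleteness:
    def _setup(self):
        pres = pd.DataFrame(
            {"p1": [1, 1, 0, 0], "p2": [1, 1, 1, 1], "p3": [0, 0, 1, 1],
             "p4": [1, 1, 1, 1]},
            index=["a", "b", "c", "d"],
        )
        membership = {"a": 1, "b": 1, "c": 1, "d": 1}
        eco = pd.Series({"p1": 1, "p2": 1, "p3": 2, "p4": 2})
        return pres, membership, eco

    def test_partial_presence_fraction(self):
        pres, membership, eco = self._setup()
        per_pop, summary = cw.module_completeness(pres, membership, eco)
        rec = per_pop.set_index("population")
        assert rec.loc["p1", "completeness"] == pytest.approx(0.5)
        assert summary.loc[1, 1] == pytest.approx((0.5 + 1.0) / 2)

    def test_all_present_everywhere_is_one(self):
        pres = pd.DataFrame(np.ones((3, 4), dtype=int),
                            index=list("abc"), columns=[f"p{i}" for i in range(4)])
        eco = pd.Series({f"p{i}": i % 2 for i in range(4)})
        _, summary = cw.module_completeness(pres, {t: 1 for t in "abc"}, eco)
        assert (summary == 1.0).all().all()

    def test_monotone_under_added_presence(self):
        pres, membership, eco = self._setup()
        _, before = cw.module_completeness(pres, membership, eco)
        pres2 = pres.copy()
        pres2.loc["c", "p1"] = 1
        _, after = cw.module_completeness(pres2, membership, eco)
        assert (after.to_numpy() >= before.to_numpy() - 1e-12).all()

    def test_planted_module_peaks_in_its_ecoregion(self, desk_data):
        """Direction check: a module's completeness is highest where planted."""
        sites = desk_data["sites"]
        truth = desk_data["truth"]
        rare, _ = cw.rarefy(desk_data["counts"]["fungi"], 8000, seed=2)
        pres = cw.presence_matrix(rare)
        membership = truth.module_membership["fungi"]
        per_pop, summary = cw.module_completeness(
            pres.loc[list(membership)], membership, truth.site_ecoregion
        )
        for m, home in truth.module_ecoregion["fungi"].items():
            col = summary[m]
            assert col.idxmax() == home
            assert col[home] > col.drop(home).max()


class TestCompareGroups:
    def test_identical_groups_share_letter(self):
        rng = np.random.default_rng(5)
        v = rng.normal(size=10)
        values = pd.Series(np.concatenate([v, v]))
        groups = pd.Series(["g1"] * 10 + ["g2"] * 10)
        out = cw.compare_groups(values, groups)
        assert out.set_index("group")["letter"]["g1"] == out.set_index("group")["letter"]["g2"]

    def test_separated_groups_differ(self):
        rng = np.random.default_rng(6)
        values = pd.Series(
            np.concatenate([rng.normal(0, 0.1, 10), rng.normal(10, 0.1, 10)])
        )
        groups = pd.Series(["lo"] * 10 + ["hi"] * 10)
        out = cw.compare_groups(values, groups).set_index("group")
        assert out.loc["lo", "letter"] != out.loc["hi", "letter"]

    def test_two_equal_one_shifted_pattern(self):
        rng = np.random.default_rng(7)
        values = pd.Series(
            np.concatenate(
                [rng.normal(0, 0.1, 10), rng.normal(0, 0.1, 10), rng.normal(5, 0.1, 10)]
            )
        )
        groups = pd.Series(["g1"] * 10 + ["g2"] * 10 + ["g3"] * 10)
        out = cw.compare_groups(values, groups).set_index("group")["letter"]
        assert out["g1"] == out["g2"]
        assert out["g3"] != out["g1"]

    def test_letters_invariant_to_group_order(self):
        rng = np.random.default_rng(8)
        values = pd.Series(rng.normal(size=30))
        groups = pd.Series(["a"] * 10 + ["b"] * 10 + ["c"] * 10)
        out1 = cw.compare_groups(values, groups).set_index("group")["letter"]
        perm = rng.permutation(30)
        out2 = cw.compare_groups(
            values.iloc[perm].reset_index(drop=True),
            groups.iloc[perm].reset_index(drop=True),
        ).set_index("group")["letter"]
        assert out1.to_dict() == out2.to_dict()

    def test_singleton_group_excluded_with_warning(self):
        values = pd.Series([1.0, 2.0, 1.5, 2.5, 9.0])
        groups = pd.Series(["a", "a", "b", "b", "c"])
        with pytest.warns(UserWarning, match="c"):
            out = cw.compare_groups(values, groups)
        assert set(out["group"]) == {"a", "b"}
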