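"""Rank-product machinery against brute-force and enumeration oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from translatome import rankprod as rp
from translatome.preprocess import MValueTable


def _mvalues(data, groups):
    arrays = list(data.columns)
    meta = pd.DataFrame(
        {
            "group": groups,
            "sample_id": arrays,
            "replicate": [1] * len(arrays),
            "dye_swap": [False] * len(arrays),
        },
        index=pd.Index(arrays, name="array_id"),
    )
    return MValueTable(values=data, meta=meta)


class TestPairwiseFoldChanges:
    def test_single_pair(self):
        m = _mvalues(
            pd.DataFrame({"t1": [3.0], "c1": [1.0]}, index=["g1"]),
            ["tumour", "control"],
        )
        fc = rp.pairwise_fold_changes(m)
        assert fc.data.shape == (1, 1)
        assert fc.data.iloc[0, 0] == 2.0

    def test_all_pairs_count(self):
        data = pd.DataFrame(
            np.zeros((3, 4)), columns=["t1", "t2", "c1", "c2"], index=list("abc")
        )
        m = _mvalues(data, ["tumour", "tumour", "control", "control"])
        assert rp.pairwise_fold_changes(m).data.shape[1] == 4

    def test_matches_nested_loop_reference(self, rng):
        data = pd.DataFrame(
            rng.normal(size=(20, 5)),
            columns=["t1", "t2", "t3", "c1", "c2"],
            index=[f"g{i}" for i in range(20)],
        )
        m = _mvalues(data, ["tumour"] * 3 + ["control"] * 2)
        fc = rp.pairwise_fold_changes(m)
        for t in ["t1", "t2", "t3"]:
            for c in ["c1", "c2"]:
                np.testing.assert_array_equal(
                    fc.data[f"{t}|{c}"].values, (data[t] - data[c]).values
                )


class TestRankProduct:
    def test_single_column_identity(self, rng):
        d = pd.DataFrame({"c": rng.normal(size=8)}, index=list("abcdefgh"))
        fc = rp.FCMatrix(data=d, pairs=[("t", "c")])
        expected = stats.rankdata(-d["c"])
        np.testing.assert_allclose(rp.rank_product(fc, "up").values, expected)

    def test_geometric_mean_of_ranks(self):
        # ranks 2 and 8 across two columns -> RP = sqrt(16) = 4
        d = pd.DataFrame(
            {"c1": [9.0, 8, 7, 6, 5, 4, 3, 2], "c2": [1.0, 2, 3, 4, 5, 6, 7, 9]},
            index=list("abcdefgh"),
        )
        fc = rp.FCMatrix(data=d, pairs=[("t", "c1"), ("t", "c2")])
        # gene 'b': rank 2 in c1 (descending), rank 7 in c2 -> check directly
        rp_up = rp.rank_product(fc, "up")
        assert rp_up["b"] == pytest.approx(np.sqrt(2 * 7))

    def test_ties_average_against_reference(self, rng):
        d = rng.integers(0, 3, size=(6, 3)).astype(float)  # many ties
        fc = rp.FCMatrix(
            data=pd.DataFrame(d, index=list("abcdef")),
            pairs=[("t", f"c{j}") for j in range(3)],
        )
        ref = np.ones(6)
        for j in range(3):
            ref *= stats.rankdata(-d[:, j])
        np.testing.assert_allclose(rp.rank_product(fc, "up").values, ref ** (1 / 3))


class TestPermutationPfp:
    def _random_fc(self, rng, G=4, k=2):
        return rp.FCMatrix(
            data=pd.DataFrame(
                rng.normal(size=(G, k)), index=[f"g{i}" for i in range(G)]
            ),
            pairs=[("t", f"c{j}") for j in range(k)],
        )

    @pytest.mark.parametrize("G,k,seed", [(4, 2, 0), (5, 2, 1), (4, 1, 2), (5, 1, 3)])
    def test_exhaustive_matches_enumeration_oracle(self, G, k, seed):
        rng = np.random.default_rng(seed)
        fc = self._random_fc(rng, G, k)
        res = rp.permutation_pfp(fc, direction="up", exhaustive=True)
        ranks = np.column_stack(
            [stats.rankdata(-fc.data.values[:, j]) for j in range(k)]
        )
        perms = list(itertools.permutations(range(G)))
        null = []
        for assignment in itertools.product(perms, repeat=k):
            prod = np.ones(G)
            for j, p in enumerate(assignment):
                prod *= ranks[list(p), j]
            null.append(prod)
        null = np.concatenate(null)
        obs = ranks.prod(axis=1)
        oracle = np.array([(null <= o).sum() / null.size for o in obs])
        np.testing.assert_array_equal(res["pval"].values, oracle)

    def test_rank_one_gene_pfp_identity(self, rng):
        fc = self._random_fc(rng, G=20, k=3)
        res = rp.permutation_pfp(fc, n_perm=100, seed=0, direction="up")
        top = res[res["rank"] == 1].iloc[0]
        assert top["pfp"] == pytest.approx(top["pval"] * 20)

    def test_deterministic_given_seed(self, rng):
        fc = self._random_fc(rng, G=30, k=4)
        a = rp.permutation_pfp(fc, n_perm=200, seed=42, direction="up")
        b = rp.permutation_pfp(fc, n_perm=200, seed=42, direction="up")
        pd.testing.assert_frame_equal(a, b)

    def test_requires_n_perm(self, rng):
        fc = self._random_fc(rng)
        with pytest.raises(ValueError):
            rp.permutation_pfp(fc, n_perm=0, seed=1)


class TestRankProductTest:
    def _toy_m(self, rng, G=40):
        arrays = ["t1", "t2", "t3", "c1", "c2"]
        data = pd.DataFrame(
            rng.normal(size=(G, 5)), columns=arrays,
            index=[f"g{i}" for i in range(G)],
        )
        return _mvalues(data, ["tumour"] * 3 + ["control"] * 2)

    @pytest.mark.parametrize("scheme", ["columns", "arrays"])
    def test_sign_symmetry(self, rng, scheme):
        """Negating all M values swaps UP and DOWN results exactly."""
        m = self._toy_m(rng)
        neg = MValueTable(values=-m.values, meta=m.meta)
        r1 = rp.rank_product_test(m, n_perm=150, seed=9, scheme=scheme).table
        r2 = rp.rank_product_test(neg, n_perm=150, seed=9, scheme=scheme).table
        np.testing.assert_allclose(r1["pval_up"], r2["pval_down"], rtol=1e-12)
        np.testing.assert_allclose(r1["rp_up"], r2["rp_down"], rtol=1e-12)
        np.testing.assert_allclose(r1["FC"], 1.0 / r2["FC"], rtol=1e-9)

    def test_gene_relabelling_permutes_outputs(self, rng):
        """Permutation invariance under the columns scheme."""
        m = self._toy_m(rng)
        perm = rng.permutation(len(m.values))
        shuffled = MValueTable(values=m.values.iloc[perm], meta=m.meta)
        r1 = rp.rank_product_test(m, n_perm=100, seed=3, scheme="columns").table
        r2 = rp.rank_product_test(shuffled, n_perm=100, seed=3, scheme="columns").table
        pd.testing.assert_frame_equal(r1.loc[r2.index], r2)

    def test_ranks_are_permutations(self, rng):
        t = rp.rank_product_test(self._toy_m(rng), n_perm=100, seed=1).table
        for col in ("rank_up", "rank_down"):
            assert sorted(t[col]) == list(range(1, len(t) + 1))


class TestSignificantGenes:
    def _result(self, fc, pfp_up, pfp_down=None):
        G = len(fc)
        table = pd.DataFrame(
            {
                "FC": fc,
                "rank_up": np.arange(1, G + 1),
                "rp_up": np.arange(1, G + 1, dtype=float),
                "pval_up": pfp_up,
                "pfp_up": pfp_up,
                "rank_down": np.arange(1, G + 1)[::-1],
                "rp_down": np.arange(1, G + 1, dtype=float)[::-1],
                "pval_down": pfp_down if pfp_down is not None else [1.0] * G,
                "pfp_down": pfp_down if pfp_down is not None else [1.0] * G,
            },
            index=[f"g{i}" for i in range(G)],
        )
        return rp.RankProdResult(table=table, n_perm=100, scheme="columns")

    def test_worked_example_gene_included(self):
        # FC 6.4 at pfp 0.000227: comfortably inside the UP list
        res = self._result([6.4, 1.0], [0.000227273, 0.9])
        up, _ = rp.significant_genes(res)
        assert up == ["g0"]

    def test_fc_below_threshold_excluded(self):
        res = self._result([1.5, 1.0], [0.01, 0.9])
        up, _ = rp.significant_genes(res)
        assert up == []

    def test_pfp_boundary_is_strict(self):
        res = self._result([4.0, 1.0], [0.2, 0.9])
        up, _ = rp.significant_genes(res)
        assert up == []

    def test_fc_boundary_is_inclusive(self):
        res = self._result([2.0, 1.0], [0.01, 0.9])
        up, _ = rp.significant_genes(res)
        assert up == ["g0"]

    def test_down_list_uses_reciprocal_threshold(self):
        res = self._result([0.4, 1.0], [0.9, 0.9], pfp_down=[0.01, 0.9])
        _, down = rp.significant_genes(res)
        assert down == ["g0"]


class TestVolcanoAndClustering:
    def test_volcano_duplication_contract(self, rng):
        arrays = ["t1", "c1"]
        data = pd.DataFrame(
            rng.normal(size=(10, 2)), columns=arrays,
            index=[f"g{i}" for i in range(10)],
        )
        m = _mvalues(data, ["tumour", "control"])
        res = rp.rank_product_test(m, n_perm=50, seed=0, scheme="columns")
        v = rp.volcano_table(res)
        assert len(v) == 20
        g0 = v[v["gene"] == "g0"]
        assert set(g0["arm"]) == {"up", "down"}
        up_row = g0[g0["arm"] == "up"].iloc[0]
        assert up_row["neg_log10_pval"] == pytest.approx(
            -np.log10(res.table.loc["g0", "pval_up"])
        )

    def test_volcano_tsv_roundtrip(self, rng, tmp_path):
        from translatome import io as tio

        data = pd.DataFrame(
            rng.normal(size=(5, 2)), columns=["t1", "c1"],
            index=[f"g{i}" for i in range(5)],
        )
        m = _mvalues(data, ["tumour", "control"])
        v = rp.volcano_table(rp.rank_product_test(m, n_perm=20, seed=0,
                                                  scheme="columns"))
        path = tmp_path / "volcano.tsv"
        tio.write_tsv(v, path, index=False)
        back = pd.read_csv(path, sep="\t")
        pd.testing.assert_frame_equal(v, back)

    def test_pearson_distance_identical_and_anticorrelated(self):
        x = np.arange(10, dtype=float)
        data = pd.DataFrame({"t1": x, "t2": x, "c1": -x})
        m = _mvalues(data, ["tumour", "tumour", "control"])
        d = rp.pearson_distance_matrix(m)
        assert d.loc["t1", "t2"] == pytest.approx(0.0, abs=1e-12)
        assert d.loc["t1", "c1"] == pytest.approx(2.0, abs=1e-12)
        assert np.allclose(np.diag(d.values), 0)

    def test_pearson_distance_matches_direct_formula(self, rng):
        data = pd.DataFrame(
            rng.normal(size=(30, 5)),
            columns=["t1", "t2", "t3", "c1", "c2"],
        )
        m = _mvalues(data, ["tumour"] * 3 + ["control"] * 2)
        d = rp.pearson_distance_matrix(m)
        for a in data.columns:
            for b in data.columns:
                r = stats.pearsonr(data[a], data[b]).statistic
                expect = 0.0 if a == b else 1 - r
                assert d.loc[a, b] == pytest.approx(expect, abs=1e-12)

    def test_zero_variance_array_named(self):
        data = pd.DataFrame({"t1": [1.0, 2.0], "c1": [3.0, 3.0]})
        m = _mvalues(data, ["tumour", "control"])
        with pytest.raises(ValueError, match="c1"):
            rp.pearson_distance_matrix(m)

    def test_average_linkage_newick_has_all_leaves(self, rng):
        data = pd.DataFrame(
            rng.normal(size=(30, 4)), columns=["t1", "t2", "c1", "c2"]
        )
        m = _mvalues(data, ["tumour", "tumour", "control", "control"])
        nwk = rp.average_linkage_tree(rp.pearson_distance_matrix(m))
        assert nwk.endswith(";")
        for a in data.columns:
            assert a in nwk
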