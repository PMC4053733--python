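import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import cophenet
from scipy.spatial.distance import squareform

import comethnet as cn
from comethnet.modules import (
    cluster_dissimilarity,
    consensus_kme,
    cut_tree_adaptive,
    kme,
    module_eigengene,
    module_trait_table,
    top_module_probes,
)
from conftest import rank1_beta


def block_dissimilarity(sizes, within=0.1, between=0.9, jitter=0.0, seed=0):
    n = sum(sizes)
    d = np.full((n, n), between)
    start = 0
    for s in sizes:
        d[start : start + s, start : start + s] = within
        start += s
    if jitter:
        rng = np.random.default_rng(seed)
        noise = rng.uniform(0, jitter, size=(n, n))
        d += (noise + noise.T) / 2
    np.fill_diagonal(d, 0.0)
    return d


class TestClustering:
    def test_top_split_separates_blocks(self):
        d = block_dissimilarity([10, 10])
        link = cluster_dissimilarity(d)
        from scipy.cluster.hierarchy import fcluster

        two = fcluster(link, t=2, criterion="maxclust")
        assert len(set(two[:10])) == 1 and len(set(two[10:])) == 1
        assert two[0] != two[10]

    def test_two_probes_single_merge(self):
        d = np.array([[0.0, 0.37], [0.37, 0.0]])
        link = cluster_dissimilarity(d)
        assert link.shape == (1, 4)
        assert link[0, 2] == pytest.approx(0.37)

    def test_permutation_invariance_via_cophenetic(self):
        d = block_dissimilarity([6, 8], jitter=0.05, seed=1)
        rng = np.random.default_rng(2)
        perm = rng.permutation(d.shape[0])
        link_a = cluster_dissimilarity(d)
        link_b = cluster_dissimilarity(d[np.ix_(perm, perm)])
        coph_a = squareform(cophenet(link_a))
        coph_b = squareform(cophenet(link_b))
        assert np.allclose(coph_a[np.ix_(perm, perm)], coph_b, atol=1e-12)

    def test_rejects_invalid_input(self):
        with pytest.raises(ValueError):
            cluster_dissimilarity(np.array([[0.0, 0.5], [0.4, 0.0]]))
        with pytest.raises(ValueError):
            cluster_dissimilarity(np.array([[0.0, -0.1], [-0.1, 0.0]]))


class TestTreeCut:
    def test_planted_blocks_recovered(self):
        d = block_dissimilarity([60, 40], jitter=0.05, seed=3)
        ids = [f"cg{i}" for i in range(100)]
        link = cluster_dissimilarity(d)
        ms = cut_tree_adaptive(link, ids, min_module_size=30, cut_height=0.5)
        assert ms.module_labels == [1, 2]
        assert set(ms.module_probes(1)) == set(ids[:60])
        assert set(ms.module_probes(2)) == set(ids[60:])

    def test_labels_ordered_by_size(self):
        d = block_dissimilarity([20, 50], jitter=0.02, seed=4)
        ids = [f"cg{i}" for i in range(70)]
        ms = cut_tree_adaptive(cluster_dissimilarity(d), ids, min_module_size=10, cut_height=0.5)
        assert len(ms.module_probes(1)) == 50
        assert len(ms.module_probes(2)) == 20

    def test_oversized_minimum_gives_all_grey(self):
        d = block_dissimilarity([10, 10])
        ids = [f"cg{i}" for i in range(20)]
        ms = cut_tree_adaptive(cluster_dissimilarity(d), ids, min_module_size=50)
        assert (ms.labels == 0).all()
        assert (ms.colors == "grey").all()

    def test_noise_rarely_yields_modules(self):
        """Dissimilarities built from pure-noise data almost never
        produce a module at default settings."""
        found = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            X = rng.uniform(0.2, 0.8, size=(120, 30))
            beta = pd.DataFrame(
                X, index=[f"cg{i}" for i in range(120)],
                columns=[f"s{j}" for j in range(30)],
            )
            adj = cn.signed_adjacency(beta, cn.NetworkConfig(correlation="pearson"))
            diss = 1.0 - cn.tom(adj)
            ms = cut_tree_adaptive(cluster_dissimilarity(diss), list(beta.index))
            found += len(ms.module_labels) > 0
        assert found < 5

    def test_min_module_size_validation(self):
        with pytest.raises(ValueError):
            cut_tree_adaptive(np.zeros((1, 4)), ["a", "b"], min_module_size=1)


class TestEigengene:
    def test_rank_one_module(self):
        beta = rank1_beta()
        eg, pve = module_eigengene(beta, list(beta.index))
        assert pve == pytest.approx(1.0, abs=1e-10)
        v = beta.iloc[0].to_numpy()
        r = np.corrcoef(eg.to_numpy(), v)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-8)

    def test_two_orthogonal_groups_split_variance(self):
        rng = np.random.default_rng(6)
        u, v = rng.normal(size=60), rng.normal(size=60)
        rows = [0.5 + 0.05 * u] * 5 + [0.5 + 0.05 * v] * 5
        beta = pd.DataFrame(
            np.clip(rows, 0, 1), index=[f"p{i}" for i in range(10)],
            columns=[f"s{j}" for j in range(60)],
        )
        _, pve = module_eigengene(beta, list(beta.index))
        assert pve == pytest.approx(0.5, abs=0.1)

    def test_orientation_positive_mean_member_correlation(self):
        beta = rank1_beta()
        flipped = 1.0 - beta  # anti-correlated copies
        eg1, _ = module_eigengene(beta, list(beta.index))
        eg2, _ = module_eigengene(flipped, list(flipped.index))
        m1 = np.mean([np.corrcoef(eg1, beta.loc[p])[0, 1] for p in beta.index])
        m2 = np.mean([np.corrcoef(eg2, flipped.loc[p])[0, 1] for p in flipped.index])
        assert m1 > 0 and m2 > 0

    def test_errors(self):
        beta = rank1_beta()
        with pytest.raises(ValueError):
            module_eigengene(beta, [beta.index[0]])
        constant = beta.copy()
        constant.iloc[:, :] = 0.5
        with pytest.raises(ValueError):
            module_eigengene(constant, list(constant.index))


class TestKME:
    def test_rank_one_module_members_have_kme_one(self):
        beta = rank1_beta()
        eg, _ = module_eigengene(beta, list(beta.index))
        table = kme(beta, pd.DataFrame({1: eg}))
        assert np.allclose(table[1], 1.0, atol=1e-8)

    def test_anticorrelated_probe_negative(self):
        beta = rank1_beta()
        eg, _ = module_eigengene(beta, list(beta.index))
        anti = pd.concat([beta, (1.0 - beta.iloc[[0]]).rename(index={"p0": "anti"})])
        table = kme(anti, pd.DataFrame({1: eg}))
        assert table.loc["anti", 1] == pytest.approx(-1.0, abs=1e-8)

    def test_consensus_is_arithmetic_mean(self):
        idx = pd.Index(["cgA"], name="probe_id")
        kmes = {
            "d1": pd.DataFrame({1: [0.5]}, index=idx),
            "d2": pd.DataFrame({1: [0.7]}, index=idx),
        }
        out = consensus_kme(kmes)
        assert out.loc["cgA", "kME1"] == pytest.approx(0.6)


class TestTraitTableAndRanking:
    def test_eigengene_equal_to_age(self):
        ages = np.linspace(20, 80, 15)
        eg = pd.DataFrame({1: (ages - 50) / 60}, index=[f"s{j}" for j in range(15)])
        st = pd.DataFrame(
            {"sample_id": eg.index, "age": ages, "sex": "female",
             "disease": "x", "tissue": "b", "dataset": "d"}
        )
        table = module_trait_table({"d": eg}, {"d": st})
        assert table.loc[0, "r"] == pytest.approx(1.0)
        assert table.loc[0, "p_one_sided"] == pytest.approx(table.loc[0, "p"] / 2)

    def test_planted_module_age_positive_everywhere(self, small_run):
        aging_rows = small_run.trait_table.query("module == 1")
        assert (aging_rows["r"] > 0).all()

    def test_permuted_age_kills_association(self, small_run):
        rng = np.random.default_rng(12)
        hits = 0
        n_perm = 100
        eg = {n: small_run.eigengenes[n] for n in small_run.eigengenes}
        for _ in range(n_perm):
            perm_tables = {}
            for n, st in small_run.sample_tables.items():
                st2 = st.copy()
                st2["age"] = rng.permutation(st2["age"].to_numpy())
                perm_tables[n] = st2
            table = module_trait_table(eg, perm_tables)
            p = table.query("module == 1")["p"]
            hits += (p < 0.01).any()
        assert hits <= 0.05 * n_perm + 3

    def test_top_module_probes_ranking(self, small_run):
        ck = small_run.consensus_kme
        top1 = top_module_probes(ck, 1, 1)
        assert top1.index[0] == ck["kME1"].idxmax()
        all_ranked = top_module_probes(ck, 1, len(ck))
        assert len(all_ranked) == len(ck)
        assert all_ranked["kME1"].is_monotonic_decreasing

    def test_planted_module_recovered_by_kme_ranking(self, small_run, small_design):
        size = small_design.planted_modules[0].size
        top = top_module_probes(small_run.consensus_kme, 1, size)
        planted = set(small_design.planted_modules[0].member_ids)
        assert len(set(top.index) & planted) / size >= 0.9

    def test_kme_and_meta_z_rank_agree_on_module(self, small_run, small_design):
        """The module-membership and marginal meta-analysis measures
        rank planted aging probes concordantly."""
        aging = list(small_design.planted_modules[0].member_ids)
        ck = small_run.consensus_kme.loc[aging, "kME1"]
        mz = small_run.meta_tables["all"].loc[aging, "metaZ"]
        rho = ck.rank().corr(mz.rank())
        assert rho > 0.3
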