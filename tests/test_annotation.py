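import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import comethnet as cn
from comethnet.annotation import (
    anova_decomposition,
    flag_filter_probes,
    grouped_membership_summary,
    hypergeometric_enrichment,
    kruskal_wallis,
    read_gene_lists,
)


class TestGroupedSummary:
    def test_constant_values_zero_se(self):
        out = grouped_membership_summary(
            pd.Series([0.3] * 6), pd.Series(["a", "a", "b", "b", "c", "c"])
        )
        assert np.allclose(out["se"], 0.0)

    def test_two_group_hand_case(self):
        out = grouped_membership_summary(
            pd.Series([0.0, 0.0, 1.0, 1.0]), pd.Series(["g0", "g0", "g1", "g1"])
        )
        assert list(out["mean"]) == [0.0, 1.0]
        assert list(out["se"]) == [0.0, 0.0]

    def test_planted_enrichment_raises_mean_kme_with_pcg(self, small_run, small_design):
        ann = cn.generate_probe_annotation(small_design, enrichment_odds=3.0)
        ann = ann.set_index("probe_id").loc[small_run.consensus_kme.index]
        out = grouped_membership_summary(
            small_run.consensus_kme["kME1"], ann["pcg_occupancy"]
        )
        means = out.sort_values("group")["mean"].to_numpy()
        assert np.all(np.diff(means) > 0)


class TestKruskalWallis:
    def test_hand_computed_no_ties(self):
        h, p = kruskal_wallis(pd.Series([1, 2, 3, 4]), pd.Series(["a", "a", "b", "b"]))
        # ranks 1,2 | 3,4: H = 12/(4*5) * (2*(1.5-2.5)^2 + 2*(3.5-2.5)^2) = 2.4
        assert h == pytest.approx(2.4)
        assert p == pytest.approx(float(stats.chi2.sf(2.4, 1)))

    def test_identical_values_null(self):
        h, p = kruskal_wallis(pd.Series([5.0] * 6), pd.Series(["a", "b", "c"] * 2))
        assert h == 0.0 and p == 1.0

    def test_large_separation_tiny_p(self):
        rng = np.random.default_rng(0)
        v = np.concatenate([rng.normal(0, 1, 50), rng.normal(20, 1, 50)])
        g = pd.Series(["lo"] * 50 + ["hi"] * 50)
        _, p = kruskal_wallis(pd.Series(v), g)
        assert p < 1e-10

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        v = pd.Series(rng.uniform(size=30))
        g = pd.Series(rng.choice(["a", "b", "c"], size=30))
        h1, _ = kruskal_wallis(v, g)
        h2, _ = kruskal_wallis(np.exp(5 * v), g)
        assert h1 == pytest.approx(h2)


class TestAnova:
    def test_perfect_binary_fit(self):
        rng = np.random.default_rng(2)
        f = pd.DataFrame({"flag": rng.integers(0, 2, size=100).astype(float)})
        out = anova_decomposition(pd.Series(f["flag"] * 2.0 + 1.0), f)
        assert out.loc["flag", "prop_var"] == pytest.approx(1.0, abs=1e-10)
        assert out.loc["residual", "prop_var"] == pytest.approx(0.0, abs=1e-10)

    def test_independent_response_attributes_nothing(self):
        rng = np.random.default_rng(3)
        n = 10_000
        f = pd.DataFrame(
            {
                "pcg": rng.integers(0, 4, size=n).astype(float),
                "island": rng.choice(["island", "shore", "outside"], size=n),
                "x_chr": rng.integers(0, 2, size=n).astype(float),
            }
        )
        out = anova_decomposition(
            pd.Series(rng.normal(size=n)), f, categorical=("island",)
        )
        for factor in ("pcg", "island", "x_chr"):
            assert out.loc[factor, "prop_var"] < 0.01

    def test_proportions_sum_to_one(self):
        rng = np.random.default_rng(4)
        f = pd.DataFrame(
            {"a": rng.normal(size=200), "b": rng.choice(["u", "v"], size=200)}
        )
        y = pd.Series(f["a"] * 0.5 + rng.normal(size=200))
        out = anova_decomposition(y, f, categorical=("b",))
        assert out.drop(index="total")["prop_var"].sum() == pytest.approx(1.0, abs=1e-12)
        assert out.loc["b", "df"] == 1

    def test_balanced_orthogonal_design_order_invariant(self):
        # full factorial 2x2, balanced -> sequential SS = marginal SS
        a = np.repeat([0.0, 1.0], 20)
        b = np.tile(np.repeat([0.0, 1.0], 10), 2)
        rng = np.random.default_rng(5)
        y = pd.Series(1.0 * a + 2.0 * b + rng.normal(0, 0.5, size=40))
        out_ab = anova_decomposition(y, pd.DataFrame({"a": a, "b": b}))
        out_ba = anova_decomposition(y, pd.DataFrame({"b": b, "a": a}))
        assert out_ab.loc["a", "sum_sq"] == pytest.approx(out_ba.loc["a", "sum_sq"], rel=1e-10)
        assert out_ab.loc["b", "sum_sq"] == pytest.approx(out_ba.loc["b", "sum_sq"], rel=1e-10)

    def test_matches_statsmodels_on_continuous_factors(self):
        """Independent check against statsmodels' type-I table (term
        order is unambiguous when all covariates are continuous)."""
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(9)
        f = pd.DataFrame({"a": rng.normal(size=80), "b": rng.normal(size=80)})
        y = pd.Series(0.4 * f["a"] - 0.2 * f["b"] + rng.normal(size=80))
        ours = anova_decomposition(y, f)
        data = f.assign(_y=y)
        ref = sm.stats.anova_lm(smf.ols("_y ~ a + b", data=data).fit(), typ=1)
        for name in ("a", "b"):
            assert ours.loc[name, "sum_sq"] == pytest.approx(ref.loc[name, "sum_sq"], rel=1e-10)
            assert ours.loc[name, "F"] == pytest.approx(ref.loc[name, "F"], rel=1e-10)
            assert ours.loc[name, "p"] == pytest.approx(ref.loc[name, "PR(>F)"], rel=1e-10)

    def test_island_status_uses_two_df(self, small_run, small_design):
        ann = cn.generate_probe_annotation(small_design).set_index("probe_id")
        ann = ann.loc[small_run.consensus_kme.index]
        f = pd.DataFrame(
            {
                "pcg_occupancy": ann["pcg_occupancy"].astype(float),
                "island_status": ann["island_status"],
                "x_chromosome": (ann["chromosome"] == "X").astype(float),
                "distance_to_tss": ann["distance_to_tss"].astype(float),
            }
        )
        out = anova_decomposition(
            small_run.consensus_kme["kME1"], f, categorical=("island_status",)
        )
        assert out.loc["island_status", "df"] == 2
        assert out.loc["x_chromosome", "df"] == 1


def brute_force_hypergeom(N, K, n, x, tail):
    """Exhaustive enumeration over all C(N, n) draws."""
    universe = range(N)
    hits = 0
    total = 0
    for draw in itertools.combinations(universe, n):
        overlap = sum(1 for g in draw if g < K)
        total += 1
        if tail == "over" and overlap >= x:
            hits += 1
        if tail == "under" and overlap <= x:
            hits += 1
    return hits / total


class TestHypergeometric:
    def test_printed_example(self):
        out = hypergeometric_enrichment(
            {f"g{i}" for i in range(4)},
            {"list": {f"g{i}" for i in range(5)}},
            {f"g{i}" for i in range(10)},
            tail="over",
        )
        assert out.loc[0, "overlap"] == 4
        assert out.loc[0, "p"] == pytest.approx(comb(5, 4) * comb(5, 0) / comb(10, 4))

    @pytest.mark.parametrize("tail", ["over", "under"])
    def test_matches_exhaustive_enumeration(self, tail):
        rng = np.random.default_rng(11)
        for _ in range(6):
            N = int(rng.integers(6, 13))
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            universe = {f"g{i}" for i in range(N)}
            lst = {f"g{i}" for i in range(K)}
            module = set(rng.choice(sorted(universe), size=n, replace=False))
            out = hypergeometric_enrichment(module, {"l": lst}, universe, tail=tail)
            x = out.loc[0, "overlap"]
            assert out.loc[0, "p"] == pytest.approx(
                brute_force_hypergeom(N, K, n, x, tail), abs=1e-12
            )

    def test_tail_identity(self):
        # P[X >= x] + P[X <= x] = 1 + P[X = x]
        N, K, n, x = 12, 5, 6, 3
        over = float(stats.hypergeom.sf(x - 1, N, K, n))
        under = float(stats.hypergeom.cdf(x, N, K, n))
        pmf = float(stats.hypergeom.pmf(x, N, K, n))
        assert over + under == pytest.approx(1.0 + pmf, abs=1e-12)

    def test_bonferroni_and_disjoint_list(self):
        universe = {f"g{i}" for i in range(20)}
        module = {f"g{i}" for i in range(5)}
        lists = {"hit": {"g0", "g1", "g2"}, "empty": {"zz1", "zz2"}}
        with pytest.warns(UserWarning, match="disjoint"):
            out = hypergeometric_enrichment(module, lists, universe)
        assert list(out["list_name"]) == ["hit"]
        assert out.loc[0, "p_bonferroni"] == pytest.approx(out.loc[0, "p"])

    def test_module_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            hypergeometric_enrichment({"nope"}, {"l": {"a"}}, {"a", "b"})


class TestFlags:
    def _probes(self, n, poly_idx=()):
        return pd.DataFrame(
            {
                "probe_id": [f"cg{i}" for i in range(n)],
                "polymorphic": [i in poly_idx for i in range(n)],
                "cross_reactive": False,
            }
        )

    def test_no_flags(self):
        counts, filtered = flag_filter_probes(self._probes(10), [f"cg{i}" for i in range(4)])
        assert (counts["module_flagged"] == 0).all()
        assert len(filtered) == 4

    def test_all_module_probes_flagged(self):
        probes = self._probes(10, poly_idx=range(4))
        counts, filtered = flag_filter_probes(probes, [f"cg{i}" for i in range(4)])
        row = counts.set_index("flag").loc["polymorphic"]
        assert row["module_flagged"] == 4 == row["module_size"]
        assert filtered == []

    def test_independent_flags_within_binomial_bounds(self, small_design):
        ann = cn.generate_probe_annotation(small_design, polymorphic_rate=0.05)
        module = [f"cg{i:05d}" for i in range(60)]
        counts, _ = flag_filter_probes(ann, module, ("polymorphic",))
        flagged = counts.loc[0, "module_flagged"]
        lo, hi = stats.binom.ppf([0.005, 0.995], 60, 0.05)
        assert lo <= flagged <= hi

    def test_unknown_flag(self):
        with pytest.raises(KeyError):
            flag_filter_probes(self._probes(5), ["cg0"], ("bogus",))


def test_read_gene_lists(tmp_path):
    path = tmp_path / "lists.tsv"
    path.write_text("list_name\tgene\nbrain\tGENE1\nbrain\tGENE2\nblood\tGENE3\n")
    lists = read_gene_lists(path)
    assert lists == {"brain": {"GENE1", "GENE2"}, "blood": {"GENE3"}}
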