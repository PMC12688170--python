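import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import leukotype as lt
from leukotype.core_io import CohortError, GeneSetCollection
from leukotype.subtype_signatures import estimate_variance_prior


def _de_table(genes, log2fc, adj_p):
    return pd.DataFrame(
        {"log2fc": log2fc, "adj_p": adj_p, "p": adj_p, "t": log2fc},
        index=pd.Index(genes),
    )


class TestModeratedT:
    def test_identical_groups_give_zero_fc_and_p_one(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(50, 6))
        res = lt.moderated_ttest(base, base.copy())
        np.testing.assert_allclose(res["diff"], 0.0, atol=1e-12)
        np.testing.assert_allclose(res["p"], 1.0, atol=1e-9)

    def test_zero_prior_df_reproduces_pooled_t(self):
        """With no moderation the statistic is the ordinary pooled t."""
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=(10, 8)), rng.normal(0.5, 1, size=(10, 9))
        res = lt.moderated_ttest(a, b, prior_df=0)
        expected = stats.ttest_ind(a, b, axis=1, equal_var=True)
        np.testing.assert_allclose(res["t"], expected.statistic, rtol=1e-9)
        np.testing.assert_allclose(res["p"], expected.pvalue, rtol=1e-9)

    def test_type_one_error_calibrated_under_null(self):
        fracs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            a = rng.normal(size=(1000, 20))
            b = rng.normal(size=(1000, 20))
            res = lt.moderated_ttest(a, b)
            fracs.append(float((res["p"] < 0.05).mean()))
        assert 0.03 <= np.mean(fracs) <= 0.07

    def test_variance_prior_recovers_planted_hyperparameters(self):
        rng = np.random.default_rng(3)
        d0_true, s0_true, df = 8.0, 2.0, 18
        s2 = (
            s0_true * d0_true / stats.chi2.rvs(d0_true, size=20_000,
                                               random_state=rng)
        ) * stats.chi2.rvs(df, size=20_000, random_state=rng) / df
        d0, s0 = estimate_variance_prior(s2, df)
        assert d0 == pytest.approx(d0_true, rel=0.15)
        assert s0 == pytest.approx(s0_true, rel=0.1)

    def test_small_groups_rejected(self):
        with pytest.raises(CohortError):
            lt.moderated_ttest(np.zeros((5, 2)), np.zeros((5, 5)))


class TestDeriveSignature:
    def test_three_subtypes_with_ample_markers_give_150(self):
        tables = {}
        for s in range(3):
            genes = [f"s{s}_g{i}" for i in range(100)] + ["shared"]
            fc = list(np.linspace(3, 1, 100)) + [2.0]
            tables[s + 1] = _de_table(genes, fc, [0.001] * 101)
        sig = lt.derive_signature(tables)
        assert [len(sig.genes(s)) for s in (1, 2, 3)] == [50, 50, 50]
        assert len(set(sig.all_genes())) == 150

    def test_shared_genes_removed_everywhere(self):
        t1 = _de_table(["u1", "both"], [2.0, 3.0], [0.01, 0.01])
        t2 = _de_table(["u2", "both"], [2.0, 3.0], [0.01, 0.01])
        sig = lt.derive_signature({1: t1, 2: t2})
        assert "both" not in sig.all_genes()
        assert sig.genes(1) == ["u1"] and sig.genes(2) == ["u2"]

    def test_short_list_warns(self):
        t1 = _de_table([f"a{i}" for i in range(30)], [2.0] * 30, [0.01] * 30)
        t2 = _de_table([f"b{i}" for i in range(60)], [2.0] * 60, [0.01] * 60)
        with pytest.warns(UserWarning, match="only 30"):
            sig = lt.derive_signature({1: t1, 2: t2})
        assert len(sig.genes(1)) == 30

    def test_no_candidates_rejected(self):
        t = _de_table(["g"], [-1.0], [0.9])
        with pytest.raises(CohortError):
            lt.derive_signature({1: t})

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(0)
        tables = {
            s: _de_table(
                [f"s{s}_g{i}" for i in range(80)],
                rng.uniform(0.5, 3, 80),
                rng.uniform(0, 0.1, 80),
            )
            for s in (1, 2)
        }
        # top_n above the candidate count: truncation would otherwise let a
        # lower-fold-change gene enter when a stricter p drops a higher one
        loose = set(
            lt.derive_signature(tables, top_n=200, adj_p_max=0.1).all_genes()
        )
        strict = set(
            lt.derive_signature(tables, top_n=200, adj_p_max=0.02).all_genes()
        )
        assert strict <= loose
        few = set(lt.derive_signature(tables, top_n=10, adj_p_max=0.1).all_genes())
        many = set(lt.derive_signature(tables, top_n=30, adj_p_max=0.1).all_genes())
        assert few <= many

    def test_invariant_to_gene_order(self):
        t1 = _de_table(["a", "b", "c"], [3.0, 2.0, 1.0], [0.01] * 3)
        t2 = _de_table(["x", "y"], [2.0, 1.0], [0.01] * 2)
        sig = lt.derive_signature({1: t1, 2: t2}, top_n=2)
        sig_r = lt.derive_signature(
            {1: t1.iloc[::-1], 2: t2.iloc[::-1]}, top_n=2
        )
        assert sig.genes(1) == sig_r.genes(1)

    def test_planted_markers_recovered_on_synthetic_cohorts(self):
        from leukotype.synthetic_cohort import marker_blocks

        rates = []
        for seed in range(5):
            cfg = lt.SimConfig(seed=seed, n_markers_per_subtype=50)
            cohort, truth = lt.simulate_cohort(cfg)
            de = {s: lt.de_one_vs_rest(cohort.expression, truth, s) for s in (1, 2, 3)}
            sig = lt.derive_signature(de)
            blocks = marker_blocks(cfg)
            found = sum(
                len(set(sig.genes(s)) & set(blocks[s])) for s in (1, 2, 3)
            )
            rates.append(found / sum(len(b) for b in blocks.values()))
        assert np.median(rates) >= 0.9


def _brute_force_es(scores, hits, weight):
    """Direct evaluation of the weighted KS running sum."""
    n = len(scores)
    n_hit = sum(hits)
    denom = sum(abs(s) ** weight for s, h in zip(scores, hits) if h)
    running, cum = [], 0.0
    for s, h in zip(scores, hits):
        cum += (abs(s) ** weight / denom) if h else -1.0 / (n - n_hit)
        running.append(cum)
    return max(running, key=abs)


class TestPrerankedGsea:
    @pytest.fixture()
    def ranked(self):
        return pd.Series(
            [3.0, 2.0, 1.0, -1.0, -2.0], index=["a", "b", "c", "d", "e"]
        )

    def test_top_set_positive_bottom_set_negative(self, ranked):
        up = lt.preranked_gsea_single(ranked, ["a", "b"], n_perm=100, seed=0)
        down = lt.preranked_gsea_single(ranked, ["d", "e"], n_perm=100, seed=0)
        assert up["es"] > 0 and down["es"] < 0

    def test_es_matches_brute_force_over_all_placements(self, ranked):
        """5-gene universe, 2-gene set: every placement equals the hand
        running-sum evaluation."""
        genes = list(ranked.index)
        for pair in itertools.combinations(genes, 2):
            res = lt.preranked_gsea_single(ranked, list(pair), n_perm=100, seed=0)
            hits = [g in pair for g in genes]
            assert res["es"] == pytest.approx(
                _brute_force_es(ranked.to_numpy(), hits, 1.0), abs=1e-12
            )

    def test_weight_zero_invariant_to_monotone_transform(self, ranked):
        transformed = pd.Series(
            np.exp(ranked.to_numpy()), index=ranked.index
        )
        a = lt.preranked_gsea_single(ranked, ["a", "c"], n_perm=100, weight=0, seed=1)
        b = lt.preranked_gsea_single(
            transformed, ["a", "c"], n_perm=100, weight=0, seed=1
        )
        assert a["es"] == pytest.approx(b["es"], abs=1e-12)

    def test_empty_overlap_rejected(self, ranked):
        with pytest.raises(CohortError, match="no overlap"):
            lt.preranked_gsea_single(ranked, ["zzz"], n_perm=100, seed=0)

    def test_es_agrees_with_independent_gsea_implementation(self):
        """Cross-check against gseapy's preranked ES on a 10-gene list."""
        import gseapy

        rnk = pd.Series(
            [3.0, 2.5, 2.0, 1.0, 0.5, -0.5, -1.0, -2.0, -2.5, -3.0],
            index=[f"g{i}" for i in range(10)],
        )
        gene_set = ["g1", "g2", "g3"]
        theirs = gseapy.prerank(
            rnk=rnk.reset_index(), gene_sets={"S": gene_set},
            permutation_num=10, seed=0, min_size=2, max_size=10,
            outdir=None, no_plot=True, verbose=False,
        ).res2d
        ours = lt.preranked_gsea_single(rnk, gene_set, n_perm=100, seed=0)
        assert ours["es"] == pytest.approx(float(theirs["ES"].iloc[0]), abs=1e-9)

    def test_collection_interface_adds_bh(self, ranked):
        coll = GeneSetCollection(
            {"top": ("d", ["a", "b"]), "bottom": ("d", ["d", "e"])}
        )
        res = lt.preranked_gsea(ranked, coll, n_perm=100, seed=0)
        assert (res["adj_p"] >= res["p"] - 1e-12).all()
        assert np.sign(res.loc["top", "nes"]) == np.sign(res.loc["top", "es"])
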