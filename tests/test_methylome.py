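import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

import leukotype as lt
from leukotype.core_io import CohortError, MethylationMatrix, ProbeAnnotation
from leukotype.methylome_cimp import beta_to_m
from leukotype.synthetic_cohort import probe_annotation, simulate_normals


def _meth(beta: dict[str, list[float]], groups: dict[str, str]):
    df = pd.DataFrame(beta).T
    df.columns = list(groups)
    return MethylationMatrix(df, pd.Series(groups))


def _annot(rows):
    """rows: probe -> (cgi_class, promoter, enhancer)."""
    table = pd.DataFrame(
        {
            "cgi_class": {p: r[0] for p, r in rows.items()},
            "promoter": {p: r[1] for p, r in rows.items()},
            "enhancer": {p: r[2] for p, r in rows.items()},
        }
    )
    return ProbeAnnotation(table)


class TestSelectCimpProbes:
    @pytest.fixture()
    def setup(self):
        groups = {**{f"t{i}": "tumor" for i in range(4)},
                  **{f"n{i}": "normal" for i in range(2)}}
        beta = {
            # island, high in normals (0.95) -> excluded
            "bg_high": [0.1, 0.9, 0.1, 0.9, 0.95, 0.95],
            # island, low normal, variable tumors -> kept
            "keep": [0.1, 0.9, 0.1, 0.9, 0.5, 0.5],
            # island, low normal, flat tumors -> excluded by SD
            "flat": [0.5, 0.52, 0.5, 0.51, 0.5, 0.5],
            # shore with perfect signal -> excluded by class
            "shore": [0.1, 0.9, 0.1, 0.9, 0.5, 0.5],
        }
        annot = _annot({
            "bg_high": ("island", True, False),
            "keep": ("island", True, False),
            "flat": ("island", True, False),
            "shore": ("shore", True, False),
        })
        return _meth(beta, groups), annot

    def test_filters_applied(self, setup):
        meth, annot = setup
        assert lt.select_cimp_probes(meth, annot) == ["keep"]

    def test_monotone_in_thresholds(self, setup):
        meth, annot = setup
        loose = set(lt.select_cimp_probes(meth, annot, 0.99, 0.1))
        tight = set(lt.select_cimp_probes(meth, annot, 0.99, 0.3))
        assert tight <= loose
        loose_beta = set(lt.select_cimp_probes(meth, annot, 0.99, 0.1))
        tight_beta = set(
            lt.select_cimp_probes(meth, annot, normal_beta_max=0.6, tumor_sd_min=0.1)
        )
        assert tight_beta <= loose_beta

    def test_nothing_survives_reports_attrition(self, setup):
        meth, annot = setup
        with pytest.raises(CohortError, match="after"):
            lt.select_cimp_probes(meth, annot, tumor_sd_min=5.0)


class TestCallCimp:
    def test_high_sample_is_cimp_positive(self):
        groups = {**{f"t{i}": "tumor" for i in range(4)},
                  **{"n0": "normal", "n1": "normal"}}
        beta = {
            "p1": [0.9, 0.85, 0.1, 0.15, 0.2, 0.2],
            "p2": [0.8, 0.9, 0.2, 0.1, 0.2, 0.2],
        }
        meth = _meth(beta, groups)
        res = lt.call_cimp(meth, ["p1", "p2"])
        assert list(res.epi_cluster[["t0", "t1"]]) == ["CIMP+", "CIMP+"]
        assert list(res.epi_cluster[["t2", "t3"]]) == ["CIMP-", "CIMP-"]
        assert res.cluster_mean_beta["CIMP+"] > res.cluster_mean_beta["CIMP-"]

    def test_planted_cimp_structure_recovered(self):
        accs = []
        for seed in range(5):
            cfg = lt.SimConfig(seed=seed)
            cohort, truth = lt.simulate_cohort(cfg)
            normals = simulate_normals(9, cfg)
            combined = MethylationMatrix(
                pd.concat([cohort.methylation.beta, normals.beta], axis=1),
                pd.concat([cohort.methylation.sample_group, normals.sample_group]),
            )
            annot = probe_annotation(cfg)
            probes = lt.select_cimp_probes(combined, annot)
            res = lt.call_cimp(combined, probes)
            pred = (res.epi_cluster == "CIMP+").to_numpy()
            accs.append((pred == np.isin(truth, [3])).mean())
        assert np.median(accs) >= 0.9

    def test_deterministic(self, default_cohort):
        cohort, _ = default_cohort
        probes = cohort.methylation.probe_ids[:50]
        a = lt.call_cimp(cohort.methylation, probes)
        b = lt.call_cimp(cohort.methylation, probes)
        pd.testing.assert_series_equal(a.epi_cluster, b.epi_cluster)


class TestCallDmps:
    def test_m_value_transform(self):
        assert beta_to_m(np.array([0.5]))[0] == 0.0
        assert beta_to_m(np.array([0.8]))[0] == pytest.approx(2.0)
        assert np.isfinite(beta_to_m(np.array([0.0, 1.0]))).all()

    def test_identical_groups_yield_no_dmps(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(0.2, 0.8, size=(40, 6))
        beta = np.hstack([base, base])
        groups = {**{f"a{i}": "tumor" for i in range(6)},
                  **{f"b{i}": "tumor" for i in range(6)}}
        df = pd.DataFrame(beta, index=[f"p{i}" for i in range(40)],
                          columns=list(groups))
        meth = MethylationMatrix(df, pd.Series(groups))
        out = lt.call_dmps(meth, [f"a{i}" for i in range(6)],
                           [f"b{i}" for i in range(6)])
        assert len(out) == 0

    def test_planted_shift_recovered(self):
        hits = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n_probes, n_planted = 300, 40
            a = rng.beta(5, 5, size=(n_probes, 10))
            b = rng.beta(5, 5, size=(n_probes, 10))
            a[:n_planted] = rng.beta(16, 4, size=(n_planted, 10))  # ~0.8
            b[:n_planted] = rng.beta(10, 10, size=(n_planted, 10))  # ~0.5
            groups = {**{f"a{i}": "tumor" for i in range(10)},
                      **{f"b{i}": "tumor" for i in range(10)}}
            df = pd.DataFrame(np.hstack([a, b]),
                              index=[f"p{i}" for i in range(n_probes)],
                              columns=list(groups))
            meth = MethylationMatrix(df, pd.Series(groups))
            out = lt.call_dmps(meth, [f"a{i}" for i in range(10)],
                               [f"b{i}" for i in range(10)])
            planted = {f"p{i}" for i in range(n_planted)}
            hits.append(len(planted & set(out.index)) / n_planted)
        assert np.median(hits) >= 0.9

    def test_direction_follows_delta_sign(self, default_cohort):
        cohort, truth = default_cohort
        plus = list(np.array(cohort.sample_ids)[np.isin(truth, [3])])[:6]
        minus = list(np.array(cohort.sample_ids)[~np.isin(truth, [3])])[:6]
        out = lt.call_dmps(cohort.methylation, plus, minus)
        assert (
            (out["direction"] == "hyper") == (out["delta_beta"] >= 0)
        ).all()


class TestRegionDistribution:
    def test_all_promoter_hyper_gives_fraction_one(self):
        dmps = pd.DataFrame(
            {"direction": ["hyper", "hyper"], "delta_beta": [0.3, 0.4]},
            index=["p1", "p2"],
        )
        annot = _annot({
            "p1": ("island", True, False),
            "p2": ("island", True, False),
            "bg1": ("openSea", False, True),
            "bg2": ("shore", False, False),
        })
        out = lt.region_distribution(dmps, annot, ["p1", "p2", "bg1", "bg2"])
        row = out[(out["direction"] == "hyper") & (out["category"] == "promoter")]
        assert row["fraction_dmp"].iloc[0] == 1.0

    def test_enrichment_matches_hypergeometric(self):
        """Constructed 2×2: odds ratio and p equal direct hypergeometric
        enumeration."""
        n_probes = 1030
        probes = [f"d{i}" for i in range(30)] + [f"b{i}" for i in range(1000)]
        promoter = {f"d{i}": i < 20 for i in range(30)}
        promoter.update({f"b{i}": i < 100 for i in range(1000)})
        annot = _annot({p: ("island", promoter[p], False) for p in probes})
        dmps = pd.DataFrame(
            {"direction": "hyper", "delta_beta": 0.3},
            index=[f"d{i}" for i in range(30)],
        )
        out = lt.region_distribution(dmps, annot, [f"b{i}" for i in range(1000)])
        row = out[(out["direction"] == "hyper") & (out["category"] == "promoter")].iloc[0]
        assert row["odds_ratio"] == pytest.approx((20 * 900) / (10 * 100))
        # oracle: sum hypergeometric probabilities no larger than observed
        M, n, N = 1030, 120, 30  # universe, promoter total, draws (DMPs)
        p_obs = hypergeom.pmf(20, M, n, N)
        p_exact = sum(
            hypergeom.pmf(k, M, n, N)
            for k in range(max(0, N + n - M), min(n, N) + 1)
            if hypergeom.pmf(k, M, n, N) <= p_obs + 1e-12
        )
        assert row["p"] == pytest.approx(p_exact, abs=1e-9)

    def test_synthetic_cimp_pattern_reproduced(self, default_cohort):
        """Promoter-dominant hyper-DMPs and enhancer-dominant hypo-DMPs in
        CIMP+ vs CIMP− tumors."""
        cohort, truth = default_cohort
        cfg = lt.SimConfig(seed=11)
        annot = probe_annotation(cfg)
        ids = np.array(cohort.sample_ids)
        plus = list(ids[np.isin(truth, [3])])
        minus = list(ids[~np.isin(truth, [3])])
        dmps = lt.call_dmps(cohort.methylation, plus, minus,
                            min_delta_beta=0.2, annot=annot)
        out = lt.region_distribution(dmps, annot, cohort.methylation.probe_ids)

        def frac(direction, cat):
            row = out[(out["direction"] == direction) & (out["category"] == cat)]
            return row["fraction_dmp"].iloc[0]

        assert frac("hyper", "promoter") > frac("hyper", "enhancer")
        assert frac("hypo", "enhancer") > frac("hypo", "promoter")

    def test_empty_background_rejected(self):
        dmps = pd.DataFrame({"direction": ["hyper"], "delta_beta": [0.2]},
                            index=["p1"])
        annot = _annot({"p1": ("island", True, False)})
        with pytest.raises(CohortError):
            lt.region_distribution(dmps, annot, [])
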