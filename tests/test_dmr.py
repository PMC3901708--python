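"""Moderated t, promoter rank-sum, FDR, call rule, and clustering."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from medipdmr import SampleSheet
from medipdmr.dmr import (EBayesPrior, bh_fdr, call_dmrs, fit_ebayes_prior,
                          probe_moderated_t, promoter_ranksum,
                          representative_probes, trigamma_inverse,
                          ward_cluster, _exact_ranksum_tail)
from medipdmr.genomics import ArrayDesign
from medipdmr.preprocess import NormalizedRatios


def _toy_design(promoter_probes):
    """Build an ArrayDesign from {promoter: [probe_ids]} with dummy coords."""
    probe_rows, prom_rows = {}, {}
    pos = 0
    for i, (prom, probes) in enumerate(promoter_probes.items()):
        tss = pos + 1000
        for p in probes:
            probe_rows[p] = {"chrom": "chr1", "start": pos, "end": pos + 60,
                             "promoter_ids": (prom,),
                             "cpg_count": 2, "c_count": 10, "g_count": 10}
            pos += 100
        prom_rows[prom] = {"gene_id": f"g_{prom}", "chrom": "chr1",
                           "tss": tss, "strand": "+",
                           "window_start": tss - 1000, "window_end": tss + 200,
                           "probe_ids": tuple(probes)}
        pos += 1000
    probes = pd.DataFrame.from_dict(probe_rows, orient="index")
    probes.index.name = "probe_id"
    promoters = pd.DataFrame.from_dict(prom_rows, orient="index")
    promoters.index.name = "promoter_id"
    return ArrayDesign(probes=probes, promoters=promoters)


class TestEBayesPrior:
    def test_scaled_f_parameter_recovery(self):
        rng = np.random.default_rng(0)
        d0, s0_sq, dg = 4.0, 0.02, 17
        s2 = s0_sq * rng.f(dg, d0, size=10_000)
        prior = fit_ebayes_prior(s2, dg)
        assert 3.0 <= prior.d0 <= 5.0
        assert 0.016 <= prior.s0_sq <= 0.024

    def test_identical_variances_give_infinite_d0(self):
        prior = fit_ebayes_prior(np.full(50, 0.3), 17)
        assert math.isinf(prior.d0)
        assert prior.s0_sq == pytest.approx(0.3)

    def test_huge_spread_gives_small_finite_d0(self):
        rng = np.random.default_rng(1)
        s2 = np.exp(rng.normal(0, 4, size=2000))  # overdispersed log-variances
        prior = fit_ebayes_prior(s2, 17)
        assert np.isfinite(prior.d0)
        assert prior.d0 < 2.0

    def test_trigamma_inverse_against_bisection(self):
        from scipy.special import polygamma

        def bisect(x):
            lo, hi = 1e-6, 1e6
            for _ in range(200):
                mid = math.sqrt(lo * hi)
                if polygamma(1, mid) > x:
                    lo = mid
                else:
                    hi = mid
            return mid

        for x in (0.01, 0.5, 2.0, 30.0):
            assert trigamma_inverse(x) == pytest.approx(bisect(x), rel=1e-5)


class TestModeratedT:
    @staticmethod
    def _ratios(X, groups):
        subjects = [f"s{i}" for i in range(X.shape[0])]
        vals = pd.DataFrame(X, index=subjects,
                            columns=[f"p{j}" for j in range(X.shape[1])])
        g = pd.Series(groups, index=subjects)
        return vals, g

    def test_equal_group_means_give_zero_t(self):
        X = np.vstack([np.ones((3, 4)), np.ones((3, 4))])
        X += np.arange(6)[:, None] * 0  # keep means identical
        X[0, 0] = 2.0
        X[3, 0] = 2.0  # same perturbation in both groups
        vals, g = self._ratios(X, ["CPA"] * 3 + ["NPA"] * 3)
        out = probe_moderated_t(vals, g, prior=EBayesPrior(4.0, 0.1))
        assert out["t"].iloc[0] == pytest.approx(0.0)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_d0_zero_limit_equals_classical_t(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(19, 1))
        groups = ["CPA"] * 5 + ["NPA"] * 14
        vals, g = self._ratios(X, groups)
        # d0 -> 0 limit taken as a tiny prior df (exact zero is disallowed
        # by the prior's own invariant, so compare at d0 = 1e-9)
        out = probe_moderated_t(vals, g, prior=EBayesPrior(1e-9, 1.0))
        t_ref, _ = stats.ttest_ind(X[:5, 0], X[5:, 0], equal_var=True)
        assert out["t"].iloc[0] == pytest.approx(t_ref, rel=1e-6)

    def test_d0_infinite_limit_is_z_statistic(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10, 3))
        vals, g = self._ratios(X, ["CPA"] * 5 + ["NPA"] * 5)
        s0 = 0.7
        out = probe_moderated_t(vals, g, prior=EBayesPrior(math.inf, s0))
        lfc = X[:5].mean(axis=0) - X[5:].mean(axis=0)
        z = lfc / (math.sqrt(s0) * math.sqrt(1 / 5 + 1 / 5))
        np.testing.assert_allclose(out["t"], z, rtol=1e-9)
        np.testing.assert_allclose(out["p"], 2 * stats.norm.sf(np.abs(z)),
                                   rtol=1e-9)

    def test_shrinkage_formula_against_stepwise_oracle(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(19, 50))
        groups = ["CPA"] * 5 + ["NPA"] * 14
        vals, g = self._ratios(X, groups)
        prior = EBayesPrior(d0=4.0, s0_sq=0.5)
        out = probe_moderated_t(vals, g, prior=prior)
        for j in [0, 7, 23, 49]:
            x1, x2 = X[:5, j], X[5:, j]
            lfc = x1.mean() - x2.mean()
            s2 = (4 * x1.var(ddof=1) + 13 * x2.var(ddof=1)) / 17
            s2_post = (4.0 * 0.5 + 17 * s2) / (4.0 + 17)
            t = lfc / math.sqrt(s2_post * (1 / 5 + 1 / 14))
            p = 2 * stats.t.sf(abs(t), 21)
            assert out["t"].iloc[j] == pytest.approx(t, rel=1e-9)
            assert out["p"].iloc[j] == pytest.approx(p, rel=1e-9)
        assert (np.sign(out["t"]) == np.sign(out["log2fc"])).all()

    def test_sign_invariant_holds(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(12, 100))
        vals, g = self._ratios(X, ["CPA"] * 6 + ["NPA"] * 6)
        out = probe_moderated_t(vals, g)
        nz = out["log2fc"] != 0
        assert (np.sign(out.loc[nz, "t"])
                == np.sign(out.loc[nz, "log2fc"])).all()
        assert out["p"].between(0, 1, inclusive="right").all()


class TestPromoterRanksum:
    def test_enumeration_example_max_enrichment(self):
        # promoter {2.0, 1.5, 1.8} vs background {-0.1, 0.0, 0.1, -0.2}:
        # every promoter probe outranks every background probe, so the
        # one-sided p is 1 / C(7,3) = 1/35
        design = _toy_design({"P": ["a", "b", "c"],
                              "BG": ["d", "e", "f", "g"]})
        ps = pd.DataFrame({"t": [2.0, 1.5, 1.8, -0.1, 0.0, 0.1, -0.2],
                           "log2fc": [1, 1, 1, 0, 0, 0, 0], "p": [0.01] * 7},
                          index=["a", "b", "c", "d", "e", "f", "g"])
        out = promoter_ranksum(ps, design, min_probes=3)
        assert out.at["P", "p_pos"] == pytest.approx(1 / 35)
        assert out.at["P", "p"] == pytest.approx(2 / 35)
        assert out.at["P", "direction"] == "hyper"

    def test_background_identical_distribution_not_enriched(self):
        design = _toy_design({"P": ["a", "b", "c"],
                              "BG": ["d", "e", "f", "g", "h", "i"]})
        t = [1.0, 2.0, 3.0] + [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        ps = pd.DataFrame({"t": t, "log2fc": t, "p": [0.5] * 9},
                          index=list("abcdefghi"))
        out = promoter_ranksum(ps, design, min_probes=3)
        assert out.at["P", "p"] > 0.5

    def test_exact_tail_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(6)
        t = np.round(rng.normal(size=18), 2)  # rounding induces ties
        ranks = stats.rankdata(t)
        for k in (3, 5, 8):
            obs = ranks[:k].sum()
            p_ge, p_le = _exact_ranksum_tail(2 * ranks, k, 2 * obs)
            sums = np.array([sum(c) for c in
                             itertools.combinations(ranks, k)])
            assert p_ge == pytest.approx((sums >= obs - 1e-9).mean())
            assert p_le == pytest.approx((sums <= obs + 1e-9).mean())

    def test_normal_approximation_close_to_exact(self):
        rng = np.random.default_rng(7)
        t = rng.normal(size=60)
        design = _toy_design({"P": [f"a{i}" for i in range(10)],
                              "BG": [f"b{i}" for i in range(50)]})
        idx = [f"a{i}" for i in range(10)] + [f"b{i}" for i in range(50)]
        ps = pd.DataFrame({"t": t, "log2fc": t, "p": [0.5] * 60}, index=idx)
        out = promoter_ranksum(ps, design, min_probes=3)
        ranks = stats.rankdata(t)
        obs = ranks[:10].sum()
        sums = []
        for _ in range(40_000):
            sums.append(rng.permutation(ranks)[:10].sum())
        sums = np.array(sums)
        mc_pos = (sums >= obs).mean()
        assert out.at["P", "p_pos"] == pytest.approx(mc_pos, abs=0.02)

    def test_small_promoters_reported_untested(self):
        design = _toy_design({"P": ["a", "b"], "BG": ["c", "d", "e"]})
        ps = pd.DataFrame({"t": [1, 2, 0, 0, 0],
                           "log2fc": [1, 1, 0, 0, 0], "p": [0.5] * 5},
                          index=list("abcde"))
        out = promoter_ranksum(ps, design, min_probes=3)
        assert not out.at["P", "tested"]
        assert np.isnan(out.at["P", "q"])


class TestBHFdr:
    def test_hand_computed_step_up(self):
        q = bh_fdr(np.array([0.01, 0.02, 0.03, 0.04, 0.2]))
        np.testing.assert_allclose(q, [0.05, 0.05, 0.05, 0.05, 0.2])

    @pytest.mark.parametrize("p,expected", [
        ([0.07], [0.07]),
        ([0.3, 0.3, 0.3], [0.3, 0.3, 0.3]),
        ([], []),
    ])
    def test_edge_cases(self, p, expected):
        np.testing.assert_allclose(bh_fdr(np.array(p)), expected)

    def test_matches_brute_force_definition(self):
        rng = np.random.default_rng(8)

        def brute(p):
            m = len(p)
            order = np.argsort(p, kind="stable")
            q = np.empty(m)
            for rank_i, idx in enumerate(order, start=1):
                candidates = [p[order[j - 1]] * m / j
                              for j in range(rank_i, m + 1)]
                q[idx] = min(1.0, min(candidates))
            return q

        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 12))
            np.testing.assert_allclose(bh_fdr(p), brute(p), atol=1e-12)

    def test_q_bounds_and_monotonicity(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=500)
        q = bh_fdr(p)
        assert (q >= p - 1e-15).all() and (q <= 1).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-15).all()


class TestCallRule:
    def _stats_for(self, design, t, lfc, p, prom_p):
        ps = pd.DataFrame({"t": t, "log2fc": lfc, "p": p},
                          index=design.probes.index)
        rows = []
        for prom in design.promoters.index:
            rows.append({"promoter_id": prom, "tested": True,
                         "p": prom_p[prom], "q": prom_p[prom],
                         "direction": "hypo" if np.mean(
                             [lfc[list(design.probes.index).index(x)]
                              for x in design.promoters.at[prom, "probe_ids"]]
                         ) < 0 else "hyper",
                         "n_probes": len(design.promoters.at[prom, "probe_ids"]),
                         "W": 0.0, "p_pos": 0.5, "p_neg": 0.5, "reason": ""})
        return ps, pd.DataFrame(rows).set_index("promoter_id")

    def test_qualifying_probe_rule(self):
        design = _toy_design({"P1": ["a", "b", "c"], "P2": ["d", "e", "f"]})
        ps, prs = self._stats_for(
            design,
            t=[-3, -1, 0, 2, 1, 0],
            lfc=[-0.30, -0.10, 0.0, 0.20, 0.10, 0.0],
            p=[0.03, 0.5, 0.9, 0.04, 0.5, 0.9],
            prom_p={"P1": 0.04, "P2": 0.04})
        calls, counts = call_dmrs(ps, prs, design)
        # P1 has a qualifying probe (p=.03, lfc=-.30); P2's best lfc is
        # only 0.20, below the fold-change threshold
        assert list(calls.index) == ["P1"]
        assert calls.at["P1", "direction"] == "hypo"
        assert counts == {"hyper": 0, "hypo": 1}

    def test_promoter_q_gate(self):
        design = _toy_design({"P1": ["a", "b", "c"]})
        ps, prs = self._stats_for(design, t=[-3, -2, -1],
                                  lfc=[-0.5, -0.4, -0.3],
                                  p=[0.001, 0.01, 0.02],
                                  prom_p={"P1": 0.2})
        calls, _ = call_dmrs(ps, prs, design)
        assert calls.empty

    def test_sign_consistency_switch(self):
        design = _toy_design({"P1": ["a", "b", "c"]})
        # promoter direction hyper but only a negative probe qualifies
        ps = pd.DataFrame({"t": [3, 2, -3], "log2fc": [0.1, 0.1, -0.4],
                           "p": [0.2, 0.2, 0.01]}, index=["a", "b", "c"])
        prs = pd.DataFrame([{"promoter_id": "P1", "tested": True, "p": 0.01,
                             "q": 0.01, "direction": "hyper", "n_probes": 3,
                             "W": 0.0, "p_pos": 0.005, "p_neg": 0.9,
                             "reason": ""}]).set_index("promoter_id")
        strict, _ = call_dmrs(ps, prs, design, sign_consistency=True)
        loose, _ = call_dmrs(ps, prs, design, sign_consistency=False)
        assert strict.empty and list(loose.index) == ["P1"]


class TestRepresentativeProbes:
    def test_most_extreme_t_and_tie_break(self):
        design = _toy_design({"P1": ["a", "b"], "P2": ["c", "d"]})
        ps = pd.DataFrame({"t": [1.2, -2.5, 2.0, -2.0],
                           "log2fc": [0.1, -0.4, 0.3, -0.3],
                           "p": [0.5, 0.01, 0.02, 0.02]},
                          index=["a", "b", "c", "d"])
        calls = pd.DataFrame({"gene_id": ["g_P1", "g_P2"],
                              "direction": ["hypo", "hyper"]},
                             index=pd.Index(["P1", "P2"],
                                            name="promoter_id"))
        subjects = ["s1", "s2"]
        ratios = pd.DataFrame(np.arange(8).reshape(2, 4) * 1.0,
                              index=subjects, columns=["a", "b", "c", "d"])
        mat = representative_probes(calls, ps, ratios, design)
        np.testing.assert_allclose(mat.loc["g_P1"], ratios["b"])  # |t|=2.5
        # P2: |t| tie 2.0 vs 2.0 -> lower start coordinate (probe c) wins
        np.testing.assert_allclose(mat.loc["g_P2"], ratios["c"])

    def test_selection_invariant_to_probe_order(self):
        rng = np.random.default_rng(10)
        design = _toy_design({"P1": ["a", "b", "c", "d"]})
        t = rng.normal(size=4)
        ps = pd.DataFrame({"t": t, "log2fc": t, "p": [0.01] * 4},
                          index=["a", "b", "c", "d"])
        calls = pd.DataFrame({"gene_id": ["g_P1"], "direction": ["hypo"]},
                             index=pd.Index(["P1"], name="promoter_id"))
        ratios = pd.DataFrame(rng.normal(size=(3, 4)), index=["s1", "s2", "s3"],
                              columns=["a", "b", "c", "d"])
        base = representative_probes(calls, ps, ratios, design)
        perm = ["c", "a", "d", "b"]
        shuffled = representative_probes(calls, ps.loc[perm],
                                         ratios[perm], design)
        np.testing.assert_allclose(base.to_numpy(), shuffled.to_numpy())


class TestWardCluster:
    def test_identical_rows_merge_first_at_zero(self):
        rng = np.random.default_rng(11)
        base = rng.normal(size=5)
        M = pd.DataFrame([base, base, rng.normal(size=5),
                          rng.normal(size=5)],
                         index=["r0", "r1", "r2", "r3"])
        link = ward_cluster(M)["rows"]
        assert set(link[0, :2].astype(int)) == {0, 1}
        assert link[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_rows_distance_two(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        M = pd.DataFrame([x, -x, x * 2 + 1], index=["a", "b", "c"])
        d = 1 - np.corrcoef(M.to_numpy())
        assert d[0, 1] == pytest.approx(2.0)

    def test_constant_row_rejected_by_name(self):
        M = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]],
                         index=["flat", "ok"])
        with pytest.raises(ValueError, match="flat"):
            ward_cluster(M)

    def test_linkage_matches_greedy_ward_oracle(self):
        rng = np.random.default_rng(12)
        M = pd.DataFrame(rng.normal(size=(6, 5)))
        link = ward_cluster(M)["rows"]

        # greedy Ward via the Lance-Williams update on 1 - Pearson r
        d = 1 - np.corrcoef(M.to_numpy())
        np.fill_diagonal(d, np.inf)
        active = {i: (d[i].copy(), 1) for i in range(6)}
        dist = {frozenset((i, j)): d[i, j] for i in range(6)
                for j in range(i + 1, 6)}
        sizes = {i: 1 for i in range(6)}
        merges = []
        next_id = 6
        clusters = list(range(6))
        while len(clusters) > 1:
            pair = min((fs for fs in dist if fs <= set(clusters)),
                       key=lambda fs: dist[fs])
            i, j = sorted(pair)
            h = dist[pair]
            merges.append((i, j, h, sizes[i] + sizes[j]))
            for k in clusters:
                if k in (i, j):
                    continue
                si, sj, sk = sizes[i], sizes[j], sizes[k]
                dik = dist[frozenset((i, k))] ** 2
                djk = dist[frozenset((j, k))] ** 2
                dij = h ** 2
                new = math.sqrt(((si + sk) * dik + (sj + sk) * djk
                                 - sk * dij) / (si + sj + sk))
                dist[frozenset((next_id, k))] = new
            sizes[next_id] = sizes[i] + sizes[j]
            clusters = [c for c in clusters if c not in (i, j)] + [next_id]
            next_id += 1
        for row, (i, j, h, size) in zip(link, merges):
            assert set(row[:2].astype(int)) == {i, j}
            assert row[2] == pytest.approx(h, rel=1e-9)
            assert int(row[3]) == size
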