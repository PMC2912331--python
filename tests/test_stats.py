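"""Statistical primitives against independent oracles.

Oracles: a naive per-probe loop for the moderated t, statsmodels'
multipletests for the step-up adjustments, exhaustive enumeration and
scipy's hypergeometric pmf for the tail, brute-force topology search for the
3-leaf dendrogram, and (when Rscript + limma are available) limma's eBayes
for the full moderated pipeline.
"""

import itertools
import math
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import special
from scipy.stats import hypergeom, t as t_dist

from inflaprof.io import ExpressionMatrix
from inflaprof.stats import (
    BackgroundCounts,
    adjust_bh,
    adjust_hochberg,
    background_counts,
    cluster_contrasts,
    contrast,
    fit_variance_prior,
    hypergeom_logtail,
    hypergeom_tail,
)


def _random_matrix(rng, n_probes, n_samples, sd=None):
    base = rng.uniform(4, 10, n_probes)
    sd = sd if sd is not None else rng.uniform(0.1, 0.6, n_probes)
    vals = base[:, None] + rng.normal(0, 1, (n_probes, n_samples)) * np.atleast_1d(sd)[:, None]
    return ExpressionMatrix(
        pd.DataFrame(vals, index=[f"p{i}" for i in range(n_probes)],
                     columns=[f"s{j}" for j in range(n_samples)])
    )


class TestContrast:
    def test_identical_group_means_give_zero_fold_change(self):
        df = pd.DataFrame(
            {"a1": [5.0, 7.0], "a2": [6.0, 8.0], "b1": [5.5, 7.5], "b2": [5.5, 7.5]},
            index=["p1", "p2"],
        )
        res = contrast(ExpressionMatrix(df), ["a1", "a2"], ["b1", "b2"], method="ordinary")
        assert np.allclose(res["log2fc"], 0)
        assert (res["direction"] == "unchanged").all()

    def test_fc_is_two_to_the_log2fc(self):
        rng = np.random.default_rng(0)
        m = _random_matrix(rng, 50, 6)
        res = contrast(m, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        assert np.allclose(res["fc"], np.exp2(res["log2fc"]), atol=1e-9)

    def test_moderated_matches_naive_formula_evaluation(self):
        """Moderated p's match an independently coded per-probe evaluation."""
        rng = np.random.default_rng(3)
        m = _random_matrix(rng, 50, 7)
        g1, g2 = ["s0", "s1", "s2"], ["s3", "s4", "s5", "s6"]
        res = contrast(m, g1, g2, method="moderated")

        # naive loop: pooled variance, squeeze, t, two-sided p
        x = m.data
        s2 = np.empty(50)
        diff = np.empty(50)
        for i, probe in enumerate(x.index):
            a = x.loc[probe, g1].to_numpy()
            b = x.loc[probe, g2].to_numpy()
            diff[i] = b.mean() - a.mean()
            s2[i] = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (len(a) + len(b) - 2)
        d_g = 5
        d0, s0 = fit_variance_prior(s2, d_g)
        assert np.isfinite(d0)
        expect_p = np.empty(50)
        for i in range(50):
            s2_tilde = (d0 * s0 + d_g * s2[i]) / (d0 + d_g)
            t = diff[i] / math.sqrt(s2_tilde * (1 / 3 + 1 / 4))
            expect_p[i] = 2 * t_dist.sf(abs(t), min(d0 + d_g, 50 * d_g))
        assert np.allclose(res["p_raw"], expect_p, atol=1e-10)

    def test_zero_prior_df_limit_equals_ordinary_t(self):
        """As d0 -> 0 the squeezed variance reduces to the per-probe variance."""
        rng = np.random.default_rng(5)
        m = _random_matrix(rng, 40, 6)
        ordinary = contrast(m, ["s0", "s1", "s2"], ["s3", "s4", "s5"], method="ordinary")
        x = m.data
        s2 = np.array(
            [
                (
                    ((x.loc[p, ["s0", "s1", "s2"]] - x.loc[p, ["s0", "s1", "s2"]].mean()) ** 2).sum()
                    + ((x.loc[p, ["s3", "s4", "s5"]] - x.loc[p, ["s3", "s4", "s5"]].mean()) ** 2).sum()
                )
                / 4
                for p in x.index
            ]
        )
        d0 = 1e-12
        s2_tilde = (d0 * 1.0 + 4 * s2) / (d0 + 4)
        t = (ordinary["log2fc"].to_numpy()) / np.sqrt(s2_tilde * (2 / 3))
        assert np.allclose(t, ordinary["t_stat"], rtol=1e-9)

    def test_infinite_prior_df_limit_is_common_variance_z_like_test(self):
        """Homoscedastic data drive d0 -> inf; every probe is tested against
        the single common variance."""
        rng = np.random.default_rng(42)
        m = _random_matrix(rng, 80, 6, sd=np.full(80, 0.3))
        res = contrast(m, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        x = m.data.to_numpy()
        s2 = (
            ((x[:, :3] - x[:, :3].mean(1, keepdims=True)) ** 2).sum(1)
            + ((x[:, 3:] - x[:, 3:].mean(1, keepdims=True)) ** 2).sum(1)
        ) / 4
        d0, s0 = fit_variance_prior(s2, 4)
        assert np.isinf(d0)
        expect_t = res["log2fc"] / math.sqrt(s0 * (2 / 3))
        assert np.allclose(res["t_stat"], expect_t, rtol=1e-12)

    def test_small_group_rejected(self, small_matrix):
        with pytest.raises(ValueError, match="at least 2"):
            contrast(small_matrix, ["s1"], ["s2", "s1"])

    def test_zero_variance_zero_difference_probe_flagged(self):
        df = pd.DataFrame(
            {"a1": [5.0, 1.0], "a2": [5.0, 2.0], "b1": [5.0, 3.0], "b2": [5.0, 4.0]},
            index=["flat", "vary"],
        )
        res = contrast(ExpressionMatrix(df), ["a1", "a2"], ["b1", "b2"], method="ordinary")
        assert res.loc["flat", "flagged"]
        assert res.loc["flat", "t_stat"] == 0.0
        assert res.loc["flat", "p_raw"] == 1.0


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not available")
def test_moderated_t_agrees_with_limma_ebayes(tmp_path):
    """Dual-route check: the moderated pipeline against Bioconductor limma."""
    rng = np.random.default_rng(7)
    m = _random_matrix(rng, 100, 6)
    fix = tmp_path / "fix.tsv"
    m.data.to_csv(fix, sep="\t", float_format="%.17g")
    rscript = tmp_path / "check.R"
    rscript.write_text(
        'suppressMessages(library(limma))\n'
        f'x <- as.matrix(read.delim("{fix}", row.names=1))\n'
        "design <- cbind(Intercept=1, Group=c(0,0,0,1,1,1))\n"
        "fit <- eBayes(lmFit(x, design))\n"
        "out <- data.frame(t=fit$t[,2], p=fit$p.value[,2])\n"
        f'write.table(format(out, digits=15), "{tmp_path / "out.tsv"}", sep="\\t", quote=FALSE)\n'
    )
    proc = subprocess.run(["Rscript", str(rscript)], capture_output=True, text=True)
    if proc.returncode != 0:
        pytest.skip(f"limma unavailable: {proc.stderr[-200:]}")
    ref = pd.read_csv(tmp_path / "out.tsv", sep="\t", index_col=0)
    res = contrast(m, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
    assert np.allclose(res["t_stat"], ref["t"], atol=1e-8)
    assert np.allclose(res["p_raw"], ref["p"], atol=1e-10)


def _bh_oracle(p):
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    out = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        out[i] = running
    return out


def _hochberg_oracle(p):
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    out = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * (m - rank + 1))
        out[i] = running
    return out


class TestAdjustments:
    def test_single_p_is_identity(self):
        assert adjust_bh([0.03]) == pytest.approx([0.03])
        assert adjust_hochberg([0.03]) == pytest.approx([0.03])

    def test_hand_evaluated_examples(self):
        assert adjust_bh([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04, 0.04, 0.04, 0.04])
        assert adjust_hochberg([0.01, 0.04]) == pytest.approx([0.02, 0.04])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.2])
        with pytest.raises(ValueError):
            adjust_hochberg([-0.1])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=6))
    @settings(deadline=None, max_examples=200)
    def test_matches_brute_force_oracles(self, p):
        assert np.allclose(adjust_bh(p), _bh_oracle(p), atol=1e-12)
        assert np.allclose(adjust_hochberg(p), _hochberg_oracle(p), atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=10), st.randoms())
    @settings(deadline=None, max_examples=100)
    def test_permutation_equivariant_and_bounded(self, p, rnd):
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        shuffled = [p[i] for i in perm]
        for adjust in (adjust_bh, adjust_hochberg):
            base = adjust(p)
            assert np.all(base >= np.asarray(p) - 1e-15)
            assert np.all(base <= 1.0)
            assert np.allclose(adjust(shuffled), [base[i] for i in perm], atol=1e-12)

    def test_hochberg_between_raw_and_bonferroni(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0, 1, 20)
        adj = adjust_hochberg(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= np.minimum(1.0, p * 20) + 1e-15)


class TestHypergeomTail:
    def test_certain_event(self):
        assert hypergeom_tail(4, 4, 10, 10) == pytest.approx(1.0)
        assert hypergeom_tail(0, 3, 5, 10) == pytest.approx(1.0)

    def test_small_case_by_enumeration(self):
        # x=4 of n_draw=4, k_bg=5 of m_total=10: C(5,4)*C(5,0)/C(10,4) = 5/210
        assert hypergeom_tail(4, 4, 5, 10) == pytest.approx(5 / 210, rel=1e-12)

    def test_exhaustive_enumeration_all_small_instances(self):
        """Agreement with direct draw enumeration for every m_total <= 12."""
        for m_total in range(1, 13):
            for k_bg in range(m_total + 1):
                for n_draw in range(m_total + 1):
                    pop = [1] * k_bg + [0] * (m_total - k_bg)
                    counts = {}
                    for combo in itertools.combinations(range(m_total), n_draw):
                        x = sum(pop[i] for i in combo)
                        counts[x] = counts.get(x, 0) + 1
                    total = sum(counts.values())
                    for x in range(min(n_draw, k_bg) + 1):
                        expect = sum(v for k, v in counts.items() if k >= x) / total
                        got = hypergeom_tail(x, n_draw, k_bg, m_total)
                        assert got == pytest.approx(expect, abs=1e-12), (x, n_draw, k_bg, m_total)

    def test_matches_scipy_sf_at_moderate_size(self):
        for x, n_draw, k_bg, m_total in [(30, 60, 500, 1000), (5, 50, 100, 2000)]:
            assert hypergeom_tail(x, n_draw, k_bg, m_total) == pytest.approx(
                float(hypergeom.sf(x - 1, m_total, k_bg, n_draw)), rel=1e-9
            )

    def test_non_increasing_in_x(self):
        vals = [hypergeom_tail(x, 20, 40, 100) for x in range(21)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_extreme_tail_stays_finite_in_log_space(self):
        lp = hypergeom_logtail(446, 454, round(0.4081 * 45101), 45101)
        assert lp / math.log(10) < -150

    def test_bounds_validated(self):
        with pytest.raises(ValueError):
            hypergeom_tail(5, 4, 10, 20)
        with pytest.raises(ValueError):
            hypergeom_tail(5, 10, 4, 20)


class TestBackgroundCounts:
    def test_counts_exclude_exact_zero_fold_changes(self):
        df = pd.DataFrame(
            {"a1": [1.0, 2.0, 3.0], "a2": [1.0, 2.0, 3.0],
             "b1": [2.0, 1.0, 3.0], "b2": [2.0, 1.0, 3.0]},
            index=["up", "down", "flat"],
        )
        res = contrast(ExpressionMatrix(df), ["a1", "a2"], ["b1", "b2"], method="ordinary")
        bg = background_counts(res)
        assert (bg.m_total, bg.k_increased, bg.k_decreased) == (3, 1, 1)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            BackgroundCounts(10, 8, 8)


class TestClusterContrasts:
    @staticmethod
    def _fake_contrast(log2fc, probes):
        return pd.DataFrame({"log2fc": log2fc}, index=probes)

    def test_identical_contrasts_merge_at_zero(self):
        probes = [f"p{i}" for i in range(10)]
        v = np.linspace(-2, 2, 10)
        res = cluster_contrasts(
            {"a": self._fake_contrast(v, probes), "b": self._fake_contrast(v, probes)},
            probes,
        )
        assert res.correlation.loc["a", "b"] == pytest.approx(1.0)
        assert res.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_negated_contrast_at_distance_two(self):
        probes = [f"p{i}" for i in range(10)]
        v = np.linspace(-2, 2, 10)
        res = cluster_contrasts(
            {"a": self._fake_contrast(v, probes), "b": self._fake_contrast(-v, probes)},
            probes,
        )
        assert res.correlation.loc["a", "b"] == pytest.approx(-1.0)
        assert res.linkage[0, 2] == pytest.approx(2.0)

    def test_three_leaf_topology_matches_brute_force(self):
        """The pair with the highest correlation must merge first."""
        rng = np.random.default_rng(9)
        probes = [f"p{i}" for i in range(30)]
        base = rng.normal(0, 1, 30)
        contrasts = {
            "a": self._fake_contrast(base + rng.normal(0, 0.1, 30), probes),
            "b": self._fake_contrast(base + rng.normal(0, 0.1, 30), probes),
            "c": self._fake_contrast(rng.normal(0, 1, 30), probes),
        }
        res = cluster_contrasts(contrasts, probes)
        corr = res.correlation
        best_pair = max(
            itertools.combinations("abc", 2), key=lambda pr: corr.loc[pr[0], pr[1]]
        )
        # first linkage row merges two leaves: ids < 3
        first = set(res.linkage[0, :2].astype(int))
        labels = {i: lab for i, lab in enumerate(res.labels)}
        assert {labels[i] for i in first} == set(best_pair)
        assert res.newick.endswith(";") and "(" in res.newick

    def test_constant_vector_rejected_by_name(self):
        probes = ["p0", "p1", "p2"]
        with pytest.raises(ValueError, match="flatliner"):
            cluster_contrasts(
                {
                    "ok": self._fake_contrast([1.0, 2.0, 3.0], probes),
                    "flatliner": self._fake_contrast([1.0, 1.0, 1.0], probes),
                },
                probes,
            )


def test_adjustments_cross_checked_against_statsmodels():
    """Independent library route for both step-up procedures."""
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(2)
    p = rng.uniform(0, 1, 50)
    assert np.allclose(adjust_bh(p), multipletests(p, method="fdr_bh")[1], atol=1e-12)
    assert np.allclose(
        adjust_hochberg(p), multipletests(p, method="simes-hochberg")[1], atol=1e-12
    )
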