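"""Differential-expression statistics and shared statistical primitives.

Contrasts between two sample groups are summarised per probe by the log2
fold change, a (optionally moderated) t statistic, and raw/BH-adjusted
p-values. The moderated t shrinks per-probe sample variances toward a common
prior fitted by empirical Bayes: the observed variances s2_g are modelled as
scaled-F distributed around a prior variance s0^2 with d0 prior degrees of
freedom, and the posterior variance

    s2_tilde_g = (d0 * s0^2 + d_g * s2_g) / (d0 + d_g)

replaces s2_g in the t denominator, with d0 + d_g degrees of freedom for the
two-sided p-value. (d0, s0^2) are estimated by moment-matching the mean and
variance of log s2_g against the theoretical moments of a log scaled-F
variate, inverting the trigamma function numerically.

Also here: step-up Benjamini-Hochberg (FDR) and Hochberg (FWER) adjustments,
an upper hypergeometric tail evaluated in log space so that astronomically
small enrichment p-values survive, and hierarchical clustering of contrasts
by Pearson correlation of their fold-change vectors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import t as t_dist

log = logging.getLogger(__name__)

__all__ = [
    "BackgroundCounts",
    "contrast",
    "background_counts",
    "adjust_bh",
    "adjust_hochberg",
    "hypergeom_tail",
    "hypergeom_logtail",
    "fit_variance_prior",
    "cluster_contrasts",
    "ClusterResult",
]

CONTRAST_COLUMNS = ["log2fc", "fc", "t_stat", "p_raw", "p_bh", "direction", "flagged"]


@dataclass(frozen=True)
class BackgroundCounts:
    """Platform-wide split of increased vs decreased probes in a contrast.

    ``m_total`` counts every probe on the platform (significant or not);
    exact-zero fold changes belong to neither direction.
    """

    m_total: int
    k_increased: int
    k_decreased: int

    def __post_init__(self) -> None:
        if min(self.m_total, self.k_increased, self.k_decreased) < 0:
            raise ValueError("counts must be non-negative")
        if self.k_increased + self.k_decreased > self.m_total:
            raise ValueError("k_increased + k_decreased exceeds m_total")

    @property
    def frac_increased(self) -> float:
        return self.k_increased / self.m_total


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (trigamma is monotone decreasing)."""
    if y <= 0:
        return np.inf
    f = lambda x: float(special.polygamma(1, x)) - y
    lo, hi = 1e-8, 1e8
    if f(lo) < 0:  # y larger than trigamma(lo): x below lo
        return lo
    if f(hi) > 0:
        return hi
    return float(optimize.brentq(f, lo, hi, xtol=1e-12, rtol=1e-12))


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match (d0, s0^2) for the scaled-F model of sample variances.

    Works on z = log(s2): E[z] and Var[z] have closed forms in terms of
    digamma/trigamma functions of df/2 and d0/2. Returns ``(d0, s0_sq)``;
    ``d0 = inf`` when the observed spread of log-variances is no larger than
    expected under a single common variance.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 >= 0)]
    if s2.size < 2:
        raise ValueError("need at least 2 finite variances to fit the prior")
    med = float(np.median(s2))
    if med == 0:
        raise ValueError("more than half of the variances are exactly zero")
    s2 = np.maximum(s2, 1e-5 * med)  # offset exact zeros away from log(0)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var <= 0:
        # observed spread consistent with one common variance
        return np.inf, float(np.mean(s2))
    d0 = 2.0 * _trigamma_inverse(e_var)
    s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def contrast(
    matrix,
    group1: Sequence[str],
    group2: Sequence[str],
    method: str = "moderated",
) -> pd.DataFrame:
    """Per-probe two-group comparison: group2 vs group1 on the log2 scale.

    Returns a DataFrame indexed by probe id with columns ``log2fc`` (mean
    log2 difference, group2 - group1), ``fc`` (2**log2fc, the ratio of
    geometric means), ``t_stat``, ``p_raw``, ``p_bh``, ``direction``
    (increased / decreased / unchanged by strict sign of log2fc) and
    ``flagged`` (True for zero-variance, zero-difference probes where the
    test is vacuous: t = 0, p = 1).

    ``method="moderated"`` applies the empirical-Bayes variance shrinkage
    described in the module docstring; ``"ordinary"`` uses the pooled
    two-sample t. Falls back to ordinary t (with a warning) when fewer than
    10 probes are available to fit the prior.
    """
    if method not in ("moderated", "ordinary"):
        raise ValueError(f"unknown method {method!r}")
    g1, g2 = list(group1), list(group2)
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least 2 samples")
    if set(g1) & set(g2):
        raise ValueError("groups must be disjoint")
    x1 = matrix.data[g1].to_numpy()
    x2 = matrix.data[g2].to_numpy()
    n1, n2 = x1.shape[1], x2.shape[1]
    m1 = x1.mean(axis=1)
    m2 = x2.mean(axis=1)
    log2fc = m2 - m1
    d_g = n1 + n2 - 2
    ss = ((x1 - m1[:, None]) ** 2).sum(axis=1) + ((x2 - m2[:, None]) ** 2).sum(axis=1)
    s2 = ss / d_g
    scale = 1.0 / n1 + 1.0 / n2

    fitted = False
    if method == "moderated" and s2.size >= 10:
        try:
            d0, s0_sq = fit_variance_prior(s2, d_g)
            fitted = True
        except ValueError as exc:
            log.warning("variance-prior fit failed (%s); using ordinary t", exc)
    elif method == "moderated":
        log.warning("too few probes to fit variance prior; using ordinary t")
    if fitted:
        pooled_df = float(s2.size * d_g)  # cap: total df cannot exceed what was observed
        if np.isinf(d0):
            s2_tilde = np.full_like(s2, s0_sq)
            df_total = pooled_df
        else:
            s2_tilde = (d0 * s0_sq + d_g * s2) / (d0 + d_g)
            df_total = min(d0 + d_g, pooled_df)
    else:
        s2_tilde = s2
        df_total = float(d_g)

    se = np.sqrt(s2_tilde * scale)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = np.where(se > 0, log2fc / np.where(se > 0, se, 1.0), 0.0)
        t_stat = np.where((se == 0) & (log2fc != 0), np.sign(log2fc) * np.inf, t_stat)
    p_raw = 2.0 * t_dist.sf(np.abs(t_stat), df_total)
    flagged = (se == 0) & (log2fc == 0)
    p_raw = np.where(flagged, 1.0, p_raw)
    p_raw = np.clip(p_raw, 0.0, 1.0)

    direction = np.where(log2fc > 0, "increased", np.where(log2fc < 0, "decreased", "unchanged"))
    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "fc": np.exp2(log2fc),
            "t_stat": t_stat,
            "p_raw": p_raw,
            "p_bh": adjust_bh(p_raw),
            "direction": direction,
            "flagged": flagged,
        },
        index=matrix.data.index.copy(),
    )
    out.index.name = "probe_id"
    return out


def background_counts(contrast_df: pd.DataFrame) -> BackgroundCounts:
    """Platform background for the hypergeometric null, from a full contrast."""
    d = contrast_df["direction"]
    return BackgroundCounts(
        m_total=len(contrast_df),
        k_increased=int((d == "increased").sum()),
        k_decreased=int((d == "decreased").sum()),
    )


def _check_pvalues(p: np.ndarray) -> None:
    if p.size and (np.min(p) < 0 or np.max(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if not np.isfinite(p).all():
        raise ValueError("p-values must be finite")


def adjust_bh(p) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, returned in input order.

    q(i) = min_{j >= i} (m/j) * p_(j), clipped at 1.
    """
    p = np.asarray(p, dtype=float)
    _check_pvalues(p)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def adjust_hochberg(p) -> np.ndarray:
    """Hochberg step-up FWER adjustment, returned in input order.

    adj(i) = min_{j >= i} (m - j + 1) * p_(j), clipped at 1. Valid under
    non-negative dependence among the tests.
    """
    p = np.asarray(p, dtype=float)
    _check_pvalues(p)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * (m - np.arange(1, m + 1) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.clip(adj, 0.0, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def _check_hypergeom_args(x: int, n_draw: int, k_bg: int, m_total: int) -> None:
    if not (0 <= x <= n_draw <= m_total):
        raise ValueError(f"need 0 <= x <= n_draw <= m_total, got {(x, n_draw, m_total)}")
    if not (x <= k_bg <= m_total):
        raise ValueError(f"need x <= k_bg <= m_total, got {(x, k_bg, m_total)}")


def hypergeom_logtail(x: int, n_draw: int, k_bg: int, m_total: int) -> float:
    """Natural log of P(X >= x) for X ~ Hypergeom(m_total, k_bg, n_draw).

    Summed in log space from per-term log pmf values (binomial coefficients
    via log-gamma), so tails far below the smallest positive double are
    representable.
    """
    _check_hypergeom_args(x, n_draw, k_bg, m_total)
    if x == 0:
        return 0.0
    hi = min(n_draw, k_bg)
    k = np.arange(x, hi + 1)

    def logc(n, r):
        return special.gammaln(n + 1) - special.gammaln(r + 1) - special.gammaln(n - r + 1)

    log_terms = logc(k_bg, k) + logc(m_total - k_bg, n_draw - k) - logc(m_total, n_draw)
    return float(special.logsumexp(log_terms))


def hypergeom_tail(x: int, n_draw: int, k_bg: int, m_total: int) -> float:
    """Upper tail P(X >= x) of the hypergeometric distribution (see logtail)."""
    return min(1.0, float(np.exp(hypergeom_logtail(x, n_draw, k_bg, m_total))))


@dataclass
class ClusterResult:
    """Correlation clustering of fold-change vectors across contrasts."""

    labels: list[str]
    correlation: pd.DataFrame  # pairwise Pearson r over the filtered probes
    linkage: np.ndarray  # scipy linkage matrix (distance = 1 - r)
    newick: str

    def write(self, corr_path, tree_path) -> None:
        self.correlation.to_csv(corr_path, sep="\t", float_format="%.10g")
        with open(tree_path, "w") as fh:
            fh.write(self.newick + "\n")


def _to_newick(node, labels: list[str]) -> str:
    if node.is_leaf():
        return labels[node.id]
    left = _to_newick(node.get_left(), labels)
    right = _to_newick(node.get_right(), labels)
    bl_l = node.dist - node.get_left().dist
    bl_r = node.dist - node.get_right().dist
    return f"({left}:{bl_l:.10g},{right}:{bl_r:.10g})"


def cluster_contrasts(
    contrasts: Mapping[str, pd.DataFrame],
    probe_filter: Sequence[str],
    linkage_method: str = "average",
) -> ClusterResult:
    """Cluster labelled contrasts by Pearson correlation of log2 fold changes.

    Fold-change vectors are restricted to ``probe_filter`` (e.g. probes
    significant in at least one contrast); distance is 1 - r; agglomeration
    uses average linkage by default. The tree is exported as newick with
    branch lengths derived from merge heights.
    """
    labels = list(contrasts)
    if len(labels) < 2:
        raise ValueError("need at least 2 contrasts to cluster")
    probe_filter = list(probe_filter)
    if not probe_filter:
        raise ValueError("probe_filter must be non-empty")
    fc = pd.DataFrame(
        {lab: contrasts[lab]["log2fc"].reindex(probe_filter) for lab in labels}
    )
    if fc.isna().any().any():
        missing = fc.columns[fc.isna().any()].tolist()
        raise ValueError(f"contrasts missing filtered probes: {missing}")
    stds = fc.std(ddof=0)
    if (stds == 0).any():
        bad = stds.index[stds == 0].tolist()
        raise ValueError(f"constant fold-change vector(s): {bad}")
    corr = fc.corr(method="pearson")
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    link = hierarchy.linkage(squareform(dist, checks=False), method=linkage_method)
    tree = hierarchy.to_tree(link)
    newick = _to_newick(tree, labels) + ";"
    return ClusterResult(labels, corr, link, newick)
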