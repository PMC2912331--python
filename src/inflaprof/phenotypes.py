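"""Phenotype correlations and the score-predictor screen.

Two downstream analyses of a computed inflammation profile:

* ``phenotype_correlations`` asks whether a set of transcripts (e.g. the
  signature transcripts of a high-scoring macrophage population) correlates
  with a clinical phenotype (e.g. total serum cholesterol) more strongly
  than the rest of the platform, comparing mean per-probe Pearson r between
  set and background with a Welch t-test.

* ``score_predictor_screen`` asks which transcripts, by their expression
  across the reference panel itself, best predict the profile score of each
  population — a screen for expression phenotypes shared by infiltrating
  cell types. Term over-representation among the top predictors uses the
  same upper hypergeometric tail as the profile tests.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import ExpressionMatrix
from .profiles import InflammationProfile
from .stats import adjust_bh, hypergeom_tail

log = logging.getLogger(__name__)

__all__ = [
    "CorrelationReport",
    "phenotype_correlations",
    "PredictorScreen",
    "score_predictor_screen",
    "term_overrepresentation",
]


def _rowwise_pearson(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r of each row of ``x`` against the vector ``y``.

    Rows with zero variance yield NaN.
    """
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    num = xc @ yc
    den = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return np.clip(r, -1.0, 1.0)


@dataclass
class CorrelationReport:
    """Per-probe correlation with a phenotype, set vs background comparison."""

    phenotype: str
    r: pd.Series  # per-probe Pearson r (NaN for constant probes)
    set_mean_r: float
    background_mean_r: float
    t_test_p: float  # Welch t on r values, set vs background; NaN if degenerate
    n_set: int
    n_background: int

    def to_frame(self) -> pd.DataFrame:
        return self.r.rename("r").to_frame()


def phenotype_correlations(
    expr: ExpressionMatrix,
    phenotype: pd.Series,
    probe_set: Iterable[str],
) -> CorrelationReport:
    """Correlate every probe with a phenotype; compare a probe set against
    the platform background.

    Samples are intersected between matrix and phenotype (missing phenotype
    values dropped); at least 3 paired samples and a non-constant phenotype
    are required. The background excludes set members (set-priority). The
    set-vs-background comparison is a Welch two-sample t-test on the per-probe
    r values; degenerate cases (empty background, too few finite r) are
    reported as NaN with a warning.
    """
    pheno = phenotype.dropna()
    samples = [s for s in expr.sample_ids if s in pheno.index]
    if len(samples) < 3:
        raise ValueError(f"need >=3 samples with both expression and phenotype, got {len(samples)}")
    y = pheno.loc[samples].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("phenotype is constant across paired samples")
    x = expr.data[samples].to_numpy()
    r = pd.Series(_rowwise_pearson(x, y), index=expr.data.index, name="r")

    probe_set = set(probe_set)
    in_set = r.index.isin(probe_set)
    r_set = r[in_set].dropna()
    r_bg = r[~in_set].dropna()
    set_mean = float(r_set.mean()) if len(r_set) else math.nan
    bg_mean = float(r_bg.mean()) if len(r_bg) else math.nan
    if len(r_set) >= 2 and len(r_bg) >= 2:
        t_p = float(sps.ttest_ind(r_set, r_bg, equal_var=False).pvalue)
    else:
        log.warning("degenerate set/background split; t-test reported as NaN")
        t_p = math.nan
    return CorrelationReport(
        phenotype=str(phenotype.name or "phenotype"),
        r=r,
        set_mean_r=set_mean,
        background_mean_r=bg_mean,
        t_test_p=t_p,
        n_set=int(len(r_set)),
        n_background=int(len(r_bg)),
    )


@dataclass
class PredictorScreen:
    """Transcripts whose panel expression predicts profile score."""

    table: pd.DataFrame  # per-probe r, slope, p_slope (constant probes excluded)
    top: pd.DataFrame  # top-k rows by descending r
    n_excluded_constant: int
    score_by_sample: pd.Series  # log2 score attached to each panel sample

    def write_tsv(self, path) -> None:
        self.top.to_csv(path, sep="\t", float_format="%.10g")


def score_predictor_screen(
    panel: ExpressionMatrix,
    profile: InflammationProfile,
    k: int = 200,
    inf_cap_factor: float = 2.0,
) -> PredictorScreen:
    """Screen for transcripts whose expression across the reference panel
    tracks the inflammation-profile score.

    Every panel sample must carry its population id in ``sample_groups``.
    The score attached to a sample is log2 of its population's n1/n2 ratio;
    populations with an infinite ratio are capped at ``inf_cap_factor`` times
    the largest finite ratio so the log is defined, and NaN-ratio populations
    are dropped. Per probe: Pearson r between log2 expression and log2 score
    across samples, plus the least-squares slope and its p-value. The top-k
    list is sorted by descending r (ties by probe id); constant probes are
    excluded and counted.
    """
    if panel.sample_groups is None:
        raise ValueError("panel must map samples to populations via sample_groups")
    ratios = {r.population_id: r.ratio for r in profile.rows}
    finite = [v for v in ratios.values() if np.isfinite(v) and v > 0]
    if len(finite) < 3:
        raise ValueError("need >=3 populations with finite positive ratio")
    cap = max(finite) * inf_cap_factor

    scores = {}
    for pid, ratio in ratios.items():
        if isinstance(ratio, float) and math.isnan(ratio):
            continue
        val = cap if math.isinf(ratio) else ratio
        if val > 0:
            scores[pid] = math.log2(val)
    samples = [s for s in panel.sample_ids if panel.sample_groups.get(s) in scores]
    if len(samples) < 3:
        raise ValueError("fewer than 3 panel samples with a scored population")
    y = np.array([scores[panel.sample_groups[s]] for s in samples])
    x = panel.data[samples].to_numpy()

    r = _rowwise_pearson(x, y)
    keep = ~np.isnan(r)
    n_excluded = int((~keep).sum())
    if n_excluded:
        log.info("excluded %d constant probes from predictor screen", n_excluded)
    nobs = len(samples)
    sy = y.std(ddof=0)
    sx = x.std(axis=1, ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = r * sy / np.where(sx > 0, sx, np.nan)
    # p-value of the regression slope via the t transform of r (df = n - 2)
    df = nobs - 2
    r_ok = np.clip(r, -0.9999999999, 0.9999999999)
    with np.errstate(invalid="ignore", divide="ignore"):
        t_stat = r_ok * np.sqrt(df / (1.0 - r_ok**2))
    p_slope = 2.0 * sps.t.sf(np.abs(t_stat), df)
    table = pd.DataFrame(
        {"r": r, "slope": slope, "p_slope": p_slope}, index=panel.data.index
    ).loc[keep]
    top = table.sort_values(
        ["r"], ascending=False, kind="stable"
    )
    top = top.iloc[np.lexsort((top.index, -top["r"].to_numpy()))].head(k)
    return PredictorScreen(
        table=table,
        top=top,
        n_excluded_constant=n_excluded,
        score_by_sample=pd.Series(y, index=samples, name="log2_score"),
    )


def term_overrepresentation(
    gene_set: Iterable[str],
    annotation: pd.DataFrame,
    universe: Iterable[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of annotation terms in a gene set.

    ``annotation`` holds (gene, term_id[, term_name]) columns; genes outside
    ``universe`` are ignored. For each term: x = term hits in the gene set,
    n_draw = gene-set members that carry any annotation, k_bg = term size in
    the annotated universe, m_total = annotated-universe size. P-values are
    the upper hypergeometric tail, reported unadjusted with a ``significant``
    flag at ``alpha`` plus a supplementary BH column.
    """
    gene_set = set(gene_set)
    if not gene_set:
        raise ValueError("gene_set is empty")
    universe = set(universe)
    if not gene_set <= universe:
        extra = sorted(gene_set - universe)
        raise ValueError(f"gene_set members outside universe: {extra[:10]}")
    ann = annotation.iloc[:, :2].copy()
    ann.columns = ["gene", "term"]
    names = None
    if annotation.shape[1] >= 3:
        names = dict(zip(annotation.iloc[:, 1], annotation.iloc[:, 2]))
    ann = ann[ann["gene"].isin(universe)].drop_duplicates()
    annotated = set(ann["gene"])
    m_total = len(annotated)
    n_draw = len(gene_set & annotated)
    records = []
    for term, members in ann.groupby("term")["gene"]:
        term_genes = set(members)
        x = len(gene_set & term_genes)
        k_bg = len(term_genes)
        p = hypergeom_tail(x, n_draw, k_bg, m_total)
        records.append(
            {
                "term": term,
                "term_name": names.get(term, term) if names else term,
                "x": x,
                "n_draw": n_draw,
                "k_bg": k_bg,
                "m_total": m_total,
                "p_raw": p,
            }
        )
    df = pd.DataFrame(records).set_index("term").sort_values(["p_raw", "term_name"])
    df["p_bh"] = adjust_bh(df["p_raw"].to_numpy())
    df["significant"] = df["p_raw"] < alpha
    return df
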