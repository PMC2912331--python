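"""Signature-transcript identification and overlap statistics.

A signature transcript of a reference cell population is a probe whose
expression is far higher in that population than in the baseline tissue:
BH-adjusted p below ``p_adj_max`` (default 1e-4) and fold change at least
``fc_min`` (default 16, inclusive). Fold change is the ratio of geometric
means, 2**(difference of log2 means). The adjustment is computed within each
population-vs-reference contrast separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import stats
from .io import ExpressionMatrix, join_matrices

__all__ = [
    "SignatureThresholds",
    "SignatureSet",
    "identify_signatures",
    "signature_overlap",
    "OverlapSummary",
    "collapse_probes_to_genes",
]


@dataclass(frozen=True)
class SignatureThresholds:
    """Gate for calling a probe a signature transcript."""

    p_adj_max: float = 1e-4
    fc_min: float = 16.0

    def __post_init__(self) -> None:
        if not (0.0 < self.p_adj_max < 1.0):
            raise ValueError("p_adj_max must lie in (0, 1)")
        if self.fc_min <= 1.0:
            raise ValueError("fc_min must exceed 1 (linear scale)")


@dataclass
class SignatureSet:
    """Signature transcripts of one reference population.

    ``transcripts`` is indexed by probe id with columns ``fc`` (population /
    reference, linear scale) and ``p_adj``, sorted by descending fold change.
    """

    population_id: str
    class_label: str
    transcripts: pd.DataFrame

    def __post_init__(self) -> None:
        if self.transcripts.index.duplicated().any():
            raise ValueError(f"{self.population_id}: duplicate signature probes")

    @property
    def n(self) -> int:
        return len(self.transcripts)

    @property
    def probes(self) -> frozenset[str]:
        return frozenset(self.transcripts.index)

    def top_markers(self, k: int = 40) -> pd.DataFrame:
        """The k transcripts most enriched over the tissue reference."""
        return self.transcripts.head(k)

    def to_frame(self) -> pd.DataFrame:
        out = self.transcripts.copy()
        out.insert(0, "population_id", self.population_id)
        out.insert(1, "class_label", self.class_label)
        return out

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.10g")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SignatureSet":
        pid = df["population_id"].iloc[0] if len(df) else "unknown"
        cls_label = df["class_label"].iloc[0] if len(df) else "unknown"
        return cls(pid, cls_label, df[["fc", "p_adj"]].copy())


def identify_signatures(
    population: ExpressionMatrix,
    reference: ExpressionMatrix,
    thresholds: SignatureThresholds = SignatureThresholds(),
    population_id: str = "population",
    class_label: str = "unknown",
    method: str = "moderated",
) -> SignatureSet:
    """Identify transcripts expressed significantly higher in ``population``
    than in the tissue ``reference``.

    Runs a moderated-t contrast (reference as group 1, population as group 2)
    over the shared probe universe, BH-adjusts within this contrast, and keeps
    probes with ``p_bh < p_adj_max`` and ``fc >= fc_min`` (boundary
    inclusive). The returned set is sorted by descending fold change, the
    natural ordering for a top-marker chart.
    """
    if population.shape[1] < 2:
        raise ValueError(
            f"{population_id}: need >=2 replicate samples, got {population.shape[1]}"
        )
    joined = join_matrices(reference, population)
    res = stats.contrast(joined, reference.sample_ids, population.sample_ids, method=method)
    keep = (res["p_bh"] < thresholds.p_adj_max) & (res["fc"] >= thresholds.fc_min)
    hits = res.loc[keep, ["fc", "p_raw", "p_bh"]].rename(columns={"p_bh": "p_adj"})
    hits = hits.sort_values("fc", ascending=False, kind="stable")[["fc", "p_adj"]]
    return SignatureSet(population_id, class_label, hits)


@dataclass
class OverlapSummary:
    """Pairwise signature overlap (percent) with median/quartile summary."""

    matrix: pd.DataFrame  # populations x populations, percent; NaN for empty sets
    median: float
    q1: float
    q3: float
    metric: str


def signature_overlap(sets: Sequence[SignatureSet], metric: str = "min") -> OverlapSummary:
    """Pairwise percent overlap between signature sets.

    ``metric="min"`` divides the intersection by the smaller set (how much of
    the smaller set is shared); ``"jaccard"`` divides by the union. Pairs
    involving an empty set are reported as missing and excluded from the
    median/quartile summary over all unordered pairs.
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 signature sets")
    if metric not in ("min", "jaccard"):
        raise ValueError(f"unknown overlap metric {metric!r}")
    ids = [s.population_id for s in sets]
    if len(set(ids)) != len(ids):
        raise ValueError("population ids must be unique")
    n = len(sets)
    mat = np.full((n, n), np.nan)
    pair_values = []
    for i in range(n):
        if sets[i].n > 0:
            mat[i, i] = 100.0
        for j in range(i + 1, n):
            if sets[i].n == 0 or sets[j].n == 0:
                continue
            inter = len(sets[i].probes & sets[j].probes)
            if metric == "min":
                denom = min(sets[i].n, sets[j].n)
            else:
                denom = len(sets[i].probes | sets[j].probes)
            val = 100.0 * inter / denom
            mat[i, j] = mat[j, i] = val
            pair_values.append(val)
    if pair_values:
        q1, med, q3 = np.percentile(pair_values, [25, 50, 75])
    else:
        q1 = med = q3 = np.nan
    return OverlapSummary(
        matrix=pd.DataFrame(mat, index=ids, columns=ids),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        metric=metric,
    )


def collapse_probes_to_genes(
    contrast_df: pd.DataFrame, annotation: pd.DataFrame
) -> pd.DataFrame:
    """Collapse a probe-level contrast to gene level: best probe per gene by
    smallest raw p. ``annotation`` holds (probe_id, gene) columns."""
    ann = annotation.iloc[:, :2].copy()
    ann.columns = ["probe_id", "gene"]
    merged = contrast_df.reset_index().merge(ann, on="probe_id", how="inner")
    merged = merged.sort_values("p_raw", kind="stable")
    best = merged.drop_duplicates("gene", keep="first").set_index("gene")
    return best
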