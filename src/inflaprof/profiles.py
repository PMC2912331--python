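"""Inflammation profiles: per-population enrichment of signature transcripts
in a case/control contrast, with redundancy-aware dual significance testing.

For each reference population with n signature transcripts, the case/control
contrast splits them into n1 increased and n2 decreased (exact-zero fold
changes count as neither). The ratio n1/n2 scores the population: if the
population infiltrates the perturbed tissue, its markers should rise almost
uniformly and the ratio should far exceed the platform-wide background ratio
of increased to decreased probes.

Because marker sets overlap heavily between related populations, a second,
redundancy-filtered score is computed: population j's signatures are reduced
to the n* transcripts not claimed by any population ranked above j (larger
n1/n2), and the split n1*/n2* is recomputed. Both counts are tested against
the platform background with an upper hypergeometric tail; each family of N
p-values is Hochberg-adjusted, and a population is called significant only
when both adjusted p-values fall below alpha. The dual test de-correlates
significance patterns: a population that merely shares markers with a true
infiltrator scores high on n1/n2 but loses its shared markers in the starred
test.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .signatures import SignatureSet
from .stats import (
    BackgroundCounts,
    adjust_hochberg,
    background_counts,
    hypergeom_logtail,
    hypergeom_tail,
)

__all__ = [
    "ProfileRow",
    "InflammationProfile",
    "score_population",
    "rank_populations",
    "filter_unique_signatures",
    "build_profile",
    "class_summary",
]


@dataclass
class ProfileRow:
    """One population's scores and tests within an inflammation profile."""

    population_id: str
    class_label: str
    n: int
    n1: int
    n2: int
    ratio: float  # n1/n2; +inf when n2 == 0 < n1; NaN when n1 == n2 == 0
    n_star: int
    n1_star: int
    n2_star: int
    ratio_star: float
    pct_increased: float
    p1_raw: float
    p1_adj: float
    p2_raw: float
    p2_adj: float
    significant: bool
    flagged: bool = False  # True when no signature probe had a direction


def _ratio(n1: int, n2: int) -> float:
    if n1 == 0 and n2 == 0:
        return math.nan
    if n2 == 0:
        return math.inf
    return n1 / n2


def score_population(
    sig: SignatureSet, contrast_df: pd.DataFrame
) -> tuple[int, int, float, float]:
    """Split a population's signature transcripts by contrast direction.

    Returns ``(n1, n2, ratio, pct_increased)`` where n1/n2 count signatures
    increased/decreased in the contrast. Signature probes absent from the
    contrast are excluded (their count is recorded by the caller via n).
    """
    present = sig.transcripts.index.intersection(contrast_df.index)
    directions = contrast_df.loc[present, "direction"]
    n1 = int((directions == "increased").sum())
    n2 = int((directions == "decreased").sum())
    ratio = _ratio(n1, n2)
    pct = 100.0 * n1 / (n1 + n2) if (n1 + n2) > 0 else math.nan
    return n1, n2, ratio, pct


def _rank_key(population_id: str, n1: int, ratio: float):
    is_na = isinstance(ratio, float) and math.isnan(ratio)
    # NaN rows last; then descending ratio (+inf first); ties by larger n1;
    # then lexicographic id for determinism.
    r = -math.inf if is_na else ratio
    return (1 if is_na else 0, -r, -n1, population_id)


def rank_populations(scores: Sequence[tuple[str, int, float]]) -> list[str]:
    """Order population ids by the profile ranking rule.

    ``scores`` holds ``(population_id, n1, ratio)`` triples. Descending
    ratio; +inf ratios sort first, among themselves by larger n1; finite
    ties broken by larger n1 then lexicographic id; NaN (no directional
    signature) rows last.
    """
    return [pid for pid, _, _ in sorted(scores, key=lambda s: _rank_key(*s))]


def filter_unique_signatures(
    sets: Mapping[str, SignatureSet], ranking: Sequence[str], j: str
) -> frozenset[str]:
    """Reduce population ``j``'s signatures to those not claimed above it.

    Removes every transcript that is also a signature transcript of any
    population ranked strictly above ``j``; the top-ranked population keeps
    its full set (n* = n).
    """
    if j not in ranking:
        raise KeyError(f"population {j!r} not in ranking")
    mine = set(sets[j].probes)
    for pid in ranking:
        if pid == j:
            break
        mine -= sets[pid].probes
    return frozenset(mine)


@dataclass
class InflammationProfile:
    """Ranked per-population rows plus the shared platform background."""

    rows: list[ProfileRow]
    background: BackgroundCounts
    alpha: float = 0.05
    contrast_label: str = ""

    def row(self, population_id: str) -> ProfileRow:
        for r in self.rows:
            if r.population_id == population_id:
                return r
        raise KeyError(population_id)

    @property
    def significant_ids(self) -> list[str]:
        """Significant population ids in rank order."""
        return [r.population_id for r in self.rows if r.significant]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([vars(r) for r in self.rows])
        return df.set_index("population_id")

    def write_tsv(self, path) -> None:
        df = self.to_frame().copy()
        for col in ("ratio", "ratio_star"):
            df[col] = df[col].map(
                lambda v: "Inf" if math.isinf(v) else ("NA" if math.isnan(v) else f"{v:.6g}")
            )
        df.to_csv(path, sep="\t", float_format="%.6g")

    def write_json(self, path) -> None:
        def encode(v):
            if isinstance(v, float):
                if math.isinf(v):
                    return {"value": None, "infinite": True}
                if math.isnan(v):
                    return None
            return v

        payload = {
            "contrast_label": self.contrast_label,
            "alpha": self.alpha,
            "background": vars(self.background),
            "rows": [{k: encode(v) for k, v in vars(r).items()} for r in self.rows],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def read_json(cls, path) -> "InflammationProfile":
        def decode(v):
            if isinstance(v, dict) and v.get("infinite"):
                return math.inf
            if v is None:
                return math.nan
            return v

        with open(path) as fh:
            payload = json.load(fh)
        rows = [
            ProfileRow(**{k: decode(v) for k, v in row.items()})
            for row in payload["rows"]
        ]
        return cls(
            rows=rows,
            background=BackgroundCounts(**payload["background"]),
            alpha=payload["alpha"],
            contrast_label=payload["contrast_label"],
        )


def build_profile(
    sets: Sequence[SignatureSet],
    contrast_df: pd.DataFrame,
    background: BackgroundCounts | None = None,
    alpha: float = 0.05,
    contrast_label: str = "",
) -> InflammationProfile:
    """Compute the full inflammation profile for one case/control contrast.

    Steps: score every population (n1/n2), rank, reduce each population's
    set to transcripts unique against higher-ranked sets (n1*/n2*), test
    both counts against the platform background with upper hypergeometric
    tails, Hochberg-adjust each test family across the N populations, and
    flag populations significant on both adjusted tests at ``alpha``.

    ``background`` defaults to the directional split of the supplied
    contrast over the whole platform.
    """
    if not sets:
        raise ValueError("need at least one signature set")
    ids = [s.population_id for s in sets]
    if len(set(ids)) != len(ids):
        raise ValueError("population ids must be unique")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if background is None:
        background = background_counts(contrast_df)
    by_id = {s.population_id: s for s in sets}

    scores: dict[str, tuple[int, int, float, float]] = {
        pid: score_population(by_id[pid], contrast_df) for pid in ids
    }
    ranking = rank_populations([(pid, scores[pid][0], scores[pid][2]) for pid in ids])

    directions = contrast_df["direction"]
    rows: list[ProfileRow] = []
    p1_list, p2_list = [], []
    for pid in ranking:
        sig = by_id[pid]
        n1, n2, ratio, pct = scores[pid]
        unique = filter_unique_signatures(by_id, ranking, pid)
        present_star = [p for p in unique if p in directions.index]
        d_star = directions.loc[present_star]
        n1s = int((d_star == "increased").sum())
        n2s = int((d_star == "decreased").sum())
        flagged = (n1 + n2) == 0
        if flagged:
            p1 = 1.0
        else:
            p1 = hypergeom_tail(n1, n1 + n2, background.k_increased, background.m_total)
        if (n1s + n2s) == 0:
            p2 = 1.0
        else:
            p2 = hypergeom_tail(n1s, n1s + n2s, background.k_increased, background.m_total)
        p1_list.append(p1)
        p2_list.append(p2)
        rows.append(
            ProfileRow(
                population_id=pid,
                class_label=sig.class_label,
                n=sig.n,
                n1=n1,
                n2=n2,
                ratio=ratio,
                n_star=len(unique),
                n1_star=n1s,
                n2_star=n2s,
                ratio_star=_ratio(n1s, n2s),
                pct_increased=pct,
                p1_raw=p1,
                p1_adj=math.nan,
                p2_raw=p2,
                p2_adj=math.nan,
                significant=False,
                flagged=flagged,
            )
        )
    p1_adj = adjust_hochberg(p1_list)
    p2_adj = adjust_hochberg(p2_list)
    for row, a1, a2 in zip(rows, p1_adj, p2_adj):
        row.p1_adj = float(a1)
        row.p2_adj = float(a2)
        row.significant = bool(a1 < alpha and a2 < alpha)
    return InflammationProfile(rows, background, alpha, contrast_label)


@dataclass
class ClassSummaryRow:
    class_label: str
    max_ratio: float
    any_significant: bool
    n_populations: int


def class_summary(
    profile: InflammationProfile, class_map: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Collapse a profile to cell-type classes.

    Per class: the largest n1/n2 ratio among member populations and a flag
    marking whether at least one member met both significance criteria.
    ``class_map`` overrides the class labels carried on the rows; every
    population must be mapped.
    """
    rows_by_class: dict[str, list[ProfileRow]] = {}
    for row in profile.rows:
        if class_map is not None:
            if row.population_id not in class_map:
                raise KeyError(f"population {row.population_id!r} missing from class map")
            label = class_map[row.population_id]
        else:
            label = row.class_label
        rows_by_class.setdefault(label, []).append(row)
    records = []
    for label, members in rows_by_class.items():
        ratios = [r.ratio for r in members if not math.isnan(r.ratio)]
        max_ratio = max(ratios) if ratios else math.nan
        records.append(
            ClassSummaryRow(
                class_label=label,
                max_ratio=max_ratio,
                any_significant=any(r.significant for r in members),
                n_populations=len(members),
            )
        )
    df = pd.DataFrame([vars(r) for r in records]).set_index("class_label")
    return df.sort_index()
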