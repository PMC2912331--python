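"""Attribute top induced transcripts to infiltrating cell populations.

The K transcripts most strongly induced in the case/control contrast are
selected by adjusted p-value among increased-direction probes and displayed
in fold-change order. Each is then checked against the signature sets of the
populations called significant in the inflammation profile (optionally
restricted to classes of interest, e.g. dendritic cells / macrophages /
monocytes): membership in a significant population's signature set serves as
an explanation for the induction, and the transcript is assigned to the
highest-ranked such population.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .profiles import InflammationProfile
from .signatures import SignatureSet

log = logging.getLogger(__name__)

__all__ = ["AttributionResult", "top_induced", "attribute"]


def top_induced(contrast_df: pd.DataFrame, k: int = 500) -> pd.DataFrame:
    """Select the ``k`` most strongly induced probes of a contrast.

    Selection: increased-direction probes with the smallest BH-adjusted p
    (ties by smaller raw p, then larger fold change). Display order of the
    selected probes: descending fold change, with ``rank`` 1..K. Returns all
    increased probes (with a warning) when fewer than ``k`` exist.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    inc = contrast_df[contrast_df["direction"] == "increased"]
    if len(inc) == 0:
        log.warning("contrast has no increased probes")
        out = inc[["log2fc", "fc", "p_raw", "p_bh"]].copy()
        out["rank"] = pd.Series(dtype=int)
        return out
    if len(inc) < k:
        log.warning("only %d increased probes available (requested %d)", len(inc), k)
    sel = inc.sort_values(
        ["p_bh", "p_raw", "fc"], ascending=[True, True, False], kind="stable"
    ).head(k)
    sel = sel.sort_values("fc", ascending=False, kind="stable")
    out = sel[["log2fc", "fc", "p_raw", "p_bh"]].copy()
    out["rank"] = range(1, len(out) + 1)
    return out


@dataclass
class AttributionResult:
    """Per-transcript assignments and per-class explained fractions."""

    assignments: pd.DataFrame  # ranked probes with assigned population/class
    explained_by_class: dict[str, float]  # percent of the K top transcripts
    k: int

    @property
    def explained_total(self) -> float:
        return sum(self.explained_by_class.values())

    def write_tsv(self, path) -> None:
        self.assignments.to_csv(path, sep="\t", float_format="%.10g")

    def write_json(self, path) -> None:
        payload = {
            "k": self.k,
            "explained_by_class_pct": self.explained_by_class,
            "explained_total_pct": self.explained_total,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def attribute(
    top: pd.DataFrame,
    profile: InflammationProfile,
    sets: Sequence[SignatureSet],
    class_filter: set[str] | None = None,
) -> AttributionResult:
    """Assign top induced transcripts to significant populations.

    A transcript that belongs to the signature set of at least one
    significant population (restricted to ``class_filter`` classes when
    given) is assigned to the highest-ranked such population. Per-class
    explained fraction = assigned count / K x 100, K = number of top
    transcripts considered.
    """
    by_id = {s.population_id: s for s in sets}
    eligible: list[tuple[str, str, frozenset[str]]] = []
    for row in profile.rows:
        if not row.significant:
            continue
        if class_filter is not None and row.class_label not in class_filter:
            continue
        if row.population_id not in by_id:
            raise KeyError(f"signature set missing for {row.population_id!r}")
        eligible.append((row.population_id, row.class_label, by_id[row.population_id].probes))

    assigned_pop: list[str | None] = []
    assigned_class: list[str | None] = []
    for probe in top.index:
        hit_pop = hit_class = None
        for pid, label, probes in eligible:  # profile rank order
            if probe in probes:
                hit_pop, hit_class = pid, label
                break
        assigned_pop.append(hit_pop)
        assigned_class.append(hit_class)

    assignments = top.copy()
    assignments["assigned_population"] = assigned_pop
    assignments["assigned_class"] = assigned_class
    k = len(top)
    explained: dict[str, float] = {}
    if k > 0:
        counts = pd.Series([c for c in assigned_class if c is not None]).value_counts()
        explained = {str(c): 100.0 * int(v) / k for c, v in counts.items()}
    return AttributionResult(assignments, explained, k)
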