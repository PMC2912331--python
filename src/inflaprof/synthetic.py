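"""Synthetic reference panels and spike-in case/control experiments.

The generator emulates the data layout the profiling algorithm consumes: a
baseline-tissue reference matrix, one small replicate matrix per candidate
cell population carrying an elevated block of marker probes, and a
case/control experiment in which case samples are linear-scale convex
mixtures of the baseline tissue and a known set of "infiltrating"
populations. Ground truth (mixing fractions, planted marker blocks,
intrinsic differential-expression shifts) is returned alongside, so every
pipeline stage can be tested against planted answers.

Model conventions: baseline log2 means are uniform on [4, 10]; marker probes
of a population sit ``log2(marker_fc)`` above baseline in that population's
matrix; measurement noise is i.i.d. Gaussian on the log2 scale (log-normal
on the linear scale), sigma defaulting to 0.25 — the magnitudes typical of
RMA-normalised microarray replicates. A case sample's expected linear-scale
signal is ``(1 - sum(f_j)) * baseline + sum_j f_j * population_j``, matching
the interpretation of infiltration as a shift in cellular composition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

__all__ = ["SpikeInTruth", "Panel", "generate_panel", "generate_experiment"]

CLASS_CYCLE = [
    "dendritic cell",
    "macrophage",
    "monocyte",
    "T cell",
    "B cell",
    "NK cell",
    "neutrophil",
    "progenitor",
    "tissue",
]


@dataclass
class SpikeInTruth:
    """Ground truth for one simulated case/control experiment."""

    spiked: dict[str, float]  # population_id -> mixing fraction in [0, 1)
    intrinsic_de: dict[str, float] = field(default_factory=dict)  # probe -> log2 shift
    seed: int = 0
    noise_sigma: float = 0.25

    def __post_init__(self) -> None:
        if any(f < 0 for f in self.spiked.values()):
            raise ValueError("mixing fractions must be non-negative")
        if sum(self.spiked.values()) >= 1.0:
            raise ValueError("mixing fractions must sum to < 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


@dataclass
class Panel:
    """A simulated reference panel with its planted marker map."""

    reference: ExpressionMatrix
    populations: list[ExpressionMatrix]  # one matrix per population, n_B samples each
    markers: dict[str, list[str]]  # population_id -> planted marker probes
    classes: dict[str, str]  # population_id -> class label
    baseline: pd.Series  # per-probe baseline log2 mean
    marker_fc: float

    @property
    def population_ids(self) -> list[str]:
        return list(self.markers)

    def population(self, pid: str) -> ExpressionMatrix:
        return self.populations[self.population_ids.index(pid)]


def generate_panel(
    n_probes: int = 5000,
    n_populations: int = 20,
    markers_per_pop: int = 60,
    marker_fc: float = 32.0,
    shared_marker_frac: float = 0.0,
    n_B: int = 3,
    n_A: int = 10,
    noise_sigma: float = 0.25,
    seed: int = 0,
) -> Panel:
    """Simulate a baseline reference and a panel of marker-bearing populations.

    Each population elevates a disjoint block of ``markers_per_pop`` probes
    by ``log2(marker_fc)`` over baseline. When ``shared_marker_frac`` > 0 the
    second population ("child") replaces that fraction of its block with
    markers of the first population ("parent"), creating the marker overlap
    that the redundancy filter is designed to neutralise. All randomness
    derives from ``seed``; identical seeds give identical matrices.
    """
    if markers_per_pop * n_populations > n_probes:
        raise ValueError("marker blocks do not fit in the probe universe")
    if not (0.0 <= shared_marker_frac < 1.0):
        raise ValueError("shared_marker_frac must lie in [0, 1)")
    if marker_fc <= 1.0:
        raise ValueError("marker_fc must exceed 1")
    rng = np.random.default_rng(seed)
    width = len(str(n_probes))
    probes = [f"p{i:0{width}d}" for i in range(n_probes)]
    pop_ids = [f"pop{j + 1:02d}" for j in range(n_populations)]
    baseline = pd.Series(rng.uniform(4.0, 10.0, size=n_probes), index=probes)

    markers: dict[str, list[str]] = {}
    for j, pid in enumerate(pop_ids):
        block = probes[j * markers_per_pop : (j + 1) * markers_per_pop]
        markers[pid] = list(block)
    if shared_marker_frac > 0 and n_populations >= 2:
        n_shared = int(round(shared_marker_frac * markers_per_pop))
        parent, child = pop_ids[0], pop_ids[1]
        markers[child] = markers[parent][:n_shared] + markers[child][n_shared:]

    shift = math.log2(marker_fc)
    ref_values = baseline.to_numpy()[:, None] + rng.normal(
        0.0, noise_sigma, size=(n_probes, n_A)
    )
    ref_ids = [f"ref_s{i + 1}" for i in range(n_A)]
    reference = ExpressionMatrix(
        pd.DataFrame(ref_values, index=probes, columns=ref_ids),
        {s: "reference" for s in ref_ids},
    )

    populations = []
    classes = {}
    marker_pos = {p: i for i, p in enumerate(probes)}
    for j, pid in enumerate(pop_ids):
        mean = baseline.to_numpy().copy()
        idx = [marker_pos[p] for p in markers[pid]]
        mean[idx] += shift
        values = mean[:, None] + rng.normal(0.0, noise_sigma, size=(n_probes, n_B))
        sample_ids = [f"{pid}_s{i + 1}" for i in range(n_B)]
        populations.append(
            ExpressionMatrix(
                pd.DataFrame(values, index=probes, columns=sample_ids),
                {s: pid for s in sample_ids},
            )
        )
        classes[pid] = CLASS_CYCLE[j % len(CLASS_CYCLE)]
    return Panel(reference, populations, markers, classes, baseline, marker_fc)


def generate_experiment(
    panel: Panel,
    truth: SpikeInTruth,
    n_case: int = 3,
    n_control: int = 3,
    case_label: str = "case",
    control_label: str = "control",
) -> ExpressionMatrix:
    """Simulate a case/control experiment with known infiltration.

    Per probe, the expected case signal on the linear scale is
    ``(1 - sum f_j) * 2**ref_mean + sum_j f_j * 2**pop_mean_j`` (the convex
    mixture of baseline tissue and the spiked populations), then log2, plus
    any intrinsic differential-expression shifts, plus per-sample Gaussian
    noise on the log2 scale. Controls are the reference mean plus noise.
    Randomness derives from ``truth.seed``.
    """
    unknown = set(truth.spiked) - set(panel.markers)
    if unknown:
        raise ValueError(f"spiked populations not in panel: {sorted(unknown)}")
    rng = np.random.default_rng(truth.seed)
    probes = panel.reference.probe_ids
    ref_mean = panel.reference.data.mean(axis=1).to_numpy()
    total_f = sum(truth.spiked.values())
    linear = (1.0 - total_f) * np.exp2(ref_mean)
    for pid, f in truth.spiked.items():
        pop_mean = panel.population(pid).data.mean(axis=1).to_numpy()
        linear = linear + f * np.exp2(pop_mean)
    case_mean = np.log2(linear)
    if truth.intrinsic_de:
        extra = set(truth.intrinsic_de) - set(probes)
        if extra:
            raise ValueError(f"intrinsic_de probes not on platform: {sorted(extra)[:10]}")
        shifts = pd.Series(0.0, index=probes)
        shifts.update(pd.Series(truth.intrinsic_de))
        case_mean = case_mean + shifts.to_numpy()

    n_probes = len(probes)
    case = case_mean[:, None] + rng.normal(0.0, truth.noise_sigma, size=(n_probes, n_case))
    ctrl = ref_mean[:, None] + rng.normal(0.0, truth.noise_sigma, size=(n_probes, n_control))
    case_ids = [f"case_s{i + 1}" for i in range(n_case)]
    ctrl_ids = [f"ctrl_s{i + 1}" for i in range(n_control)]
    data = pd.DataFrame(
        np.hstack([case, ctrl]), index=probes, columns=case_ids + ctrl_ids
    )
    groups = {s: case_label for s in case_ids}
    groups.update({s: control_label for s in ctrl_ids})
    return ExpressionMatrix(data, groups)


def expected_marker_log2fc(marker_fc: float, fraction: float) -> float:
    """Closed-form expected log2 fold change of a spiked population's marker.

    A marker at ``marker_fc`` times baseline in the population, mixed at
    fraction ``f``, shifts the case mean by ``log2((1 - f) + f * marker_fc)``
    (single-population spike, no marker sharing).
    """
    return math.log2((1.0 - fraction) + fraction * marker_fc)
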