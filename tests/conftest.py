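"""Shared fixtures: small synthetic panels and experiments.

Everything is generated programmatically at session scope with fixed seeds,
so the suite needs no data files and is fully deterministic.
"""

import numpy as np
import pandas as pd
import pytest

from inflaprof import identify_signatures
from inflaprof.io import ExpressionMatrix
from inflaprof import synthetic as syn
from inflaprof.stats import contrast


@pytest.fixture(scope="session")
def small_matrix():
    """3 probes x 2 samples, hand-written values."""
    df = pd.DataFrame(
        [[4.5, 5.5], [8.0, 8.0], [10.25, 9.75]],
        index=["pA", "pB", "pC"],
        columns=["s1", "s2"],
    )
    return ExpressionMatrix(df)


@pytest.fixture(scope="session")
def default_panel():
    """The default spike-in study panel: 5,000 probes, 20 populations,
    60 markers each at 32-fold, sigma = 0.25, with an 80%-marker-sharing
    decoy (pop02 shares 48 of pop01's markers)."""
    return syn.generate_panel(
        n_probes=5000,
        n_populations=20,
        markers_per_pop=60,
        marker_fc=32.0,
        shared_marker_frac=0.8,
        n_B=3,
        n_A=10,
        noise_sigma=0.25,
        seed=11,
    )


@pytest.fixture(scope="session")
def default_signatures(default_panel):
    return [
        identify_signatures(
            mat,
            default_panel.reference,
            population_id=pid,
            class_label=default_panel.classes[pid],
        )
        for pid, mat in zip(default_panel.population_ids, default_panel.populations)
    ]


@pytest.fixture(scope="session")
def spiked_experiment(default_panel):
    """Case/control experiment with pop01 and pop05 spiked at f = 0.2."""
    truth = syn.SpikeInTruth(spiked={"pop01": 0.2, "pop05": 0.2}, seed=12, noise_sigma=0.25)
    expt = syn.generate_experiment(default_panel, truth, n_case=3, n_control=3)
    return expt, truth


@pytest.fixture(scope="session")
def spiked_contrast(spiked_experiment):
    expt, _ = spiked_experiment
    return contrast(expt, expt.samples_in_group("control"), expt.samples_in_group("case"))
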