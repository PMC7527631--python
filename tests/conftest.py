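"""Shared fixtures: small simulated panels reused across module tests."""

import numpy as np
import pandas as pd
import pytest

from scafqtl import simulate, structure


SMALL = dict(
    n_accessions=60,
    n_subpops=2,
    fst_targets=(0.05,),
    n_scaffolds=30,
    markers_per_scaffold=10,
    locations=("L1", "L2"),
    seed=7,
)


@pytest.fixture(scope="session")
def small_config():
    return simulate.SimulationConfig(**SMALL)


@pytest.fixture(scope="session")
def small_panel(small_config):
    _, sub = simulate.simulate_subpop_frequencies(small_config)
    panel, index, assignment = simulate.simulate_pooled_genotypes(sub, small_config)
    return panel, index, assignment


@pytest.fixture(scope="session")
def small_phenotypes(small_config, small_panel):
    panel, _, _ = small_panel
    return simulate.simulate_phenotypes(panel, small_config)


@pytest.fixture(scope="session")
def small_kinship(small_panel):
    panel, _, _ = small_panel
    return structure.vanraden_kinship(panel)


@pytest.fixture()
def toy_freq_table():
    """Three accessions x four markers covering the QC rule space."""
    rows = []

    def add(mid, scaf, pos, freqs_by_acc):
        for acc, (a, c, g, t) in freqs_by_acc.items():
            rows.append(
                {"marker_id": mid, "scaffold": scaf, "position": pos, "accession": acc,
                 "A": a, "C": c, "G": g, "T": t}
            )

    # informative biallelic marker (A major)
    add("s1_10", "s1", 10, {"x": (0.9, 0.1, 0, 0), "y": (0.5, 0.5, 0, 0), "z": (0.2, 0.8, 0, 0)})
    # near-fixed marker: panel major frequency > 0.98
    add("s1_20", "s1", 20, {"x": (1.0, 0, 0, 0), "y": (0.98, 0.02, 0, 0), "z": (1.0, 0, 0, 0)})
    # tri-allelic: top-two sum 0.9 < 0.95
    add("s2_5", "s2", 5, {"x": (0.5, 0.4, 0.1, 0), "y": (0.5, 0.4, 0.1, 0), "z": (0.5, 0.4, 0.1, 0)})
    # no variation: SD of major-allele frequency is 0
    add("s2_9", "s2", 9, {"x": (0.55, 0.45, 0, 0), "y": (0.55, 0.45, 0, 0), "z": (0.55, 0.45, 0, 0)})
    return pd.DataFrame(rows)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
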