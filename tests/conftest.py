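import numpy as np
import pandas as pd
import pytest

from crisprsel import (
    CountMatrix,
    LibraryAnnotation,
    preset,
    score_simulated_screen,
    simulate_screen,
)


def make_annotation(rows):
    """rows: (sgrna, gene, control_class, core_essential)"""
    df = pd.DataFrame(rows, columns=["sgrna", "gene", "control_class", "core"])
    table = pd.DataFrame(
        {
            "gene": df["gene"].to_numpy(),
            "control_class": df["control_class"].to_numpy(),
            "is_core_essential": df["core"].astype(bool).to_numpy(),
        },
        index=pd.Index(df["sgrna"], name="sgrna"),
    )
    return LibraryAnnotation(table)


@pytest.fixture
def toy_annotation():
    """Three genes (GA 6 guides, GB 2 guides) plus two non-targeting controls."""
    rows = [(f"a{i}", "GA", "targeting", False) for i in range(1, 7)]
    rows += [("b1", "GB", "targeting", False), ("b2", "GB", "targeting", False)]
    rows += [("nt1", "", "non_targeting", False), ("nt2", "", "non_targeting", False)]
    return make_annotation(rows)


@pytest.fixture
def toy_counts(toy_annotation):
    """Hand-built 10-sgRNA count table; initial counts chosen around the 100 cut."""
    initial = [100, 150, 200, 250, 300, 120, 400, 99, 500, 50]
    final = [90, 160, 180, 260, 310, 110, 800, 20, 510, 55]
    counts = pd.DataFrame(
        {"initial": initial, "dmso": final, "drug": final},
        index=toy_annotation.sgrna_ids,
    )
    roles = {"initial": "initial", "dmso": "final_control", "drug": "final_treated"}
    return CountMatrix(counts, roles, toy_annotation.table["gene"])


@pytest.fixture(scope="session")
def small_sim():
    """One small simulated screen (counts, annotation, truth), fixture-sized."""
    return simulate_screen(preset("small", seed=7))


@pytest.fixture(scope="session")
def scored_default():
    """A default-sized simulated screen scored end to end, with its truth."""
    return score_simulated_screen(preset("lowdose", seed=3))
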