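import numpy as np
import pandas as pd
import pytest

from genescape.catalog import GeneRecord, OrthoMatrix, SpeciesPanel
from genescape.pipeline import AnalysisParams, analyze
from genescape.simulate import SimConfig, simulate_panel


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition synthetic panel, reused across read-only tests."""
    return simulate_panel(SimConfig(seed=11))


@pytest.fixture(scope="session")
def default_analysis(default_sim):
    return analyze(sim=default_sim, params=AnalysisParams(seed=11))


@pytest.fixture
def small_panel():
    return SpeciesPanel(
        reference="human",
        avian=("chicken", "tit", "goose", "kiwi"),
        non_avian=("gar", "turtle", "lizard"),
    )


def make_matrix(panel, presence_rows, length_rows=None):
    """Build an OrthoMatrix from dicts: gene -> {species: length or True}."""
    genes = sorted(presence_rows)
    species = list(panel.all_species)
    lengths = pd.DataFrame(np.nan, index=genes, columns=species, dtype=float)
    for gene, row in presence_rows.items():
        for sp, val in row.items():
            lengths.loc[gene, sp] = 1000.0 if val is True else float(val)
    return OrthoMatrix(genes, panel, lengths.notna(), lengths)


@pytest.fixture
def matrix_factory(small_panel):
    def factory(presence_rows, panel=None):
        return make_matrix(panel or small_panel, presence_rows)

    return factory


def toy_records(species="human"):
    return [
        GeneRecord(species, "A1", "chr1", 100, "t1", 500),
        GeneRecord(species, "B2", "chr1", 50, "t2", 600),
        GeneRecord(species, "C3", "chr2", 10, "t3", 700),
    ]
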