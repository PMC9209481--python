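import numpy as np
import pandas as pd
import pytest

from somaclone import GeneModel, SimulationConfig, annotate_mutations, generate_panel
from somaclone.simulate import panel_site_table


@pytest.fixture
def toy_gene():
    """Met-Glu-stop minigene used in the worked codon examples."""
    return GeneModel("g1", "ATGGAATAA", "driver", flank5="A", flank3="A")


@pytest.fixture(scope="session")
def small_panel():
    cfg = SimulationConfig(
        seed=42, n_driver=3, n_immune=2, n_housekeeping=2,
        min_codons=60, max_codons=120,
    )
    return generate_panel(cfg)


@pytest.fixture(scope="session")
def small_sites(small_panel):
    return panel_site_table(small_panel)


def make_annotated(panel, rows):
    """Annotated mutation table from (sample, gene, pos, ref, alt, vaf) rows."""
    df = pd.DataFrame(rows, columns=["sample_id", "gene_id", "pos", "ref", "alt", "vaf"])
    df["phase_tag"] = None
    return annotate_mutations(df, panel)
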