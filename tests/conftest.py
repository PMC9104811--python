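import numpy as np
import pandas as pd
import pytest

from neurobiota.glm import build_design_matrix
from neurobiota.microbiome import TaxaTable
from neurobiota.paradigm import build_eat_design

TR_S = 2.5
N_VOLUMES = 192


@pytest.fixture(scope="session")
def eat_design():
    return build_eat_design()


@pytest.fixture(scope="session")
def design_matrix(eat_design):
    return build_design_matrix(eat_design, TR_S, N_VOLUMES)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_taxa_table():
    """4 taxa x 4 samples with hand-set counts (used by diversity tests)."""
    counts = pd.DataFrame(
        np.array([[10, 0, 5, 2], [0, 8, 5, 1], [3, 3, 5, 9], [7, 1, 5, 4]]).T,
        index=[f"t{i}" for i in range(4)],
        columns=list("ABCD"),
    )
    meta = pd.DataFrame(
        {"subject": list("ABCD"), "TREAT": ["placebo"] * 4, "TIME": ["before"] * 4},
        index=list("ABCD"),
    )
    taxonomy = pd.Series(
        [
            "Bacteria;Firmicutes;Clostridia;Eubacteriales;Lachnospiraceae;Blautia;sp1",
            "Bacteria;Firmicutes;Clostridia;Eubacteriales;Lachnospiraceae;Blautia;sp2",
            "Bacteria;Bacteroidota;Bacteroidia;Bacteroidales;Bacteroidaceae;Bacteroides;sp3",
            "Bacteria;Firmicutes;Negativicutes;Veillonellales;Veillonellaceae;Dialister;sp4",
        ],
        index=counts.index,
    )
    return TaxaTable(counts=counts, taxonomy=taxonomy, sample_meta=meta)
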