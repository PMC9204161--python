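import numpy as np
import pandas as pd
import pytest

import twopan as tp
from twopan.genetics import AMINO_ACIDS


def make_cmap(arm: str, entries: dict, n_positions: int = 11) -> tp.ClassificationMap:
    """Build a classification map from {"R@P1": +1, ...} token entries."""
    idx = [f"P{i + 1}" for i in range(n_positions)]
    mat = pd.DataFrame(0, index=idx, columns=list(AMINO_ACIDS), dtype=np.int8)
    for token, value in entries.items():
        aa, pos = token.split("@")
        mat.at[pos, aa] = value
    return tp.ClassificationMap(arm=arm, cutoff=5.0, matrix=mat)


# Classification cells quoted in the study's text: nine residues enriched in
# both arms; S@P5 enriched against pTyr but depleted against sTyr; L@P6 the
# opposite; everything else neutral.
BOTH_ENRICHED = ["R@P1", "C@P2", "S@P3", "E@P4", "Y@P7", "V@P8", "H@P9", "Y@P10", "L@P11"]


@pytest.fixture(scope="session")
def text_fixture_maps():
    ptyr = {t: 1 for t in BOTH_ENRICHED} | {"S@P5": 1, "L@P6": -1}
    styr = {t: 1 for t in BOTH_ENRICHED} | {"S@P5": -1, "L@P6": 1}
    return make_cmap("sTyr", styr), make_cmap("pTyr", ptyr)


@pytest.fixture(scope="session")
def design():
    return tp.default_design()


@pytest.fixture(scope="session")
def small_scenario(tmp_path_factory):
    """A reduced-scale simulated dataset shared across test modules."""
    outdir = tmp_path_factory.mktemp("sim_small")
    config = tp.ScenarioConfig(n_clones=5000, depth=20_000, seed=7)
    return tp.run_scenario(config, outdir)


@pytest.fixture(scope="session")
def small_analysis(small_scenario):
    return tp.analyze_run(small_scenario.sample_sheet, small_scenario.design)
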