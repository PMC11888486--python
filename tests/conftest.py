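import logging

import numpy as np
import pandas as pd
import pytest

from csfcyto import (build_default_config, default_gate_tree,
                     default_thresholds)
from csfcyto.panel import MarkerPanel

logging.getLogger("csfcyto").setLevel(logging.ERROR)

PANEL = MarkerPanel()


@pytest.fixture(scope="session")
def tree():
    return default_gate_tree()


@pytest.fixture(scope="session")
def thresholds():
    return default_thresholds()


def make_events(rows: list[dict[str, float]]) -> pd.DataFrame:
    """Event frame from sparse per-event channel dicts (others 0.0)."""
    data = np.zeros((len(rows), len(PANEL.channels)))
    frame = pd.DataFrame(data, columns=list(PANEL.channels))
    for i, row in enumerate(rows):
        for ch, v in row.items():
            frame.loc[i, ch] = v
    return frame


@pytest.fixture(scope="session")
def toy_events():
    """Eight hand-gateable events covering the major lineages.

    e1 myeloid; e2 CD4 central-memory T; e3 naive CD8 T; e4 ASC (B);
    e5 NK; e6 DC; e7 granulocyte (SSC-high); e8 CD45-negative (excluded).
    """
    return make_events([
        {"CD45": 4, "CD14": 4},
        {"CD45": 4, "CD3": 4, "CD4": 4, "CD27": 4, "CD45RA": 0},
        {"CD45": 4, "CD3": 4, "CD8": 4, "CD27": 4, "CD45RA": 4},
        {"CD45": 4, "CD19": 4, "CD27": 6, "CD38": 6},
        {"CD45": 4, "CD56": 4},
        {"CD45": 4, "HLA-DR": 4, "CD11c": 4},
        {"CD45": 4, "SSC": 6},
        {"CD45": 0},
    ])


@pytest.fixture(scope="session")
def nind_config():
    return build_default_config(["NIND"], master_seed=1)
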