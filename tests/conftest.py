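import numpy as np
import pandas as pd
import pytest

from secdrug.pgx_io import DoseResponsePanel


def make_panel(values, drugs=None, lines=None, annotations=None):
    """Build a small DoseResponsePanel from a nested list / array (nM)."""
    values = np.asarray(values, dtype=float)
    drugs = drugs or [f"drug{i}" for i in range(values.shape[0])]
    lines = lines or [f"line{i}" for i in range(values.shape[1])]
    return DoseResponsePanel(
        pd.DataFrame(values, index=drugs, columns=lines), annotations=annotations
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def gu_annotated_panel():
    """One-drug panel over the genito-urinary fixture lines plus 10 lung lines."""
    from secdrug.synthetic import make_tissue_annotations

    ann = make_tissue_annotations()
    extra = pd.DataFrame(
        {"tissue": "lung", "subtype": ""},
        index=pd.Index([f"LU{i:02d}" for i in range(10)], name="cell_line_id"),
    )
    ann = pd.concat([ann, extra])
    values = np.full((1, len(ann)), 10.0)
    return make_panel(values, drugs=["docetaxel"], lines=list(ann.index),
                      annotations=ann)
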