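import numpy as np
import pandas as pd
import pytest

from sfcoupling.parcellation_io import ParcellationScheme, default_scheme


@pytest.fixture
def small_scheme() -> ParcellationScheme:
    """4 ROIs in 2 networks of 2 — the minimal valid aggregation scheme."""
    return ParcellationScheme(
        roi_ids=np.arange(1, 5),
        roi_names=("L_FPN_1", "R_FPN_2", "L_DMN_1", "R_DMN_2"),
        networks=("FPN", "FPN", "DMN", "DMN"),
        hemispheres=("L", "R", "L", "R"),
    )


@pytest.fixture
def scheme42() -> ParcellationScheme:
    """42-ROI scheme over the canonical 7 networks (6 ROIs each)."""
    return default_scheme(42)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


def make_lookup_table(tmp_path, rows, sep="\t", name="scheme.tsv"):
    path = tmp_path / name
    header = sep.join(["roi_id", "roi_name", "network", "hemisphere"])
    lines = [header] + [sep.join(str(v) for v in row) for row in rows]
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def lookup_table_factory(tmp_path):
    return lambda rows, **kw: make_lookup_table(tmp_path, rows, **kw)
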