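import dataclasses

import numpy as np
import pandas as pd
import pytest

from honeyspec.spectra_io import Platform, SampleTable, SpectralBlock
from honeyspec.synthetic import default_config, generate


def fast_config(seed, n_per_class=12, harvests=(2014, 2015, 2016, 2017), classes=None):
    """Reduced generator for Monte-Carlo module tests: coarser grids, 1 replicate."""
    cfg = default_config(seed)
    platforms = {
        name: dataclasses.replace(spec, axis_step=spec.axis_step * 4, replicates=1)
        for name, spec in cfg.platforms.items()
    }
    return dataclasses.replace(
        cfg,
        platforms=platforms,
        harvests=tuple(harvests),
        n_per_class_per_harvest=n_per_class,
        classes=classes if classes is not None else cfg.classes,
    )


@pytest.fixture(scope="session")
def default_dataset():
    """One full-size dataset under the default study conditions."""
    ds = generate(default_config(0))
    blocks, table = ds.averaged()
    return ds, blocks, table


@pytest.fixture
def toy_block():
    axis = np.array([900.0, 1000.0, 1100.0, 1200.0])
    x = np.array([[1.0, 2.0, 3.0, 4.0], [2.0, 4.0, 6.0, 8.0], [0.0, 1.0, 0.0, 1.0]])
    return SpectralBlock(Platform.FTMIR, axis, x, ["s1", "s2", "s3"])


@pytest.fixture
def toy_table():
    return SampleTable(pd.DataFrame({
        "sample_id": ["s1", "s2", "s3"],
        "class_label": ["BA", "BA", "Mis"],
        "harvest_year": [2014, 2014, 2014],
        "replicate": [1, 1, 1],
    }))
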