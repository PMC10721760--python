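import numpy as np
import pandas as pd
import pytest

from plantpp import SimulationSpec, simulate_dataset, write_fixtures
from plantpp.profiles import filter_and_floor, normalize_lpp, zscore_columns


@pytest.fixture(scope="session")
def small_dataset():
    """300 genes, 2 clades of 12 species, one planted 20-gene module."""
    spec = SimulationSpec(n_genes=300, clade_sizes=(12, 12), modules=((20, 0.9),),
                          missing_rate=0.05, seed=11)
    return simulate_dataset(spec)


@pytest.fixture(scope="session")
def small_npp(small_dataset):
    filtered = filter_and_floor(small_dataset.bitscore_matrix)
    return zscore_columns(normalize_lpp(filtered))


@pytest.fixture()
def fixture_dir(small_dataset, tmp_path):
    manifest = write_fixtures(small_dataset, tmp_path / "fx")
    return manifest


def hit_files_from_manifest(manifest):
    return {key.split(":", 1)[1]: path
            for key, path in manifest.items() if key.startswith("hits:")}
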