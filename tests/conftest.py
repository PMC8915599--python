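import numpy as np
import pandas as pd
import pytest

from intrinsol.records import PKa
from intrinsol.synthetic import GeneratorSpec, generate_dataset


@pytest.fixture(scope="session")
def linear_dataset():
    """Moderate ABSOLV-linear-truth dataset with lab-level noise."""
    return generate_dataset(GeneratorSpec(n_molecules=800, seed=42))


@pytest.fixture(scope="session")
def noise_free_dataset():
    return generate_dataset(GeneratorSpec(n_molecules=400, seed=7, noise_sd=0.0))


@pytest.fixture(scope="session")
def nonlinear_dataset():
    return generate_dataset(GeneratorSpec(n_molecules=1500, seed=7, truth="nonlinear"))


@pytest.fixture
def base_pka():
    return [PKa(9.0, "base")]


@pytest.fixture
def acid_pka():
    return [PKa(4.0, "acid")]


@pytest.fixture
def ampholyte_pkas():
    # ordinary ampholyte: basic group protonates well below the acidic pKa,
    # leaving a neutral window in between
    return [PKa(10.0, "acid"), PKa(4.0, "base")]


def merge_dataset(ds) -> pd.DataFrame:
    """Molecule-level benchmark table: intrinsic + descriptors."""
    return ds.intrinsic.merge(ds.descriptors, on="molecule_id")
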