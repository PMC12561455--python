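from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from kisse import AbundanceMatrix, GeneratorConfig, build_library, generate_library
from kisse.matrix import SCALE_NORMALIZED


def make_matrix(values: dict, manifest_rows: list[tuple], scale=SCALE_NORMALIZED):
    """Small hand-built matrix.

    values: {peptide: {sample: abundance or None}}
    manifest_rows: [(sample_id, species, individual), ...]
    """
    manifest = pd.DataFrame(
        manifest_rows, columns=["sample_id", "species", "individual"]
    )
    samples = manifest["sample_id"].tolist()
    frame = pd.DataFrame(
        {
            s: {p: (np.nan if row.get(s) is None else row.get(s, np.nan))
                for p, row in values.items()}
            for s in samples
        },
        dtype=float,
    )
    frame = frame.sort_index()
    man = manifest.set_index("sample_id")
    return AbundanceMatrix(
        values=frame,
        missing_mask=frame.isna(),
        species=man["species"],
        individuals=man["individual"],
        scale=scale,
    )


@pytest.fixture(scope="session")
def sim8():
    """Default 8-species x 3-individuals synthetic library."""
    return generate_library(GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def lib8(sim8):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_library(sim8.tables, sim8.manifest)


@pytest.fixture(scope="session")
def sim8_reps():
    """8 species x 3 individuals x 3 replicates (well-trained classifier)."""
    return generate_library(GeneratorConfig(seed=12, replicates=3))


@pytest.fixture(scope="session")
def lib8_reps(sim8_reps):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_library(sim8_reps.tables, sim8_reps.manifest)


@pytest.fixture(scope="session")
def sim3():
    """Small 3-species library for fast IO/CLI round-trips."""
    return generate_library(
        GeneratorConfig(
            n_species=3,
            n_specific_per_species=14,
            n_shared_lineage=6,
            n_universal=30,
            seed=21,
        )
    )


@pytest.fixture(scope="session")
def lib3(sim3):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_library(sim3.tables, sim3.manifest)
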