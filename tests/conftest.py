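"""Shared fixtures: a small simulated crossbred herd reused across tests."""

import numpy as np
import pandas as pd
import pytest

from bovrr import records, relmat, simdata


@pytest.fixture(scope="session")
def small_herd():
    """~150 phenotyped cows, 600 linked variants, known generating truth."""
    return simdata.simulate_herd(
        n_cows=150,
        n_variants=600,
        ratio_a8=0.5,
        ratio_d8=0.05,
        seed=42,
        n_breeds=3,
        n_chromosomes=3,
        chrom_length=30_000_000,
        n_founders_per_breed=12,
    )


@pytest.fixture(scope="session")
def small_records(small_herd):
    ped = small_herd["pedigree"]
    seasons = dict(zip(ped.table["animal_id"], ped.table["birth_season"]))
    return records.build_records(small_herd["events"], ped.composition, seasons)


@pytest.fixture(scope="session")
def small_grms(small_herd):
    G, M, c_a = relmat.additive_grm(small_herd["genotypes"])
    D, H, c_d = relmat.dominance_grm(small_herd["genotypes"])
    return dict(G=G, M=M, c_a=c_a, D=D, H=H, c_d=c_d)


def genotypes_from_calls(calls, positions=None, chrom=None):
    """Helper to build a GenotypeMatrix from a literal call array."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    if positions is None:
        positions = (np.arange(m) + 1) * 1000
    if chrom is None:
        chrom = ["1"] * m
    return relmat.GenotypeMatrix(
        animal_ids=np.array([f"a{i}" for i in range(n)]),
        variants=pd.DataFrame({"chrom": chrom, "pos": positions, "annotation": ""}),
        calls=calls,
    )
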