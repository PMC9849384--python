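"""Shared fixtures: hand-written potentials, toy structures, synthetic datasets."""

import numpy as np
import pandas as pd
import pytest

from ddgfeat import (
    AMINO_ACIDS,
    GeneratorSpec,
    PairPotential,
    StabilityClass,
    ToyStructureSpec,
    generate_toy_structure,
    generate_variant_dataset,
    make_fixture_study,
)

AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


@pytest.fixture(scope="session")
def hand_potential() -> PairPotential:
    """Deterministic symmetric potential v(a, b) = 0.1*(i_a + i_b) - 0.05*i_a*i_b.

    Hand-computable for any pair, symmetric by construction, with enough
    spread that differences never cancel accidentally.
    """
    n = len(AMINO_ACIDS)
    vals = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            vals[i, j] = 0.1 * (i + j) - 0.005 * i * j
    frame = pd.DataFrame(vals, index=list(AMINO_ACIDS), columns=list(AMINO_ACIDS))
    return PairPotential(values=frame)


@pytest.fixture(scope="session")
def toy_extended():
    """A 7-residue extended peptide and its PDB text."""
    spec = ToyStructureSpec(sequence="ACDEFGH", mode="extended", name="TOY1")
    return generate_toy_structure(spec)


@pytest.fixture(scope="session")
def synth_10k():
    """A 10,000-variant synthetic dataset at the default 55/30/15 composition."""
    ds, truth = generate_variant_dataset(GeneratorSpec(n_variants=10_000, seed=42))
    return ds, truth


@pytest.fixture(scope="session")
def synth_arrays(synth_10k):
    """(ddg, classes) arrays of the session synthetic dataset."""
    ds, _ = synth_10k
    ddg = np.array([r.ddg_exp for r in ds.records])
    classes = np.array([r.stability_class.value for r in ds.records])
    return ddg, classes


@pytest.fixture(scope="session")
def fixture_study(tmp_path_factory):
    """A complete miniature study directory written by the generator."""
    out = tmp_path_factory.mktemp("study")
    paths = make_fixture_study(out, n_variants_per_protein=6, n_proteins=3, seed=7)
    return paths


TARGET_PATTERN = {
    StabilityClass.DESTABILIZING: 0.26,
    StabilityClass.NEUTRAL: -0.02,
    StabilityClass.STABILIZING: -0.18,
}
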