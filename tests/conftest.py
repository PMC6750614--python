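import numpy as np
import pandas as pd
import pytest

from complexoscope import SpeciesQuantTable, SyntheticConfig
from complexoscope.synthetic import generate_multispecies_proteome


def make_quant_table(species, abundances, peptides=None):
    """Build a SpeciesQuantTable from a dict accession -> per-replicate values."""
    idx = pd.Index(list(abundances), name="accession")
    ab = pd.DataFrame([abundances[a] for a in idx], index=idx, dtype=float)
    ab.columns = [f"rep{i + 1}" for i in range(ab.shape[1])]
    if peptides is None:
        pep = pd.DataFrame(5, index=idx, columns=ab.columns)
    else:
        pep = pd.DataFrame([peptides[a] for a in idx], index=idx, columns=ab.columns)
    return SpeciesQuantTable(species=species, peptides=pep, abundance=ab)


@pytest.fixture
def noise_free_config():
    """Deterministic generator settings: no noise, no missingness, no dropouts."""
    return SyntheticConfig(
        seed=7,
        n_reference_proteins=120,
        noise_sigma=0.0,
        missingness=0.0,
        unquantifiable_fraction=0.0,
        homeolog_fraction=0.3,
        n_complexes=12,
    )


@pytest.fixture
def noise_free_proteome(noise_free_config):
    return generate_multispecies_proteome(noise_free_config)


@pytest.fixture
def rng():
    return np.random.default_rng(20250921)
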