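import numpy as np
import pandas as pd
import pytest

from dyesol import GeneratorSpec, generate


@pytest.fixture(scope="session")
def small_synth():
    """Small noiseless dataset: 4 scaffolds x 8 substituents, 2 solvents."""
    spec = GeneratorSpec(
        n_scaffolds=4,
        substituents_per_scaffold=8,
        solvents=(("O", 25.0), ("CCO", 10.0)),
        noise_sd_nm=0.0,
        lowfi_noise_sd_nm=0.0,
        replicate_fraction=1.0,
        seed=11,
    )
    ds, truth = generate(spec)
    return spec, ds, truth


@pytest.fixture(scope="session")
def noisy_synth():
    """Mid-size noisy dataset used by split and model tests."""
    spec = GeneratorSpec(
        n_scaffolds=8,
        substituents_per_scaffold=12,
        noise_sd_nm=5.0,
        lowfi_noise_sd_nm=3.0,
        replicate_fraction=0.5,
        seed=7,
    )
    ds, truth = generate(spec)
    return spec, ds, truth


@pytest.fixture()
def raw_table():
    """A raw measurement table exercising every curation drop reason."""
    return pd.DataFrame(
        {
            "smiles": [
                "c1ccc2cc3ccccc3cc2c1",  # anthracene, named solvent
                "Cc1ccccc1",  # valid
                "C1CC",  # invalid dye smiles
                "CCO.[Na+]",  # multi-component dye
                "c1ccccc1",  # negative wavelength
                "c1ccncc1",  # unmappable solvent name
                "Cc1ccc(N)cc1",  # duplicate pair, within 5 nm
                "Cc1ccc(N)cc1",
                "Oc1ccccc1",  # duplicate pair, conflicting
                "Oc1ccccc1",
                None,  # missing dye
            ],
            "solvent": [
                "thf",
                "O",
                "O",
                "O",
                "O",
                "unknownium",
                "CCO",
                "OCC",  # same solvent, different spelling
                "O",
                "O",
                "O",
            ],
            "peak_wavelength_nm": [
                375.0,
                420.0,
                400.0,
                410.0,
                -5.0,
                390.0,
                500.0,
                503.0,
                500.0,
                507.0,
                450.0,
            ],
            "source": ["A"] * 11,
        }
    )


@pytest.fixture()
def name_map():
    return {"thf": "C1CCOC1", "water": "O"}
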