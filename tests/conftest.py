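from __future__ import annotations

import numpy as np
import pytest

from dyespec.spectra import Spectrum, make_grid
from dyespec.synthetic import (GeneratorConfig, make_dimer_bands,
                               make_monomer_spectrum)


@pytest.fixture(scope="session")
def gen_config() -> GeneratorConfig:
    return GeneratorConfig(seed=0)


@pytest.fixture(scope="session")
def grid(gen_config) -> np.ndarray:
    return gen_config.grid()


@pytest.fixture(scope="session")
def monomer_basis(gen_config) -> Spectrum:
    return make_monomer_spectrum(gen_config)


@pytest.fixture(scope="session")
def dimer_bases(grid) -> tuple[Spectrum, Spectrum]:
    return (make_dimer_bands("parallel", grid=grid),
            make_dimer_bands("antiparallel", grid=grid))


@pytest.fixture
def cavity_grid() -> np.ndarray:
    return make_grid(1.2, 2.6, 0.0005)
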