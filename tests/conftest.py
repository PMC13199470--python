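import numpy as np
import pytest

from pdiff.synthetic import Phenotype, render_field, sample_library


@pytest.fixture(scope="session")
def small_library():
    """60 compounds, 6 mechanisms (18 series by default), reproducible."""
    return sample_library(60, 6, profile_width=24, seed=42)


@pytest.fixture(scope="session")
def toy_images():
    """A handful of rendered fields across distinct phenotypes."""
    phenos = {
        "dense": Phenotype(20, 4.5),
        "sparse": Phenotype(5, 5.0),
        "toxic": Phenotype(12, 5.0, death=True),
    }
    return {
        name: np.stack([render_field(p, 64, 64, seed=100 * i + j) for j in range(4)])
        for i, (name, p) in enumerate(phenos.items())
    }
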