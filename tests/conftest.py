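import numpy as np
import pytest

from locuslens.ld import HaplotypePanel


@pytest.fixture
def two_locus_panel() -> HaplotypePanel:
    """Hand-countable panel: haplotype counts AB:6, Ab:2, aB:2, ab:10."""
    h = np.array([[1, 1]] * 6 + [[1, 0]] * 2 + [[0, 1]] * 2 + [[0, 0]] * 10)
    return HaplotypePanel(["va", "vb"], np.array([100, 200]), h)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)
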