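import numpy as np
import pytest

from regazyme import NussinovEngine, Part, RegazymeLayout, RegionRef, toy_layout


@pytest.fixture(scope="session")
def toy_engine():
    return NussinovEngine()


@pytest.fixture(scope="session")
def layout():
    """The enumerable toy design problem (64 transducers, optimum 0)."""
    return toy_layout()


@pytest.fixture(scope="session")
def small_layout():
    """A layout whose assembled sequences stay within oracle reach (≤ 11 nt)."""
    parts = (
        Part("tr", "transducer", "A", mutable=True),
        Part("apt", "aptamer", "GAAAC"),
        Part("ribo", "riboregulator", "GGGA"),
    )
    return RegazymeLayout(
        parts=parts,
        cleavage_after="tr",
        seed=RegionRef("ribo", 0, 3),
        target_aptamer_structure="(...)",
        transducer_length_bounds=(1, 2),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
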