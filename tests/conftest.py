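import numpy as np
import pytest

from lexcap import Compendium, ModelParams, ResourceSet, TermRecord


def build_compendium(rows, resources, mode="undirected_concepts"):
    """rows: iterable of (concept, term, bits, preferred)."""
    comp = Compendium(ResourceSet(tuple(resources)), mode=mode)
    for concept, term, bits, pref in rows:
        comp.add_record(concept, TermRecord(term, tuple(bits), is_preferred=pref))
    comp.validate()
    return comp


@pytest.fixture
def two_resource_compendium():
    return build_compendium(
        [
            ("c1", "alpha", (1, 0), True),
            ("c1", "alef", (0, 1), False),
            ("c2", "beta", (1, 1), True),
            ("c2", "vita", (1, 0), False),
            ("c2", "b", (0, 1), False),
            ("c3", "gamma", (0, 1), True),
        ],
        resources=("MSH", "NCI"),
    )


@pytest.fixture
def single_class_params():
    return ModelParams.single_class([0.2, 0.3, 0.4, 0.3, 0.25], 0.5)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
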