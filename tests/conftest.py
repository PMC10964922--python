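import numpy as np
import pytest

import phonohpp as p


@pytest.fixture(scope="session")
def inventory():
    return p.study_inventory()


@pytest.fixture(scope="session")
def toy_lexicon(inventory):
    """{sa, su, ʃa, ta, api}: 2 of 5 types are /s/-initial."""
    entries = [
        p.LexEntry("sa", ("s", "a")),
        p.LexEntry("su", ("s", "u")),
        p.LexEntry("ʃa", ("ʃ", "a")),
        p.LexEntry("ta", ("t", "a")),
        p.LexEntry("api", ("a", "p", "i")),
    ]
    return p.Lexicon.from_entries(entries, inventory, {"language": "toy", "register": "ADS"})


@pytest.fixture(scope="session")
def versions():
    return p.default_versions(seed=99)


@pytest.fixture(scope="session")
def simulated(versions):
    """Default-parameter dataset at the study's size (24 per language group)."""
    return p.simulate_dataset(p.SimParams(n_per_group=24, seed=42), versions=versions)


@pytest.fixture(scope="session")
def analysis_table(simulated):
    return p.preprocess(simulated)
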