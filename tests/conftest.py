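import pytest

from abnsynth.conditions import semantic_index
from abnsynth.network import AbstractBooleanNetwork, Component, Interaction


@pytest.fixture(scope="session")
def some_act():
    """Index of the 'some activators, no repressors' template."""
    return semantic_index("some_activators_no_repressors")


@pytest.fixture(scope="session")
def some_act_any():
    """Index of the repressor-blind 'some activators' template."""
    return semantic_index("some_activators")


def make_abn(components, interactions):
    """Shorthand ABN builder for tests.

    ``components``: iterable of (name, menu) pairs;
    ``interactions``: iterable of (source, target, sign, definite).
    """
    return AbstractBooleanNetwork(
        [Component(name=n, condition_menu=frozenset(menu)) for n, menu in components],
        [Interaction(s, t, sign, definite) for s, t, sign, definite in interactions],
    )
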