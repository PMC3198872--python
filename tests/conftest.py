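import datetime as dt

import pytest

from ontoevo import OntologySnapshot, generate_base

D0 = dt.date(2000, 1, 1)
D1 = dt.date(2001, 1, 1)
D2 = dt.date(2002, 1, 1)


def make_snapshot(concepts, isa_edges=(), date=D0, source="TST", **extra_attrs):
    """Small hand-built snapshot: concepts is {acc: name} or an iterable of accs."""
    snap = OntologySnapshot(source, date)
    if isinstance(concepts, dict):
        for acc, name in concepts.items():
            snap.add_element(acc, name=name)
    else:
        for acc in concepts:
            snap.add_element(acc, name=f"name of {acc}")
    for child, parent in isa_edges:
        snap.add_relationship(child, parent, "is_a")
    for acc, (attr, value) in extra_attrs.items():
        snap.elements[acc].add_attribute(attr, value)
    return snap


@pytest.fixture
def chain_snapshot():
    """a is-a b is-a c."""
    return make_snapshot(["a", "b", "c"], [("a", "b"), ("b", "c")])


@pytest.fixture
def base200():
    return generate_base(200, seed=42)
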