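import pytest

import minibao as mb
from minibao.query import _plain
from minibao.synth import fixture_example1, fixture_example2, fixture_example3


@pytest.fixture(scope="session")
def onto_schema():
    return mb.build_mini_bao()


@pytest.fixture(scope="session")
def onto(onto_schema):
    return onto_schema[0]


@pytest.fixture(scope="session")
def schema_graph(onto_schema):
    return onto_schema[1]


def _pipeline(rows, onto):
    res = mb.load_annotations(rows, onto)
    assert not res.rejected, f"fixture rows rejected: {res.rejected}"
    return mb.materialize(res.graph, onto)


@pytest.fixture(scope="session")
def ex1(onto):
    rows, expected = fixture_example1()
    return _pipeline(rows, onto), expected


@pytest.fixture(scope="session")
def ex2(onto):
    rows, expected = fixture_example2()
    return _pipeline(rows, onto), expected


@pytest.fixture(scope="session")
def ex3(onto):
    rows, expected = fixture_example3()
    return _pipeline(rows, onto), expected


def plain_rows(rows):
    """Query result rows as plain-string dicts for comparison."""
    return [{k.name: _plain(v) for k, v in r.items()} for r in rows]
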