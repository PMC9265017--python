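import pytest

from equide import NS_EQUATION, ZK_EQUATION, load_table1


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture(scope="session")
def complete24(table1):
    return table1.complete()


@pytest.fixture(params=["ns", "zk"], ids=["ns", "zk"])
def equation(request):
    return {"ns": NS_EQUATION, "zk": ZK_EQUATION}[request.param]
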