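import pytest

from strongcoupling import intervention, synthetic


@pytest.fixture(scope="session")
def toy1():
    return synthetic.make_toy("TOY1")


@pytest.fixture(scope="session")
def toy3():
    return synthetic.make_toy("TOY3")


@pytest.fixture(scope="session")
def toy3g():
    return synthetic.make_toy("TOY3-G")


@pytest.fixture(scope="session")
def toy3g_iso():
    return synthetic.make_toy("TOY3-G-ISO")


def problem_for(fix, product="EX_P", level=0.5):
    return intervention.build_coupling_problem(fix.network, fix.config, product, level)
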