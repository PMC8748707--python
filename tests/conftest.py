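import networkx as nx
import numpy as np
import pytest

from polyforge.synthetic import toy_library


@pytest.fixture(scope="session")
def bead_spring():
    return toy_library("bead_spring")


@pytest.fixture(scope="session")
def vinyl3():
    return toy_library("vinyl3")


@pytest.fixture(scope="session")
def nucleotide1():
    return toy_library("nucleotide1")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def path_graph(n, resname="B"):
    g = nx.path_graph(n)
    nx.set_node_attributes(g, resname, "resname")
    return g


def cycle_graph(n, resname="B"):
    g = nx.cycle_graph(n)
    nx.set_node_attributes(g, resname, "resname")
    return g


def star_graph(arms, resname="B"):
    g = nx.star_graph(arms)
    nx.set_node_attributes(g, resname, "resname")
    return g
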