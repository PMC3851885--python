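import pytest

from orthofix.fixtures import load_fixture
from orthofix.simgen import iter_sized_instances, make_goc_instance


@pytest.fixture(scope="session")
def fig1():
    return load_fixture("fig1")


@pytest.fixture(scope="session")
def fig2():
    return load_fixture("fig2")


@pytest.fixture(scope="session")
def fig4():
    return load_fixture("fig4")


@pytest.fixture(scope="session")
def fig5():
    return load_fixture("fig5")


def sized_instances(count, n_species, min_leaves, max_leaves, **kw):
    """First `count` simulated reconciled trees in a leaf-count range."""
    out = []
    for seed, R, true_dups in iter_sized_instances(
            range(100_000), n_species, min_leaves, max_leaves, **kw):
        out.append((seed, R, true_dups))
        if len(out) >= count:
            break
    assert len(out) == count, "simulator starved the test of instances"
    return out


def goc_instances(count, n_species, min_leaves, max_leaves, k_pairs=2, **kw):
    out = []
    for seed, R, _ in iter_sized_instances(
            range(100_000), n_species, min_leaves, max_leaves, **kw):
        try:
            _, P = make_goc_instance(R, min(k_pairs, R.tree.n_leaves), seed)
        except ValueError:
            continue
        out.append((seed, R, P))
        if len(out) >= count:
            break
    assert len(out) == count, "simulator starved the test of instances"
    return out
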