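import sys
from pathlib import Path

import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")

from ppinet.fixtures import FixtureSpec, generate_fixture  # noqa: E402


@pytest.fixture(scope="session")
def fixture_set(tmp_path_factory):
    """One default synthetic dataset shared across the suite."""
    outdir = tmp_path_factory.mktemp("fixture")
    return generate_fixture(FixtureSpec(seed=7), outdir)


@pytest.fixture(scope="session")
def small_spec():
    """A reduced dataset specification for replicate-heavy tests."""
    return FixtureSpec(n_genes=50, n_edges=80, go_module_sizes=(10, 8),
                       n_duplicate_pairs=6, n_multi_map=2, seed=0)
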