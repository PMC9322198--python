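import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes oracles importable

import synloop as sl


@pytest.fixture(scope="session")
def default_world():
    """One default synthetic world shared by read-only tests."""
    return sl.build_world(sl.WorldConfig(seed=42))


@pytest.fixture(scope="session")
def world_dir(tmp_path_factory):
    # built from a fresh world object so that tests which re-plant layers on
    # the shared in-memory world cannot perturb the files
    d = tmp_path_factory.mktemp("world")
    sl.write_world(sl.build_world(sl.WorldConfig(seed=42)), d)
    return d


@pytest.fixture(scope="session")
def pipeline_records(default_world):
    """Interactions prepared, lifted and classified from the default world."""
    w = default_world
    lris = sl.prepare_interactions(w.anchor_pairs, w.genes_source,
                                   w.source_k4me1, w.source_k27ac)
    records = sl.map_interactions(lris, sl.ChainIndex(w.chain_set))
    records = sl.annotate_interactions(records, w.genes_target)
    return lris, records
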