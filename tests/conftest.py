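"""Shared fixtures.

Structure fixtures are session-scoped: the sheet builders run a small
deterministic placement optimization, so rebuilding them per test would
dominate the suite's runtime.  Tests that mutate structures must copy.
"""

import numpy as np
import pytest

from strandlink.fixtures import (
    RepeatProteinSpec,
    build_dhr,
    build_ideal_helix,
    build_ideal_sheet,
    build_scaffold,
)
from strandlink.secondary import assign_secondary_structure


@pytest.fixture(scope="session")
def helix18():
    return build_ideal_helix(18)


@pytest.fixture(scope="session")
def sheet_2x5():
    s = build_ideal_sheet(2, 5, "antiparallel")
    assign_secondary_structure(s)
    return s


@pytest.fixture(scope="session")
def sheet_4x6():
    s = build_ideal_sheet(4, 6, "antiparallel")
    assign_secondary_structure(s)
    return s


@pytest.fixture(scope="session")
def dhr_spec():
    return RepeatProteinSpec(4)


@pytest.fixture(scope="session")
def dhr4(dhr_spec):
    return build_dhr(dhr_spec)


@pytest.fixture(scope="session")
def scaffold_open():
    """Exposed edge strand, no blocking elements."""
    s = build_scaffold(edge_exposed=True, blocking_helix=False)
    assign_secondary_structure(s)
    return s


@pytest.fixture(scope="session")
def scaffold_blocked():
    """Exposed edge strand flanked by homodimer-blocking helices."""
    s = build_scaffold(edge_exposed=True, blocking_helix=True)
    assign_secondary_structure(s)
    return s


@pytest.fixture(scope="session")
def scaffold_buried():
    """No exposed edge strand at all."""
    s = build_scaffold(edge_exposed=False, blocking_helix=False)
    assign_secondary_structure(s)
    return s


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
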