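"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import pytest

from mitoribo import synthetic_data as sd
from mitoribo.counting import LibraryMeta


@pytest.fixture(scope="session")
def annotation():
    return sd.make_mito_annotation()


@pytest.fixture(scope="session")
def preset():
    return sd.default_ko_preset()


@pytest.fixture(scope="session")
def fixture_tree_matrix():
    return sd.presence_matrix_fixture()


@pytest.fixture()
def contrast_libraries():
    def _make(n_reads: int, seed: int, **kwargs):
        specs = sd.library_specs_for_contrast(n_reads=n_reads, seed=seed, **kwargs)
        meta = {s.library_id: LibraryMeta(s.assay, s.condition) for s in specs}
        return specs, meta

    return _make
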