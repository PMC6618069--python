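"""Shared synthetic fixtures: one small genome and its assembly versions."""

import pytest

from chromoforge import synthio


@pytest.fixture(scope="session")
def truth():
    """5-chromosome truth genome, ~150 kb, with 5% interspersed repeats."""
    return synthio.generate_truth_genome(5, (20_000, 40_000), 0.05, seed=42)


@pytest.fixture(scope="session")
def draft_and_map(truth):
    return synthio.fragment_genome(
        truth, 4_000, (50, 300), seed=43, missing_span_range=(0, 1_500)
    )


@pytest.fixture(scope="session")
def scaffolded_and_map(draft_and_map):
    draft, tmap = draft_and_map
    return synthio.scaffold_draft(draft, tmap, join_gap=1000, join_error_rate=0.0, seed=44)


@pytest.fixture(scope="session")
def filled_and_map(truth, scaffolded_and_map):
    scaf, tmap = scaffolded_and_map
    return synthio.fill_gaps_synthetic(scaf, truth, tmap, fill_rate=0.8, seed=45)
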