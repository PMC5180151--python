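import pandas as pd
import pytest

from edna.seqio import tag_lookup_from_design
from edna.synth import StudyDesign, generate_species_pool, simulate_reads


@pytest.fixture(scope="session")
def small_pool():
    """18 metazoan species (8 habitat-A-only, 6 B-only, 4 shared)."""
    return generate_species_pool(8, 6, 4, 0, seed=3)


@pytest.fixture(scope="session")
def noiseless_run(small_pool):
    """Full noiseless simulation + pipeline over the small pool."""
    from edna.pipeline import run_reads_pipeline

    reads, truth = simulate_reads(small_pool, depth_per_replicate=60, seed=3)
    results = run_reads_pipeline(
        reads,
        tag_lookup_from_design(small_pool.design.tag_map),
        small_pool.reference_records(),
        small_pool.design.metadata(),
    )
    return small_pool, reads, truth, results


def make_motu_table(counts: dict, meta_rows: list[tuple]) -> "object":
    """Build a MotuTable from {motu: {sample: count}} plus
    (sample, habitat, site, depth) rows."""
    from edna.ecology import MotuTable

    meta = pd.DataFrame(
        meta_rows, columns=["sample", "habitat", "site", "depth"]
    ).set_index("sample")
    frame = pd.DataFrame(counts).T.reindex(columns=meta.index).fillna(0).astype(int)
    return MotuTable(counts=frame, meta=meta)


@pytest.fixture
def two_habitat_design():
    return StudyDesign().assign_tags(seed=0)
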