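import pandas as pd
import pytest

from evmirna import SimConfig, make_count_matrix, simulate_counts


@pytest.fixture
def tiny_matrix():
    """3 features x 4 samples in 2 groups, hand-written counts."""
    counts = pd.DataFrame(
        {
            "A_1": [10, 0, 5],
            "A_2": [20, 0, 7],
            "B_1": [0, 3, 5],
            "B_2": [0, 9, 6],
        },
        index=pd.Index(["hsa-miR-1-3p", "hsa-miR-2-5p", "hsa-miR-3-5p"], name="miRNA"),
    )
    groups = pd.Series({"A_1": "A", "A_2": "A", "B_1": "B", "B_2": "B"})
    return make_count_matrix(counts, groups)


@pytest.fixture
def four_group_matrix():
    """Simulated default 4-group design, small, deterministic."""
    matrix, truth = simulate_counts(
        SimConfig(n_features=300, de_fraction=0.1, structural_zero_fraction=0.1, seed=42)
    )
    return matrix, truth


@pytest.fixture
def count_file(tmp_path):
    """A small well-formed count file + metadata on disk."""
    counts = tmp_path / "counts.tsv"
    counts.write_text(
        "miRNA\ts1\ts2\n"
        "hsa-miR-21-5p\t10\t20\n"
        "hsa-miR-22-3p\t0\t5\n"
        "hsa-let-7a-5p\t3\t0\n"
    )
    meta = tmp_path / "meta.tsv"
    meta.write_text("sample\tgroup\ns1\tX\ns2\tY\n")
    return counts, meta
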