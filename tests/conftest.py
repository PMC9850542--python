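import numpy as np
import pytest
from hypothesis import settings

from omninorm.data_model import CountMatrix, SampleMetadata

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def small_counts():
    """6 samples x 3 taxa with a planted strong taxon (t1 tracks group)."""
    values = np.array(
        [
            [50, 520, 480],
            [40, 500, 470],
            [60, 510, 460],
            [5, 515, 475],
            [2, 505, 465],
            [8, 495, 485],
        ]
    )
    return CountMatrix(values, [f"s{i}" for i in range(6)], ["t1", "t2", "t3"])


@pytest.fixture
def small_meta():
    return SampleMetadata(
        [f"s{i}" for i in range(6)],
        np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0]),
        outcome_name="group",
    )


@pytest.fixture
def counts_tsv(tmp_path, small_counts):
    path = tmp_path / "counts.tsv"
    import pandas as pd

    pd.DataFrame(
        small_counts.values,
        index=small_counts.sample_ids,
        columns=small_counts.taxon_ids,
    ).to_csv(path, sep="\t", index_label="sample_id")
    return path


@pytest.fixture
def meta_tsv(tmp_path):
    path = tmp_path / "meta.tsv"
    lines = ["sample_id\tgroup\tage"]
    groups = [1, 1, 1, 0, 0, 0]
    ages = [31, 45, 38, 29, 52, 41]
    for i, (g, a) in enumerate(zip(groups, ages)):
        lines.append(f"s{i}\t{g}\t{a}")
    path.write_text("\n".join(lines) + "\n")
    return path
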