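import numpy as np
import pytest

from mtvlmm.data_io import LongitudinalDataset


@pytest.fixture
def toy_dataset():
    """3 taxa, 2 individuals, 2 time points each; closed columns."""
    m_a = np.array([[0.2, 0.5], [0.3, 0.25], [0.5, 0.25]])
    m_b = np.array([[0.1, 0.6], [0.4, 0.2], [0.5, 0.2]])
    return LongitudinalDataset(
        taxa_ids=["t1", "t2", "t3"],
        individuals=["A", "B"],
        matrices={"A": m_a, "B": m_b},
        time_labels={"A": np.array([1.0, 2.0]), "B": np.array([1.0, 2.0])},
    )


@pytest.fixture
def toy_tables(tmp_path):
    """TSV pair matching ``toy_dataset``; returns (abundance, metadata) paths."""
    abundance = tmp_path / "abund.tsv"
    metadata = tmp_path / "meta.tsv"
    abundance.write_text(
        "taxon_id\tA_t1\tA_t2\tB_t1\tB_t2\n"
        "t1\t0.2\t0.5\t0.1\t0.6\n"
        "t2\t0.3\t0.25\t0.4\t0.2\n"
        "t3\t0.5\t0.25\t0.5\t0.2\n"
    )
    metadata.write_text(
        "sample_id\tindividual_id\ttime_index\n"
        "A_t1\tA\t1\nA_t2\tA\t2\nB_t1\tB\t1\nB_t2\tB\t2\n"
    )
    return abundance, metadata


def make_series_dataset(series: dict[str, np.ndarray], m_extra: int = 0,
                        seed: int = 0):
    """Dataset with one focal taxon per given series plus filler taxa."""
    rng = np.random.default_rng(seed)
    individuals = list(series)
    taxa = ["focal"] + [f"x{k}" for k in range(m_extra)]
    matrices, labels = {}, {}
    for ind, y in series.items():
        T = len(y)
        rows = [np.asarray(y, float)]
        for _ in range(m_extra):
            rows.append(rng.uniform(0.0, 1.0, size=T))
        matrices[ind] = np.vstack(rows)
        labels[ind] = np.arange(1.0, T + 1.0)
    return LongitudinalDataset(
        taxa_ids=taxa, individuals=individuals, matrices=matrices,
        time_labels=labels, closed=False,
    )
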