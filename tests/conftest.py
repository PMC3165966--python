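import numpy as np
import pytest

from relrank import Document, TrainRecord


@pytest.fixture
def toy_corpus() -> list[Document]:
    """Six tiny articles sharing a vocabulary (gene/cancer/therapy/flu...)."""
    return [
        Document("d1", "Breast cancer gene study", "BRCA1 gene mutations in breast cancer."),
        Document("d2", "Swine flu outbreak", "Influenza virus surveillance and swine flu cases."),
        Document("d3", "Gene therapy advances", "Novel gene therapy vectors for cancer treatment."),
        Document("d4", "Cancer treatment review", "Chemotherapy and radiation therapy for cancer."),
        Document("d5", "Flu vaccine efficacy", "Seasonal influenza vaccine trial results."),
        Document("d6", "Breast cancer screening", "Mammography screening reduces cancer mortality."),
    ]


def _random_records(rng: np.random.Generator, n: int, d: int, groups: int = 1,
                    levels: int = 3, nonneg: bool = False) -> list[TrainRecord]:
    records = []
    for i in range(n):
        x = rng.random(d) if nonneg else rng.normal(size=d)
        vec = {j: float(v) for j, v in enumerate(x) if abs(v) > 1e-12}
        records.append(
            TrainRecord(
                f"r{i:03d}", vec, f"g{i % groups}",
                int(rng.integers(1, levels + 1)),
            )
        )
    return records


@pytest.fixture
def random_records():
    """Factory for random training records (normal or non-negative features)."""
    return _random_records


@pytest.fixture
def separable_records() -> list[TrainRecord]:
    """2-D records whose levels follow the hidden direction w* = (1, -1) with margin."""
    pts = [
        ((4.0, 0.0), 3), ((3.5, 0.5), 3),
        ((2.0, 1.0), 2), ((1.5, 1.5), 2),
        ((0.0, 2.0), 1), ((0.5, 3.0), 1),
    ]
    return [
        TrainRecord(f"s{i}", {0: x, 1: y}, "q", lvl)
        for i, ((x, y), lvl) in enumerate(pts)
    ]
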