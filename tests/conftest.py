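from __future__ import annotations

import numpy as np
import pytest

from chipdeg.segments import GeneModel
from chipdeg.simulate import SimulationConfig, generate_dataset


def random_gene(rng: np.random.Generator, gene_id: str = "g0", offset: int = 0) -> GeneModel:
    """A random valid gene model for property tests."""
    n_exons = int(rng.integers(1, 6))
    exons = []
    pos = offset + int(rng.integers(2000, 5000))
    for j in range(n_exons):
        exons.append((pos, pos + int(rng.integers(50, 500))))
        pos = exons[-1][1] + int(rng.integers(50, 400))
    start, end = exons[0][0], exons[-1][1]
    has_cds = rng.random() < 0.8
    d1 = int(rng.integers(10, 40))
    d2 = int(rng.integers(10, 40))
    return GeneModel(
        gene_id=gene_id,
        transcript_id=f"{gene_id}.1",
        chromosome="chr1",
        strand="+" if rng.random() < 0.5 else "-",
        exons=tuple(exons),
        cds_start=start + d1 if has_cds else None,
        cds_end=end - d2 if has_cds else None,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_bundle():
    """Shared small synthetic bundle with a strong planted effect."""
    config = SimulationConfig(
        n_genes=150,
        n_chromosomes=2,
        frac_up=0.15,
        frac_down=0.15,
        effect_size=3.0,
        read_depth=10000,
        seed=7,
    )
    return generate_dataset(config)
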