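"""Small shared helpers: chromosome ordering and seeded RNG streams."""
from __future__ import annotations

import numpy as np


def chrom_sort_key(chrom: str):
    """Sort key giving numeric chromosomes ascending, then X, Y, others.

    Chromosome labels are strings ("1", "2", ..., "19", "X"); mapping code
    orders them the way genome browsers do.
    """
    c = str(chrom)
    if c.isdigit():
        return (0, int(c), "")
    special = {"X": 0, "Y": 1, "M": 2, "MT": 2}
    return (1, special.get(c.upper(), 9), c)


def order_chromosomes(chroms) -> list[str]:
    """Unique chromosome labels in canonical genome order."""
    return sorted({str(c) for c in chroms}, key=chrom_sort_key)


def rng_stream(seed: int, stream: int) -> np.random.Generator:
    """Independent, reproducible generator for one simulation stage.

    Seeding with the pair (seed, stream) keeps stages decoupled: changing
    e.g. the number of expression genes never perturbs the genotype draw.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))
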