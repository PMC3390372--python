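import numpy as np
import pandas as pd
import pytest

from rerepseq.core import ReadPlacements, RegionSet, TEAnnotation
from rerepseq.simulate import SimConfig, simulate_genome


@pytest.fixture
def tiny_config():
    """A 2 x 400-kb genome with four small heterochromatin patches."""
    return SimConfig(
        seed=11,
        n_chroms=2,
        chrom_length=400_000,
        n_patches=4,
        patch_size_range=(20_000, 40_000),
        min_patch_gap=50_000,
        mean_coverage=40.0,
    )


@pytest.fixture
def tiny_genome(tiny_config):
    return simulate_genome(tiny_config)


@pytest.fixture
def simple_regions():
    return RegionSet.from_tuples(
        [("chr1", 100, 200), ("chr1", 500, 900), ("chr2", 0, 300)],
        label="test",
    )


@pytest.fixture
def simple_tes():
    return TEAnnotation(
        pd.DataFrame(
            {
                "te_id": ["TE1", "TE2", "TE3", "TE4"],
                "chrom": ["chr1", "chr1", "chr1", "chr2"],
                "start": [100, 1000, 2000, 50],
                "end": [200, 1500, 2100, 1050],
                "superfamily": [
                    "LTR/Gypsy",
                    "LTR/Gypsy",
                    "LTR/Copia",
                    "LINE/L1",
                ],
                "strand": ["+", "-", "+", "+"],
            }
        )
    )


def placements(sample_id, rows):
    """rows: iterable of (chrom, pos5, strand)."""
    chrom, pos, strand = zip(*rows) if rows else ((), (), ())
    return ReadPlacements.from_arrays(
        sample_id,
        np.array(chrom, dtype=object),
        np.array(pos, dtype=np.int64),
        np.array(strand, dtype=object),
    )
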