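import numpy as np
import pandas as pd
import pytest

from bivalos import (
    GeneRecord,
    GenomeModel,
    assign_promoter_states,
    generate_genome_annotation,
)


@pytest.fixture(scope="session")
def small_genome() -> GenomeModel:
    """100 genes on a 3 Mb chromosome (deterministic)."""
    return generate_genome_annotation(100, 3_000_000, seed=1)


@pytest.fixture(scope="session")
def small_truth(small_genome):
    return assign_promoter_states(small_genome, coupling=0.8, specific_gene_fraction=0.06, seed=2)


@pytest.fixture()
def toy_genome() -> GenomeModel:
    """Hand-built two-gene genome for exact-window assertions."""
    return GenomeModel(
        chrom_sizes={"chr1": 1_000_000},
        genes=[
            GeneRecord("plus_gene", "chr1", 100_000, 105_000, "+"),
            GeneRecord("minus_gene", "chr1", 300_000, 305_000, "-"),
        ],
    )


def fragments_frame(rows):
    """rows: (chrom, start, end, mapq[, duplicate])."""
    recs = [(r + (False,))[:5] for r in rows]
    df = pd.DataFrame(recs, columns=["chrom", "start", "end", "mapq", "duplicate"])
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    df["mapq"] = df["mapq"].astype(np.int64)
    df["duplicate"] = df["duplicate"].astype(bool)
    return df


def peak_frame(rows):
    """rows: (chrom, start, end, score)."""
    return pd.DataFrame(
        {
            "chrom": [r[0] for r in rows],
            "start": [r[1] for r in rows],
            "end": [r[2] for r in rows],
            "name": [f"p{i}" for i in range(len(rows))],
            "score": [float(r[3]) if len(r) > 3 else 0.0 for r in rows],
            "strand": ".",
            "signal": 0.0,
            "pvalue": -1.0,
            "qvalue": -1.0,
            "summit": -1,
        }
    )
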