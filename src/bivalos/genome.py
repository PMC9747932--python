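"""Genome annotation model: chromosome sizes, gene records, TSS and promoter windows.

Coordinates are 0-based half-open (BED convention) throughout the package.
For a + strand gene the TSS is ``start``; for a − strand gene it is ``end``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

import pandas as pd

__all__ = ["GeneRecord", "GenomeModel", "promoter_window", "read_genes_bed", "write_genes_bed"]


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene on a 0-based half-open interval."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str  # "+" or "-"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"gene {self.gene_id}: start ({self.start}) must be < end ({self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end


@dataclass
class GenomeModel:
    """Chromosome sizes plus an ordered gene annotation.

    Invariants (checked on construction): gene IDs unique, every gene lies
    within the bounds of a known chromosome.
    """

    chrom_sizes: dict[str, int]
    genes: list[GeneRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene ID: {g.gene_id}")
            seen.add(g.gene_id)
            if g.chrom not in self.chrom_sizes:
                raise ValueError(f"gene {g.gene_id} on unknown chromosome {g.chrom}")
            if g.end > self.chrom_sizes[g.chrom]:
                raise ValueError(
                    f"gene {g.gene_id} extends past end of {g.chrom} "
                    f"({g.end} > {self.chrom_sizes[g.chrom]})"
                )

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def gene(self, gene_id: str) -> GeneRecord:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def to_frame(self) -> pd.DataFrame:
        """Genes as a DataFrame indexed by gene_id with a ``tss`` column."""
        df = pd.DataFrame(
            {
                "chrom": [g.chrom for g in self.genes],
                "start": [g.start for g in self.genes],
                "end": [g.end for g in self.genes],
                "strand": [g.strand for g in self.genes],
                "tss": [g.tss for g in self.genes],
            },
            index=pd.Index(self.gene_ids, name="gene_id"),
        )
        return df

    def promoter_windows(self, upstream: int = 2000, downstream: int = 1000) -> pd.DataFrame:
        """Strand-aware promoter windows around every TSS, clipped to chromosome.

        Default window spans 2 kb upstream to 1 kb downstream of the TSS.
        """
        rows = []
        for g in self.genes:
            s, e = promoter_window(g, upstream, downstream, self.chrom_sizes[g.chrom])
            rows.append((g.chrom, s, e, g.strand))
        return pd.DataFrame(
            rows,
            columns=["chrom", "start", "end", "strand"],
            index=pd.Index(self.gene_ids, name="gene_id"),
        )


def promoter_window(
    gene: GeneRecord,
    upstream: int = 2000,
    downstream: int = 1000,
    chrom_length: Union[int, None] = None,
) -> tuple[int, int]:
    """Promoter interval around the TSS, strand-aware, clipped to [0, chrom_length).

    + strand: [TSS − upstream, TSS + downstream); − strand mirrored so that
    "upstream" always means 5′ of the gene.
    """
    if gene.strand == "+":
        s, e = gene.tss - upstream, gene.tss + downstream
    else:
        s, e = gene.tss - downstream, gene.tss + upstream
    s = max(0, s)
    if chrom_length is not None:
        e = min(e, chrom_length)
    return s, e


def read_genes_bed(path: Union[str, Path], chrom_sizes: Union[dict[str, int], None] = None) -> GenomeModel:
    """Read a BED6 gene annotation into a GenomeModel.

    If ``chrom_sizes`` is omitted, each chromosome's size is taken as the
    maximum gene end observed (adequate for round-tripping synthetic data).
    """
    genes: list[GeneRecord] = []
    maxima: dict[str, int] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{i}: BED6 line has {len(parts)} fields")
            chrom, start, end, name, _score, strand = parts[:6]
            genes.append(GeneRecord(name, chrom, int(start), int(end), strand))
            maxima[chrom] = max(maxima.get(chrom, 0), int(end))
    sizes = dict(chrom_sizes) if chrom_sizes is not None else maxima
    return GenomeModel(chrom_sizes=sizes, genes=genes)


def write_genes_bed(genome: GenomeModel, path: Union[str, Path, io.TextIOBase]) -> None:
    """Write genes as BED6 (score column carries 0)."""

    def _emit(fh: Iterable) -> None:
        for g in genome.genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")

    if isinstance(path, io.TextIOBase):
        _emit(path)
    else:
        with open(path, "w") as fh:
            _emit(fh)
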