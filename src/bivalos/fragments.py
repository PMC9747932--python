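"""Paired-end fragment ingestion and retention filters.

Fragments live in pandas DataFrames with columns ``chrom, start, end, mapq,
duplicate`` (0-based half-open; insert size = end − start). The retention
rules are the standard CUT&RUN ones: keep uniquely-mapped fragments
(MAPQ ≥ 20), remove coordinate duplicates keeping the best-mapped copy, and
keep inserts between 150 and 500 bp inclusive — the mono-/di-nucleosome
range targeted by MNase cleavage.

Also here: the INTACT cell-counting QC (specificity and yield from
DAPI+/GFP+ hemocytometer counts).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FRAGMENT_COLUMNS",
    "QCReport",
    "read_fragments",
    "write_fragments_bedpe",
    "filter_mapq",
    "deduplicate",
    "filter_insert_size",
    "apply_retention_filters",
    "intact_specificity_yield",
]

FRAGMENT_COLUMNS = ["chrom", "start", "end", "mapq", "duplicate"]

#: read length used when a fragment is re-serialized as a BEDPE mate pair
_BEDPE_READ_LEN = 36


def _empty_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=str),
            "start": pd.Series(dtype=np.int64),
            "end": pd.Series(dtype=np.int64),
            "mapq": pd.Series(dtype=np.int64),
            "duplicate": pd.Series(dtype=bool),
        }
    )


def _as_fragment_frame(rows: list[tuple]) -> pd.DataFrame:
    if not rows:
        return _empty_frame()
    df = pd.DataFrame(rows, columns=FRAGMENT_COLUMNS)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    df["mapq"] = df["mapq"].astype(np.int64)
    df["duplicate"] = df["duplicate"].astype(bool)
    return df


def read_fragments(path: Union[str, Path], fmt: Optional[str] = None) -> pd.DataFrame:
    """Read aligned paired-end fragments from BEDPE, BED, or BAM/SAM.

    BEDPE: the fragment spans min(start1, start2) to max(end1, end2); column
    8 (the BEDPE score slot) is interpreted as MAPQ. BED: columns 1–3 give
    the fragment, column 5 (score) the MAPQ if present. BAM/SAM: properly
    paired reads only; the fragment spans the leftmost mate start to the
    rightmost mate end, and unpaired reads are dropped with a warning.

    Malformed lines (including end ≤ start) are skipped and logged with
    their line number.

    Parameters
    ----------
    fmt
        One of ``"bedpe"``, ``"bed"``, ``"bam"``; inferred from the file
        suffix when omitted.
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = {".bedpe": "bedpe", ".bed": "bed", ".bam": "bam", ".sam": "bam"}.get(suffix)
        if fmt is None:
            raise ValueError(f"cannot infer fragment format from suffix {suffix!r}; pass fmt=")
    fmt = fmt.lower()
    if fmt == "bedpe":
        return _read_bedpe(path)
    if fmt == "bed":
        return _read_bed(path)
    if fmt == "bam":
        return _read_bam(path)
    raise ValueError(f"unknown fragment format: {fmt!r}")


def _read_bedpe(path: Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                logger.warning("%s:%d: BEDPE line has %d fields, skipped", path, i, len(parts))
                continue
            try:
                c1, s1, e1, c2, s2, e2 = parts[0], int(parts[1]), int(parts[2]), parts[3], int(parts[4]), int(parts[5])
            except ValueError:
                logger.warning("%s:%d: unparseable coordinates, skipped", path, i)
                continue
            if e1 <= s1 or e2 <= s2:
                logger.warning("%s:%d: end <= start, skipped", path, i)
                continue
            if c1 != c2:
                logger.warning("%s:%d: inter-chromosomal pair, skipped", path, i)
                continue
            mapq = int(parts[7]) if len(parts) > 7 and parts[7] not in (".", "") else 0
            rows.append((c1, min(s1, s2), max(e1, e2), mapq, False))
    return _as_fragment_frame(rows)


def _read_bed(path: Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                logger.warning("%s:%d: BED line has %d fields, skipped", path, i, len(parts))
                continue
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            except ValueError:
                logger.warning("%s:%d: unparseable coordinates, skipped", path, i)
                continue
            if end <= start:
                logger.warning("%s:%d: end <= start, skipped", path, i)
                continue
            mapq = int(float(parts[4])) if len(parts) > 4 and parts[4] not in (".", "") else 0
            rows.append((chrom, start, end, mapq, False))
    return _as_fragment_frame(rows)


def _read_bam(path: Path) -> pd.DataFrame:
    import pysam

    mode = "r" if path.suffix.lower() == ".sam" else "rb"
    rows = []
    n_unpaired = 0
    with pysam.AlignmentFile(str(path), mode) as bam:
        for read in bam.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if not read.is_paired or not read.is_proper_pair:
                n_unpaired += 1
                continue
            # one fragment per pair: emit from the leftmost mate only
            if read.is_reverse and read.reference_start >= read.next_reference_start:
                continue
            if not read.is_reverse and read.template_length <= 0:
                continue
            start = read.reference_start
            end = start + abs(read.template_length)
            if end <= start:
                continue
            rows.append(
                (read.reference_name, start, end, int(read.mapping_quality), bool(read.is_duplicate))
            )
    if n_unpaired:
        warnings.warn(f"{path}: dropped {n_unpaired} unpaired/improper reads", stacklevel=2)
    return _as_fragment_frame(rows)


def write_fragments_bedpe(frags: pd.DataFrame, path: Union[str, Path], name_prefix: str = "frag") -> None:
    """Serialize fragments as 10-column BEDPE.

    Each fragment is written as a synthetic mate pair: mate 1 at the 5′ end,
    mate 2 at the 3′ end, so [min start, max end) reconstructs the fragment.
    """
    with open(path, "w") as fh:
        for i, row in enumerate(frags.itertuples(index=False)):
            s, e = int(row.start), int(row.end)
            rlen = min(_BEDPE_READ_LEN, e - s)
            fh.write(
                f"{row.chrom}\t{s}\t{s + rlen}\t{row.chrom}\t{e - rlen}\t{e}\t"
                f"{name_prefix}{i}\t{int(row.mapq)}\t+\t-\n"
            )


def filter_mapq(frags: pd.DataFrame, min_mapq: int = 20) -> pd.DataFrame:
    """Keep fragments with MAPQ ≥ ``min_mapq`` (default 20, i.e. unique mappers)."""
    out = frags[frags["mapq"] >= min_mapq]
    logger.info("filter_mapq(>=%d): %d -> %d", min_mapq, len(frags), len(out))
    return out.reset_index(drop=True)


def deduplicate(frags: pd.DataFrame) -> pd.DataFrame:
    """Keep one fragment per identical (chrom, start, end) coordinate key.

    The retained representative is the highest-MAPQ copy; ties keep the first
    in input order. Operates per sample — callers handling multiple libraries
    should deduplicate each separately.
    """
    if len(frags) == 0:
        return frags.reset_index(drop=True)
    work = frags.reset_index(drop=True)
    keep = work.groupby(["chrom", "start", "end"], sort=False)["mapq"].idxmax()
    out = work.loc[sorted(keep)]
    logger.info("deduplicate: %d -> %d", len(frags), len(out))
    return out.reset_index(drop=True)


def filter_insert_size(frags: pd.DataFrame, min_len: int = 150, max_len: int = 500) -> pd.DataFrame:
    """Keep fragments with min_len ≤ insert size ≤ max_len (both ends inclusive)."""
    if min_len > max_len:
        raise ValueError(f"min_len ({min_len}) > max_len ({max_len})")
    size = frags["end"] - frags["start"]
    out = frags[(size >= min_len) & (size <= max_len)]
    logger.info("filter_insert_size([%d,%d]): %d -> %d", min_len, max_len, len(frags), len(out))
    return out.reset_index(drop=True)


def apply_retention_filters(
    frags: pd.DataFrame,
    min_mapq: int = 20,
    min_len: int = 150,
    max_len: int = 500,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """MAPQ filter → deduplication → insert-size filter, with stage counts.

    Returns the surviving fragments and a dict of fragment counts after each
    stage (keys ``input, mapq, dedup, size``), for QC bookkeeping.
    """
    counts = {"input": len(frags)}
    frags = filter_mapq(frags, min_mapq)
    counts["mapq"] = len(frags)
    frags = deduplicate(frags)
    counts["dedup"] = len(frags)
    frags = filter_insert_size(frags, min_len, max_len)
    counts["size"] = len(frags)
    return frags, counts


@dataclass
class QCReport:
    """INTACT cell-counting QC: specificity and yield in percent.

    specificity = GFP+/(GFP+ + GFP−) × aliquot scale;
    yield = bead-bound GFP+ / isolation GFP+ × aliquot scale. The aliquot
    scale corrects for counting a sub-aliquot and is applied verbatim, so
    values above 100% are possible and are reported as computed.
    """

    specificity_pct: Optional[float]
    yield_pct: Optional[float]
    aliquot_scale: float
    stage_counts: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "specificity_pct": self.specificity_pct,
            "yield_pct": self.yield_pct,
            "aliquot_scale": self.aliquot_scale,
            "stage_counts": dict(self.stage_counts),
        }


def intact_specificity_yield(
    gfp_pos: Optional[int] = None,
    gfp_neg: Optional[int] = None,
    bead_bound_gfp_pos: Optional[int] = None,
    isolation_gfp_pos: Optional[int] = None,
    aliquot_scale: float = 1.0,
) -> QCReport:
    """Specificity and yield of an INTACT nuclei isolation, as percentages.

    Either metric may be computed alone by passing only its counts. Zero
    denominators raise; negative counts raise.
    """
    for name, v in (
        ("gfp_pos", gfp_pos),
        ("gfp_neg", gfp_neg),
        ("bead_bound_gfp_pos", bead_bound_gfp_pos),
        ("isolation_gfp_pos", isolation_gfp_pos),
    ):
        if v is not None and v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")

    specificity = None
    if gfp_pos is not None and gfp_neg is not None:
        denom = gfp_pos + gfp_neg
        if denom == 0:
            raise ZeroDivisionError("specificity undefined: GFP+ + GFP- is zero")
        specificity = 100.0 * gfp_pos / denom * aliquot_scale

    yld = None
    if bead_bound_gfp_pos is not None and isolation_gfp_pos is not None:
        if isolation_gfp_pos == 0:
            raise ZeroDivisionError("yield undefined: isolation GFP+ count is zero")
        yld = 100.0 * bead_bound_gfp_pos / isolation_gfp_pos * aliquot_scale

    return QCReport(specificity_pct=specificity, yield_pct=yld, aliquot_scale=aliquot_scale)
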