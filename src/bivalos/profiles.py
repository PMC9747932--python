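"""Signal matrices around anchors and expression-stratified metaprofiles.

Two matrix modes mirror the two standard ways of summarizing coverage:
``reference-point`` (fixed ±flank around a TSS or peak center) and
``scale-regions`` (region bodies linearly rescaled to a common bin count,
plus fixed flanks). Rows of strand-oriented matrices are reversed for −
strand anchors so column 0 is always 5′. Signal is integrated exactly over
the piecewise-constant coverage track, and flank positions off the end of a
chromosome are missing (NaN), not zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .coverage import CoverageTrack

logger = logging.getLogger(__name__)

__all__ = [
    "SignalMatrix",
    "tss_anchors",
    "peak_center_anchors",
    "reference_point_matrix",
    "scale_regions_matrix",
    "stratify_by_expression",
    "metaprofile",
    "plot_metaprofile",
]

EXPRESSION_STRATA = ("high", "medium", "low")


@dataclass
class SignalMatrix:
    """anchors × bins signal matrix.

    ``values`` rows follow ``anchor_ids``; NaN marks positions off the
    chromosome. For strand-oriented matrices, − strand rows are reversed at
    construction so columns read 5′→3′.
    """

    anchor_ids: list[str]
    values: np.ndarray
    bin_size: int
    mode: str  # "reference-point" | "scale-regions"
    strand_oriented: bool = True

    def __post_init__(self) -> None:
        if self.values.shape[0] != len(self.anchor_ids):
            raise ValueError("row count must equal anchor count")
        if np.nanmin(self.values, initial=0.0) < 0:
            raise ValueError("negative signal values")

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.anchor_ids, name="anchor"))


def tss_anchors(genome) -> pd.DataFrame:
    """TSS anchor table (chrom, pos, strand) indexed by gene ID."""
    df = genome.to_frame()
    return pd.DataFrame(
        {"chrom": df["chrom"], "pos": df["tss"], "strand": df["strand"]}, index=df.index
    )


def peak_center_anchors(peaks) -> pd.DataFrame:
    """Peak-center anchor table from a PeakSet (unstranded)."""
    df = peaks.peaks
    return pd.DataFrame(
        {
            "chrom": df["chrom"].to_numpy(),
            "pos": ((df["start"] + df["end"]) // 2).to_numpy(),
            "strand": ".",
        },
        index=pd.Index(df["name"].astype(str), name="anchor"),
    )


def _integral(values: np.ndarray, bin_size: int):
    """Cumulative integral of a piecewise-constant track; evaluate at bp x."""
    cum = np.concatenate([[0.0], np.cumsum(values) * bin_size])
    n = len(values)

    def at(x: np.ndarray) -> np.ndarray:
        x = np.clip(x, 0, n * bin_size)
        k = np.minimum((x // bin_size).astype(int), n - 1)
        return cum[k] + values[k] * (x - k * bin_size)

    return at


def reference_point_matrix(
    track: CoverageTrack,
    anchors: pd.DataFrame,
    flank: int = 5000,
    bin: int = 50,
    strand_oriented: bool = True,
) -> SignalMatrix:
    """Mean signal in ``bin``-bp bins across [pos − flank, pos + flank).

    ``anchors`` needs columns chrom/pos/strand (see :func:`tss_anchors`).
    Anchors on unknown chromosomes yield all-NaN rows and are logged.
    """
    if flank <= 0 or bin <= 0 or flank % bin != 0:
        raise ValueError("flank must be a positive multiple of bin")
    n_bins = 2 * flank // bin
    out = np.full((len(anchors), n_bins), np.nan)
    integrals = {c: _integral(v, track.bin_size) for c, v in track.values.items()}
    edges_rel = np.arange(n_bins + 1) * bin - flank
    n_off = 0
    for i, row in enumerate(anchors.itertuples(index=False)):
        I = integrals.get(row.chrom)
        if I is None:
            n_off += 1
            continue
        L = track.chrom_sizes[row.chrom]
        edges = row.pos + edges_rel
        vals = np.diff(I(edges.astype(float))) / bin
        # positions fully off-chromosome are missing, not zero
        starts, ends = edges[:-1], edges[1:]
        vals[(ends <= 0) | (starts >= L)] = np.nan
        if strand_oriented and row.strand == "-":
            vals = vals[::-1]
        out[i] = vals
    if n_off:
        logger.warning("reference_point_matrix: %d anchors on unknown chromosomes", n_off)
    return SignalMatrix(
        anchor_ids=list(anchors.index.astype(str)),
        values=out,
        bin_size=bin,
        mode="reference-point",
        strand_oriented=strand_oriented,
    )


def scale_regions_matrix(
    track: CoverageTrack,
    regions: pd.DataFrame,
    flank: int = 5000,
    body_bins: int = 100,
    bin: int = 50,
    strand_oriented: bool = True,
) -> SignalMatrix:
    """Flank–body–flank matrix with region bodies rescaled to ``body_bins``.

    ``regions`` needs columns chrom/start/end (strand optional). Bodies
    shorter than one body bin are stretched (nearest-neighbor over the
    piecewise-constant track) with a warning.
    """
    if len(regions) == 0:
        raise ValueError("scale_regions_matrix: no regions")
    if flank % bin != 0:
        raise ValueError("flank must be a multiple of bin")
    n_flank = flank // bin
    n_bins = 2 * n_flank + body_bins
    out = np.full((len(regions), n_bins), np.nan)
    integrals = {c: _integral(v, track.bin_size) for c, v in track.values.items()}
    has_strand = "strand" in regions.columns
    n_short = 0
    for i, row in enumerate(regions.itertuples(index=False)):
        I = integrals.get(row.chrom)
        if I is None:
            continue
        L = track.chrom_sizes[row.chrom]
        s, e = int(row.start), int(row.end)
        if e - s < body_bins:
            n_short += 1
        up_edges = s + np.arange(-n_flank, 1) * bin
        dn_edges = e + np.arange(0, n_flank + 1) * bin
        body_edges = s + (e - s) * np.arange(body_bins + 1) / body_bins
        up = np.diff(I(up_edges.astype(float))) / bin
        up[(up_edges[1:] <= 0) | (up_edges[:-1] >= L)] = np.nan
        dn = np.diff(I(dn_edges.astype(float))) / bin
        dn[(dn_edges[1:] <= 0) | (dn_edges[:-1] >= L)] = np.nan
        body = np.diff(I(body_edges)) / np.diff(body_edges)
        vals = np.concatenate([up, body, dn])
        if strand_oriented and has_strand and row.strand == "-":
            vals = vals[::-1]
        out[i] = vals
    if n_short:
        logger.warning("scale_regions_matrix: %d regions shorter than body_bins; stretched", n_short)
    return SignalMatrix(
        anchor_ids=list(regions.index.astype(str)),
        values=out,
        bin_size=bin,
        mode="scale-regions",
        strand_oriented=strand_oriented,
    )


def stratify_by_expression(fpkm: pd.Series) -> pd.Series:
    """Three expression strata: high (FPKM ≥ 10), medium (1 ≤ FPKM < 10), low (< 1)."""
    v = fpkm.astype(float)
    if (v < 0).any():
        bad = v.index[v < 0][0]
        raise ValueError(f"negative FPKM for gene {bad}")
    out = pd.Series("low", index=v.index, dtype=object, name="stratum")
    out[v >= 1] = "medium"
    out[v >= 10] = "high"
    return out


def metaprofile(
    matrix: SignalMatrix,
    groups: Optional[pd.Series] = None,
    n_boot: int = 1000,
    seed: int = 0,
    ci: float = 0.95,
) -> pd.DataFrame:
    """Per-group column means with a bootstrap confidence band.

    ``groups`` maps anchor ID → group label (must cover the anchors; missing
    anchors form no group). Returns a tidy frame with columns
    group, bin, mean, lo, hi. Empty groups are excluded with a warning.
    With ``n_boot=0`` the band columns equal the mean.
    """
    ids = pd.Index(matrix.anchor_ids)
    if groups is None:
        groups = pd.Series("all", index=ids)
    rng = np.random.default_rng(seed)
    alpha = (1 - ci) / 2
    rows = []
    for label in pd.unique(groups):
        members = np.flatnonzero(ids.isin(groups.index[groups == label]))
        if len(members) == 0:
            logger.warning("metaprofile: group %r has no anchors; excluded", label)
            continue
        sub = matrix.values[members]
        mean = np.nanmean(sub, axis=0)
        if n_boot > 0:
            boots = np.empty((n_boot, matrix.n_bins))
            for b in range(n_boot):
                take = rng.integers(0, len(members), size=len(members))
                boots[b] = np.nanmean(sub[take], axis=0)
            lo = np.nanquantile(boots, alpha, axis=0)
            hi = np.nanquantile(boots, 1 - alpha, axis=0)
        else:
            lo = hi = mean
        for j in range(matrix.n_bins):
            rows.append((label, j, mean[j], lo[j], hi[j]))
    return pd.DataFrame(rows, columns=["group", "bin", "mean", "lo", "hi"])


def plot_metaprofile(profile: pd.DataFrame, ax=None, title: Optional[str] = None):
    """Line plot of group metaprofiles with their bootstrap bands."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    for label, sub in profile.groupby("group", sort=False):
        ax.plot(sub["bin"], sub["mean"], label=str(label))
        ax.fill_between(sub["bin"], sub["lo"], sub["hi"], alpha=0.2)
    ax.set_xlabel("bin")
    ax.set_ylabel("mean signal")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    return ax
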