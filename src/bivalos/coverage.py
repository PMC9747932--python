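"""Binned coverage tracks, CPM normalization, replicate correlation, and
invariant-gene quantile anchoring across samples.

A :class:`CoverageTrack` holds per-chromosome vectors of per-bin values.
Normalization state moves strictly raw → CPM → quantile-anchored. CPM
divides by the total fragment count; quantile anchoring maps each sample's
signal distribution onto a shared reference built from promoter signal at
transcriptionally constant genes — genes whose expression is equal between
cell types, where signal is assumed equal — which removes global
efficiency/depth distortions that depth normalization alone cannot see.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .genome import GenomeModel

logger = logging.getLogger(__name__)

__all__ = [
    "CoverageTrack",
    "ConstantGeneSet",
    "bin_coverage",
    "cpm_normalize",
    "correlation_matrix",
    "select_constant_genes",
    "promoter_signal",
    "quantile_anchor",
    "write_bedgraph",
]

_STATE_ORDER = ("raw", "CPM", "quantile-anchored")


@dataclass
class CoverageTrack:
    """Per-bin signal for one sample on a fixed bin grid.

    ``values`` maps chromosome → vector of length ceil(chrom_len/bin_size).
    ``n_fragments`` is the total input fragment count (CPM denominator).
    """

    bin_size: int
    values: dict[str, np.ndarray]
    chrom_sizes: dict[str, int]
    state: str = "raw"
    sample: Optional[tuple] = None
    n_fragments: int = 0

    def __post_init__(self) -> None:
        if self.state not in _STATE_ORDER:
            raise ValueError(f"unknown normalization state {self.state!r}")
        for chrom, v in self.values.items():
            expected = math.ceil(self.chrom_sizes[chrom] / self.bin_size)
            if len(v) != expected:
                raise ValueError(
                    f"{chrom}: {len(v)} bins, expected ceil({self.chrom_sizes[chrom]}/{self.bin_size}) = {expected}"
                )
            if (v < 0).any():
                raise ValueError(f"{chrom}: negative coverage values")

    def concat(self) -> np.ndarray:
        """All bins as one vector, chromosomes in sorted order."""
        return np.concatenate([self.values[c] for c in sorted(self.values)])

    @property
    def total(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))

    def same_grid(self, other: "CoverageTrack") -> bool:
        return (
            self.bin_size == other.bin_size
            and self.chrom_sizes == other.chrom_sizes
            and set(self.values) == set(other.values)
        )


@dataclass
class ConstantGeneSet:
    """Transcriptionally constant genes used as normalization anchors."""

    gene_ids: list[str]
    max_abs_log2fc: float
    min_fpkm: float

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError("constant gene set is empty")

    def __len__(self) -> int:
        return len(self.gene_ids)


def bin_coverage(
    frags: pd.DataFrame,
    genome: GenomeModel,
    bin_size: int = 1000,
    sample: Optional[tuple] = None,
) -> CoverageTrack:
    """Count fragments per fixed-width bin, assigning each to its midpoint bin.

    Midpoint assignment keeps counts integral and conserves totals.
    Fragments on chromosomes absent from the genome are skipped and logged.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    values = {
        c: np.zeros(math.ceil(L / bin_size), dtype=float) for c, L in genome.chrom_sizes.items()
    }
    n_skipped = 0
    if len(frags):
        mid = ((frags["start"].to_numpy() + frags["end"].to_numpy()) // 2).astype(np.int64)
        for chrom, idx in frags.groupby("chrom", sort=False).indices.items():
            if chrom not in values:
                n_skipped += len(idx)
                continue
            bins = np.clip(mid[idx] // bin_size, 0, len(values[chrom]) - 1)
            np.add.at(values[chrom], bins, 1.0)
    if n_skipped:
        logger.warning("bin_coverage: skipped %d fragments on unknown chromosomes", n_skipped)
    return CoverageTrack(
        bin_size=bin_size,
        values=values,
        chrom_sizes=dict(genome.chrom_sizes),
        state="raw",
        sample=sample,
        n_fragments=len(frags),
    )


def cpm_normalize(track: CoverageTrack) -> CoverageTrack:
    """Counts-per-million: value × 1e6 / total input fragment count."""
    if track.state != "raw":
        raise ValueError(f"cpm_normalize expects a raw track, got state={track.state!r}")
    if track.n_fragments == 0:
        raise ZeroDivisionError("CPM undefined: track has zero input fragments")
    scale = 1e6 / track.n_fragments
    return replace(track, values={c: v * scale for c, v in track.values.items()}, state="CPM")


def correlation_matrix(
    tracks: Sequence[CoverageTrack],
    skip_zeros: bool = True,
    labels: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Pairwise Pearson correlation of per-bin signal across samples.

    ``skip_zeros`` drops bins that are zero in every track (the deepTools
    ``--skipZeros`` convention). All tracks must share the bin grid.
    """
    if len(tracks) < 2:
        raise ValueError("correlation_matrix needs at least 2 tracks")
    first = tracks[0]
    for t in tracks[1:]:
        if not first.same_grid(t):
            raise ValueError("all tracks must share the same bin grid")
    mat = np.vstack([t.concat() for t in tracks])
    if skip_zeros:
        keep = (mat != 0).any(axis=0)
        mat = mat[:, keep]
    if mat.shape[1] < 2:
        raise ValueError("not enough non-zero bins to correlate")
    r = np.corrcoef(mat)
    if labels is None:
        labels = [str(t.sample) if t.sample is not None else f"track{i}" for i, t in enumerate(tracks)]
    return pd.DataFrame(r, index=list(labels), columns=list(labels))


def select_constant_genes(
    expr_a: pd.Series,
    expr_b: pd.Series,
    max_abs_log2fc: float = 0.25,
    min_fpkm: float = 1.0,
) -> ConstantGeneSet:
    """Genes expressed (FPKM ≥ min_fpkm) in both cell types with |log2FC| ≤ threshold."""
    shared = expr_a.index.intersection(expr_b.index)
    a = expr_a.loc[shared].astype(float)
    b = expr_b.loc[shared].astype(float)
    expressed = (a >= min_fpkm) & (b >= min_fpkm)
    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.log2(a.where(a > 0)) - np.log2(b.where(b > 0))
    keep = expressed & (lfc.abs() <= max_abs_log2fc)
    ids = list(shared[keep])
    if not ids:
        raise ValueError(
            "no transcriptionally constant genes at "
            f"|log2FC| <= {max_abs_log2fc}, FPKM >= {min_fpkm}; "
            "loosen max_abs_log2fc or lower min_fpkm"
        )
    return ConstantGeneSet(gene_ids=ids, max_abs_log2fc=max_abs_log2fc, min_fpkm=min_fpkm)


def promoter_signal(
    track: CoverageTrack,
    genome: GenomeModel,
    gene_ids: Optional[Sequence[str]] = None,
    upstream: int = 2000,
    downstream: int = 1000,
) -> pd.Series:
    """Mean per-bin signal over each gene's promoter window.

    The window (default −2 kb/+1 kb around the TSS, strand-aware) is averaged
    over the track bins it overlaps, weighted by overlap length.
    """
    windows = genome.promoter_windows(upstream, downstream)
    if gene_ids is not None:
        windows = windows.loc[list(gene_ids)]
    out = np.empty(len(windows))
    B = track.bin_size
    for i, (gid, row) in enumerate(windows.iterrows()):
        v = track.values.get(row["chrom"])
        if v is None:
            out[i] = np.nan
            continue
        s, e = int(row["start"]), int(row["end"])
        out[i] = _window_mean(v, B, s, e)
    return pd.Series(out, index=windows.index, name="promoter_signal")


def _window_mean(values: np.ndarray, bin_size: int, start: int, end: int) -> float:
    """Length-weighted mean of a piecewise-constant track over [start, end)."""
    if end <= start:
        return np.nan
    b0, b1 = start // bin_size, (end - 1) // bin_size
    b1 = min(b1, len(values) - 1)
    b0 = min(b0, len(values) - 1)
    if b0 == b1:
        return float(values[b0])
    total = 0.0
    # first and last bins contribute fractionally
    total += values[b0] * ((b0 + 1) * bin_size - start)
    total += values[b1] * (end - b1 * bin_size)
    if b1 - b0 > 1:
        total += values[b0 + 1 : b1].sum() * bin_size
    return float(total / (end - start))


def quantile_anchor(
    tracks: Sequence[CoverageTrack],
    genome: GenomeModel,
    constant_genes: ConstantGeneSet,
    upstream: int = 2000,
    downstream: int = 1000,
    min_genes: int = 10,
) -> list[CoverageTrack]:
    """Anchor samples to a shared reference via constant-gene promoter quantiles.

    For each CPM track, the per-bin signal inside the constant-gene promoter
    windows is collected; the cross-sample reference is the mean of the
    sorted signal vectors (classical quantile normalization). Each sample
    then gets a monotone piecewise-linear map from its own constant-gene
    signal quantiles to the reference, extended linearly beyond the observed
    range, applied to every bin genome-wide. After anchoring, constant-gene
    promoter-signal quantiles agree across samples (exactly at the knots,
    up to tie-averaging), the map preserves within-sample ranks, and
    re-anchoring is a no-op.
    """
    if len(constant_genes) < min_genes:
        raise ValueError(
            f"need >= {min_genes} constant genes for anchoring, got {len(constant_genes)}"
        )
    for t in tracks:
        if t.state != "CPM":
            raise ValueError(
                f"quantile_anchor expects CPM tracks (sample {t.sample}, state={t.state!r})"
            )

    windows = genome.promoter_windows(upstream, downstream).loc[list(constant_genes.gene_ids)]
    sorted_signals = []
    for t in tracks:
        sig = _window_bin_values(t, windows)
        if len(sig) < min_genes:
            raise ValueError(f"sample {t.sample}: fewer than {min_genes} usable anchor bins")
        if np.ptp(sig) == 0:
            raise ValueError(f"sample {t.sample}: constant-gene signal is degenerate (no spread)")
        sorted_signals.append(np.sort(sig))

    n_ref = min(len(s) for s in sorted_signals)
    if any(len(s) != n_ref for s in sorted_signals):
        grid = np.linspace(0, 1, n_ref)
        sorted_signals = [np.interp(grid, np.linspace(0, 1, len(s)), s) for s in sorted_signals]
    reference = np.mean(sorted_signals, axis=0)

    out = []
    for t, knots_x in zip(tracks, sorted_signals):
        x, y = _monotone_knots(knots_x, reference)
        mapped = {c: _piecewise_linear(v, x, y) for c, v in t.values.items()}
        out.append(replace(t, values=mapped, state="quantile-anchored"))
    return out


def _window_bin_values(track: CoverageTrack, windows: pd.DataFrame) -> np.ndarray:
    """Values of every track bin overlapping each window (one entry per window-bin)."""
    vals: list[np.ndarray] = []
    B = track.bin_size
    for row in windows.itertuples(index=False):
        v = track.values.get(row.chrom)
        if v is None:
            continue
        b0 = int(row.start) // B
        b1 = min((int(row.end) - 1) // B, len(v) - 1)
        vals.append(v[b0 : b1 + 1])
    return np.concatenate(vals) if vals else np.empty(0)


def _monotone_knots(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse duplicate x knots (averaging y) so interpolation is well-defined."""
    df = pd.DataFrame({"x": x, "y": y}).groupby("x", sort=True)["y"].mean()
    xs = df.index.to_numpy()
    ys = np.maximum.accumulate(df.to_numpy())  # enforce monotone map
    return xs, ys


def _piecewise_linear(v: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """np.interp with linear extension of the terminal segments beyond the knots."""
    out = np.interp(v, x, y)
    if len(x) >= 2:
        lo_slope = (y[1] - y[0]) / (x[1] - x[0]) if x[1] > x[0] else 1.0
        hi_slope = (y[-1] - y[-2]) / (x[-1] - x[-2]) if x[-1] > x[-2] else 1.0
        below = v < x[0]
        above = v > x[-1]
        out[below] = y[0] + (v[below] - x[0]) * lo_slope
        out[above] = y[-1] + (v[above] - x[-1]) * hi_slope
    return np.maximum(out, 0.0)


def write_bedgraph(track: CoverageTrack, path) -> None:
    """Write non-zero bins as bedGraph."""
    with open(path, "w") as fh:
        for chrom in sorted(track.values):
            v = track.values[chrom]
            L = track.chrom_sizes[chrom]
            nz = np.nonzero(v)[0]
            for b in nz:
                s = b * track.bin_size
                fh.write(f"{chrom}\t{s}\t{min(s + track.bin_size, L)}\t{v[b]:.6g}\n")
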