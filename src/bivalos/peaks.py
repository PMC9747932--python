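"""Peak ingestion, merging, overlap counting, FRiP, top-N selection, and a
minimal Poisson peak caller used as test plumbing for synthetic data.

Peaks are pandas DataFrames with narrowPeak-style columns
``chrom, start, end, name, score, strand, signal, pvalue, qvalue, summit``
wrapped in a :class:`PeakSet` that carries sample identity and provenance.
The internal caller is deliberately simple (per-bin Poisson tail against the
genome-wide mean with BH adjustment) and is not equivalent to MACS2/SICER;
real-data pipelines should ingest externally called peak files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import stats

from .coverage import CoverageTrack

logger = logging.getLogger(__name__)

__all__ = [
    "PEAK_COLUMNS",
    "PeakSet",
    "read_peaks",
    "write_narrowpeak",
    "merge_within",
    "top_n_by_score",
    "overlap_peaks",
    "frip",
    "call_peaks_simple",
]

PEAK_COLUMNS = [
    "chrom", "start", "end", "name", "score", "strand",
    "signal", "pvalue", "qvalue", "summit",
]


def _sorted_peak_frame(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)


@dataclass
class PeakSet:
    """Scored peak intervals for one mark × cell type."""

    peaks: pd.DataFrame
    sample: Optional[tuple] = None
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        df = self.peaks
        missing = [c for c in PEAK_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"peak frame missing columns: {missing}")
        if len(df) and (df["start"] >= df["end"]).any():
            raise ValueError("peak with start >= end")
        if len(df) and not np.isfinite(df["score"].to_numpy(dtype=float)).all():
            raise ValueError("non-finite peak score")

    def __len__(self) -> int:
        return len(self.peaks)


def read_peaks(path: Union[str, Path], fmt: Optional[str] = None, sample: Optional[tuple] = None) -> PeakSet:
    """Read narrowPeak or BED peaks, returned sorted by (chrom, start).

    BED files with fewer than 5 columns get score 0 with a warning.
    Malformed lines raise with their line number.
    """
    path = Path(path)
    if fmt is None:
        fmt = "narrowpeak" if path.suffix.lower() == ".narrowpeak" else "bed"
    fmt = fmt.lower()
    if fmt not in ("narrowpeak", "bed"):
        raise ValueError(f"unknown peak format {fmt!r}")
    rows = []
    warned_score = False
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            try:
                if fmt == "narrowpeak":
                    if len(parts) < 10:
                        raise ValueError(f"narrowPeak needs 10 fields, got {len(parts)}")
                    rows.append((
                        parts[0], int(parts[1]), int(parts[2]), parts[3], float(parts[4]),
                        parts[5], float(parts[6]), float(parts[7]), float(parts[8]), int(parts[9]),
                    ))
                else:
                    if len(parts) < 3:
                        raise ValueError(f"BED needs >= 3 fields, got {len(parts)}")
                    name = parts[3] if len(parts) > 3 else f"peak_{i}"
                    if len(parts) > 4 and parts[4] not in (".", ""):
                        score = float(parts[4])
                    else:
                        score = 0.0
                        if not warned_score:
                            logger.warning("%s: no score column; defaulting scores to 0", path)
                            warned_score = True
                    strand = parts[5] if len(parts) > 5 else "."
                    rows.append((parts[0], int(parts[1]), int(parts[2]), name, score, strand,
                                 0.0, -1.0, -1.0, -1))
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{i}: malformed peak line: {exc}") from exc
    df = pd.DataFrame(rows, columns=PEAK_COLUMNS)
    return PeakSet(peaks=_sorted_peak_frame(df), sample=sample, provenance=[f"read:{path.name}"])


def write_narrowpeak(peaks: Union[PeakSet, pd.DataFrame], path: Union[str, Path]) -> None:
    df = peaks.peaks if isinstance(peaks, PeakSet) else peaks
    with open(path, "w") as fh:
        for r in df.itertuples(index=False):
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t{r.score:g}\t{r.strand}\t"
                f"{r.signal:g}\t{r.pvalue:g}\t{r.qvalue:g}\t{r.summit}\n"
            )


def merge_within(peaks: PeakSet, max_gap: int = 5000) -> PeakSet:
    """Transitively merge peaks whose gap is ≤ ``max_gap`` bp.

    bedtools ``merge -d`` semantics: book-ended and overlapping intervals
    always merge; merged score is the max of the members. Idempotent.
    """
    df = _sorted_peak_frame(peaks.peaks)
    if len(df) <= 1:
        return replace(peaks, peaks=df, provenance=peaks.provenance + [f"merge_within:{max_gap}"])
    out_rows = []
    cur = None
    for r in df.itertuples(index=False):
        if cur is not None and r.chrom == cur["chrom"] and r.start - cur["end"] <= max_gap:
            cur["end"] = max(cur["end"], r.end)
            cur["score"] = max(cur["score"], r.score)
            cur["n"] += 1
        else:
            if cur is not None:
                out_rows.append(cur)
            cur = {"chrom": r.chrom, "start": r.start, "end": r.end, "score": r.score, "n": 1}
    out_rows.append(cur)
    merged = pd.DataFrame(
        {
            "chrom": [r["chrom"] for r in out_rows],
            "start": [r["start"] for r in out_rows],
            "end": [r["end"] for r in out_rows],
            "name": [f"merged_{i}" for i in range(len(out_rows))],
            "score": [r["score"] for r in out_rows],
            "strand": ".",
            "signal": 0.0,
            "pvalue": -1.0,
            "qvalue": -1.0,
            "summit": -1,
        }
    )
    return replace(peaks, peaks=merged, provenance=peaks.provenance + [f"merge_within:{max_gap}"])


def top_n_by_score(peaks: PeakSet, n: int = 20000) -> PeakSet:
    """The n highest-score peaks (all if fewer), ties broken by genomic order."""
    if n < 1:
        raise ValueError("n must be >= 1")
    df = _sorted_peak_frame(peaks.peaks)
    order = df.sort_values("score", ascending=False, kind="stable").index[:n]
    out = df.loc[sorted(order)].reset_index(drop=True)
    return replace(peaks, peaks=out, provenance=peaks.provenance + [f"top_n:{n}"])


def _any_overlap(q_start: np.ndarray, q_end: np.ndarray, q_chrom: np.ndarray,
                 t: pd.DataFrame, min_overlap: int) -> np.ndarray:
    """For each query interval, does it overlap ≥ min_overlap bp of any target?"""
    hit = np.zeros(len(q_start), dtype=bool)
    for chrom, tsub in t.groupby("chrom", sort=False):
        qi = np.nonzero(q_chrom == chrom)[0]
        if len(qi) == 0:
            continue
        ts = tsub["start"].to_numpy()
        te = tsub["end"].to_numpy()
        order = np.argsort(ts, kind="stable")
        ts, te = ts[order], te[order]
        # max end among targets starting at or before a given position
        te_cummax = np.maximum.accumulate(te)
        for i in qi:
            s, e = q_start[i], q_end[i]
            # targets with start < e could overlap
            j = np.searchsorted(ts, e, side="left")
            if j == 0:
                continue
            # overlap = min(te, e) - max(ts, s); need >= min_overlap
            ov = np.minimum(te[:j], e) - np.maximum(ts[:j], s)
            if ov.max(initial=-1) >= min_overlap:
                hit[i] = True
    return hit


def overlap_peaks(set_a: PeakSet, set_b: PeakSet, min_overlap: int = 1) -> dict:
    """Count peaks in each set that overlap ≥ ``min_overlap`` bp of the other.

    Returns per-set overlapping counts and fractions plus the base-pair
    Jaccard index of the two (internally merged) interval sets.
    """
    a, b = set_a.peaks, set_b.peaks
    hit_a = _any_overlap(a["start"].to_numpy(), a["end"].to_numpy(), a["chrom"].to_numpy(), b, min_overlap)
    hit_b = _any_overlap(b["start"].to_numpy(), b["end"].to_numpy(), b["chrom"].to_numpy(), a, min_overlap)
    inter, union = _bp_jaccard_parts(a, b)
    return {
        "count_a": int(len(a)),
        "count_b": int(len(b)),
        "count_a_overlapping": int(hit_a.sum()),
        "count_b_overlapping": int(hit_b.sum()),
        "frac_a_overlapping": float(hit_a.mean()) if len(a) else 0.0,
        "frac_b_overlapping": float(hit_b.mean()) if len(b) else 0.0,
        "jaccard": float(inter / union) if union > 0 else 0.0,
    }


def _flatten(df: pd.DataFrame) -> dict[str, np.ndarray]:
    """Merge overlapping intervals per chrom; return stacked [start, end) pairs."""
    out = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        iv = sub[["start", "end"]].sort_values("start").to_numpy()
        merged = []
        for s, e in iv:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out[chrom] = np.array(merged, dtype=np.int64).reshape(-1, 2)
    return out


def _bp_jaccard_parts(a: pd.DataFrame, b: pd.DataFrame) -> tuple[int, int]:
    fa, fb = _flatten(a), _flatten(b)
    inter = 0
    total_a = sum(int((iv[:, 1] - iv[:, 0]).sum()) for iv in fa.values())
    total_b = sum(int((iv[:, 1] - iv[:, 0]).sum()) for iv in fb.values())
    for chrom in set(fa) & set(fb):
        ia, ib = fa[chrom], fb[chrom]
        i = j = 0
        while i < len(ia) and j < len(ib):
            s = max(ia[i, 0], ib[j, 0])
            e = min(ia[i, 1], ib[j, 1])
            if e > s:
                inter += int(e - s)
            if ia[i, 1] < ib[j, 1]:
                i += 1
            else:
                j += 1
    return inter, total_a + total_b - inter


def frip(frags: pd.DataFrame, peaks: PeakSet, min_overlap: int = 1) -> float:
    """Fraction of fragments overlapping ≥ ``min_overlap`` bp of any peak.

    Invariant under peak merging. Raises on an empty fragment set.
    """
    if len(frags) == 0:
        raise ValueError("FRiP undefined: no fragments")
    if len(peaks) == 0:
        return 0.0
    hit = _any_overlap(
        frags["start"].to_numpy(), frags["end"].to_numpy(), frags["chrom"].to_numpy(),
        peaks.peaks, min_overlap,
    )
    return float(hit.mean())


def call_peaks_simple(
    track: CoverageTrack,
    q_threshold: float = 0.01,
    min_bins: int = 2,
    sample: Optional[tuple] = None,
) -> PeakSet:
    """Minimal enrichment caller on a binned track (synthetic-data plumbing).

    Per-bin upper-tail Poisson probability against the genome-wide mean
    rate, Benjamini-Hochberg adjusted; adjacent significant bins merge into
    peaks and runs shorter than ``min_bins`` are dropped. Scores are the
    peak's best −10·log10(q). Not a MACS2/SICER substitute.
    """
    if track.state == "CPM":
        if track.n_fragments == 0:
            raise ValueError("cannot recover counts from CPM track with no fragments")
        counts = {c: v * track.n_fragments / 1e6 for c, v in track.values.items()}
    else:
        counts = track.values
    allv = np.concatenate([counts[c] for c in sorted(counts)])
    if allv.sum() == 0:
        raise ValueError("no signal: track is all zeros")
    lam = allv.mean()

    from statsmodels.stats.multitest import multipletests

    pvals = {c: stats.poisson.sf(np.round(v) - 1, lam) for c, v in counts.items()}
    flat_p = np.concatenate([pvals[c] for c in sorted(pvals)])
    flat_q = multipletests(flat_p, method="fdr_bh")[1]
    qvals = {}
    off = 0
    for c in sorted(pvals):
        n = len(pvals[c])
        qvals[c] = flat_q[off : off + n]
        off += n

    rows = []
    B = track.bin_size
    for chrom in sorted(counts):
        sig = qvals[chrom] <= q_threshold
        if not sig.any():
            continue
        # runs of consecutive significant bins
        idx = np.nonzero(sig)[0]
        splits = np.nonzero(np.diff(idx) > 1)[0] + 1
        for run in np.split(idx, splits):
            if len(run) < min_bins:
                continue
            qmin = float(qvals[chrom][run].min())
            score = -10.0 * np.log10(max(qmin, 1e-300))
            s = int(run[0]) * B
            e = min((int(run[-1]) + 1) * B, track.chrom_sizes[chrom])
            best = int(run[np.argmax(counts[chrom][run])])
            rows.append((chrom, s, e, f"peak_{len(rows)}", score, ".",
                         float(counts[chrom][run].max()), -1.0, qmin, best * B + B // 2 - s))
    df = pd.DataFrame(rows, columns=PEAK_COLUMNS)
    return PeakSet(peaks=_sorted_peak_frame(df), sample=sample, provenance=["call_peaks_simple"])
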