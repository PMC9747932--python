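"""Cell-type-specific gene selection and two-cell-type regulatory patterns.

Cell-type-specific genes are selected from a differential-expression table
at q < 0.05 and |log2FC| > 1 (strict inequalities). For each such gene the
promoter signal of each mark is compared between the two cell types on
quantile-anchored tracks, and the pair of per-mark calls is folded into a
regulatory pattern: ``derepression`` (permissive mark shared, repressive
mark selectively lost in the expressing subtype — the Egr3 configuration),
``permissive_gain``, ``both``, or ``neither``; configurations that point the
wrong way (e.g. the permissive mark higher in the non-expressing subtype)
are reported as ``discordant`` rather than forced into a class.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .coverage import CoverageTrack, promoter_signal
from .genome import GenomeModel

logger = logging.getLogger(__name__)

__all__ = [
    "select_specific_genes",
    "promoter_signal_table",
    "signal_floor",
    "differential_mark_signal",
    "classify_regulatory_pattern",
    "classify_patterns",
]

CALLS = ("higher_in_A", "higher_in_B", "similar")
PATTERNS = ("derepression", "permissive_gain", "both", "neither", "discordant")


def select_specific_genes(
    diff: pd.DataFrame,
    min_abs_log2fc: float = 1.0,
    max_q: float = 0.05,
) -> tuple[pd.Index, pd.Index]:
    """(A-specific, B-specific) gene lists from a differential table.

    ``diff`` needs columns ``log2fc`` (A over B) and ``qvalue``. Both
    thresholds are strict: q < max_q and |log2FC| > min_abs_log2fc; the sign
    of log2FC routes the gene.
    """
    for col in ("log2fc", "qvalue"):
        if col not in diff.columns:
            raise ValueError(f"differential table missing column {col!r}")
    lfc = diff["log2fc"].astype(float)
    q = diff["qvalue"].astype(float)
    passing = (q < max_q) & (lfc.abs() > min_abs_log2fc) & np.isfinite(lfc)
    a_specific = diff.index[passing & (lfc > 0)]
    b_specific = diff.index[passing & (lfc < 0)]
    return a_specific, b_specific


def promoter_signal_table(
    tracks: dict,
    genome: GenomeModel,
    gene_ids: Optional[Sequence[str]] = None,
    upstream: int = 2000,
    downstream: int = 1000,
    require_anchored: bool = True,
) -> pd.DataFrame:
    """Gene × sample table of mean promoter signal.

    ``tracks`` maps a sample label to its CoverageTrack. Cross-sample
    comparison is only meaningful after quantile anchoring, so non-anchored
    tracks are refused unless ``require_anchored=False``.
    """
    cols = {}
    for label, track in tracks.items():
        if require_anchored and track.state != "quantile-anchored":
            raise ValueError(
                f"track {label!r} has state {track.state!r}; cross-sample promoter "
                "comparison needs quantile-anchored tracks "
                "(pass require_anchored=False to override)"
            )
        cols[label] = promoter_signal(track, genome, gene_ids, upstream, downstream)
    return pd.DataFrame(cols)


def signal_floor(tracks: Sequence[CoverageTrack], quantile: float = 0.05) -> float:
    """Pseudo-floor: the 5th percentile of genome-wide nonzero signal.

    Added to both sides of promoter-signal ratios so empty promoters cannot
    produce infinite log-ratios.
    """
    vals = np.concatenate([t.concat() for t in tracks])
    nz = vals[vals > 0]
    if len(nz) == 0:
        raise ValueError("signal_floor: all-zero tracks")
    return float(np.quantile(nz, quantile))


def differential_mark_signal(
    signal_a: pd.Series,
    signal_b: pd.Series,
    min_abs_log2ratio: float = 1.0,
    floor: float = 0.0,
) -> pd.DataFrame:
    """Per-gene call of where a mark's promoter signal is higher.

    call = higher_in_A if log2((sA+floor)/(sB+floor)) > min_abs_log2ratio,
    symmetric for B, else similar. Signals must be non-negative and anchored
    to the same scale.
    """
    shared = signal_a.index.intersection(signal_b.index)
    a = signal_a.loc[shared].astype(float)
    b = signal_b.loc[shared].astype(float)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("negative promoter signal")
    if floor < 0:
        raise ValueError("floor must be >= 0")
    if floor == 0.0 and ((a == 0) | (b == 0)).any():
        logger.warning("differential_mark_signal: zero signals with zero floor; ratios may be infinite")
    with np.errstate(divide="ignore"):
        log2r = np.log2(a + floor) - np.log2(b + floor)
    call = np.where(
        log2r > min_abs_log2ratio, "higher_in_A",
        np.where(log2r < -min_abs_log2ratio, "higher_in_B", "similar"),
    )
    return pd.DataFrame({"log2_ratio": log2r, "call": call}, index=shared)


def classify_regulatory_pattern(k4_call: str, k27_call: str, expressing: str) -> str:
    """Fold one gene's two mark calls into a regulatory pattern.

    ``expressing`` is ``"A"`` or ``"B"`` — the cell type in which the gene
    is expressed. With marks oriented to the expressing cell type:

    - K4 similar and K27 lower in the expressing type → ``derepression``
    - K4 higher in the expressing type and K27 similar → ``permissive_gain``
    - K4 higher and K27 lower in the expressing type → ``both``
    - both marks similar → ``neither``
    - any call pointing the opposite way → ``discordant``

    Total and deterministic; swapping the A/B labels of both calls together
    with the expressing label leaves the result unchanged.
    """
    for call, name in ((k4_call, "k4_call"), (k27_call, "k27_call")):
        if call not in CALLS:
            raise ValueError(f"{name} must be one of {CALLS}, got {call!r}")
    if expressing not in ("A", "B"):
        raise ValueError(f"expressing must be 'A' or 'B', got {expressing!r}")
    higher_expr = "higher_in_A" if expressing == "A" else "higher_in_B"
    higher_other = "higher_in_B" if expressing == "A" else "higher_in_A"

    k4_up = k4_call == higher_expr  # permissive mark enriched in expressing type
    k27_down = k27_call == higher_other  # repressive mark depleted in expressing type
    k4_sim = k4_call == "similar"
    k27_sim = k27_call == "similar"

    if k4_sim and k27_down:
        return "derepression"
    if k4_up and k27_sim:
        return "permissive_gain"
    if k4_up and k27_down:
        return "both"
    if k4_sim and k27_sim:
        return "neither"
    return "discordant"


def classify_patterns(
    k4_calls: pd.Series,
    k27_calls: pd.Series,
    expressing: pd.Series,
) -> pd.Series:
    """Vectorized :func:`classify_regulatory_pattern` over a gene index."""
    shared = k4_calls.index.intersection(k27_calls.index).intersection(expressing.index)
    out = pd.Series(
        [
            classify_regulatory_pattern(k4_calls[g], k27_calls[g], expressing[g])
            for g in shared
        ],
        index=shared,
        name="pattern",
    )
    return out
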