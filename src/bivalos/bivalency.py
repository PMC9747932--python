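"""Promoter-state classification and bivalency statistics.

A promoter (−2 kb/+1 kb around the TSS, strand-aware) is classified per
cell type into one of four exhaustive, exclusive states by ≥ 1 bp overlap
with H3K4me3 and H3K27me3 peaks: ``bivalent`` (both marks), ``K4only``,
``K27only``, or ``none``. Downstream statistics: expression by state
(Wilcoxon rank-sum with BH correction; bivalent genes sit at intermediate
expression between the K4-only and K27-only groups), the mutually exclusive
index (expected-under-independence over observed co-occurrence of the two
marks; 1.0 = independent, > 1 = the marks avoid each other), and the
two-cell-type bivalent-domain overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GeneRecord, GenomeModel
from .genome import promoter_window as _promoter_window
from .peaks import PeakSet, _any_overlap

logger = logging.getLogger(__name__)

__all__ = [
    "PromoterStateTable",
    "MEIndexResult",
    "promoter_window",
    "classify_promoter_states",
    "compare_expression_by_state",
    "mutually_exclusive_index",
    "bivalent_overlap",
]

STATES = ("K4only", "bivalent", "K27only", "none")


def promoter_window(
    gene: GeneRecord,
    upstream: int = 2000,
    downstream: int = 1000,
    chrom_length: Optional[int] = None,
) -> tuple[int, int]:
    """Strand-aware promoter interval around the TSS (−2 kb/+1 kb default)."""
    return _promoter_window(gene, upstream, downstream, chrom_length)


@dataclass
class PromoterStateTable:
    """Per-gene promoter state for one cell type, plus the window used."""

    states: pd.Series  # gene_id -> state
    cell_type: Optional[str] = None
    upstream: int = 2000
    downstream: int = 1000

    def __post_init__(self) -> None:
        bad = set(self.states.unique()) - set(STATES)
        if bad:
            raise ValueError(f"unknown promoter states: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.states)

    def counts(self) -> pd.Series:
        return self.states.value_counts().reindex(STATES, fill_value=0)

    def genes_in(self, state: str) -> pd.Index:
        return self.states.index[self.states == state]

    @property
    def has_k4(self) -> pd.Series:
        return self.states.isin(["K4only", "bivalent"])

    @property
    def has_k27(self) -> pd.Series:
        return self.states.isin(["K27only", "bivalent"])


def classify_promoter_states(
    k4_peaks: PeakSet,
    k27_peaks: PeakSet,
    genome: GenomeModel,
    upstream: int = 2000,
    downstream: int = 1000,
    cell_type: Optional[str] = None,
) -> PromoterStateTable:
    """Four-way promoter state per gene from the two peak sets of one cell type.

    Presence of a mark = ≥ 1 bp overlap between any of its peaks and the
    promoter window.
    """
    windows = genome.promoter_windows(upstream, downstream)
    ws = windows["start"].to_numpy()
    we = windows["end"].to_numpy()
    wc = windows["chrom"].to_numpy()
    k4 = _any_overlap(ws, we, wc, k4_peaks.peaks, 1) if len(k4_peaks) else np.zeros(len(windows), bool)
    k27 = _any_overlap(ws, we, wc, k27_peaks.peaks, 1) if len(k27_peaks) else np.zeros(len(windows), bool)
    state = np.where(k4 & k27, "bivalent", np.where(k4, "K4only", np.where(k27, "K27only", "none")))
    return PromoterStateTable(
        states=pd.Series(state, index=windows.index, name="state"),
        cell_type=cell_type,
        upstream=upstream,
        downstream=downstream,
    )


def compare_expression_by_state(
    states: PromoterStateTable,
    fpkm: pd.Series,
    contrasts: tuple[tuple[str, str], ...] = (("bivalent", "K4only"), ("bivalent", "K27only")),
) -> pd.DataFrame:
    """Wilcoxon rank-sum tests of expression between promoter-state groups.

    Two-sided Mann-Whitney tests for each contrast (default: bivalent vs
    K4-only and bivalent vs K27-only), BH-corrected across the reported
    contrasts. Returns a frame with the W statistic, raw and adjusted p, and
    both group medians. Contrasts with fewer than 2 genes in either group
    are skipped with a warning.
    """
    shared = states.states.index.intersection(fpkm.index)
    st = states.states.loc[shared]
    ex = fpkm.loc[shared].astype(float)
    rows = []
    for g1, g2 in contrasts:
        x = ex[st == g1].to_numpy()
        y = ex[st == g2].to_numpy()
        if len(x) < 2 or len(y) < 2:
            logger.warning("contrast %s vs %s skipped: group too small (%d, %d)", g1, g2, len(x), len(y))
            rows.append((g1, g2, len(x), len(y), np.nan, np.nan,
                         float(np.median(x)) if len(x) else np.nan,
                         float(np.median(y)) if len(y) else np.nan, True))
            continue
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
        rows.append((g1, g2, len(x), len(y), float(res.statistic), float(res.pvalue),
                     float(np.median(x)), float(np.median(y)), False))
    out = pd.DataFrame(
        rows,
        columns=["group1", "group2", "n1", "n2", "W", "pvalue", "median1", "median2", "skipped"],
    )
    ok = ~out["skipped"] & out["pvalue"].notna()
    out["padj"] = np.nan
    if ok.any():
        from statsmodels.stats.multitest import multipletests

        out.loc[ok, "padj"] = multipletests(out.loc[ok, "pvalue"], method="fdr_bh")[1]
    return out


@dataclass
class MEIndexResult:
    """Mutually exclusive index over a promoter universe.

    index = (p_K4 × p_K27) / p_both. 1.0 means the two marks co-occur
    exactly as often as independence predicts; > 1 means bivalency is rarer
    than chance (the marks exclude each other). ``flag`` is set instead of a
    numeric index when a marginal or the joint frequency is zero.
    """

    n_promoters: int
    p_k4: float
    p_k27: float
    p_both_observed: float
    p_both_expected: float
    index: Optional[float]
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    flag: Optional[str] = None  # "infinite" | "undefined" | None

    def to_dict(self) -> dict:
        return {
            "n_promoters": self.n_promoters,
            "p_k4": self.p_k4,
            "p_k27": self.p_k27,
            "p_both_observed": self.p_both_observed,
            "p_both_expected": self.p_both_expected,
            "index": self.index,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "flag": self.flag,
        }


def mutually_exclusive_index(
    states: PromoterStateTable,
    n_boot: int = 1000,
    seed: int = 0,
    ci: float = 0.95,
) -> MEIndexResult:
    """Mutually exclusive index with a percentile bootstrap CI over genes.

    The universe is every promoter in the table (marked or not). With a zero
    observed joint frequency the index is flagged infinite; with a zero
    marginal it is flagged undefined.
    """
    n = len(states)
    if n < 1:
        raise ValueError("mutually_exclusive_index needs >= 1 promoter")
    k4 = states.has_k4.to_numpy()
    k27 = states.has_k27.to_numpy()
    res = _mei_from_flags(k4, k27)
    if res.index is None or n_boot <= 0:
        return res
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        take = rng.integers(0, n, size=n)
        b = _mei_from_flags(k4[take], k27[take])
        if b.index is not None:
            boots.append(b.index)
    if boots:
        alpha = (1 - ci) / 2
        res.ci_low = float(np.quantile(boots, alpha))
        res.ci_high = float(np.quantile(boots, 1 - alpha))
    return res


def _mei_from_flags(k4: np.ndarray, k27: np.ndarray) -> MEIndexResult:
    n = len(k4)
    p4 = float(k4.mean())
    p27 = float(k27.mean())
    p_both = float((k4 & k27).mean())
    p_exp = p4 * p27
    if p4 == 0.0 or p27 == 0.0:
        return MEIndexResult(n, p4, p27, p_both, p_exp, None, flag="undefined")
    if p_both == 0.0:
        return MEIndexResult(n, p4, p27, p_both, p_exp, None, flag="infinite")
    return MEIndexResult(n, p4, p27, p_both, p_exp, p_exp / p_both)


def bivalent_overlap(states_a: PromoterStateTable, states_b: PromoterStateTable) -> dict:
    """Partition of bivalent genes across two cell types (Venn counts)."""
    shared = states_a.states.index.intersection(states_b.states.index)
    biv_a = set(states_a.genes_in("bivalent")) & set(shared)
    biv_b = set(states_b.genes_in("bivalent")) & set(shared)
    return {
        "only_a": len(biv_a - biv_b),
        "only_b": len(biv_b - biv_a),
        "shared": len(biv_a & biv_b),
    }
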