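"""Synthetic-data generator with known ground truth.

Emulates an INTACT + CUT&RUN experiment on two striatal neuron subtypes
(A2a and D1 by default): per-cell-type promoter chromatin states
(H3K4me3-only / H3K27me3-only / bivalent / none), expression coupled to
state (active > bivalent > repressed), cell-type-specific genes whose state
flips between subtypes (including Egr3-style de-repression, where H3K4me3 is
shared but H3K27me3 is lost in the expressing subtype), and per-sample
fragment libraries with promoter enrichment over a uniform background, PCR
duplicates, low-MAPQ reads, a realistic insert-size distribution, and global
efficiency differences between samples.

Every quantity the generator draws is recorded in a :class:`TruthManifest`
so downstream stages can be tested against known truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .genome import GeneRecord, GenomeModel, read_genes_bed, write_genes_bed

__all__ = [
    "STATES",
    "MARKS",
    "MARKED_STATES",
    "PATTERNS",
    "TruthManifest",
    "ExpressionTable",
    "SimulationConfig",
    "SyntheticDataset",
    "generate_genome_annotation",
    "assign_promoter_states",
    "sample_expression",
    "simulate_fragments",
    "truth_peaks",
    "simulate_dataset",
    "write_dataset",
    "read_dataset",
]

STATES = ("K4only", "bivalent", "K27only", "none")
MARKS = ("H3K4me3", "H3K27me3", "IgG")
#: promoter states that carry each mark
MARKED_STATES = {
    "H3K4me3": frozenset({"K4only", "bivalent"}),
    "H3K27me3": frozenset({"K27only", "bivalent"}),
    "IgG": frozenset(),
}
PATTERNS = ("derepression", "permissive_gain", "both", "neither")

#: promoter window (upstream, downstream of TSS) used for mark placement
PROMOTER_WINDOW = (2000, 1000)

DEFAULT_PROPORTIONS = {"K4only": 0.40, "bivalent": 0.15, "K27only": 0.20, "none": 0.25}
DEFAULT_STATE_MEANS = {"K4only": 4.0, "bivalent": 1.5, "K27only": -1.0, "none": -2.0}


# ---------------------------------------------------------------------------
# Truth containers
# ---------------------------------------------------------------------------


@dataclass
class TruthManifest:
    """Ground truth for one simulated experiment.

    ``states``: genes × cell types, values in :data:`STATES`.
    ``patterns``: per gene, the cross-cell-type regulatory pattern
    (:data:`PATTERNS`) and, for non-"neither" genes, the expressing cell type.
    ``params``: every simulation parameter, including the seed.
    """

    states: pd.DataFrame
    patterns: pd.DataFrame
    cell_types: tuple[str, ...]
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        bad = set(np.unique(self.states.to_numpy())) - set(STATES)
        if bad:
            raise ValueError(f"unknown promoter states: {sorted(bad)}")
        for k, v in self.params.items():
            if isinstance(v, (int, float)) and not isinstance(v, bool) and v < 0:
                raise ValueError(f"simulation parameter {k} must be non-negative, got {v}")

    def genes_with_pattern(self, pattern: str) -> pd.Index:
        return self.patterns.index[self.patterns["pattern"] == pattern]

    def marked_genes(self, mark: str, cell_type: str) -> pd.Index:
        """Genes whose promoter carries ``mark`` in ``cell_type``."""
        states = self.states[cell_type]
        return states.index[states.isin(MARKED_STATES[mark])]


@dataclass
class ExpressionTable:
    """Per-gene FPKM per cell type plus a differential table.

    ``diff`` columns: ``log2fc`` (first cell type over second), ``pvalue``
    (label-permutation), ``qvalue`` (Benjamini-Hochberg).
    ``replicates``: log2-FPKM per replicate, columns MultiIndex
    (cell_type, replicate); may be None for tables read from disk.
    """

    cell_types: tuple[str, ...]
    fpkm: pd.DataFrame
    diff: pd.DataFrame
    replicates: Optional[pd.DataFrame] = None

    def fpkm_for(self, cell_type: str) -> pd.Series:
        return self.fpkm[cell_type]


# ---------------------------------------------------------------------------
# Genome annotation
# ---------------------------------------------------------------------------


def generate_genome_annotation(
    n_genes: int,
    chrom_length: Union[int, dict[str, int]] = 10_000_000,
    seed: int = 0,
    min_gap: int = 10_000,
    gene_length_range: tuple[int, int] = (2_000, 8_000),
) -> GenomeModel:
    """Random non-overlapping gene annotation with guaranteed spacing.

    Genes are placed one per equal-width slot so any two genes are at least
    ``min_gap`` apart; strands are random. ``chrom_length`` may be a dict of
    chromosome sizes for a multi-chromosome genome (genes are apportioned by
    length). Deterministic per seed.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    lo, hi = gene_length_range
    if not (0 < lo <= hi):
        raise ValueError(f"bad gene_length_range {gene_length_range}")

    chrom_sizes = {"chr1": int(chrom_length)} if isinstance(chrom_length, int) else dict(chrom_length)
    total_len = sum(chrom_sizes.values())
    required = n_genes * (hi + min_gap)
    if total_len < required:
        raise ValueError(
            f"cannot place {n_genes} genes with >= {min_gap} bp gaps on "
            f"{total_len} bp; need at least {required} bp"
        )

    rng = np.random.default_rng(seed)
    # apportion genes to chromosomes by length (largest-remainder)
    names = list(chrom_sizes)
    fracs = np.array([chrom_sizes[c] for c in names], dtype=float) / total_len
    alloc = np.floor(fracs * n_genes).astype(int)
    rema = fracs * n_genes - alloc
    for i in np.argsort(-rema)[: n_genes - alloc.sum()]:
        alloc[i] += 1

    genes: list[GeneRecord] = []
    gid = 0
    for chrom, k in zip(names, alloc):
        if k == 0:
            continue
        slot = chrom_sizes[chrom] // k
        if slot < hi + min_gap:
            raise ValueError(
                f"cannot place {k} genes on {chrom} ({chrom_sizes[chrom]} bp); "
                f"need at least {k * (hi + min_gap)} bp"
            )
        lengths = rng.integers(lo, hi + 1, size=k)
        offsets = rng.integers(0, slot - lengths - min_gap + 1)
        strands = rng.choice(["+", "-"], size=k)
        for i in range(k):
            start = int(i * slot + offsets[i])
            genes.append(
                GeneRecord(f"gene_{gid:05d}", chrom, start, start + int(lengths[i]), str(strands[i]))
            )
            gid += 1
    return GenomeModel(chrom_sizes=chrom_sizes, genes=genes)


# ---------------------------------------------------------------------------
# Promoter states and patterns
# ---------------------------------------------------------------------------


def _validate_proportions(props: dict[str, float]) -> np.ndarray:
    if set(props) != set(STATES):
        raise ValueError(f"proportions must have exactly the states {STATES}, got {sorted(props)}")
    p = np.array([props[s] for s in STATES], dtype=float)
    if (p < 0).any():
        raise ValueError("proportions must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"proportions must sum to 1 (got {p.sum():.12f})")
    return p


def assign_promoter_states(
    genome: GenomeModel,
    proportions: Optional[dict] = None,
    coupling: float = 0.8,
    specific_gene_fraction: float = 0.05,
    seed: int = 0,
    cell_types: tuple[str, str] = ("A2a", "D1"),
) -> TruthManifest:
    """Draw per-cell-type promoter states and cross-cell-type pattern labels.

    Each gene draws a state for the first cell type from ``proportions``;
    with probability ``coupling`` the second cell type shares it, otherwise
    it redraws independently (most bivalent domains are shared between
    subtypes at the default coupling). A random ``specific_gene_fraction``
    of genes is then overwritten with a cell-type-specific configuration and
    a pattern label, cycling through:

    - ``derepression``: K4only in the expressing cell type, bivalent in the
      other (permissive mark shared, repressive mark selectively lost);
    - ``permissive_gain``: K4only vs none (permissive mark gained);
    - ``both``: K4only vs K27only.

    ``proportions`` may be a single state→fraction map used for both cell
    types, or a map cell_type→(state→fraction).
    """
    if not 0.0 <= coupling <= 1.0:
        raise ValueError(f"coupling must be in [0, 1], got {coupling}")
    if not 0.0 <= specific_gene_fraction <= 1.0:
        raise ValueError(f"specific_gene_fraction must be in [0, 1], got {specific_gene_fraction}")
    if proportions is None:
        proportions = DEFAULT_PROPORTIONS
    if set(proportions) == set(cell_types):
        per_cell = {c: _validate_proportions(proportions[c]) for c in cell_types}
    else:
        p = _validate_proportions(proportions)
        per_cell = {c: p for c in cell_types}

    rng = np.random.default_rng(seed)
    gene_ids = genome.gene_ids
    n = len(gene_ids)
    ct_a, ct_b = cell_types

    idx_a = rng.choice(len(STATES), size=n, p=per_cell[ct_a])
    share = rng.random(n) < coupling
    idx_b = np.where(share, idx_a, rng.choice(len(STATES), size=n, p=per_cell[ct_b]))
    states = pd.DataFrame(
        {ct_a: np.array(STATES)[idx_a], ct_b: np.array(STATES)[idx_b]},
        index=pd.Index(gene_ids, name="gene_id"),
    )

    patterns = pd.DataFrame(
        {"pattern": "neither", "expressing": pd.NA}, index=states.index, dtype=object
    )
    n_spec = int(round(specific_gene_fraction * n))
    if n_spec > 0:
        chosen = rng.choice(n, size=n_spec, replace=False)
        spec_patterns = ("derepression", "permissive_gain", "both")
        other_state = {"derepression": "bivalent", "permissive_gain": "none", "both": "K27only"}
        for j, gi in enumerate(sorted(chosen)):
            pat = spec_patterns[j % 3]
            expressing = cell_types[j % 2]
            silent = ct_b if expressing == ct_a else ct_a
            gid = gene_ids[gi]
            states.loc[gid, expressing] = "K4only"
            states.loc[gid, silent] = other_state[pat]
            patterns.loc[gid, "pattern"] = pat
            patterns.loc[gid, "expressing"] = expressing

    return TruthManifest(
        states=states,
        patterns=patterns,
        cell_types=cell_types,
        params={
            "coupling": coupling,
            "specific_gene_fraction": specific_gene_fraction,
            "proportions": {c: dict(zip(STATES, per_cell[c].tolist())) for c in cell_types},
        },
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Expression coupled to state
# ---------------------------------------------------------------------------


def sample_expression(
    truth: TruthManifest,
    state_means: Optional[dict[str, float]] = None,
    sd: float = 1.0,
    n_reps: int = 5,
    n_perm: int = 1000,
    seed: int = 0,
    allow_unordered: bool = False,
) -> ExpressionTable:
    """Log-normal FPKM per gene × cell type, driven by the promoter state.

    ``state_means`` are log2-FPKM means per state; the default (4, 1.5, −1,
    −2 for K4only/bivalent/K27only/none) makes bivalent genes intermediate
    between active and repressed. ``n_reps`` replicate libraries per cell
    type feed a label-permutation differential test (``n_perm`` shuffles of
    the replicate labels, two-sided on the mean log2 difference), BH-adjusted
    to a q-value. With ``sd=0`` FPKM is an exact function of state.
    """
    if state_means is None:
        state_means = DEFAULT_STATE_MEANS
    if sd < 0:
        raise ValueError(f"sd must be >= 0, got {sd}")
    mu = {s: float(state_means[s]) for s in STATES}
    if not allow_unordered and not (mu["K4only"] > mu["bivalent"] > mu["K27only"] >= mu["none"]):
        raise ValueError(
            "state means must satisfy K4only > bivalent > K27only >= none "
            "(pass allow_unordered=True to override)"
        )

    rng = np.random.default_rng(seed)
    ct_a, ct_b = truth.cell_types
    genes = truth.states.index
    n = len(genes)

    mu_mat = np.column_stack(
        [truth.states[c].map(mu).to_numpy(dtype=float) for c in (ct_a, ct_b)]
    )  # (n, 2)
    noise = rng.standard_normal((n, 2, n_reps)) * sd
    log2_reps = mu_mat[:, :, None] + noise  # (n, 2, n_reps)

    mean_log2 = log2_reps.mean(axis=2)  # (n, 2)
    fpkm = pd.DataFrame(2.0 ** mean_log2, index=genes, columns=[ct_a, ct_b])

    log2fc = mean_log2[:, 0] - mean_log2[:, 1]
    pvals = _permutation_pvalues(log2_reps, n_perm, rng)
    from statsmodels.stats.multitest import multipletests

    qvals = multipletests(pvals, method="fdr_bh")[1]
    diff = pd.DataFrame({"log2fc": log2fc, "pvalue": pvals, "qvalue": qvals}, index=genes)

    rep_cols = pd.MultiIndex.from_product([(ct_a, ct_b), range(1, n_reps + 1)], names=["cell_type", "replicate"])
    replicates = pd.DataFrame(log2_reps.reshape(n, 2 * n_reps), index=genes, columns=rep_cols)
    return ExpressionTable(cell_types=(ct_a, ct_b), fpkm=fpkm, diff=diff, replicates=replicates)


def _permutation_pvalues(log2_reps: np.ndarray, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """Two-sided label-permutation p for mean(log2 A) − mean(log2 B) per gene.

    The null statistics from every gene × permutation are pooled into one
    empirical null (replicate noise is exchangeable across genes here), so
    the attainable p-value granularity is 1/(n_genes · n_perm) rather than
    the 2/C(2k, k) floor of a per-gene permutation test.
    """
    n, _, n_reps = log2_reps.shape
    pooled = log2_reps.reshape(n, 2 * n_reps)

    def stat(mat: np.ndarray, s0: float) -> np.ndarray:
        a, b = mat[:, :n_reps], mat[:, n_reps:]
        diff = a.mean(axis=1) - b.mean(axis=1)
        se = np.sqrt((a.var(axis=1, ddof=1) + b.var(axis=1, ddof=1)) / n_reps)
        return np.abs(diff) / (se + s0)

    # variance-stabilizing offset (SAM-style): keeps low-variance genes from
    # dominating and bounds the statistic for degenerate (sd=0) draws
    a, b = pooled[:, :n_reps], pooled[:, n_reps:]
    se_all = np.sqrt((a.var(axis=1, ddof=1) + b.var(axis=1, ddof=1)) / n_reps)
    s0 = max(float(np.median(se_all)), 1e-12)

    t_obs = stat(pooled, s0)
    null = np.empty((n_perm, n))
    for p in range(n_perm):
        perm = rng.permutation(2 * n_reps)
        null[p] = stat(pooled[:, perm], s0)
    flat = np.sort(null.ravel())
    # p = (1 + #null >= |t|) / (1 + N)
    ge = len(flat) - np.searchsorted(flat, t_obs - 1e-12, side="left")
    return (1.0 + ge) / (1.0 + len(flat))


# ---------------------------------------------------------------------------
# Fragment simulation
# ---------------------------------------------------------------------------


def simulate_fragments(
    truth: TruthManifest,
    genome: GenomeModel,
    mark: str,
    cell_type: str,
    replicate: int = 1,
    depth: int = 50_000,
    seed: int = 0,
    *,
    enrichment: float = 20.0,
    duplicate_rate: float = 0.1,
    low_mapq_fraction: float = 0.1,
    insert_mu: float = 200.0,
    insert_sigma: float = 30.0,
    insert_clip: tuple[int, int] = (50, 700),
    efficiency: float = 1.0,
) -> tuple[pd.DataFrame, dict]:
    """Simulate one fragment library for (mark, cell type, replicate).

    Promoters carrying the mark receive fragments at ``enrichment`` × the
    uniform background rate, centered on the promoter window. The per-sample
    ``efficiency`` scalar multiplies total depth *and* the enrichment excess
    (effective enrichment 1 + s·(e−1)), so that more efficient captures put
    a larger share of their reads into marked regions — the way global
    capture-efficiency differences manifest after depth normalization.
    Fragment length ~ Normal(insert_mu, insert_sigma) clipped to
    ``insert_clip``; duplicates are injected at ``duplicate_rate`` as exact
    coordinate copies; ``low_mapq_fraction`` of records get MAPQ < 20.

    Returns (fragments, info) where ``info`` records the realized counts
    needed for exact filter bookkeeping: total fragments, injected
    duplicates, low-MAPQ records, and the count expected to survive the
    standard MAPQ→dedup→insert-size retention filters.
    """
    if mark not in MARKS:
        raise ValueError(f"unknown mark {mark!r}; expected one of {MARKS}")
    if cell_type not in truth.cell_types:
        raise ValueError(f"unknown cell type {cell_type!r}; expected one of {truth.cell_types}")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if enrichment < 1:
        raise ValueError("enrichment must be >= 1")
    for name, v in (("duplicate_rate", duplicate_rate), ("low_mapq_fraction", low_mapq_fraction)):
        if not 0.0 <= v < 1.0:
            raise ValueError(f"{name} must be in [0, 1), got {v}")

    rng = np.random.default_rng(seed)
    n_total = max(1, int(round(depth * efficiency)))
    eff_enrichment = 1.0 + efficiency * (enrichment - 1.0) if mark != "IgG" else 1.0

    # enriched windows: promoters of genes carrying this mark in this cell type
    windows = genome.promoter_windows(*PROMOTER_WINDOW)
    marked = truth.marked_genes(mark, cell_type)
    windows = windows.loc[windows.index.intersection(marked)]

    chrom_names = list(genome.chrom_sizes)
    chrom_lens = np.array([genome.chrom_sizes[c] for c in chrom_names], dtype=float)
    genome_len = chrom_lens.sum()

    win_chrom = windows["chrom"].to_numpy()
    win_start = windows["start"].to_numpy(dtype=float)
    win_end = windows["end"].to_numpy(dtype=float)
    win_len = win_end - win_start
    extra = (eff_enrichment - 1.0) * win_len
    weights = np.concatenate([[genome_len], extra])
    probs = weights / weights.sum()

    n_dup = rng.binomial(n_total, duplicate_rate) if duplicate_rate > 0 else 0
    n_unique = n_total - n_dup

    chroms, starts, ends = _draw_unique_fragments(
        rng, n_unique, chrom_names, chrom_lens, probs, win_chrom, win_start, win_end,
        insert_mu, insert_sigma, insert_clip,
    )

    if n_dup > 0:
        src = rng.integers(0, n_unique, size=n_dup)
        chroms = np.concatenate([chroms, chroms[src]])
        starts = np.concatenate([starts, starts[src]])
        ends = np.concatenate([ends, ends[src]])
    dup_flag = np.zeros(n_total, dtype=bool)
    dup_flag[n_unique:] = True

    low = rng.random(n_total) < low_mapq_fraction
    mapq = np.where(low, rng.integers(0, 20, size=n_total), rng.integers(20, 61, size=n_total))

    order = rng.permutation(n_total)
    frags = pd.DataFrame(
        {
            "chrom": chroms[order],
            "start": starts[order].astype(np.int64),
            "end": ends[order].astype(np.int64),
            "mapq": mapq[order].astype(np.int64),
            "duplicate": dup_flag[order],
        }
    )

    info = {
        "mark": mark,
        "cell_type": cell_type,
        "replicate": int(replicate),
        "seed": int(seed),
        "depth": int(depth),
        "efficiency": float(efficiency),
        "enrichment": float(enrichment),
        "effective_enrichment": float(eff_enrichment),
        "duplicate_rate": float(duplicate_rate),
        "low_mapq_fraction": float(low_mapq_fraction),
        "insert_mu": float(insert_mu),
        "insert_sigma": float(insert_sigma),
        "insert_clip": list(insert_clip),
        "n_fragments": int(n_total),
        "n_duplicates_injected": int(n_dup),
        "n_low_mapq": int(low.sum()),
        "expected_surviving": _expected_surviving(frags),
    }
    return frags, info


def _draw_unique_fragments(
    rng, n, chrom_names, chrom_lens, probs, win_chrom, win_start, win_end,
    insert_mu, insert_sigma, insert_clip,
):
    """Draw n fragments with distinct (chrom, start, end); resample collisions."""

    def draw(k: int):
        src = rng.choice(len(probs), size=k, p=probs)
        is_bg = src == 0
        mids = np.empty(k, dtype=float)
        ch = np.empty(k, dtype=object)
        # background: chromosome by length, position uniform
        nbg = int(is_bg.sum())
        if nbg:
            ci = rng.choice(len(chrom_names), size=nbg, p=chrom_lens / chrom_lens.sum())
            mids[is_bg] = rng.random(nbg) * chrom_lens[ci]
            ch[is_bg] = np.array(chrom_names, dtype=object)[ci]
        # enriched: truncated normal centered on the promoter window
        pe = ~is_bg
        npe = int(pe.sum())
        if npe:
            wi = src[pe] - 1
            center = 0.5 * (win_start[wi] + win_end[wi])
            sdv = (win_end[wi] - win_start[wi]) / 4.0
            m = rng.normal(center, sdv)
            mids[pe] = np.clip(m, win_start[wi], win_end[wi] - 1)
            ch[pe] = win_chrom[wi]
        lens = np.clip(np.round(rng.normal(insert_mu, insert_sigma, size=k)), *insert_clip).astype(np.int64)
        st = np.round(mids).astype(np.int64) - lens // 2
        size_of = {c: int(s) for c, s in zip(chrom_names, chrom_lens)}
        chrom_cap = np.fromiter((size_of[c] for c in ch), dtype=np.int64, count=k)
        st = np.clip(st, 0, chrom_cap - lens)
        return ch, st, st + lens

    ch, st, en = draw(n)
    for _ in range(60):
        df = pd.DataFrame({"c": ch, "s": st, "e": en})
        dup_mask = df.duplicated(subset=["c", "s", "e"], keep="first").to_numpy()
        k = int(dup_mask.sum())
        if k == 0:
            break
        rc, rs, re = draw(k)
        ch = ch.copy(); st = st.copy(); en = en.copy()
        ch[dup_mask], st[dup_mask], en[dup_mask] = rc, rs, re
    else:
        raise RuntimeError("could not draw coordinate-unique fragments; genome too small for depth")
    return ch, st, en


def _expected_surviving(frags: pd.DataFrame) -> int:
    """Fragments surviving MAPQ≥20 → dedup (MAPQ-max) → insert size 150–500.

    A coordinate key survives iff its best-mapped copy has MAPQ ≥ 20 and its
    insert size is in [150, 500]; computed exactly from the generated records.
    """
    g = frags.groupby(["chrom", "start", "end"], sort=False)["mapq"].max().reset_index()
    size = g["end"] - g["start"]
    return int(((g["mapq"] >= 20) & (size >= 150) & (size <= 500)).sum())


def truth_peaks(truth: TruthManifest, genome: GenomeModel, mark: str, cell_type: str) -> pd.DataFrame:
    """Ground-truth peak intervals: promoter windows of genes carrying the mark.

    Returned in the narrowPeak-style frame used by :mod:`bivalos.peaks`.
    """
    windows = genome.promoter_windows(*PROMOTER_WINDOW)
    marked = truth.marked_genes(mark, cell_type)
    w = windows.loc[windows.index.intersection(marked)]
    df = pd.DataFrame(
        {
            "chrom": w["chrom"].to_numpy(),
            "start": w["start"].to_numpy(),
            "end": w["end"].to_numpy(),
            "name": w.index.to_numpy(),
            "score": 1000.0,
            "strand": ".",
            "signal": 0.0,
            "pvalue": -1.0,
            "qvalue": -1.0,
            "summit": -1,
        }
    )
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Whole-experiment bundle
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """All knobs of one simulated two-cell-type, two-mark experiment."""

    n_genes: int = 400
    chrom_length: int = 8_000_000
    cell_types: tuple[str, str] = ("A2a", "D1")
    marks: tuple[str, ...] = ("H3K4me3", "H3K27me3")
    n_replicates: int = 2
    depth: int = 30_000
    proportions: dict = field(default_factory=lambda: dict(DEFAULT_PROPORTIONS))
    coupling: float = 0.8
    specific_gene_fraction: float = 0.05
    state_means: dict = field(default_factory=lambda: dict(DEFAULT_STATE_MEANS))
    expression_sd: float = 1.0
    n_expression_reps: int = 5
    n_permutations: int = 1000
    enrichment: float = 20.0
    duplicate_rate: float = 0.1
    low_mapq_fraction: float = 0.1
    insert_mu: float = 200.0
    insert_sigma: float = 30.0
    insert_clip: tuple[int, int] = (50, 700)
    efficiency: dict = field(default_factory=lambda: {"A2a": 1.5, "D1": 1.0})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for k in ("cell_types", "marks", "insert_clip"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class SyntheticDataset:
    """A complete simulated experiment plus its ground truth."""

    genome: GenomeModel
    truth: TruthManifest
    expression: ExpressionTable
    fragments: dict[tuple[str, str, int], pd.DataFrame]
    fragment_info: dict[tuple[str, str, int], dict]
    config: SimulationConfig
    seed: int

    def sample_keys(self) -> list[tuple[str, str, int]]:
        return sorted(self.fragments)


def simulate_dataset(config: Optional[SimulationConfig] = None, seed: int = 0) -> SyntheticDataset:
    """Generate a full experiment: annotation, truth, expression, fragments.

    All randomness derives from ``seed`` through named child streams, so a
    dataset regenerates byte-identically from (config, seed).
    """
    cfg = config or SimulationConfig()
    ss = np.random.SeedSequence(seed)
    # fixed number of named child streams keeps seeding stable across configs
    s_genome, s_states, s_expr, s_frag = ss.spawn(4)

    genome = generate_genome_annotation(
        cfg.n_genes, cfg.chrom_length, seed=_child_seed(s_genome)
    )
    truth = assign_promoter_states(
        genome,
        proportions=cfg.proportions,
        coupling=cfg.coupling,
        specific_gene_fraction=cfg.specific_gene_fraction,
        seed=_child_seed(s_states),
        cell_types=cfg.cell_types,
    )
    truth.params.update(
        enrichment=cfg.enrichment,
        duplicate_rate=cfg.duplicate_rate,
        low_mapq_fraction=cfg.low_mapq_fraction,
        insert_mu=cfg.insert_mu,
        insert_sigma=cfg.insert_sigma,
        efficiency=dict(cfg.efficiency),
        depth=cfg.depth,
    )
    truth.seed = seed
    expression = sample_expression(
        truth,
        state_means=cfg.state_means,
        sd=cfg.expression_sd,
        n_reps=cfg.n_expression_reps,
        n_perm=cfg.n_permutations,
        seed=_child_seed(s_expr),
    )

    frag_seeds = s_frag.spawn(len(cfg.marks) * len(cfg.cell_types) * cfg.n_replicates)
    fragments: dict[tuple[str, str, int], pd.DataFrame] = {}
    infos: dict[tuple[str, str, int], dict] = {}
    i = 0
    for mark in cfg.marks:
        for ct in cfg.cell_types:
            for rep in range(1, cfg.n_replicates + 1):
                frags, info = simulate_fragments(
                    truth, genome, mark, ct, replicate=rep,
                    depth=cfg.depth, seed=_child_seed(frag_seeds[i]),
                    enrichment=cfg.enrichment,
                    duplicate_rate=cfg.duplicate_rate,
                    low_mapq_fraction=cfg.low_mapq_fraction,
                    insert_mu=cfg.insert_mu, insert_sigma=cfg.insert_sigma,
                    insert_clip=cfg.insert_clip,
                    efficiency=float(cfg.efficiency.get(ct, 1.0)),
                )
                fragments[(mark, ct, rep)] = frags
                infos[(mark, ct, rep)] = info
                i += 1
    return SyntheticDataset(genome, truth, expression, fragments, infos, cfg, seed)


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def write_dataset(ds: SyntheticDataset, out_dir: Union[str, Path]) -> Path:
    """Write the experiment as a plain-text file bundle.

    Layout: ``genes.bed`` (BED6), ``fragments/<mark>_<cell>_rep<k>.bedpe``,
    ``truth_peaks/<mark>_<cell>.narrowPeak``, ``expression.tsv``,
    ``differential.tsv``, ``manifest.json`` (truth states, patterns, config,
    per-sample counts, seed).
    """
    from .fragments import write_fragments_bedpe
    from .peaks import write_narrowpeak

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_genes_bed(ds.genome, out / "genes.bed")

    (out / "fragments").mkdir(exist_ok=True)
    for (mark, ct, rep), frags in sorted(ds.fragments.items()):
        write_fragments_bedpe(frags, out / "fragments" / f"{mark}_{ct}_rep{rep}.bedpe")

    (out / "truth_peaks").mkdir(exist_ok=True)
    for mark in ds.config.marks:
        for ct in ds.config.cell_types:
            write_narrowpeak(truth_peaks(ds.truth, ds.genome, mark, ct), out / "truth_peaks" / f"{mark}_{ct}.narrowPeak")

    ds.expression.fpkm.rename_axis("gene_id").to_csv(out / "expression.tsv", sep="\t")
    ds.expression.diff.rename_axis("gene_id").to_csv(out / "differential.tsv", sep="\t")

    manifest = {
        "seed": ds.seed,
        "config": ds.config.to_dict(),
        "chrom_sizes": ds.genome.chrom_sizes,
        "cell_types": list(ds.truth.cell_types),
        "states": {c: ds.truth.states[c].to_dict() for c in ds.truth.cell_types},
        "patterns": {
            g: {"pattern": row["pattern"], "expressing": None if pd.isna(row["expressing"]) else row["expressing"]}
            for g, row in ds.truth.patterns.iterrows()
        },
        "truth_params": _jsonable(ds.truth.params),
        "samples": {f"{m}_{c}_rep{r}": info for (m, c, r), info in sorted(ds.fragment_info.items())},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def read_dataset(in_dir: Union[str, Path]) -> SyntheticDataset:
    """Re-read a written dataset bundle.

    Fragment duplicate flags are not serialized in BEDPE, so re-read
    fragments carry ``duplicate=False``; ground-truth counts live in the
    manifest. Expression replicates are likewise manifest-only.
    """
    from .fragments import read_fragments

    d = Path(in_dir)
    with open(d / "manifest.json") as fh:
        manifest = json.load(fh)
    cfg = SimulationConfig.from_dict(manifest["config"])
    genome = read_genes_bed(d / "genes.bed", chrom_sizes=manifest["chrom_sizes"])
    cell_types = tuple(manifest["cell_types"])
    states = pd.DataFrame({c: pd.Series(manifest["states"][c]) for c in cell_types})
    states.index.name = "gene_id"
    states = states.loc[genome.gene_ids]
    patt = pd.DataFrame.from_dict(manifest["patterns"], orient="index").loc[genome.gene_ids]
    patt["expressing"] = patt["expressing"].where(patt["expressing"].notna(), pd.NA)
    truth = TruthManifest(states=states, patterns=patt, cell_types=cell_types,
                          params=manifest["truth_params"], seed=manifest["seed"])

    fpkm = pd.read_csv(d / "expression.tsv", sep="\t", index_col="gene_id")
    diff = pd.read_csv(d / "differential.tsv", sep="\t", index_col="gene_id")
    expression = ExpressionTable(cell_types=cell_types, fpkm=fpkm, diff=diff)

    fragments = {}
    infos = {}
    for name, info in manifest["samples"].items():
        key = (info["mark"], info["cell_type"], int(info["replicate"]))
        fragments[key] = read_fragments(d / "fragments" / f"{name}.bedpe", fmt="bedpe")
        infos[key] = info
    return SyntheticDataset(genome, truth, expression, fragments, infos, cfg, manifest["seed"])
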