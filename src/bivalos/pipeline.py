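"""Configuration-driven orchestration: simulate → QC → normalize → peaks →
bivalency → compare, with a reproducibility manifest.

The pipeline is a fixed acyclic sequence of named stages. Each stage writes
its outputs under the run directory before the next starts, so a failed run
keeps partial outputs; a rerun over the same directory reuses a previously
simulated dataset (the expensive, checkpointed stage) and recomputes the
deterministic downstream stages. All randomness flows from one root seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genome import read_genes_bed
from . import bivalency as bv
from . import compare as cmp_mod
from . import coverage as cov
from . import fragments as fr
from . import peaks as pk
from .synthetic import (
    SimulationConfig,
    SyntheticDataset,
    read_dataset,
    simulate_dataset,
    write_dataset,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "StageFailure", "validate_config", "run_pipeline"]

KNOWN_MARKS = ("H3K4me3", "H3K27me3", "IgG")


class PipelineError(Exception):
    """Configuration problem; nothing was run."""


class StageFailure(Exception):
    def __init__(self, stage: str, hint: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause} ({hint})")
        self.stage = stage
        self.hint = hint
        self.cause = cause


@dataclass
class PipelineConfig:
    """Validated pipeline settings (see :func:`validate_config`)."""

    out_dir: Path
    seed: int = 0
    simulate: bool = True
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    samples: list[dict] = field(default_factory=list)  # path/mark/cell_type/replicate
    genes_bed: Optional[Path] = None
    expression_tsv: Optional[Path] = None
    differential_tsv: Optional[Path] = None
    min_mapq: int = 20
    min_insert: int = 150
    max_insert: int = 500
    bin_size: int = 1000
    peak_bin_size: int = 500
    peak_q: float = 0.01
    peak_min_bins: int = 2
    upstream: int = 2000
    downstream: int = 1000
    constant_max_abs_log2fc: float = 0.25
    constant_min_fpkm: float = 1.0
    specific_min_abs_log2fc: float = 1.0
    specific_max_q: float = 0.05
    signal_min_abs_log2ratio: float = 1.0
    n_boot: int = 500


def validate_config(raw: dict) -> PipelineConfig:
    """Validate a raw (YAML) config dict, collecting every error before raising."""
    errors: list[str] = []
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        errors.append(f"unknown config keys: {sorted(unknown)}")
    d = {k: v for k, v in raw.items() if k in known}

    if "out_dir" not in d:
        errors.append("out_dir is required")
    if isinstance(d.get("simulation"), dict):
        try:
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        except TypeError as exc:
            errors.append(f"bad simulation settings: {exc}")
            d.pop("simulation")

    for key, lo in (
        ("min_mapq", 0), ("min_insert", 0), ("bin_size", 1), ("peak_bin_size", 1),
        ("upstream", 0), ("downstream", 0), ("peak_min_bins", 1), ("n_boot", 0),
    ):
        if key in d and d[key] < lo:
            errors.append(f"{key} must be >= {lo}, got {d[key]}")
    if d.get("min_insert", 150) > d.get("max_insert", 500):
        errors.append("min_insert > max_insert")
    if not 0 < d.get("peak_q", 0.01) <= 1:
        errors.append("peak_q must be in (0, 1]")
    if d.get("upstream", 2000) == 0 and d.get("downstream", 1000) == 0:
        errors.append("promoter window has zero width")

    simulate = d.get("simulate", True)
    if not simulate:
        for k in ("genes_bed", "expression_tsv", "differential_tsv"):
            if not d.get(k):
                errors.append(f"{k} is required when simulate is false")
        samples = d.get("samples") or []
        if not samples:
            errors.append("samples are required when simulate is false")
        for i, s in enumerate(samples):
            for k in ("path", "mark", "cell_type"):
                if k not in s:
                    errors.append(f"samples[{i}]: missing {k!r}")
            if s.get("mark") and s["mark"] not in KNOWN_MARKS:
                logger.warning(
                    "samples[%d]: mark %r is not one of %s; accepted, but bivalency "
                    "uses H3K4me3/H3K27me3 pairs only", i, s["mark"], KNOWN_MARKS,
                )
    if errors:
        raise PipelineError("; ".join(errors))
    for k in ("out_dir", "genes_bed", "expression_tsv", "differential_tsv"):
        if d.get(k):
            d[k] = Path(d[k])
    return PipelineConfig(**d)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return validate_config(raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage, writing outputs and a manifest under ``config.out_dir``.

    Returns the report dict (also written as ``report.md`` and
    ``manifest.json``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "seed": config.seed}

    def stage(name: str, hint: str, fn):
        logger.info("stage: %s", name)
        try:
            return fn()
        except Exception as exc:  # halt with stage name; keep partial outputs
            raise StageFailure(name, hint, exc) from exc

    # -- inputs ------------------------------------------------------------
    def _inputs():
        if config.simulate:
            ds_dir = out / "dataset"
            if (ds_dir / "manifest.json").exists():
                ds = read_dataset(ds_dir)
                if ds.seed == config.seed and ds.config == config.simulation:
                    logger.info("reusing simulated dataset in %s", ds_dir)
                    return ds
            ds = simulate_dataset(config.simulation, seed=config.seed)
            write_dataset(ds, ds_dir)
            return ds
        genome = read_genes_bed(config.genes_bed)
        fpkm = pd.read_csv(config.expression_tsv, sep="\t", index_col=0)
        diff = pd.read_csv(config.differential_tsv, sep="\t", index_col=0)
        frags = {}
        for s in config.samples:
            key = (s["mark"], s["cell_type"], int(s.get("replicate", 1)))
            frags[key] = fr.read_fragments(s["path"], fmt=s.get("format"))
        return genome, fpkm, diff, frags

    data = stage("inputs", "check paths in the config", _inputs)
    if isinstance(data, SyntheticDataset):
        genome = data.genome
        fpkm = data.expression.fpkm
        diff = data.expression.diff
        raw_frags = data.fragments
        cell_types = list(data.truth.cell_types)
    else:
        genome, fpkm, diff, raw_frags = data
        cell_types = sorted({k[1] for k in raw_frags})
    marks = sorted({k[0] for k in raw_frags if k[0] != "IgG"})

    # -- QC ----------------------------------------------------------------
    def _qc():
        filtered, counts = {}, {}
        for key, f in sorted(raw_frags.items()):
            kept, c = fr.apply_retention_filters(
                f, config.min_mapq, config.min_insert, config.max_insert
            )
            filtered[key] = kept
            counts["_".join(map(str, key))] = c
        with open(out / "qc.json", "w") as fh:
            json.dump(counts, fh, indent=1)
        return filtered, counts

    filtered, qc_counts = stage("qc", "inspect fragment files and filter thresholds", _qc)
    report["qc"] = qc_counts

    # -- coverage + correlation -------------------------------------------
    def _coverage():
        tracks = {
            key: cov.cpm_normalize(cov.bin_coverage(f, genome, config.bin_size, sample=key))
            for key, f in sorted(filtered.items())
        }
        labels = ["_".join(map(str, k)) for k in sorted(tracks)]
        corr = cov.correlation_matrix([tracks[k] for k in sorted(tracks)], labels=labels)
        corr.to_csv(out / "correlation.tsv", sep="\t")
        return tracks, corr

    tracks, corr = stage("coverage", "need >= 2 samples with non-zero coverage", _coverage)
    report["correlation"] = corr.round(4).to_dict()

    # -- peaks + FRiP ------------------------------------------------------
    def _peaks():
        peak_sets, frips = {}, {}
        for mark in marks:
            for ct in cell_types:
                pooled = pd.concat(
                    [filtered[k] for k in filtered if k[0] == mark and k[1] == ct],
                    ignore_index=True,
                )
                if len(pooled) == 0:
                    continue
                track = cov.bin_coverage(pooled, genome, config.peak_bin_size)
                ps = pk.call_peaks_simple(track, config.peak_q, config.peak_min_bins, sample=(mark, ct))
                peak_sets[(mark, ct)] = ps
                pk.write_narrowpeak(ps, out / f"peaks_{mark}_{ct}.narrowPeak")
                frips[f"{mark}_{ct}"] = pk.frip(pooled, ps) if len(ps) else 0.0
        with open(out / "frip.json", "w") as fh:
            json.dump(frips, fh, indent=1)
        return peak_sets, frips

    peak_sets, frips = stage("peaks", "no fragments survived filtering for a sample", _peaks)
    report["frip"] = frips

    # -- invariant-gene anchoring -----------------------------------------
    def _normalize():
        cells = fpkm.columns[:2] if not isinstance(data, SyntheticDataset) else cell_types
        const = cov.select_constant_genes(
            fpkm[cells[0]], fpkm[cells[1]],
            config.constant_max_abs_log2fc, config.constant_min_fpkm,
        )
        anchored = {}
        for mark in marks:
            keys = [k for k in sorted(tracks) if k[0] == mark]
            anch = cov.quantile_anchor(
                [tracks[k] for k in keys], genome, const, config.upstream, config.downstream
            )
            anchored.update(dict(zip(keys, anch)))
        return const, anchored

    const_genes, anchored = stage(
        "normalize", "loosen constant-gene thresholds if no genes qualify", _normalize
    )
    report["n_constant_genes"] = len(const_genes)

    # -- bivalency ---------------------------------------------------------
    def _bivalency():
        states, mei, expr_stats = {}, {}, {}
        for ct in cell_types:
            k4 = peak_sets.get(("H3K4me3", ct))
            k27 = peak_sets.get(("H3K27me3", ct))
            if k4 is None or k27 is None:
                logger.warning("bivalency: missing a mark for %s; skipped", ct)
                continue
            st = bv.classify_promoter_states(
                k4, k27, genome, config.upstream, config.downstream, cell_type=ct
            )
            states[ct] = st
            st.states.rename_axis("gene_id").to_csv(out / f"states_{ct}.tsv", sep="\t")
            mei[ct] = bv.mutually_exclusive_index(st, n_boot=config.n_boot, seed=config.seed).to_dict()
            if ct in fpkm.columns:
                expr_stats[ct] = bv.compare_expression_by_state(st, fpkm[ct]).to_dict("records")
        overlap = None
        if len(states) == 2:
            a, b = (states[c] for c in cell_types[:2])
            overlap = bv.bivalent_overlap(a, b)
        with open(out / "mei.json", "w") as fh:
            json.dump(mei, fh, indent=1)
        return states, mei, expr_stats, overlap

    states, mei, expr_stats, overlap = stage("bivalency", "need peaks for both marks", _bivalency)
    report["mutually_exclusive_index"] = mei
    report["expression_by_state"] = expr_stats
    report["bivalent_overlap"] = overlap
    report["state_counts"] = {
        ct: st.counts().to_dict() for ct, st in states.items()
    }

    # -- cell-type comparison ---------------------------------------------
    def _compare():
        if len(cell_types) < 2 or not marks:
            return None
        ct_a, ct_b = cell_types[:2]
        a_spec, b_spec = cmp_mod.select_specific_genes(
            diff, config.specific_min_abs_log2fc, config.specific_max_q
        )
        genes_of_interest = a_spec.union(b_spec)
        if len(genes_of_interest) == 0:
            return {"n_specific": 0}
        # pooled anchored track per mark × cell type (mean of replicates)
        floor_tracks = []
        sig = {}
        for mark in marks:
            for ct in (ct_a, ct_b):
                keys = [k for k in anchored if k[0] == mark and k[1] == ct]
                if not keys:
                    return {"n_specific": int(len(genes_of_interest)), "note": f"no {mark} track for {ct}"}
                merged = _mean_tracks([anchored[k] for k in keys])
                sig[(mark, ct)] = merged
                floor_tracks.append(merged)
        floor = cmp_mod.signal_floor(floor_tracks)
        table = cmp_mod.promoter_signal_table(
            {k: v for k, v in sig.items()}, genome, list(genes_of_interest),
            config.upstream, config.downstream,
        )
        calls = {}
        for mark in marks:
            calls[mark] = cmp_mod.differential_mark_signal(
                table[(mark, ct_a)], table[(mark, ct_b)],
                config.signal_min_abs_log2ratio, floor,
            )
        expressing = pd.Series(
            ["A" if g in a_spec else "B" for g in genes_of_interest], index=genes_of_interest
        )
        patterns = cmp_mod.classify_patterns(
            calls["H3K4me3"]["call"] if "H3K4me3" in calls else None,
            calls["H3K27me3"]["call"] if "H3K27me3" in calls else None,
            expressing,
        ) if {"H3K4me3", "H3K27me3"} <= set(calls) else pd.Series(dtype=object)
        ptab = pd.DataFrame({"expressing": expressing, "pattern": patterns})
        for mark in calls:
            ptab[f"{mark}_log2_ratio"] = calls[mark]["log2_ratio"]
            ptab[f"{mark}_call"] = calls[mark]["call"]
        ptab.rename_axis("gene_id").to_csv(out / "patterns.tsv", sep="\t")
        return {
            "n_specific": int(len(genes_of_interest)),
            "n_a_specific": int(len(a_spec)),
            "n_b_specific": int(len(b_spec)),
            "pattern_counts": patterns.value_counts().to_dict() if len(patterns) else {},
            "signal_floor": floor,
        }

    report["compare"] = stage("compare", "needs anchored tracks for both marks", _compare)

    # -- report ------------------------------------------------------------
    def _report():
        with open(out / "manifest.json", "w") as fh:
            json.dump(_jsonable({
                "version": __version__,
                "seed": config.seed,
                "config": {k: str(v) if isinstance(v, Path) else v
                           for k, v in dataclasses.asdict(config).items()},
            }), fh, indent=1)
        (out / "report.md").write_text(_render_report(report))
        return True

    stage("report", "output directory not writable", _report)
    return report


def _mean_tracks(tracks):
    """Average several tracks on the same grid (state preserved)."""
    first = tracks[0]
    vals = {
        c: np.mean([t.values[c] for t in tracks], axis=0) for c in first.values
    }
    return dataclasses.replace(first, values=vals)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _render_report(report: dict) -> str:
    lines = [f"# bivalos pipeline report", "", f"seed: {report['seed']}", ""]
    lines += ["## Fragment QC", "", "| sample | input | mapq | dedup | size |", "|---|---|---|---|---|"]
    for s, c in report.get("qc", {}).items():
        lines.append(f"| {s} | {c['input']} | {c['mapq']} | {c['dedup']} | {c['size']} |")
    lines += ["", "## FRiP", ""]
    for s, v in report.get("frip", {}).items():
        lines.append(f"- {s}: {v:.3f}")
    lines += ["", "## Promoter states", ""]
    for ct, counts in report.get("state_counts", {}).items():
        lines.append(f"- {ct}: " + ", ".join(f"{k}={v}" for k, v in counts.items()))
    lines += ["", "## Mutually exclusive index", ""]
    for ct, m in report.get("mutually_exclusive_index", {}).items():
        idx = m.get("index")
        ci = (m.get("ci_low"), m.get("ci_high"))
        lines.append(
            f"- {ct}: index = {idx if idx is None else round(idx, 3)}"
            + (f" (95% CI {ci[0]:.3f}-{ci[1]:.3f})" if ci[0] is not None else "")
        )
    if report.get("bivalent_overlap"):
        ov = report["bivalent_overlap"]
        lines += ["", f"Bivalent domains: shared={ov['shared']}, only_a={ov['only_a']}, only_b={ov['only_b']}"]
    comp = report.get("compare") or {}
    if comp:
        lines += ["", "## Cell-type-specific genes", "",
                  f"- specific genes: {comp.get('n_specific', 0)}"]
        for pat, n in (comp.get("pattern_counts") or {}).items():
            lines.append(f"- {pat}: {n}")
    lines.append("")
    return "\n".join(lines)
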