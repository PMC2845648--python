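"""End-to-end analysis: annotate, stratify, bin, fit, bootstrap, compare.

The report is a plain JSON-serialisable dict; identical inputs, config
and seed yield byte-identical serialised reports.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from . import __version__
from .binstats import (
    bin_fst_profile,
    correlation_significance,
    fit_linear,
    fit_quadratic,
    format_pvalue,
    make_bins,
    single_snp_analysis,
)
from .genmap import ChromosomeStructure, GeneticMap, annotate_snps
from .mbb import bootstrap_framework, compare_analyses
from .panel import SnpPanel

__all__ = ["AnalysisConfig", "stratify", "run_analysis", "report_json"]

MAF_LABELS = "ABCDEFGH"


@dataclass
class AnalysisConfig:
    """Knobs of the full analysis (defaults mirror the standard run)."""

    window_bp: int = 3_000_000
    extend_mask_bp: int = 0
    bins: int = 10
    bootstraps: int = 1_000
    block_len: int = 200
    seed: int = 0
    model: str = "linear"
    maf_edges: Tuple[float, ...] = (0.125, 0.25, 0.375)
    pops: Optional[List[str]] = None
    maf_strata: bool = True
    coding_strata: bool = True

    def __post_init__(self) -> None:
        if min(self.window_bp, self.bins, self.bootstraps, self.block_len) <= 0:
            raise ValueError("window_bp, bins, bootstraps and block_len must be positive")
        if self.extend_mask_bp < 0:
            raise ValueError("extend_mask_bp must be >= 0")
        edges = tuple(self.maf_edges)
        if any(not (0 < e <= 0.5) for e in edges) or list(edges) != sorted(set(edges)):
            raise ValueError("maf_edges must be strictly ascending within (0, 0.5]")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "AnalysisConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "maf_edges" in data:
            data["maf_edges"] = tuple(data["maf_edges"])
        return cls(**data)

    def as_dict(self) -> dict:
        d = asdict(self)
        d["maf_edges"] = list(self.maf_edges)
        return d


def _merge_intervals(ivs: List[Tuple[int, int]]) -> Tuple[np.ndarray, np.ndarray]:
    for s, e in ivs:
        if s > e or s < 1:
            raise ValueError(f"malformed interval ({s}, {e})")
    ivs = sorted(ivs)
    merged: List[Tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return np.array([s for s, _ in merged]), np.array([e for _, e in merged])


def stratify(
    panel: SnpPanel,
    coding_intervals: Optional[Dict[str, List[Tuple[int, int]]]] = None,
    maf_edges: Sequence[float] = (0.125, 0.25, 0.375),
) -> Dict[str, np.ndarray]:
    """Label SNPs coding/non-coding and by MAF category.

    Returns boolean masks keyed "coding", "noncoding", and "maf_A" ...;
    MAF categories are left-open/right-closed, with the first category
    including its upper edge (MAF <= edge_1) and the last open-ended up
    to 0.5.  When ``coding_intervals`` (1-based closed, per chromosome)
    are given, the panel's coding flags are (re)assigned from them.
    """
    if coding_intervals is not None:
        flag = np.zeros(len(panel), dtype=bool)
        for c in set(str(x) for x in panel.chrom):
            if c not in coding_intervals or not coding_intervals[c]:
                continue
            starts, ends = _merge_intervals(coding_intervals[c])
            mask = panel.chrom.astype(str) == c
            j = np.searchsorted(starts, panel.pos[mask], side="right") - 1
            hit = (j >= 0) & (panel.pos[mask] <= ends[np.clip(j, 0, None)])
            flag[np.flatnonzero(mask)] = hit
        panel.coding = flag
    strata: Dict[str, np.ndarray] = {
        "coding": panel.coding.copy(),
        "noncoding": ~panel.coding,
    }
    maf = panel.maf()
    edges = [0.0] + list(maf_edges) + [0.5]
    for i in range(len(edges) - 1):
        lo, hi = edges[i], edges[i + 1]
        mask = (maf > lo) & (maf <= hi) if i > 0 else (maf <= hi)
        strata[f"maf_{MAF_LABELS[i]}"] = mask
    return strata


def _digest(obj) -> str:
    h = hashlib.sha256()
    if isinstance(obj, (str, Path)):
        with open(obj, "rb") as fh:
            for chunk in iter(lambda: fh.read(1 << 20), b""):
                h.update(chunk)
    else:
        h.update(repr(obj).encode())
    return h.hexdigest()[:16]


def _pair_key(a: str, b: str) -> str:
    return f"{a}|{b}"


def _naive_block(panel: SnpPanel, K: int, pops, mode: str, model: str) -> dict:
    bins = make_bins(panel.rho, K, chrom=panel.chrom, pos=panel.pos)
    profile = bin_fst_profile(panel, bins, pops=pops, mode=mode)
    fit = fit_linear(profile) if model == "linear" else fit_quadratic(profile)
    p_r = correlation_significance(fit.r, K) if abs(fit.r) < 1 else 0.0
    return {
        "profile": [[x, y] for x, y in profile],
        "bin_counts": bins.counts.tolist(),
        "fit": fit.as_dict(),
        "r_pvalue": p_r,
        "r_pvalue_text": format_pvalue(p_r),
    }


def _bootstrap_block(panel, K, pops, mode, model, config, seed_sequence) -> dict:
    bins = make_bins(panel.rho, K, chrom=panel.chrom, pos=panel.pos)
    # small strata: cap the block length so each replicate still draws a
    # reasonable number of blocks (>= ~4 per bin), else the bootstrap
    # degenerates to resampling the panel whole
    block_len = min(config.block_len, max(1, len(panel) // (4 * K)))
    summary = bootstrap_framework(
        panel,
        bins,
        B=config.bootstraps,
        pops=pops,
        mode=mode,
        model=model,
        block_len=block_len,
        seed_sequence=seed_sequence,
    )
    return summary.as_dict()


def run_analysis(
    gmap: GeneticMap,
    structure: ChromosomeStructure,
    panel: SnpPanel,
    config: AnalysisConfig,
    coding_intervals: Optional[Dict[str, List[Tuple[int, int]]]] = None,
    provenance: Optional[dict] = None,
) -> dict:
    """Run the full analysis and return the report dict.

    Stages: recombination-rate annotation -> stratification -> per-analysis
    binning, naive fits and bootstrap summaries (global, each population
    pair, coding and non-coding) -> naive fits for MAF strata ->
    single-SNP analyses -> between-analysis comparisons (one-sided
    coding vs non-coding on b0/b1/b1-over-b0; two-sided pair vs pair on
    b1-over-b0).
    """
    pops = list(config.pops) if config.pops else list(panel.pops)
    annotated, filter_log = annotate_snps(
        panel, gmap, structure, window_bp=config.window_bp, extend_mask_bp=config.extend_mask_bp
    )
    if len(annotated) < config.bins:
        raise RuntimeError("annotate stage left fewer SNPs than bins")
    strata = stratify(annotated, coding_intervals, maf_edges=config.maf_edges)

    # one stable seed substream per analysis, derived from the user seed
    root = np.random.SeedSequence(config.seed)
    analysis_names = ["global"] + [_pair_key(a, b) for a, b in combinations(pops, 2)]
    if config.coding_strata:
        analysis_names += ["coding", "noncoding"]
    streams = dict(zip(analysis_names, root.spawn(len(analysis_names))))

    analyses: Dict[str, dict] = {}

    def analyse(name: str, sub: SnpPanel, sub_pops, mode: str) -> None:
        analyses[name] = {
            "n_snps": len(sub),
            "naive": _naive_block(sub, config.bins, sub_pops, mode, config.model),
            "bootstrap": _bootstrap_block(
                sub, config.bins, sub_pops, mode, config.model, config, streams[name]
            ),
        }

    analyse("global", annotated, pops, "global")
    for a, b in combinations(pops, 2):
        analyse(_pair_key(a, b), annotated, [a, b], "pairwise")
    if config.coding_strata:
        for name in ("coding", "noncoding"):
            sub = annotated.take(strata[name])
            # a stratum too thin to fill every bin reliably is skipped
            if len(sub) >= 30 * config.bins:
                analyse(name, sub, pops, "global")

    maf_blocks: Dict[str, dict] = {}
    if config.maf_strata:
        for name, mask in strata.items():
            if not name.startswith("maf_"):
                continue
            sub = annotated.take(mask)
            if len(sub) >= config.bins:
                maf_blocks[name] = {
                    "n_snps": len(sub),
                    "naive": _naive_block(sub, config.bins, pops, "global", config.model),
                }

    single_snp = {"global": single_snp_analysis(annotated, pops, model=config.model).as_dict()}
    for a, b in combinations(pops, 2):
        single_snp[_pair_key(a, b)] = single_snp_analysis(
            annotated, [a, b], model=config.model
        ).as_dict()

    comparisons: Dict[str, dict] = {}
    if config.coding_strata and "coding" in analyses and "noncoding" in analyses:
        cvn = {}
        for stat, alternative in (
            ("b0", "greater"),  # coding intercept larger
            ("b1", "less"),  # coding slope steeper (more negative)
            ("b1_over_b0", "less"),
        ):
            a_ = analyses["coding"]["bootstrap"]["stats"][stat]
            b_ = analyses["noncoding"]["bootstrap"]["stats"][stat]
            if a_["se"] <= 0 or b_["se"] <= 0:
                continue
            cvn[stat] = {
                "mean_coding": a_["mean"],
                "se_coding": a_["se"],
                "mean_noncoding": b_["mean"],
                "se_noncoding": b_["se"],
                "alternative": alternative,
                "p": compare_analyses(a_["mean"], a_["se"], b_["mean"], b_["se"], alternative),
            }
        comparisons["coding_vs_noncoding"] = cvn
    pair_names = [_pair_key(a, b) for a, b in combinations(pops, 2)]
    for pa, pb in combinations(pair_names, 2):
        a_ = analyses[pa]["bootstrap"]["stats"]["b1_over_b0"]
        b_ = analyses[pb]["bootstrap"]["stats"]["b1_over_b0"]
        comparisons[f"{pa}_vs_{pb}"] = {
            "statistic": "b1_over_b0",
            "alternative": "two-sided",
            "p": compare_analyses(a_["mean"], a_["se"], b_["mean"], b_["se"], "two-sided"),
        }

    return {
        "config": config.as_dict(),
        "filter_log": {k: int(v) for k, v in sorted(filter_log.items())},
        "n_snps_input": len(panel),
        "n_snps_retained": len(annotated),
        "analyses": analyses,
        "maf_strata": maf_blocks,
        "single_snp": single_snp,
        "comparisons": comparisons,
        "provenance": {
            "version": __version__,
            "inputs": provenance or {},
        },
    }


def report_json(report: dict) -> str:
    """Deterministic JSON serialisation of a report."""
    return json.dumps(report, sort_keys=True, indent=2) + "\n"
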