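"""Allele-frequency differentiation (FST) estimators.

The primary estimator works per SNP from sample allele frequencies
p̂ᵢ = altᵢ/nᵢ of two populations:

    N = (p̂₁ − p̂₂)² − p̂₁(1 − p̂₁)/(n₁ − 1) − p̂₂(1 − p̂₂)/(n₂ − 1)
    D = p̂₁(1 − p̂₂) + p̂₂(1 − p̂₁)

and aggregates over SNPs as a ratio of sums, ΣN/ΣD.  Global
differentiation across more than two populations is the unweighted mean
of the pairwise ratio-of-sums values.  A two-population Weir–Cockerham
theta is provided as an independent cross-check.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np

from .panel import SnpPanel, SnpRecord, folded_maf

__all__ = [
    "pair_fst_components",
    "fst_ratio_of_sums",
    "per_snp_fst",
    "panel_pair_components",
    "pairwise_fst",
    "global_fst",
    "per_snp_global_fst",
    "weir_cockerham_fst",
    "read_counts_table",
    "read_vcf",
]


def pair_fst_components(alt1, n1, alt2, n2) -> Tuple[np.ndarray, np.ndarray]:
    """Per-SNP numerator and denominator of the pairwise FST estimator.

    Accepts scalars or aligned arrays.  Requires n >= 2 in both
    populations (the sampling-variance correction divides by n - 1).
    The numerator may be negative; always N <= D.
    """
    alt1, n1 = np.asarray(alt1, dtype=float), np.asarray(n1, dtype=float)
    alt2, n2 = np.asarray(alt2, dtype=float), np.asarray(n2, dtype=float)
    if np.any(n1 < 2) or np.any(n2 < 2):
        raise ValueError("pair_fst_components requires n >= 2 in both populations")
    p1, p2 = alt1 / n1, alt2 / n2
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def _split_components(components, den) -> Tuple[np.ndarray, np.ndarray]:
    if den is not None:
        return np.asarray(components, dtype=float), np.asarray(den, dtype=float)
    arr = np.asarray(list(components), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("expected a sequence of (N, D) pairs")
    return arr[:, 0], arr[:, 1]


def fst_ratio_of_sums(components, den=None) -> float:
    """Ratio-of-sums FST, ΣN/ΣD.

    Call either with a sequence of (N, D) pairs or with two aligned
    arrays.  ΣD must be positive ("no informative SNPs" otherwise).
    """
    num, den = _split_components(components, den)
    sd = den.sum()
    if sd <= 0:
        raise ValueError("no informative SNPs (sum of denominators is not positive)")
    return float(num.sum() / sd)


def per_snp_fst(components, den=None) -> Union[float, np.ndarray]:
    """Per-SNP FST value N/D; NaN where D == 0 (undefined, not an error)."""
    num, den = _split_components(np.atleast_1d(components), np.atleast_1d(den) if den is not None else None)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / den, np.nan)
    if out.size == 1:
        return float(out[0])
    return out


def panel_pair_components(panel: SnpPanel, pop1: str, pop2: str) -> Tuple[np.ndarray, np.ndarray]:
    i, j = panel.pop_index(pop1), panel.pop_index(pop2)
    return pair_fst_components(panel.alt[:, i], panel.n[:, i], panel.alt[:, j], panel.n[:, j])


def pairwise_fst(panel: SnpPanel, pop1: str, pop2: str) -> float:
    return fst_ratio_of_sums(*panel_pair_components(panel, pop1, pop2))


def _pairs(pops: Sequence[str]) -> List[Tuple[str, str]]:
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    return list(combinations(pops, 2))


def global_fst(panel: SnpPanel, pops: Optional[Sequence[str]] = None) -> float:
    """Unweighted mean of the pairwise ratio-of-sums FST over all pairs."""
    pops = list(pops) if pops is not None else list(panel.pops)
    return float(np.mean([pairwise_fst(panel, a, b) for a, b in _pairs(pops)]))


def per_snp_global_fst(panel: SnpPanel, pops: Optional[Sequence[str]] = None) -> np.ndarray:
    """Per-SNP global FST: unweighted mean of defined pairwise N/D values.

    NaN for SNPs where every pair has D == 0.
    """
    pops = list(pops) if pops is not None else list(panel.pops)
    vals = np.column_stack(
        [per_snp_fst(*panel_pair_components(panel, a, b)) for a, b in _pairs(pops)]
    )
    vals = np.atleast_2d(vals)
    defined = ~np.isnan(vals)
    n_def = defined.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(defined, vals, 0.0).sum(axis=1) / n_def
    return np.where(n_def > 0, out, np.nan)


def weir_cockerham_fst(panel: SnpPanel, pops: Optional[Sequence[str]] = None) -> float:
    """Weir–Cockerham (1984) theta from allele counts, ratio-of-sums over SNPs.

    Two populations per estimate (the ANOVA form for allele-frequency
    data); for more than two populations the unweighted mean over pairs
    is returned, mirroring :func:`global_fst`.  Used as an independent
    cross-check of the primary estimator.
    """
    pops = list(pops) if pops is not None else list(panel.pops)
    if len(pops) > 2:
        return float(np.mean([weir_cockerham_fst(panel, [a, b]) for a, b in _pairs(pops)]))
    i, j = panel.pop_index(pops[0]), panel.pop_index(pops[1])
    n1, n2 = panel.n[:, i].astype(float), panel.n[:, j].astype(float)
    if np.any(n1 < 2) or np.any(n2 < 2):
        raise ValueError("weir_cockerham_fst requires n >= 2 in both populations")
    p1, p2 = panel.alt[:, i] / n1, panel.alt[:, j] / n2
    ntot = n1 + n2
    pbar = (n1 * p1 + n2 * p2) / ntot
    msp = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2  # r - 1 = 1
    msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (ntot - 2)
    nc = ntot - (n1**2 + n2**2) / ntot
    num = msp - msg
    den = msp + (nc - 1) * msg
    sd = den.sum()
    if sd <= 0:
        raise ValueError("no informative SNPs (sum of denominators is not positive)")
    return float(num.sum() / sd)


# ---------------------------------------------------------------------------
# readers


def read_counts_table(path) -> SnpPanel:
    """Read the long-format allele-count table.

    Tab-separated columns: snp_id, chrom, pos, pop, n_chrom, alt_count,
    coding_flag (0/1).  One row per SNP x population; every SNP must
    cover the same set of populations.
    """
    import pandas as pd

    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        names=["snp_id", "chrom", "pos", "pop", "n_chrom", "alt_count", "coding_flag"],
        dtype={"snp_id": str, "chrom": str, "pop": str},
        header=None,
        skiprows=_count_header_rows(path),
    )
    pops = list(pd.unique(df["pop"]))
    wide_alt = df.pivot_table(index="snp_id", columns="pop", values="alt_count", sort=False)
    wide_n = df.pivot_table(index="snp_id", columns="pop", values="n_chrom", sort=False)
    if wide_alt.isna().any().any() or wide_n.isna().any().any():
        raise ValueError(f"{path}: not every SNP has counts for every population")
    meta = df.drop_duplicates("snp_id").set_index("snp_id")
    ids = list(wide_alt.index)
    meta = meta.loc[ids]
    return SnpPanel(
        ids=ids,
        chrom=meta["chrom"].to_numpy(),
        pos=meta["pos"].astype(np.int64).to_numpy(),
        pops=pops,
        alt=wide_alt[pops].to_numpy(dtype=np.int64),
        n=wide_n[pops].to_numpy(dtype=np.int64),
        coding=meta["coding_flag"].astype(int).to_numpy().astype(bool),
    ).sort_genomic()


def _count_header_rows(path) -> int:
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            try:
                int(fields[2])
                return 0
            except (ValueError, IndexError):
                return 1
    return 0


def read_vcf(path, pop_samples: dict) -> SnpPanel:
    """Read biallelic SNVs from a VCF into a panel.

    ``pop_samples`` maps population id to a list of sample names (or a
    path to a one-name-per-line file).  Allele counts are derived from
    genotypes; missing alleles are excluded from n.  Non-SNV and
    multi-allelic records are skipped.
    """
    from cyvcf2 import VCF

    pop_samples = {
        pop: (_read_sample_list(v) if isinstance(v, (str,)) else list(v))
        for pop, v in pop_samples.items()
    }
    vcf = VCF(str(path))
    sample_idx = {s: k for k, s in enumerate(vcf.samples)}
    pops = list(pop_samples)
    pop_cols = {}
    for pop, samples in pop_samples.items():
        missing = [s for s in samples if s not in sample_idx]
        if missing:
            raise ValueError(f"samples not in VCF for population {pop}: {missing}")
        pop_cols[pop] = [sample_idx[s] for s in samples]

    ids, chroms, poss, alts, ns = [], [], [], [], []
    for var in vcf:
        if not var.is_snp or len(var.ALT) != 1:
            continue
        gts = var.genotype.array()  # (n_samples, ploidy + 1); last col is phasing
        alleles = gts[:, :-1]
        row_alt, row_n = [], []
        for pop in pops:
            sub = alleles[pop_cols[pop]]
            called = sub >= 0
            row_alt.append(int((sub == 1).sum()))
            row_n.append(int(called.sum()))
        ids.append(var.ID if var.ID else f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
        alts.append(row_alt)
        ns.append(row_n)
    return SnpPanel(
        ids=ids,
        chrom=chroms,
        pos=poss,
        pops=pops,
        alt=np.asarray(alts, dtype=np.int64).reshape(len(ids), len(pops)),
        n=np.asarray(ns, dtype=np.int64).reshape(len(ids), len(pops)),
    ).sort_genomic()


def _read_sample_list(path) -> List[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip() and not line.startswith("#")]
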