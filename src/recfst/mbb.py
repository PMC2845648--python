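"""Moving-block-bootstrap (MBB) inference.

SNPs in genomic order are resampled as overlapping blocks of L
consecutive SNPs (with replacement), preserving short-range correlation
due to LD.  Each replicate regroups the resampled SNPs by their original
recombination-rate bin, recomputes per-bin FST and median rates, refits
the regression, and records the statistics; the standard deviation
across replicates is reported as the standard error and feeds z-tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .binstats import BinningScheme, RegressionFit, fit_linear, fit_quadratic
from .fst import panel_pair_components
from .panel import SnpPanel

__all__ = [
    "BlockScheme",
    "BootstrapSummary",
    "make_blocks",
    "resample_indices",
    "bootstrap_framework",
    "z_test",
    "compare_analyses",
]


@dataclass
class BlockScheme:
    """Overlapping, non-circular blocks of L consecutive SNPs out of n."""

    n: int
    L: int

    def __post_init__(self) -> None:
        if not (1 <= self.L <= self.n):
            raise ValueError(f"block length {self.L} outside [1, n={self.n}]")

    @property
    def n_starts(self) -> int:
        return self.n - self.L + 1

    @property
    def blocks_per_replicate(self) -> int:
        return -(-self.n // self.L)  # ceil(n / L)


def make_blocks(n: int, L: int) -> BlockScheme:
    return BlockScheme(n=n, L=L)


def resample_indices(scheme: BlockScheme, rng: np.random.Generator) -> np.ndarray:
    """One MBB resample: ceil(n/L) uniform block starts, concatenated and
    truncated to length n.  Deterministic given the generator state."""
    nb = scheme.blocks_per_replicate
    starts = rng.integers(0, scheme.n_starts, size=nb)
    idx = (starts[:, None] + np.arange(scheme.L)[None, :]).ravel()
    return idx[: scheme.n]


def z_test(mean: float, se: float, alternative: str = "two-sided") -> float:
    """Normal-reference test of a bootstrap mean against zero.

    ``alternative``: "two-sided" gives 2*Phi(-|z|); "greater"/"less"
    give the one-sided tail for the stated direction of the alternative.
    """
    if se <= 0:
        raise ValueError("standard error must be positive")
    z = mean / se
    if alternative == "two-sided":
        return float(2 * sps.norm.sf(abs(z)))
    if alternative == "greater":
        return float(sps.norm.sf(z))
    if alternative == "less":
        return float(sps.norm.cdf(z))
    raise ValueError(f"unknown alternative {alternative!r}")


def compare_analyses(
    mean_a: float,
    se_a: float,
    mean_b: float,
    se_b: float,
    alternative: str = "two-sided",
) -> float:
    """z-test on the difference of two independent bootstrap estimates.

    z = (mean_a - mean_b) / sqrt(se_a^2 + se_b^2); ``alternative`` as in
    :func:`z_test` ("less" tests whether A is below B, e.g. a steeper
    negative slope).
    """
    if se_a <= 0 or se_b <= 0:
        raise ValueError("standard errors must be positive")
    diff_se = float(np.hypot(se_a, se_b))
    return z_test(mean_a - mean_b, diff_se, alternative)


@dataclass
class BootstrapSummary:
    """Per-statistic replicate values with mean/SD summaries."""

    B: int
    seed: Optional[int]
    L: int
    stats: Dict[str, np.ndarray]
    bin_fst: np.ndarray  # (B, K)
    n_rejected: int = 0

    def mean(self, name: str) -> float:
        return float(np.mean(self.stats[name]))

    def se(self, name: str) -> float:
        return float(np.std(self.stats[name], ddof=1))

    def p_two_sided(self, name: str) -> float:
        return z_test(self.mean(name), self.se(name), "two-sided")

    def bin_fst_se(self) -> np.ndarray:
        return np.std(self.bin_fst, axis=0, ddof=1)

    def as_dict(self) -> dict:
        out = {"B": self.B, "L": self.L, "n_rejected": self.n_rejected, "stats": {}}
        for name in self.stats:
            se = self.se(name)
            entry = {"mean": self.mean(name), "se": se}
            if se > 0:
                entry["p_two_sided"] = self.p_two_sided(name)
            out["stats"][name] = entry
        return out


def bootstrap_framework(
    panel: SnpPanel,
    bins: BinningScheme,
    B: int,
    pops: Optional[Sequence[str]] = None,
    mode: str = "global",
    model: str = "linear",
    block_len: int = 200,
    seed: Optional[int] = None,
    seed_sequence: Optional[np.random.SeedSequence] = None,
    max_reject_frac: float = 0.1,
) -> BootstrapSummary:
    """Run B MBB replicates of the binned FST-vs-recombination analysis.

    Bin membership is fixed at the original assignment and carried by
    each SNP into the resamples; per-bin FST and per-bin median rho are
    recomputed from the resampled SNPs.  A replicate that leaves a bin
    empty (or uninformative) is rejected and redrawn; more than
    ``max_reject_frac * B`` rejections is a hard error.

    The user seed spawns one independent RNG substream per replicate, so
    results do not depend on evaluation order.
    """
    if B < 2:
        raise ValueError("need B >= 2 replicates")
    if panel.rho is None:
        raise ValueError("panel is not annotated with recombination rates")
    if len(bins) != len(panel):
        raise ValueError("binning scheme and panel have different lengths")
    pops = list(pops) if pops is not None else list(panel.pops)
    from itertools import combinations

    if mode == "global":
        pairs = list(combinations(pops, 2))
    elif mode == "pairwise":
        if len(pops) != 2:
            raise ValueError("pairwise mode needs exactly two populations")
        pairs = [tuple(pops)]
    else:
        raise ValueError(f"unknown mode {mode!r}")

    n = len(panel)
    K = bins.K
    L = min(block_len, n)
    scheme = BlockScheme(n=n, L=L)
    comps = [panel_pair_components(panel, a, b) for a, b in pairs]
    num = np.stack([c[0] for c in comps])  # (n_pairs, n)
    den = np.stack([c[1] for c in comps])
    rho = panel.rho
    bin_idx = bins.bin_index
    fit = fit_linear if model == "linear" else fit_quadratic
    if model not in ("linear", "quadratic"):
        raise ValueError(f"unknown model {model!r}")

    names = ["b0", "b1", "r", "t", "b1_over_b0"]
    if model == "quadratic":
        names += ["b2", "t_b2"]
    out = {name: np.empty(B) for name in names}
    bin_fst = np.empty((B, K))

    ss = seed_sequence if seed_sequence is not None else np.random.SeedSequence(seed)
    max_reject = int(np.ceil(max_reject_frac * B))
    n_rejected = 0
    b = 0
    while b < B:
        rng = np.random.default_rng(ss.spawn(1)[0])
        idx = resample_indices(scheme, rng)
        bsel = bin_idx[idx]
        counts = np.bincount(bsel, minlength=K)
        sums_n = np.vstack([np.bincount(bsel, weights=nm[idx], minlength=K) for nm in num])
        sums_d = np.vstack([np.bincount(bsel, weights=dn[idx], minlength=K) for dn in den])
        if np.any(counts == 0) or np.any(sums_d <= 0):
            n_rejected += 1
            if n_rejected > max_reject:
                raise RuntimeError(
                    f"more than {max_reject_frac:.0%} of replicates left a bin empty "
                    f"({n_rejected} rejections in {b} accepted replicates)"
                )
            continue
        fst_bins = np.mean(sums_n / sums_d, axis=0)
        rho_r = rho[idx]
        med = np.empty(K)
        for k in range(K):
            med[k] = np.median(rho_r[bsel == k])
        f = fit(list(zip(med, fst_bins)))
        out["b0"][b] = f.b0
        out["b1"][b] = f.b1
        out["r"][b] = f.r
        out["t"][b] = f.t
        out["b1_over_b0"][b] = f.slope_ratio
        if model == "quadratic":
            out["b2"][b] = f.b2
            out["t_b2"][b] = f.t_b2
        bin_fst[b] = fst_bins
        b += 1
    return BootstrapSummary(
        B=B, seed=seed, L=L, stats=out, bin_fst=bin_fst, n_rejected=n_rejected
    )
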