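"""Recombination-rate binning, bin-level FST profiles and regressions.

SNPs are ranked by their window recombination rate and split into K
equal-count bins; each bin contributes one (median rate, FST) point.
Linear/quadratic fits across those points, the Pearson correlation, a
t-statistic for the slope, and the normalised slope b1/b0 summarise the
relationship.  Single-SNP (unbinned) analysis is also provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .fst import (
    fst_ratio_of_sums,
    panel_pair_components,
    per_snp_global_fst,
)
from .panel import SnpPanel

__all__ = [
    "BinningScheme",
    "RegressionFit",
    "make_bins",
    "bin_fst_profile",
    "fit_linear",
    "fit_quadratic",
    "correlation_significance",
    "single_snp_analysis",
    "format_pvalue",
]

#: p-values below this are rendered "<<1e-12" in text output.
PVALUE_FLOOR = 1e-12


def format_pvalue(p: float) -> str:
    if p < PVALUE_FLOOR:
        return "<<1e-12"
    return f"{p:.3g}"


@dataclass
class BinningScheme:
    """Assignment of SNPs to K equal-count recombination-rate bins.

    ``bin_index`` is aligned to the SNP order it was built from
    (0-based, in [0, K)).  Bin sizes differ by at most one; when K does
    not divide n the lower-index bins get the extra SNP.
    """

    K: int
    bin_index: np.ndarray
    counts: np.ndarray
    medians: np.ndarray
    edges: np.ndarray

    def __len__(self) -> int:
        return len(self.bin_index)


def make_bins(
    rho: np.ndarray,
    K: int,
    chrom: Optional[np.ndarray] = None,
    pos: Optional[np.ndarray] = None,
) -> BinningScheme:
    """Split SNPs into K equal-count bins by recombination rate.

    Ties are broken by (chromosome, position) when given, by input order
    otherwise (stable sort), so the scheme is deterministic.
    """
    rho = np.asarray(rho, dtype=float)
    n = len(rho)
    if K < 2:
        raise ValueError("need at least 2 bins")
    if n < K:
        raise ValueError(f"fewer SNPs ({n}) than bins ({K})")
    if chrom is not None and pos is not None:
        chrom_keys = np.asarray([str(c) for c in chrom])
        order = np.lexsort((np.asarray(pos), chrom_keys, rho))
    else:
        order = np.argsort(rho, kind="stable")
    base, rem = divmod(n, K)
    sizes = np.full(K, base, dtype=np.int64)
    sizes[:rem] += 1
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    bin_index = np.empty(n, dtype=np.int64)
    medians = np.empty(K)
    for k in range(K):
        members = order[bounds[k] : bounds[k + 1]]
        bin_index[members] = k
        medians[k] = np.median(rho[members])
    sorted_rho = rho[order]
    edges = np.concatenate(
        [[sorted_rho[0]], sorted_rho[bounds[1:-1]], [sorted_rho[-1]]]
    )
    return BinningScheme(K=K, bin_index=bin_index, counts=sizes, medians=medians, edges=edges)


def bin_fst_profile(
    panel: SnpPanel,
    scheme: BinningScheme,
    pops: Optional[Sequence[str]] = None,
    mode: str = "global",
) -> List[Tuple[float, float]]:
    """One (median rho, FST) point per bin.

    ``mode`` is "global" (mean of pairwise ratio-of-sums over all pairs
    of ``pops``) or "pairwise" (``pops`` must then name exactly two
    populations).  The median rho is recomputed from the SNPs currently
    in each bin, so the profile is valid for resampled panels too.
    """
    if len(scheme) != len(panel):
        raise ValueError("scheme and panel have different lengths")
    pops = list(pops) if pops is not None else list(panel.pops)
    if mode == "pairwise" and len(pops) != 2:
        raise ValueError("pairwise mode needs exactly two populations")
    if mode not in ("global", "pairwise"):
        raise ValueError(f"unknown mode {mode!r}")
    from itertools import combinations

    pairs = list(combinations(pops, 2)) if mode == "global" else [tuple(pops)]
    comps = [panel_pair_components(panel, a, b) for a, b in pairs]
    points = []
    for k in range(scheme.K):
        members = scheme.bin_index == k
        if not members.any():
            raise ValueError(f"bin {k} is empty")
        vals = []
        for num, den in comps:
            sd = den[members].sum()
            if sd <= 0:
                raise ValueError(f"bin {k} has no informative SNPs (sum D = 0)")
            vals.append(num[members].sum() / sd)
        points.append((float(np.median(panel.rho[members])), float(np.mean(vals))))
    return points


@dataclass
class RegressionFit:
    """OLS fit of bin FST on bin median recombination rate."""

    b0: float
    b1: float
    r: float
    t: float
    slope_ratio: float  # b1 / b0
    b2: Optional[float] = None
    t_b2: Optional[float] = None
    degenerate: bool = False

    def as_dict(self) -> Dict[str, float]:
        out = {
            "b0": self.b0,
            "b1": self.b1,
            "r": self.r,
            "t": self.t,
            "b1_over_b0": self.slope_ratio,
        }
        if self.b2 is not None:
            out["b2"] = self.b2
            out["t_b2"] = self.t_b2
        return out


def _as_xy(points) -> Tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("expected a sequence of (x, y) points")
    return arr[:, 0], arr[:, 1]


def _ols(X: np.ndarray, y: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Coefficients and their standard errors via least squares (QR/SVD path)."""
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient design matrix")
    resid = y - X @ beta
    dof = X.shape[0] - X.shape[1]
    s2 = resid @ resid / dof if dof > 0 else np.nan
    cov = s2 * np.linalg.inv(X.T @ X)
    return beta, np.sqrt(np.diag(cov))


def fit_linear(points) -> RegressionFit:
    """OLS of y on x with Pearson r, slope t-statistic (df = K - 2) and b1/b0."""
    x, y = _as_xy(points)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("all x values are equal")
    # constant y up to float rounding: slope/correlation are pure noise
    if np.ptp(y) <= 1e-12 * max(1.0, float(np.abs(y).max())):
        b0 = float(np.mean(y))
        return RegressionFit(b0=b0, b1=0.0, r=0.0, t=0.0, slope_ratio=0.0, degenerate=True)
    X = np.column_stack([np.ones_like(x), x])
    beta, se = _ols(X, y)
    b0, b1 = float(beta[0]), float(beta[1])
    t = b1 / se[1] if se[1] > 0 else 0.0
    r = float(np.corrcoef(x, y)[0, 1])
    return RegressionFit(b0=b0, b1=b1, r=r, t=float(t), slope_ratio=b1 / b0)


def fit_quadratic(points) -> RegressionFit:
    """OLS of y on (1, x, x^2); t-statistics for both the linear and
    quadratic coefficients.  Concavity is sign(b2) < 0."""
    x, y = _as_xy(points)
    if len(x) < 4:
        raise ValueError("need at least 4 points")
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 distinct x values")
    X = np.column_stack([np.ones_like(x), x, x**2])
    beta, se = _ols(X, y)
    b0, b1, b2 = (float(b) for b in beta)
    t1 = b1 / se[1] if se[1] > 0 else 0.0
    t2 = b2 / se[2] if se[2] > 0 else 0.0
    r = float(np.corrcoef(x, y)[0, 1]) if np.ptp(y) > 0 else 0.0
    return RegressionFit(
        b0=b0, b1=b1, r=r, t=float(t1), slope_ratio=b1 / b0, b2=b2, t_b2=float(t2)
    )


def correlation_significance(r: float, K: int) -> float:
    """Two-sided p-value for a Pearson correlation across K bins.

    Uses t = r * sqrt(K - 2) / sqrt(1 - r^2) against the t-distribution
    with K - 2 degrees of freedom.  |r| = 1 returns 0 (degenerate).
    """
    if K < 3:
        raise ValueError("need K >= 3")
    if abs(r) > 1:
        raise ValueError("|r| must be <= 1")
    if abs(r) == 1:
        return 0.0
    t = r * np.sqrt(K - 2) / np.sqrt(1 - r**2)
    return float(2 * stats.t.sf(abs(t), df=K - 2))


@dataclass
class SingleSnpResult:
    """Unbinned regression of per-SNP FST on recombination rate."""

    n: int
    r: float
    p_r: float
    fit: RegressionFit
    p_coeffs: Dict[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "r": self.r,
            "p_r": self.p_r,
            "p_r_text": format_pvalue(self.p_r),
            "fit": self.fit.as_dict(),
            "p_coeffs": self.p_coeffs,
        }


def single_snp_analysis(
    panel: SnpPanel,
    pops: Optional[Sequence[str]] = None,
    model: str = "linear",
) -> SingleSnpResult:
    """Correlate per-SNP FST with rho without binning.

    Per-SNP FST is the unweighted mean of defined pairwise N/D values;
    SNPs with no defined pair (or no rho) are dropped.  Naive p-values
    come from the t-distribution with (n - #coefficients) df and ignore
    LD — the bootstrap framework is the LD-aware alternative.
    """
    if panel.rho is None:
        raise ValueError("panel is not annotated with recombination rates")
    y = per_snp_global_fst(panel, pops)
    keep = ~np.isnan(y) & ~np.isnan(panel.rho)
    x, y = panel.rho[keep], y[keep]
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 SNPs with defined per-SNP FST")
    if np.ptp(x) == 0:
        raise ValueError("recombination rate has zero variance")
    if np.ptp(y) == 0:
        raise ValueError("per-SNP FST has zero variance")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1:  # numerically exact relationship
        p_r = 0.0
    else:
        t_r = r * np.sqrt(n - 2) / np.sqrt(1 - r**2)
        p_r = float(2 * stats.t.sf(abs(t_r), df=n - 2))
    if model == "linear":
        X = np.column_stack([np.ones_like(x), x])
        names = ["b0", "b1"]
    elif model == "quadratic":
        X = np.column_stack([np.ones_like(x), x, x**2])
        names = ["b0", "b1", "b2"]
    else:
        raise ValueError(f"unknown model {model!r}")
    beta, se = _ols(X, y)
    dof = n - X.shape[1]
    p_coeffs = {
        name: float(2 * stats.t.sf(abs(b / s), df=dof))
        for name, b, s in zip(names, beta, se)
    }
    b0, b1 = float(beta[0]), float(beta[1])
    fit = RegressionFit(
        b0=b0,
        b1=b1,
        r=r,
        t=float(beta[1] / se[1]),
        slope_ratio=b1 / b0,
        b2=float(beta[2]) if model == "quadratic" else None,
        t_b2=float(beta[2] / se[2]) if model == "quadratic" else None,
    )
    return SingleSnpResult(n=n, r=r, p_r=p_r, fit=fit, p_coeffs=p_coeffs)
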