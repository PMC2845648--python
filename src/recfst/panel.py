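"""Carriers for per-SNP, per-population allele counts.

`SnpRecord` is the single-SNP view used at API boundaries; `SnpPanel`
holds the same information column-wise (numpy arrays) so that estimators
and the bootstrap can run vectorised over hundreds of thousands of SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

__all__ = ["SnpRecord", "SnpPanel", "folded_maf"]


def folded_maf(alt_total: np.ndarray, n_total: np.ndarray) -> np.ndarray:
    """Pooled alternate-allele frequency over all populations, folded to [0, 0.5]."""
    alt_total = np.asarray(alt_total, dtype=float)
    n_total = np.asarray(n_total, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_total > 0, alt_total / n_total, np.nan)
    return np.minimum(p, 1.0 - p)


@dataclass
class SnpRecord:
    """One SNP: position, per-population allele counts and annotations.

    ``counts`` maps population id to ``(alt_count, n_chromosomes)``.
    """

    id: str
    chrom: str
    pos: int
    counts: Dict[str, Tuple[int, int]]
    coding: bool = False
    rho: Optional[float] = None
    status: Optional[str] = None

    def __post_init__(self) -> None:
        for pop, (alt, n) in self.counts.items():
            if not (0 <= alt <= n):
                raise ValueError(
                    f"SNP {self.id}: population {pop} has alt={alt} outside [0, n={n}]"
                )

    @property
    def maf(self) -> float:
        alt = sum(a for a, _ in self.counts.values())
        n = sum(n for _, n in self.counts.values())
        return float(folded_maf(alt, n))


class SnpPanel:
    """Column-wise container of SNPs across populations.

    Attributes
    ----------
    ids : object ndarray, shape (m,)
    chrom : object ndarray, shape (m,)
    pos : int64 ndarray, shape (m,)
    pops : list of population ids (column order of ``alt`` / ``n``)
    alt : int64 ndarray, shape (m, n_pops) — alternate-allele counts
    n : int64 ndarray, shape (m, n_pops) — genotyped chromosome counts
    coding : bool ndarray, shape (m,)
    rho : float ndarray or None — window recombination rate (cM/Mb)
    status : object ndarray or None — annotation status per SNP
    """

    def __init__(
        self,
        ids: Sequence[str],
        chrom: Sequence[str],
        pos: Sequence[int],
        pops: Sequence[str],
        alt: np.ndarray,
        n: np.ndarray,
        coding: Optional[Sequence[bool]] = None,
        rho: Optional[np.ndarray] = None,
        status: Optional[Sequence[str]] = None,
    ) -> None:
        self.ids = np.asarray(ids, dtype=object)
        self.chrom = np.asarray(chrom, dtype=object)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.pops = list(pops)
        self.alt = np.asarray(alt, dtype=np.int64)
        self.n = np.asarray(n, dtype=np.int64)
        m = len(self.ids)
        if self.alt.shape != (m, len(self.pops)) or self.n.shape != self.alt.shape:
            raise ValueError("alt/n shape must be (n_snps, n_pops)")
        if np.any(self.alt < 0) or np.any(self.alt > self.n):
            raise ValueError("allele counts must satisfy 0 <= alt <= n")
        self.coding = (
            np.zeros(m, dtype=bool)
            if coding is None
            else np.asarray(coding, dtype=bool)
        )
        self.rho = None if rho is None else np.asarray(rho, dtype=float)
        self.status = None if status is None else np.asarray(status, dtype=object)

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_pops(self) -> int:
        return len(self.pops)

    def pop_index(self, pop: str) -> int:
        try:
            return self.pops.index(pop)
        except ValueError:
            raise KeyError(f"unknown population {pop!r}") from None

    def maf(self) -> np.ndarray:
        return folded_maf(self.alt.sum(axis=1), self.n.sum(axis=1))

    def take(self, index) -> "SnpPanel":
        """Subset (boolean mask or integer index), preserving order given."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return SnpPanel(
            ids=self.ids[index],
            chrom=self.chrom[index],
            pos=self.pos[index],
            pops=self.pops,
            alt=self.alt[index],
            n=self.n[index],
            coding=self.coding[index],
            rho=None if self.rho is None else self.rho[index],
            status=None if self.status is None else self.status[index],
        )

    def genomic_order(self) -> np.ndarray:
        """Stable ordering by (chromosome name, position)."""
        chrom_keys = np.asarray([str(c) for c in self.chrom])
        return np.lexsort((self.pos, chrom_keys))

    def sort_genomic(self) -> "SnpPanel":
        return self.take(self.genomic_order())

    @classmethod
    def from_records(cls, records: Iterable[SnpRecord], pops: Optional[Sequence[str]] = None) -> "SnpPanel":
        records = list(records)
        if pops is None:
            seen: List[str] = []
            for r in records:
                for p in r.counts:
                    if p not in seen:
                        seen.append(p)
            pops = seen
        m = len(records)
        alt = np.zeros((m, len(pops)), dtype=np.int64)
        n = np.zeros((m, len(pops)), dtype=np.int64)
        for i, r in enumerate(records):
            for j, p in enumerate(pops):
                if p not in r.counts:
                    raise ValueError(f"SNP {r.id} lacks counts for population {p}")
                alt[i, j], n[i, j] = r.counts[p]
        rho = np.array([np.nan if r.rho is None else r.rho for r in records])
        has_rho = any(r.rho is not None for r in records)
        has_status = any(r.status is not None for r in records)
        return cls(
            ids=[r.id for r in records],
            chrom=[r.chrom for r in records],
            pos=[r.pos for r in records],
            pops=pops,
            alt=alt,
            n=n,
            coding=[r.coding for r in records],
            rho=rho if has_rho else None,
            status=[r.status for r in records] if has_status else None,
        )

    def to_records(self) -> List[SnpRecord]:
        out = []
        for i in range(len(self)):
            out.append(
                SnpRecord(
                    id=str(self.ids[i]),
                    chrom=str(self.chrom[i]),
                    pos=int(self.pos[i]),
                    counts={
                        p: (int(self.alt[i, j]), int(self.n[i, j]))
                        for j, p in enumerate(self.pops)
                    },
                    coding=bool(self.coding[i]),
                    rho=None if self.rho is None else float(self.rho[i]),
                    status=None if self.status is None else str(self.status[i]),
                )
            )
        return out
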