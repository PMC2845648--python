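"""Genetic-map interpolation and windowed recombination-rate annotation.

A SNP's local recombination rate is the genetic length (cM) of a fixed
physical window centred on it, divided by the window length in Mb.  The
genetic position of each window endpoint is obtained by linear
interpolation between the nearest flanking markers of the map.  Windows
falling off the chromosome start, overlapping centromeres or telomeres,
or leaving the marker span are flagged and excluded from analysis.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .panel import SnpPanel

__all__ = [
    "GeneticMap",
    "ChromosomeStructure",
    "RecombAnnotation",
    "STATUS_OK",
    "STATUSES",
    "read_genetic_map",
    "read_rate_map",
    "read_bed_intervals",
    "read_chrom_lengths",
    "genetic_position",
    "window_recombination_rate",
    "annotate_snps",
]

STATUS_OK = "ok"
STATUS_WINDOW_START = "window_start"
STATUS_CENTROMERE = "centromere"
STATUS_TELOMERE = "telomere"
STATUS_MAP_SPAN = "map_span"
STATUS_EXTENDED_MASK = "extended_mask"

#: All statuses, in reporting order.
STATUSES = (
    STATUS_OK,
    STATUS_WINDOW_START,
    STATUS_CENTROMERE,
    STATUS_TELOMERE,
    STATUS_EXTENDED_MASK,
    STATUS_MAP_SPAN,
)


class GeneticMapError(ValueError):
    pass


@dataclass
class GeneticMap:
    """Per chromosome: markers at 1-based physical positions (bp) with
    cumulative genetic positions (cM), strictly increasing in bp and
    non-decreasing in cM."""

    markers: Dict[str, Tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def add_chromosome(self, chrom: str, pos: np.ndarray, cm: np.ndarray) -> None:
        pos = np.asarray(pos, dtype=np.int64)
        cm = np.asarray(cm, dtype=float)
        order = np.argsort(pos, kind="stable")
        pos, cm = pos[order], cm[order]
        if len(pos) and np.any(np.diff(pos) <= 0):
            i = int(np.flatnonzero(np.diff(pos) <= 0)[0])
            raise GeneticMapError(
                f"duplicate physical position on {chrom} at bp {pos[i + 1]}"
            )
        if len(cm) and np.any(np.diff(cm) < 0):
            i = int(np.flatnonzero(np.diff(cm) < 0)[0])
            raise GeneticMapError(
                f"genetic position decreases on {chrom} at marker bp {pos[i + 1]} "
                f"({cm[i + 1]} cM after {cm[i]} cM)"
            )
        if len(cm) and np.any(cm < 0):
            raise GeneticMapError(f"negative genetic position on {chrom}")
        self.markers[chrom] = (pos, cm)

    @property
    def chromosomes(self) -> List[str]:
        return list(self.markers)

    def span(self, chrom: str) -> Tuple[int, int]:
        pos, _ = self._get(chrom)
        return int(pos[0]), int(pos[-1])

    def _get(self, chrom: str) -> Tuple[np.ndarray, np.ndarray]:
        if chrom not in self.markers:
            raise KeyError(f"chromosome {chrom!r} not in genetic map")
        return self.markers[chrom]


@dataclass
class ChromosomeStructure:
    """Chromosome lengths plus centromere/telomere intervals (1-based, closed)."""

    lengths: Dict[str, int] = field(default_factory=dict)
    centromeres: Dict[str, List[Tuple[int, int]]] = field(default_factory=dict)
    telomeres: Dict[str, List[Tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, table in (("centromere", self.centromeres), ("telomere", self.telomeres)):
            for chrom, ivs in table.items():
                length = self.lengths.get(chrom)
                for s, e in ivs:
                    if s > e:
                        raise ValueError(f"{name} interval on {chrom} has start > end")
                    if length is not None and (s < 1 or e > length):
                        raise ValueError(
                            f"{name} interval [{s}, {e}] outside [1, {length}] on {chrom}"
                        )

    @classmethod
    def from_dir(cls, path: Union[str, Path]) -> "ChromosomeStructure":
        """Read `chrom_lengths.tsv`, `centromeres.bed`, `telomeres.bed` from a directory."""
        path = Path(path)
        return cls(
            lengths=read_chrom_lengths(path / "chrom_lengths.tsv"),
            centromeres=read_bed_intervals(path / "centromeres.bed"),
            telomeres=read_bed_intervals(path / "telomeres.bed"),
        )

    def masked_intervals(self, chrom: str) -> List[Tuple[int, int]]:
        return list(self.centromeres.get(chrom, [])) + list(self.telomeres.get(chrom, []))


@dataclass
class RecombAnnotation:
    """Window recombination rate for one SNP.  ``rho`` is defined (>= 0)
    only when ``status == "ok"``."""

    window: Tuple[int, int]
    window_bp: int
    rho: Optional[float]
    status: str

    @property
    def ok(self) -> bool:
        return self.status == STATUS_OK


# ---------------------------------------------------------------------------
# readers


def _read_table(path, n_cols: int, col_names: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        dtype=str,
        skip_blank_lines=True,
    )
    if df.shape[1] < n_cols:
        raise GeneticMapError(
            f"{path}: expected {n_cols} tab-separated columns, found {df.shape[1]}"
        )
    df = df.iloc[:, :n_cols]
    df.columns = list(col_names)
    # optional single header line: first row with non-numeric numeric fields
    try:
        float(df.iloc[0, 1])
    except (ValueError, IndexError):
        df = df.iloc[1:].reset_index(drop=True)
    return df


def read_genetic_map(path: Union[str, Path, io.IOBase]) -> GeneticMap:
    """Read a tab-separated (chrom, pos_bp, cM) table into a :class:`GeneticMap`.

    Lines starting with '#' are ignored; one optional header line is allowed.
    Rows may appear in any order; they are sorted per chromosome.  A genetic
    position that decreases with physical position is a hard error.
    """
    df = _read_table(path, 3, ["chrom", "pos", "cm"])
    try:
        pos = df["pos"].astype(np.int64)
        cm = df["cm"].astype(float)
    except ValueError as exc:
        bad = None
        for i, (p, c) in enumerate(zip(df["pos"], df["cm"])):
            try:
                int(p), float(c)
            except ValueError:
                bad = i
                break
        raise GeneticMapError(f"{path}: unparseable map line {bad}: {exc}") from exc
    gmap = GeneticMap()
    for chrom, sub in pd.DataFrame(
        {"chrom": df["chrom"], "pos": pos, "cm": cm}
    ).groupby("chrom", sort=True):
        gmap.add_chromosome(str(chrom), sub["pos"].to_numpy(), sub["cm"].to_numpy())
    return gmap


def read_rate_map(path: Union[str, Path], chrom: Optional[str] = None) -> GeneticMap:
    """Read the (chrom, pos_bp, rate_cM_per_Mb, cumulative_cM) dialect.

    If the file has only three columns (pos, rate, cM), ``chrom`` must be
    given.  The rate column is ignored for interpolation; the cumulative
    map carries the information.
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    if df.shape[1] >= 4:
        df = df.iloc[:, :4]
        df.columns = ["chrom", "pos", "rate", "cm"]
    elif df.shape[1] == 3:
        if chrom is None:
            raise GeneticMapError(f"{path}: 3-column rate map needs an explicit chromosome")
        df.columns = ["pos", "rate", "cm"]
        df["chrom"] = chrom
    else:
        raise GeneticMapError(f"{path}: rate map needs 3 or 4 columns")
    try:
        float(df["pos"].iloc[0])
    except ValueError:
        df = df.iloc[1:]
    gmap = GeneticMap()
    for c, sub in df.groupby("chrom", sort=True):
        gmap.add_chromosome(
            str(c), sub["pos"].astype(np.int64).to_numpy(), sub["cm"].astype(float).to_numpy()
        )
    return gmap


def read_bed_intervals(path: Union[str, Path]) -> Dict[str, List[Tuple[int, int]]]:
    """Read a BED file (0-based, half-open) into 1-based closed intervals."""
    out: Dict[str, List[Tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED line needs >= 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end <= start:
                raise ValueError(f"{path}:{lineno}: empty or inverted interval")
            out.setdefault(chrom, []).append((start + 1, end))
    for chrom in out:
        out[chrom].sort()
    return out


def read_chrom_lengths(path: Union[str, Path]) -> Dict[str, int]:
    """Two-column (chrom, length_bp) tab-separated table."""
    out: Dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected chrom<TAB>length")
            try:
                out[parts[0]] = int(parts[1])
            except ValueError:
                if lineno == 1:  # header
                    continue
                raise
    return out


# ---------------------------------------------------------------------------
# interpolation and windows


def genetic_position(gmap: GeneticMap, chrom: str, pos) -> Union[float, np.ndarray]:
    """Linearly interpolated genetic position (cM) at physical position(s).

    Positions outside the chromosome's marker span return NaN — no
    extrapolation is attempted.  Unknown chromosome is an error.
    """
    mpos, mcm = gmap._get(chrom)
    pos_arr = np.asarray(pos, dtype=float)
    out = np.interp(pos_arr, mpos, mcm)
    out = np.where((pos_arr < mpos[0]) | (pos_arr > mpos[-1]), np.nan, out)
    if np.isscalar(pos) or pos_arr.ndim == 0:
        return float(out)
    return out


def _interval_overlap(s: int, e: int, ivs: Sequence[Tuple[int, int]]) -> bool:
    return any(s <= ie and e >= is_ for is_, ie in ivs)


def _interval_distance(s: int, e: int, ivs: Sequence[Tuple[int, int]]) -> float:
    """Smallest gap (bp) between [s, e] and any interval; 0 if overlapping."""
    if not ivs:
        return np.inf
    return min(max(0, is_ - e, s - ie) for is_, ie in ivs)


def window_bounds(pos: int, window_bp: int) -> Tuple[int, int]:
    """Closed window of physical length ``window_bp`` centred on ``pos``.

    For odd lengths the start offset rounds down and the end offset up,
    so end - start == window_bp exactly.
    """
    half = window_bp // 2
    return pos - half, pos + (window_bp - half)


def window_recombination_rate(
    gmap: GeneticMap,
    structure: ChromosomeStructure,
    chrom: str,
    pos: int,
    window_bp: int = 3_000_000,
    extend_mask_bp: int = 0,
) -> RecombAnnotation:
    """Recombination rate (cM/Mb) of the ``window_bp`` window centred on ``pos``.

    Filters are applied in a fixed order and the first failing one is
    recorded: window start before the chromosome start; window end beyond
    the chromosome length (classed as telomere when the window overlaps a
    telomere interval, map_span otherwise); centromere overlap; telomere
    overlap; proximity within ``extend_mask_bp`` of a centromere/telomere;
    window endpoint outside the marker span.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    if extend_mask_bp < 0:
        raise ValueError("extend_mask_bp must be >= 0")
    s, e = window_bounds(int(pos), int(window_bp))
    ann = lambda rho, status: RecombAnnotation((s, e), window_bp, rho, status)

    if s < 1:
        return ann(None, STATUS_WINDOW_START)
    length = structure.lengths.get(chrom)
    cents = structure.centromeres.get(chrom, [])
    telos = structure.telomeres.get(chrom, [])
    if length is not None and e > length:
        if _interval_overlap(s, e, telos):
            return ann(None, STATUS_TELOMERE)
        return ann(None, STATUS_MAP_SPAN)
    if _interval_overlap(s, e, cents):
        return ann(None, STATUS_CENTROMERE)
    if _interval_overlap(s, e, telos):
        return ann(None, STATUS_TELOMERE)
    if extend_mask_bp > 0:
        if _interval_distance(s, e, cents + telos) <= extend_mask_bp:
            return ann(None, STATUS_EXTENDED_MASK)
    g_start = genetic_position(gmap, chrom, s)
    g_end = genetic_position(gmap, chrom, e)
    if np.isnan(g_start) or np.isnan(g_end):
        return ann(None, STATUS_MAP_SPAN)
    rho = (g_end - g_start) / (window_bp / 1e6)
    return ann(float(rho), STATUS_OK)


def _annotate_chrom(
    gmap: GeneticMap,
    structure: ChromosomeStructure,
    chrom: str,
    pos: np.ndarray,
    window_bp: int,
    extend_mask_bp: int,
) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorised annotation for all SNPs of one chromosome.

    Mirrors :func:`window_recombination_rate` exactly (cross-checked in
    the test suite).
    """
    m = len(pos)
    rho = np.full(m, np.nan)
    status = np.full(m, STATUS_OK, dtype=object)
    half = window_bp // 2
    s = pos - half
    e = pos + (window_bp - half)

    undecided = np.ones(m, dtype=bool)

    def mark(cond, st):
        hit = undecided & cond
        status[hit] = st
        undecided[hit] = False

    mark(s < 1, STATUS_WINDOW_START)

    length = structure.lengths.get(chrom)
    cents = structure.centromeres.get(chrom, [])
    telos = structure.telomeres.get(chrom, [])

    def overlaps(ivs):
        hit = np.zeros(m, dtype=bool)
        for is_, ie in ivs:
            hit |= (s <= ie) & (e >= is_)
        return hit

    telo_overlap = overlaps(telos)
    if length is not None:
        past_end = e > length
        mark(past_end & telo_overlap, STATUS_TELOMERE)
        mark(past_end, STATUS_MAP_SPAN)
    mark(overlaps(cents), STATUS_CENTROMERE)
    mark(telo_overlap, STATUS_TELOMERE)
    if extend_mask_bp > 0:
        near = np.zeros(m, dtype=bool)
        for is_, ie in cents + telos:
            gap = np.maximum(0, np.maximum(is_ - e, s - ie))
            near |= gap <= extend_mask_bp
        mark(near, STATUS_EXTENDED_MASK)

    if chrom in gmap.markers and np.any(undecided):
        idx = np.flatnonzero(undecided)
        g_start = genetic_position(gmap, chrom, s[idx].astype(float))
        g_end = genetic_position(gmap, chrom, e[idx].astype(float))
        bad = np.isnan(g_start) | np.isnan(g_end)
        status[idx[bad]] = STATUS_MAP_SPAN
        good = idx[~bad]
        rho[good] = (g_end[~bad] - g_start[~bad]) / (window_bp / 1e6)
    elif np.any(undecided):
        status[undecided] = STATUS_MAP_SPAN
    return rho, status


def annotate_snps(
    panel: SnpPanel,
    gmap: GeneticMap,
    structure: ChromosomeStructure,
    window_bp: int = 3_000_000,
    extend_mask_bp: int = 0,
) -> Tuple[SnpPanel, Counter]:
    """Attach a window recombination rate to every SNP and drop filtered ones.

    Returns the retained panel in genomic order (every SNP carrying
    ``status == "ok"`` and a defined rho) and a counter of SNPs removed
    per filter reason.
    """
    panel = panel.sort_genomic()
    rho = np.full(len(panel), np.nan)
    status = np.full(len(panel), STATUS_OK, dtype=object)
    for chrom in pd.unique(panel.chrom):
        mask = panel.chrom == chrom
        rho[mask], status[mask] = _annotate_chrom(
            gmap, structure, str(chrom), panel.pos[mask], window_bp, extend_mask_bp
        )
    log = Counter({st: 0 for st in STATUSES if st != STATUS_OK})
    for st in status[status != STATUS_OK]:
        log[st] += 1
    keep = status == STATUS_OK
    out = panel.take(keep)
    out.rho = rho[keep]
    out.status = status[keep]
    return out, log
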