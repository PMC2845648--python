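"""Synthetic inputs: genetic maps, chromosome structure, and
multi-population allele-count panels with a planted FST(rho) relation.

Per-population allele frequencies follow a Balding–Nichols model: given
an ancestral frequency p and a per-locus drift parameter c, each
population's frequency is Beta-distributed with mean p and variance
c*p*(1-p), so the expected pairwise FST equals c.  The drift parameter
is a (clamped) linear or quadratic function of the SNP's true window
recombination rate, planting a recoverable FST–recombination relation.
An LD surrogate correlates neighbouring SNPs: within blocks of
consecutive SNPs the Gaussian-copula deviates share a latent factor with
mixing weight lambda, inducing positive short-range correlation of
per-SNP statistics without changing the Beta marginals.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats as sps

from .genmap import (
    ChromosomeStructure,
    GeneticMap,
    annotate_snps,
)
from .panel import SnpPanel

__all__ = [
    "SyntheticTruth",
    "simulate_genetic_map",
    "simulate_snp_panel",
    "write_fixture",
    "read_fixture",
]

#: Clamp range for the planted drift parameter.
DRIFT_MIN, DRIFT_MAX = 0.001, 0.99


@dataclass
class SyntheticTruth:
    """Planted generative parameters of a synthetic panel.

    Drift is c(rho) = intercept + slope*rho + quad*rho^2, clamped to
    [0.001, 0.99].  The default magnitudes match a realistic fitted
    FST-on-rate line (intercept ~0.128, slope ~-0.005).
    """

    intercept: float = 0.128
    slope: float = -0.005
    quad: float = 0.0
    ld_block: int = 50
    lam: float = 0.8
    pops: Dict[str, int] = field(default_factory=lambda: {"pop1": 100, "pop2": 100, "pop3": 100})
    anc_low: float = 0.05
    anc_high: float = 0.95
    coding_frac: float = 0.02
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.ld_block < 1:
            raise ValueError("ld_block must be >= 1")
        if not (0.0 <= self.lam <= 1.0):
            raise ValueError("lambda must be in [0, 1]")
        if len(self.pops) < 2:
            raise ValueError("need at least 2 populations")

    def drift(self, rho: np.ndarray) -> np.ndarray:
        c = self.intercept + self.slope * np.asarray(rho, dtype=float)
        if self.quad:
            c = c + self.quad * np.asarray(rho, dtype=float) ** 2
        return np.clip(c, DRIFT_MIN, DRIFT_MAX)

    def as_dict(self) -> dict:
        return asdict(self)


def _lognormal_params(median: float, mean: float) -> Tuple[float, float]:
    if mean <= median:
        raise ValueError("right-skewed rate model needs mean > median")
    mu = np.log(median)
    sigma = np.sqrt(2 * np.log(mean / median))
    return mu, sigma


def simulate_genetic_map(
    chrom_lengths: Dict[str, int],
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    marker_spacing: Tuple[int, int] = (50_000, 500_000),
    rate: Union[float, Tuple[float, float]] = (1.23, 1.39),
    telomere_bp: int = 1_000_000,
    centromere_bp: int = 3_000_000,
) -> Tuple[GeneticMap, ChromosomeStructure]:
    """Generate a marker map with heterogeneous rates plus structure.

    ``rate`` is either a constant (cM/Mb) or a (median, mean) pair of a
    right-skewed lognormal distribution of per-interval rates.  Each
    chromosome gets one centromere interval at its middle and a telomere
    interval at each end.  Deterministic given the seed.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    gmap = GeneticMap()
    lengths, cents, telos = {}, {}, {}
    for chrom, length in chrom_lengths.items():
        length = int(length)
        positions = [1]
        while positions[-1] < length:
            positions.append(positions[-1] + int(rng.integers(*marker_spacing)))
        positions[-1] = length
        pos = np.asarray(positions, dtype=np.int64)
        gaps_mb = np.diff(pos) / 1e6
        if isinstance(rate, (int, float)):
            rates = np.full(len(gaps_mb), float(rate))
        else:
            mu, sigma = _lognormal_params(*rate)
            rates = rng.lognormal(mu, sigma, size=len(gaps_mb))
        cm = np.concatenate([[0.0], np.cumsum(rates * gaps_mb)])
        gmap.add_chromosome(chrom, pos, cm)
        lengths[chrom] = length
        mid = length // 2
        cents[chrom] = [(mid - centromere_bp // 2, mid + centromere_bp // 2)]
        telos[chrom] = [(1, telomere_bp), (length - telomere_bp + 1, length)]
    return gmap, ChromosomeStructure(lengths=lengths, centromeres=cents, telomeres=telos)


def _sample_positions(
    gmap: GeneticMap,
    structure: ChromosomeStructure,
    n_snps: int,
    window_bp: int,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rejection-sample positions uniform over the mappable genome
    (window status ok); returns (chrom, pos, rho) in genomic order."""
    chroms = list(structure.lengths)
    lens = np.array([structure.lengths[c] for c in chroms], dtype=float)
    w = lens / lens.sum()
    got_chrom: List[str] = []
    got_pos: List[int] = []
    got_rho: List[float] = []
    guard = 0
    while len(got_pos) < n_snps:
        guard += 1
        if guard > 200:
            raise RuntimeError("could not place SNPs on mappable regions (map too masked?)")
        need = n_snps - len(got_pos)
        batch = max(1000, 2 * need)
        ci = rng.choice(len(chroms), size=batch, p=w)
        pos = (rng.random(batch) * lens[ci]).astype(np.int64) + 1
        trial = SnpPanel(
            ids=[f"t{i}" for i in range(batch)],
            chrom=[chroms[k] for k in ci],
            pos=pos,
            pops=["x"],
            alt=np.zeros((batch, 1), dtype=np.int64),
            n=np.full((batch, 1), 2, dtype=np.int64),
        )
        ok, _ = annotate_snps(trial, gmap, structure, window_bp=window_bp)
        # annotate_snps returns genomic order; subsample at random so the
        # final truncation does not bias toward low-sorting chromosomes
        perm = rng.permutation(len(ok))[: min(need, len(ok))]
        got_chrom.extend(str(c) for c in ok.chrom[perm])
        got_pos.extend(int(p) for p in ok.pos[perm])
        got_rho.extend(float(r) for r in ok.rho[perm])
    chrom = np.asarray(got_chrom, dtype=object)
    pos = np.asarray(got_pos, dtype=np.int64)
    rho = np.asarray(got_rho)
    order = np.lexsort((pos, chrom.astype(str)))
    return chrom[order], pos[order], rho[order]


def _simulate_exons(
    structure: ChromosomeStructure,
    frac: float,
    rng: np.random.Generator,
    exon_bp: int = 1500,
) -> Dict[str, List[Tuple[int, int]]]:
    """Random exon-like intervals covering ~frac of each chromosome (1-based closed)."""
    out: Dict[str, List[Tuple[int, int]]] = {}
    for chrom, length in structure.lengths.items():
        n_exons = max(1, int(frac * length / exon_bp))
        starts = np.sort(rng.integers(1, max(2, length - exon_bp), size=n_exons))
        out[chrom] = [(int(s), int(s + exon_bp - 1)) for s in starts]
    return out


def _flag_coding(
    chrom: np.ndarray, pos: np.ndarray, exons: Dict[str, List[Tuple[int, int]]]
) -> np.ndarray:
    flag = np.zeros(len(pos), dtype=bool)
    for c in np.unique(chrom.astype(str)):
        ivs = exons.get(c, [])
        if not ivs:
            continue
        mask = chrom.astype(str) == c
        starts = np.array([s for s, _ in ivs])
        ends = np.array([e for _, e in ivs])
        j = np.searchsorted(starts, pos[mask], side="right") - 1
        hit = (j >= 0) & (pos[mask] <= ends[np.clip(j, 0, None)])
        flag[np.flatnonzero(mask)] = hit
    return flag


def simulate_snp_panel(
    gmap: GeneticMap,
    structure: ChromosomeStructure,
    truth: SyntheticTruth,
    n_snps: int,
    window_bp: int = 3_000_000,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[SnpPanel, SyntheticTruth, dict]:
    """Draw a Balding–Nichols panel with the planted drift function.

    Returns the panel (genomic order, with the true window rates stored
    in ``panel.rho``), the truth record, and extras (exon intervals and
    the per-SNP true drift values).
    """
    if rng is None:
        rng = np.random.default_rng(seed if seed is not None else truth.seed)
    chrom, pos, rho = _sample_positions(gmap, structure, n_snps, window_bp, rng)
    c = truth.drift(rho)
    if np.any((c <= 0) | (c >= 1)):
        raise ValueError("drift parameter outside (0, 1) after clamping")
    p = rng.uniform(truth.anc_low, truth.anc_high, size=n_snps)
    a_beta = p * (1 - c) / c
    b_beta = (1 - p) * (1 - c) / c

    block = np.arange(n_snps) // truth.ld_block
    n_blocks = int(block[-1]) + 1
    lam = truth.lam
    pops = list(truth.pops)
    alt = np.empty((n_snps, len(pops)), dtype=np.int64)
    nmat = np.empty_like(alt)
    for j, pop in enumerate(pops):
        z = rng.standard_normal(n_blocks)
        eps = rng.standard_normal(n_snps)
        u = lam * z[block] + np.sqrt(1 - lam**2) * eps
        freq = sps.beta.ppf(sps.norm.cdf(u), a_beta, b_beta)
        freq = np.clip(freq, 0.0, 1.0)
        n_chrom = truth.pops[pop]
        alt[:, j] = rng.binomial(n_chrom, freq)
        nmat[:, j] = n_chrom

    exons = _simulate_exons(structure, truth.coding_frac, rng)
    coding = _flag_coding(chrom, pos, exons)
    panel = SnpPanel(
        ids=[f"snp{i + 1}" for i in range(n_snps)],
        chrom=chrom,
        pos=pos,
        pops=pops,
        alt=alt,
        n=nmat,
        coding=coding,
        rho=rho,
        status=np.full(n_snps, "ok", dtype=object),
    )
    extras = {"exons": exons, "drift": c}
    return panel, truth, extras


# ---------------------------------------------------------------------------
# fixture output


def write_fixture(
    outdir: Union[str, Path],
    gmap: GeneticMap,
    structure: ChromosomeStructure,
    panel: SnpPanel,
    truth: SyntheticTruth,
    exons: Optional[Dict[str, List[Tuple[int, int]]]] = None,
    write_vcf: bool = False,
) -> Dict[str, Path]:
    """Write the pipeline's input files (plain text) to a directory.

    Emits genetic map TSV, chromosome-structure BEDs and lengths table,
    the long-format allele-count table, an exon BED, a truth JSON, and
    optionally an uncompressed VCF.  Everything round-trips losslessly
    through the package readers.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}

    paths["map"] = outdir / "map.tsv"
    with open(paths["map"], "w") as fh:
        fh.write("#chrom\tpos\tcm\n")
        for chrom, (pos, cm) in gmap.markers.items():
            for p, c in zip(pos, cm):
                fh.write(f"{chrom}\t{p}\t{c:.10g}\n")

    paths["chrom_lengths"] = outdir / "chrom_lengths.tsv"
    with open(paths["chrom_lengths"], "w") as fh:
        for chrom, length in structure.lengths.items():
            fh.write(f"{chrom}\t{length}\n")

    for name, table in (("centromeres", structure.centromeres), ("telomeres", structure.telomeres)):
        paths[name] = outdir / f"{name}.bed"
        with open(paths[name], "w") as fh:
            for chrom, ivs in table.items():
                for s, e in ivs:  # 1-based closed -> BED 0-based half-open
                    fh.write(f"{chrom}\t{s - 1}\t{e}\n")

    paths["counts"] = outdir / "counts.tsv"
    with open(paths["counts"], "w") as fh:
        fh.write("#snp_id\tchrom\tpos\tpop\tn_chrom\talt_count\tcoding_flag\n")
        for i in range(len(panel)):
            for j, pop in enumerate(panel.pops):
                fh.write(
                    f"{panel.ids[i]}\t{panel.chrom[i]}\t{panel.pos[i]}\t{pop}\t"
                    f"{panel.n[i, j]}\t{panel.alt[i, j]}\t{int(panel.coding[i])}\n"
                )

    if exons:
        paths["exons"] = outdir / "exons.bed"
        with open(paths["exons"], "w") as fh:
            for chrom, ivs in exons.items():
                for s, e in ivs:
                    fh.write(f"{chrom}\t{s - 1}\t{e}\n")

    paths["truth"] = outdir / "truth.json"
    with open(paths["truth"], "w") as fh:
        json.dump(truth.as_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")

    if write_vcf:
        paths["vcf"] = outdir / "panel.vcf"
        _write_vcf(paths["vcf"], panel)
        paths["samples"] = outdir / "samples"
        paths["samples"].mkdir(exist_ok=True)
        for pop, names in _vcf_sample_names(panel).items():
            with open(paths["samples"] / f"{pop}.txt", "w") as fh:
                fh.write("\n".join(names) + "\n")
    return paths


def _vcf_sample_names(panel: SnpPanel) -> Dict[str, List[str]]:
    """Diploid sample names per population (last sample haploid if n is odd)."""
    out = {}
    for j, pop in enumerate(panel.pops):
        n_chrom = int(panel.n[0, j])
        if np.any(panel.n[:, j] != n_chrom):
            raise ValueError("VCF output requires a constant n per population")
        n_samples = (n_chrom + 1) // 2
        out[pop] = [f"{pop}_s{k + 1}" for k in range(n_samples)]
    return out


def _write_vcf(path: Path, panel: SnpPanel) -> None:
    """Minimal uncompressed VCF with genotypes realising the counts exactly.

    Alt alleles are packed into the leading chromosomes of each
    population's samples; allele counts (not haplotype structure) are
    what the readers consume.
    """
    samples = _vcf_sample_names(panel)
    all_names = [s for pop in panel.pops for s in samples[pop]]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        chrom_seen = []
        for c in panel.chrom:
            if c not in chrom_seen:
                chrom_seen.append(c)
        for c in chrom_seen:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(all_names) + "\n")
        for i in range(len(panel)):
            gts = []
            for j, pop in enumerate(panel.pops):
                n_chrom = int(panel.n[i, j])
                alleles = [1] * int(panel.alt[i, j]) + [0] * (n_chrom - int(panel.alt[i, j]))
                for k in range(0, n_chrom, 2):
                    if k + 1 < n_chrom:
                        gts.append(f"{alleles[k]}|{alleles[k + 1]}")
                    else:
                        gts.append(str(alleles[k]))
            fh.write(
                f"{panel.chrom[i]}\t{panel.pos[i]}\t{panel.ids[i]}\tA\tG\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def read_fixture(indir: Union[str, Path]):
    """Read a fixture directory back into (gmap, structure, panel, truth)."""
    from .fst import read_counts_table
    from .genmap import read_genetic_map

    indir = Path(indir)
    gmap = read_genetic_map(indir / "map.tsv")
    structure = ChromosomeStructure.from_dir(indir)
    panel = read_counts_table(indir / "counts.tsv")
    truth = None
    truth_path = indir / "truth.json"
    if truth_path.exists():
        with open(truth_path) as fh:
            truth = SyntheticTruth(**json.load(fh))
    return gmap, structure, panel, truth
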