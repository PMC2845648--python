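# recfst

Analysis pipeline relating SNP allele-frequency differentiation (FST)
between populations to local recombination rate:

- **genmap** — read genetic maps (chrom / bp / cumulative cM) and
  chromosome structure (lengths, centromere/telomere BEDs); assign each
  SNP the recombination rate of a fixed-width window centred on it
  (default 3 Mb), with filters for windows that fall off the chromosome
  start, overlap a centromere or telomere, come too close to one
  (optional extended mask), or leave the marker span.
- **fst** — per-SNP variance-corrected pairwise FST components
  aggregated as a ratio of sums; global FST as the unweighted mean over
  population pairs; a Weir–Cockerham theta as an independent
  cross-check; readers for allele-count tables and VCF.
- **binstats** — equal-count recombination-rate bins; per-bin
  (median rate, FST) profiles; linear/quadratic OLS fits with slope
  t-statistics, Pearson correlations, and the normalised slope b1/b0;
  unbinned single-SNP analysis.
- **mbb** — moving-block bootstrap over SNPs in genomic order
  (overlapping blocks, default 200 SNPs) that re-estimates all bin and
  regression statistics per replicate; SD across replicates is the
  standard error; z-tests and between-analysis comparisons.
- **pipeline** — orchestrates annotate → stratify (coding/non-coding,
  MAF categories) → bins → naive fits → bootstrap per stratum and
  population pair → comparisons, into a deterministic JSON report.
- **synth** — synthetic genetic maps with right-skewed rates, and
  Balding–Nichols allele-count panels whose per-locus drift follows a
  planted linear/quadratic function of the true window recombination
  rate, with latent-factor LD-like block correlation.

## CLI

```sh
recfst simulate --chroms 2 --length-mb 50 --n-snps 20000 --pops 3 \
    --planted "0.128,-0.005,0" --ld-block 50 --lambda 0.8 --seed 1 --out fix/
recfst annotate --map fix/map.tsv --structure fix/ --snps fix/counts.tsv \
    --window-mb 3 --out annotated.tsv
recfst analyze --fixture fix/ --bootstraps 1000 --block-len 200 --bins 10 \
    --seed 1 --out report.json
recfst compare --mean-a -0.0081 --se-a 0.0022 --mean-b -0.0048 --se-b 0.0007 \
    --sided less
```

## Python API sketch

```python
import recfst as rf

gmap = rf.read_genetic_map("map.tsv")
structure = rf.ChromosomeStructure.from_dir("structure/")
panel = rf.fst.read_counts_table("counts.tsv")
annotated, log = rf.annotate_snps(panel, gmap, structure, window_bp=3_000_000)

bins = rf.make_bins(annotated.rho, 10, chrom=annotated.chrom, pos=annotated.pos)
profile = rf.bin_fst_profile(annotated, bins)            # (median rate, FST) per bin
fit = rf.fit_linear(profile)
summary = rf.bootstrap_framework(annotated, bins, B=1000, block_len=200, seed=1)
p = rf.z_test(summary.mean("b1"), summary.se("b1"))
```
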