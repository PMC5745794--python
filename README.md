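# adaptkit

Population-genomics and quantitative-genetics toolkit for studying how a
selfing plant adapts to a new range, modelled on the colonization of the
Yangtze River basin by *Arabidopsis thaliana*. The package re-creates the
full computational chain on data it simulates itself:

* a **two-deme structured-coalescent simulator** (numba-compiled; optional
  Hudson ancestral-recombination-graph mode so LD decays with distance),
  with the four competing gene-flow histories of the system as ready-made
  templates — the best-supported one has two waves of asymmetric gene flow
  after a divergence 61,409 generations ago from an ancestral population of
  179,724;
* **SFS demographic inference**: Monte-Carlo expected joint folded spectra,
  a multinomial composite likelihood with low-support cells masked,
  multi-start Nelder–Mead with common random numbers, AIC/Akaike-weight
  model choice, and parametric-bootstrap confidence intervals;
* **selective-sweep scans**: a SweepFinder-style composite likelihood ratio
  on the folded spectrum and an OmegaPlus-style LD contrast (ω), both with
  cutoffs calibrated on neutral null simulations at a chosen false-positive
  rate, region merging, two-method consensus, and GFF gene overlap;
* **windowed diversity statistics** (π, Watterson's θ, Hudson's F_ST in
  200-kb/10-kb sliding windows), joint folded SFS construction, private-SNP
  counts and SNP-saturation curves;
* **variant hard filters** replicating a GATK-style pass (Q/MQ/QD/
  ReadPosRankSum/DP/FS thresholds, SNP-density and call-rate rules,
  noncoding masking) over VCF/BED/GFF3 via pysam and gffutils;
* **F2 QTL mapping** of flowering time: cross simulation on a genetic map
  (Haldane), Haley–Knott interval mapping, permutation LOD thresholds,
  drop-one variance explained, haplotype association and nonsynonymous
  candidate filtering.

For the models, assumptions and numerical choices, see
[`docs/methods.md`](docs/methods.md).

## Worked example

Each script in `examples/` exercises one capability. Simulating the study
design and mapping the two flowering-time QTLs
(`python examples/04_qtl_mapping.py`) prints:

```
F2 cross: 86 plants, 32 markers; mean flowering 37.2 days

genome-wide 5% LOD threshold (1000 permutations): 3.02
per-chromosome LOD maxima:
  chr1     28.0 cM   LOD  1.59
  chr2     45.0 cM   LOD 20.06  *
  chr3     22.0 cM   LOD  1.22
  chr4     85.0 cM   LOD  0.92
  chr5     52.3 cM   LOD  5.80  *

variance explained (drop-one partition):
  chr2 peak: 58.0% (generating values 60.9% and 21.6%)
  chr5 peak: 18.8% (generating values 60.9% and 21.6%)

haplotype association at the chr2 peak (homozygotes only): p = 4.97e-08;
group means 28.8 vs 46.7 days
```

The starred chromosomes exceed the permutation threshold: the cross
segregates two real QTLs, and the drop-one partition attributes most of the
flowering-time variance to the chromosome-2 locus — the configuration the
generator encodes (60.9% vs 21.6%, parents flowering at 50.33 and 24.87
days). The haplotype test shows the phenotype splitting cleanly by genotype
class at the peak marker.

Other examples: `01_simulate_panel.py` (panel simulation + windowed π/θ/F_ST
+ VCF export), `02_demographic_fit.py` (divergence-time refit and AIC model
ranking), `03_sweep_scan.py` (calibrated CLR + ω scans and consensus
regions), `05_full_pipeline.py` (the end-to-end pipeline with a checksummed
manifest). A thin CLI wraps the pipeline: `adaptkit simulate|pipeline|report ...`.

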