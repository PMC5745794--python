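# Methods

`adaptkit` re-creates, on self-generated data, the computational chain used
to study how *Arabidopsis thaliana* colonized the Yangtze River basin: a
two-population coalescent simulator, SFS-based demographic inference with
model choice, dual selective-sweep scans with simulation-calibrated cutoffs,
sliding-window diversity statistics, GATK-style variant hard filters, and F2
interval mapping of flowering time. This note documents the models, the
numerical choices, and what the synthetic experiments do and do not show.

## The coalescent simulator

The engine is a backwards-in-time structured coalescent over one or two
demes with piecewise-constant diploid sizes, a divergence event (the demes
merge into an ancestral deme of size `N_anc`), and time-windowed,
possibly asymmetric migration. Because *A. thaliana* is highly selfing, each
strain is treated as a single haploid genome; with diploid effective size
`N`, lineage pairs within a deme coalesce at rate `k(k-1)/2 / (2N)` per
generation. Migration is implemented backwards in time as a per-lineage
deme-switch rate, the usual coalescent convention, so `m_01` is the fraction
of deme-0 lineages whose parent lineage is in deme 1.

Rates are piecewise constant between the breakpoints formed by epoch starts,
migration-window bounds and the divergence time; waiting times are
exponential within a piece and truncated at the next breakpoint. The event
loop is compiled with numba (~20,000 genealogies of 111 haplotypes per
second on one core), which is what makes a simulation-based likelihood
usable interactively.

Mutations follow the infinite-sites approximation: Poisson with mean
`mu * total_branch_length * L`, placed uniformly on branches and assigned
distinct integer positions (collisions re-drawn). Defaults are the study's
calibration: `mu = 7e-9` per bp per generation, `r = 3.6 cM/Mb`, one
generation per year.

With recombination enabled, a Hudson-style ancestral recombination graph is
simulated in Python: lineages carry ancestral-material segment lists,
recombine at rate `r x span` (trapped material included), and mutations are
laid down on the fly with carriers given by the segment's descendant set,
which avoids materializing marginal trees. The ARG makes r² decay with
distance, as the LD-based sweep statistic requires. It is the slow path —
per-bp rates and deep two-deme histories produce large graphs — so
recombination-on runs are kept to ≤100-kb windows at moderate sizes;
the no-recombination kernel serves everything SFS-shaped (the expected SFS
is recombination-invariant).

Reproducibility: every public entry point takes one seed; replicate seeds
are derived through `numpy.random.SeedSequence`, so any replicate can be
regenerated in isolation.

### The four demographic templates

`reference_models()` returns the four competing gene-flow scenarios for the
Yangtze-basin (popY) versus north-western China (popN) split: M1 isolation,
M2 one migration window, M3 continuous migration, M4 two asymmetric windows.
All four share the published size/time skeleton: divergence 61,409
generations ago from an ancestral population of 179,724; post-divergence
sizes 78,454 (popY) and 26,959 (popN); size changes to 45,089 at 7,543 and
to 45,617 at 7,169 generations ago; migration windows 18,652–14,307 and
8,440–7,660 generations ago. The published account calls the popY change an
expansion and the popN change a reduction although the printed numbers move
the other way; the templates use the printed numbers verbatim and the model
type imposes no direction. Migration magnitudes were published only as
"weak"; templates default to 1e-5 per generation, and the recovery
experiments fix migration at the template value in both simulation and
refit, so their conclusions do not depend on it.

## Expected SFS and composite likelihood

`expected_sfs` estimates the expected joint folded SFS by the branch-area
(tree-length) estimator: every non-root lineage adds its lifetime to the
cell indexed by its descendant counts `(j, k)`, and the accumulated matrix,
normalized, is the expected proportion of SNPs per frequency class. This has
the same expectation as binning simulated segregating sites — mutations are
Poisson on branch area — with far lower variance per simulated tree.
Folding maps each cell onto its minor orientation (ties broken
lexicographically); the fixed corners carry no information and are always
masked.

The composite log-likelihood is multinomial over retained cells:
`LL = sum obs_i * ln p_i` with expected proportions renormalized over the
retained cells and floored at 1e-12. Cells with observed support below 10
SNPs are ignored, following the study's masking rule; the mask applies to
observed counts. An optional Poisson term on the total SNP count
(`lambda = mu * L * E[tree length]`) can be added; it is required whenever a
pure size scaling is free, because the normalized spectrum shape of a
constant-size population is scale-free. Shape-identifiable single-parameter
refits (the recovery experiments) run without it.

`fit_model` is multi-start Nelder–Mead on internally transformed parameters
(sizes and rates on log10 scale, times linear), organized in cycles: within
a cycle the Monte-Carlo seed is frozen (common random numbers, which makes
the surface smooth enough for a derivative-free step) and the simulation
count per evaluation escalates geometrically between the schedule's bounds
across cycles. The study's full budget (50 runs, 10–40 cycles, 100k–1M
simulations) is the default signature; desk-scale work uses 1–3 runs, 3–6
cycles and 10³–10⁴ simulations. Changing the divergence time truncates
migration windows it no longer spans — windows are defined relative to the
divergence event.

Model choice is by `AIC = 2k − 2 LL` with Akaike weights. Because the
returned likelihood is itself a Monte-Carlo estimate, comparing models
fairly requires rescoring each fit's end point on a common fresh seed with a
generous simulation count (`final_sims`); without it, optimizer noise of
tens of LL units makes the 2-unit-per-parameter penalty meaningless. Even
with rescoring, AIC at desk scale can detect a strongly supported extra
process (gene flow vs isolation) but cannot reliably reject a harmless
extra parameter whose true likelihood gain is below the noise floor — a
known limit of simulated composite likelihoods, and the reason the
model-identification experiment simulates under the gene-flow model.

Uncertainty comes from a parametric bootstrap: simulate replicate observed
spectra (multinomial draws with the data's SNP count) at the point estimate,
refit each with a reduced budget, and take percentile intervals; refit
failures are counted, never silently dropped.

## Sweep scans

**CLR.** At each grid position the scan compares the composite likelihood of
per-site folded frequencies under the genome-wide background spectrum
against a hard-sweep alternative. In the sweep model a lineage at distance
`d` escapes the sweep with probability `p_e = 1 − exp(−alpha d)`; the
non-escapees collapse onto the single swept ancestor. Concretely, with
`K ~ Binomial(n, p_e)` escapees the post-sweep sample corresponds to a
pre-sweep draw of `K+1` lineages (hypergeometric within the background
configuration) with the ancestor's allele copied to the `n−K` non-escapees;
the resulting spectrum is conditioned on polymorphism, folded, and compared
over a 64-point log-spaced `alpha` grid spanning 1e-7 to 1e-1 per bp. The
neutral limit (`p_e = 1`, spectrum = background) is always included, so
`CLR = 2[max_alpha log CL_sweep − log CL_background] ≥ 0`. Spectra are
precomputed on a 48-point grid of `alpha·d` and looked up per site;
contributions vanish for `alpha·d > 25`, where the transformed spectrum is
numerically the background. The scan uses SNP frequency classes only (no
invariant-site term), matching a folded-fSFS input. A background class with
zero mass is refused; `folded_background` regularizes empty classes with a
0.5 pseudocount for desk-scale panels.

**Omega.** At each grid point, SNPs within `maxwin` of the point are split
into left and right flanks and
`omega = [mean within-flank r²] / [mean cross-flank r²]`,
maximized over flank extents that include at least all SNPs within `minwin`
and at least two SNPs per side (ties: leftmost split). r² is computed
directly from phased haplotypes. Grid points with fewer than two usable SNPs
on either side report NaN, not zero. Defaults mirror the study: 10-kb grid,
`minwin` 10 kb, `maxwin` 100 kb. The extent maximization biases neutral
omega above 1 (it is a maximum of ratios), which is why cutoffs must come
from null simulation rather than a fixed constant; flanks truncated by
sequence ends inflate the statistic further, so scans ignore nothing but
callers should discount grid points within `maxwin` of the ends.

**Calibration and regions.** Cutoffs are the `(1 − FPR)` quantile of the
pooled statistic over neutral panels simulated under the calibration model
and scanned with identical parameters; the study's configuration (10,000
1-Mb nulls at 0.01% FPR) is supported but desk-scale runs use smaller null
sets at larger FPRs, with a warning whenever fewer than `1/FPR` null values
are available. Significant grid points within `max_gap` (default: the grid
spacing) merge into regions; regions from the two methods are intersected,
and genes whose GFF span overlaps a consensus region by ≥1 bp are reported.

## Diversity statistics and filters

Per-site diversity is `2p(1−p)·n/(n−1)`; Watterson's estimator is
`S/(a_{n−1} L)`; both are reported per window of the study geometry (200 kb
sliding, 10-kb step), dividing by full window length (not accessible
sites). FST is Hudson's ratio of averages, `1 − mean(pi_within)/pi_between`,
with the unbiased within-deme term — centred at zero for unstructured data,
at the price of `−1/(n−1)` for identical sample frequencies at small n.
Weir–Cockerham is deliberately not duplicated here; the ratio-of-averages
form is robust at low diversity.

Hard filters replicate the variant-calling thresholds: Q ≥ 30, MQ ≥ 20,
QD ≥ 10, ReadPosRankSum ≥ −8, DP ≥ 3, FS ≤ 10 (SNP) / 200 (indel), with a
missing annotation passing its rule (tallied separately, mirroring common
VariantFiltration behaviour) and each rejected record attributed to its
first failing rule. The SNP-density rule reads "no more than three SNPs per
10 bp" conservatively: any 10-bp span (endpoints inclusive) holding ≥4 SNPs
disqualifies every SNP in the span; a thinning mode keeping the first three
is available. Call-rate filtering keeps biallelic SNPs called in ≥219 of 221
samples by default. Coding-mask subtraction treats a 1-based position as
covered when `start ≤ pos ≤ end` of a BED interval — the conservative
boundary reading, excluding SNPs that touch either interval edge.

## F2 cross and QTL mapping

Gametes are simulated along the genetic map with the Haldane map function
(no interference); an F2 genotype is the sum of two independent F1 gametes,
so markers segregate 1:2:1. The default map mirrors the study design: five
chromosomes (136, 90, 105, 85, 122 cM), 32 markers, 86 phenotyped plants.
Phenotype = grand mean + per-QTL additive/dominance effects + Gaussian
noise. The study-truth generator places two additive QTLs *at genotyped
markers* on chromosomes 2 and 5 with effects solving
`a2²/2 : a5²/2 : sd² = 0.609 : 0.216 : 0.175` and
`2(a2+a5) = 50.33 − 24.87` days (a2 = 7.978, a5 = 4.752, sd = 3.024 days),
so the parents flower at the two observed means and the drop-one variance
fractions are the published 60.9% and 21.6%. Placing causal loci between the
~17-cM-spaced markers would attenuate the estimable PVE by the marker
information loss; at-marker placement represents the fine-mapped design.

Mapping is Haley–Knott regression on conditional expected genotype scores at
pseudo-markers every 2 cM. Conditional probabilities come from the nearest
informative flanking markers per individual (exact under the Markov model;
missing genotypes are handled by walking outward), with AB phases summed
over. `LOD = (n/2) log10(RSS0/RSS1)`; at a fully informative marker this
equals the single-marker ANOVA LOD. Genome-wide significance is the
`(1 − alpha)` quantile of the max-LOD distribution over phenotype
permutations (design matrices fixed, projections precomputed, so 1000
permutations take ~2 s). Variance explained is `1 − 10^(−2·LOD/n)` for one
QTL and a drop-one (type-III) partition of the joint Haley–Knott fit for
several. Haplotype–phenotype association uses the two-sided Wilcoxon
rank-sum (exact for small groups; Welch's t as an alternative), and the
fine-mapping step is represented by a nonsynonymous-effect variant filter
over a candidate interval.

## What the synthetic experiments show — and what they do not

The generators emulate neutral polymorphism under the inferred demography,
sweep-like spectrum distortions (imposed post hoc, not forward-simulated
selection), and an idealized F2 cross: no genotyping error, no missing-data
structure beyond uniform thinning, no background selection or mutation-rate
variation, single-contig panels, and nulls sharing the observed data's
generative process by construction. Passing tests therefore demonstrate
that the estimators recover what their own models generate at the study's
sample sizes — internal consistency and correct implementation — not that
the published biological conclusions would replicate from raw reads. The
published real-data outputs that depend on the 221 genomes (1.97 M SNPs,
the 27.85/11.92 cutoffs, the 530 sweep genes, the 130-kb fine-map) are
context, not targets.

Desk-scale budgets used by the reference experiments: truth spectra from
60,000 genealogies; observed spectra of 200,000 SNPs; single-parameter
refits with 3 runs × 6 cycles and 3,000→15,000 simulations per evaluation
(~25 s each); 25 replicate crosses for PVE recovery; 1000 permutations for
the LOD threshold. Medians over replicate seeds are reported throughout so
a single unlucky Monte-Carlo draw cannot dominate.

## Known limitations

* The ARG is pure Python; genome-scale (1-Mb × 10⁴) null generation with
  recombination is supported in the API but slow — hours, not minutes.
* AIC between nested simulated-likelihood fits is noise-limited at desk
  scale (see above); weights should be read as strong/weak evidence only.
* The omega statistic's flank maximization has no analytic null; its
  cutoff is meaningful only relative to nulls scanned with identical
  parameters.
* `density_filter` is quadratic in cluster size in the worst case and
  assumes single-chromosome position lists; callers split by contig.
* One-deme spectra are stored with a trivial second axis, which keeps the
  joint-SFS container uniform but means `sample_sizes` always has length 2.
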