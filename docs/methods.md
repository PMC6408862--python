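# Methods

## The problem and the design

Invertebrate methylomes are sparse and mosaic: global CpG methylation of
well under 1%, concentrated in runs of methylated gene-body CpGs separated
by long unmethylated stretches. Detecting differential methylation between
two dietary conditions in such a genome, at 8–12× coverage, needs three
things: borrowing strength across neighbouring CpGs (smoothing), modelling
the dominant nuisance factor (clonal replicates paired by mother, whose
profiles co-vary more than same-treatment profiles), and guarding the
region calls against the correlation that smoothing itself induces
(autocorrelation-aware p-value combination).

The pipeline assumes one NF and one CR replicate per mother (n pairs,
default 6), per-CpG methylated/unmethylated counts per replicate, and an
organism with negligible non-CpG methylation, so that methylated CHH/CHG
calls mark bisulphite-unconverted reads.

## Filtering model

* **Non-conversion filter.** A read containing any methylated CHH/CHG call
  is removed whole. The per-replicate percentage of non-CpG calls that are
  methylated estimates the conversion-failure rate; 100 minus it is the
  conversion efficiency. In a methylome this sparse, a few percent of
  unconverted reads multiply the apparent global methylation several-fold,
  which is why this filter runs first.
* **Variant hard filter.** The usual SNP thresholds are applied as
  exclusion bounds: fail if QD < 2, FS > 60, MQ < 40, MQRankSum < −12.5 or
  ReadPosRankSum < −8.0. A missing annotation passes that criterion
  (strict mode inverts this). The sources we follow phrase these as
  keep-conditions; the exclusion-bound reading is the standard one and is
  what we implement.
* **CpG masking.** At a heterozygous C/T site the T allele is read as
  unmethylated C, biasing the site's level down by ~half. A forward-strand
  CpG is masked when a passing C/T SNP sits on its C, or a G/A SNP on the
  following G (reverse-strand reads report methylation at the G);
  reverse-strand sites mirror this. The G-side rule is an extension of the
  one-line C-side rule and can be disabled (`mask_g_position=False`).
* **Coverage rule.** Keep a site iff ≥ `min_replicates_per_treatment` (2)
  replicates in each treatment have ≥ `min_reads` (6) reads. Masking and
  the coverage rule act on disjoint information and commute (tested).

## Smoothing

For each CpG j, the window is the smallest symmetric neighbourhood with at
least `min_cpgs_in_window` CpGs and spanning at least `min_window_bp`
(published defaults 70 / 1000 for dense data; the synthetic benchmark uses
10 / 300 — see below). Weights are tricube(distance / half-width) ×
coverage; the fit is weighted least squares of raw proportions on
(1, dx, dx²) (degree 2) or the weighted mean (degree 0), evaluated at j
and clipped to [0, 1]. WLS on proportions is a one-step approximation of
the binomial local likelihood; an iteratively reweighted local-logistic
fit is available (`iterative_logistic=True`) for fidelity studies, but the
two coincide on the constant and polynomial test cases and the WLS route
is used by default. Zero-coverage sites get weight 0 but receive fitted
values from their neighbours; a window with no coverage at all falls back
to a kernel-only average over covered sites (and 0 if there are none).
Numerical note: the per-site 3×3 normal equations get a 1e-12 ridge; exact
singularity falls back to least squares.

## Paired testing and candidate regions

d_k = smoothed(CR_k) − smoothed(NF_k) per mother k. The per-site sd of the
d_k is floored at the genome-wide `variance_floor_quantile` (default 0.75)
of per-site sds — the "local correction" that stops near-zero sampling
variances from inflating t. t = d̄/(s*/√n), df = n − 1, two-tailed p.
If the floor itself is zero (degenerate all-identical input) t is set to
0. q-values are BH by default; `storey` scales BH by π̂₀ estimated with
the smoother method (cubic spline through π̂₀(λ) on λ = 0.05…0.95,
evaluated at 0.95, clipped to (0, 1]).

Candidates are maximal same-sign runs of |t| > `t_cut` (4.6), broken by
sub-threshold sites, sign changes, scaffold changes, or inter-CpG gaps
over `max_gap_bp` (300 — a convention of the cited region callers, exposed
in config). Filters: ≥ `min_cpgs` (3) members and |region mean difference|
strictly > `min_abs_meandiff` (0.1). The per-CpG q < 0.05 rule is carried
as an annotation (`n_cpgs_site_fdr`) and as an optional extra filter
(`require_site_fdr`), off by default: region selection follows the
t-cut-off narrative, and composing both rules is ambiguous enough that we
expose both behaviours.

## Region combination

Autocorrelation: z = Φ⁻¹(1 − p); for each lag bin (width 50 bp up to
500 bp) the Pearson correlation of (z_i, z_j) over same-scaffold pairs at
that distance; bins with < 10 pairs, or constant z, get ρ = 0.
Combination per candidate region: z_comb = Σz_i / √(n + 2Σ_{i<j} ρ_ij)
with ρ looked up from the pair's lag bin, distances beyond the last bin
→ 0, negative ρ clipped to 0 (keeps the denominator ≥ √n; conservative).
Boundary p-values are clamped to a machine-safe ε. Combined p-values are
BH-adjusted across the **unfiltered** candidate set, so the multiplicity
adjustment spans every tested region; the final set is the intersection of
filtered candidates with regions at corrected p < α (0.05). A standalone
low-p peak finder (seed p, extension threshold) is provided for
completeness but is off the main path: the candidate regions themselves
define the regions to combine.

## Clustering

Distances are 1 − Pearson correlation of raw proportion profiles,
zero-coverage cells excluded pairwise (avoids spurious zeros). Ward.D2 is
implemented via Lance–Williams on squared distances (merge height = √ of
the merged squared distance) with a deterministic tie-break: among equally
close pairs, the cluster containing the lowest leaf index wins (then the
second-lowest). Bootstrap support resamples CpG rows with replacement and
counts the fraction of trees containing each leaf bipartition (BP).
Multiscale/approximately-unbiased support is not implemented: on data of
this kind BP and AU values coincide in practice, and BP answers the
structural question asked here; noted as an extension point.

## Annotation and enrichment

Interval intersection is 1-based inclusive at both ends; region length is
defined as end − start (this matches three of the four published example
rows exactly; the fourth prints a length one below its own end − start and
we keep the convention rather than guess the intent). An overlap is
exonic if only exon sequence is hit, intronic if only intron, mixed if
both; the reported exon hit is the lowest overlapped exon index with the
gene's exon count ("2 of 8"). Exon indices count in transcription order
(reversed for − strand genes).

"Methylated CpG" for the gene universes = pooled methylated count across
replicates > 0 (the most literal reading); a stricter per-replicate
variant (≥1 methylated call in a majority of replicates) is behind a flag.
Enrichment: annotations are up-propagated to all ancestor terms; classic
tests each term with the hypergeometric upper tail; elim processes terms
deepest-first and removes the genes of significant (p < α) terms from
their ancestors before testing them. The exact weight01 hybrid weighting
of topGO is deliberately out of scope; classic and elim are the published,
well-specified alternatives. No multiplicity correction is applied, per
the convention of that tool family.

## The synthetic-data generator

What it emulates: (i) the mosaic methylome — CpGs placed uniformly at
`cpg_density` (20/kbp), genes tiling ~50% of each scaffold, and "high"
baseline methylation assigned to runs of 3–20 consecutive exonic CpGs
until `frac_methylated_sites` (0.007) of gene-body CpGs are high; baseline
levels drawn Beta(6, 2) for high sites and Beta(0.2, 150) for the rest,
which puts global methylation at ~0.7–0.8% under default conditions;
(ii) the paired design — a per-site, per-mother Gaussian effect
(`mother_sd`, default 0.3 on the logit scale) shared by the two replicates
of a mother, added to logit(level), which makes within-pair correlation
exceed within-treatment correlation; (iii) planted DMRs — disjoint runs of
`dmr_width` (3–20) consecutive exonic CpGs, hyper with probability 0.35,
effect uniform in `dmr_effect` (0.10–0.35) applied on the proportion scale
to the CR level and clipped to [0, 1]; hypo regions re-draw their baseline
from the high component first so there is signal to lose; (iv) coverage —
Poisson(10) (or negative binomial) independently per site and replicate;
(v) conversion failure — each read is unconverted with probability 0.03,
in which case all its cytosine calls (CpG and non-CpG) are methylated;
(vi) SNP confounding — `n_snps` C/T (or G/A at the following G) variants
planted on non-DMR CpGs, halving the apparent level (heterozygote), with
passing hard-filter annotations in the emitted VCF.

Counts are drawn by two routes with the same marginal model: a fast
count-level route (binomial counts; unconverted reads folded in as
`u ~ Binomial(c, f)` always-methylated calls) used at the 2×10⁴-CpG
benchmark scale, and a read-level route emitting one call string per read
(z/Z, x/X, h/H alphabet) from which the matrix is aggregated — the route
the non-conversion filter is tested against.

What it does **not** emulate: alignment error, PCR duplicates, m-bias,
fragment-level coverage correlation, CpG-island structure, or real
*Daphnia* annotation; passing tests demonstrate the statistical machinery
under the stated generative model, not performance on any real library.
The per-site level distribution (the beta mixture) is a modelling choice,
not an empirical claim; its parameters are configuration.

## Benchmark conditions and problem sizes

The self-validation studies (`mosaicmeth.validation`, also run by
`scripts/acceptance.py`) use one 1-Mbp scaffold (~2×10⁴ CpGs), six pairs
at 10×, and the 10-CpG / 300-bp smoother window scaled to the generator's
CpG density (a 70-CpG window would average planted 5–10-CpG regions away).
Recovery plants 20 DMRs of 5–10 CpGs at a fixed 0.25 mean difference with
mother sd 0.3; null calibration re-runs the same conditions with zero
effects over 20 seeds; clustering uses mother sd 1.0 with no treatment
effect and 500 bootstrap resamples; the conversion study uses a 150-kbp
scaffold with the read-level route at 3% failure. These sizes keep each
study in seconds-to-a-minute territory while leaving the Monte-Carlo
noise well inside the margins being tested.

## Known limitations

* The smoother's variance behaviour near scaffold edges is that of local
  polynomials generally: edge windows are one-sided and noisier.
* The elim implementation follows the published algorithm but processes
  terms by depth, not by topGO's level bookkeeping; on DAGs where a term
  has parents at different depths the processing order can differ.
* `storey` π̂₀ estimation is unstable for small site counts; BH is the
  default.
* The read-level simulator draws non-CpG cytosines per read from a Poisson
  rather than from genome positions; sufficient for the filter it
  exercises, not for positional analyses of non-CpG calls.
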