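# Methods

This note documents the models, defaults, and numerical choices behind
`temdyn`, and what the synthetic benchmark does and does not establish.

## 1. The synthetic world

The generator (`temdyn.synthetic`) states a miniature version of the
measured system once; its defaults are not tuned afterwards.

**Genome and annotation.** Two 500-kb chromosomes of random sequence at
36% GC (Arabidopsis-like). Three latent TE classes are placed without
overlap: class A (euchromatic; 120 TEs, log-normal lengths, median
400 bp) and siRNA-depleted TEs (80, median 500 bp) dispersed along the
chromosome arms, class B (heterochromatic; 80 TEs, median 2500 bp)
packed mostly (85%) into a centromeric window of ±100 kb around each
chromosome midpoint. Placement draws Dirichlet-distributed gaps within
each region, so packing is exact and an over-full region is a hard
error. Each TE carries a superfamily label drawn from class-specific
pools (class B: Gypsy/Copia/MuDR/EnSpm; class A: HAT/SINE/SADHU/LINE/
Harbinger), mirroring which families the field associates with RdDM-
versus CMT2-dependent methylation.

**Temporal siRNA templates.** The ten samples are floral bud (fb),
eight embryonic stages (pg, gl, eh, lh, et, lt, bc, mg), and leaf (lf).
Per-class relative output is a piecewise-linear idealization — no
numeric profile exists to copy, only the qualitative shapes: class A
low at preglobular, rising mid-embryogenesis, jumping at mature green
and staying high post-embryonically; class B high from preglobular,
peaking mid-embryogenesis, collapsing at maturity; depleted ≈ 0
(relative amplitude 1e-4). Template amplitudes are config values, not
claims about measured levels.

**Libraries.** Each of the 30 libraries holds exactly 100,000 collapsed
reads (mass conservation is exact by multinomial allocation). A TE's
expected share is length × template × a per-(TE, library) gamma
multiplier with dispersion 0.2, giving negative-binomial-like counts.
30% of reads are background placed uniformly in non-TE space — keeping
background out of TEs matters because at this depth one read is already
10 RPM. Read lengths are 18–30 nt with a 24-nt mode (75%); 24-nt reads
start with A at 55%. A fraction (25%) of TE reads is multimapping with
3 candidate loci: the true origin plus decoys drawn from TEs of the
same superfamily (topped up from the same class when the family is
small), with the true candidate's position recorded.

**Methylomes.** Cytosines on both strands get contexts from the
sequence (CG / CHG / CHH; CHH subclassified CWA = C-[A/T]-A versus
nonCWA). Baselines are 24% CG, 10% CHG, 3% CHH — typical weighted rates
for vegetative Arabidopsis tissue. Thirty to forty 300-bp DMR intervals
are planted inside class A/B TEs; their CHH sites gain
`dmr_effect` × ramp, with ramp 0 → 1 across pg, eh, et, bc, mg and
default effect 0.40 (40 percentage points at mature green). Coverage is
Poisson(20) per replicate and counts are Binomial(cov, p) with a 0.5%
conversion-error floor; three replicates per stage are simulated and
pooled downstream, so the effective tested depth is ~60×, matching the
pooling the analysis itself performs.

**Nucleosome track.** Long (>2114 bp) class-B TEs carry one of three
occupancy archetypes at the shares reported for the real groups
(56.7% / 33.1% / 10.2%): (1) high occupancy throughout, (2) low edges
(outer 15%) and high body, (3) low throughout, over a 0.3 baseline with
Gaussian noise (sd 0.25) smoothed by a 50-bp moving average.

**What a green test establishes.** Recovery tests show the pipeline can
re-identify the latent structure the generator planted, at desk scale,
under idealized noise (binomial counts, no mapping bias, no sequence
composition effects, no replicate batch structure, single-isoform TE
families). They do not establish performance on real libraries with
millions of reads, genomic repeat structure, or bisulfite artifacts.

## 2. Multimapper reassignment

The update rule is a fixed point of preferential assignment: candidate
weight ∝ total current coverage (unique reads + fractional multimapper
mass, counts included) in the candidate's footprint extended ±25 bp,
renormalized per read; iteration stops when the largest per-candidate
change is <1e-6 or after 100 iterations (the partial result is still a
valid fractional assignment; a warning is logged). If no candidate of a
read sees any coverage, weights fall back to uniform. Total mass is
conserved exactly (a final per-read renormalization removes float
drift). Near-symmetric repeat families converge slowly — the uniform
point is an unstable equilibrium of a winner-take-all dynamic — which
is why `max_iter` rather than the tolerance often terminates on dense
synthetic families; the 9:1-skew oracle converges in a handful of
iterations.

## 3. VEV mixture and class assignment

EM with the covariance family Σ_k = λ_k D_k A D_kᵀ (A diagonal,
det A = 1, shared across components). The M-step alternates: D_k and
the eigenvalue vectors come from eigendecompositions of the component
scatter matrices (eigenvalues floored at 1e-8 × data variance); A and
λ_k then alternate to a joint optimum (≤20 inner iterations).
Initialization is k-means++ with 10 restarts, best final log-likelihood
kept; a component whose responsibility mass falls below 1e-6 is
reseeded at a random point and logged. BIC uses the sign convention in
which larger is better, with free-parameter count
(G−1) + Gd + G + (d−1) + Gd(d−1)/2.

The mixture is fitted on log2(RPM + 1) profiles: raw RPM spans four
orders of magnitude at this scale, and on the raw scale the largest TEs
dominate every component. Thresholding (max across samples of the
replicate-mean RPM ≥ 2 → detected) and template correlation both use
the RPM scale. Cluster→class assignment correlates each cluster's mean
profile with the two stage templates (Pearson); the larger correlation
wins, and |Δr| < 1e-6 yields an explicit `unclassified` label. The
"≥2 RPM in at least one sample" reading of the detection rule was
chosen over "in all samples" because the depleted negative-control set
should only contain TEs that never produce siRNAs.

## 4. RMS differential methylation

For S pooled samples at one cytosine, the statistic is the root mean
square of (observed − expected)/N over the 2×S table of (methylated,
unmethylated) counts, expected values from the pooled proportion times
the per-sample coverages. The null resamples each sample's methylated
count from Binomial(cov_s, pooled p); p = (b+1)/(n_sim+1). Identical
proportions short-circuit to p = 1. p-values are refined on a
simulation ladder (300 → 3000 → 30000 → n_sim), a site stopping once 10
null exceedances have been seen; this keeps null sites cheap while
candidate sites get full resolution. The ladder matters because the
Monte-Carlo floor 1/(n_sim+1) must undercut the Benjamini–Hochberg
step-up threshold (≈ fdr × k/m for k rejections among m tested sites):
with m ≈ 3×10⁴ CHH sites per comparison, n_sim = 3000 cannot produce
any rejection at FDR 0.01 regardless of effect size, so the pairwise
DMR pipeline defaults to n_sim = 30000 while the single-site default
stays 3000.

Coverage floors (≥4 reads per sample, ≥3 for preglobular) apply before
testing. DMSs chain within 100 bp (single linkage, transitive) into
0-based half-open regions spanning the first to last site; regions
survive with ≥4 DMSs and ≥20 percentage points of weighted-CHH
difference between the compared samples (the filter compares the two
samples of each pairwise test, not all samples). All 10 pairwise
combinations of the five embryonic methylome stages are tested and the
per-comparison DMRs merged (union; bookended intervals merge). Under a
global null the realized false-DMS proportion measured by the
acceptance suite is ~0 at FDR 0.01 — BH over conservative Monte-Carlo
p-values is itself conservative.

## 5. Chromatin association

Metaplot matrices rescale each region body to a fixed number of bins
with natively binned flanks (defaults 5/4000/2000/2000 → 1600
columns); bin values are mean per-base signal via linear interpolation
of prefix sums, so sub-bin-sized regions degrade gracefully instead of
erroring; minus-strand rows are column-reversed to 5'→3'. Nucleosome
groups come from best-of-10 k-means with groups renumbered by
descending mean occupancy (group 1 = densest). Heterochromatic vs
euchromatic enrichment is the ratio of length-normalized summed RPM
(class B density / class A density), undefined — never infinite — when
the class A density is zero; comparisons across genotypes use Welch's
t on replicate-level ratios (the equal-variance assumption was never
stated, so the safer test is used). TE-family enrichment is
log2(O/E) with a two-sided Fisher's exact test; an absent family
reports NaN for the ratio with the p-value still computed. Mann-Whitney
U is enumerated exactly for n+m ≤ 12 (ties get half counts; two-sided
p = 2·min(tails), capped at 1) and uses the tie-corrected normal
approximation otherwise. Percentile ranking breaks ties by stable TE id
so bin composition is reproducible.

## 6. Degenerate inputs and conventions

- Cytosine tables are 1-based (allc convention); all intervals (BED,
  DMRs, TEs) are 0-based half-open; converters are explicit at the DMR
  boundary (site p → region [p−1, p)).
- A cytosine within 2 bp of its strand's 3' end has no context and is
  skipped with a log entry.
- Zero total coverage in a region is an explicit "no data" (`None`),
  never 0; a zero conversion-control coverage is an error.
- Zero-variance input: PCA returns a flagged degenerate result;
  z-scores return zeros with a flag; Pearson rows give NaN.
- Writers emit sorted rows with %.6g floats so byte-identical
  round-trips are testable.

## 7. Scaling choices for test budgets

The classification-recovery acceptance test runs the full default world
(280 TEs, 30 libraries × 100k reads, ~2 min). The DMR-recovery and
null-FDR acceptance runs use a 2 × 60-kb genome (~30k CHH sites per
comparison, ~2.5 min for all ten comparisons) instead of the 2 × 500-kb
default purely for runtime; effect sizes, depths, thresholds, and seeds
are the stated-world values. The acceptance script additionally scales
the live classification run to 30k reads/library on the benchmark
genome for the same reason.
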