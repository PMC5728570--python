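# Methods

## Data model

Genotypes are stored as a dense individuals × sites `int8` matrix over
{MAJOR = 0, HET = 1, MINOR = 2, TERTIARY = 3, MISSING = −1}, with site
metadata (chromosome, 1-based position, allele pair) kept sorted by
(chromosome, position). The panel is assumed to consist of inbred
(expected-homozygous) lines, so heterozygous calls are treated as noise and
the post-QC state space is haploid-coded: {0, 2, missing}. All internal
intervals are 1-based closed; BED output converts to 0-based half-open.

## Synthetic panel generator

The generator emulates, at the genotype-matrix level, a structured panel of
inbred lines genotyped on two partially overlapping GBS platforms.

**Divergence.** Per site, an ancestral frequency p ~ U(0.1, 0.9) is drawn;
each group's frequency follows the Balding–Nichols model
Beta(p(1−F)/F, (1−p)(1−F)/F), so the expected fixation index among groups
equals the configured `divergence_F`. With `recycle_generations = 0` lines
are independent Bernoulli draws from the group frequencies — the
analytically clean condition used for divergence-recovery checks.

**Relatedness and LD.** With recycling enabled, each group starts from a
small founder pool; every generation, new lines are produced by crossing two
same-group parents, recombining (Poisson crossover count per chromosome,
uniform breakpoints) and collapsing the F1 gamete to a doubled-haploid
line. This yields pedigree relatedness and distance-decaying LD whose scale
is chromosome length / (generations × crossover rate).

**Cross-group haplotype sharing.** Founder Bernoulli draws are coupled
across groups through shared uniforms: founder k of every group uses the
same u_{k,s}, so marginally each founder is an exact Balding–Nichols draw
for its group while groups share an ancestral haplotype background and
differ only where their frequencies diverge. Without this coupling the
groups' local haplotype phases are mutually random — a situation real
breeding pools, which diverged recently from common ancestors, are not in —
and panel-wide imputation is artificially capped. Only cross-group
dependence is introduced; every within-group distribution is unchanged, and
independently drawn (recycle = 0) panels are not affected.

**Missingness and noise.** Per-individual missing rates are
N(`miss_rate_mean`, `miss_rate_sd`) clipped to [0, 1] plus
`ref_bias_weight` × (allele-sharing distance to the first simulated line,
the designated reference), clipped to 0.95 — a linear model of the
reference-alignment bias by which lines close to the reference genome have
fewer missing calls. Residual heterozygous and third-allele calls are
injected uniformly at random at rates `het_rate` and `tertiary_rate`; they
exist purely to exercise QC.

**Platforms.** A fraction `platform_overlap` of the site union is shared;
the remaining sites split evenly into platform-private halves. Individuals
split between platforms at `platform1_fraction` (default 291/349, the ratio
of the two real GBS sets this design emulates), since the merge contract
requires disjoint individual sets.

### Default configuration

| parameter | default | why |
|---|---|---|
| n_groups / lines_per_group | 3 × 44 | three heterotic groups at the balanced-subsample size |
| n_chrom × sites_per_chrom | 10 × 1,000 | ten maize chromosomes, compressed |
| chrom_length_bp | 200,000 | compressed chromosome; sets the bp scale of LD |
| divergence_F | 0.15 | moderate divergence, the regime reported for elite maize pools |
| n_founders_per_group | 2 | two founder haplotypes per pool give strong local LD |
| recycle_generations | 2 | two rounds of cross-and-self; pedigree depth |
| recomb_rate | 10 / chromosome / meiosis | LD decay scale ≈ 10 kb ≫ 200 bp marker spacing |
| miss_rate_mean / sd | 0.0622 / 0.03 | the per-individual missing level the QC stage reports |
| ref_bias_weight | 0.05 | mild positive missingness–distance coupling |
| het_rate / tertiary_rate | 0.0025 / 0.001 | trace call noise (~0.25 % hets) |
| platform_overlap | 0.172 | the shared-site fraction of the two-platform design |

These values were fixed by a calibration pass before the test suite was
written. On this configuration the masked-data imputation accuracy is
≈ 0.83, the k = 3 Ward/Nei cut recovers the planted groups exactly, and
adjacent-site mean r² (≈ 0.27) clearly exceeds the long-range background
(≈ 0.07). A dedicated LD configuration (one group, 2 founders,
`recomb_rate = 55`, 4 × 1,000 sites) places the true r² = 0.2 crossing near
1 kb; the estimated crossing is stable at ≈ 1.1–1.2 kb across seeds.

### What the generator does not emulate

Sequencing reads, depth-dependent call quality, selection, gene conversion,
realistic genetic maps, allele-frequency spectra skewed toward rare variants
(ancestral frequencies are uniform on [0.1, 0.9]), and more than two
platforms. Passing recovery tests therefore demonstrates correctness of the
estimators under a clean, analytically known model — not robustness to
every artefact of real GBS data. With recycling enabled, drift inflates
realized group divergence above the nominal `divergence_F`, which is why
divergence recovery is checked on independent-lines panels.

## Statistical procedures and numerical choices

**Merging.** Sites are keyed on (chromosome, position). A site present in
both inputs with a swapped allele pair is kept with the second input's
calls recoded; an irreconcilable allele pair drops the site (counted in the
report). Report percentages are recomputed from the merged matrix, never
carried over.

**QC ordering.** HET → missing, TERTIARY → missing, then the missingness
filter, then the MAF filter, with MAF and missingness recomputed after the
conversions (a `maf_before_conversion` flag provides the alternative
order). A site failing both filters is attributed to the missingness rule.
The per-individual 30 % missing cap is a report-only check: it is a
consequence of the site filters, not a filter of its own. The site
missingness default is 0.172; 0.10 is a plausible alternative and both are
plain config values.

**Imputation.** Transition tables use pseudocount 0.5 per cell; rows are
normalised over lines observed at both pair sites. Decoding is greedy
argmax (not sampling) for determinism, with ties broken toward the major
allele; a missing call at the start of a chromosome uses the site-marginal
argmax. Chromosomes with one site carry marginals only. Accuracy
estimation refits the model on the masked matrix by default, mirroring real
use and avoiding optimistic bias.

**LD.** r² is computed within chromosomes only, on polymorphic sites, as
the squared Pearson correlation of 0/2 call vectors (provably equal to the
haplotype-count form for haploid data; the equivalence is tested). Pair
counts above `max_pairs` trigger a seeded uniform subsample, flagged in the
result. The decay curve is Nadaraya–Watson regression with a Gaussian
kernel on log10(distance); bandwidth defaults to Silverman's rule on the
pooled log-distances, floored at 0.05 log10-bp. d* is the first grid point
where the smoothed curve drops to 0.2, reported only when the curve starts
above 0.2.

**PCA** is an SVD of the column-centered (optionally scaled) call matrix;
percent variance is defined only when total variance is positive. The
scree "elbow" (largest second difference of eigenvalues) is advisory; k is
always a user decision.

**Nei distance.** For fully-inbred individuals the per-locus allele
frequencies are 0/1 indicators, so D = −ln(fraction of matching loci).
The normalising denominator uses √(J_X · J_Y). A pair sharing no allele
anywhere gets infinite distance and is flagged; clustering refuses infinite
inputs.

**Ward.** Lance–Williams with Ward coefficients applied to the supplied
dissimilarities as-is (`ward.D`, the historical R dialect, appropriate for
a non-Euclidean Nei matrix) or to their squares with square-rooted heights
(`ward.D2`). Height inversions are possible on non-Euclidean input and are
counted, not raised. `cut_tree` removes the k−1 highest merges, breaking
height ties by merge order, and numbers groups by leaf order.

**Weir–Cockerham θ** uses the haploid variance decomposition (no
heterozygote component — QC removed hets, lines are inbred). Loci are
estimable when ≥ 2 groups have ≥ 2 non-missing calls; monomorphic loci are
flagged undefined and excluded from the overall mean. The overall
statistic is the simple average of per-locus θ; a ratio-of-sums variant is
available (`overall_method="ratio"`). The simple average is a
mean-of-ratios and sits slightly below the simulated F (≈ 0.135 at
F = 0.15 for 3 × 44 lines); it is kept because it is the field's reported
statistic for this analysis.

**Regions.** The genome scan averages θ over 70 consecutive defined loci
(per chromosome, step 1, anchored to first/last marker positions). Region
extraction visits windows in descending mean; a window overlapping an
already-open region on its chromosome is absorbed (span union, mean = max
window mean), otherwise it opens a new region, until the requested count
exists — lower-ranked windows are then no longer absorbed, which keeps
step-1 sliding windows from chain-absorbing whole chromosomes. Ties order
by (chromosome, position). Region size is last − first marker position.

**Balanced unrelated subsampling** greedily removes, from each group's
current closest pair, the member with the smaller average distance to the
rest (ties lexicographic) until the target size remains, so exact
duplicates go first. The procedure is deterministic and the kept/removed
roster is always emitted. It is a heuristic: single swaps can occasionally
improve the kept set's minimum pairwise distance, but on exhaustive small
instances the greedy choice ranks in the top 30 % of all same-size subsets.

**Candidate genes.** A gene is a hit when its closed 1-based interval
intersects [pos − 10,000, pos + 10,000]; distance is 0 inside the gene,
else the gap to the nearer end. GFF3 is read through an in-memory gffutils
database (`gene` features); plain 4/5-column TSV is also accepted.

**Reporting.** Table-style percentages round half-away-from-zero at the
configured precision. Pipeline runs write a manifest with a SHA-256
checksum per artifact; identical configurations reproduce identical
checksums.

## Problem sizes

The default test panel is 132 lines × 10,000 sites; divergence recovery
uses 3 × 44 independent lines × 10,000 loci; LD calibration uses 60 lines ×
4,000 sites with up to 100,000 pairs; masked-accuracy estimates use 3–5
repetitions at 6.22 % masking. These sizes make every recovery check
reproducible on a single CPU in seconds while keeping Monte-Carlo noise
well inside the stated tolerances.

## Known limitations

- The imputation model is first-order and forward-only by design; no
  forward–backward smoothing, no haplotype-library imputation.
- θ confidence intervals (jackknife/bootstrap) are not provided.
- The LD smoother's bandwidth is a global plug-in value, not locally
  adaptive; very sparse distance ranges are smoothed coarsely.
- Multi-allelic sites are collapsed to a TERTIARY state rather than
  modelled; lift-over between genome builds is out of scope.
- The region-coalescing rule is one reasonable reduction of overlapping
  windows; alternatives (e.g. threshold-based peak calling) would give
  different region boundaries.
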