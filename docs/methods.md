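# Methods

This note documents the models behind each stage, the parameters that
matter, the numerical choices, and what the synthetic data do and do not
establish.

## Synthetic populations

**RIL generator.** Lines are simulated by single-seed descent: a fully
heterozygous F1 selfs for `selfing_generations` generations (default 6, a
typical advanced-RIL depth; the generation number of the emulated
population is not published, so it is a free parameter). Each meiosis is a
Markov chain along the marker map — the gamete starts on a random parental
haplotype and switches between haplotypes with probability
r = (1 − e^(−2d/100))/2 per inter-marker interval of d cM (Haldane map
function: no crossover interference; chosen for its closed form — at the
0.8-cM default spacing interference is immaterial). This reproduces the
two diagnostic expectations tested in the suite: heterozygote frequency
(1/2)^g and allele frequency 1/2, plus monotone LD decay with map
distance. Backcross or intercross designs are not modeled. The default
map is 12 chromosomes × 125 evenly spaced markers (60 Mb / 100 cM per
chromosome, linear cM–bp relation), roughly the marker density of a
resequenced tomato RIL panel after parental-index filtering.

**Trait generator.** y = a·g_QTL + u + e with each component centered and
scaled against its empirical standard deviation so the realized variance
fractions equal `pve_qtl` and `pve_polygenic` exactly; e carries the
remainder and a baseline of 50 shifts values into a plausible
compression-force range. The polygenic term is a random weighting of all
marker columns rather than a draw from N(0, K) — deliberately, so the
generator shares no code with the kinship/REML machinery it is used to
test. Because components are mutually uncorrelated only in expectation,
the causal-marker R² of a single replicate scatters around the simulated
PVE (±0.05 is routine at n = 219); claims are therefore made about means
over replicates.

**Masking.** Calls are hidden independently at `missing_rate`, and the
mask index records the truth, giving imputation an exact scoring set.

**Diversity panel.** Two cohorts of near-inbred accessions (defaults 53
wild vs 166 cultivars, matching the accession panel sizes of the emulated
study) are simulated as consensus haplotypes (calls 0/2) at segregating
sites placed by a Poisson process. Site frequencies are drawn
p ~ U(0.05, 0.95), and the site density is θ / E[2p(1−p)] so the expected
windowed per-bp diversity equals `theta_per_bp` (default 0.005, a
tomato-like resequencing diversity) — the suite verifies the calibration
to within 5%. Inside the engineered sweep interval each site is fixed in
the cultivated cohort with probability 1 − `sweep_reduction`, scaling its
expected diversity linearly. Sites are exchangeable: there is no
linkage, no coalescent genealogy, no demography, and no selection
dynamics. Passing sweep-recovery tests therefore show that the windowing,
ratio, cutoff and merging logic recover a diversity deficit of known
location and depth; they do not show robustness to background LD or
bottleneck-induced diversity troughs in real panels.

All generators are pure functions of (config, seed); per-component
streams are derived from the seed with stable label hashes, so adding a
stage never perturbs another stage's draws.

## Variant filtering and genotype I/O

The hard filter removes a site iff any of QD < 2.0, FS > 60.0, MQ < 40.0,
MQRankSum < −12.5, ReadPosRankSum < −8.0 (strict inequalities) holds, or
DP < 10. A criterion whose annotation is absent does not fire — the
behavior of the GATK VariantFiltration idiom the expression comes from —
and absences are tallied separately in the rejection report. Multiallelic
sites are flagged and excluded from the analysis matrix, which is defined
on biallelic dosages. VCF input is parsed by cyvcf2 (diploid GT → dosage
of the alternate allele; `./.` → missing); output is a minimal VCF v4.2
text emitter, since matrices here are born in memory rather than edited
from an existing file. htslib does not expose text line numbers on parse
failure, so malformed-input errors name the file and the 1-based record
index where the defect is detectable. The parental marker index keeps
markers where the two inbred parents are clean opposite homozygotes and
orients coding so 0 counts the parent-A allele.

## Imputation

`flank_total` = 20 flanking SNPs are split 10 per side by map order
(truncated at chromosome ends and counted). A candidate line matches the
focal line iff their calls agree at every flanking marker where both are
observed, with at least `min_overlap` (default 10) informative
comparisons — requiring complete overlap would leave most cells
unimputable at realistic missingness, and the unanimity rule already
guards against loose matches. Heterozygous calls participate as ordinary
states. If all matching lines with an observed target call agree, that
call is imputed; otherwise the cell stays missing with a recorded reason
(no match / conflict / too few observed focal flanks). One pass reads
evidence from a snapshot of the input, so observed calls are never
altered, newly imputed calls are never evidence within the pass, and the
result is independent of cell visiting order (tested by column-reversal).
`max_passes` > 1 chains passes on successive snapshots for users who want
iterative filling; the default is one pass to prevent error propagation.
On simulated RIL data at 10% missingness the unanimity rule imputes
~80% of hidden cells at >99% accuracy; the cells it declines are mostly
lines whose local haplotype is unique in the population.

## Mixed-model association

Kinship is the VanRaden centered cross-product
K = W W′ / (2Σ_j p_j(1−p_j)) with missing dosages mean-imputed for this
computation only. REML profiles the restricted log-likelihood over
δ = σ²_e/σ²_g in K's eigenbasis: a 100-point grid on log₁₀δ ∈ [−5, 5]
followed by bounded Brent refinement of the best bracket (the suite
checks the optimum against a 2000-point dense grid). Eigenvalues are
clipped at zero below a PSD tolerance of 1e-8·trace/n.

The default scan protocol is a P3D screen with exact refit:

1. **Screen (P3D).** δ is estimated once under the no-marker model and
   held fixed; each marker is then a GLS fit in the rotated coordinates,
   with a Wald t-test on n − rank(X) − 1 df (t rather than normal for
   small-n calibration).
2. **Exact refit.** Markers with screening p < `exact_refit_p` (default
   0.01) are re-tested with the marker in the fixed effects and δ
   re-profiled per marker on a 161-point grid, vectorized across markers.

The refit exists because P3D with an all-marker kinship absorbs part of a
strong marker's own signal into σ²_g (proximal contamination): in
single-QTL simulations at 19% PVE this deflates the causal test by
several orders of magnitude and costs roughly a quarter of the detections
at the fixed 1 × 10⁻⁶ threshold, while moving the marker into the fixed
effects before estimating the variance components removes the deflation.
The screen is kept because the pure per-marker-REML scan is slightly
anti-conservative marker-wise (null rejection ~0.057 at α = 0.05 in the
calibration runs, versus ~0.049 for the hybrid), and because it makes the
scan effectively one GLS pass. Leave-one-chromosome-out kinship was
considered and rejected: it restores power but cannot absorb the tested
chromosome's share of a marker-built polygenic background, which grossly
inflates the null. Setting `exact_refit_p=None` gives plain EMMAX/P3D;
`p3d=False` gives the exact test everywhere.

Compression (the "compressed" MLM) average-linkage-clusters lines on
kinship similarity, replaces K by group-mean kinship, and reproduces the
uncompressed scan exactly at one group per line (the default — at
n = 219 compression is an approximation with no computational need; the
path exists to mirror the named method). Significant markers
(p < 1 × 10⁻⁶) merge into loci within a 1-Mb gap; per-locus variance
explained is reported as the plain marker R², the natural reading of a
"percent of variation explained" figure (a mixed-model PVE would be an
alternative; the marker R² interpretation is implemented and tested).

## Sweep scan

Per-site diversity is the unbiased estimator π = n/(n−1)(1 − Σp̂²).
Het-free (haplotype-coded) cohorts count one allele copy per accession;
diploid-coded cohorts count two, heterozygotes contributing one of each
(`ploidy="auto"`). Window π divides the summed site values by the full
window length (100 kb, step 10 kb), the common resequencing convention;
callable-site masks are out of scope. Windows are half-open
[start, start + window) on 1-based starts anchored at 1; trailing partial
windows are dropped so windows stay comparable. Ratios π_wild/π_cultivar
are undefined (and excluded from everything downstream) where the
cultivar window has zero diversity, which avoids inflating the empirical
quantile with infinities. The top-5% cutoff is the nearest-rank-lower
order statistic — the ⌈0.95·m⌉-th of m finite ratios — pinned because
interpolation conventions differ between libraries; candidates are
windows strictly above it, merged when overlapping or within
`merge_gap_bp` (default 0, i.e. touching windows only). The cutoff is
computed over whatever window set is supplied; whether a "top 5%"
threshold should be genome-wide or region-local is a study-design choice
the caller makes by choosing the input.

## Pipeline

Runs are described by a YAML config validated against a full-default
schema (unknown keys rejected with their path, scalars coerced);
every stage seed derives from the global seed and the stage name; the
manifest records the config, package version, SHA-256 of every output,
and wall times. Exit codes: 0 ok, 1 stage failure, 2 config error.

## Problem sizes and runtimes

The replication experiments use 200 populations (219 × 1500) for QTL
recovery/power, 100 polygenic nulls (219 × 1000) for type-I error, 50
five-Mb panels for sweep recovery, and 50 random 30 × 200 matrices
against the exhaustive imputation oracle — sizes at which each claim's
Monte-Carlo error is well below its margin. The full test suite runs in
about two minutes on one core; the acceptance script in well under one.

## Known limitations

No coalescent realism in the panel generator (see above); no multi-locus
or epistatic trait models; no binary traits; biallelic SNPs only; no
phasing, indels, or genotype likelihoods; the fixed 1 × 10⁻⁶ threshold is
the only multiple-testing control, by design.
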