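# Methods

## Scope and model

nucleoidscope analyses binned Hi-C contact maps of small (here ~5.2 Mb,
two-chromosome) bacterial genomes together with transcription and
variant data. All coordinates are 0-based half-open internally and
1-based inclusive in every user-facing report. Contact matrices are
stored full-symmetric with a doubled diagonal (cell *(i,j)* = pairs
linking bins *i* and *j*; cell *(i,i)* = twice the intra-bin pairs), so
block sums equal twice the pair count and binning at 10 kb followed by
2×2 aggregation is exactly binning at 20 kb. Windowed operators (DI,
FIRE, Savitzky–Golay) wrap around circular chromosomes.

## Synthetic data generator

The generator is the package's ground-truth instrument: it plants the
structures the analysis claims to recover and is itself first-class,
tested code.

Expected weight of an intra-chromosomal bin pair at circular distance
*d* (bp) is

    w = (1 + d/binsize)^(-alpha)
        x beta_cid        if the bins share a CID
        x gamma_arm       if the bins are symmetric about the ori-ter axis
                          (within one bin of x_i + x_j = 0 mod L,
                          coordinates taken relative to ori)
        x delta_prophage  if either bin lies in a prophage region.

Distance enters in bin units: with a bp-unit power law at alpha = 1 the
self-bin weight would exceed a 10 kb-distant pair's by 1e4 and virtually
every simulated pair would land on the diagonal, which matches no real
bacterial map. Inter-chromosomal cells carry a uniform background
`epsilon_trans`, multiplied by `rho_ori2crts` in a ±2-bin zone around
the (crtS, ori2) bin pair and by `1 + (rho-1)/2` in a matching zone
around (ter1, ter2). The zones reflect that replichore tethering in
two-chromosome bacteria is a region tens of kb wide, not a single point;
the ter companion models the symmetric ter-ter colocalization that
weakens together with the ori2–crtS contact in the perturbed condition.

Weights are normalized to probabilities over unordered bin pairs and
`n_pairs` contacts are drawn as a single multinomial, so total depth is
controlled exactly (valid-pairs bookkeeping). The *observed* matrix
multiplies the true counts by a rank-1 bias `b_i b_j` and re-rounds,
where `b` is the exponential of a moving-average-smoothed white-noise
field (a cheap smooth Gaussian-process proxy), scaled to log-sd
`bias_amplitude` and mean 1 — a stand-in for the GC/mappability/
restriction-site visibility biases that iterative correction removes.

Defaults (chosen once as the study conditions; all exposed):

| parameter | default | meaning |
|---|---|---|
| alpha | 1.0 | distance-decay exponent |
| beta_cid | 2.0 | within-CID enrichment |
| gamma_arm | 1.5 | ori-ter cross-diagonal enrichment |
| delta_prophage | 0.5 (mutant) / 1.0 (WT) | prophage depletion |
| epsilon_trans | 0.005 | inter-chromosomal background (~15% of contacts) |
| rho_ori2crts | 8 (WT) / 4 (mutant) | tether-zone multiplier |
| n_pairs | 2,000,000 | valid pairs per sample |
| bias_amplitude | 0.3 | log-sd of per-bin visibility bias |
| binsize | 10 kb | default working resolution |

Default layout: chr1 3.2 Mb, chr2 2.0 Mb, both circular; ori at 0 and
ter at L/2 on each; crtS at 40% of the ori1→ter1 replichore (640 kb); a
single 200 kb prophage interval on chr1 (1.30–1.50 Mb); five irregularly
spaced CID borders per chromosome.

Transcription: genes (log-normal lengths ~0.9 kb, clipped 150–6000 bp)
are placed uniformly; expected expression is
`exp(N(mu, sigma)) * exp(k_fire * z)` with `z` the FIRE z-score of the
gene's bin, and replicate counts are Poisson draws scaled to `libsize`
fragments. Coverage spreads pooled counts over gene footprints by bp
overlap. Variants are uniform background positions plus a uniform
cluster inside a chosen region, typed SNV/insertion/deletion with
concrete alleles.

What the generator does **not** emulate: read-level artifacts (dangling
ends, self-circles, PCR duplicates), restriction-fragment granularity,
condition-dependent decay exponents, overdispersed (non-Poisson)
expression noise, and any causal link between variants and contacts —
variant placement and contact depletion are planted independently.
Passing recovery tests therefore demonstrates correctness of the
estimators under these statistical conditions, not performance on real
libraries.

## Balancing

`ice_normalize` is plain iterative correction: divide by row/column
marginals until the coefficient of variation of unmasked marginals is
below `tol` (default 1e-5, `max_iter` 300). Bins in the lowest 2%
marginal quantile (or empty) are masked; output is rescaled to preserve
the depth of the unmasked submatrix — whether published maps were
depth-rescaled after normalization is generally unstated, so we preserve
depth and say so. The returned bias vector satisfies
`balanced = raw / (b_i b_j)` and is NaN on masked bins.

## Replicate concordance and map resolution

Concordance is the depth-weighted mean over intra-chromosomal distance
strata (one per bin distance up to `max_dist`) of the Pearson
correlation between the two matrices' cells at that distance, skipping
zero-variance strata. It is a documented, desk-implementable replacement
for QuASAR-style replicate QC: same intent, simpler machinery. Map
resolution follows the standard criterion: the smallest candidate bin
size at which ≥ 80% of bins have a marginal of ≥ 1,000 contacts, falling
back to the largest candidate with a warning flag.

## Significant interactions

The caller mirrors Fit-Hi-C v1 semantics without its spline machinery:
intra-chromosomal pairs with circular distance in [L, U] (defaults
20 kb / 2 Mb) are grouped into up to `n_strata` (default 200)
equal-occupancy distance strata (pairs at one distance never split; on
this genome at 10 kb there are fewer distinct distances than 200, so the
stratification reduces with a warning). Stratum probability = stratum
counts / window total / stratum pair count, smoothed to be non-increasing
in distance by isotonic regression and renormalized. The p-value of a
pair is the exact binomial upper tail `P(X >= x)` with `n` the window
total and per-pair probability the stratum probability times the
normalized product of the two bins' ICE biases (raw counts with
bias-adjusted expectation — the documented default; balanced input works
too). Inter-chromosomal pairs, which have no genomic distance, share one
pooled probability (uniform over inter pairs) with `n` the inter total.
BH q-values are computed jointly; records with p < 0.01, q < 0.01 and
count > 2 (strict, i.e. ≥ 3) are reported. With `passes=2`, pass-1
significant pairs are removed, the model refit **on the same stratum
boundaries** (boundaries always derive from the full pair set, so the
refit only re-estimates probabilities), and all pairs re-scored.

Calibration caveat, measured by the test suite: the exact binomial tail
is discrete and conservative, so on the pure-decay null the attained
fraction of p < t sits below t at these per-pair depths. The suite
asserts non-anti-conservativeness as the operative guarantee and records
the attained level.

## Structural summaries

DI is Dixon's signed chi-squared statistic over upstream/downstream
windows (default scale 100 kb), zero when A = B. Cells in masked columns
are imputed at the per-distance mean of live cells before windowing:
masked bins cluster (visibility biases are smooth), and either dropping
or flat-imputing them biases one window near every masked run, faking
border signatures. CID borders are negative-to-positive DI crossings
whose flanking run extrema both exceed `min_amplitude`; since DI on a
count-scale matrix behaves like a signed chi-squared(2) variable away
from borders (O(1) regardless of depth) the default gate is the 0.999
chi-squared(2) quantile (~13.8). Insulation-score border calling is out
of scope.

The FIRE-like score is the windowed sum of contacts within ±10 kb (self
excluded), z-transformed per chromosome over unmasked bins — a
deliberate simplification of the full FIRE pipeline that keeps its
"local interaction frequency" meaning.

Differential maps are cell-wise `log2((P_B + pc)/(P_A + pc))` of
matrices rescaled to total 1 (depth invariance), with
`pc = 1/(2 min depth)`; cells empty in both samples, or touching masked
bins, are NaN. **Differential comparisons default to depth-normalized
raw matrices, not balanced ones.** Iterative correction equalizes every
bin's visibility by construction, so any per-locus depletion that
multiplies a bin's contacts — exactly the signal a WT-vs-mutant contrast
looks for — is absorbed into the bias vector and vanishes from balanced
maps (on the generator this is provable: the planted depletion leaves a
near-zero, slightly positive row marginal after balancing). Balanced
inputs remain valid for contrasts of internal structure. Differential
regions are maximal runs of ≥ `min_run` (3) bins whose row-mean log2
ratio crosses ±`threshold` (0.3); both defaults are ours — no published
threshold exists for calling such regions — and are echoed in output.

`region_pair_score` reports mean contact probability of a
region-by-region block in two maps and their pseudocounted log2 ratio.

## Expression and variants

FPKM is `1e9 * count / (libsize * length)`. With two replicates per
condition a dispersion estimate is not meaningful, so differential
expression uses a two-sided exact binomial test of a gene's pooled
counts against the pooled library-size ratio; fold change is the ratio
of mean FPKM with a pseudo-FPKM of 0.1 on both means; a DEG needs fold
change ≥ 2 (or ≤ 1/2) **and** BH q < 0.05. All-zero genes are flagged
and skipped. This test is calibrated under Poisson noise (the
generator's regime) and anti-conservative under real biological
overdispersion — a stated limitation.

Variant tables are parsed into typed records (type from allele lengths;
dash alleles normalized; rows annotated only as upstream of an ORF are
excluded from frameshift accounting). Positional clustering is
single-linkage gap chaining: consecutive same-chromosome variants at
most `max_gap` apart join a cluster. The 5 kb default reproduces the
15-member indel hotspot of the bundled resequencing table and is exposed
as a flag; the rule is a reconstruction — the original clustering
criterion behind the published hotspot windows is not stated anywhere.

## Integration

Coverage binning keeps reads with MAPQ strictly above 30 and splits
boundary-spanning reads by bp overlap. Both the contact signal (FIRE z
by default; a ≤ 50 kb short-range-sum variant is provided) and the
coverage track are smoothed with a Savitzky–Golay filter (window 21
bins, order 3 — our defaults, recorded in the report object) before the
Pearson correlation, reported pooled and per chromosome. At ~500 bins a
window-21 smoother leaves the null sd of r near 0.13, so single-run
correlations near ±0.1 are uninformative; coupling conclusions should
average over replicates or seeds, as the test suite does.

Variant–contact enrichment is a permutation test: observed = mean
marginal over unmasked variant-bearing bins; null = the same statistic
for equally many distinct bins redrawn uniformly without replacement;
one-sided p with the add-one estimator (never below `1/(n_perm+1)`).
The published claim this operationalizes names no statistic or
threshold, so the permutation design cannot be validated against a
printed number — it is validated against its exchangeable null and
planted-truth power instead.

The crtS scan slides the query motif over both strands of the (circular)
chromosome-1 sequence, scores fraction identity (ambiguous bases are
mismatches), and reports the best hit's position along whichever
ori1→ter1 replichore arc contains it, as a fraction in [0, 1].

## Numerical and engineering choices

* Strand columns of pairs files are read and preserved but ignored:
  the analysis is strand-agnostic.
* Equal-occupancy stratification warns and degrades gracefully when
  distinct distances are scarce; a single-distance window yields one
  stratum.
* Isotonic smoothing uses scikit-learn's PAVA; BH is implemented
  directly (step-up with monotonicity) and cross-checked against
  statsmodels in the tests.
* ICE non-convergence raises with the final CV; all-zero matrices and
  all-masked inputs are errors, not NaN cascades.
* Simulation determinism: one `numpy` Generator per entry point, seeded
  from the params object; identical seeds give byte-identical outputs.
* Problem sizes in the test suite (2e6 pairs at 10 kb over 5.2 Mb;
  10–20 seeds for recovery rates; 1,000 genes; 1,000 permutations) are
  the package's chosen desk-scale study conditions.

## Known limitations

* No FASTQ/read-level processing, no restriction-fragment model, no
  eigenvector/compartment analysis, no pathway enrichment.
* The significance caller's discrete binomial tail is conservative at
  low per-pair depth (quantified above); no mid-p option is offered.
* The DEG test assumes Poisson counts; use a dispersion-aware tool for
  real libraries with ≥ 3 replicates.
* Balanced-map differential contrasts cannot, by construction, exhibit
  per-locus visibility depletion; use the raw-map default when that is
  the question.
* cool-format export is not provided; matrices interchange as plain-text
  bins BED + COO triplets.
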