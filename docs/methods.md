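# Methods

This note documents the evaluation procedure `dbsconcord` implements, the
generative model behind its synthetic cohorts, the numerical conventions,
and the design choices made where more than one reasonable convention
exists.

## Evaluation procedure

### Call-set model

A call set is a position-sorted list of variant records over a fixed
sample roster. Genotypes are unordered diploid allele pairs; phase is
discarded on input (`0|1 ≡ 1/0`). Half-calls (`./1`) are collapsed to
MISSING at read time: the five comparison categories distinguish only
"present" and "no call", and keeping half-calls would create an undefined
sixth state. FILTER `PASS` and `.` both count as PASS (rewritten or merged
records may carry no filter annotation); any other label — e.g. a VQSR
tranche — counts as FILTERED. Records with symbolic alleles, breakends or
non-diploid genotypes are skipped with a logged count. Coordinates are
VCF-native 1-based; BED inputs are 0-based half-open and converted only
inside the coverage module. Contig names are compared as exact strings —
no `chr` normalization — for bit-exact determinism.

### Caller merge

Sites are identified by their `(chrom, pos)` anchor. "Overlap" therefore
means identical anchor, not interval overlap of REF spans: both callers
genotype the same alignments in multi-sample mode, so allele
representations at a site share an anchor, and interval semantics would
require an allele-normalization step the procedure does not include. When
both callers PASS the same anchor with different alleles, the priority
caller's record wins wholesale (record-level, not allele-level, priority).
A strict mode can reject anchors whose REF differs between callers. The
merge report partitions both inputs: `merged = n_hc_pass + n_ug_rescued +
n_unique_ug`.

### Classification

Each alternate allele is typed against REF by length: equal length 1 →
SNP; longer → insertion; shorter → deletion; equal length > 1 → complex
(MNP). Multi-alt records whose alts are all SNPs are classed SNP — the
multiallelic definitions both require indel involvement or mixed types —
while all-indel multi-alt records are MULTIALLELIC_COMPLEX and any mixture
(or any complex alt) is MULTIALLELIC_MIXED. A single-alt MNP has no bucket
of its own in the four-group taxonomy; it is reported under the
multiallelic group (as MULTIALLELIC_MIXED, an MNP being a combination of
SNPs) and logged rather than silently absorbed, since the choice is a
convention, not a fact of the taxonomy.

### Filtering

Two criteria, both strict (boundary values are removed):

| criterion | statistic | default |
|---|---|---|
| variant level | average sample depth = site DP / roster size | > 20 |
| sample level | minimum GQ across reference-standard samples (minGQ_WB) | > 30 |

The depth denominator is the full roster size of the calling, not the
number of non-missing calls at the site. A reference-standard call that is
missing or lacks GQ contributes 0 to minGQ_WB, so any gap in the reference
standard removes the site at any positive threshold. Whether replicated
whole-blood samples belong to the reference-standard set is not fixed by
the procedure; the manifest flag `is_reference_standard` (and the
generator option `replica_is_reference`, default off) makes it an explicit
choice. Filtering is a pure subset operation — idempotent, order-
preserving, monotone in both thresholds — and every decision is logged
with both statistics.

### Concordance

The five categories (concordant, het/homo, homo/homo, other, missing) are
exhaustive and mutually exclusive, so the rate denominator is **all**
compared sites in the group. That places single-sample no-calls in the
denominator and both-missing pairs in the numerator (they are "identical:
both missing"). Whether both-missing sites should inflate concordance at
poorly covered sites is a legitimate question — pre-filtering they can —
so the long-format category table reports every category count and
fraction, letting any alternative denominator be recomputed. Two further
conventions: identical genotypes involving alleles beyond the first
alternate (e.g. 1/2 vs 1/2) are concordant, since the identity rule takes
precedence over "other"; and comparison is subject-matched — cross-subject
pairs are rejected.

Replicate handling mirrors the triplicate design: each replicate of type A
is compared with each replicate of type B, the resulting **rates** (not
pooled counts) are averaged per subject, and the cohort value is the mean
of per-subject rates. Empty groups yield NaN, never 0, and are skipped in
averaging.

### Coverage

Coverage above a threshold is computed per target base (the default,
matching a "percentage of exome coverage" axis) with a `region_mean` mode
available for the alternative reading, "fraction of regions whose mean
depth exceeds the threshold". Thresholds are strict (`>30X`, `>10X`).
Box-plot quartiles use linear interpolation between order statistics
(numpy's default, the convention of the common plotting systems); whiskers
sit on the most extreme data points within 1.5×IQR of the quartiles and
everything beyond is an outlier.

## Synthetic cohort generator

The generator emulates the three pilot designs (7, 8 and 7 subjects:
DBS+WB; DBS+WB+WB-replica; DBS at two disc sizes with triplicate small
discs, WB and amplified WB — 14, 24 and 42 samples respectively) and
produces two caller-style call sets, a manifest, ground truth, target
intervals and per-base depth tracks, all from one integer seed.

**Sites and truth.** The variant-class mix defaults to 89% SNP, 5%
insertion, 3.5% deletion, 2.5% multiallelic — SNP-dominated inside the
84–94% range observed for exome call sets and ordered SNPs > insertions >
deletions > multiallelic. Per-site alternate allele frequency is
Beta(0.8, 0.8); truth genotypes are Hardy–Weinberg draws per subject
(two-alt sites split the alternate mass 3:1) and are shared by all of a
subject's sample types.

**Depth.** Per-sample, per-site depth is negative binomial with mean
60X × (sample-type attenuation) × (per-site Gamma(3) factor shared across
samples). The shared factor models site capture efficiency — it is what
makes low depth co-occur across samples, so a site that is marginal in the
DBS sample tends to be marginal in the reference too. Attenuation is 1.0
for whole-blood types and 0.78–0.85 for WGA-derived types, producing the
qualitative DBS-vs-WB coverage deficit (roughly 10 percentage points of
target bases above 30X at defaults) without modelling its mechanism.

**Artifacts,** applied per call in the fixed order dropout → error →
missingness (a fixed order keeps analytic expectations computable):

* *Allele dropout* (default 0.05): a truth-het call becomes one of the two
  homozygotes, equiprobably. Confined to WGA-derived types — including the
  amplified whole-blood control, because the artifact belongs to the
  amplification chemistry, not to DBS storage.
* *Genotype error* (default 0.005): the call is replaced by a uniformly
  chosen different genotype over the site's alleles; any sample type.
* *Missingness* (default up to 0.03): a logistic function of depth
  (midpoint 8X) — no-calls concentrate where there is nothing to call.

Dropout and error probabilities are optionally **depth-coupled**
(`artifact_depth_coupling`, default 0.8): the marginal rate is scaled by
`(1−c) + c·w(depth)` with `w` a logistic weight that is ≈1 below ~15X and
≈0 at high depth. At the default coupling, artifacts concentrate at
poorly covered sites — the empirical signature that motivates the depth
filter — and since reference-sample GQ also falls with depth (below), the
minGQ_WB filter removes the same sites from the other side. This is what
produces the filter-rescue effect: post-filter DBS-vs-WB concordance
rises and its gap to the WB-vs-WB baseline shrinks. At coupling 0 the
nominal rates are exact marginals; parameter-recovery experiments use
that setting so the injected dropout probability is the quantity the
het/homo discordance fraction estimates.

**Genotype quality.** GQ is generated, not derived from simulated reads
(read-level simulation is out of scope; the pipeline consumes VCF fields
only): correct calls get `≈ 3.3 × min(depth, 30) + noise`, saturating near
99 above 30X and falling through the 30 threshold below ~10X;
artifact-affected calls draw low GQ (mean 20). Missing calls carry depth
but no GQ.

**Caller disagreement.** Independently per site: priority-caller-filtered/
secondary-PASS (2%), priority-PASS/secondary-filtered (1%), and 2% each of
sites private to one caller. This exercises every merge rule; genotypes at
shared sites are identical between callers, since reconciling caller
genotype differences is not part of the merge procedure.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: linkage disequilibrium and realistic allele-
frequency spectra; alignment and allele-representation discrepancies
between callers; capture-kit-specific target differences; error modes
correlated across sites or samples (e.g. amplification bias shared by a
subject's replicates); GC/mappability structure in depth; and any
calibration of artifact rates to real cohorts — the defaults are chosen
for test power, not estimated from data.

## Numerical choices and degenerate inputs

* Strict inequalities everywhere a threshold is stated (`>20`, `>30`,
  `>30X`); boundary values fail.
* Empty denominators give NaN (never 0): rates of empty groups, summaries
  of empty call sets.
* Sorting is by `(chrom, pos)` with a stable sort, so input order breaks
  ties deterministically.
* Same config + seed ⇒ byte-identical VCF/TSV outputs; all randomness
  flows from one `numpy` generator in a fixed draw order.
* Depth-0 genotypes are not forced missing — missingness is governed
  solely by `missing_prob`, so the artifact-free limit is exactly
  artifact-free.
* VCF parse errors name the data-line index (the underlying htslib parser
  does not expose file line numbers).

## Problem sizes

The test suite and the acceptance script run cohorts of 10,000–20,000
sites and 14–42 samples — large enough that binomial standard errors on
default artifact rates are below half a percentage point, while a full
suite run stays around ten seconds. The full-scale designs (three pilots,
22 subjects, exome-scale site counts) run through the identical code
paths; only `n_sites`, `n_subjects` and the target count change.

## Known limitations

* The merge is anchor-based; call sets produced by differently-normalized
  pipelines (decomposed vs joint multiallelic representation) would need
  external normalization first.
* minGQ_WB presumes at least one designated reference sample per pilot;
  designs without a whole-blood standard cannot use the sample-level
  filter.
* Concordance compares genotypes at shared merged sites only; it does not
  measure site-discovery sensitivity.
* The coverage module consumes per-base depth tables; it does not compute
  depth from alignments.
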