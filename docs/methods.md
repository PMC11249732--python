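# Methods

This note documents the models and procedures behind `rohdice`, the
parameter defaults and why they were chosen, what the synthetic-data
generators do and do not emulate, and the numerical conventions used
throughout.

## ROH diplotype clusters and the calling pipeline

An *ROH diplotype cluster* is a set of at least `W` individuals whose
unphased genotypes are homozygous and identical over at least `L`
consecutive biallelic sites. The caller works on one chromosome at a time:

1. **Compression.** Genotypes (alternative-allele counts, {0,1,2}) are
   mapped to a binary alphabet: 0→0, 2→1; each heterozygous cell is assigned
   0 or 1 by a fair coin from a single seeded generator. The positions of
   heterozygous cells are retained in a mask. The seed is part of the run
   configuration and is written into every output header.
2. **PBWT scan.** The compressed panel is sorted site by site by reversed
   prefix (stable; ties broken by original row index). The update maintains
   the prefix array `a` and divergence array `d` (`d[i]` = start of the
   longest suffix match between sorted neighbours, `d[0] = k` sentinel) in
   O(M) per site using a vectorized segmented-maximum. An optional
   per-column "missing" mask makes specified cells match nothing — used by
   the ground-truth construction, where heterozygous filler must not match.
3. **Block enumeration.** At each end position `e`, runs of consecutive
   sorted entries with divergence ≤ `e − L` are maximal candidate blocks.
   Two objectives:
   * *width-maximal* — a run of ≥ `W` entries with start `s` = the maximum
     divergence inside the run is reported exactly when the run is about to
     lose a member (allele split or panel end). This maximizes carrier
     counts, the quantity association tests care about.
   * *length-maximal* — the laminar family of runs (recursively split at
     their internal maximum divergence) is enumerated; a node is reported
     when no ≥ `W` subset survives extension by one site on either side.
   The normative semantics of both is a brute-force window enumeration
   (`oracle_blocks`); the scans are tested to agree with it exactly on
   randomized panels, including with exclusion masks. A by-hand Quickselect
   (`quickselect`) is provided for order-statistic queries on divergence
   values; the scans themselves use direct maxima, which profiling showed to
   be simpler and no slower at these scales.
4. **Post-processing.** Within each block, members whose heterozygous
   fraction inside the span exceeds `max_member_het` (default 0.01) are
   dropped; blocks whose width then falls below `W` are discarded (the
   output contract "≥ W carriers" stays true); clusters with identical
   (start, end, consensus) are merged by uniting member sets (idempotent).
   Genomic coordinates are attached from the site metadata; genetic length
   is linearly interpolated from a user-supplied genetic map and left null
   otherwise — converting bp to cM by a fixed factor would be
   population-specific and is deliberately not done.

Conventions: sites are 0-based with half-open intervals internally; all
user-facing files carry 1-based inclusive bp coordinates (VCF convention);
the conversion lives in the I/O module only.

### False-positive control

For unrelated sequences the probability that `W` compressed rows collide
over `L` sites is of order 2^−L per window; at the default working point
(L=100, W=100) the expected number of spurious clusters in any realistic
panel is effectively zero. The test suite verifies zero calls on twenty
500×1000 null panels with allele frequency 0.5.

## Synthetic data

### Planted-cluster generator

`plant_clusters` draws independent Hardy–Weinberg genotypes at alternative
allele frequency 0.1 (≈18% heterozygous cells, the typical array-data rate),
overwrites chosen members with one shared homozygous diplotype per planted
span, and optionally flips planted cells to heterozygous at a given noise
rate. The planted truth is exact by construction, which makes it the fixture
for recovery, filtering and calibration tests. It does **not** emulate
linkage disequilibrium, allele-frequency spectra, or relatedness — sites are
independent — so passing planted tests demonstrates correctness of the
machinery, not performance on real data.

### Coalescent generator

`simulate_coalescent_panel` simulates with msprime and extracts, via tskit,
the within-individual IBD segments — maximal intervals over which an
individual's two haplotypes coalesce in the same ancestral node, i.e. true
runs of homozygosity by descent, with the ancestral node recorded.

**Demography.** ROH diplotype clusters require many individuals to be
autozygous for the *same* ancestral haplotype at the same locus. Broad
European demographic models (out-of-Africa with recent growth) produce
essentially none of this at the target widths: we verified that a
Gravel-style three-population model yields zero ground-truth clusters at
W≥20, L≥100 in a 200-diploid sample, which would make the evaluation
vacuous. The default demography is therefore a **sustained founder
isolate**: 30 diploids for the last 50 generations, splitting from a
constant ancestral population of 40,000 (European-scale diversity), with
mutation rate 1.25×10⁻⁸ and recombination rate 1×10⁻⁸ per bp per
generation. These values reproduce the panel regime this package is
designed for: ~2.4×10⁴ sites at MAF ≥ 1% from 200 diploids over 10 Mbp,
and order 10³ width-maximal clusters at L=100, W=5 when 0.1% genotyping
error is present. The isolate is at the extreme end of published human
founder populations (Pingelap-scale rather than Ashkenazi-scale); headline
power/accuracy numbers are sensitive to this choice, which is why the
demography object is a public, overridable argument.

**Filtering and error.** Sites with minor allele frequency < 1% (diploid
counts) are removed before anything else. Genotyping error perturbs each
cell independently with the given probability, redrawing uniformly from the
two other genotype states (the text this follows states only the rate; the
symmetric redraw is our choice). Ancestry, mutation and error use separate
streams derived from one master seed, so clean and error panels from the
same seed share the same underlying genotypes.

**IBD floor.** Segments shorter than `min_ibd_span` (default 2 kb) are not
reported: at ~2.4 sites/kb a segment far below L×(site spacing) cannot
support a cluster, and the floor keeps the segment list small. Lowering the
floor adds short truth segments and slightly lowers measured power (more
truth to recover); 2 kb is comfortably below the ~20 kb an L=50 block
occupies.

## Ground truth and metrics

`ground_truth_clusters` builds an interim genotype panel: heterozygous
filler everywhere (excluded from matching), and each IBD span painted
homozygous. Two painting modes:

* **Clean-panel painting** (used whenever the error-free panel is
  available, including by the acceptance script): each span is filled with
  the individual's own clean genotypes, heterozygous cells staying
  excluded. Individuals autozygous for nested coalescence heights of the
  same haplotype line then merge exactly as their real sequences dictate,
  and sites broken by private mutations are excluded — the truth is the
  descent-supported, data-visible identity.
* **Node-keyed painting** (fallback when only segments are available, e.g.
  from a file): random alleles drawn once per (ancestral node, site), so
  individuals sharing the same MRCA node share alleles. This undercounts
  cluster widths because nested ancestors are treated as distinct; it is a
  fallback, not the reference construction.

The block finder is then run on the interim panel with heterozygous cells
masked, at the same (L, W) as the evaluation target.

**Metrics** operate in (member × site) cell space: `overlap_ratio(r, t)` =
|cells(r) ∩ cells(t)| / |cells(r)|. *Accuracy* averages, over reported
clusters, the best overlap ratio against any truth cluster (a precision).
*Power* averages, over truth clusters, the capped cumulative fraction of
truth cells recovered by all reported clusters together — large true
clusters reported as several fragments are fully credited. Cell space
penalizes wrong members and wrong spans simultaneously; a site-only variant
(`mode="sites"`) is exposed for sensitivity analysis.

Because this truth contains only genuine, data-visible autozygosity, the
caller recovers it nearly completely in founder panels: detection power and
accuracy here run *higher* than evaluations whose painted truth includes
identity the observed genotypes do not support (e.g. painting from pairwise
between-individual IBD with order-dependent overwrites). Comparisons with
such evaluations should lean on orderings (error robustness, threshold
behaviour, method rankings) rather than absolute percentages.

## Association and linkage statistics

* **Chi-squared association**: 2×2 carrier × disease table with D1 =
  diseased carriers, N1 = healthy carriers, D2 = diseased non-carriers,
  N2 = M − D1 − N1 − D2; Pearson statistic with 1 df, no continuity
  correction by default (a Yates flag exists). Any zero expected cell flags
  the result degenerate (p = NaN). Odds ratio (D1·N2)/(N1·D2), infinite
  when the denominator vanishes.
* **D′**: between cluster membership (frequency p_R) and a SNP's alternate
  allele (allele frequency p_S), with p_RS the fraction of individuals both
  in the cluster and carrying ≥1 alternate allele; D = p_RS − p_R·p_S. The
  default normalization is the standard D/Dmax with
  Dmax = min(p_R·p_s, p_r·p_S) for D>0 and min(p_R·p_S, p_r·p_s) for D<0,
  giving |D′| ≤ 1. A `paper-literal` mode evaluates the unnormalized
  max-form expression sometimes printed; it is not bounded and exists for
  comparison only.
* **Hotspot/coldspot scan**: each site scores the maximum member count over
  covering clusters (0 if uncovered); hotspots are sites strictly above the
  99.5th percentile of site scores, coldspots strictly below the 0.5th.
* **Power comparison**: per replicate, a causal cluster is drawn uniformly
  and Y = Xβ + N(0, σ²) simulated on its carrier indicator (σ² = 0.1
  default). The cluster method tests every cluster's membership with a
  pooled two-sample t-test (equivalent to the regression slope test) and
  succeeds when the *causal* cluster passes α/#clusters. Each GWAS coding
  (additive 0/1/2, dominant ≥1, recessive =2) runs per-site simple linear
  regressions and succeeds when any site inside the causal span passes
  α/#informative sites; constant codings are skipped and excluded from the
  Bonferroni count. The replicate-wise *any-rejection* rate is also
  reported (`fwer` column), which at β = 0 estimates the family-wise error
  rate; with Bonferroni at α = 0.05 it stays below 5% (verified by binomial
  test at 200 replicates). The effect-size grid defaults to 0–0.3 in steps
  of 0.05.

## Problem sizes

The default evaluation (as run by `scripts/acceptance.py`) uses 200 and
1000 diploids over 10 Mbp — panels of ~2×10⁴ sites — with 100 phenotype
replicates per effect size; the whole run completes in about a minute on
one CPU. The test suite uses the same machinery at smaller sizes (≤200
individuals, ≤2000 sites for planted fixtures; one full 200-diploid
coalescent run).

## Known limitations

* Panels are processed in memory and per chromosome; biobank-scale runs
  (10⁵–10⁶ samples) would need a streaming PBWT, which is out of scope.
* The heterozygote coin makes calls seed-dependent at block boundaries;
  the planted-fixture tests bound this at ±2 sites and ≥95% membership.
* The founder-isolate default is a stylized demography chosen to produce a
  cluster-rich regime, not a fitted model of any specific population.
* The evaluation's ground truth is conservative (descent-supported identity
  only), so absolute power/accuracy values are not comparable across
  differently-constructed truths; use the provided orderings.
* Covariate-adjusted regression, mixed models/kinship, binary-trait
  logistic GWAS and phasing are out of scope.
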