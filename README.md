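# rohdice

**PBWT-based enumeration of runs-of-homozygosity (ROH) diplotype clusters in
genotype panels**, with a simulation-based evaluation harness and
cluster-level association statistics.

## The problem

A run of homozygosity is a stretch of a diploid genome where an individual's
two haplotypes are identical — both inherited, ultimately, from one ancestral
haplotype. Classical ROH studies collapse each genome's ROH content into a
single number (total length or count), which cannot map trait loci. The
object of interest here is instead the **ROH diplotype cluster**: a set of at
least *W* individuals whose unphased genotypes are homozygous *and identical*
over at least *L* consecutive biallelic sites — i.e. many carriers of the
same doubled ancestral haplotype. Such clusters act as multi-marker recessive
alleles: membership can be tested directly against phenotypes, recovering
recessive signals that single-SNP additive GWAS misses.

Enumerating all diplotypes above a length and frequency threshold naively is
hopeless in a biobank-scale panel. `rohdice` does it in **O(N·M)** time for
*M* individuals and *N* sites:

1. **Compression.** Each genotype x ∈ {0, 1, 2} (alternative-allele count) is
   collapsed onto a binary alphabet: 0 → 0, 2 → 1, and each heterozygous site
   is assigned 0 or 1 by a fair, seeded coin. True shared ROH survive this
   almost untouched (they contain few heterozygous calls), while the chance
   that unrelated sequences collide over ≥ L sites is ~2^−L.
2. **Positional Burrows–Wheeler transform.** The compressed panel is sorted
   site by site by reversed prefix, maintaining the prefix array a_k and the
   divergence array d_k (d_k[i] = start of the longest match between
   neighbouring sorted sequences). Sequences sharing a long suffix are then
   adjacent, and match blocks are runs of entries with small divergence.
3. **Block-maximal matches.** Blocks of ≥ W sequences identical over ≥ L
   sites are reported under either of two objectives — **width-maximal**
   (maximize the number of carriers; preferred for association) or
   **length-maximal** (maximize the number of sites). Both scans are tested
   to agree *exactly* with a brute-force definition on randomized panels.
4. **Post-processing.** Members with more than 1% heterozygous sites inside
   the block are removed, widths are re-checked, and clusters with identical
   span and consensus are merged.

The package also ships:

* `simulate` — coalescent panels of a European-ancestry founder isolate
  (msprime), with within-individual IBD segments (tskit) as ground truth,
  plus a planted-cluster generator for exact unit fixtures;
* `evaluate` — IBD-painted ground-truth clusters and the cell-space
  **accuracy** (precision of reported clusters) and **power** (cumulative
  recovery of true clusters) metrics;
* `assoc` — 2×2 chi-squared cluster–disease association, D/D′ linkage
  between a cluster and a SNP, per-site ROH hotspot/coldspot scores, and a
  phenotype-simulation power comparison (cluster test vs additive, dominant
  and recessive single-site GWAS).

## Worked example

```python
import rohdice as rd

panel, ibd = rd.simulate_coalescent_panel(100, 2_000_000, seed=7)
clusters = rd.call_roh_clusters(panel, L=100, W=10, seed=7)
_, truth = rd.ground_truth_clusters(ibd, panel.site_meta, L=100, W=10,
                                    n_individuals=100, panel=panel)
table = rd.power_comparison(panel, clusters, betas=[0.3], n_reps=50, seed=7)
```

prints (via the accompanying report lines):

```
panel: 100 diploids x 7553 sites (MAF >= 1%), 12089 within-individual IBD segments
30 ROH diplotype clusters at L=100 sites, W=10 carriers
widest: sites [6903, 7006) = 1:1828632-1849005, 64 carriers
ground truth: 12 clusters; power=1.000, accuracy=0.846
  roh       beta=0.3: power=0.50
  additive  beta=0.3: power=0.00
  dominant  beta=0.3: power=0.12
  recessive beta=0.3: power=0.12
```

Reading this: from 100 simulated diploids over 2 Mbp the caller reports 30
clusters of ≥ 10 individuals sharing an identical homozygous diplotype over
≥ 100 sites; the widest has 64 carriers. Every ground-truth cluster derived
from the simulated genealogies is recovered (power 1.0) and 84.6% of each
reported cluster's member-site cells lie inside a true cluster (accuracy).
When a quantitative trait is attached to one cluster's carriers
(Y = Xβ + N(0, 0.1), β = 0.3), testing cluster membership finds the signal
in 50% of replicates under Bonferroni correction, whereas the best
single-site GWAS coding reaches 12% — the recessive multi-marker signal is
largely invisible to site-by-site tests.

The same pipeline is available from the shell:

```sh
rohdice simulate --n-diploid 200 --seed 1 --out-vcf panel.vcf --out-ibd ibd.tsv
rohdice find panel.vcf -L 100 -W 100 --objective width --seed 1 -o clusters.tsv
rohdice evaluate panel.vcf ibd.tsv -L 100 -W 20
rohdice power-sim panel.vcf -L 100 -W 5 -o power.tsv
rohdice hotspots clusters.tsv --n-sites 23699 -o scores.tsv
```

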