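# Methods

This note records the models, estimators and design choices behind `satkit`,
what the synthetic-data generator does and does not emulate, and the
numerical conventions used throughout.

## Coordinate and format conventions

All intervals crossing module boundaries are 0-based half-open; conversion
from 1-based closed conventions (GFF3, VCF POS) happens in `io_formats` and
nowhere else. Phased (`0|1`) and unphased (`0/1`) genotypes compare equal
everywhere dosages or genotype identity are needed; phase is retained only
when SV records are written back out. `N` bases never match any base, so
they count against identity (the denominator is always the full motif
length).

## Telomere detection and the T2T criterion

Chromosome ends are scanned for the vertebrate telomeric hexamer — TTAGGG
on the G-rich q terminus, CCCTAA (its reverse complement) on the p terminus
of the forward strand. Copies are non-overlapping exact hexamer matches
chained into tandem runs; a run may bridge at most one divergent hexamer
(parameter `max_interruptions`, default 1), and only runs whose outer edge
lies within the terminal search window count. The window defaults to 10 kb:
larger than any terminal array the generator produces, small enough to
exclude interstitial telomeric repeats. A chromosome is classified
T2T-complete when both ends carry at least 10 motif copies; the threshold
is exposed (`min_copies`) and completeness is monotone in it by
construction.

Telomere patching replaces the sequence distal to an alignment anchor with
the donor contig's distal sequence, reverse-complemented for minus-strand
anchors. The operation refuses to run when the target end is already
complete, when the anchor lies more than 100 kb (configurable) from the
end, or when the donor carries fewer than `min_copies` motifs distal to its
anchored interval. Provenance (donor id, anchor, bases replaced/added) is
returned alongside the patched sequence.

## Satellite monomer discovery

Tandem periodicity is detected by k-mer offset autocorrelation: for each
candidate period p in [20, 500], the genome-wide fraction of positions i
with base(i) = base(i+p), length-weighted across chromosomes. Local maxima
exceeding the median score by `peak_delta` (default 0.02) propose candidate
periods. For each, the array is localized as the longest region where the
smoothed lag-p match signal exceeds 0.6; the region is chopped into
p-length units and the consensus is the column-wise majority vote (ties
break alphabetically). Candidates are dropped when the consensus is
low-complexity (base-composition entropy < 1 bit — rejects homopolymer and
AT-microsatellite artifacts), when mean unit identity falls below 0.8, or
when fewer than `min_copies` (50) units support them. Because a true period
p also scores at every multiple m·p, peaks are folded into harmonic
families and reported at the smallest period that passes the identity
threshold: the monomer is the fundamental; the higher-order multiple is
recovered separately by HOR decomposition. Candidates are ranked by total
supporting copy count. Substitution-only mutation does not shift phase, so
peaks stay crisp; indel-rich satellites would smear them (see Limitations).

## HOR decomposition

The array is segmented into monomer-length units. Because the discovered
consensus is defined only up to cyclic rotation, the segmentation phase
cannot be anchored to it; instead every phase offset is classified and the
offset maximizing the majority unit-class share is kept — mis-phased cuts
split each variant unit's substitutions across two segmented units and
visibly dilute the classes.

Units are classified by their alleles at *systematic variant columns*:
columns whose minor-allele frequency across units is at least 0.1. Fixed
substitutions that distinguish HOR unit classes stand far above the random
per-copy mutation rate there, while single-linkage clustering on whole-unit
identity cannot separate classes whose divergence (a couple of bases in
42) is smaller than the mutation noise radius. Units are assigned to the
nearest anchor signature (signatures carried by ≥ 5% of units), which
absorbs sporadic mutations hitting a variant column. The unit-class string
is then tested for periods 1..12 and the HOR period is the smallest one
whose positional majority classes explain ≥ 90% of units; the variant unit
indices are the positions within the period whose majority class differs
from the global majority. Arrays whose mean unit identity to their own
consensus falls below 70% are flagged degenerate rather than decomposed.

## Copy quantification and centromere calls

Genome-wide copy counts use greedy left-to-right tiling: a position opens a
copy when its monomer-length window matches the consensus or its reverse
complement at ≥ `min_identity` (default 0.96, echoing the high
cross-species identities typical of this satellite family), after which the
scan jumps one monomer length. Tiled (non-overlapping) counting was chosen
over counting every overlapping hit because tiled counts approximate the
number of physical repeat units. Note that at 0.96 a 42-mer tolerates only
one mismatch, so under 2% per-copy mutation and with HOR variant units
diverging from the majority consensus, roughly half the physical units
match at the default threshold; lower the threshold (e.g. 0.90) to count
essentially all units. Counts are non-increasing in `min_identity` by
construction.

Centromeres are delineated from copy density in 10 kb windows: windows
whose tiled copies cover ≥ 20% of the window are satellite-positive,
near-adjacent positive windows (gap ≤ 1 window) merge into blocks, and the
largest block — refined to the exact extent of its hits — is the single
centromere call (one centromere per chromosome is assumed; further blocks
are reported as secondary warnings, and chromosomes with no positive
window are explicitly uncalled). Arm lengths are measured from the call to
the chromosome ends; morphology uses the long/short arm ratio with
Levan-convention cutoffs (metacentric ≤ 1.7 < submetacentric ≤ 3.0 <
subtelocentric ≤ 7.0 < acrocentric; a zero-length short arm is
telocentric). The cutoffs are configurable because cytogenetic conventions
differ between laboratories.

## 5S rDNA clusters

Clusters are chains of probe hits (same tiled matcher, default identity
0.9) with start-to-start gaps ≤ `max_gap` (5 kb). The inter-copy spacer is
reported as the *modal* end-to-start distance between adjacent hits —
equivalently the modal start-to-start distance minus the probe length — so
that occasionally deleted or diverged copies do not bias the estimate the
way a mean would; both the gene length and the spacer are independent
generator parameters because a "repeat interval" can be measured
gene-to-gene or unit-to-unit. Single-copy clusters report no spacer.

TE co-localization is assessed by permutation: the statistic is the
fraction of clusters with at least one family member within `flank`
(10 kb); the null re-places every cluster uniformly on its own chromosome
`n_perm` times (seeded), and p = (1 + #{null ≥ observed}) / (1 + n_perm).
This add-one estimator never reports zero and is valid (conservative) for
discrete statistics. When the family is dense relative to the chromosome
the null saturates and the test is powerless by design — significance
requires the family to be genuinely concentrated near clusters.

## Population-genetic statistics

Site QC keeps a site when its missing fraction is < 0.2, its minor allele
frequency over non-missing alleles is ≥ 0.05, and the exact Hardy–Weinberg
test on genotype counts pooled across all samples gives p ≥ 1e-5. The HWE
test enumerates all heterozygote configurations consistent with the
observed allele counts and sums the probabilities of those no more likely
than observed.

Windows tile chromosomes in non-overlapping 10 kb blocks (a sliding step
is exposed but the default is tiling). Per window and population:

- π is the per-site unbiased expected heterozygosity 2p̂(1−p̂)·2n/(2n−1)
  summed over sites and divided by the full window span in bp (so windows
  with no variants have π = 0, and missing genotypes reduce n per site);
- S counts segregating sites;
- Tajima's D = (π_sum − S/a₁) / √(e₁S + e₂S(S−1)) with the 1989
  coefficients evaluated at the window's haplotype count (the median
  non-missing count over used sites; sites with fewer than 4 non-missing
  haplotypes are skipped). D is undefined exactly when S = 0.

Between populations, FST is the Weir–Cockerham (1984) weighted
(ratio-of-sums) estimator Σa / Σ(a+b+c) from the per-site variance
components for two populations, using per-site observed sample sizes and
heterozygote frequencies. Negative window estimates are retained — the
estimator is unbiased around zero and clipping would bias region means.
Note the estimator is only *approximately* zero on identical populations:
its finite-sample b/c corrections leave a small negative value on
duplicated data.

Region stratification assigns windows by midpoint and reports mean ± SD
(n−1 denominator) per region and statistic, over defined values only.

## SV merging and the population-specific filter

Merging follows the SURVIVOR positional-parameter semantics
(max_dist = 1000, min_support = 2, type agreement, strand agreement, no
distance estimation, min_size = 30): records shorter than min_size are
dropped first (translocations exempt, having no length); records from
*different* inputs link when their breakpoints lie within max_dist and the
required attributes agree; single-linkage connected components form
clusters, which makes the merge symmetric in input order; clusters
supported by ≥ min_support inputs emit one record at the member-median
position (even counts break toward the smaller coordinate), carrying the
first non-missing genotype per sample in deterministic member order and
the supporting input count. Insertions compare by breakpoint distance
only; no sequence comparison is attempted.

The population-specific filter retains a merged record when every
population-B sample is homozygous reference or absent, at least one
population-A sample carries the variant, and all population-A samples
share one identical non-reference genotype — an absent or homozygous-
reference A sample breaks consistency. Presence/absence is evaluated on
the merged genotypes, not per-caller.

## Region statistics

TE copies and genes are assigned to short-arm / centromere / long-arm by
midpoint (deterministic and symmetric for boundary-straddling features);
family fractions sum to 1 per family. Methylation enrichment uses one-way
ANOVA across the three regions followed by Fisher's LSD pairwise
comparisons: t = (m_i − m_j)/√(MSE(1/n_i + 1/n_j)) on the pooled
within-group mean square with N − k error degrees of freedom, two-sided
and unadjusted, as the LSD convention specifies. Both the whole-chromosome
baseline (centromere included) and an arms-only baseline are reported,
since "chromosome-wide" means can be read either way. Genes count as
actively expressed at abundance ≥ 1 (TPM-like units; `active_min` flag) —
a conventional detection floor, not a biological claim.

## The synthetic-data generator

The generator's defaults are the study conditions the analyses are
validated under:

| parameter | default | rationale |
|---|---|---|
| monomer length | 42 bp | croaker-like centromeric satellite |
| HOR | 4 units, 2 variant units, 2 fixed subs each | 168 bp higher-order unit with two diverged monomers |
| array | 300 HOR copies, 2% per-copy substitution | ~50 kb array, mutation level that keeps units ~96% identical |
| telomeres | 30 copies per end | comfortably above the 10-copy criterion |
| 5S cluster | 120 bp gene, 98 bp spacer, 200 copies | conserved inter-copy spacer on the short arm |
| TE families | ERV1-like 200 bp × 60 copies, 85% pericentromeric; L2-like 150 bp × 40 copies, arms | emulates centromeric ERV1 concentration and 5S-linked L2 |
| cohort | 20 + 21 diploids | the two-population resequencing design |
| region F (short/cen/long) | 0.19 / 0.33 / 0.13 | centromere > short arm > long arm differentiation |
| region θ (short/cen/long) | 0.22 / 0.08 / 0.30 | diversity lowest in the centromere |
| site density | 0.01 /bp | equal density across regions so per-bp π tracks θ |
| background GC | 41.5% | cosmetic match to the assemblies |

Design points worth recording:

- **Substreams.** All randomness flows from one top-level seed through
  named substreams (one per feature class and chromosome), so adding or
  resizing one feature never perturbs another and outputs are
  byte-reproducible.
- **Variant units are fixed.** The two variant monomers carry the same
  substitutions in every HOR copy (at positions distinct between the two
  units), so the higher-order signal is genuinely periodic; random
  per-copy substitution is layered on top.
- **Pericentromeric TE placement.** Centromeric TE copies are placed in
  margins flanking the satellite array (truth centromere = array ±15 kb),
  not inside it: real ERV1 invasions interrupt arrays, but interrupting
  the generated array would conflate TE placement with the satellite
  recovery the tests measure. The truth set keeps the exact array interval
  separately.
- **Differentiation model.** Per site, an ancestral minor-allele frequency
  is drawn uniformly on (0, m) with m solving m − (2/3)m² = θ so the
  expected heterozygosity equals θ; each population's frequency is
  Beta(p(1−F)/F, (1−p)(1−F)/F) — the Balding–Nichols model, under which
  the Weir–Cockerham estimator concentrates near F, making recovery
  testable. F = 0 degenerates to a shared frequency. θ is capped at 0.375,
  the uniform-MAF model's maximum.
- **Methylation** frequencies are Normal(mean, 0.1) clipped to [0, 1],
  elevated by `centromere_delta` inside the centromere. Clipping is rare
  at the defaults, so null ANOVA p-values stay uniform.
- **SV truth sets** keep breakpoints ≥ 5 kb apart so that distinct events
  remain distinguishable after caller jitter; per-caller sets drop each
  record with probability `fn_rate` and jitter positions with seeded
  Gaussian noise.

What the generator does *not* emulate — and therefore what passing tests
do not show about real data: indel mutation within repeats (real satellite
arrays drift in register, smearing autocorrelation peaks), nested or
fragmented TE insertions inside arrays, linkage disequilibrium and
genealogical correlation between sites (sites are independent draws, so
windowed variances are optimistic), sequencing or genotyping error, and
reference bias. Problem sizes (hundreds of kb, thousands of sites) were
chosen as the smallest at which the recovery targets are comfortably
identifiable; all scale linearly.

## Numerical choices and degenerate inputs

Majority-vote ties break alphabetically; merged-position median ties break
toward the smaller coordinate; the centromere-partition tie (centromere at
the exact middle) assigns the p side as the short arm. Empty inputs return
empty results rather than errors wherever the empty case is meaningful
(no sites, no hits, no clusters); impossible requests (features exceeding
chromosome length, probe shorter than 50 bp, unknown sample ids) raise
with a diagnostic. Statistics that are undefined (D at S = 0, FST with a
zero denominator, ANOVA with one populated group) are flagged as
undefined, never silently zeroed.

## Known limitations

Monomer discovery assumes substitution-dominated divergence and a single
dominant satellite family per harmonic family; HOR periods are searched
only up to 12 units; the SV merger compares breakpoints, not alternate
sequences; the exact HWE test pools genotypes across populations, so
strong Wahlund structure can remove truly good sites; Tajima's D uses one
haplotype count per window, an approximation under heavy missingness; and
the co-localization test conditions on cluster lengths and chromosome
assignment only.
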