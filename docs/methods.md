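# Methods

This note documents the models behind `apomixis-scan`: what each
component computes, the defaults and why, what the synthetic-data
generator does and does not emulate, and the numerical conventions.

## Genotype representation and coordinates

Diploid genotypes are coded 0 (hom-ref), 1 (het), 2 (hom-alt), −1
(missing) in a samples × sites int8 array with per-call depth (DP) and
allele depths (AD). Coordinates are 0-based half-open internally and
1-based only at the VCF/GFF boundary. All-sites (gVCF-derived) matrices
carry invariant records so window denominators and π/d_xy are per-bp
exact; variant-only matrices are supported with explicitly flagged
approximations (below).

## Genotype QC and site filtering

Per-call QC mirrors standard practice for detecting LOH against
sequencing artifacts: a call is kept only when its depth lies inside an
individual-specific envelope of one-third to twice that sample's mean
depth, with an absolute floor of 6× for adult (≈30×) and 3× for embryo
(≈10×) libraries. Heterozygotes are then screened by allele balance
(alt-read fraction): at high depth (≥20× adult / ≥6× embryo) the accepted
band is 0.2–0.8, at moderate depth (≥10× / ≥3×) it widens to 0.1–0.9;
failing heterozygotes are reassigned to the homozygote of the majority
allele rather than dropped, since a strongly unbalanced het most likely
reflects a miscalled homozygote. QC never creates a heterozygote and
changes homozygotes only to missing. The depth envelope is applied before
allele balance because balance is meaningless at excluded depths.

Site filtering proceeds in a fixed, logged order: (1) biallelic SNPs only
(multi-allelic records dropped, not decomposed); (2) optional site-QUAL
floor, off by default since per-call depth QC is the binding filter;
(3) missing-rate ceiling (off by default); (4) singleton removal, where a
singleton is minor-allele count exactly 1 over the retained samples (a
het counts 1); (5) exclusion of coding intervals ± 20 kb for neutral-site
analyses; (6) thinning to the first (lowest-coordinate) site per 20-kb
window — a deterministic tie-break where any rule would do. Retention is
logged per step and is monotone non-increasing.

The orchestrated pipeline keeps two site sets: a *basic* set (QC +
biallelic + missing-rate) used for kinship, individual heterozygosity,
the folded SFS and diversity — statistics that must see the full
genome-wide SNP complement — and the full six-step *neutral* set intended
for structure-style analyses. Thinning before kinship would only discard
information; the KING estimator does not require LD pruning.

## Kinship and clone detection

The pairwise estimator is the between-family KING-robust coefficient
φ = (N_het,het − 2·N_AA,aa)/(N_het(i) + N_het(j)), computed over sites
called in both samples. It requires no allele-frequency estimates, which
makes it robust to the strong structure clonal complexes create. φ is
undefined (flagged, excluded from classification) when neither member has
a heterozygote at shared sites. Degree classes use the published bands
(duplicate > 0.354; 1st 0.177–0.354; 2nd 0.0884–0.177; 3rd
0.0442–0.0884); intervals are open at the lower bound — a pair must
*exceed* 0.354 to be called duplicate. Clones are connected components of
the duplicate graph (transitive closure): if A–B and B–C are duplicates,
{A, B, C} is one clone even if A–C falls marginally below the threshold.
Between clones, the reported relationship is the closest degree over
cross-component pairs.

## Diversity statistics

π and d_xy follow the all-sites convention: per site, allele differences
k(c−k) (within) or k₁(c₂−k₂)+k₂(c₁−k₁) (between) and comparable pairs
c(c−1)/2 or c₁c₂ are accumulated over fixed windows (default 20 kb) and
divided at window level, so missing genotypes and invariant sites are
handled exactly. F_ST is the Hudson/Nei form (d_xy − mean within-π)/d_xy.
The folded SFS uses complete-case sites only (no projection), binning
min(alt count, 2n − alt count); monomorphic sites are excluded.
Individual heterozygosity h is heterozygous sites / genome length, per bp.
When a taxon contains clonal replicates they are deliberately *not*
deduplicated — the multimodal SFS this produces is itself the clonality
signature the spectrum is used to detect.

## LOH segmentation

Heterozygosity is computed per sample in fixed, non-overlapping 50-kb
tiles from coordinate 0 (step size is configurable; window counts in
tiled mode are what the block statistics assume). With all-sites input
the denominator is the window's non-missing site count and a window is NA
when over half its sites are missing for that sample; with variant-only
input the denominator falls back to the callable window span in bp
(flagged `span_denominator`), which puts values on the same per-bp scale
as h. A terminal partial window is kept only if it spans ≥ 20% of the
window size. A window is LOH iff het < cutoff, strictly — a window at
exactly 0.001 is not LOH. The default cutoff 0.001 follows the
sexual-control benchmarking logic (the package's `benchmark_cutoff`
reports the fraction of control windows below any candidate cutoff); the
0.0005 variant is provided for robustness checks, and its LOH set is
provably a subset of the 0.001 set. Consecutive LOH windows merge into
blocks; NA windows break blocks.

## Residual-sex detection in embryo sets

Within a mother's embryo set, background LOH is the window set called LOH
in ≥ 80% of embryos (fraction over non-NA calls) — this captures
ancestral LOH inherited clonally from the mother. An embryo's novel LOH
is its LOH set minus the background. The embryo is classified sexual when
it has a run of ≥ 10 consecutive novel windows (500 kb at defaults) or
novel LOH totalling ≥ 2 Mb. These two thresholds quantify a criterion
that is intrinsically verbal ("large LOH segments differing from most
siblings"); they are configuration keys, logged with every run, and were
chosen so that a single meiosis (which converts on the order of half the
maternal heterozygous genome to homozygosity in coherent multi-megabase
tracts) is far above threshold while window-level QC noise is far below.
Note the irreducible biology: a selfed embryo whose two meioses happened
to deliver opposite haplotypes everywhere has no LOH and is genuinely
indistinguishable from a clonal copy; detection power is a function of
crossover count and chromosome number, not of the classifier.

For load partitioning, *ancestral* LOH windows are those LOH in every
embryo with a non-NA call and non-NA in ≥ 80% of embryos; a sexual
embryo's *novel* windows are its LOH minus the ancestral set.

## Polarization and load accounting

Ancestral alleles are assigned by strict two-outgroup concordance: both
outgroups must be homozygous for the same allele; heterozygous, missing
or discordant outgroups leave the site unpolarized and excluded from
every derived count (an exclusion audited by the conservation tests).
Probabilistic polarization is intentionally not implemented — the
concordance rule is the binding filter and keeps the exclusion set
transparent. Derived load counts heterozygotes once and derived
homozygotes twice; percent-homozygous load is 2·n_hom/(n_het + 2·n_hom),
the realized share of the total. Ratios (DEL/SYN, LOF/SYN at het and hom
sites; 0-fold/4-fold heterozygosity with per-class non-missing genotyped
sites as denominators) are NA on zero denominators, never 0 or ∞.

Degeneracy is computed from reference + CDS intervals by codon
enumeration (4-fold: no change alters the amino acid; 0-fold: every
change does), strand-aware, with genes skipped (warned) when the spliced
CDS is not a multiple of 3 and positions claimed by conflicting
overlapping genes demoted to 'other'. Functional classes (SYN/TOL/DEL/
LOF) are consumed from an annotation table in real use; a Grantham-
distance classifier (DEL iff score ≥ 150, inclusive) is built in as the
self-contained alternative, with the full 20×20 Grantham matrix embedded.

Haplotype-stratified load uses a per-site haplotype-of-origin label (E/W
pools); in the simulator this is exact truth, whereas with real data the
analogous procedure maps to the two haplotype references separately —
the label-based idealization sidesteps mapping bias but cannot emulate
it. Region-stratified load assigns each site to LOH/non-LOH by its
sample-specific window call; heterozygous burden in LOH regions is
reported as raw counts (ratio normalization fails where hets are nearly
absent by construction), homozygous burden as DEL/SYN and LOF/SYN ratios.
Group comparisons use two-sided Welch's t-tests, or the Wilcoxon rank-sum
test for strongly unbalanced groups, without multiple-testing correction;
significance stars at 0.05/0.01/0.001.

## The synthetic-data generator

The generator produces true genotypes first and overlays sequencing noise
second, so every statistic has exact truth to be scored against.

- **Sites are unlinked** (drawn independently per bp). None of the
  implemented statistics require LD; crossover-driven LOH tracts, the one
  positional signal analyzed, are simulated explicitly through meiosis.
- **Founder variation.** Polymorphic positions are drawn at
  `polymorphism_density` (default 0.02/bp, chosen so that per-bp
  heterozygosity lands near 4 × 10⁻³, the scale typical of outcrossing
  tree populations, given the neutral frequency spectrum below). Allele
  counts per site follow a configurable spectrum: `neutral` (count a with
  probability ∝ 1/a, assigned exactly within the founder haplotype pool,
  giving the folded 1/i + 1/(2n−i) SFS in expectation), `uniform`, or
  `fixed` (frequency solving 2p(1−p) = `founder_diversity`).
- **Genome scaffold.** Default 4 chromosomes × 5 Mb — a desk-scale
  stand-in; all window logic is length-agnostic. Each chromosome carries
  20 single-exon CDS genes of 3 kb with real random codon sequences on
  random strands, so degeneracy labels are genuine codon properties and
  the emitted FASTA + GFF3 are exactly consistent with the truth tables.
  Variants at 4-fold sites are SYN; variants at 0-fold sites draw their
  class from `deleterious_fractions` (default DEL 0.3 / TOL 0.6 / LOF
  0.1 among 0-fold variants, settable per haplotype pool for hybrid
  asymmetry).
- **Scenarios.** *Sexual*: random union of pool haplotypes
  (Hardy–Weinberg). *Clonal complex*: lineage founders form a
  parent–offspring pedigree chain (each founder the child of the previous
  one and an unrelated mate), members add private somatic mutations
  (Poisson with mean rate × `somatic_generations`, placed uniformly on
  homozygous sites, hom→het only — the dominant direction at low rates);
  pairwise within-lineage differences therefore average 2·rate·g.
  *Hybrid*: each individual pairs one haplotype from pool E and one from
  pool W; fixed differences (density `hybrid_divergence`) are obligate
  heterozygotes whose derived allele arose on either pool's branch with
  equal probability. *Embryo set*: each embryo is a clonal copy of the
  mother with probability 1 − `p_sexual_embryo`, else produced by selfing
  — two independent meioses with Poisson(`crossovers_per_chromosome`)
  crossovers at uniform positions; true LOH tracts are the intervals
  where both gametes copied the same maternal haplotype, and expected
  retained heterozygosity is exactly 1/2. Selfing is the default sexual
  event because it creates the LOH signature under study; outcrossing can
  be emulated by supplying another simulated genotype as co-parent.
- **Sequencing model.** Per call: depth ~ Poisson(30 adult / 10 embryo);
  genotype flipped to one of the other two states with probability
  `genotype_error` (symmetric — the simplest model adequate for threshold
  testing); missing with probability `missing_rate` or when depth is 0;
  allele depths Binomial(depth, ½) at heterozygotes. Outgroups are
  homozygous-ancestral with independent 2% lineage-specific divergence,
  so strict concordance polarization has ≈ d² error (~4 × 10⁻⁴).

What the generator does **not** emulate: linkage disequilibrium and
demographic history (no coalescent genealogies), mapping and reference
bias, indels and multi-nucleotide variants, base-calling error profiles,
GC/coverage bias, gene conversion, and chromosome-scale features
(centromere/telomere effects). Consequently, passing tests demonstrate
the correctness and calibration of the estimators under the stated
sampling and noise models — not robustness to alignment artifacts or
reference bias in real resequencing data.

## Numerical conventions and edge cases

Determinism: every scenario is fully reproducible from `SimConfig.seed`
(byte-identical VCFs); the pipeline derives per-stage RNGs from the run
seed and manifests record SHA-256 checksums of all outputs. Ratios with
zero denominators are NaN. φ is NaN when undefined. Empty SFS and empty
control-window sets raise or warn explicitly rather than returning
silent zeros. Thinning and window assignment use floor division of the
0-based position. Problem sizes in the test-suite simulations
(chromosomes of 1–5 Mb, 10⁵-SNP kinship panels, 60-embryo sets in
triplicate) were chosen as the smallest designs at which the targeted
quantities are statistically resolvable at 3-SE precision.

## Known limitations

- The span-denominator LOH mode assumes uniform callability; capture or
  repeat-dense genomes would need the all-sites mode.
- Clone grouping by transitive closure can chain distinct lineages
  through borderline pairs in principle; the φ gap between duplicates
  (~0.5) and first-degree pairs (~0.25) makes this unlikely at genome
  scale but it is not impossible at low marker counts.
- The sexual-embryo thresholds are calibrated for genomes with at least a
  few hundred 50-kb windows; very small simulated genomes need
  proportionally smaller `min_novel_span`.
- SIFT-style functional scoring is out of scope; DEL/TOL classes come
  from the annotation input or the Grantham classifier.
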