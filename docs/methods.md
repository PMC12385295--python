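# Methods

## The scan

`tibscan` detects recent positive selection in a focal population T
relative to two outgroups S and H from phased biallelic SNVs.  Four
per-SNV statistics are computed and combined.

**Allele-frequency statistics.**  The ancestral allele is identified
with the reference allele, so the derived allele frequency (DAF) is the
ALT frequency.  ΔDAF = ((DAF_T − DAF_S) + (DAF_T − DAF_H))/2 measures
the focal population's mean frequency excess.  Pairwise per-SNV FST uses
Hudson's estimator,

    FST = [(p1−p2)² − p1(1−p1)/(n1−1) − p2(1−p2)/(n2−1)] / [p1(1−p2) + p2(1−p1)],

chosen for its low bias under unequal sample sizes; a per-site
Weir–Cockerham estimator is available (`fst_estimator="wc"`).  Negative
estimates are clipped to 0.  When two populations are monomorphic for
the same allele the estimator is 0/0; the pipeline assigns the
continuous limit FST = 0 there so that PBS stays defined at SNVs whose
derived allele is private to the focal population — exactly the
configuration a completed local sweep produces.  PBS combines the three
pairwise values, by default linearly,

    PBS = (FST_TH + FST_TS − FST_SH) / 2,

with `pbs_mode="log"` applying the same combination to the
branch-length transform T = −ln(1−FST) (FST pre-clipped to 1−1e-9).
Both modes ship because the linear form is what the headline formula
states while the log form is the canonical population-branch
construction; they are rank-equivalent for small FST.

**Haplotype statistics.**  EHH at distance x from a core SNV is the
probability that two random carrier haplotypes are identical over
[core, x], computed by incremental group refinement (a compiled kernel
with a pure-Python fallback; both are exercised against an O(n²)
pair-counting reference).  For pooled-core EHH (used by XP-EHH) the
core's own allele is part of the extended haplotype; the curve's value
at offset 0 is defined as 1.  iHH integrates EHH over physical distance
(trapezoid rule) outward on both sides, truncating at the first point
below the decay cutoff (0.05).  A site is scored only if EHH decays
below the cutoff on both sides before the chromosome edge, a >200 kb
inter-SNV gap, or the 1 Mb maximum extension — sites failing this decay
rule are excluded before standardization, mirroring the practice of
excluding SNVs with EHH decay < 0.05.  Physical distance is used
throughout; no genetic map is assumed.

iHS_unstd = ln(iHH_ancestral/iHH_derived), requiring ≥2 carriers of each
allele and minor-allele frequency ≥ 0.05, standardized within
equal-count DAF bins (20 by default, merged when a bin would hold fewer
than 10 scores).  XP-EHH_unstd = ln(iHH_T/iHH_ref) from pooled-core EHH
computed separately per population (reference = pooled S+H by default,
configurable to a single outgroup), z-standardized genome-wide; positive
means longer haplotypes in T.  If the spread of XP-EHH_unstd is exactly
zero (identical populations) standardization degrades to centring.

**Composite and regions.**  Each component is ranked into a one-sided
empirical p-value p = (r+1)/(N+1), where r counts strictly more extreme
SNVs in the selection direction (larger PBS, ΔDAF, |iHS|, XP-EHH; ties
share p).  CMS = Σ −log10(p) over the four components, defined only
where all four are defined; SNVs missing a component are excluded, not
imputed.  This rank-based composition is monotone in every component,
scale-free, and yields magnitudes on the familiar scale (top scores
≈ 4·log10 N).  The exact composition recipe is an interpretation — the
combination of these four statistics into a sum of −log10 empirical
rank p-values is this package's documented choice.  |iHS| enters
two-sided because a sweep lengthens haplotypes around whichever allele
hitchhikes; the other three are one-sided toward focal-population
selection.  Selected SNVs are those strictly above the empirical
(1−q)-quantile order statistic (q = 0.005).  Greedy LD clumping then
repeatedly takes the highest-CMS unassigned SNV as a peak and absorbs
all selected SNVs within 500 kb at r² > 0.2 (dosage r² over jointly
non-missing samples; phased haplotype r² optional), yielding regions
whose surviving peaks are pairwise independent under that rule.  Genes
whose 1-based closed span intersects peak ± 5 kb (boundary inclusive)
are assigned to the region.

## QC

Samples first, then variants, each rule counted on the survivors of the
previous rule so `in − Σ removed = out` holds exactly:

1. sample missingness ≥ 3% (inclusive, as stated);
2. heterozygosity rate outside mean ± 3 SD (SD = 0 ⇒ no outliers);
3. IBD: PLINK-style method-of-moments PI_HAT from IBS0/1/2 counts
   (no finite-sample corrections; probabilities clipped to [0,1]);
   pairs above 0.25 pruned greedily, dropping the member with more
   missingness.  When a population map is supplied, relatedness is
   estimated within populations with within-population frequencies —
   pooled frequencies across diverged populations otherwise inflate
   PI_HAT for every cross-population pair.
4. singletons (minor-allele count exactly 1);
5. variant missingness > 5% (strict, as stated);
6. HWE exact test p < 1e-6 on the pooled cohort (per-population option
   available).  The exact test enumerates the conditional distribution
   of heterozygote counts given allele counts in rational arithmetic
   and sums the probabilities ≤ that of the observed count.

A hook accepts an external exclusion list (e.g. PCA outliers from an
off-the-shelf tool); PCA itself is out of scope.  Whether sample or
variant filters ran first is not derivable from the cohort-level counts
this package reproduces; samples-first is fixed and documented.

## The synthetic cohort generator

A discrete-generation forward Wright–Fisher simulator with three demes:
one ancestral deme evolves for a burn-in, splits into T and the (S,H)
ancestor, which later splits into S and H; no migration.  Reproduction
is random mating with selfing allowed, one gamete per parent per child
haplotype, and at most one crossover per meiosis.  Variation enters as
standing variants drawn from the neutral SFS (P(count=i) ∝ 1/i) at
burn-in start, plus Poisson new mutations; the ancestral allele is REF
everywhere.  The sweep applies fitness 1, 1+s/2, 1+s (derived-allele
dosage) in T only, from `sweep_start_gen` generations before sampling;
the beneficial allele starts from a handful of standing copies
(re-seeded at the selection onset if drift lost it).  Attempts in which
the allele is lost, or in which its final focal-deme frequency falls
outside the configured band, are re-run from the selection-onset
checkpoint with a fresh substream up to `max_sweep_retries`, after
which "sweep lost" is raised.  Conditioning on a *partial* sweep
(default band 0.7–0.9) reflects the regime the composite is designed
for: at complete fixation iHS is undefined at the swept site and the
haplotype contrast collapses.

**Desk-scale rescaling.**  Real ovine effective sizes (~10⁴) are
unreachable at test scale, so the demes hold ~400 diploids and rates are
rescaled by λ = N_real/N_desk ≈ 25 to preserve the population-scaled
parameters: recombination 2×10⁻⁷ per bp per generation (≈ λ·10⁻⁸,
capped by the single-crossover model at one crossover per meiosis over
the 5 Mb chromosome) and divergence times of 110 and 55 generations
(FST ≈ 0.12 between T and each outgroup, ≈ 0.06 between S and H, the
magnitude expected between related domestic breeds).  Defaults: 50
diploid samples per population, 5 Mb chromosome, 6,000 standing
variants (≈ 2,300–2,900 segregating in the sample), s = 0.1, selection
for the final 110 generations.  Missingness, when enabled, is i.i.d.
per genotype after phasing and affects genotype-level operations only;
haplotype statistics use complete-case sites.

**What the generator does not emulate:** realistic ovine karyotype and
demography (bottlenecks, migration, admixture), multi-chromosome
genomes (one consequence: genome-wide relatedness estimates on the
single simulated chromosome are noisy and sweep-inflated, so simulated
cohorts are best QC'd with the IBD stage disabled), gene conversion,
genotyping error, unphased or sporadically phased data, and structural
variation.  Passing tests therefore demonstrate algorithmic
correctness and desk-scale operating characteristics, not performance
on real cohorts.

## Numerical choices

* Empirical quantile thresholds are order statistics
  (k = ⌈(1−q)·N⌉-th smallest); selection is strictly above the
  threshold, so an all-tied score table selects nothing.
* CMS ties in clumping break by ascending (chrom, pos).
* HWE exact probabilities are computed in exact rational arithmetic and
  cached per (n, minor-allele-count); the two-sided sum uses a 1+1e-12
  relative guard against float ties.
* Floating-point output is printed to 6 significant digits; identical
  config + seed reproduces outputs byte-for-byte.  All randomness flows
  from one seed through `numpy` `SeedSequence` substreams (phase A,
  each sweep attempt, sampling, allele-base assignment).
* Monomorphic columns cannot split haplotype groups, so EHH walks skip
  them (values carry over); results are identical to the naive walk.

## Known limitations

* The per-SNV Hudson FST is noisy at small sample sizes; PBS inherits
  that noise.  Windowed FST is deliberately out of scope.
* The decay rule excludes strongly swept cores whose haplotype
  homozygosity never falls below 0.05 within the maximum extension —
  at desk scale this can exclude the sweep site itself; localization
  then rests on flanking SNVs, which is why recovery is scored as
  distance from the top clump's peak rather than identity of the peak
  SNV.
* `empirical_p` requires ≥100 scored SNVs and `top_quantile` ≥ 1/q, so
  the composite is not computable on toy-sized (tens of SNVs) inputs;
  end-to-end regression uses a seeded simulated cohort instead.
* IBD pruning uses naive moment expectations (no finite-sample
  correction); adequate for duplicate/close-kin flagging, not for
  precise kinship estimation.
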