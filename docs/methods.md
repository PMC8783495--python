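# Methods

`wffsim` models the management of a fully recessive, fully penetrant lethal
allele — modelled on the warmblood fragile foal syndrome (WFFS) variant in
*PLOD1* — in a closed sport-horse breeding program, together with the two
statistical analyses that surround such an allele in practice: exact
carrier-count statistics and a de-regressed-EBV association analysis.

## Breeding-program model

### Population and life cycle

Generations are discrete and non-overlapping. Every generation consists of
6000 individuals with an exact 50:50 sex ratio. Of the 3000 males, 300 are
selected as sires by truncation on own phenotype: the top 180 on the
breeding-goal-2 phenotype (show-jumping-type merit) are taken first, then
the top 120 on the breeding-goal-1 phenotype (dressage-type merit) from the
remaining males, giving exactly 300 distinct sires (a male who would
qualify for both goals counts for the larger group; the order is
configurable). Ties are broken by individual id so a run is fully
deterministic given its seed. All 3000 females are dams.

The 6000 offspring are apportioned to sires by phenotype decile, pooled
over both goals on the shared index scale: the 30 sires in each decile get
an equal per-sire quota, by default (1, 1, 1, 3, 6, 10, 16, 20, 26, 116)
from the lowest to the highest decile. The endpoints reproduce the skewed
use of popular stallions: one offspring per sire in the lowest three
deciles, 116 per sire — 58% of the whole crop — in the top decile. The
middle deciles are a monotone interpolation between those fixed endpoints
and are fully configurable. For each offspring slot of each sire a dam is
drawn uniformly with replacement from the eligible dams; dam family sizes
are therefore approximately Poisson.

### Genome, traits and phenotypes

The genome has 30 chromosomes of 100 cM. Each chromosome carries 3
causative loci (QTL) and 400 neutral biallelic loci at uniform random
positions. QTL effect pairs for the two breeding goals are i.i.d. bivariate
normal with unit variances and correlation 0.3; genetic values are purely
additive in allele dosage. An affine scaling per goal is calibrated once,
on the founder cohort, so that founder genetic values have mean 100 and SD
20 (the scale used in routine genetic evaluation), and is then frozen —
later cohorts show genetic trend on this scale. Phenotypes add independent
normal noise with SD 20·sqrt((1−h²)/h²) ≈ 30.55 index units at the default
heritability h² = 0.3 for both goals; the environmental variance is fixed
at its founder value and not re-tuned as genetic variance erodes. The
realized founder genetic correlation is ≈ 0.3 and declines — on average
below zero — under simultaneous selection on both goals, as antagonistic
variants persist longer than synergistic ones.

### Founder haplotypes

Founders stand in for a coalescent sample from a generic domestic-animal
demography in which the effective population size shrank from 10⁵ one
million generations ago to 500 a hundred generations ago and 100 at
present. Instead of running a coalescent program inside the simulator,
per-locus derived-allele frequencies are drawn from a frozen inverse-CDF
table of that demography's site frequency spectrum, obtained from msprime
(60 independent replicates, 14 298 segregating sites in samples of 6000
diploids; `scripts/derive_generic_spectrum.py` regenerates it). The
bottleneck leaves a U-shaped spectrum with mean heterozygosity 2pq ≈ 0.24.
Alleles are then assigned independently across loci and haplotypes, so
founders carry no background LD; linkage builds up in later generations
through meiosis. A constant-size `"neutral"` spectrum (density ∝ 1/q,
truncated to the segregating range) and fixed-frequency spectra are also
available, and externally simulated haplotypes can be imported as TSV for
users who need founder LD.

The spectrum choice is not cosmetic: because the index scaling pins the
total founder genetic SD at 20, the heterozygosity of the *other* 89 QTL
determines how many index units the lethal QTL's effect is worth. Under
the bottleneck spectrum the QTL chosen in the balancing scenario carries a
mean effect of ≈ +3.8 index units per allele copy on goal 1 (SD ≈ 3.8,
about one fifth negative); the 1/q spectrum would inflate this to ≈ +5.7.

### The lethal allele

The lethal locus is chosen among founder loci whose *observed* carrier
(heterozygote) frequency lies in 0.08–0.12, in one of three modes: a
uniformly random eligible neutral locus (`neutral`); the eligible QTL with
the largest goal-1 effect (`balancing`); or that same QTL with its effects
replaced by exactly +7 index units per allele copy on goal 1 and 0 on goal
2 (`wffs_like`, matching the estimated carrier association of dressage
traits). Two conventions here deserve note. First, the carrier window is
symmetric in allele frequency, so it also admits mirror-image loci at
derived frequency ≈ 0.95 where ~90% of founders would be homozygous
lethal; since a segregating recessive lethal is necessarily rare, the
derived allele is additionally required to be the minor one. Second, the
+7 override is interpreted as the carrier-vs-noncarrier contrast on the
final index scale: the locus's raw effect is zeroed before calibration and
the override added after scaling, so it is exactly 7 index units per copy
(homozygotes never breed, so per-copy and carrier-contrast codings
coincide). If no eligible locus exists the founders are resampled with a
fresh derived seed, up to 100 attempts.

Homozygotes for the lethal are "affected": they are counted as born but
excluded from selection and mating. Three management policies are modelled:
`no_testing` (only the viability exclusion), `avoid_carrier_mating`
(carrier sires only to noncarrier dams and vice versa — eliminating
affected offspring entirely), and `exclude_carrier_sires` (carrier males
barred from selection, except an exemption for the top k = 0, 10 or 100
males per goal, ranked before exclusion; carrier-mating avoidance is kept
for exempt sires). A consequence worth flagging: under avoidance with
per-slot dam redraws, carrier dams lose access to the offspring slots of
carrier sires, which induces selection against the allele of the same
order as the lethality itself (both shrink the allele frequency q at rate
≈ q² per generation) — this, plus drift, is why avoidance scenarios
decline from 10% to ≈ 4–5% carriers in 20 generations even though no
affected individuals are ever born.

### Meiosis

Crossovers per chromosome are Poisson with mean 1 per Morgan, positions
uniform, no interference; the starting haplotype is a fair coin. The
single-gamete `meiosis` routine implements this explicitly. The batch path
used by the engine samples the identical law marginalized to the marker
loci: crossover counts in disjoint intervals are independent Poisson
variables and only their parity matters for the allele outcome, with
P(odd) = (1 − exp(−2d))/2 for an interval of d Morgan (Haldane's map
function). The equivalence is exact, and a test compares observable switch
rates between the two paths.

### Tracked loci

Once the lethal locus is chosen, the simulation tracks only the 90 QTL
plus the lethal locus through meiosis. Untracked neutral loci have no
trait effects and enter no reported statistic, so dropping them changes no
output; in the balancing/wffs modes (where the lethal is itself a QTL)
founders are sampled at causative loci only, which is distributionally
identical because founder loci are independent given the map. In the
neutral mode the lethal locus and its founder genotype column are drawn by
an exact count-based factorization (per-locus genotype counts are
multinomial; eligibility depends only on the heterozygote count; the
column given its counts is an exchangeable assignment with uniform phase),
avoiding the full 12 000 × 12 090 founder matrix.

### Experiments and summaries

A scenario (lethal mode × policy × breeding constants) is repeated 100
times by default for 20 generations plus the generation-0 baseline.
Replicate streams derive from `SeedSequence([base_seed, replicate,
attempt])`, so a (scenario, seed) pair reproduces every trajectory
bit-identically and founder resampling is itself reproducible. Each
generation records carrier frequency, affected count, per-goal genetic
means, the realized genetic correlation, and the carrier frequency among
the top 10% of individuals per goal (ranked by phenotype, since selection
is phenotypic). Summaries report the pointwise mean and the empirical 5th
and 95th percentiles across replicates (linear-interpolation definition).

## Carrier-count statistics

Frequencies are carrier counts over totals; exact confidence intervals are
Clopper–Pearson (inverse incomplete-beta), with Wilson available as the
non-exact alternative — only an exact method reproduces the published
bounds, though note that an exact **95%** interval on 38/511 gives
(5.3%, 10.1%), matching the bounds printed under a "90%" label; both
levels are computed and the discrepancy documented rather than silently
matched. The probability of an all-noncarrier sample is the binomial mass
(1 − p)ⁿ. Fisher's exact two-sided test uses the standard sum-of-small-p
definition (degenerate margins give p = 1 by convention, logged).
Birth-cohort frequencies use nine cohorts over 1971–2020: a ten-year first
cohort (1971–1980) followed by 5-year bins — the only binning that
reconciles nine cohorts with a 5-year interval; empty cohorts are reported
as missing, not zero.

## De-regressed EBV association

EBVs blend own and family information; to associate a genotyped locus with
performance, each EBV is de-regressed into a pseudo-record with the
parent-average contribution removed, using the information-splitting
mixed-model-equations method (equations in the `ebv_association` module
docstring; λ = (1 − h²)/h²). Records whose reliability does not exceed the
parent-average reliability r²PA = (r²sire + r²dam)/4 carry no own
information and are removed. An animal with unknown parents reduces to
simple de-regression DEBV = EBV/r². The weighted least-squares model
regresses DEBV on carrier genotype and 5-year birth period with weights
w = (1 − h²)/((c + (1 − r²DEBV)/r²DEBV)·h²), c = 0.80 being the fraction
of genetic variance not captured by the marker. With only fixed effects
and known weights, WLS is the same estimator class as the mixed-model
software used in practice. Least-square means average the period levels
with equal weight, so the LSM difference equals the genotype contrast; the
period effect is tested jointly by F-test. No multiple-testing correction
is applied (traits are reported at nominal 0.05/0.01 thresholds). A fully
aliased genotype-by-period design raises an error naming the confounding.

The synthetic EBV generator runs the same mixed-model blend *forward*: it
simulates true breeding values (SD 20 around a per-period genetic trend,
plus the carrier contrast δ for carriers), draws a pseudo-record
DEBV\* = TBV + noise with the information content implied by the target
reliability, and blends it with the simulated parent average exactly as
the de-regression assumes. De-regression therefore recovers DEBV\* to
machine precision, estimates are unbiased for δ, and PA-only animals are
emitted (and flagged) for the filter to remove. For unknown-parent animals
this reduces to EBV deviation = r²·TBV + noise of variance r²(1 − r²)·400,
the marginal BLUP property. Defaults mirror the dressage-type (NS)
subgroup of the motivating data: 621 animals, carrier fraction 0.106,
δ = +7.46 index units, reliabilities 0.6–0.9.

## What the synthetic data do and do not show

The generators emulate the *stated* structure of the study system —
population sizes, selection fractions, offspring skew, heritability, trait
scale, carrier windows, reliabilities. They do not emulate founder LD,
overlapping generations, pedigree-BLUP selection, genotyping error, or the
real SWB pedigree; passing tests show the algorithms are correct and the
stated mechanisms reproduce the published simulation endpoints, not that
the real horse data would. The real-data association tables are used only
as parameter sources for recovery tests. The exact level at which
balancing selection holds the carrier frequency (≈ 12% in the study) is
sensitive to the founder frequency spectrum through the index scaling;
with the bottleneck spectrum derived from the stated demography our
balancing scenarios equilibrate slightly higher (≈ 14–15% at 100
replicates), with overlapping replicate distributions (replicate SD ≈ 10
points) — the directional claims (balancing ≫ neutral decline; avoidance
≈ no-testing; exclusion < 1% in four generations) are robust.

## Numerical and design choices

- Population SDs (ddof = 0) everywhere in calibration; scaling exact on
  the founder cohort.
- Phenotype ties in selection broken by id; percentiles interpolated;
  `top_fraction` takes the ceiling of fraction·n.
- Problem sizes in the default test run are scaled down (50-individual
  cohorts for engine tests; 40 replicates for trajectory endpoints, with
  tolerances widened by sqrt(100/40) to keep the Monte-Carlo confidence of
  the 100-replicate tolerances). `scripts/acceptance.py` runs the full
  100-replicate study.
- Seeds: every stochastic routine accepts either an integer seed or a
  numpy Generator; experiment replicates use `SeedSequence` spawning as
  described above.

## Known limitations

- No founder LD (import hook provided); no mutation, so a lost lethal
  stays lost.
- Dams are drawn with replacement and uncapped; litter-size variation,
  overlapping generations, inbreeding management and pedigree-BLUP
  selection are out of scope.
- The de-regression implements the parent-average-removal variant only
  (no contemporary-group de-regression).
- Partial penetrance and the distinction between in-utero and neonatal
  loss are not modelled.
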