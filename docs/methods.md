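# Methods

## The deficiency test

For a focal haplotype — an exact allele string over a window of *L*
consecutive phased SNPs — every parent-offspring trio in which both parents
carry at least one copy contributes one carrier mating. Parental
transmission probabilities are p = ½ (heterozygous) or 1 (homozygous for the
string), so the Mendelian expectation of homozygous offspring over n trios
is E_hh = Σ p_i q_i; the observed count O_hh is the number of offspring whose
two phases both match the string exactly. The test statistic is the two-term
1-df chi-square over the homozygous / non-homozygous classes, with no
continuity correction; since O_non − E_non = −(O_hh − E_hh), it reduces to
(O−E)² (1/E + 1/(n−E)). The upper-tail p-value is computed in log space
(`chi2.logsf`) so extreme deficits at long haplotypes do not underflow.

Assumptions worth keeping in mind:

* **Exact-string identity.** Haplotype matching tolerates no mismatches; a
  single recombination or genotyping/phasing error inside the window
  converts a carrier into a non-carrier. Consequently the test is only
  calibrated when the window's genetic length is small (a few cM): the
  transmission probabilities ½/1 ignore within-window crossovers. With the
  default synthetic map (6 kb/SNP, 1 cM/Mb) a 400-SNP window spans ~2.4 cM,
  so ~2.4 % of meioses break the haplotype — a small conservative deficit
  under the null. Windows spanning tens of cM would produce genuine
  homozygote deficits with no lethality at all; the scan should not be run
  on such maps.
* **One offspring = one mating.** A parent pair with k offspring contributes
  k carrier trios, so "matings" counts trios, not distinct pairs. This is
  the convention under which the published per-haplotype counts reproduce
  their printed chi-square p-values exactly.
* **Two-sided statistic, one-sided question.** The chi-square also fires on
  homozygote *excess*; reported hits are filtered to the deficit direction
  (O < E), but the p-value itself is not halved.
* The deficiency percentage 1 − O/E is *not* an unbiased estimate of the
  embryonic death probability s: carrier trios are ascertained among
  surviving offspring, so for het × het matings E[O/E] = (1−s)/(1−s/4)
  (e.g. 0.60 at s = 0.47, i.e. a ~40 % observed deficit). The generator
  tests assert this conditional expectation, not the naive s.

**Multiple testing.** M_eff is estimated SimpleM-style: the SNP dosage
matrix is split into blocks of 1,000 consecutive SNPs (block size is not
critical; it bounds the eigendecomposition cost), and per block the
smallest k such that the top-k eigenvalues of the SNP–SNP correlation
matrix reach 99.5 % of the eigenvalue sum is accumulated. The genome-wide
threshold is α/M_eff. As in any sliding-window haplotype scan the threshold
is approximate: windows overlap almost completely (conservative direction)
while each window tests several haplotypes (anti-conservative direction).
The synthetic neutral-scan experiment measures the net effect: across 20
neutral replicates no window crossed the threshold.

## Gene-drop simulations

Cohorts are birth years. The analysis span starts at the earliest year from
which every later cohort has ≥ 70 % of individuals genotyped (or an explicit
first cohort); the first three analysis cohorts are "sampled", the rest
"simulated". Per simulation: founders (both parents unknown) in sampled
cohorts draw each allele Bernoulli(observed frequency of their cohort);
non-founders draw from each known parent with probability ½ per parental
allele; a missing parent in a sampled cohort falls back to the
cohort-frequency draw. In simulated cohorts non-founders inherit
Mendelianly; founders and missing-parent alleles are drawn from the current
simulation's frequency among the cohort members who inherited from two
known parents (the "rest of the cohort", which by construction excludes
the individual being assigned; if a cohort has none, the previous cohorts'
simulated frequency is used). Parents born before the analysis span have no
simulated alleles and are treated as missing. Cohort frequencies — observed
and simulated — are computed over genotyped individuals only, so the two
are directly comparable.

Two summaries over the simulated-cohort years:

* **Directional:** the OLS slope of frequency on calendar year (unweighted;
  cohort sizes vary but the reference procedure specifies a plain linear
  regression). The *lower-tail slope quantile* — the fraction of
  simulations with slope below the observed — is uniform under the drift
  null and is the quantity used in calibration and recovery experiments.
  The *direction-aware* quantile ("fraction of simulations steeper than
  observed, in the observed direction") equals it for declining haplotypes,
  which is the only case the motivating study exercises; for a rising
  haplotype it counts the other tail and is therefore ~U(0, 0.5) under the
  null — useful as a descriptive statistic, not as a calibrated p-value.
* **Balancing:** cumulative change Σ|f(t+1) − f(t)|; the quantile is the
  fraction of simulations with *lower* cumulative change than observed.
  Small values flag unusual frequency stability.

**Recombination variant.** Each meiotic transmission of a carrier allele
converts it to non-carrier with probability r = λ/100 (λ = window genetic
length in cM, r capped at ½). Haplotypes are destroyed but never re-created;
re-creation would require complementary recombinant partners and is
negligible at the frequencies of interest. λ = 0 reproduces the plain drop
bit-for-bit at the same seed.

## Single-locus models

Viability selection once per discrete generation in an effectively infinite
random-mating population: q′ = q(q·w_aa + (1−q)·w_Aa)/w̄. Parameterizations:
recessive (1, 1, 1−s) and overdominant (1−s₁, 1, 1−s₂) with interior
equilibrium s₁/(s₁+s₂). Prenatal (embryonic) and postnatal selection on the
same genotypes compose multiplicatively into one fitness vector
(`SelectionModel.compose`); this collapse of within-generation episodes is
a modelling choice exposed to the user. Years-to-generations conversion is
left to the user (no generation time is assumed).

## The synthetic study system

`simulate_dataset` runs an annual cycle: pre-study founder adults (birth
years spread over the six years before the study window, genotyped at a
lower rate, 60 %, than study-era individuals, 95 %) plus a small immigrant
trickle; each year dams are paired with (possibly repeated) sires, litters
are Poisson; each conceptus receives gametes formed with Poisson crossovers
(mean = chromosome cM/100, positions uniform on the genetic map, no
interference). A conceptus homozygous for the focal string dies pre-birth
with probability `s_embryo` — the litter is lost, not redrawn, so emitted
carrier-mating trio counts reflect surviving offspring exactly as a field
study would observe them. Culled conceptuses exist only in the `SimTruth`
record. Heterozygotes can receive an additive first-winter survival bonus
(`het_advantage`), which acts on the survival *draw* and therefore on
future breeding; it only exists in the integrated generator —
`apply_selection` as a standalone post-hoc operation can cull homozygotes
(and their descendants) from a neutral pedigree but cannot retroactively
change who survived, so it ignores the postnatal term.

Founder phases carry the focal string at *exactly* the configured founder
frequency (deterministic allocation over the planned founder-phase pool);
non-carrier founder phases that match the string by chance are perturbed at
one site so the planned frequency is exact. All other sites are drawn
site-wise from per-SNP founder frequencies ~ U(0.05, 0.95) — founder
haplotypes therefore carry no background LD; all LD in the data is
pedigree- and window-generated. That is the main respect in which passing
tests do not certify behaviour on real data: real chip data has strong
baseline LD, which affects M_eff and the haplotype frequency spectrum,
though not the trio-level transmission logic.

Default demography (200 founders, 100 matings/yr, litter mean 1.2, juvenile
survival 0.5, adult survival 0.78, 29 cohorts) gives a stable ~270-ewe
population and ~3,800 individuals — a deliberately scaled-down study. Two
standard experiment scales in `embryoscan.studies`:

* `scan_study_config` — 6 cohorts, ~2,700 individuals, founder carrier
  frequency 0.32, near-complete genotyping: concentrates carrier × carrier
  matings (~330 on average) while the haplotype is still common, the regime
  in which a fully lethal haplotype is genome-wide detectable. Used for the
  localization (s = 1) and false-positive (s = 0) experiments at 20
  replicates each.
* `cohort_study_config` — 29 cohorts, ~2,300 individuals, one small
  chromosome (the focal region only): used for gene-drop calibration (200
  pseudo-observed replicates × 200 simulations) and selection recovery
  (50 replicates × 200 simulations per s ∈ {0.27, 0.47, 1}).

These replicate counts keep the full suite and the acceptance script in the
minutes range on one core; they are the problem sizes at which the reported
rates and KS p-values are computed.

## Numerical and degenerate-case choices

* Haplotype enumeration orders by descending frequency, ties broken
  lexicographically; rows are bit-packed before grouping so window
  haplotyping is a short-key sort.
* `deficiency_test` requires 0 < E < n; windows where every carrier mating
  is hom × hom (E = n) or none exists are skipped as degenerate.
* p-values are floored at the smallest positive double; log₁₀ p is carried
  alongside for ranking beyond that floor.
* Constant SNP columns are excluded from M_eff with a warning (their
  correlation is undefined).
* Gene-drop quantiles use strict inequalities; with 200–1,000 simulations
  the lattice granularity is well below the decision thresholds used.
* The pedigree validator rejects cycles (reporting one offending cycle) and
  parents born after their offspring (strict mode) or warns (permissive).

## Known limitations

* No background LD, no mutation, no genotyping or phasing error in the
  generator; the scan's robustness to phase error is untested here.
* The gene-drop null conditions on the observed pedigree and genotyped set;
  it does not model genotyping ascertainment bias within cohorts.
* The deficiency scan reports exact-string haplotypes only; a semi-lethal
  *allele* shared across several haplotype backgrounds would dilute across
  strings and lose power.
* Sex is recorded but unused in the core computations (transmission is
  sex-symmetric); sex-specific transmission distortion is out of scope.
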