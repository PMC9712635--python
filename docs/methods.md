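# Methods

This note records the models implemented in `selfline`, the defaults and
why they were chosen, the numerical decisions, and what the synthetic data
can and cannot demonstrate.

## Selfing-line model

A selfing line is propagated by single-seed descent: exactly one offspring
is sampled per line and generation, and the next generation descends from
that sampled individual. Genotypes are diploid codes (HOM_REF, HET,
HOM_ALT, MISSING) per locus; phase is never used. A selfed homozygote
breeds true; a selfed heterozygote's offspring follow the Mendelian kernel
(¼, ½, ¼) over (HOM_REF, HET, HOM_ALT). Viability selection re-weights the
kernel by a per-locus fitness triple (w_RR, w_RA, w_AA) and renormalises;
this is the minimal mechanism that produces heterozygote excess, and it is
applied to the sampled offspring's genotype distribution. An optional
two-locus mode models associative overdominance: a neutral marker linked at
recombination fraction r to a deleterious recessive in repulsion phase,
evolved on 16 two-haplotype states with a precomputed viability-weighted
transition matrix.

All drift expectations follow from the kernel: P(heterozygous at
generation t) = (½)^t, the remainder splitting evenly between the fixed
classes; the inbreeding recurrence F_{t+1} = ½(1 + F_t) has closed form
1 − (1 − F_0)/2^t.

## Synthetic data: what it emulates, and what it does not

`SimulationConfig` defaults encode the study conditions rather than
convenient values:

| parameter | default | rationale |
| --- | --- | --- |
| `n_lines` | 28 | lines with complete FS–S4 data in the study design |
| `n_generations` | 5 | S1–S5 |
| `fs_het_fraction` | 0.3 | observed S1 heterozygosity ≈ 0.15 doubled under the halving law |
| `mean_depth` | 30 | capture-seq mean depth (~30×) |
| `het_allele_balance` | 0.5 | unbiased sequencing of a true heterozygote |
| `selfing_rate` | 0.3 | outcrossing rate 0.7, giving F_eq = s/(2−s) ≈ 0.17 |
| `miscall_rate` / `missing_rate` | 0.005 / 0.02 | plausible capture-seq error rates; the study does not report its own, so these are placeholders, not measured values |

Genotyping errors are symmetric (HET→either HOM with equal probability;
HOM→HET), applied after the error-free truth record is stored; read depths
are Poisson with binomial allele splits at heterozygotes, and a "paralog
mimic" mode skews the heterozygote allele balance (default 0.8) to exercise
the read-ratio-deviation filter. The mixed-mating population draws
genotypes at the inbreeding-equilibrium frequencies p² + pqF, 2pq(1−F),
q² + pqF with F = s/(2−s).

The simulator does **not** model: linkage among panel loci (each locus
segregates independently, so LD-based analyses are fed by the dedicated
curve-plus-noise pair generator instead), ascertainment of the capture
panel toward variable sites, family structure among FS founders (lines are
exchangeable), reference bias in depths, or sequence-level errors. Passing
tests therefore demonstrate the correctness of the statistics and
algorithms under the stated model, not robustness to those real-data
complications.

All randomness flows through one seeded `numpy.random.Generator`; the
pipeline splits its global seed per stage by hashing the stage name, so the
same config and seed reproduce identical bytes and disabling one stage
does not shift another's stream.

## QC cascade

Per-locus statistics are computed over called genotypes only. H_E is the
plug-in 2p̂(1−p̂) without small-sample correction, because the F_IS filter
uses the ratio H_O/H_E and the correction would cancel unevenly. Allele
balance is defined at site level — pooled alternate-read fraction over
heterozygous calls — because the thresholds are quoted once per SNP; the
read-ratio deviation uses the same pooled reads as the binomial(½) z-score
D = (ΣA − ΣB)/√(ΣA + ΣB). Exact Hardy–Weinberg and excess-heterozygosity
p-values come from full enumeration of heterozygote counts conditional on
the allele counts (no mid-p); the excess-het p is the one-sided upper tail.

Boundary conventions, as printed in the recipe they reproduce: call rate
and mean depth bounds inclusive; the allele-balance window (0.2, 0.8)
strict; the D window |D| ≤ 5 inclusive; H_O > 0.55 removed; F_IS removed
only when strictly negative; MAF/MAC thresholds inclusive. Loci with no
heterozygous calls pass the allele-balance and D filters vacuously, and
invariant sites see only the basic filter (without the QUAL condition).
The unusual "or allele balance < 0.01" retention clause is implemented as
printed. QUAL is interpreted as the site quality, not genotype quality.
The default cascade order is basic → allele balance → D → het/HWE → F_IS
→ MAF/MAC → LD prune; order is configurable, removal reasons record the
first filter that removed each locus, and the report satisfies
loci-in = loci-out + Σ removals by construction.

LD pruning is a greedy positional scan per scaffold: a locus is dropped
when its dosage-correlation r² with any already-retained locus within the
window exceeds the threshold — deterministic given input order. The same
dosage r² estimator (composite LD over unphased genotypes) serves the
decay analysis; it can differ slightly from EM-haplotype r², but is
deterministic and handles missing data by pairwise-complete samples.
Relatedness uses the VanRaden genomic relationship matrix
A = ZZᵀ/(2Σp̂(1−p̂)) with missing dosages imputed to 2p̂; exclusion
greedily drops the sample in the most violating pairs (ties by higher mean
relatedness, then input order) until no pair exceeds the cutoff.

## Genotype correction

Two rules, both justified by single-seed descent: two consecutive identical
homozygous calls force that homozygote for all later generations (a
homozygote breeds true), and two consecutive heterozygous calls force
heterozygosity for all earlier generations including FS (a heterozygous
child requires a heterozygous parent). Rules trigger on the observed calls
only, in a single scan, and then all overwrites are applied — iterative
re-triggering on corrected values is disabled, which removes cascade
ambiguity and makes correction idempotent by construction. MISSING entries
neither trigger nor block a rule but are overwritten (provenance
"imputed") when a rule covers their slot. If the rules assign conflicting
values to any slot — including two different homozygote runs in order —
the locus is removed globally across lines ("uncorrectable"); per-line
removal is available behind a flag. For lines without an S3 sample, S3 is
imputed from the corrected S2/S4 flanks when only one genotype is possible
(identical flanking homozygotes, or a heterozygous S4); a heterozygous S2
with homozygous S4 leaves two possibilities and stays missing, and
contradictory flanks remove the locus.

A consequence worth stating plainly: two consecutive *same-direction*
miscalls can legitimately trigger a rule and overwrite a correct call
(e.g. a truth-homozygous line whose S1 and S2 are both miscalled
heterozygous back-corrects FS to HET). With symmetric miscall rate m the
probability is O(m²) per adjacent pair — a handful of cells per million at
m = 0.01 — and is an inherent property of the published rules, not of this
implementation; the conflict check catches most such events (the locus is
then removed rather than silently altered), but not those at the ends of a
line where no contradicting pair exists.

## Trajectories and tests

Observed heterozygosity is computed per locus and generation as the
heterozygous fraction of lines with a non-missing call; the expectation at
generation g is half the previous generation's *observed* value at the same
locus (per-locus first, then averaged — the alternative per-line-first
average is not implemented). The sign test is the exact two-sided binomial
on per-locus (observed − expected) pairs with ties dropped. F_UNI uses the
allele frequency of the analysed genotype set itself and averages the
per-locus term over non-missing polymorphic loci; the one-sample t-test
compares each generation's per-sample F with the recurrence value seeded at
the FS mean.

The drift test tabulates S4 fixation categories over FS-heterozygous lines
(S5 excluded; never substituted for a missing S4), requires data in at
least three lines, and uses the asymptotic χ² with df = 2 even where the
expected heterozygote count is below 5 — matching the procedure it
reproduces; an exact multinomial alternative is available but not default.
BH-FDR is applied across tested loci. Direction flags are observed >
expected per category, with no secondary test. Lines are treated as
independent replicates even though they share FS parents within families,
again matching the source procedure.

## Diversity and LD

π and d_XY are ratio-of-sums estimators: per site, pairwise allele
differences and comparisons among called alleles (within-sample pairs for
π; cross-population pairs m_A·m_B for d_XY) are accumulated separately and
divided once per region. Invariant sites belong in the input table
(`is_variant=False`) so the denominator reflects callable sequence; windows
are 10-kb non-overlapping by default. Degeneracy classification uses the
standard nuclear codon table; 2- and 3-fold sites are classified but only
0- and 4-fold enter the π₀/π₄ ratio; CDSs with internal stops or lengths
not divisible by three are skipped and reported. The folded SFS is
complete-case by default, with opt-in hypergeometric projection.

The decay fit minimises unweighted squared residuals of the adjusted
E(r²) curve over c_per_bp ≥ 0 (log-parameterised Levenberg–Marquardt,
multi-start over a 10⁻⁸–10⁻⁴ log grid, tolerances 10⁻¹⁴), with an explicit
flat-curve (c = 0) comparison so decay-free data do not return a spurious
positive scale. Derived distances are solved on the fitted curve by
bracketing and Brent's method; the half-decay reference level is half the
90th percentile of all observed r² values (not distance-binned — the
percentile's reference set is genuinely ambiguous in the source recipe, and
"overall" is the simpler reading), and a threshold outside the curve's
range yields an absent distance rather than an extrapolation.

## Problem sizes

The test suite exercises the statistics at sizes where their expectations
are sharp but cheap: 10⁵ lines for the S4 heterozygosity check, 28 lines ×
10⁴ loci × 20 seeds for false-positive control of the drift test, 5,000
LD pairs × 20 seeds for parameter recovery, 100 random tables for the
π/d_XY brute-force oracles, and 28 × 1,000-locus panels for the correction
checks. The full suite runs in well under a minute on one core.

## Known limitations

- The correction rules cannot distinguish two consecutive consistent
  miscalls from signal (see above); their error-correction reading (rules
  overwrite conflicting observed calls rather than only filling gaps) is
  implemented because the procedure is described as correcting erroneous
  calls.
- The composite (dosage) r² is not the EM-haplotype r²; for the filtering
  and decay-fitting purposes here the difference is immaterial, but fitted
  scales should not be compared against haplotype-based estimates to high
  precision.
- The exact HWE enumeration is conditional on observed allele counts and
  assumes a single undifferentiated population; no stratified variant is
  provided.
- `f_uni` returns NaN for samples with no usable (polymorphic, called)
  loci, and trajectory rows for generations with no informative loci are
  absent rather than zero.
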