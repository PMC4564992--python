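# Methods

## The model

`poescan` tests for parent-of-origin (imprinting) effects at biallelic SNPs
using genotype data from case-parent trios, case-mother duos and case-father
duos. Genotypes are coded as minor-allele dosages; "2" denotes the minor
allele, which is modeled as the risk allele.

At a SNP, a trio falls into one of the 15 Mendelian-consistent categories
(g_m, g_f, g_c); a duo falls into one of 7 observable (g_parent, g_child)
pairs. The probability of category c in an ascertained case family is
modeled as w_c / W with multinomial weight

    w_c = mu_mt(gm,gf) * S_gm * R_gc * gamma(gm,gc) *
          sum over consistent ordered transmissions (a_m, a_p) of
          Im^(a_m) * Ip^(a_p)

where R1, R2 are the child relative risks for one/two risk-allele copies
(R0 = 1), S1, S2 the maternal-genotype relative risks, Im and Ip the
multiplicative risk factors for a maternally / paternally inherited risk
allele, gamma11 an optional mother-child interaction (carried through the
weights but fixed at 1 throughout this package), and mu1..mu6 nuisance
parameters stratifying on the unordered parental mating type (mt1 = 2/2 x
2/2, mt2 = 2/2 x 1/2, mt3 = 2/2 x 1/1, mt4 = 1/2 x 1/2, mt5 = 1/2 x 1/1,
mt6 = 1/1 x 1/1; mu6 = 1 is the reference). Duo weights are trio weights
summed over the untyped parent's genotype, so the maternal-genotype terms
follow the mother whether or not she is typed. The weight table is built by
transmission enumeration at run time, not transcribed; an independent
enumeration oracle in the test suite checks every cell.

The all-heterozygous configurations are the only ones in which the parental
origin of the child's minor allele is not determined by the single SNP:
trio cell 9 (weight mu4 R1 S1 (Ip + Im) gamma11) splits into cell 9a
(paternal minor, mu4 R1 S1 Ip gamma11) and 9b (maternal minor, mu4 R1 S1 Im
gamma11); duo cell 4 (R1 S1 gamma11 (Im (mu4 + mu5) + Ip (mu2 + mu4)) for
case-mother duos) splits into 4a and 4b analogously. Because a dataset may
contain both phased and unphased units, the likelihood keeps 9, 9a and 9b
(and 4, 4a, 4b) as separate categories — 17 trio cells and 9 duo cells in
total. Phasing availability is treated as ancillary (independent of the
genotype category), so the phased fraction factors out of the likelihood
and the three cells share parameters: the log-likelihood is

    l = sum_{c != 9} n_c log(w_c / W) + n_9 log((w_9a + w_9b) / W)
        + n_9a log(w_9a / W) + n_9b log(w_9b / W),

with W the sum of the 15 base-cell weights (cell 9 counted once as
w_9a + w_9b), and analogously for each duo table. The likelihood of a
dataset is the product over the tables present. With zero phased counts it
reduces exactly to the unsplit 15/7-cell likelihood. Counts need not be
integers; the adjusted duo counts (below) generally are not.

Tests are 1-df likelihood-ratio tests of Im or Ip (null: parameter = 1),
optionally conditioning on child effects (freeing R1, R2) and/or maternal
effects (freeing S1, S2); the mating-type nuisances are always free.
P-values come from the upper tail of chi-square(1) with the statistic
clipped at zero. Genomic control is lambda = median(LRT) / median of
chi-square(1) (~0.45494).

## Fitting

The likelihood is maximized over log-transformed free parameters with
L-BFGS-B, bounded at |log theta| <= 15 to stop drift along flat directions
(a duo-only table does not identify every mu separately), tolerance 1e-6,
all-ones start. Two structural shortcuts are exact:

- a free mating-type parameter whose stratum supports no positive count is
  fixed at 0, its MLE limit;
- when only a trio table is present and all supported mating-type
  parameters are free, the mu block is profiled out analytically (the
  mating-type margin attains the observed frequencies), leaving a 0-5
  dimensional optimization. If the reference stratum mt6 is unobserved the
  profiled optimum is a supremum and the reported mu are scaled to the
  largest observed stratum; log-likelihood differences (hence every LRT)
  are unaffected.

## Resolving parental origin

Outside the all-heterozygous configuration the origin is forced by
Mendelian rules. Inside it, single-family Mendelian logic can never decide:
both phase completions are consistent at every flanking SNP. What breaks
the tie is population haplotype frequency — specifically at flanking SNPs
where the transmitting parent is also heterozygous but their transmission
is forced, the two completions imply different parental diplotypes, and
their relative plausibility under the local haplotype distribution resolves
the origin. The built-in phaser therefore:

1. enumerates, for each unit, the founder-haplotype configurations
   consistent with all genotypes in a window centred on the test SNP
   (15 SNPs for trios, 7 for duos by default; no recombination within the
   window; windows truncate at chromosome ends; units with missing window
   genotypes, a Mendelian inconsistency, or more than 12 ambiguous sites
   are left unresolved);
2. estimates window haplotype frequencies by EM across the whole sample
   (uniform initialization; deterministic; monotone log-likelihood;
   tolerance 1e-6, max 200 iterations);
3. computes each ambiguous unit's posterior probability that the minor
   allele is paternal and commits the maximum-a-posteriori origin
   (posteriors are exposed for diagnostics; an exact 0.5 stays ambiguous).

Committing the single most likely assignment rather than fractional counts
is deliberate: allowing for phase uncertainty by sampling haplotypes has
not been found to improve power or type-I error in this design.
Externally phased haplotypes in SHAPEIT haps/sample format can be ingested
instead; child haplotypes are labelled maternal/paternal by matching to
parental haplotypes, and a unit whose best match still mismatches more than
10% of SNPs is dropped with a warning.

Default window sizes (15 trio / 7 duo SNPs) exceed the simulated 8-SNP
block length, so a window always spans the full LD context of its test SNP;
they are configurable for denser maps.

## Duo-count adjustment

Haplotype-estimated origin assignments in duos can be biased as a function
of the minor allele frequency p, inflating the test genome-wide. Under the
null with random mating and HWE, the expected fraction of ambiguous
case-mother duos whose minor allele is paternal is exactly p (1 - p for
case-father duos). The per-SNP deviation d = n_4a - (n_4a + n_4b) * p is
fitted across all SNPs as a degree-3 polynomial f(p) in p by weighted least
squares (weights n_4a + n_4b); counts are then adjusted to n_4a - f(p) and
n_4b + f(p), clipped at zero with the total preserved. The fit refuses to
run on fewer than 50 informative SNPs — the procedure assumes a genome-wide
panel in which the vast majority of SNPs carry no parent-of-origin effect,
and is unsuitable for candidate-SNP studies. A single genuinely skewed SNP
among many null SNPs moves the genome-wide fit only marginally, so its own
signal survives. Degree and the guard threshold are configurable; trio
counts are never adjusted.

## Synthetic data

The simulator emulates an ascertained family study on a chromosome of 25
independent haplotype blocks of 8 SNPs (200 SNPs; causal SNP 100; all
defaults configurable). Per block, a pool of 6 distinct haplotypes receives
Dirichlet(1) frequencies, with alleles relabelled so the designated minor
allele is minor at every position and pools resampled until every
position's pool MAF lies in [0.1, 0.4]; pool construction is deterministic
given the seed. Parental haplotypes are drawn independently per block
(linkage equilibrium across blocks), one haplotype is transmitted from each
parent with no recombination within blocks, and the child is ascertained
affected by rejection sampling with probability risk/max-risk, where
risk = R_gc * S_gm * Im^(a_m) * Ip^(a_p) at the causal SNP. The baseline
penetrance cancels under ascertainment and is not a parameter. Duos drop
the untyped parent's genotypes after sampling; true per-SNP origins are
retained for every unit. SNP minor-allele frequencies are recorded from the
typed parents (capped at 0.5).

What the generator does not emulate: genotyping error, missing data,
recombination within blocks, population stratification, and realistic
genome-scale LD structure. Passing studies therefore demonstrate the
statistical behaviour of the method under its own assumptions, not its
robustness to data-quality artefacts — on real data the external-phaser
route and the Mendelian-error handling of the surrounding tooling matter.

## Study harness and problem sizes

`run_study` evaluates power or type-I error over seeded replicates
(per-replicate seeds derived from one master seed via SeedSequence; all
origin modes — known truth, window-phaser estimate, or none — are evaluated
on the same datasets so comparisons share sampling noise). Detection means
any SNP in the window around the causal position (SNPs 97-104 by default)
falling below the threshold; the family-wise thresholds for 8 independent
tests are 6.25e-3 (FWER 0.05) and 1.25e-3 (FWER 0.01). Estimated-origin duo
studies tabulate and phase all SNPs so the genome-wide adjustment can be
fitted; trio studies phase only the tested SNPs.

The validation suite uses scaled-down problem sizes chosen to make each
check decisive at its tolerance: type-I error from 500 replicates of 300
trios at 24 SNPs (12,000 tests; exact binomial 99% band around 0.05;
lambda in [0.9, 1.1]); power orderings at Im = 2 with 500 trios (60
replicates, detection threshold 1e-6) and 500 case-mother duos (40
replicates, threshold 1e-4) — thresholds sit on the steep part of each
power curve, where ordering differences are real rather than ceiling ties;
Im recovery from 100 replicates of 2,000 trios at a single 8-SNP block;
adjustment efficacy on 1,000 duos x 200 SNPs with an injected paternal
assignment bias of 0.25*(0.5 - p); and the case-father/case-mother
comparison at 500 duos with unknown origin, where the asymmetry is purely
structural. `scripts/acceptance.py` recomputes the same quantities (type-I
error at 300 replicates) from scratch under a caller-supplied seed.

## Numerical and degenerate-input conventions

- LRT statistics are clipped at 0; p = 1 when the alternative MLE of the
  tested parameter is 1.
- A positive count on a zero-weight cell returns -inf log-likelihood
  (flagged, never silently dropped); zero counts contribute nothing.
- Mendelian-inconsistent units and units with a missing member genotype
  contribute nothing at that SNP (per-SNP complete case).
- Monomorphic SNPs read from files get MAF 0 and an undefined minor allele
  ("0"); minor/major ties at 0.5 break to the lexicographically smaller
  allele label.
- Family-unit selection is order-independent: pedigrees are processed
  sorted by family id, and equal-missingness candidate trios tie-break on
  the smallest child id.
- EM haplotype frequencies are deterministic (uniform initialization, no
  sampling); non-convergence after 200 iterations warns and returns the
  last iterate.

## Known limitations

- The built-in window phaser handles missing genotypes by leaving the unit
  unresolved in that window rather than imputing; heavily missing data
  should be phased externally and ingested via the haps/sample reader.
- X-chromosome SNPs, multi-allelic sites, covariates and the wider family
  units of full pedigree-likelihood frameworks (lone cases, controls,
  parents of cases) are out of scope; gamma11 is carried but not estimated.
- Mating-type symmetry is assumed (one mu per unordered parental pair).
- The adjustment's least-squares polynomial is one reasonable smoother for
  the deviation curve; a binomial-likelihood fit is a natural alternative
  and the functional family is a configuration choice, not a finding.
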