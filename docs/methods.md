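# Methods

This note records the models, parameter choices, numerical conventions and
known limitations behind the package, in the order the analysis runs.

## The locus model

`GeneModel` stores sorted, disjoint, 0-based half-open exon intervals;
introns are always derived from the gaps, never stored, so the two can
never disagree.  The synthetic fixture has 51 exons (one 108-bp exon at
each end, 49 x 54 bp between, all multiples of 9 echoing the ancestral
single 54-bp collagen exon) and 50 introns laid out so the first 21 total
exactly 6700 bp and the last 29 exactly 8900 bp.  Those block sizes matter:
all spatial tests compare counts against the 6700/15600 base fraction, so
the fixture reproduces the real locus's geometry where it is load-bearing.
Residue numbering is 1-based and derived from `coding_offset` along the
coding strand; the domain partition (N-terminal 1-178, triple helix
179-800, C-terminal 801-954) tiles the 954-residue protein.

Conversions to 1-based coordinates happen only at the VCF boundary and in
residue numbering.  Multiallelic records and indels are excluded rather
than split: every statistic here is biallelic, and splitting would silently
change frequency denominators.  Missing genotypes leave the denominator of
every frequency (no imputation).

## Synthetic data: what it emulates and what it does not

**Two-haplogroup haplotypes.**  A stem-and-star genealogy: the sample MRCA
sits `t_split` years back, each haplogroup hangs from a stem of length
`t_split - t_within`, and tips attach in a star at depth `t_within`.
Mutations are Poisson with rate `mu` per base-year on every branch, each at
a fresh uniform position (infinite sites), and the generator records every
mutation's branch, so fixed differences and the per-tip counts `x_i` are
known exactly.  Defaults are the study conditions for the deep chimpanzee
haplogroup pair: `t_split` = 2.8 My, `t_within` = 0.1 t_split (a free
parameter; within-group depth is otherwise unconstrained), locus length
15600 bp (the fixture's intron span), 20 haplotypes per group, and
`mu` = 5.7e-10 per base per year — the rate at which the two stems expect
~45 fixed differences at that age, the regime the analyses target.  An
optional outgroup lineage (`t_outgroup`) adds a pre-MRCA branch and an
outgroup haplotype for polarization, rooting and rate calibration.

This generator deliberately omits recombination, recurrent mutation and
population-size dynamics.  That matches the Thomson estimator's
assumptions and the no-recombination LD structure the analyses probe, but
it means passing tests say nothing about loci where recombination breaks
haplotype blocks.

**Population pairs.**  Balding-Nichols: per site an ancestral frequency
(uniform by default; optionally density ~ 1/f to emulate the rare-skewed
spectrum of large human samples), population frequencies Beta-distributed
around it with variance parameter `fst_true`, genotypes binomial.  The
single truth parameter makes F_ST calibration a sharp test.  No linkage
between sites and no shared drift beyond the one parameter.

**Conservation tracks.**  Per-base Normal(block mean, sd) over caller-
defined feature blocks.  Real phyloP tracks are heavy-tailed and spatially
autocorrelated; the Gaussian blocks test the machinery (length weighting,
permutation nulls), not distributional robustness.

**Disease-mutation catalogs.**  Exact per-category counts; Bernoulli
glycine involvement and multinomial domain placement per category; site
scores Normal with per-category means rising with severity.  The default
profile uses glycine probabilities (0.57, 0.91, 0.95, 0.98) for categories
1-4 and domain weights that concentrate severe categories in the triple
helix — the qualitative structure of clinical collagen catalogs.

## Estimators and tests

**Watterson's theta** is `S / (a_{n-1} L)` per site.  **Allele
frequencies** are dosage sums over called genotypes.

**Hudson F_ST** per SNP is `1 - H_w/H_b` with the sample-size-unbiased
`H_w`; sites monomorphic in both populations return NaN and leave all
averages.  Negative per-SNP values are retained — clamping would bias both
the mean and the permutation null.  Two cross-SNP combinations are
reported: the arithmetic mean of per-SNP values (the reporting default,
matching per-SNP averaging practice) and the ratio of summed components.
Only the latter is a consistent estimator of the Balding-Nichols truth
(the mean of ratios is biased low by Jensen's inequality — about 0.21 at a
truth of 0.30 under the default conditions), so calibration checks use the
ratio-of-averages form.  The outlier scan pools each SNP's called allele
copies and re-deals them hypergeometrically into the original sample
sizes; SNPs with F_ST > 0.30 are flagged as reported outliers, and
Benjamini-Hochberg adjustment is available but off by default.

**LD** uses haplotype counts with pairwise deletion; sites below 5% MAF
are removed before any pair computation (strictly below: MAF exactly at
the cutoff is retained).

**The 2x2 polymorphism/divergence contrast** uses the two-sided Fisher
exact test (p sums hypergeometric probabilities no larger than the
observed table's).  The odds ratio applies the Haldane-Anscombe 0.5
correction only when a zero in an off-diagonal cell would make it
undefined, and flags it.  An optional MAF cutoff recomputes the
polymorphism counts from per-variant frequencies before testing.

**Permutation tests** all report `p = (n_as_extreme + 1)/(n_perm + 1)`, so
no Monte-Carlo p is ever zero, and every result is bit-identical under a
fixed seed.  Counting ties as extreme makes the reported p conservative
whenever the resampled statistic is discrete (the F_ST scan's
hypergeometric null carries ~10% tie mass); a randomized tie-splitting
mode — exactly Uniform(0,1) under the null — exists for calibration
studies, and the deterministic rule remains the reporting default.

The **intron-block contrast** statistic is the length-weighted mean score
of introns 1..k minus introns k+1..end (weights = covered intron lengths),
with intron identities permuted between the groups; a site-level
permutation mode is exposed as an alternative since either scheme is
defensible.  The default alternative is "greater" — the fixed,
hypothesized direction that the 5' block is more conserved.  A data-chosen
direction ("auto") halves the null range of the p-value and is therefore
not the default.  Excluding introns (e.g. intron 1, typically long and
conserved genome-wide) happens before the split.

The **spatial clustering test** throws `n` mutations uniformly over the
concatenated intron bases and counts arrivals in the target introns; its
exact companion sums the binomial upper tail in rational arithmetic, so
tails near 1e-8 are exact rather than float-summed.

**Haplogroup partition** is 2-medoid clustering on Hamming distance,
seeded with the maximally distant pair, all ties resolved to the lowest
sample index (fully deterministic).  **Fixed differences** require the two
groups to share no allele at a site; sites uncalled in a whole group are
excluded and counted.

**Neighbor joining** follows the Saitou-Nei Q-criterion with ties broken
by the lexicographically smallest pair of subtree labels; branch lengths
use the standard two-point formulas, negative estimates are clamped to
zero with the deficit moved to the sister branch and the label flagged.
On any additive matrix the algorithm reproduces the generating tree's
topology and path lengths exactly (tested to 1e-8 on random trees of up to
12 taxa).  Trees are carried as newick; monophyly is judged on the tree
rerooted at the outgroup leaf.

**TMRCA** is the Thomson moment estimator `t = sum(x_i)/(n mu)`.  `x_i`
counts differences from the MRCA sequence over outgroup-polarizable sites
only; unpolarizable sites fall back to majority rule for the MRCA
sequence, are flagged, and never enter `x_i`.  The rate `mu` is
interspecies substitutions divided by twice the divergence time —
substitutions accrue along both lineages; the doubled alternative reading
is exposed as an option but not used.  The reported standard error
`sqrt(sum x_i)/(n mu)` treats the total count as Poisson, which is exact
for a star genealogy; with deep shared stems the true replicate spread is
several times larger (the stems contribute variance once per group but
appear in every tip), so the SE is documented and tested as a star-regime
approximation, and the divergence-time uncertainty (+/- 1 My on 5 My) is
propagated separately as a rate interval.

## Problem sizes and numerical conventions

Calibration studies run at: 500 replicates for TMRCA recovery (mean within
2% of truth) and for each permutation-null uniformity check (KS against
uniform, 199 permutations per seed); 2000 SNPs with 100 diploids per
population for F_ST calibration (+/- 0.02) and scan-null uniformity (1000
resamples per SNP); 1000 replicates for the type-I error of the 2x2
contrast (0.05 +/- 0.02 — cell means of a few tens keep Fisher's
discreteness from dominating); all 46k tables with margin totals <= 30 for
Fisher-vs-enumeration exactness; 200 random additive matrices for NJ.
Statistic comparisons inside permutation loops use an absolute tolerance
of 1e-9 (scaled by the observed magnitude) so a degenerate constant
statistic ties with itself instead of resolving by float noise.

The pipeline derives one sub-seed per stage by hashing the stage name with
the top-level seed, so adding a stage never perturbs the randomness of the
others, and a fixed seed reproduces `summary.json` byte-for-byte (runtimes
aside).

## Limitations

- The simulators are structural stand-ins: they reproduce the statistical
  shapes the tests consume (two deep haplogroups, a known differentiation
  parameter, block-structured scores, severity-stratified catalogs), not
  the full complexity of resequencing data (no recombination, no
  demography, no base composition, Gaussian rather than heavy-tailed
  conservation scores).  Green tests certify the estimators and test
  machinery under those conditions, not robustness to real-data artifacts.
- Phasing is assumed done upstream; unphased VCFs yield genotype analyses
  only.
- The mean-of-ratios F_ST is reported because per-SNP averaging is the
  field's common reporting choice, but it should not be read as an
  estimate of the generating differentiation parameter; use the
  ratio-of-averages value for that.
- The clinical severity categories are consumed as input; nothing here
  recomputes them.
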