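# colsel

Population-genetic selection-signature analysis of a collagen-like locus
(COL1A1-style: 51 short exons, 50 introns, an N-terminal / triple-helix /
C-terminal domain partition), aimed at the questions a comparative study of
clinical and natural variation in a bone-structural gene asks:

- Is amino-acid variation in natural populations rarer, milder, and
  differently placed than clinically catalogued disease-associated
  mutations?  (domain x severity and glycine x severity contingency tests,
  conservation-score contrasts)
- Do introns show spatial heterogeneity in evolutionary constraint, and do
  population-differentiation outliers and haplogroup-defining variants
  cluster into the same 5' intron block?  (length-weighted intron
  randomization, Hudson F_ST outlier scan, spatial clustering tests)
- How old is a deep two-haplogroup structure in strong linkage
  disequilibrium?  (neighbor-joining trees, monophyly against an outgroup,
  Thomson TMRCA)

Everything runs end to end over synthetic inputs whose statistical
structure matches what the analyses assume, so the whole battery is
testable without any external data.

## The statistics at the core

- Watterson's estimator `theta_S = S / (a_{n-1} L)` with
  `a_{n-1} = sum_{i=1}^{n-1} 1/i`, per site over `L` surveyed bases.
- Per-SNP Hudson F_ST `1 - H_w / H_b`, `H_w` the mean unbiased
  within-population heterozygosity `2p(1-p) n/(n-1)`,
  `H_b = p1(1-p2) + p2(1-p1)`; combined across SNPs either as the mean of
  per-SNP values or as the ratio of summed components.  Outlier SNPs are
  judged against a null that pools both populations' allele copies and
  re-deals them into the original sample sizes, 1000 times per SNP.
- Haplotype LD `r2 = D^2 / (p_A(1-p_A) p_B(1-p_B))` over common SNPs
  (MAF >= 5%).
- The McDonald-Kreitman 2x2 contrast of replacement vs intronic variation,
  polymorphism vs divergence, by two-sided Fisher exact test.
- Randomization tests with the add-one convention
  `p = (n_as_extreme + 1) / (n_perm + 1)`: rank-sum location contrasts,
  a length-weighted intron-block conservation contrast, and the uniform
  placement null for mutation clustering (with an exact binomial-tail
  companion computed in rational arithmetic).
- The Thomson TMRCA estimator `t = sum_i x_i / (n mu)`, `x_i` the mutation
  count separating sequence `i` from the sample MRCA (reconstructed by
  outgroup polarization), `mu` the per-locus per-year rate calibrated as
  interspecies substitutions / (2 x divergence time).

## Worked example

The seven numbered scripts under `analysis/` run the full study over a
synthetic bundle; `python analysis/01_simulate_inputs.py` writes the inputs
and each later script consumes them.  `analysis/07_haplogroups_and_tmrca.py`
prints, for the default simulated sample:

```
two core haplogroups of 20 and 20 haplotypes (separation 0.86); 30 of 131 SNPs are fixed between them
15 of 30 fixed differences fall in introns 1-21 (43% of intron bases): exact tail p = 2.74e-01, Monte-Carlo p = 2.73e-01
  (the simulator places mutations uniformly, so no clustering is expected here; a clustered sample such as 38 of 45 gives p = 1.2e-08)
haplogroups monophyletic against the outgroup: True
mu = 9.55e-06 per locus per year from 95.5 interspecies substitutions over 5 +/- 1 My
haplogroup TMRCA = 1.8 My (sampling se 0.07 My; mu uncertainty span 1.5-2.2 My)
```

Reading this: the 2-medoid partition cleanly splits the 40 phased
haplotypes into the two simulated haplogroups; 30 SNPs separate them
completely.  Because the generator scatters mutations uniformly, their
placement across the intron blocks is unremarkable (p = 0.27) — whereas a
5'-clustered configuration like 38 of 45 in the 6700-bp block would be a
~1e-8 tail.  The outgroup roots a neighbor-joining tree on which both
haplogroups are monophyletic, and the Thomson estimator dates their split
at 1.8 My under the outgroup-calibrated rate (the true simulated age is
2.8 My; this realization drew few stem mutations, and the quoted sampling
SE is the star-genealogy approximation, which understates the spread
contributed by the shared stems — see `docs/methods.md`).

The same battery is available as a single command:

```
colsel run-all --seed 1 --out-dir results/run
```

which writes one TSV per stage plus `summary.json` with every statistic,
p-value, permutation count and seed.

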