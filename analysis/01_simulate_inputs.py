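#!/usr/bin/env python
"""Generate the synthetic input bundle every later step consumes.

Writes, under results/inputs/: the collagen-like gene model (51 exons whose
first 21 introns total 6700 bp and last 29 total 8900 bp), a phased VCF of
the two-haplogroup chimpanzee-like sample plus an outgroup, a
conservation-score bedGraph with a more-conserved 5' intron block, a
genotype VCF for an African-like vs non-African-like population pair, and a
severity-stratified disease-mutation catalog.
"""

from pathlib import Path

import numpy as np

from colsel import io as cio
from colsel import synthetic
from colsel.pipeline import DEFAULT_DOMAIN_WEIGHTS, DEFAULT_GLY_PROB, DEFAULT_N_PER_CATEGORY

SEED = 20220121
OUT = Path(__file__).resolve().parent.parent / "results" / "inputs"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    model = synthetic.make_colgene_fixture()
    cio.write_gene_model(model, OUT / "gene_model.tsv")

    hm, truth = synthetic.simulate_two_haplogroup_locus(
        synthetic.TwoHaplogroupParams(seed=SEED, t_outgroup=5e6)
    )
    # ingroup rows come in sample pairs; the outgroup haplotype is written
    # as a homozygous pseudo-diploid so the VCF stays rectangular
    alleles = np.vstack([hm.alleles, hm.alleles[-1]])
    cio.write_vcf(
        OUT / "haplotypes.vcf", hm.positions, hm.ref, hm.alt, model.chrom,
        haplotypes=alleles,
        sample_ids=[f"chimp{i}" for i in range(20)] + ["outgroup"],
    )

    track = synthetic.simulate_conservation_track(
        model, synthetic.intron_block_means(model, 0.5, -0.5), sd=1.0,
        seed=SEED + 1,
    )
    cio.write_bedgraph(track, OUT / "conservation.bedgraph")

    gt = synthetic.simulate_population_pair(
        synthetic.PopulationPairParams(
            fst_true=0.10, n_sites=300, n_per_pop=100,
            freq_spectrum="neutral", ancestral_freq_range=(0.005, 0.95),
            seed=SEED + 2,
        ),
        positions=np.sort(np.random.default_rng(SEED + 3).choice(
            np.arange(model.start, model.end), 300, replace=False
        )),
    )
    cio.write_vcf(
        OUT / "populations.vcf", gt.positions,
        ["A"] * gt.n_sites, ["G"] * gt.n_sites, model.chrom,
        genotypes=gt.genotypes, sample_ids=gt.sample_ids,
    )
    with open(OUT / "populations.pops.tsv", "w") as fh:
        fh.write("sample\tpopulation\n")
        for s, p in zip(gt.sample_ids, gt.population):
            fh.write(f"{s}\t{p}\n")

    dams = synthetic.simulate_dam_catalog(
        DEFAULT_N_PER_CATEGORY, DEFAULT_GLY_PROB, DEFAULT_DOMAIN_WEIGHTS,
        model, seed=SEED + 4,
    )
    cio.write_dam_table(dams, OUT / "dam_catalog.tsv")

    print(f"locus: {len(model.exons)} exons over {model.end - model.start} bp, "
          f"{model.total_intron_length} bp of introns")
    print(f"phased sample: {hm.n_haplotypes} haplotypes, {hm.n_sites} SNPs "
          f"({len(truth.fixed_diff_positions)} true fixed differences)")
    print(f"population pair: {gt.n_samples} diploids x {gt.n_sites} SNPs")
    print(f"DAM catalog: {len(dams)} records")
    print(f"wrote inputs to {OUT}")


if __name__ == "__main__":
    main()
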