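"""End-to-end orchestration of the analysis battery.

A single top-level seed deterministically derives one sub-seed per stage by
hashing the stage name, so adding or reordering stages never perturbs the
randomness of the others.  Every stage writes a TSV; the run ends with a
machine-readable JSON summary carrying every statistic, p-value,
permutation count and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import haplotypes as hap
from . import io as cio
from . import popgen, protein, scan, synthetic
from .model import GeneModel, polarize_with_outgroup

log = logging.getLogger(__name__)


def derive_seed(seed: int, stage: str) -> int:
    """Stable per-stage sub-seed below 2^31."""
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Inputs and knobs for one full run.

    Either ``synthetic=True`` (the default profile generates every input) or
    the four real-input paths; the two are mutually exclusive.  ``seed`` is
    mandatory because every permutation stage consumes randomness.
    """

    output_dir: str = "results/run"
    seed: int = 1
    n_perm: int = 1999
    maf_min: float = 0.05
    block_split: int = 21
    synthetic: bool = True
    vcf_path: Optional[str] = None
    bedgraph_path: Optional[str] = None
    dam_path: Optional[str] = None
    gene_model_path: Optional[str] = None
    pop_map: dict = field(default_factory=dict)

    def __post_init__(self):
        real = [self.vcf_path, self.bedgraph_path, self.dam_path, self.gene_model_path]
        if self.synthetic and any(p is not None for p in real):
            raise ValueError("synthetic mode and real input paths are mutually exclusive")
        if not self.synthetic and any(p is None for p in real):
            raise ValueError("real mode needs VCF, bedGraph, DAM and gene-model paths")


DEFAULT_GLY_PROB = {1: 0.57, 2: 0.91, 3: 0.95, 4: 0.98}
DEFAULT_DOMAIN_WEIGHTS = {
    1: (0.25, 0.45, 0.30),
    2: (0.05, 0.80, 0.15),
    3: (0.05, 0.85, 0.10),
    4: (0.02, 0.90, 0.08),
}
DEFAULT_N_PER_CATEGORY = {1: 120, 2: 110, 3: 90, 4: 100}


def _stage(summary, name, t0, **payload):
    payload["runtime_s"] = round(time.perf_counter() - t0, 3)
    summary[name] = payload
    log.info("stage %s done in %.2fs", name, payload["runtime_s"])


def run_full_analysis(cfg: RunConfig) -> dict:
    """Run annotation through TMRCA, writing per-stage TSVs plus a summary.

    Returns the summary dict (also written as ``summary.json``).  Any stage
    error aborts with the stage name; the outputs of completed stages stay
    on disk.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary = {"config": {
        "seed": cfg.seed, "n_perm": cfg.n_perm, "maf_min": cfg.maf_min,
        "block_split": cfg.block_split, "synthetic": cfg.synthetic,
    }}

    stage = "inputs"
    try:
        t0 = time.perf_counter()
        if cfg.synthetic:
            model = synthetic.make_colgene_fixture()
            dams = synthetic.simulate_dam_catalog(
                DEFAULT_N_PER_CATEGORY, DEFAULT_GLY_PROB, DEFAULT_DOMAIN_WEIGHTS,
                model, seed=derive_seed(cfg.seed, "dam"),
            )
            track = synthetic.simulate_conservation_track(
                model,
                synthetic.intron_block_means(model, 0.5, -0.5, split=cfg.block_split),
                sd=1.0, seed=derive_seed(cfg.seed, "track"),
            )
            gt = synthetic.simulate_population_pair(
                synthetic.PopulationPairParams(
                    fst_true=0.10, n_sites=300, n_per_pop=100,
                    freq_spectrum="neutral", ancestral_freq_range=(0.005, 0.95),
                    seed=derive_seed(cfg.seed, "pops"),
                ),
                positions=np.sort(
                    np.random.default_rng(derive_seed(cfg.seed, "pos")).choice(
                        np.arange(model.start, model.end), 300, replace=False
                    )
                ),
            )
            hm, truth = synthetic.simulate_two_haplogroup_locus(
                synthetic.TwoHaplogroupParams(
                    t_outgroup=5.0e6, seed=derive_seed(cfg.seed, "haps")
                )
            )
        else:
            model = cio.read_gene_model(cfg.gene_model_path)
            dams = cio.read_dam_table(cfg.dam_path)
            track = cio.read_conservation_track(
                cfg.bedgraph_path, (model.chrom, model.start, model.end)
            )
            data = cio.read_vcf(
                cfg.vcf_path, (model.chrom, model.start, model.end), cfg.pop_map
            )
            gt, hm, truth = data.genotypes, data.haplotypes, None
        _stage(summary, stage, t0, n_dam_records=len(dams),
               n_genotype_sites=gt.n_sites,
               n_haplotypes=None if hm is None else hm.n_haplotypes)

        # ------------------------------------------------ 1. variant annotation
        stage = "variant_annotation"
        t0 = time.perf_counter()
        by_cat = {}
        for r in dams:
            by_cat.setdefault(r.severity, []).append(r)
        gly_frac = {c: float(np.mean([r.glycine_flag for r in rs]))
                    for c, rs in sorted(by_cat.items())}
        dom_tab = protein.build_domain_contingency(dams, "severity", "domain")
        dom_tab.table.to_csv(out / "domain_by_severity.tsv", sep="\t")
        _stage(summary, stage, t0, n_records=len(dams),
               glycine_fraction_by_category=gly_frac)

        # ------------------------------------------------ 2. frequency / SFS
        stage = "frequency_sfs"
        t0 = time.perf_counter()
        freqs = {}
        for pop in sorted(set(gt.population)):
            f = popgen.population_frequencies(gt, pop)
            f = f[~np.isnan(f)]
            maf = np.minimum(f, 1 - f)
            seg = maf > 0
            freqs[pop] = {
                "n_snps": int(seg.sum()),
                "theta_w_per_site": popgen.watterson_theta(
                    int(seg.sum()), 2 * int(gt.samples_in(pop).sum()),
                    model.end - model.start,
                ),
                "fraction_below_1pct": (
                    popgen.sfs_fraction_below(maf[seg], 0.01) if seg.any() else None
                ),
            }
        pd.DataFrame(freqs).T.to_csv(out / "diversity_by_population.tsv", sep="\t")
        _stage(summary, stage, t0, per_population=freqs)

        # ------------------------------------------------ 3. conservation
        stage = "conservation_contrasts"
        t0 = time.perf_counter()
        block = scan.intron_block_randomization(
            track, model, cfg.block_split, n_perm=cfg.n_perm,
            seed=derive_seed(cfg.seed, stage),
        )
        block_no1 = scan.intron_block_randomization(
            track, model, cfg.block_split, n_perm=cfg.n_perm,
            seed=derive_seed(cfg.seed, stage + ":omit1"), exclude_introns={1},
        )
        cat_scores = {c: [r.site_score for r in rs] for c, rs in sorted(by_cat.items())}
        sev_contrast = scan.permutation_location_test(
            cat_scores.get(1, []),
            sum((cat_scores.get(c, []) for c in (2, 3, 4)), []),
            n_perm=cfg.n_perm, seed=derive_seed(cfg.seed, stage + ":dam"),
        )
        _stage(summary, stage, t0,
               block_contrast=_perm(block), block_contrast_omit_intron1=_perm(block_no1),
               category1_vs_234_scores=_perm(sev_contrast))

        # ------------------------------------------------ 4. F_ST outliers
        stage = "fst_outlier_scan"
        t0 = time.perf_counter()
        pops = sorted(set(gt.population))
        popA, popB = pops[0], pops[1]
        pair = popgen.hudson_fst_pair(gt, popA, popB)
        outliers = scan.fst_outlier_scan(
            gt, popA, popB, n_perm=min(cfg.n_perm, 1000),
            seed=derive_seed(cfg.seed, stage),
        )
        pd.DataFrame(
            [{"position": o.position, "fst": o.fst, "p": o.result.p_value,
              "flagged": o.flagged} for o in outliers]
        ).to_csv(out / "fst_per_snp.tsv", sep="\t", index=False)
        _stage(summary, stage, t0, mean_fst=pair.mean_fst,
               mean_fst_ratio_of_averages=pair.mean_fst_ratio_of_averages,
               n_snps=pair.n_snps,
               n_flagged_outliers=int(sum(o.flagged for o in outliers)))

        # restrict the phased matrix to ingroup haplotypes and their
        # segregating sites (the simulated matrix carries an outgroup row)
        hm_in, outgroup_bases = None, None
        if hm is not None:
            if truth is not None:
                ingroup_rows = [i for i, g in enumerate(hm.group_labels)
                                if g != "outgroup"]
                out_row = [i for i, g in enumerate(hm.group_labels)
                           if g == "outgroup"]
                seg_in = [
                    s for s in range(hm.n_sites)
                    if 0 < hm.alleles[ingroup_rows, s].mean() < 1
                ]
                hm_in = hm.take_sites(seg_in).take_haplotypes(ingroup_rows)
                outgroup_bases = [
                    hm.ref[s] if (not out_row or hm.alleles[out_row[0], s] == 0)
                    else hm.alt[s]
                    for s in seg_in
                ]
            else:
                hm_in = hm

        # ------------------------------------------------ 5. LD
        stage = "ld_structure"
        t0 = time.perf_counter()
        if hm_in is None:
            _stage(summary, stage, t0, skipped="no phased haplotypes")
        else:
            ingroup = hm_in
            r2, kept = popgen.ld_r2_matrix(ingroup, maf_min=cfg.maf_min)
            pairs = []
            for i in range(len(kept)):
                for j in range(i + 1, len(kept)):
                    pairs.append({
                        "pos_a": int(ingroup.positions[kept[i]]),
                        "pos_b": int(ingroup.positions[kept[j]]),
                        "r2": r2[i, j],
                    })
            pd.DataFrame(pairs).to_csv(out / "ld_pairs.tsv", sep="\t", index=False)
            _stage(summary, stage, t0, n_sites_retained=int(len(kept)),
                   mean_r2=float(np.mean([p["r2"] for p in pairs])))

        # ------------------------------------------------ 6-9: phased stages
        if hm is not None and truth is not None:
            stage = "haplogroup_partition"
            t0 = time.perf_counter()
            part = hap.partition_core_haplogroups(hm_in)
            _stage(summary, stage, t0, separation=part.separation,
                   group_sizes=[int(np.sum(part.assignment == g)) for g in (0, 1)])

            stage = "fixed_differences_spatial"
            t0 = time.perf_counter()
            fixed = hap.fixed_differences(hm_in, part.assignment)
            intron_of = {}
            n_in_target = 0
            for pos in fixed.positions:
                # simulated haplotype coordinates are offsets into the intron span
                feat = _intron_of_offset(model, int(pos))
                intron_of[int(pos)] = feat
                if feat is not None and feat <= cfg.block_split:
                    n_in_target += 1
            spatial = scan.spatial_clustering_test(
                fixed.count, model, set(range(1, cfg.block_split + 1)),
                n_in_target, n_perm=min(cfg.n_perm * 10, 100_000),
                seed=derive_seed(cfg.seed, stage),
            )
            exact = scan.exact_spatial_tail(
                fixed.count,
                model.intron_lengths[: cfg.block_split].sum()
                / model.intron_lengths.sum(),
                n_in_target,
            )
            _stage(summary, stage, t0, n_fixed=fixed.count,
                   n_in_first_block=n_in_target, spatial_mc=_perm(spatial),
                   spatial_exact_p=exact)

            stage = "nj_tree"
            t0 = time.perf_counter()
            dm = hap.p_distance_matrix(hm.take_sites(range(hm.n_sites)))
            tree = hap.neighbor_joining(dm)
            hap.write_newick(tree, out / "haplotypes.nwk")
            mono = {}
            if out_row:
                for g in ("A", "B"):
                    leaves = [hm.sample_ids[i] for i in ingroup_rows
                              if hm.group_labels[i] == g]
                    mono[g] = hap.is_monophyletic(tree, leaves, "outgroup")
            _stage(summary, stage, t0, monophyly=mono,
                   n_clamped=len(tree.clamped))

            stage = "tmrca"
            t0 = time.perf_counter()
            counts = hap.mutations_from_mrca(hm_in, outgroup_bases)
            # interspecies substitutions: mean pairwise differences between
            # the ingroup haplotypes and the outgroup over all sites
            out_alleles_full = hm.alleles[out_row[0]]
            n_div = float(np.mean(
                (hm.alleles[ingroup_rows] != out_alleles_full[None, :]).sum(axis=1)
            ))
            mu = hap.estimate_mu(n_div, 5.0e6, time_uncertainty_years=1.0e6)
            est = hap.thomson_tmrca(counts.x, mu.mu)
            lo = hap.thomson_tmrca(counts.x, hap.estimate_mu(n_div, 6.0e6).mu)
            hi = hap.thomson_tmrca(counts.x, hap.estimate_mu(n_div, 4.0e6).mu)
            _stage(summary, stage, t0, t_years=est.t, se_years=est.se,
                   t_interval_from_mu=[min(lo.t, hi.t), max(lo.t, hi.t)],
                   mu_per_locus_per_year=mu.mu, n_sequences=est.n)
        elif hm is not None:
            # real phased input: partition + fixed differences only
            stage = "haplogroup_partition"
            t0 = time.perf_counter()
            part = hap.partition_core_haplogroups(hm)
            fixed = hap.fixed_differences(hm, part.assignment)
            _stage(summary, stage, t0, separation=part.separation,
                   n_fixed=fixed.count)
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_jsonable)
    return summary


def _perm(r) -> dict:
    return {"observed": r.observed, "n_perm": r.n_perm, "p": r.p_value,
            "seed": r.seed, "sidedness": r.sidedness}


def _intron_of_offset(model: GeneModel, offset: int):
    """Intron index (1-based) of an offset into the concatenated intron span."""
    acc = 0
    for j, L in enumerate(model.intron_lengths, start=1):
        if offset < acc + L:
            return j
        acc += L
    return None


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")
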