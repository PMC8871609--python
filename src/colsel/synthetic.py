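"""Synthetic inputs with the statistical structure the analyses assume.

The generators emulate the study conditions: a 51-exon collagen-like locus
whose first 21 introns total ~6.7 kb and last 29 total ~8.9 kb; a
two-haplogroup, recombination-free haplotype sample separated by dozens of
fixed differences; population pairs with a known differentiation parameter
(Balding-Nichols); block-structured conservation scores; and a
severity-stratified missense-mutation catalog.  Every generator is a pure
function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .model import (
    ConservationTrack,
    DAMRecord,
    GeneModel,
    GenotypeTable,
    HaplotypeMatrix,
    locate_site,
)


# --------------------------------------------------------------------------
# gene model fixture
# --------------------------------------------------------------------------

def make_colgene_fixture(locus_start: int = 1000, chrom: str = "chr17") -> GeneModel:
    """A collagen-like gene model: 51 exons, 50 introns, domain partition.

    Exon lengths are short multiples of 9 (45-108 bp), echoing the ancestral
    single 54-bp collagen exon.  The first 21 introns total exactly 6700 bp
    and the last 29 exactly 8900 bp, so spatial tests over the two intron
    blocks use the same base fractions as the real locus.
    """
    exon_lengths = [108] + [54] * 49 + [108]            # 2862 coding bases
    intron_lengths = [1200] + [275] * 20 + [307] * 28 + [304]
    assert sum(intron_lengths[:21]) == 6700 and sum(intron_lengths[21:]) == 8900
    exons = []
    pos = locus_start
    for i, el in enumerate(exon_lengths):
        exons.append((pos, pos + el))
        pos += el
        if i < len(intron_lengths):
            pos += intron_lengths[i]
    n_res = sum(exon_lengths) // 3                       # 954 residues
    domains = {
        "N_terminal": (1, 178),
        "triple_helix": (179, 800),
        "C_terminal": (801, n_res),
    }
    return GeneModel(
        chrom=chrom, strand="+", exons=tuple(exons), domains=domains,
        coding_offset=locus_start,
    )


# --------------------------------------------------------------------------
# two-haplogroup haplotype simulator
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TwoHaplogroupParams:
    """Stem-and-star genealogy for a deep two-haplogroup locus.

    The sample MRCA sits ``t_split`` years back; each haplogroup hangs from a
    stem of length ``t_split - t_within`` with its tips attached in a star at
    depth ``t_within``.  Mutations fall as a Poisson process at ``mu`` per
    base per year along every branch, each at a fresh position
    (infinite sites).  Defaults reproduce the study conditions for the
    chimpanzee locus: a 2.8-My-old pair of haplogroups over the 15.6-kb
    intron span, 40 sampled haplotypes, and a mutation rate at which the two
    stems expect ~45 fixed differences.
    """

    n_per_group: int = 20
    locus_length: int = 15600
    mu: float = 5.7e-10          # per base per year
    t_split: float = 2.8e6       # years
    t_within: float = 2.8e5      # years; default 0.1 * t_split
    t_outgroup: Optional[float] = None   # species split, years; adds an outgroup
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.t_within < self.t_split):
            raise ValueError("need 0 <= t_within < t_split")
        if self.mu < 0 or self.n_per_group < 1 or self.locus_length < 1:
            raise ValueError("invalid simulation parameters")
        if not all(np.isfinite([self.mu, self.t_split, self.t_within])):
            raise ValueError("parameters must be finite")
        if self.t_outgroup is not None and self.t_outgroup <= self.t_split:
            raise ValueError("t_outgroup must exceed t_split")


@dataclass
class TwoHaplogroupTruth:
    """Exact bookkeeping of the simulated genealogy."""

    group: np.ndarray                 # 0/1 per ingroup haplotype
    fixed_diff_positions: np.ndarray  # stem-mutation positions (sorted)
    x: np.ndarray                     # per-tip mutation count back to the MRCA
    mrca: np.ndarray                  # MRCA allele (0/1) at each retained site
    t_split: float
    outgroup_positions: np.ndarray = field(default_factory=lambda: np.empty(0, int))


def simulate_two_haplogroup_locus(p: TwoHaplogroupParams):
    """Simulate phased haplotypes under the stem-and-star genealogy.

    Returns ``(HaplotypeMatrix, TwoHaplogroupTruth)``.  The matrix holds the
    ingroup tips (plus one ``outgroup`` haplotype when ``t_outgroup`` is set)
    over all sites variable in that matrix; the truth records every
    mutation's branch, so fixed differences between haplogroups and the
    per-tip counts ``x_i`` are known exactly.
    """
    rng = np.random.default_rng(p.seed)
    n = p.n_per_group
    stem_t = p.t_split - p.t_within
    rate = p.mu * p.locus_length

    # branch list: (n_carriers_mask builder, branch length in years)
    branch_counts = {
        "stem0": rng.poisson(rate * stem_t),
        "stem1": rng.poisson(rate * stem_t),
    }
    for g in (0, 1):
        for i in range(n):
            branch_counts[f"tip{g}_{i}"] = rng.poisson(rate * p.t_within)
    n_out_branch = 0
    if p.t_outgroup is not None:
        # ingroup-ancestral branch (species split -> sample MRCA) plus the
        # outgroup lineage back to the species split
        branch_counts["pre_mrca"] = rng.poisson(rate * (p.t_outgroup - p.t_split))
        branch_counts["outgroup"] = rng.poisson(rate * p.t_outgroup)
        n_out_branch = branch_counts["outgroup"]

    total = sum(branch_counts.values())
    if total > p.locus_length:
        raise ValueError("more mutations than sites; increase locus_length")
    all_pos = rng.choice(p.locus_length, size=total, replace=False)

    n_haps = 2 * n + (1 if p.t_outgroup is not None else 0)
    cols, col_pos, col_branch = [], [], []
    cursor = 0
    for name, k in branch_counts.items():
        for _ in range(k):
            pos = all_pos[cursor]
            cursor += 1
            col = np.zeros(n_haps, dtype=np.int8)
            if name == "stem0":
                col[:n] = 1
            elif name == "stem1":
                col[n : 2 * n] = 1
            elif name == "pre_mrca":
                col[: 2 * n] = 1
            elif name == "outgroup":
                col[2 * n] = 1
            else:
                g, i = name[3:].split("_")
                col[int(g) * n + int(i)] = 1
            cols.append(col)
            col_pos.append(pos)
            col_branch.append(name)

    col_pos = np.asarray(col_pos, dtype=np.int64)
    order = np.argsort(col_pos)
    alleles = (
        np.stack(cols, axis=1)[:, order]
        if cols
        else np.zeros((n_haps, 0), dtype=np.int8)
    )
    positions = col_pos[order]
    branches = [col_branch[j] for j in order]

    sample_ids = [f"hapA_{i}" for i in range(n)] + [f"hapB_{i}" for i in range(n)]
    groups = ["A"] * n + ["B"] * n
    if p.t_outgroup is not None:
        sample_ids.append("outgroup")
        groups.append("outgroup")
    hm = HaplotypeMatrix(
        alleles=alleles,
        positions=positions,
        sample_ids=sample_ids,
        ref=np.array(["A"] * len(positions), dtype=object),
        alt=np.array(["G"] * len(positions), dtype=object),
        group_labels=groups,
    )

    group = np.array([0] * n + [1] * n)
    fixed = np.sort(
        [pos for pos, b in zip(positions, branches) if b in ("stem0", "stem1")]
    ).astype(np.int64)
    x = np.zeros(2 * n, dtype=np.int64)
    for pos, b in zip(positions, branches):
        if b == "stem0":
            x[:n] += 1
        elif b == "stem1":
            x[n:] += 1
        elif b.startswith("tip"):
            g, i = b[3:].split("_")
            x[int(g) * n + int(i)] += 1
    # MRCA of the sampled ingroup carries the pre-MRCA-branch derived alleles
    mrca = np.array(
        [1 if b == "pre_mrca" else 0 for b in branches], dtype=np.int8
    )
    out_pos = np.sort(
        [pos for pos, b in zip(positions, branches) if b == "outgroup"]
    ).astype(np.int64)
    truth = TwoHaplogroupTruth(
        group=group, fixed_diff_positions=fixed, x=x, mrca=mrca,
        t_split=p.t_split, outgroup_positions=out_pos,
    )
    return hm, truth


# --------------------------------------------------------------------------
# population-pair genotype simulator
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PopulationPairParams:
    """Balding-Nichols population pair with a known F_ST truth.

    Each site draws an ancestral frequency (uniform on
    ``ancestral_freq_range``, or proportional to 1/f under
    ``freq_spectrum="neutral"`` to emulate the rare-skewed site-frequency
    spectrum of a large human sample), then each population's frequency from
    a Beta with that mean and variance parameter ``fst_true``; genotypes are
    binomial(2, freq).
    """

    fst_true: float = 0.15
    n_sites: int = 2000
    n_per_pop: int = 100
    ancestral_freq_range: tuple = (0.1, 0.9)
    freq_spectrum: str = "uniform"    # "uniform" | "neutral"
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.fst_true < 1):
            raise ValueError("fst_true must lie in (0, 1)")
        lo, hi = self.ancestral_freq_range
        if not (0 < lo < hi < 1):
            raise ValueError("need 0 < lo < hi < 1 for ancestral_freq_range")
        if self.freq_spectrum not in ("uniform", "neutral"):
            raise ValueError("freq_spectrum must be 'uniform' or 'neutral'")


def simulate_population_pair(p: PopulationPairParams,
                             positions=None) -> GenotypeTable:
    """Draw a two-population genotype table under the Balding-Nichols model."""
    rng = np.random.default_rng(p.seed)
    lo, hi = p.ancestral_freq_range
    if p.freq_spectrum == "uniform":
        anc = rng.uniform(lo, hi, p.n_sites)
    else:
        # density proportional to 1/f on [lo, hi]: inverse-CDF sampling
        u = rng.random(p.n_sites)
        anc = lo * (hi / lo) ** u
    a = anc * (1 - p.fst_true) / p.fst_true
    b = (1 - anc) * (1 - p.fst_true) / p.fst_true
    freq = {pop: rng.beta(a, b) for pop in ("A", "B")}
    blocks = [
        rng.binomial(2, freq[pop][None, :], (p.n_per_pop, p.n_sites)).astype(np.int8)
        for pop in ("A", "B")
    ]
    if positions is None:
        positions = np.arange(p.n_sites)
    return GenotypeTable(
        genotypes=np.vstack(blocks),
        positions=np.asarray(positions),
        sample_ids=[f"A{i}" for i in range(p.n_per_pop)]
        + [f"B{i}" for i in range(p.n_per_pop)],
        population=["A"] * p.n_per_pop + ["B"] * p.n_per_pop,
    )


# --------------------------------------------------------------------------
# conservation track simulator
# --------------------------------------------------------------------------

def simulate_conservation_track(model: GeneModel, block_means, sd: float,
                                seed: int = 0) -> ConservationTrack:
    """Per-base scores Normal(block mean, sd) over the locus.

    ``block_means`` maps groups of feature names (e.g. ``("intron_1", ...,
    "intron_21")``) to a mean score; together the groups must cover every
    exon and intron of the model.
    """
    rng = np.random.default_rng(seed)
    feature_mean = {}
    for features, mean in block_means.items():
        if isinstance(features, str):
            features = (features,)
        for f in features:
            feature_mean[f] = mean
    all_features = [f"exon_{i + 1}" for i in range(len(model.exons))] + [
        f"intron_{j + 1}" for j in range(len(model.introns))
    ]
    uncovered = [f for f in all_features if f not in feature_mean]
    if uncovered:
        raise ValueError(f"block means do not cover the locus: missing {uncovered[:3]}...")
    scores = np.empty(model.end - model.start)
    for i, (s, e) in enumerate(model.exons):
        m = feature_mean[f"exon_{i + 1}"]
        scores[s - model.start : e - model.start] = rng.normal(m, sd, e - s)
    for j, (s, e) in enumerate(model.introns):
        m = feature_mean[f"intron_{j + 1}"]
        scores[s - model.start : e - model.start] = rng.normal(m, sd, e - s)
    return ConservationTrack(chrom=model.chrom, start=model.start, scores=scores)


def intron_block_means(model: GeneModel, first_mean: float, rest_mean: float,
                       split: int = 21, exon_mean: float = 3.0) -> dict:
    """Convenience block map: exons at one mean, introns split at ``split``."""
    n_ex, n_in = len(model.exons), len(model.introns)
    return {
        tuple(f"exon_{i + 1}" for i in range(n_ex)): exon_mean,
        tuple(f"intron_{j + 1}" for j in range(split)): first_mean,
        tuple(f"intron_{j + 1}" for j in range(split, n_in)): rest_mean,
    }


# --------------------------------------------------------------------------
# disease-mutation catalog simulator
# --------------------------------------------------------------------------

#: Amino acids used for the non-glycine reference draw.
_NON_GLY = list("ARNDCEQHILKMFPSTWYV")

def simulate_dam_catalog(n_per_category: dict, glycine_prob_per_category: dict,
                         domain_weights_per_category: dict, model: GeneModel,
                         seed: int = 0,
                         score_means=None) -> list:
    """Draw a severity-stratified missense-mutation catalog.

    Counts are exact per category; whether the mutated (reference) residue is
    glycine is Bernoulli with the category's probability; domains are
    multinomial with the category's weights over (N_terminal, triple_helix,
    C_terminal); residues are uniform within the drawn domain; site scores
    are Normal(mean, 1) with per-category means (default: higher conservation
    for more severe categories, emulating the clinical catalog).
    """
    rng = np.random.default_rng(seed)
    if score_means is None:
        score_means = {1: 1.5, 2: 3.0, 3: 3.5, 4: 4.0}
    records = []
    for cat in sorted(n_per_category):
        n = n_per_category[cat]
        gp = glycine_prob_per_category[cat]
        if not (0 <= gp <= 1):
            raise ValueError("glycine probabilities must lie in [0, 1]")
        weights = np.asarray(domain_weights_per_category[cat], dtype=float)
        if weights.min() < 0:
            raise ValueError("domain weights must be non-negative")
        weights = weights / weights.sum()
        domains = rng.choice(
            ["N_terminal", "triple_helix", "C_terminal"], size=n, p=weights
        )
        for d in domains:
            a, b = model.domains[d]
            residue = int(rng.integers(a, b + 1))
            gly = rng.random() < gp
            aa_from = "G" if gly else str(rng.choice(_NON_GLY))
            aa_to = str(rng.choice([x for x in "ARNDCEQGHILKMFPSTWYV" if x != aa_from]))
            records.append(
                DAMRecord(
                    residue=residue, aa_from=aa_from, aa_to=aa_to, domain=str(d),
                    severity=int(cat),
                    site_score=float(rng.normal(score_means[int(cat)], 1.0)),
                )
            )
    return records


# --------------------------------------------------------------------------
# neutral polymorphism/divergence counts (2x2 calibration)
# --------------------------------------------------------------------------

def simulate_neutral_mk_counts(p: TwoHaplogroupParams, t_divergence: float,
                               replacement_fraction: float, seed: int = 0) -> dict:
    """Neutral polymorphism and divergence counts split into two site classes.

    Polymorphic-site counts come from a stem-and-star locus simulation;
    divergence is Poisson over the two interspecies branches
    (2 * mu * L * t_divergence).  Each mutation is labeled "replacement" with
    probability ``replacement_fraction`` independently of everything else
    (thinning), so the class ratios are equal in expectation -- the null of
    the polymorphism/divergence contrast.
    """
    rng = np.random.default_rng(seed)
    sim = TwoHaplogroupParams(
        n_per_group=p.n_per_group, locus_length=p.locus_length, mu=p.mu,
        t_split=p.t_split, t_within=p.t_within,
        seed=int(rng.integers(2**31)),
    )
    hm, _ = simulate_two_haplogroup_locus(sim)
    n_poly = hm.n_sites
    n_div = rng.poisson(2 * p.mu * p.locus_length * t_divergence)
    rp = rng.binomial(n_poly, replacement_fraction)
    rd = rng.binomial(n_div, replacement_fraction)
    return {
        "replacement_poly": int(rp),
        "replacement_div": int(rd),
        "neutral_poly": int(n_poly - rp),
        "neutral_div": int(n_div - rd),
    }
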