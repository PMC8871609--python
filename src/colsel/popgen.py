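"""Classical population-genetic statistics.

Watterson's theta, allele frequencies and site-frequency-spectrum summaries,
the per-SNP Hudson F_ST estimator, haplotype r-squared linkage
disequilibrium, and the replacement-vs-neutral polymorphism/divergence
contingency (McDonald-Kreitman) test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .model import MISSING, GenotypeTable, HaplotypeMatrix

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# diversity and frequencies
# --------------------------------------------------------------------------

def harmonic_number(k: int) -> float:
    """a_k = sum_{i=1}^{k} 1/i."""
    return float(np.sum(1.0 / np.arange(1, k + 1)))


def watterson_theta(S: int, n: int, L: float) -> float:
    """Per-site Watterson diversity estimate theta = S / (a_{n-1} * L).

    Parameters
    ----------
    S : int
        Number of segregating sites.
    n : int
        Number of sampled allele copies (>= 2).
    L : float
        Surveyed length in base pairs.
    """
    if n < 2:
        raise ValueError("need at least two allele copies")
    if L <= 0:
        raise ValueError("surveyed length must be positive")
    if S < 0:
        raise ValueError("segregating-site count cannot be negative")
    return S / (harmonic_number(n - 1) * L)


def allele_frequency(gt: GenotypeTable, site: int) -> float:
    """Alternate-allele frequency at one site, excluding missing genotypes."""
    col = gt.genotypes[:, site]
    called = col != MISSING
    if not called.any():
        raise ValueError(f"site {site} has no called genotypes")
    return float(col[called].sum() / (2 * called.sum()))


def population_frequencies(gt: GenotypeTable, pop: str) -> np.ndarray:
    """Per-site alternate-allele frequencies within one population (NaN when
    the population has < 1 called genotype at a site)."""
    sub = gt.genotypes[gt.samples_in(pop)]
    called = sub != MISSING
    counts = np.where(called, sub, 0).sum(axis=0)
    denom = 2 * called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, counts / denom, np.nan)


def sfs_fraction_below(freqs: Sequence[float], cutoff: float) -> float:
    """Proportion of frequencies strictly below ``cutoff``."""
    freqs = np.asarray(freqs, dtype=float)
    if freqs.size == 0:
        raise ValueError("empty frequency list")
    if not (0 < cutoff < 1):
        raise ValueError("cutoff must lie in (0, 1)")
    return float(np.mean(freqs < cutoff))


# --------------------------------------------------------------------------
# Hudson F_ST
# --------------------------------------------------------------------------

def hudson_fst_snp(p1, n1, p2, n2):
    """Per-SNP Hudson F_ST = 1 - H_w / H_b.

    ``H_w`` is the mean of the two sample-size-unbiased within-population
    heterozygosities 2p(1-p)n/(n-1); ``H_b = p1(1-p2) + p2(1-p1)``.  ``n``
    counts allele copies.  Sites monomorphic in both populations for the
    same allele (H_b = 0) return NaN -- the undefined flag, excluded from
    averages.  Accepts scalars or arrays.
    """
    p1, p2 = np.asarray(p1, dtype=float), np.asarray(p2, dtype=float)
    n1, n2 = np.asarray(n1, dtype=float), np.asarray(n2, dtype=float)
    if np.any(n1 < 2) or np.any(n2 < 2):
        raise ValueError("need >= 2 allele copies per population")
    hw = 0.5 * (2 * p1 * (1 - p1) * n1 / (n1 - 1) + 2 * p2 * (1 - p2) * n2 / (n2 - 1))
    hb = p1 * (1 - p2) + p2 * (1 - p1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = 1.0 - hw / hb
    out = np.where(hb == 0, np.nan, fst)
    return float(out) if out.ndim == 0 else out


@dataclass
class FstResult:
    """Per-SNP Hudson F_ST values and their combinations across SNPs.

    ``mean_fst`` is the arithmetic mean of per-SNP values (average of
    ratios, the reporting default).  ``mean_fst_ratio_of_averages`` combines
    numerator and denominator sums first (1 - sum(H_w)/sum(H_b)); it is the
    consistent estimator of the generating differentiation parameter and is
    the quantity used for calibration checks.
    """

    per_snp: list                          # (position, fst) for defined SNPs
    mean_fst: float
    mean_fst_ratio_of_averages: float
    n_snps: int


def hudson_fst_pair(gt: GenotypeTable, popA: str, popB: str) -> FstResult:
    """Hudson F_ST per SNP between two labelled populations, plus averages."""
    pA = population_frequencies(gt, popA)
    pB = population_frequencies(gt, popB)
    mA = gt.samples_in(popA)
    mB = gt.samples_in(popB)
    nA = 2 * (gt.genotypes[mA] != MISSING).sum(axis=0)
    nB = 2 * (gt.genotypes[mB] != MISSING).sum(axis=0)
    usable = (nA >= 2) & (nB >= 2) & ~np.isnan(pA) & ~np.isnan(pB)
    hw = 0.5 * (
        2 * pA * (1 - pA) * nA / np.maximum(nA - 1, 1)
        + 2 * pB * (1 - pB) * nB / np.maximum(nB - 1, 1)
    )
    hb = pA * (1 - pB) + pB * (1 - pA)
    defined = usable & (hb > 0)
    if not defined.any():
        raise ValueError("no SNP polymorphic across the two populations")
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = 1.0 - hw / hb
    per_snp = [(int(p), float(f)) for p, f in zip(gt.positions[defined], fst[defined])]
    return FstResult(
        per_snp=per_snp,
        mean_fst=float(np.mean(fst[defined])),
        mean_fst_ratio_of_averages=float(1.0 - hw[defined].sum() / hb[defined].sum()),
        n_snps=int(defined.sum()),
    )


# --------------------------------------------------------------------------
# linkage disequilibrium
# --------------------------------------------------------------------------

def minor_allele_frequency(hm: HaplotypeMatrix, s: int) -> float:
    f = hm.site_frequency(s)
    return min(f, 1.0 - f)


def ld_r2_pair(hm: HaplotypeMatrix, siteA: int, siteB: int) -> float:
    """Haplotype r^2 between two sites over haplotypes called at both.

    r^2 = D^2 / (pA(1-pA) pB(1-pB)) with D = p_AB - pA pB.
    """
    a = hm.alleles[:, siteA]
    b = hm.alleles[:, siteB]
    ok = (a != MISSING) & (b != MISSING)
    a, b = a[ok].astype(float), b[ok].astype(float)
    if a.size == 0:
        raise ValueError("no haplotype called at both sites")
    pA, pB = a.mean(), b.mean()
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        raise ValueError("both sites must be polymorphic among shared haplotypes")
    D = (a * b).mean() - pA * pB
    return float(D * D / (pA * (1 - pA) * pB * (1 - pB)))


def ld_r2_matrix(hm: HaplotypeMatrix, maf_min: float = 0.05):
    """Symmetric r^2 matrix over sites passing the MAF filter.

    Sites with minor allele frequency strictly below ``maf_min`` are removed
    before any pair computation.  Returns ``(matrix, retained_site_indices)``.
    """
    keep = np.array(
        [minor_allele_frequency(hm, s) >= maf_min for s in range(hm.n_sites)]
    )
    idx = np.flatnonzero(keep)
    if idx.size < 2:
        raise ValueError(
            f"fewer than two sites retained by the MAF >= {maf_min} filter"
        )
    k = idx.size
    r2 = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            r2[i, j] = r2[j, i] = ld_r2_pair(hm, int(idx[i]), int(idx[j]))
    return r2, idx


def ld_decay_profile(hm: HaplotypeMatrix, anchor_sites, distance_bins):
    """Mean r^2 between anchor SNPs and other SNPs, per distance bin.

    ``distance_bins`` is an ordered sequence of (lo, hi) half-open distance
    ranges in bp.  Bins with no pair are returned as NaN with an
    ``empty`` flag rather than zero.
    """
    anchor_sites = list(anchor_sites)
    means, empties = [], []
    for lo, hi in distance_bins:
        vals = []
        for a in anchor_sites:
            for s in range(hm.n_sites):
                if s == a:
                    continue
                d = abs(int(hm.positions[s]) - int(hm.positions[a]))
                if lo <= d < hi:
                    try:
                        vals.append(ld_r2_pair(hm, a, s))
                    except ValueError:
                        continue  # monomorphic partner
        if vals:
            means.append(float(np.mean(vals)))
            empties.append(False)
        else:
            means.append(float("nan"))
            empties.append(True)
    return np.asarray(means), np.asarray(empties)


# --------------------------------------------------------------------------
# McDonald-Kreitman
# --------------------------------------------------------------------------

@dataclass
class MKTable:
    """2x2 replacement/neutral x polymorphism/divergence contrast."""

    replacement_poly: int
    replacement_div: int
    neutral_poly: int
    neutral_div: int
    odds_ratio: float
    p_value: float
    maf_cutoff: Optional[float] = None
    haldane_corrected: bool = False

    @property
    def counts(self) -> np.ndarray:
        return np.array(
            [[self.replacement_poly, self.replacement_div],
             [self.neutral_poly, self.neutral_div]]
        )


def mk_test(replacement_poly: int, replacement_div: int, neutral_poly: int,
            neutral_div: int, maf_exclude: Optional[float] = None,
            replacement_freqs=None, neutral_freqs=None) -> MKTable:
    """Two-sided Fisher exact test on the polymorphism/divergence table.

    Rows are replacement vs. neutral-proxy (intronic) variation; columns are
    within-species polymorphism vs. between-species divergence.  When
    ``maf_exclude`` is given together with per-variant frequency lists, the
    polymorphism counts are recomputed from variants at frequency >= the
    cutoff before testing.  The odds ratio uses the Haldane-Anscombe 0.5
    correction only when a zero cell would make it undefined (flagged).
    """
    counts = [replacement_poly, replacement_div, neutral_poly, neutral_div]
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    maf_cutoff = None
    if maf_exclude is not None:
        if replacement_freqs is None or neutral_freqs is None:
            raise ValueError("maf_exclude requires per-variant frequency lists")
        replacement_poly = int(np.sum(np.asarray(replacement_freqs) >= maf_exclude))
        neutral_poly = int(np.sum(np.asarray(neutral_freqs) >= maf_exclude))
        maf_cutoff = maf_exclude
    table = np.array([[replacement_poly, replacement_div],
                      [neutral_poly, neutral_div]])
    if table.sum() == 0:
        raise ValueError("all-zero contingency table")
    _, p = stats.fisher_exact(table, alternative="two-sided")
    a, b, c, d = table.ravel().astype(float)
    corrected = False
    if b == 0 or c == 0:  # odds ratio undefined (division by zero)
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    odds = (a * d) / (b * c)
    return MKTable(
        replacement_poly=int(table[0, 0]), replacement_div=int(table[0, 1]),
        neutral_poly=int(table[1, 0]), neutral_div=int(table[1, 1]),
        odds_ratio=float(odds), p_value=float(p),
        maf_cutoff=maf_cutoff, haldane_corrected=corrected,
    )
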