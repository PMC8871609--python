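"""Permutation and randomization tests.

All tests follow the add-one convention p = (n_as_extreme + 1)/(n_perm + 1),
so no Monte-Carlo p-value is ever exactly zero, and every result is
bit-identical under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .model import MISSING, ConservationTrack, GeneModel, GenotypeTable
from .popgen import hudson_fst_snp, population_frequencies


@dataclass(frozen=True)
class PermutationResult:
    """Uniform return type of every randomization test."""

    observed: float
    n_perm: int
    n_as_extreme: int
    p_value: float
    seed: int
    sidedness: str

    def __post_init__(self):
        if not (0 < self.p_value <= 1):
            raise ValueError("permutation p-values lie in (0, 1]")


def _add_one_p(n_as_extreme: int, n_perm: int) -> float:
    return (n_as_extreme + 1) / (n_perm + 1)


# --------------------------------------------------------------------------
# two-sample location contrast
# --------------------------------------------------------------------------

def permutation_location_test(valuesA, valuesB, n_perm: int = 9999,
                              seed: int = 0, statistic: str = "rank_sum",
                              sidedness: str = "two-sided") -> PermutationResult:
    """Nonparametric two-group location contrast with permutation p-values.

    The default statistic is the rank sum of group A over the pooled sample
    (``statistic="mean_diff"`` uses mean(A) - mean(B)).  Labels are permuted
    wholesale; the two-sided p doubles the smaller tail, capped at 1.
    """
    a = np.asarray(valuesA, dtype=float)
    b = np.asarray(valuesB, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    pooled = np.concatenate([a, b])
    nA = a.size
    if statistic == "rank_sum":
        scores = stats.rankdata(pooled)
    elif statistic == "mean_diff":
        # mean difference is a monotone function of sum(A) at fixed totals
        scores = pooled.copy()
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    obs = scores[:nA].sum()

    rng = np.random.default_rng(seed)
    perm = np.empty(n_perm)
    idx = np.arange(pooled.size)
    for k in range(n_perm):
        rng.shuffle(idx)
        perm[k] = scores[idx[:nA]].sum()
    n_ge = int(np.sum(perm >= obs))
    n_le = int(np.sum(perm <= obs))
    if sidedness == "two-sided":
        n_extreme = min(n_ge, n_le)
        p = min(1.0, 2 * _add_one_p(n_extreme, n_perm))
    elif sidedness == "greater":
        n_extreme = n_ge
        p = _add_one_p(n_ge, n_perm)
    elif sidedness == "less":
        n_extreme = n_le
        p = _add_one_p(n_le, n_perm)
    else:
        raise ValueError(f"unknown sidedness {sidedness!r}")
    if statistic == "mean_diff":
        observed = float(a.mean() - b.mean())
    else:
        observed = float(obs)
    return PermutationResult(
        observed=observed, n_perm=n_perm, n_as_extreme=n_extreme,
        p_value=float(p), seed=seed, sidedness=sidedness,
    )


# --------------------------------------------------------------------------
# F_ST outlier scan
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FstOutlier:
    """Per-SNP outcome of the pooled-resampling differentiation scan."""

    position: int
    fst: float
    result: PermutationResult
    flagged: bool


def fst_outlier_scan(gt: GenotypeTable, popA: str, popB: str,
                     n_perm: int = 1000, seed: int = 0,
                     flag_threshold: float = 0.30,
                     tie_break: str = "conservative") -> list:
    """Per-SNP F_ST significance by pooling and resampling allele copies.

    For every SNP the called allele copies of both populations are pooled
    and re-dealt without replacement into the original sample sizes
    (hypergeometric), rebuilding the per-SNP Hudson F_ST each time; the
    one-sided p is the add-one fraction of resampled values >= observed.
    SNPs with F_ST above ``flag_threshold`` (default 0.30) are flagged as
    reported outliers.

    ``tie_break="conservative"`` counts resampled values tied with the
    observed one as extreme (the reporting default; with a discrete
    resampling distribution this is deliberately conservative).
    ``tie_break="randomized"`` draws a uniform tie-splitting variate, which
    makes the null p-value distribution exactly uniform -- the mode used for
    calibration checks.
    """
    if tie_break not in ("conservative", "randomized"):
        raise ValueError(f"unknown tie_break {tie_break!r}")
    rng = np.random.default_rng(seed)
    mA, mB = gt.samples_in(popA), gt.samples_in(popB)
    pA, pB = population_frequencies(gt, popA), population_frequencies(gt, popB)
    nA = 2 * (gt.genotypes[mA] != MISSING).sum(axis=0)
    nB = 2 * (gt.genotypes[mB] != MISSING).sum(axis=0)
    out = []
    for s in range(gt.n_sites):
        n1, n2 = int(nA[s]), int(nB[s])
        if n1 < 2 or n2 < 2:
            continue
        obs = hudson_fst_snp(pA[s], n1, pB[s], n2)
        if np.isnan(obs):
            continue
        k_alt = int(round(pA[s] * n1 + pB[s] * n2))
        k1 = rng.hypergeometric(k_alt, n1 + n2 - k_alt, n1, n_perm)
        perm = hudson_fst_snp(k1 / n1, n1, (k_alt - k1) / n2, n2)
        perm = np.nan_to_num(perm, nan=-np.inf)  # both-fixed resamples: not extreme
        n_gt = int(np.sum(perm > obs + 1e-12))
        n_eq = int(np.sum(np.abs(perm - obs) <= 1e-12))
        if tie_break == "conservative":
            n_extreme = n_gt + n_eq
            p = _add_one_p(n_extreme, n_perm)
        else:
            u = rng.random()
            n_extreme = n_gt + n_eq
            p = (n_gt + u * (n_eq + 1)) / (n_perm + 1)
        out.append(
            FstOutlier(
                position=int(gt.positions[s]), fst=float(obs),
                result=PermutationResult(
                    observed=float(obs), n_perm=n_perm, n_as_extreme=n_extreme,
                    p_value=float(p), seed=seed, sidedness="greater",
                ),
                flagged=bool(obs > flag_threshold),
            )
        )
    return out


def benjamini_hochberg(pvals: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values (optional multiple-testing view of the scan)."""
    return stats.false_discovery_control(np.asarray(pvals, dtype=float), method="bh")


# --------------------------------------------------------------------------
# intron-block conservation randomization
# --------------------------------------------------------------------------

def _intron_scores(track: ConservationTrack, model: GeneModel):
    """Per-intron (score sum over covered bases, covered length)."""
    sums, lens = [], []
    for s, e in model.introns:
        vals = track.slice(s, e)
        ok = ~np.isnan(vals)
        sums.append(vals[ok].sum())
        lens.append(ok.sum())
    return np.asarray(sums), np.asarray(lens, dtype=float)


def intron_block_randomization(track: ConservationTrack, model: GeneModel,
                               block_split: int, n_perm: int = 9999,
                               seed: int = 0,
                               exclude_introns: Optional[set] = None,
                               alternative: str = "greater",
                               mode: str = "labels") -> PermutationResult:
    """Length-weighted contrast of mean conservation between intron blocks.

    The statistic is the length-weighted mean score of introns 1..k minus
    that of introns k+1..end (weights are covered intron lengths in bases).
    Under the default ``mode="labels"`` the null permutes intron identities
    between the two groups, keeping group sizes; ``mode="sites"`` instead
    permutes per-base scores across all intron bases and rebuilds the
    statistic, a site-level bootstrap of the same contrast.
    ``exclude_introns`` (1-based indices) removes introns entirely before
    splitting -- e.g. {1} reruns the contrast without the first intron.

    ``alternative="greater"`` (default) tests the hypothesized direction
    that the 5' block is more conserved; "less", "two-sided" and "auto"
    (the direction the observed statistic happens to point) are available.
    """
    n_introns = len(model.introns)
    if not (1 <= block_split < n_introns):
        raise ValueError(f"block_split must lie in 1..{n_introns - 1}")
    excluded = set(exclude_introns or ())
    first_idx = [i for i in range(block_split) if (i + 1) not in excluded]
    rest_idx = [i for i in range(block_split, n_introns) if (i + 1) not in excluded]
    if not first_idx or not rest_idx:
        raise ValueError("exclusion left an intron group empty")

    rng = np.random.default_rng(seed)
    if mode == "labels":
        sums, lens = _intron_scores(track, model)
        keep = np.asarray(first_idx + rest_idx)
        sums, lens = sums[keep], lens[keep]
        k = len(first_idx)

        def stat(order):
            g1, g2 = order[:k], order[k:]
            return sums[g1].sum() / lens[g1].sum() - sums[g2].sum() / lens[g2].sum()

        base = np.arange(len(keep))
        obs = stat(base)
        perm = np.empty(n_perm)
        for t in range(n_perm):
            rng.shuffle(base)
            perm[t] = stat(base)
    elif mode == "sites":
        segs1 = [track.slice(*model.introns[i]) for i in first_idx]
        segs2 = [track.slice(*model.introns[i]) for i in rest_idx]
        v1 = np.concatenate(segs1)
        v2 = np.concatenate(segs2)
        v1, v2 = v1[~np.isnan(v1)], v2[~np.isnan(v2)]
        obs = v1.mean() - v2.mean()
        pooled = np.concatenate([v1, v2])
        n1 = v1.size
        perm = np.empty(n_perm)
        for t in range(n_perm):
            rng.shuffle(pooled)
            perm[t] = pooled[:n1].mean() - pooled[n1:].mean()
    else:
        raise ValueError(f"unknown mode {mode!r}")

    # tolerance absorbs float noise so a degenerate (constant) statistic ties
    tol = 1e-9 * max(1.0, abs(obs))
    n_ge = int(np.sum(perm >= obs - tol))
    n_le = int(np.sum(perm <= obs + tol))
    side = alternative
    if alternative == "auto":
        side = "greater" if obs >= 0 else "less"
    if side == "greater":
        n_extreme, p = n_ge, _add_one_p(n_ge, n_perm)
    elif side == "less":
        n_extreme, p = n_le, _add_one_p(n_le, n_perm)
    elif side == "two-sided":
        n_extreme = min(n_ge, n_le)
        p = min(1.0, 2 * _add_one_p(n_extreme, n_perm))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return PermutationResult(
        observed=float(obs), n_perm=n_perm, n_as_extreme=n_extreme,
        p_value=float(p), seed=seed, sidedness=side,
    )


# --------------------------------------------------------------------------
# spatial clustering of mutations over introns
# --------------------------------------------------------------------------

def _target_fraction(model: GeneModel, target_introns) -> float:
    lens = model.intron_lengths
    target = sorted(target_introns)
    if not target:
        raise ValueError("target intron set must be non-empty")
    bad = [j for j in target if not (1 <= j <= len(lens))]
    if bad:
        raise ValueError(f"unknown intron indices {bad}")
    return float(lens[[j - 1 for j in target]].sum() / lens.sum())


def spatial_clustering_test(n_mutations: int, model: GeneModel,
                            target_introns, observed_in_target: int,
                            n_perm: int = 100_000, seed: int = 0) -> PermutationResult:
    """Monte-Carlo test of mutation clustering into a set of introns.

    Each permutation throws ``n_mutations`` points uniformly over the
    concatenated intron bases of the model; the statistic is the count
    landing in the target introns, and p = P(count >= observed) with the
    add-one rule.
    """
    if observed_in_target > n_mutations:
        raise ValueError("observed count cannot exceed the number of mutations")
    lens = model.intron_lengths
    total = int(lens.sum())
    if total == 0:
        raise ValueError("model has zero intron length")
    target = set(target_introns)
    _ = _target_fraction(model, target)  # validates the set
    # membership mask over concatenated intron bases
    mask = np.zeros(total, dtype=bool)
    off = 0
    for j, L in enumerate(lens, start=1):
        if j in target:
            mask[off : off + L] = True
        off += L
    rng = np.random.default_rng(seed)
    n_extreme = 0
    chunk = max(1, min(n_perm, 2_000_000 // max(n_mutations, 1)))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        draws = rng.integers(0, total, size=(m, n_mutations))
        counts = mask[draws].sum(axis=1)
        n_extreme += int(np.sum(counts >= observed_in_target))
        done += m
    return PermutationResult(
        observed=float(observed_in_target), n_perm=n_perm,
        n_as_extreme=n_extreme, p_value=_add_one_p(n_extreme, n_perm),
        seed=seed, sidedness="greater",
    )


def exact_spatial_tail(n_mutations: int, fraction_in_target: float,
                       observed: int) -> float:
    """Exact binomial upper tail P(X >= observed), X ~ Bin(n, fraction).

    Summed in exact rational arithmetic, so tails far below machine epsilon
    (e.g. ~1e-8 for 38 of 45 points in a 0.43 fraction) are exact.
    """
    if not (0 <= fraction_in_target <= 1):
        raise ValueError("fraction must lie in [0, 1]")
    if observed <= 0:
        return 1.0
    f = Fraction(fraction_in_target)
    tail = Fraction(0)
    for k in range(observed, n_mutations + 1):
        tail += comb(n_mutations, k) * f**k * (1 - f) ** (n_mutations - k)
    return float(tail)
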