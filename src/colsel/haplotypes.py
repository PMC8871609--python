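"""Haplogroup structure, distance trees, and haplogroup age estimation.

The age estimator is the Thomson moment estimator t = sum(x_i) / (n * mu),
where x_i counts the mutational differences between sequence i and the MRCA
of the sample and mu is the per-locus per-year mutation rate.  It needs no
population-equilibrium assumption and tolerates the absence of
recombination, which is exactly the regime of a deep two-haplogroup locus in
strong LD.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np

from .model import MISSING, HaplotypeMatrix


# --------------------------------------------------------------------------
# haplogroup partition
# --------------------------------------------------------------------------

def hamming_matrix(hm: HaplotypeMatrix) -> np.ndarray:
    """Pairwise mismatch counts with pairwise deletion of missing alleles."""
    H = hm.n_haplotypes
    A = hm.alleles
    D = np.zeros((H, H))
    for i in range(H):
        ai = A[i]
        for j in range(i + 1, H):
            aj = A[j]
            ok = (ai != MISSING) & (aj != MISSING)
            D[i, j] = D[j, i] = np.sum(ai[ok] != aj[ok])
    return D


@dataclass
class HaplogroupPartition:
    assignment: np.ndarray       # 0/1 per haplotype
    medoids: tuple               # haplotype indices of the two medoids
    separation: float            # silhouette-style score in [-1, 1]


def partition_core_haplogroups(hm: HaplotypeMatrix) -> HaplogroupPartition:
    """Split haplotypes into two core haplogroups by 2-medoid clustering.

    Hamming distance; the seed medoids are the maximally distant haplotype
    pair, then assignment and medoid updates iterate to convergence.  Ties
    always resolve to the lowest sample index, so the result is
    deterministic.  Raises on an all-identical sample.
    """
    if hm.n_haplotypes < 4:
        raise ValueError("need at least 4 haplotypes")
    if hm.n_sites < 1:
        raise ValueError("need at least one segregating site")
    D = hamming_matrix(hm)
    if D.max() == 0:
        raise ValueError("all haplotypes identical: degenerate partition")
    m0, m1 = np.unravel_index(np.argmax(D), D.shape)  # first (lowest-index) max
    if m0 > m1:
        m0, m1 = m1, m0
    medoids = (int(m0), int(m1))
    for _ in range(100):
        d0, d1 = D[medoids[0]], D[medoids[1]]
        assignment = (d1 < d0).astype(int)  # ties -> group 0 (lower medoid index)
        new = []
        for g in (0, 1):
            members = np.flatnonzero(assignment == g)
            within = D[np.ix_(members, members)].sum(axis=1)
            new.append(int(members[np.argmin(within)]))  # argmin: lowest index on ties
        new = tuple(new)
        if new == medoids:
            break
        medoids = new

    sil = []
    for i in range(hm.n_haplotypes):
        own = np.flatnonzero(assignment == assignment[i])
        other = np.flatnonzero(assignment != assignment[i])
        a = D[i, own[own != i]].mean() if own.size > 1 else 0.0
        b = D[i, other].mean()
        sil.append(0.0 if max(a, b) == 0 else (b - a) / max(a, b))
    return HaplogroupPartition(
        assignment=assignment, medoids=medoids, separation=float(np.mean(sil))
    )


# --------------------------------------------------------------------------
# fixed differences
# --------------------------------------------------------------------------

@dataclass
class FixedDifferences:
    count: int
    positions: np.ndarray
    n_excluded: int      # sites entirely missing in one group


def fixed_differences(hm: HaplotypeMatrix, assignment) -> FixedDifferences:
    """Sites at which the two groups share no allele.

    A site counts iff every non-missing allele in one group differs from
    every non-missing allele in the other.  Sites with no call in a group
    are excluded (counted separately).
    """
    assignment = np.asarray(assignment)
    g0 = hm.alleles[assignment == 0]
    g1 = hm.alleles[assignment == 1]
    if g0.size == 0 or g1.size == 0:
        raise ValueError("both groups must be non-empty")
    positions, n_excluded = [], 0
    for s in range(hm.n_sites):
        a0 = g0[:, s][g0[:, s] != MISSING]
        a1 = g1[:, s][g1[:, s] != MISSING]
        if a0.size == 0 or a1.size == 0:
            n_excluded += 1
            continue
        if len(set(a0.tolist()) & set(a1.tolist())) == 0:
            positions.append(int(hm.positions[s]))
    return FixedDifferences(
        count=len(positions), positions=np.asarray(positions, dtype=np.int64),
        n_excluded=n_excluded,
    )


# --------------------------------------------------------------------------
# distance matrices
# --------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    matrix: np.ndarray
    labels: list
    metric: str      # p_distance_per_variable_site | raw_differences

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("distance matrix must have a zero diagonal")
        if m.min() < 0:
            raise ValueError("distances must be non-negative")
        if len(self.labels) != m.shape[0]:
            raise ValueError("labels must match the matrix dimension")


def p_distance_matrix(hm: HaplotypeMatrix,
                      metric: str = "p_distance_per_variable_site") -> DistanceMatrix:
    """Pairwise distances: mismatch counts, optionally per variable site.

    With the normalized metric each pair's mismatch count is divided by the
    number of variable sites at which both haplotypes are called
    (pairwise deletion).
    """
    if hm.n_haplotypes < 2:
        raise ValueError("need at least two haplotypes")
    A = hm.alleles
    called = A != MISSING
    variable = np.array(
        [len(set(A[:, s][called[:, s]].tolist())) > 1 for s in range(hm.n_sites)]
    )
    H = hm.n_haplotypes
    D = np.zeros((H, H))
    for i in range(H):
        for j in range(i + 1, H):
            ok = called[i] & called[j]
            mism = np.sum((A[i] != A[j]) & ok)
            if metric == "raw_differences":
                D[i, j] = D[j, i] = mism
            elif metric == "p_distance_per_variable_site":
                denom = np.sum(ok & variable)
                if denom == 0:
                    raise ValueError(
                        "no shared variable site: per-variable-site distance undefined"
                    )
                D[i, j] = D[j, i] = mism / denom
            else:
                raise ValueError(f"unknown metric {metric!r}")
    return DistanceMatrix(matrix=D, labels=list(hm.sample_ids), metric=metric)


# --------------------------------------------------------------------------
# neighbor joining
# --------------------------------------------------------------------------

@dataclass
class Tree:
    """An unrooted tree carried as newick plus a dendropy handle."""

    newick: str
    clamped: tuple = ()       # labels whose pendant branch was clamped to 0

    def dendropy_tree(self) -> dendropy.Tree:
        return dendropy.Tree.get(
            data=self.newick, schema="newick",
            suppress_internal_node_taxa=True, preserve_underscores=True,
        )

    @property
    def leaf_labels(self) -> list:
        return sorted(
            lf.taxon.label for lf in self.dendropy_tree().leaf_node_iter()
        )

    def path_lengths(self) -> dict:
        """Leaf-pair path lengths {frozenset({a, b}): distance}."""
        t = self.dendropy_tree()
        pdm = t.phylogenetic_distance_matrix()
        out = {}
        taxa = list(t.taxon_namespace)
        for i, ta in enumerate(taxa):
            for tb in taxa[i + 1 :]:
                out[frozenset({ta.label, tb.label})] = pdm.distance(ta, tb)
        return out


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    At each step the pair minimizing the Q-criterion is joined (ties broken
    by the lexicographically smallest pair of subtree labels); branch
    lengths come from the standard two-point formulas, and the final
    three-way join closes the unrooted tree.  Negative branch-length
    estimates are clamped to zero with the deficit moved to the sister
    branch, and the affected subtree labels are flagged.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    D = {}
    nodes = {}
    for i, lab in enumerate(dm.labels):
        nodes[i] = {"newick": _quote(lab), "label": lab}
    for i in range(n):
        for j in range(i + 1, n):
            D[(i, j)] = float(dm.matrix[i, j])

    def d(a, b):
        return D[(a, b) if a < b else (b, a)]

    clamped = []
    active = list(range(n))
    next_id = n
    while len(active) > 3:
        N = len(active)
        r = {a: sum(d(a, b) for b in active if b != a) for a in active}
        best, best_q, best_key = None, None, None
        for ii, a in enumerate(active):
            for b in active[ii + 1 :]:
                q = (N - 2) * d(a, b) - r[a] - r[b]
                key = tuple(sorted((nodes[a]["label"], nodes[b]["label"])))
                if best is None or q < best_q - 1e-12 or (
                    abs(q - best_q) <= 1e-12 and key < best_key
                ):
                    best, best_q, best_key = (a, b), q, key
        a, b = best
        ba = 0.5 * d(a, b) + (r[a] - r[b]) / (2 * (N - 2))
        bb = d(a, b) - ba
        ba, bb = _clamp_pair(ba, bb, nodes[a]["label"], nodes[b]["label"], clamped)
        u = next_id
        next_id += 1
        nodes[u] = {
            "newick": f"({nodes[a]['newick']}:{_fmt(ba)},{nodes[b]['newick']}:{_fmt(bb)})",
            "label": min(nodes[a]["label"], nodes[b]["label"]),
        }
        for m in active:
            if m in (a, b):
                continue
            D[(min(u, m), max(u, m))] = 0.5 * (d(a, m) + d(b, m) - d(a, b))
        active = [m for m in active if m not in (a, b)] + [u]

    # final three-way join
    a, b, c = sorted(active, key=lambda k: nodes[k]["label"])
    ba = 0.5 * (d(a, b) + d(a, c) - d(b, c))
    bb = 0.5 * (d(a, b) + d(b, c) - d(a, c))
    bc = 0.5 * (d(a, c) + d(b, c) - d(a, b))
    for lab, v in ((nodes[a]["label"], ba), (nodes[b]["label"], bb),
                   (nodes[c]["label"], bc)):
        if v < 0:
            clamped.append(lab)
    ba, bb, bc = max(ba, 0.0), max(bb, 0.0), max(bc, 0.0)
    newick = (
        f"({nodes[a]['newick']}:{_fmt(ba)},{nodes[b]['newick']}:{_fmt(bb)},"
        f"{nodes[c]['newick']}:{_fmt(bc)});"
    )
    return Tree(newick=newick, clamped=tuple(clamped))


def _clamp_pair(ba, bb, lab_a, lab_b, clamped):
    if ba < 0:
        bb += ba
        clamped.append(lab_a)
        ba = 0.0
    if bb < 0:
        ba += bb
        clamped.append(lab_b)
        bb = 0.0
    return max(ba, 0.0), max(bb, 0.0)


def _fmt(x: float) -> str:
    return f"{x:.12g}"


def _quote(label: str) -> str:
    return label.replace(" ", "_")


def write_newick(tree: Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.newick.rstrip("\n") + "\n")


def read_newick(path) -> Tree:
    with open(path) as fh:
        return Tree(newick=fh.read().strip())


# --------------------------------------------------------------------------
# monophyly
# --------------------------------------------------------------------------

def is_monophyletic(tree: Tree, leaf_set, outgroup_leaf: str) -> bool:
    """True iff ``leaf_set`` is exactly one clade of the outgroup-rooted tree."""
    target = set(leaf_set)
    if not target:
        raise ValueError("leaf_set must be non-empty")
    if outgroup_leaf in target:
        raise ValueError("leaf_set must exclude the outgroup")
    t = tree.dendropy_tree()
    labels = {lf.taxon.label for lf in t.leaf_node_iter()}
    unknown = (target | {outgroup_leaf}) - labels
    if unknown:
        raise ValueError(f"unknown leaves: {sorted(unknown)}")
    og = t.find_node_with_taxon_label(outgroup_leaf)
    t.reroot_at_edge(og.edge, update_bipartitions=False)
    for nd in t.preorder_node_iter():
        leaves = {lf.taxon.label for lf in nd.leaf_iter()}
        if leaves == target:
            return True
    return False


# --------------------------------------------------------------------------
# mutation rate and TMRCA
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MuEstimate:
    mu: float                      # per locus per year
    interval: Optional[tuple] = None   # from divergence-time uncertainty


def estimate_mu(substitutions_between_species: float, divergence_time_years: float,
                time_uncertainty_years: Optional[float] = None,
                convention: str = "per_lineage") -> MuEstimate:
    """Calibrate the per-locus per-year mutation rate from divergence.

    Substitutions accumulate along both lineages since the species split, so
    the default per-lineage rate is ``substitutions / (2 T)``.  The
    alternative reading ``convention="doubled"`` (2 x substitutions / T) is
    exposed for comparison.  With ``time_uncertainty_years`` the rate
    interval implied by T +/- dT is reported alongside.
    """
    if divergence_time_years <= 0:
        raise ValueError("divergence time must be positive")
    if substitutions_between_species < 0:
        raise ValueError("substitution count cannot be negative")

    def rate(T):
        if convention == "per_lineage":
            return substitutions_between_species / (2 * T)
        if convention == "doubled":
            return 2 * substitutions_between_species / T
        raise ValueError(f"unknown convention {convention!r}")

    mu = rate(divergence_time_years)
    interval = None
    if time_uncertainty_years is not None:
        lo_T = divergence_time_years - time_uncertainty_years
        hi_T = divergence_time_years + time_uncertainty_years
        if lo_T <= 0:
            raise ValueError("time uncertainty exceeds the divergence time")
        interval = (rate(hi_T), rate(lo_T))  # larger T -> smaller rate
    return MuEstimate(mu=float(mu), interval=interval)


@dataclass
class MrcaMutations:
    """Per-haplotype mutation counts back to the reconstructed MRCA."""

    x: np.ndarray                # over polarizable sites only
    mrca: np.ndarray             # reconstructed allele per site (0/1)
    polarizable: np.ndarray      # per-site bool
    n_unpolarizable: int         # sites filled by majority rule, excluded from x


def mutations_from_mrca(hm: HaplotypeMatrix, outgroup_alleles: Sequence,
                        assignment=None) -> MrcaMutations:
    """Reconstruct the sample MRCA sequence and count differences to it.

    Per site the MRCA allele is the outgroup-matching (ancestral) state
    where the outgroup base equals the reference or alternate; sites that
    cannot be polarized fall back to the sample-majority allele, are
    flagged, and are excluded from the x_i counts.  Missing alleles never
    contribute to x_i.
    """
    if hm.ref is None or hm.alt is None:
        raise ValueError("haplotype matrix needs ref/alt bases")
    if len(outgroup_alleles) != hm.n_sites:
        raise ValueError("need one outgroup allele slot per site")
    mrca = np.zeros(hm.n_sites, dtype=np.int8)
    polarizable = np.zeros(hm.n_sites, dtype=bool)
    for s, out in enumerate(outgroup_alleles):
        if out == hm.ref[s]:
            mrca[s] = 0
            polarizable[s] = True
        elif out == hm.alt[s]:
            mrca[s] = 1
            polarizable[s] = True
        else:
            col = hm.alleles[:, s]
            called = col[col != MISSING]
            mrca[s] = 1 if called.mean() > 0.5 else 0
    if not polarizable.any():
        raise ValueError("no polarizable site")
    sub = hm.alleles[:, polarizable]
    anc = mrca[polarizable]
    diffs = (sub != anc[None, :]) & (sub != MISSING)
    return MrcaMutations(
        x=diffs.sum(axis=1).astype(np.int64),
        mrca=mrca, polarizable=polarizable,
        n_unpolarizable=int((~polarizable).sum()),
    )


@dataclass(frozen=True)
class TMRCAEstimate:
    """Thomson moment estimate of the sample TMRCA."""

    t: float          # years
    se: float         # years, Poisson star-genealogy approximation
    n: int
    mu: float         # per locus per year
    x: tuple

    def __post_init__(self):
        if self.t < 0:
            raise ValueError("TMRCA cannot be negative")


def thomson_tmrca(x: Sequence[int], mu: float) -> TMRCAEstimate:
    """t = sum(x_i) / (n mu); se = sqrt(sum(x_i)) / (n mu).

    ``mu`` is the per-locus per-year mutation rate.  The standard error
    treats the total mutation count as Poisson, exact for a star genealogy
    and an approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("need at least one sequence")
    if mu <= 0:
        raise ValueError("mu must be positive")
    n = x.size
    total = x.sum()
    return TMRCAEstimate(
        t=float(total / (n * mu)), se=float(np.sqrt(total) / (n * mu)),
        n=int(n), mu=float(mu), x=tuple(int(v) for v in x),
    )
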