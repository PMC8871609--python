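"""Core data model for the collagen-locus analyses.

All genomic coordinates are 0-based half-open.  Conversion to and from the
1-based conventions of VCF and protein residue numbering happens only at the
I/O and residue boundaries, never inside the statistics.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

MISSING = -1

DOMAIN_NAMES = ("N_terminal", "triple_helix", "C_terminal")


class EmptyRegionError(ValueError):
    """Raised when a requested region retains no usable records."""


@dataclass(frozen=True)
class GeneModel:
    """Exon/intron structure of a single protein-coding locus.

    Parameters
    ----------
    chrom : str
        Chromosome name.
    strand : str
        '+' or '-'.
    exons : sequence of (start, end)
        Sorted, disjoint, 0-based half-open exon intervals.  Introns are the
        derived inter-exon gaps and are never stored independently.
    domains : dict
        Maps ``N_terminal``/``triple_helix``/``C_terminal`` to 1-based,
        inclusive (first_residue, last_residue) ranges that tile the protein.
    coding_offset : int
        Genomic position of the first coding base (on the coding strand the
        highest-coordinate exonic base for '-' loci).
    """

    chrom: str
    strand: str
    exons: tuple
    domains: dict
    coding_offset: int

    def __post_init__(self):
        exons = tuple((int(s), int(e)) for s, e in self.exons)
        object.__setattr__(self, "exons", exons)
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if len(exons) < 2:
            raise ValueError("a gene model needs >= 2 exons (total intron span > 0)")
        for (s, e) in exons:
            if e <= s:
                raise ValueError(f"empty exon interval {(s, e)}")
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValueError(f"exons overlap or are unsorted: {(s1, e1)} vs {(s2, e2)}")
            if s2 == e1:
                raise ValueError(f"adjacent exons {(s1, e1)} and {(s2, e2)} leave no intron")
        # domain ranges: contiguous, non-overlapping, jointly covering the protein
        n_res = self.coding_length // 3
        ranges = [self.domains[name] for name in DOMAIN_NAMES]
        if ranges[0][0] != 1:
            raise ValueError("domain ranges must start at residue 1")
        for (a1, b1), (a2, b2) in zip(ranges, ranges[1:]):
            if a2 != b1 + 1:
                raise ValueError("domain residue ranges must be contiguous")
        if ranges[-1][1] != n_res:
            raise ValueError(
                f"domain ranges must cover the protein (last residue {ranges[-1][1]} != {n_res})"
            )

    # ------------------------------------------------------------------ spans
    @property
    def introns(self) -> tuple:
        """Derived inter-exon intervals; ``len == len(exons) - 1``."""
        return tuple((e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]))

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def intron_lengths(self) -> np.ndarray:
        return np.array([e - s for s, e in self.introns], dtype=int)

    @property
    def total_intron_length(self) -> int:
        return int(self.intron_lengths.sum())

    @property
    def coding_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def n_residues(self) -> int:
        return self.coding_length // 3

    # -------------------------------------------------------------- locate
    def locate(self, position: int):
        """Map a genomic position to its feature; see :func:`locate_site`."""
        return locate_site(position, self)

    def domain_of_residue(self, residue: int) -> str:
        for name in DOMAIN_NAMES:
            a, b = self.domains[name]
            if a <= residue <= b:
                return name
        raise ValueError(f"residue {residue} outside the protein (1..{self.n_residues})")


@dataclass(frozen=True)
class SiteLocation:
    """Result of mapping a genomic position onto a :class:`GeneModel`."""

    feature: str                 # "exon_<i>" or "intron_<j>", 1-based indices
    residue: Optional[int] = None      # 1-based, exonic coding sites only
    codon_position: Optional[int] = None  # 1, 2 or 3


def locate_site(position: int, model: GeneModel) -> SiteLocation:
    """Assign a position to exactly one exon or intron of the locus.

    The exon/intron features partition the locus span, so every base maps to
    one feature.  For exonic positions at or downstream of the coding start
    the 1-based residue index and codon position are computed from
    ``coding_offset`` along the coding strand.
    """
    if not (model.start <= position < model.end):
        raise ValueError(
            f"position {position} outside locus span [{model.start}, {model.end})"
        )
    starts = [s for s, _ in model.exons]
    i = bisect.bisect_right(starts, position) - 1
    s, e = model.exons[i]
    if position < e:
        cidx = _coding_index(position, model)
        if cidx is None:
            return SiteLocation(feature=f"exon_{i + 1}")
        return SiteLocation(
            feature=f"exon_{i + 1}", residue=cidx // 3 + 1, codon_position=cidx % 3 + 1
        )
    return SiteLocation(feature=f"intron_{i + 1}")


def _coding_index(position: int, model: GeneModel) -> Optional[int]:
    """0-based index of an exonic base within the coding sequence, or None."""
    exonic_before = 0  # exonic bases strictly 5' of `position` on the coding strand
    found = False
    for s, e in model.exons:
        if s <= position < e:
            found = True
        if model.strand == "+":
            exonic_before += max(0, min(position, e) - s)
        else:
            exonic_before += max(0, e - max(position + 1, s))
    if not found:
        return None
    off = _coding_index_offset(model)
    cidx = exonic_before - off
    if cidx < 0 or cidx >= model.coding_length:
        return None
    return cidx


def _coding_index_offset(model: GeneModel) -> int:
    """Exonic bases 5' of the first coding base (0 when CDS starts at exon 1)."""
    pos = model.coding_offset
    before = 0
    for s, e in model.exons:
        if model.strand == "+":
            before += max(0, min(pos, e) - s)
        else:
            before += max(0, e - max(pos + 1, s))
    return before


# --------------------------------------------------------------------------
# variation containers
# --------------------------------------------------------------------------

@dataclass
class HaplotypeMatrix:
    """H phased haplotypes x S biallelic sites.

    ``alleles`` holds 0 (reference/ancestral when polarized), 1 (alternate/
    derived when polarized) or -1 (missing).  ``positions`` are 0-based and
    strictly increasing.  When ``polarized[s]`` is true, allele 1 at site s is
    the derived state.
    """

    alleles: np.ndarray
    positions: np.ndarray
    sample_ids: list
    ref: Optional[np.ndarray] = None          # per-site reference base
    alt: Optional[np.ndarray] = None          # per-site alternate base
    polarized: Optional[np.ndarray] = None    # per-site bool
    group_labels: Optional[list] = None

    def __post_init__(self):
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be 2-D (haplotypes x sites)")
        if self.alleles.shape[1] != self.positions.shape[0]:
            raise ValueError("positions length must match the site dimension")
        if self.n_sites > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        if self.n_sites and np.any((self.alleles != MISSING).sum(axis=0) == 0):
            raise ValueError("every site needs at least one non-missing allele")
        if self.polarized is None:
            self.polarized = np.zeros(self.n_sites, dtype=bool)
        else:
            self.polarized = np.asarray(self.polarized, dtype=bool)
        if len(self.sample_ids) != self.alleles.shape[0]:
            raise ValueError("sample_ids length must match the haplotype dimension")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def site_frequency(self, s: int) -> float:
        """Alternate/derived allele frequency among non-missing haplotypes."""
        col = self.alleles[:, s]
        called = col != MISSING
        return float(col[called].mean())

    def take_haplotypes(self, idx) -> "HaplotypeMatrix":
        idx = list(idx)
        return HaplotypeMatrix(
            alleles=self.alleles[idx],
            positions=self.positions.copy(),
            sample_ids=[self.sample_ids[i] for i in idx],
            ref=None if self.ref is None else np.asarray(self.ref).copy(),
            alt=None if self.alt is None else np.asarray(self.alt).copy(),
            polarized=self.polarized.copy(),
            group_labels=None if self.group_labels is None
            else [self.group_labels[i] for i in idx],
        )

    def take_sites(self, idx) -> "HaplotypeMatrix":
        idx = np.asarray(idx)
        return HaplotypeMatrix(
            alleles=self.alleles[:, idx],
            positions=self.positions[idx],
            sample_ids=list(self.sample_ids),
            ref=None if self.ref is None else np.asarray(self.ref)[idx],
            alt=None if self.alt is None else np.asarray(self.alt)[idx],
            polarized=self.polarized[idx],
            group_labels=None if self.group_labels is None else list(self.group_labels),
        )


@dataclass
class GenotypeTable:
    """N diploid individuals x S biallelic sites of alternate-allele dosage.

    Dosages are 0, 1, 2 or -1 (missing).  ``population`` labels each sample.
    """

    genotypes: np.ndarray
    positions: np.ndarray
    sample_ids: list
    population: list

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-D (samples x sites)")
        bad = ~np.isin(self.genotypes, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("dosages must be 0, 1, 2 or -1 (missing)")
        if self.genotypes.shape[1] != self.positions.shape[0]:
            raise ValueError("positions length must match the site dimension")
        if len(self.sample_ids) != self.genotypes.shape[0]:
            raise ValueError("sample_ids length must match the sample dimension")
        if len(self.population) != self.genotypes.shape[0]:
            raise ValueError("population length must match the sample dimension")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]

    def samples_in(self, pop: str) -> np.ndarray:
        mask = np.array([p == pop for p in self.population])
        if not mask.any():
            raise ValueError(f"population {pop!r} absent from the table")
        return mask


@dataclass
class ConservationTrack:
    """Per-base conservation scores over one genomic interval.

    Scores carry phyloP semantics: signed -log p-values against a neutral
    null, positive for conservation and negative for acceleration.  Bases the
    source track does not cover are NaN and flagged by :attr:`covered`.
    """

    chrom: str
    start: int
    scores: np.ndarray

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if np.any(np.isinf(self.scores)):
            raise ValueError("conservation scores must be finite")

    @property
    def end(self) -> int:
        return self.start + self.scores.shape[0]

    @property
    def covered(self) -> np.ndarray:
        return ~np.isnan(self.scores)

    def slice(self, start: int, end: int) -> np.ndarray:
        """Scores over [start, end); the interval must lie inside the track."""
        if start < self.start or end > self.end:
            raise ValueError(
                f"[{start}, {end}) outside track span [{self.start}, {self.end})"
            )
        return self.scores[start - self.start : end - self.start]

    def score_at(self, position: int) -> float:
        return float(self.slice(position, position + 1)[0])


@dataclass(frozen=True)
class DAMRecord:
    """One catalogued disease-associated missense mutation."""

    residue: int
    aa_from: str
    aa_to: str
    domain: str
    severity: int
    site_score: float

    def __post_init__(self):
        if self.severity not in (1, 2, 3, 4):
            raise ValueError(f"severity must be 1..4, got {self.severity}")
        if self.aa_from == self.aa_to:
            raise ValueError("aa_from and aa_to must differ")
        if self.domain not in DOMAIN_NAMES:
            raise ValueError(f"unknown domain {self.domain!r}")

    @property
    def glycine_flag(self) -> bool:
        """True when the mutated (reference) residue is glycine."""
        return self.aa_from == "G"


@dataclass(frozen=True)
class VariantAnnotation:
    """Feature/codon annotation of one biallelic SNP."""

    position: int
    feature: str
    variant_class: str                      # replacement | silent | intronic
    residue: Optional[int] = None
    aa_from: Optional[str] = None
    aa_to: Optional[str] = None
    glycine_flag: Optional[bool] = None     # defined for replacement variants only
    domain: Optional[str] = None
    frequencies: dict = field(default_factory=dict)
    site_score: Optional[float] = None

    def __post_init__(self):
        if self.variant_class not in ("replacement", "silent", "intronic"):
            raise ValueError(f"unknown variant class {self.variant_class!r}")
        if self.variant_class != "replacement" and self.glycine_flag is not None:
            raise ValueError("glycine_flag is defined only for replacement variants")


# --------------------------------------------------------------------------
# polarization
# --------------------------------------------------------------------------

def polarize_with_outgroup(
    hm: HaplotypeMatrix, outgroup_alleles: Sequence[Optional[str]]
) -> HaplotypeMatrix:
    """Orient allele codes so that 1 is the derived state, using an outgroup.

    Sites where the outgroup base matches the reference keep their codes
    (ancestral = reference); sites where it matches the alternate have their
    0/1 codes flipped so that 1 is derived.  The ref/alt labels are site
    identity and are never altered, which makes a second polarization with
    the alternate base an involution (flip twice restores the coding).
    Sites with a third-state or unknown outgroup base remain unpolarized.
    """
    if hm.ref is None or hm.alt is None:
        raise ValueError("haplotype matrix needs ref/alt bases for polarization")
    if len(outgroup_alleles) != hm.n_sites:
        raise ValueError("need one outgroup allele slot per site")
    alleles = hm.alleles.copy()
    ref = np.asarray(hm.ref, dtype=object)
    alt = np.asarray(hm.alt, dtype=object)
    polarized = np.zeros(hm.n_sites, dtype=bool)
    for s, out in enumerate(outgroup_alleles):
        if out is None:
            continue
        if out == ref[s]:
            polarized[s] = True
        elif out == alt[s]:
            col = alleles[:, s]
            flip = col != MISSING
            col[flip] = 1 - col[flip]
            polarized[s] = True
    return HaplotypeMatrix(
        alleles=alleles,
        positions=hm.positions.copy(),
        sample_ids=list(hm.sample_ids),
        ref=ref.copy(),
        alt=alt.copy(),
        polarized=polarized,
        group_labels=None if hm.group_labels is None else list(hm.group_labels),
    )
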