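"""Amino-acid variant classification and contingency analyses.

Covers the replacement/silent classification of coding SNPs, the
domain x severity and glycine x severity cross-tabulations of the
disease-mutation catalog, Fisher and Pearson chi-square tests on those
tables, and the reading-frame arithmetic for an exon duplication.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats

from .model import DAMRecord, GeneModel, VariantAnnotation, _coding_index, locate_site

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def classify_aa_variant(position: int, ref_base: str, alt_base: str,
                        model: GeneModel, coding_sequence: str,
                        frequencies: Optional[dict] = None,
                        site_score: Optional[float] = None) -> VariantAnnotation:
    """Classify an exonic SNP as replacement or silent.

    ``coding_sequence`` is the spliced coding sequence on the coding strand,
    starting at ``model.coding_offset``.  The codon is rebuilt from the
    coding offset, both codons are translated, and a variant is a
    replacement iff the encoded residue changes.  ``glycine_flag`` records
    whether the reference residue is glycine, and is defined only for
    replacement variants.
    """
    loc = locate_site(position, model)
    if not loc.feature.startswith("exon") or loc.residue is None:
        raise ValueError(
            f"position {position} is not coding ({loc.feature}); "
            "intronic variants take the intron pathway"
        )
    cidx = _coding_index(position, model)
    if model.strand == "-":
        ref_base = ref_base.translate(_COMPLEMENT)
        alt_base = alt_base.translate(_COMPLEMENT)
    if coding_sequence[cidx] != ref_base:
        raise ValueError(
            f"reference base {ref_base!r} does not match the coding sequence "
            f"({coding_sequence[cidx]!r} at coding index {cidx})"
        )
    codon_start = (cidx // 3) * 3
    ref_codon = coding_sequence[codon_start : codon_start + 3]
    alt_codon = (
        ref_codon[: cidx % 3] + alt_base + ref_codon[cidx % 3 + 1 :]
    )
    aa_from = str(Seq(ref_codon).translate())
    aa_to = str(Seq(alt_codon).translate())
    if aa_from == aa_to:
        return VariantAnnotation(
            position=position, feature=loc.feature, variant_class="silent",
            residue=loc.residue, aa_from=aa_from, aa_to=aa_to,
            domain=model.domain_of_residue(loc.residue),
            frequencies=frequencies or {}, site_score=site_score,
        )
    return VariantAnnotation(
        position=position, feature=loc.feature, variant_class="replacement",
        residue=loc.residue, aa_from=aa_from, aa_to=aa_to,
        glycine_flag=(aa_from == "G"),
        domain=model.domain_of_residue(loc.residue),
        frequencies=frequencies or {}, site_score=site_score,
    )


# --------------------------------------------------------------------------
# contingency tables
# --------------------------------------------------------------------------

@dataclass
class ContingencyTable:
    """Integer cross-tabulation plus the test applied to it."""

    table: pd.DataFrame
    statistic: Optional[float] = None
    p_value: Optional[float] = None
    method: Optional[str] = None
    df: Optional[int] = None
    low_expected: bool = False

    @property
    def counts(self) -> np.ndarray:
        return self.table.to_numpy()


def build_domain_contingency(records, grouping: str = "severity",
                             dimension: str = "domain") -> ContingencyTable:
    """Cross-tabulate variant records.

    ``records`` are :class:`DAMRecord` or replacement
    :class:`VariantAnnotation` objects (mixing is fine; annotations are
    grouped as dataset ``"population"``).  ``grouping`` is ``"severity"``
    (clinical category 1-4, population SNPs labelled ``"population"``) or
    ``"dataset"`` (clinical vs population).  ``dimension`` is ``"domain"``
    or ``"glycine_flag"``.  Cell sums always equal the record count.
    """
    if grouping not in ("severity", "dataset"):
        raise ValueError(f"unknown grouping {grouping!r}")
    if dimension not in ("domain", "glycine_flag"):
        raise ValueError(f"unknown dimension {dimension!r}")
    rows = []
    for r in records:
        if isinstance(r, DAMRecord):
            group = r.severity if grouping == "severity" else "clinical"
        elif isinstance(r, VariantAnnotation):
            if r.variant_class != "replacement":
                raise ValueError("only replacement annotations enter the table")
            group = "population"
        else:
            raise TypeError(f"unsupported record type {type(r).__name__}")
        rows.append({"group": group, "dim": getattr(r, dimension)})
    if not rows:
        raise ValueError("empty record set")
    df = pd.DataFrame(rows)
    table = pd.crosstab(df.group, df.dim, dropna=False)
    return ContingencyTable(table=table)


def fisher_exact_2x2(table) -> tuple:
    """Two-sided Fisher exact test: p sums hypergeometric probabilities of
    all margin-compatible tables no more probable than the observed one.

    Returns ``(odds_ratio, p)``; the odds ratio is the sample ad/bc.
    """
    t = _as_counts(table)
    if t.shape != (2, 2):
        raise ValueError("need a 2x2 table")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero margin")
    odds, p = stats.fisher_exact(t, alternative="two-sided")
    return float(odds), float(p)


def chi_square_rxc(table) -> ContingencyTable:
    """Pearson chi-square test of independence on an r x c table.

    No continuity correction (matching plain X^2 reporting); a warning flag
    is set when any expected count falls below 5.
    """
    t = _as_counts(table)
    if t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("need at least a 2x2 table")
    if t.sum() == 0:
        raise ValueError("zero grand total")
    res = stats.chi2_contingency(t, correction=False)
    frame = table.table if isinstance(table, ContingencyTable) else pd.DataFrame(t)
    return ContingencyTable(
        table=frame, statistic=float(res.statistic), p_value=float(res.pvalue),
        method="pearson_chi2", df=int(res.dof),
        low_expected=bool((res.expected_freq < 5).any()),
    )


def _as_counts(table) -> np.ndarray:
    if isinstance(table, ContingencyTable):
        t = table.counts
    elif isinstance(table, pd.DataFrame):
        t = table.to_numpy()
    else:
        t = np.asarray(table)
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(float)
        if np.any(t < 0) or np.any(t != np.round(t)):
            raise ValueError("counts must be non-negative integers")
        t = t.astype(int)
    return t


# --------------------------------------------------------------------------
# exon duplication frame analysis
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class InsertionEffect:
    in_frame: bool
    added_residues: Optional[int]    # None on frameshift
    frameshift: bool


def exon_insertion_effect(insertion_length_nt: int,
                          splice_sites_intact: bool) -> InsertionEffect:
    """Reading-frame consequence of an exonic insertion/duplication.

    An insertion is in frame iff its length is divisible by 3 and the
    flanking splice sites are intact, in which case it adds length/3
    residues; otherwise it is a frameshift.
    """
    if insertion_length_nt < 0:
        raise ValueError("insertion length cannot be negative")
    if insertion_length_nt % 3 == 0 and splice_sites_intact:
        return InsertionEffect(
            in_frame=True, added_residues=insertion_length_nt // 3, frameshift=False
        )
    return InsertionEffect(in_frame=False, added_residues=None, frameshift=True)
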