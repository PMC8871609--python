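"""Readers and writers for the locus inputs.

VCF parsing goes through cyvcf2; the tabular formats (bedGraph conservation
tracks, the disease-mutation catalog, the gene-model table) are plain TSV so
that every fixture in this repository stays text.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .model import (
    MISSING,
    ConservationTrack,
    DAMRecord,
    EmptyRegionError,
    GeneModel,
    GenotypeTable,
    HaplotypeMatrix,
)

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# VCF
# --------------------------------------------------------------------------

@dataclass
class VcfData:
    """Parsed biallelic-SNP content of one VCF region."""

    genotypes: GenotypeTable
    haplotypes: Optional[HaplotypeMatrix]
    n_skipped: int          # multiallelic / indel records dropped
    n_unphased: int         # retained records that were not fully phased


def read_vcf(path, region=None, pop_map: Optional[dict] = None) -> VcfData:
    """Read biallelic SNPs from a VCF 4.x file.

    Parameters
    ----------
    path : str
        VCF file (plain text or bgzipped).
    region : (chrom, start, end), optional
        0-based half-open interval filter; records outside it are ignored.
    pop_map : dict, optional
        sample id -> population label; unmapped samples get ``"unknown"``.

    Multiallelic and indel records are skipped (counted, logged).  Positions
    are converted to 0-based.  A :class:`HaplotypeMatrix` is returned only
    when every retained record is fully phased; a record mixing phased and
    unphased samples is treated as unphased and logged.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    positions, refs, alts, dosage_rows, hap_rows, phased_flags = [], [], [], [], [], []
    n_skipped = 0
    for v in vcf:
        if region is not None:
            chrom, start, end = region
            if end <= start:
                raise ValueError("region must be non-empty")
            if v.CHROM != chrom or not (start <= v.start < end):
                continue
        if not v.is_snp or len(v.ALT) != 1 or len(v.REF) != 1:
            n_skipped += 1
            continue
        gts = v.genotypes  # per sample: [allele0, allele1, phased]
        dos = np.empty(len(samples), dtype=np.int8)
        haps = np.empty(2 * len(samples), dtype=np.int8)
        record_phased = True
        for i, g in enumerate(gts):
            a = [x for x in g[:-1]]
            if len(a) != 2:
                raise ValueError(f"non-diploid genotype at {v.CHROM}:{v.POS}")
            if a[0] < 0 or a[1] < 0:
                dos[i] = MISSING
                haps[2 * i] = haps[2 * i + 1] = MISSING
            else:
                dos[i] = a[0] + a[1]
                haps[2 * i], haps[2 * i + 1] = a
            if not g[-1] and a != [a[0], a[0]]:
                # an unphased het makes the record unphased; unphased homs are
                # orientation-free and tolerated
                record_phased = False
        if not record_phased:
            log.info("record %s:%d not fully phased", v.CHROM, v.POS)
        positions.append(v.start)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        dosage_rows.append(dos)
        hap_rows.append(haps)
        phased_flags.append(record_phased)
    if n_skipped:
        log.info("skipped %d multiallelic/indel records", n_skipped)
    if not positions:
        raise EmptyRegionError(f"no biallelic SNP records retained from {path}")

    order = np.argsort(positions, kind="stable")
    positions = np.asarray(positions)[order]
    refs = np.asarray(refs, dtype=object)[order]
    alts = np.asarray(alts, dtype=object)[order]
    dosages = np.stack(dosage_rows, axis=1)[:, order]
    pops = [(pop_map or {}).get(s, "unknown") for s in samples]
    gt = GenotypeTable(
        genotypes=dosages, positions=positions, sample_ids=samples, population=pops
    )

    hm = None
    n_unphased = int(np.sum(~np.asarray(phased_flags)))
    if n_unphased == 0:
        hap_ids = [f"{s}_{k}" for s in samples for k in (1, 2)]
        hap_groups = [p for p in pops for _ in (1, 2)]
        hm = HaplotypeMatrix(
            alleles=np.stack(hap_rows, axis=1)[:, order],
            positions=positions,
            sample_ids=hap_ids,
            ref=refs,
            alt=alts,
            group_labels=hap_groups,
        )
    return VcfData(genotypes=gt, haplotypes=hm, n_skipped=n_skipped, n_unphased=n_unphased)


def write_vcf(path, positions, ref, alt, chrom, *, haplotypes=None, genotypes=None,
              sample_ids=None) -> None:
    """Write a minimal VCF 4.2 file from haplotypes (phased) or dosages.

    Exactly one of ``haplotypes`` (H x S, paired rows per sample) or
    ``genotypes`` (N x S dosages) must be given.
    """
    if (haplotypes is None) == (genotypes is None):
        raise ValueError("give exactly one of haplotypes or genotypes")
    if haplotypes is not None:
        haplotypes = np.asarray(haplotypes)
        if haplotypes.shape[0] % 2:
            raise ValueError("phased haplotypes must come in sample pairs")
        n_samples = haplotypes.shape[0] // 2
    else:
        genotypes = np.asarray(genotypes)
        n_samples = genotypes.shape[0]
    if sample_ids is None:
        sample_ids = [f"S{i}" for i in range(n_samples)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_ids) + "\n")
        for s, pos in enumerate(positions):
            fields = [chrom, str(int(pos) + 1), ".", str(ref[s]), str(alt[s]),
                      ".", "PASS", ".", "GT"]
            if haplotypes is not None:
                for i in range(n_samples):
                    a, b = haplotypes[2 * i, s], haplotypes[2 * i + 1, s]
                    fields.append("{}|{}".format(*(("." if x == MISSING else int(x))
                                                   for x in (a, b))))
            else:
                code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
                for i in range(n_samples):
                    fields.append(code[int(genotypes[i, s])])
            fh.write("\t".join(fields) + "\n")


# --------------------------------------------------------------------------
# bedGraph conservation track
# --------------------------------------------------------------------------

def read_conservation_track(path, interval=None) -> ConservationTrack:
    """Expand a 4-column bedGraph into per-base scores.

    ``interval`` is (chrom, start, end), 0-based half-open; when omitted the
    union span of the file is used.  Bases not covered by any row are NaN.
    Overlapping rows are an error naming the first overlap.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#",
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str, "start": int, "end": int, "value": float},
    )
    if interval is not None:
        chrom, start, end = interval
        df = df[df.chrom == chrom]
    else:
        chroms = df.chrom.unique()
        if len(chroms) != 1:
            raise ValueError("give an interval when the file spans several chromosomes")
        chrom = chroms[0]
        start, end = int(df.start.min()), int(df.end.max())
    df = df.sort_values(["start", "end"], kind="stable").reset_index(drop=True)
    prev_end, prev_row = None, None
    for row in df.itertuples():
        if prev_end is not None and row.start < prev_end:
            raise ValueError(
                f"overlapping bedGraph rows: ({prev_row.start}, {prev_row.end}) "
                f"and ({row.start}, {row.end})"
            )
        prev_end, prev_row = row.end, row
    scores = np.full(end - start, np.nan)
    for row in df.itertuples():
        lo, hi = max(row.start, start), min(row.end, end)
        if lo < hi:
            scores[lo - start : hi - start] = row.value
    return ConservationTrack(chrom=chrom, start=start, scores=scores)


def write_bedgraph(track: ConservationTrack, path) -> None:
    """Write a track back to bedGraph, merging equal-valued runs."""
    with open(path, "w") as fh:
        s = 0
        scores = track.scores
        while s < len(scores):
            if np.isnan(scores[s]):
                s += 1
                continue
            e = s + 1
            while e < len(scores) and scores[e] == scores[s]:
                e += 1
            fh.write(f"{track.chrom}\t{track.start + s}\t{track.start + e}\t"
                     f"{scores[s]:.6g}\n")
            s = e


# --------------------------------------------------------------------------
# disease-mutation catalog
# --------------------------------------------------------------------------

DAM_COLUMNS = ["residue", "aa_from", "aa_to", "domain", "severity", "site_score"]


def read_dam_table(path) -> list:
    """Read the missense disease-mutation catalog.

    Records with a severity outside 1-4 are dropped with a logged count
    (only catalogued severity categories enter the contrasts; length and
    splice variants never appear in this table).  A malformed row raises an
    error with its line number.
    """
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing_cols = set(DAM_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"DAM table lacks columns: {sorted(missing_cols)}")
    records, n_dropped = [], 0
    for idx, row in df.iterrows():
        line_no = idx + 2  # header is line 1
        try:
            severity = int(row.severity)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed severity on line {line_no}") from exc
        if severity not in (1, 2, 3, 4):
            n_dropped += 1
            continue
        try:
            records.append(
                DAMRecord(
                    residue=int(row.residue),
                    aa_from=str(row.aa_from),
                    aa_to=str(row.aa_to),
                    domain=str(row.domain),
                    severity=severity,
                    site_score=float(row.site_score),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed DAM row on line {line_no}: {exc}") from exc
    if n_dropped:
        log.info("dropped %d DAM rows with severity outside 1-4", n_dropped)
    return records


def write_dam_table(records, path) -> None:
    pd.DataFrame(
        [
            {
                "residue": r.residue, "aa_from": r.aa_from, "aa_to": r.aa_to,
                "domain": r.domain, "severity": r.severity, "site_score": r.site_score,
            }
            for r in records
        ],
        columns=DAM_COLUMNS,
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


# --------------------------------------------------------------------------
# gene model table
# --------------------------------------------------------------------------

def write_gene_model(model: GeneModel, path) -> None:
    """Serialize a gene model to TSV (meta, exon, and domain rows)."""
    rows = [
        {"record": "meta", "name": "chrom", "start": "", "end": "", "value": model.chrom},
        {"record": "meta", "name": "strand", "start": "", "end": "", "value": model.strand},
        {"record": "meta", "name": "coding_offset", "start": "", "end": "",
         "value": model.coding_offset},
    ]
    for i, (s, e) in enumerate(model.exons, 1):
        rows.append({"record": "exon", "name": f"exon_{i}", "start": s, "end": e, "value": ""})
    for name, (a, b) in model.domains.items():
        rows.append({"record": "domain", "name": name, "start": a, "end": b, "value": ""})
    pd.DataFrame(rows, columns=["record", "name", "start", "end", "value"]).to_csv(
        path, sep="\t", index=False
    )


def read_gene_model(path) -> GeneModel:
    df = pd.read_csv(path, sep="\t", dtype=str)
    meta = {r["name"]: r["value"] for _, r in df[df.record == "meta"].iterrows()}
    exons = [
        (int(r.start), int(r.end))
        for r in df[df.record == "exon"].itertuples()
    ]
    domains = {
        r.name: (int(r.start), int(r.end))
        for r in df[df.record == "domain"].itertuples()
    }
    return GeneModel(
        chrom=meta["chrom"], strand=meta["strand"], exons=tuple(exons),
        domains=domains, coding_offset=int(meta["coding_offset"]),
    )
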