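"""Readers and writers for PLINK text (.ped/.map) and binary (.bed/.bim/.fam) panels.

Both readers return a :class:`~rohscan.model.GenotypeMatrix` with SNPs
sorted by (chromosome, position) and any non-autosomal records dropped
with a logged count.  The binary layout is the SNP-major PLINK format:
three header bytes ``6C 1B 01`` followed by ceil(n_samples / 4) bytes per
SNP, two bits per sample with the first sample in the lowest-order bits:

====  ==================
bits  genotype
====  ==================
00    homozygous A1
01    missing
10    heterozygous
11    homozygous A2
====  ==================
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .model import (
    GENOTYPE_CODES,
    HET,
    HOM_A1,
    HOM_A2,
    MISSING,
    GenotypeMatrix,
    SampleRecord,
    SNPRecord,
)

logger = logging.getLogger(__name__)

_MAGIC = b"\x6c\x1b"
_SNP_MAJOR = 0x01

# 2-bit field -> genotype code
_BITS_TO_CODE = np.array([HOM_A1, MISSING, HET, HOM_A2], dtype=np.int8)
# genotype code (indexed by code % 4 so MISSING=-1 -> 3) -> 2-bit field
_CODE_TO_BITS = np.zeros(4, dtype=np.uint8)
_CODE_TO_BITS[HOM_A1] = 0b00
_CODE_TO_BITS[HET] = 0b10
_CODE_TO_BITS[HOM_A2] = 0b11
_CODE_TO_BITS[MISSING % 4] = 0b01

# decode table: byte value -> 4 genotype codes (low bits first)
_DECODE = np.empty((256, 4), dtype=np.int8)
for _b in range(256):
    for _k in range(4):
        _DECODE[_b, _k] = _BITS_TO_CODE[(_b >> (2 * _k)) & 0b11]

_PHENO_TO_LABEL = {"2": "case", "1": "control"}
_LABEL_TO_PHENO = {"case": "2", "control": "1", "missing": "-9"}
_SEX_TO_LABEL = {"1": "male", "2": "female"}
_LABEL_TO_SEX = {"male": "1", "female": "2", "unknown": "0"}


class PlinkFormatError(ValueError):
    """Raised when a PLINK file violates the expected format."""


def _read_table(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep=r"\s+", header=None, dtype=str)
    except pd.errors.EmptyDataError:
        return pd.DataFrame()


def _parse_sample_row(fields: Sequence[str]) -> SampleRecord:
    fid, iid, _pat, _mat, sex, pheno = fields[:6]
    return SampleRecord(
        family_id=fid,
        sample_id=iid,
        sex=_SEX_TO_LABEL.get(sex, "unknown"),
        phenotype=_PHENO_TO_LABEL.get(pheno, "missing"),
    )


def _autosome_filter(records: list[SNPRecord | None], what: str) -> list[int]:
    """Indices of autosomal records; logs how many were dropped."""
    keep = [i for i, r in enumerate(records) if r is not None]
    dropped = len(records) - len(keep)
    if dropped:
        logger.warning("dropped %d non-autosomal SNP(s) from %s", dropped, what)
    if not keep:
        raise PlinkFormatError(f"no autosomal SNPs remain in {what}")
    return keep


def _try_snp_record(
    chrom: str, snp_id: str, pos: str, a1: str = "A", a2: str = "C"
) -> SNPRecord | None:
    try:
        c = int(chrom)
    except ValueError:
        return None
    if not 1 <= c <= 22:
        return None
    return SNPRecord(
        chromosome=c,
        snp_id=snp_id,
        position_bp=int(pos),
        allele_a1=a1,
        allele_a2=a2,
    )


def _sorted_snp_order(snps: Sequence[SNPRecord]) -> np.ndarray:
    keys = np.array([(r.chromosome, r.position_bp) for r in snps], dtype=np.int64)
    return np.lexsort((keys[:, 1], keys[:, 0]))


# ----------------------------------------------------------------------
# text format
# ----------------------------------------------------------------------


def read_plink_text(ped_path: str | Path, map_path: str | Path) -> GenotypeMatrix:
    """Read a whitespace-delimited .ped/.map pair.

    A1 is assigned per SNP as the lexicographically smaller observed
    allele; ``0 0`` (and half-missing calls) become the missing code.
    """
    map_rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 4:
                raise PlinkFormatError(
                    f"{map_path}: line {lineno}: expected 4 columns "
                    f"(chrom, id, cM, bp), got {len(fields)}"
                )
            map_rows.append((fields[0], fields[1], fields[3]))
    n_snps = len(map_rows)

    samples: list[SampleRecord] = []
    allele_rows: list[np.ndarray] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_snps:
                raise PlinkFormatError(
                    f"{ped_path}: line {lineno}: expected {6 + 2 * n_snps} fields "
                    f"(6 metadata + 2 alleles per .map SNP), got {len(fields)}"
                )
            samples.append(_parse_sample_row(fields))
            allele_rows.append(np.array(fields[6:], dtype=object))

    n = len(samples)
    genotypes = np.full((n, n_snps), MISSING, dtype=np.int8)
    snp_records: list[SNPRecord | None] = []
    alleles = (
        np.stack(allele_rows) if n else np.empty((0, 2 * n_snps), dtype=object)
    )
    for j, (chrom, snp_id, pos) in enumerate(map_rows):
        a = alleles[:, 2 * j] if n else np.empty(0, dtype=object)
        b = alleles[:, 2 * j + 1] if n else np.empty(0, dtype=object)
        observed = sorted({x for x in np.concatenate([a, b]) if x != "0"})
        if len(observed) > 2:
            raise PlinkFormatError(
                f"{ped_path}: SNP {snp_id}: more than two alleles observed: {observed}"
            )
        a1 = observed[0] if observed else "A"
        a2 = observed[1] if len(observed) > 1 else "0"
        rec = _try_snp_record(chrom, snp_id, pos, a1, a2)
        snp_records.append(rec)
        if rec is None or n == 0:
            continue
        missing = (a == "0") | (b == "0")
        het = (a != b) & ~missing
        hom1 = (a == a1) & (b == a1)
        hom2 = (a == a2) & (b == a2) if len(observed) > 1 else np.zeros(n, bool)
        col = np.full(n, MISSING, dtype=np.int8)
        col[hom1] = HOM_A1
        col[het] = HET
        col[hom2] = HOM_A2
        genotypes[:, j] = col

    keep = _autosome_filter(snp_records, str(map_path))
    snps = [snp_records[i] for i in keep]
    genotypes = genotypes[:, keep]
    order = _sorted_snp_order(snps)
    return GenotypeMatrix(samples, [snps[i] for i in order], genotypes[:, order])


def write_plink_text(panel: GenotypeMatrix, prefix: str | Path) -> tuple[Path, Path]:
    """Write a panel as .ped/.map; returns the two paths."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    map_path = prefix.with_suffix(".map")
    ped_path = prefix.with_suffix(".ped")
    with open(map_path, "w") as fh:
        for r in panel.snps:
            fh.write(f"{r.chromosome}\t{r.snp_id}\t0\t{r.position_bp}\n")
    # genotype code -> two allele strings per SNP
    with open(ped_path, "w") as fh:
        for i, s in enumerate(panel.samples):
            fields = [
                s.family_id,
                s.sample_id,
                "0",
                "0",
                _LABEL_TO_SEX[s.sex],
                _LABEL_TO_PHENO[s.phenotype],
            ]
            row = panel.genotypes[i]
            for j, snp in enumerate(panel.snps):
                g = row[j]
                if g == HOM_A1:
                    fields += [snp.allele_a1, snp.allele_a1]
                elif g == HET:
                    fields += [snp.allele_a1, snp.allele_a2]
                elif g == HOM_A2:
                    fields += [snp.allele_a2, snp.allele_a2]
                else:
                    fields += ["0", "0"]
            fh.write(" ".join(fields) + "\n")
    return ped_path, map_path


# ----------------------------------------------------------------------
# binary format
# ----------------------------------------------------------------------


def read_plink_binary(
    bed_path: str | Path, bim_path: str | Path, fam_path: str | Path
) -> GenotypeMatrix:
    """Read a SNP-major PLINK binary fileset."""
    fam = _read_table(fam_path)
    samples = [_parse_sample_row(list(row)) for row in fam.itertuples(index=False)]
    bim = _read_table(bim_path)
    snp_records: list[SNPRecord | None] = [
        _try_snp_record(row[0], row[1], row[3], row[4], row[5])
        for row in bim.itertuples(index=False)
    ]

    raw = Path(bed_path).read_bytes()
    if len(raw) < 3 or raw[:2] != _MAGIC:
        raise PlinkFormatError(f"{bed_path}: missing PLINK magic bytes 6C 1B")
    if raw[2] != _SNP_MAJOR:
        raise PlinkFormatError(
            f"{bed_path}: only SNP-major mode (0x01) is supported, got {raw[2]:#04x}"
        )
    n, m = len(samples), len(snp_records)
    bytes_per_snp = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != bytes_per_snp * m:
        raise PlinkFormatError(
            f"{bed_path}: expected {bytes_per_snp * m} data bytes for "
            f"{n} samples x {m} SNPs, found {body.size}"
        )
    if m and n:
        decoded = _DECODE[body.reshape(m, bytes_per_snp)].reshape(m, -1)[:, :n]
        genotypes = np.ascontiguousarray(decoded.T)
    else:
        genotypes = np.empty((n, m), dtype=np.int8)

    keep = _autosome_filter(snp_records, str(bim_path)) if m else []
    snps = [snp_records[i] for i in keep]
    genotypes = genotypes[:, keep] if m else genotypes
    order = _sorted_snp_order(snps) if snps else np.empty(0, dtype=int)
    return GenotypeMatrix(samples, [snps[i] for i in order], genotypes[:, order])


def write_plink_binary(
    panel: GenotypeMatrix, prefix: str | Path
) -> tuple[Path, Path, Path]:
    """Write a panel as .bed/.bim/.fam; round-trips exactly through
    :func:`read_plink_binary`."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    bed_path = prefix.with_suffix(".bed")
    bim_path = prefix.with_suffix(".bim")
    fam_path = prefix.with_suffix(".fam")

    with open(fam_path, "w") as fh:
        for s in panel.samples:
            fh.write(
                f"{s.family_id}\t{s.sample_id}\t0\t0\t"
                f"{_LABEL_TO_SEX[s.sex]}\t{_LABEL_TO_PHENO[s.phenotype]}\n"
            )
    with open(bim_path, "w") as fh:
        for r in panel.snps:
            fh.write(
                f"{r.chromosome}\t{r.snp_id}\t0\t{r.position_bp}\t"
                f"{r.allele_a1}\t{r.allele_a2}\n"
            )

    n, m = panel.shape
    bytes_per_snp = (n + 3) // 4
    with open(bed_path, "wb") as fh:
        fh.write(_MAGIC + bytes([_SNP_MAJOR]))
        if m:
            bits = _CODE_TO_BITS[panel.genotypes.T % 4].astype(np.uint8)
            padded = np.zeros((m, bytes_per_snp * 4), dtype=np.uint8)
            padded[:, :n] = bits
            packed = (
                padded[:, 0::4]
                | (padded[:, 1::4] << 2)
                | (padded[:, 2::4] << 4)
                | (padded[:, 3::4] << 6)
            )
            fh.write(packed.tobytes())
    return bed_path, bim_path, fam_path
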