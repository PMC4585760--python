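"""In-memory genotype panel model shared by every pipeline stage.

A panel is a samples x SNPs matrix of genotype codes plus two ordered
metadata lists.  Genotype codes are small signed integers so that a whole
cohort fits comfortably in memory as ``int8``:

=========  =====  =========================================
code       value  meaning
=========  =====  =========================================
HOM_A1       0    homozygous for the A1 allele
HET          1    heterozygous
HOM_A2       2    homozygous for the A2 allele
MISSING     -1    no genotype call
=========  =====  =========================================

Only autosomes (chromosomes 1-22) are modelled; SNPs are kept sorted by
(chromosome, position) so that every chromosome occupies one contiguous
column block.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

HOM_A1: int = 0
HET: int = 1
HOM_A2: int = 2
MISSING: int = -1

GENOTYPE_CODES = (HOM_A1, HET, HOM_A2, MISSING)

SEXES = ("male", "female", "unknown")
PHENOTYPES = ("case", "control", "missing")

AUTOSOMES = tuple(range(1, 23))


@dataclass(frozen=True)
class SampleRecord:
    """One genotyped individual with its case/control label."""

    family_id: str
    sample_id: str
    sex: str = "unknown"
    phenotype: str = "missing"

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.phenotype not in PHENOTYPES:
            raise ValueError(
                f"phenotype must be one of {PHENOTYPES}, got {self.phenotype!r}"
            )


@dataclass(frozen=True)
class SNPRecord:
    """One autosomal SNP with 1-based base-pair coordinates."""

    chromosome: int
    snp_id: str
    position_bp: int
    allele_a1: str = "A"
    allele_a2: str = "C"

    def __post_init__(self) -> None:
        if self.chromosome not in AUTOSOMES:
            raise ValueError(
                f"chromosome must be an autosome 1-22, got {self.chromosome!r}"
            )
        if self.position_bp < 1:
            raise ValueError("position_bp must be a positive 1-based coordinate")


class GenotypeMatrix:
    """Samples x SNPs genotype panel.

    Parameters
    ----------
    samples
        Ordered :class:`SampleRecord` list; (family_id, sample_id) pairs
        must be unique.
    snps
        Ordered :class:`SNPRecord` list, sorted by (chromosome, position)
        with strictly increasing positions within each chromosome.
    genotypes
        ``(n_samples, n_snps)`` array of genotype codes, coerced to int8.
    """

    def __init__(
        self,
        samples: Sequence[SampleRecord],
        snps: Sequence[SNPRecord],
        genotypes: np.ndarray,
    ) -> None:
        self.samples = list(samples)
        self.snps = list(snps)
        self.genotypes = np.asarray(genotypes, dtype=np.int8)
        self._validate()

    # -- construction / validation -------------------------------------

    def _validate(self) -> None:
        n, s = len(self.samples), len(self.snps)
        if self.genotypes.ndim != 2 or self.genotypes.shape != (n, s):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{n} samples x {s} SNPs"
            )
        keys = {(r.family_id, r.sample_id) for r in self.samples}
        if len(keys) != n:
            raise ValueError("duplicate (family_id, sample_id) pairs in panel")
        if s:
            codes = np.unique(self.genotypes)
            bad = set(codes.tolist()) - set(GENOTYPE_CODES)
            if bad:
                raise ValueError(f"invalid genotype codes present: {sorted(bad)}")
            chrom = self.chromosomes
            pos = self.positions
            if np.any(np.diff(chrom) < 0):
                raise ValueError("SNPs are not sorted by chromosome")
            same = np.diff(chrom) == 0
            if np.any(np.diff(pos)[same] <= 0):
                raise ValueError(
                    "positions must be strictly increasing within a chromosome"
                )

    # -- basic shape ----------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_samples, self.n_snps)

    # -- derived arrays -------------------------------------------------

    @property
    def chromosomes(self) -> np.ndarray:
        return np.fromiter(
            (r.chromosome for r in self.snps), dtype=np.int16, count=self.n_snps
        )

    @property
    def positions(self) -> np.ndarray:
        return np.fromiter(
            (r.position_bp for r in self.snps), dtype=np.int64, count=self.n_snps
        )

    @property
    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.samples]

    @property
    def phenotypes(self) -> np.ndarray:
        return np.array([r.phenotype for r in self.samples], dtype=object)

    @property
    def case_mask(self) -> np.ndarray:
        return np.array([r.phenotype == "case" for r in self.samples])

    @property
    def control_mask(self) -> np.ndarray:
        return np.array([r.phenotype == "control" for r in self.samples])

    def chrom_blocks(self) -> list[tuple[int, slice]]:
        """Contiguous column slice for each chromosome, in genome order."""
        chrom = self.chromosomes
        blocks: list[tuple[int, slice]] = []
        if self.n_snps == 0:
            return blocks
        bounds = np.flatnonzero(np.diff(chrom)) + 1
        starts = np.concatenate(([0], bounds))
        stops = np.concatenate((bounds, [self.n_snps]))
        for a, b in zip(starts, stops):
            blocks.append((int(chrom[a]), slice(int(a), int(b))))
        return blocks

    # -- subsetting -----------------------------------------------------

    def subset_samples(self, index: Iterable[int] | np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(list(index) if not isinstance(index, np.ndarray) else index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            [self.samples[int(i)] for i in idx], self.snps, self.genotypes[idx, :]
        )

    def subset_snps(self, index: Iterable[int] | np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(list(index) if not isinstance(index, np.ndarray) else index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            self.samples, [self.snps[int(i)] for i in idx], self.genotypes[:, idx]
        )

    # -- equality (used heavily by round-trip tests) ---------------------

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.samples == other.samples
            and self.snps == other.snps
            and np.array_equal(self.genotypes, other.genotypes)
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"GenotypeMatrix({self.n_samples} samples x {self.n_snps} SNPs)"
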