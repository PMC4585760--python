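"""Synthetic case-control SNP panels with the structure the ROH analysis
assumes.

The generator emulates a genotyped outbred cohort:

* per-SNP allele frequencies drawn uniformly from a configurable MAF
  range (the default range, combined with the finite haplotype pools,
  yields a genome-wide heterozygosity of about 0.34);
* linkage disequilibrium from finite haplotype pools: SNPs are grouped
  into blocks, a small pool of haplotypes is generated per block and
  each individual draws two pool haplotypes per block;
* background autozygosity: with a configurable probability an individual
  receives one autozygous segment (a single haplotype copied over both
  chromosomes across a contiguous SNP interval);
* a planted risk ROH: carriers, drawn at different frequencies in cases
  and controls, receive an autozygous segment spanning exactly the
  configured risk region;
* symmetric genotyping error (a called genotype flips to one of the
  other two codes) and missingness.

The generator also provides iid null panels (independent calls,
heterozygous with probability h) for calibrating the chance-run formula.
All output is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (
    HET,
    HOM_A1,
    HOM_A2,
    MISSING,
    GenotypeMatrix,
    SampleRecord,
    SNPRecord,
)

_BASES = ("A", "C", "G", "T")


@dataclass
class SimulationConfig:
    """Study-condition parameters for the synthetic cohort.

    The defaults describe a balanced 500/500 case-control panel of 2,000
    SNPs on two chromosomes with ~20 kb marker spacing, LD blocks of 20
    SNPs drawn from pools of 20 haplotypes, 10% background autozygosity
    of 90-140 SNP segments, a risk ROH carried by 15% of cases and 8% of
    controls, 0.2% genotyping error and 1% missingness.  The MAF range
    (0.05, 0.48) sets the genome-wide heterozygosity near 0.34.
    """

    n_cases: int = 500
    n_controls: int = 500
    n_snps: int = 2000
    n_chromosomes: int = 2
    maf_range: tuple[float, float] = (0.05, 0.48)
    ld_block_snps: int = 20
    haplotype_pool_size: int = 20
    autozygosity_rate: float = 0.10
    autozygous_segment_snps: tuple[int, int] = (90, 140)
    risk_region: tuple[int, int, int] | None = (1, 300, 405)
    carrier_freq_cases: float = 0.15
    carrier_freq_controls: float = 0.08
    genotype_error_rate: float = 0.002
    missing_rate: float = 0.01
    spacing_bp: tuple[int, int] = (10_000, 30_000)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "autozygosity_rate",
            "carrier_freq_cases",
            "carrier_freq_controls",
            "genotype_error_rate",
            "missing_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        lo, hi = self.maf_range
        if not 0.0 < lo <= hi <= 0.5:
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.n_chromosomes < 1 or self.n_chromosomes > 22:
            raise ValueError("n_chromosomes must be in 1..22")
        if self.risk_region is not None:
            chrom, lo_i, hi_i = self.risk_region
            per_chrom = self.n_snps // self.n_chromosomes
            if not 1 <= chrom <= self.n_chromosomes:
                raise ValueError("risk_region chromosome outside the panel")
            if not 0 <= lo_i <= hi_i < per_chrom:
                raise ValueError(
                    "risk_region SNP interval exceeds the chromosome "
                    f"(chromosome holds {per_chrom} SNPs)"
                )


@dataclass(frozen=True)
class PlantedSegment:
    """A planted autozygous interval (chromosome-local SNP indices)."""

    sample_id: str
    chromosome: int
    start_index: int
    end_index: int


@dataclass
class SimulationTruth:
    """Ground truth emitted next to the genotypes."""

    segments: list[PlantedSegment] = field(default_factory=list)
    risk_carrier: dict[str, bool] = field(default_factory=dict)
    allele_freqs: np.ndarray | None = None
    risk_region: tuple[int, int, int] | None = None


def _chromosome_sizes(n_snps: int, n_chromosomes: int) -> list[int]:
    base = n_snps // n_chromosomes
    sizes = [base] * n_chromosomes
    for k in range(n_snps - base * n_chromosomes):
        sizes[k] += 1
    return sizes


def simulate_panel(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, SimulationTruth]:
    """Generate a case-control panel plus its ground truth."""
    rng = np.random.default_rng(config.seed)
    n = config.n_cases + config.n_controls
    s = config.n_snps
    sizes = _chromosome_sizes(s, config.n_chromosomes)

    # marker map
    snps: list[SNPRecord] = []
    chrom_offsets: dict[int, int] = {}
    offset = 0
    for chrom_idx, size in enumerate(sizes, start=1):
        chrom_offsets[chrom_idx] = offset
        spacing = rng.integers(
            config.spacing_bp[0], config.spacing_bp[1] + 1, size=size
        )
        pos = np.cumsum(spacing)
        for k in range(size):
            a1, a2 = sorted(rng.choice(4, size=2, replace=False))
            snps.append(
                SNPRecord(
                    chromosome=chrom_idx,
                    snp_id=f"snp{offset + k + 1}",
                    position_bp=int(pos[k]),
                    allele_a1=_BASES[a1],
                    allele_a2=_BASES[a2],
                )
            )
        offset += size

    samples = [
        SampleRecord(family_id=f"F{i + 1}", sample_id=f"case{i + 1}", phenotype="case")
        for i in range(config.n_cases)
    ] + [
        SampleRecord(
            family_id=f"F{config.n_cases + i + 1}",
            sample_id=f"ctrl{i + 1}",
            phenotype="control",
        )
        for i in range(config.n_controls)
    ]

    freqs = rng.uniform(config.maf_range[0], config.maf_range[1], size=s)

    # haplotype pools per LD block; each individual draws two haplotypes
    allele_counts = np.empty((n, s), dtype=np.int8)
    pools: list[tuple[int, int, np.ndarray]] = []  # (global start, stop, pool)
    for chrom_idx, size in enumerate(sizes, start=1):
        off = chrom_offsets[chrom_idx]
        for a in range(0, size, config.ld_block_snps):
            b = min(a + config.ld_block_snps, size)
            pool = (
                rng.random((config.haplotype_pool_size, b - a))
                < freqs[off + a : off + b]
            ).astype(np.int8)
            idx1 = rng.integers(config.haplotype_pool_size, size=n)
            idx2 = rng.integers(config.haplotype_pool_size, size=n)
            allele_counts[:, off + a : off + b] = pool[idx1] + pool[idx2]
            pools.append((off + a, off + b, pool))

    truth = SimulationTruth(
        allele_freqs=freqs, risk_region=config.risk_region
    )

    def plant_autozygous(row: int, chrom: int, lo: int, hi: int) -> None:
        """Copy one pool haplotype over both chromosomes on [lo, hi]
        (chromosome-local, inclusive)."""
        g_lo = chrom_offsets[chrom] + lo
        g_hi = chrom_offsets[chrom] + hi
        for start, stop, pool in pools:
            if stop <= g_lo or start > g_hi:
                continue
            a = max(start, g_lo)
            b = min(stop - 1, g_hi)
            hap = pool[rng.integers(pool.shape[0])]
            allele_counts[row, a : b + 1] = 2 * hap[a - start : b + 1 - start]

    # background autozygosity
    autozygous = rng.random(n) < config.autozygosity_rate
    for row in np.flatnonzero(autozygous):
        length = int(
            rng.integers(
                config.autozygous_segment_snps[0],
                config.autozygous_segment_snps[1] + 1,
            )
        )
        eligible = [c for c, size in enumerate(sizes, start=1) if size >= length]
        chrom = int(eligible[rng.integers(len(eligible))])
        lo = int(rng.integers(sizes[chrom - 1] - length + 1))
        hi = lo + length - 1
        plant_autozygous(int(row), chrom, lo, hi)
        truth.segments.append(
            PlantedSegment(samples[row].sample_id, chrom, lo, hi)
        )

    # planted risk ROH
    if config.risk_region is not None:
        chrom, lo, hi = config.risk_region
        carrier = np.concatenate(
            [
                rng.random(config.n_cases) < config.carrier_freq_cases,
                rng.random(config.n_controls) < config.carrier_freq_controls,
            ]
        )
        for row in np.flatnonzero(carrier):
            plant_autozygous(int(row), chrom, lo, hi)
            truth.segments.append(
                PlantedSegment(samples[row].sample_id, chrom, lo, hi)
            )
        truth.risk_carrier = {
            samples[i].sample_id: bool(carrier[i]) for i in range(n)
        }
    else:
        truth.risk_carrier = {smp.sample_id: False for smp in samples}

    genotypes = allele_counts  # codes: 0 = hom_a1, 1 = het, 2 = hom_a2

    # symmetric genotyping error: flip to one of the other two codes
    if config.genotype_error_rate > 0:
        flip = rng.random((n, s)) < config.genotype_error_rate
        shift = rng.integers(1, 3, size=int(flip.sum())).astype(np.int8)
        genotypes[flip] = (genotypes[flip] + shift) % 3

    if config.missing_rate > 0:
        miss = rng.random((n, s)) < config.missing_rate
        genotypes[miss] = MISSING

    panel = GenotypeMatrix(samples, snps, genotypes)
    return panel, truth


def simulate_iid_null(
    n_samples: int,
    n_snps: int,
    heterozygosity_h: float,
    seed: int,
    chromosome: int = 1,
    spacing_bp: int = 20_000,
) -> GenotypeMatrix:
    """Panel of independent genotype calls: heterozygous with probability
    h, otherwise homozygous (the two homozygote codes equiprobable), no
    missingness.  This is the null model behind the chance-run formula."""
    if not 0.0 < heterozygosity_h < 1.0:
        raise ValueError("heterozygosity_h must be in (0, 1)")
    rng = np.random.default_rng(seed)
    r = rng.random((n_samples, n_snps))
    genotypes = np.full((n_samples, n_snps), HOM_A2, dtype=np.int8)
    genotypes[r < heterozygosity_h] = HET
    genotypes[
        (r >= heterozygosity_h) & (r < heterozygosity_h + (1 - heterozygosity_h) / 2)
    ] = HOM_A1
    samples = [
        SampleRecord(family_id=f"F{i + 1}", sample_id=f"null{i + 1}")
        for i in range(n_samples)
    ]
    snps = [
        SNPRecord(
            chromosome=chromosome,
            snp_id=f"snp{k + 1}",
            position_bp=(k + 1) * spacing_bp,
        )
        for k in range(n_snps)
    ]
    return GenotypeMatrix(samples, snps, genotypes)
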