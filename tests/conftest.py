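import numpy as np
import pytest

from rohscan.model import GenotypeMatrix, SampleRecord, SNPRecord


def make_panel(
    genotypes,
    chromosomes=None,
    positions=None,
    phenotypes=None,
    spacing_bp=20_000,
):
    """Build a small panel from a genotype array with sensible defaults:
    all SNPs on chromosome 1, evenly spaced, all samples controls."""
    g = np.asarray(genotypes, dtype=np.int8)
    n, s = g.shape
    if chromosomes is None:
        chromosomes = [1] * s
    if positions is None:
        positions, last = [], {}
        for c in chromosomes:
            last[c] = last.get(c, 0) + spacing_bp
            positions.append(last[c])
    if phenotypes is None:
        phenotypes = ["control"] * n
    samples = [
        SampleRecord(family_id=f"F{i}", sample_id=f"S{i}", phenotype=phenotypes[i])
        for i in range(n)
    ]
    snps = [
        SNPRecord(chromosome=chromosomes[k], snp_id=f"snp{k}", position_bp=positions[k])
        for k in range(s)
    ]
    return GenotypeMatrix(samples, snps, g)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
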