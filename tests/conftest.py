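import numpy as np
import pytest

from varprior.genemodel import GeneModel, Transcript
from varprior.synthetic import (
    PlantSpec,
    generate_gene_model,
    generate_pedigree,
    generate_variant_set,
)


@pytest.fixture(scope="session")
def study_pedigree():
    """Two nuclear families, two affected children each (8 samples)."""
    return generate_pedigree(2, 2)


@pytest.fixture(scope="session")
def gene_model():
    return generate_gene_model(30)


@pytest.fixture
def toy_model():
    """Two overlapping isoforms on opposite strands plus a lone gene.

    GA(+): exons [100,200) and [300,400), CDS [150,350) — UTR5 at
    [100,150), UTR3 at [350,400), intron [200,300).
    GB(-): single exon [180,260), CDS [220,250) — on the minus strand
    positions below cds_start are 3'UTR.
    GC(+): single-exon gene far away at [5000,5200), CDS [5050,5150).
    """
    return GeneModel(
        [
            Transcript("GA", "chr1", "+", ((100, 200), (300, 400)), 150, 350),
            Transcript("GB", "chr1", "-", ((180, 260),), 220, 250),
            Transcript("GC", "chr1", "+", ((5000, 5200),), 5050, 5150),
        ]
    )


@pytest.fixture
def make_dataset(tmp_path, study_pedigree, gene_model):
    """Factory: write a planted VCF for a seed, return (vcf_path, truth)."""

    def _make(rng_seed=0, **kwargs):
        spec = PlantSpec(rng_seed=rng_seed, **kwargs)
        vcf = tmp_path / f"planted_{rng_seed}.vcf"
        truth = generate_variant_set(study_pedigree, gene_model, spec, vcf)
        return vcf, truth

    return _make


def fibonacci_shell(n_atoms: int, radius: float) -> np.ndarray:
    """Near-uniform atom centres on a sphere (hollow-shell fixture)."""
    i = np.arange(n_atoms)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n_atoms
    rho = np.sqrt(1.0 - z * z)
    return radius * np.stack([rho * np.cos(phi), rho * np.sin(phi), z], axis=1)
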