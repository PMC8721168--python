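"""Shared fixtures: small genotype matrices and generated files."""

from __future__ import annotations

import numpy as np
import pytest

from sweeptx.core_io import GenotypeMatrix


def make_gm(dosage, pos=None, chrom=None, qual=None, depth=None,
            pops=None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from a dosage array with sensible defaults."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n_s, n_v = dosage.shape
    if pos is None:
        pos = np.arange(1, n_v + 1) * 100
    if chrom is None:
        chrom = np.asarray(["chr1"] * n_v, dtype=object)
    else:
        chrom = np.asarray(chrom, dtype=object)
    sample_ids = [f"s{i + 1}" for i in range(n_s)]
    if pops is None:
        pops = ["A"] * (n_s // 2) + ["B"] * (n_s - n_s // 2)
    return GenotypeMatrix(
        chrom=chrom,
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.asarray(["A"] * n_v, dtype=object),
        alt=np.asarray(["G"] * n_v, dtype=object),
        qual=np.asarray(qual if qual is not None else [50.0] * n_v, dtype=float),
        site_depth=np.asarray(depth if depth is not None else [30] * n_v, dtype=np.int64),
        dosage=dosage,
        sample_ids=sample_ids,
        pop_labels=dict(zip(sample_ids, pops)),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def two_pop_gm():
    """8+8 samples, 8k SNPs, moderately diverged (F = 0.2): strong structure."""
    from sweeptx.synthetic_data import SimConfig, simulate_genotypes

    cfg = SimConfig(seed=5, n_pops=2, samples_per_pop=8,
                    chrom_lengths={"chr1": 1_000_000}, n_snps=8000,
                    fst_background=0.2)
    gm, _ = simulate_genotypes(cfg)
    return gm
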