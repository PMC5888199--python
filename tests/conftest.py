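import numpy as np
import pandas as pd
import pytest

from permqtl import loci, synthio


@pytest.fixture(scope="session")
def planted_cohort():
    """Small cohort with one strong planted cis effect and tight LD."""
    cfg = synthio.SimConfig(
        n_samples=150,
        n_loci=2,
        snps_per_locus=6,
        probes_per_locus=3,
        maf_range=(0.2, 0.5),
        ld_decay=0.9,
        effect_sizes=(1.0,),
        noise_sd=1.0,
        seed=7,
    )
    geno, expr, truth, meta = synthio.simulate_cohort(cfg)
    return cfg, geno, expr, truth, meta


@pytest.fixture(scope="session")
def planted_blocks(planted_cohort):
    _, geno, expr, _, _ = planted_cohort
    blocks, skipped = loci.blocks_from_simulation(geno, r2_min=0.5)
    assert not skipped
    assignments = loci.classify_probes(blocks, expr.probes)
    return blocks, assignments


def toy_genotypes(dosage_columns, chrom="1", start=1_000_000, spacing=1000,
                  sample_prefix="S"):
    """Hand-built GenotypeMatrix from a dict rsid -> dosage list."""
    from permqtl.core import GenotypeMatrix

    rsids = list(dosage_columns)
    n = len(next(iter(dosage_columns.values())))
    dosages = pd.DataFrame(
        {r: np.asarray(v, dtype=float) for r, v in dosage_columns.items()},
        index=[f"{sample_prefix}{i:03d}" for i in range(n)],
    )
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": [start + i * spacing for i in range(len(rsids))],
            "ref": "A",
            "alt": "G",
        },
        index=pd.Index(rsids, name="rsid"),
    )
    return GenotypeMatrix(dosages, variants)


def toy_expression(value_columns, chrom="1", start=1_000_500, spacing=1000,
                   sample_prefix="S", state="normalized"):
    """Hand-built ExpressionMatrix from a dict probe_id -> value list."""
    from permqtl.core import ExpressionMatrix

    pids = list(value_columns)
    n = len(next(iter(value_columns.values())))
    values = pd.DataFrame(
        {p: np.asarray(v, dtype=float) for p, v in value_columns.items()},
        index=[f"{sample_prefix}{i:03d}" for i in range(n)],
    )
    probes = pd.DataFrame(
        {
            "gene_symbol": [f"G_{p}" for p in pids],
            "chrom": chrom,
            "start_pos": [start + i * spacing for i in range(len(pids))],
            "blacklisted": False,
        },
        index=pd.Index(pids, name="probe_id"),
    )
    return ExpressionMatrix(values, probes, state=state)
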