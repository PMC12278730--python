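import numpy as np
import pandas as pd
import pytest

from mutload import (
    FilterConfig,
    PopulationPanel,
    SimulationConfig,
    load_variants,
    simulate_panel,
)
from mutload.ingest import VcfData


@pytest.fixture(scope="session")
def study_sim(tmp_path_factory):
    """Default 17-population study-condition panel (seeded)."""
    cfg = SimulationConfig(seed=1)
    return simulate_panel(cfg, tmp_path_factory.mktemp("study"))


@pytest.fixture(scope="session")
def study_table(study_sim):
    table, _ = load_variants(study_sim.vcf_path, study_sim.config.outgroup_name)
    return table


@pytest.fixture(scope="session")
def clean_sim(tmp_path_factory):
    """Small noise-free panel (no genotype errors/missingness/quality noise)."""
    cfg = SimulationConfig(
        n_pops=4,
        n_ind_per_pop=4,
        chromosomes=[("LG1", 2_000_000), ("LG2", 2_000_000), ("LG12", 1_000_000)],
        sex_chromosome="LG12",
        target_f_roh=[0.0, 0.2, 0.4, 0.6],
        roh_length_mix=[(0.6, 100_000, 400_000), (0.4, 400_000, 900_000)],
        class_site_counts={
            "LOF": 100, "MISSENSE": 300, "SYNONYMOUS": 300,
            "INTERGENIC": 1200, "OTHER": 50,
        },
        genotype_error_rate=0.0,
        missing_rate=0.0,
        low_gq_rate=0.0,
        low_qual_rate=0.0,
        depth_outlier_rate=0.0,
        ann_warning_rate=0.0,
        seed=7,
    )
    return simulate_panel(cfg, tmp_path_factory.mktemp("clean"))


def make_vcf_data(
    dosage,
    samples,
    chrom=None,
    pos=None,
    qual=None,
    gq=None,
    dp=None,
    effect=None,
    ann_warning=None,
):
    """Hand-built VcfData for unit tests (ALT dosages, MISSING = -1)."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, k = dosage.shape
    return VcfData(
        chrom=np.array(chrom if chrom is not None else ["LG1"] * n, dtype=object),
        pos=np.array(pos if pos is not None else np.arange(1, n + 1) * 100, dtype=np.int64),
        ref=np.array(["A"] * n, dtype=object),
        alt=np.array(["T"] * n, dtype=object),
        qual=np.array(qual if qual is not None else [100.0] * n, dtype=float),
        effect=np.array(effect if effect is not None else ["MISSENSE"] * n, dtype=object),
        ann_warning=np.array(
            ann_warning if ann_warning is not None else [False] * n, dtype=bool
        ),
        dosage=dosage,
        gq=np.array(gq if gq is not None else np.full((n, k), 99), dtype=np.int32),
        dp=np.array(dp if dp is not None else np.full((n, k), 15), dtype=np.int32),
        samples=list(samples),
    )
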