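"""Shared fixtures: a compact synthetic study (2 Mb focal chromosome) used
across module tests so the expensive simulations run once per session."""

import numpy as np
import pandas as pd
import pytest

from ztrscan import pipeline as pl
from ztrscan import synthetic_data as sd

KB = 1_000


def small_layouts() -> tuple[sd.SimLayout, sd.SimLayout]:
    """2 Mb focal chromosome (40 windows) plus a 0.5 Mb diploid baseline."""
    genes = [
        sd.GeneSpec("GENE_OK", 620 * KB, 640 * KB, "+",
                    cds=((621_000, 622_998),)),
        sd.GeneSpec("GENE_PARTIAL", 790 * KB, 810 * KB, "+",
                    cds=((791_000, 791_600),)),
        sd.GeneSpec("GENE_DEL", 820 * KB, 840 * KB, "-",
                    cds=((821_000, 821_600),)),
        sd.GeneSpec("GENE_PSI", 1_000 * KB, 1_020 * KB, "+",
                    cds=((1_001_000, 1_002_998),),
                    planted_fate="pseudogene_frameshift"),
    ]
    chrz = sd.SimLayout(
        chrom_name="chrZ",
        chrom_length=2_000 * KB,
        window_size=50 * KB,
        regions=[
            sd.RegionSpec(0, 200 * KB, "PAR"),
            sd.RegionSpec(200 * KB, 600 * KB, "HEMIZYGOUS_Z"),
            sd.RegionSpec(600 * KB, 1_300 * KB, "ZTR"),
            sd.RegionSpec(1_300 * KB, 1_800 * KB, "HEMIZYGOUS_Z"),
            sd.RegionSpec(1_800 * KB, 1_900 * KB, "Z_DUP"),
            sd.RegionSpec(1_900 * KB, 2_000 * KB, "HEMIZYGOUS_Z"),
        ],
        w_deletions=[(800 * KB, 950 * KB)],
        genes=genes,
    )
    chra = sd.SimLayout(
        chrom_name="chrA",
        chrom_length=500 * KB,
        window_size=50 * KB,
        regions=[sd.RegionSpec(0, 500 * KB, "AUTOSOME_LIKE")],
    )
    return chrz, chra


@pytest.fixture(scope="session")
def layouts():
    return small_layouts()


@pytest.fixture(scope="session")
def params():
    return sd.SimParams(seed=11)


@pytest.fixture(scope="session")
def reference(layouts, params):
    return sd.simulate_reference(layouts[0], params)


@pytest.fixture(scope="session")
def small_run(layouts):
    """One full pipeline run on the compact study (seed 11)."""
    cfg = pl.RunConfig(seed=11)
    cfg.omega_w = {"GENE_OK": 0.0}
    cfg.n_codons = 400
    return pl.run_pipeline(cfg, layouts=small_layouts())
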