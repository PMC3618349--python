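"""Shared fixtures: one demo pipeline run reused across the suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sppmap import haplotype, linkage, simulate
from sppmap.pipeline import PipelineConfig, run_pipeline


@pytest.fixture(scope="session")
def demo_report():
    """Full pipeline run on the demo simulation (40 RILs, 2 x 120 cM,
    300 unigenes), kept in memory; the expensive shared fixture."""
    cfg = PipelineConfig(seed=0, outdir="unused")
    cfg.sections["simulate"] = {"demo": True}
    return run_pipeline(cfg, write_files=False)


@pytest.fixture(scope="session")
def demo_objects(demo_report):
    return demo_report["_objects"]


@pytest.fixture(scope="session")
def small_dataset():
    """A small simulated array dataset for unit tests."""
    cfg = simulate.SimConfig(
        n_rils=12, n_chromosomes=1, chrom_lengths=(80.0,), n_unigenes=40,
        seed=11)
    truth, data = simulate.simulate_dataset(cfg)
    return cfg, truth, data


def make_locus_set(geno: np.ndarray) -> haplotype.LocusSet:
    """Wrap a raw call matrix (loci x RILs) as a coded LocusSet."""
    geno = np.asarray(geno, dtype=np.int8)
    table = pd.DataFrame({
        "locus_id": np.arange(len(geno)),
        "unigene_id": np.arange(len(geno)),
        "part": "whole",
        "n_missing": (geno == -1).sum(axis=1),
    })
    ls = haplotype.LocusSet(table=table, geno=geno,
                            ril_ids=np.arange(geno.shape[1]))
    return haplotype.assign_codes(ls)


def make_genotype_matrix(geno: np.ndarray) -> linkage.GenotypeMatrix:
    return linkage.GenotypeMatrix.from_locus_set(make_locus_set(geno))


@pytest.fixture
def truth_matrix_map():
    """Noise-free genotype matrix straight from a simulated pedigree,
    with its built linkage map; used by curation/stats tests."""
    cfg = simulate.SimConfig(n_rils=50, n_chromosomes=2,
                             chrom_lengths=(100.0, 100.0), n_unigenes=150,
                             seed=21)
    truth = simulate.simulate_pedigree(cfg)
    m = truth.unigene_genotype_matrix().astype(np.int8)
    m[m == simulate.GENOTYPE_H] = -1
    gm = make_genotype_matrix(m)
    lmap, pairs = linkage.build_linkage_map(gm, min_support=30)
    return cfg, truth, gm, lmap, pairs
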