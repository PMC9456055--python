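"""Shared fixtures: bundled knowledge tables and small hand-built inputs."""

from __future__ import annotations

import numpy as np
import pytest

from pgxcohort import datasets
from pgxcohort.cohort import CohortGenotypes, MarkerRecord
from pgxcohort.knowledge import GeneDefinitionSet, StarAllele, VariantSite


@pytest.fixture(scope="session")
def defs():
    return datasets.load_default_definitions()


@pytest.fixture(scope="session")
def pmap():
    return datasets.load_default_phenotype_map()


@pytest.fixture(scope="session")
def gene_drug():
    return datasets.load_default_gene_drug()


@pytest.fixture(scope="session")
def annotations():
    return datasets.load_default_annotations()


@pytest.fixture(scope="session")
def hap_freqs():
    return datasets.load_default_haplotype_frequencies()


def make_site(pos: int, chrom: str = "1", rsid: str = "") -> VariantSite:
    return VariantSite(chrom=chrom, pos=pos, rsid=rsid or f"rs{pos}", ref="A", alt="G")


@pytest.fixture(scope="session")
def toy_defs() -> GeneDefinitionSet:
    """One gene G1: sites s1, s2; alleles *1 (ref), *2 (s1), *3 (s1+s2)."""
    s1, s2 = make_site(100), make_site(200)
    return GeneDefinitionSet(
        genes={
            "G1": [
                StarAllele(gene="G1", name="*1", is_reference=True),
                StarAllele(gene="G1", name="*2", defining={s1: "G"}),
                StarAllele(gene="G1", name="*3", defining={s1: "G", s2: "G"}),
            ]
        },
        sites={"G1": [s1, s2]},
    )


def make_cohort(haps: np.ndarray, sites=None, quality=None, samples=None) -> CohortGenotypes:
    """Build a CohortGenotypes from an (n, m, 2) int array."""
    haps = np.asarray(haps, dtype=np.int8)
    n, m, _ = haps.shape
    sites = sites or [make_site(100 + 10 * j) for j in range(m)]
    quality = quality if quality is not None else [None] * m
    samples = samples or [f"S{i + 1:03d}" for i in range(n)]
    markers = []
    for j, (site, q) in enumerate(zip(sites, quality)):
        col = haps[:, j, :].ravel()
        valid = col != -1
        af = float(col[valid].sum() / valid.sum()) if valid.any() else float("nan")
        markers.append(
            MarkerRecord(site=site, imputation_quality=q, alt_freq=af, maf=min(af, 1 - af))
        )
    return CohortGenotypes(
        samples=samples,
        markers=markers,
        haplotypes=haps,
        phased=np.ones((n, m), dtype=bool),
    )
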