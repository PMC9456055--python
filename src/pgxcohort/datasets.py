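"""Bundled toy knowledge fixtures and published cohort summary tables.

Two kinds of data ship with the package, all as small plain-text TSVs:

* a **toy 14-gene knowledge fixture** (allele definitions, diplotype →
  phenotype map with nontypical flags, level-A gene–drug table, clinical
  annotations, simulator haplotype frequencies).  It is schema-compatible
  with real PharmCAT/PharmGKB-style exports but deliberately small: each
  gene carries a handful of star alleles over one or two defining sites.
  It exists so the whole pipeline is exercisable and testable at desk
  scale; real exports load through the same functions.
* **published summary tables for a survey of 1577 unrelated Sardinian
  individuals**: the at-risk-drug burden distribution, the per-gene
  phenotype count table, and study-vs-reference allele-frequency tables
  for the clinically annotated variants (high-evidence 1A–2B and
  low-evidence 3/4 tiers).  REF alleles in the frequency tables are
  synthetic placeholders (the source tables print only the ALT allele),
  chosen to avoid strand-ambiguous pairs; the low-evidence clinical
  annotation rows are likewise synthetic stand-ins at level 3.
"""

from __future__ import annotations

from importlib.resources import files
from pathlib import Path

import pandas as pd

from . import knowledge
from .knowledge import GeneDefinitionSet, PhenotypeMap

__all__ = [
    "COHORT_SIZE",
    "data_path",
    "load_default_definitions",
    "load_default_phenotype_map",
    "load_default_gene_drug",
    "load_default_annotations",
    "load_default_haplotype_frequencies",
    "load_burden_distribution_table",
    "load_gene_phenotype_counts",
    "load_af_table",
    "DEFAULT_LD_LOCKED_PAIRS",
]

#: size of the unrelated study cohort behind the bundled summary tables
COHORT_SIZE = 1577

#: variant pair reported in perfect LD (r^2 = 1) in the study population;
#: the default simulator config locks it
DEFAULT_LD_LOCKED_PAIRS = (("rs9923231", "rs9934438"),)


def data_path(name: str) -> Path:
    return Path(str(files("pgxcohort").joinpath("data", name)))


def load_default_definitions() -> GeneDefinitionSet:
    return knowledge.load_allele_definitions(data_path("allele_definitions.tsv"))


def load_default_phenotype_map() -> PhenotypeMap:
    return knowledge.load_phenotype_map(
        data_path("phenotype_map.tsv"), data_path("phenotype_flags.tsv")
    )


def load_default_gene_drug(level_filter=frozenset({"A"})):
    return knowledge.load_gene_drug_table(
        data_path("gene_drug_cpic.tsv"), level_filter=level_filter
    )


def load_default_annotations():
    return knowledge.load_clinical_annotations(data_path("clinical_annotations.tsv"))


def load_default_haplotype_frequencies() -> dict[str, dict[str, float]]:
    df = pd.read_csv(data_path("haplotype_frequencies.tsv"), sep="\t")
    out: dict[str, dict[str, float]] = {}
    for row in df.itertuples():
        out.setdefault(str(row.gene), {})[str(row.allele)] = float(row.frequency)
    return out


def load_burden_distribution_table() -> pd.DataFrame:
    """Published at-risk-drug burden histogram (n_individuals, n_drugs)."""
    return pd.read_csv(data_path("burden_distribution.tsv"), sep="\t")


def load_gene_phenotype_counts() -> dict[str, dict[str, int]]:
    """Published per-gene phenotype counts (each gene sums to the cohort size)."""
    df = pd.read_csv(data_path("gene_phenotype_counts.tsv"), sep="\t")
    out: dict[str, dict[str, int]] = {}
    for row in df.itertuples():
        out.setdefault(str(row.gene), {})[str(row.phenotype)] = int(row.count)
    return out


def load_af_table(tier: str) -> pd.DataFrame:
    """Study/reference AF table for the ``"high"`` or ``"low"`` evidence tier."""
    if tier not in {"high", "low"}:
        raise ValueError("tier must be 'high' or 'low'")
    return pd.read_csv(data_path(f"af_{tier}_evidence.tsv"), sep="\t")
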