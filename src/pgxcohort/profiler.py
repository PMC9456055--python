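"""Phenotype assignment and cohort-level burden summaries.

Each sample's diplotype at each gene is mapped to a CPIC phenotype label
and a *nontypical* flag (CPIC recommends an alternate dosage or drug for
that phenotype).  Cohort summaries then quantify the burden of nontypical
response: the per-gene phenotype frequency table, the fraction of the
cohort with at least one nontypical diplotype, the per-sample count of
at-risk drugs (the union of level-A drugs over that sample's nontypical
genes), and the per-drug at-risk fraction.

Conventions: "Not available" and "Indeterminate" are never nontypical;
burden counts genes (diplotypes), not phenotype labels, so a sample
contributes at most one unit per gene; per-drug risk counts individuals
nontypical in *any* gene linked to the drug (a union, not a per-gene
maximum).  Percentages round half-up to 2 decimals, frequencies to 8.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import pandas as pd

from .caller import DiplotypeCall
from .knowledge import GeneDrugPair, PhenotypeMap

__all__ = [
    "PhenotypeCall",
    "BurdenRecord",
    "BurdenDistribution",
    "CohortSummary",
    "ProfilerError",
    "assign_phenotype",
    "individual_burden",
    "cohort_summary",
    "burden_distribution",
    "summarize_burden_distribution",
]

NOT_AVAILABLE = "Not available"
INDETERMINATE = "Indeterminate"


class ProfilerError(ValueError):
    pass


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal half-up rounding (matches how the summary tables print)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PhenotypeCall:
    sample: str
    gene: str
    phenotype: str
    nontypical: bool


@dataclass(frozen=True)
class BurdenRecord:
    sample: str
    n_nontypical_genes: int
    at_risk_drugs: frozenset[str]


@dataclass
class BurdenDistribution:
    """Rows of (n_individuals, n_drugs) for individuals with >= 1 at-risk drug."""

    rows: list[tuple[int, int]]
    cohort_size: int

    def __post_init__(self) -> None:
        if any(d < 1 for _, d in self.rows):
            raise ProfilerError("burden rows must have n_drugs >= 1")
        if sum(n for n, _ in self.rows) > self.cohort_size:
            raise ProfilerError("burden rows exceed cohort size")


@dataclass
class CohortSummary:
    cohort_size: int
    #: gene -> phenotype -> (count, frequency)
    gene_phenotypes: dict[str, dict[str, tuple[int, float]]]
    #: fraction of samples with >= 1 nontypical diplotype
    fraction_ge1: float
    #: mean |at_risk_drugs| over all samples
    mean_drugs: float
    #: drug -> (n at risk, fraction at risk)
    drug_risk: dict[str, tuple[int, float]]
    #: drugs whose at-risk fraction exceeds the configured threshold
    drugs_over_threshold: list[str]
    risk_threshold: float

    def gene_phenotype_frame(self) -> pd.DataFrame:
        rows = [
            {"gene": g, "phenotype": p, "count": c,
             "frequency": round_half_up(f, 8)}
            for g, per in sorted(self.gene_phenotypes.items())
            for p, (c, f) in sorted(per.items())
        ]
        return pd.DataFrame(rows)

    def drug_risk_frame(self) -> pd.DataFrame:
        rows = [
            {"drug": d, "n_at_risk": n, "fraction": round_half_up(f, 8)}
            for d, (n, f) in sorted(self.drug_risk.items())
        ]
        return pd.DataFrame(rows)


def assign_phenotype(call: DiplotypeCall, pmap: PhenotypeMap) -> PhenotypeCall:
    """Map one diplotype call to its phenotype label and nontypical flag.

    Uncalled diplotypes get "Not available"; called pairs absent from the
    map get "Indeterminate".  Both are typical by definition.
    """
    if call.gene not in pmap.genes():
        raise ProfilerError(f"gene {call.gene} absent from phenotype map")
    if call.status != "called":
        return PhenotypeCall(call.sample, call.gene, NOT_AVAILABLE, False)
    label = pmap.lookup(call.gene, *call.allele_pair)
    if label is None:
        return PhenotypeCall(call.sample, call.gene, INDETERMINATE, False)
    return PhenotypeCall(call.sample, call.gene, label, pmap.is_nontypical(call.gene, label))


def _drug_map(gene_drug: Sequence[GeneDrugPair]) -> Mapping[str, frozenset[str]]:
    out: dict[str, set[str]] = {}
    for pair in gene_drug:
        out.setdefault(pair.gene, set()).add(pair.drug)
    return {g: frozenset(d) for g, d in out.items()}


def individual_burden(
    calls: Sequence[PhenotypeCall], gene_drug: Sequence[GeneDrugPair]
) -> BurdenRecord:
    """Burden of one sample: nontypical gene count and at-risk drug union."""
    samples = {c.sample for c in calls}
    if len(samples) != 1:
        raise ProfilerError("individual_burden expects calls for exactly one sample")
    genes = [c.gene for c in calls]
    if len(genes) != len(set(genes)):
        raise ProfilerError(f"duplicate gene in calls for sample {samples.pop()}")
    drugs_by_gene = _drug_map(gene_drug)
    drugs: set[str] = set()
    n_nontypical = 0
    for c in calls:
        if c.nontypical:
            n_nontypical += 1
            drugs |= drugs_by_gene.get(c.gene, frozenset())
    return BurdenRecord(
        sample=calls[0].sample,
        n_nontypical_genes=n_nontypical,
        at_risk_drugs=frozenset(drugs),
    )


def cohort_summary(
    all_calls: Sequence[PhenotypeCall],
    gene_drug: Sequence[GeneDrugPair],
    risk_threshold: float = 0.40,
) -> CohortSummary:
    """Cohort-wide phenotype frequency and drug-risk summary.

    Expects a complete grid (every sample x every gene, one call each);
    per-gene phenotype counts then sum to the cohort size.
    """
    if not all_calls:
        raise ProfilerError("empty cohort")
    samples = sorted({c.sample for c in all_calls})
    n = len(samples)
    by_sample: dict[str, list[PhenotypeCall]] = {s: [] for s in samples}
    counts: dict[str, Counter] = {}
    for c in all_calls:
        by_sample[c.sample].append(c)
        counts.setdefault(c.gene, Counter())[c.phenotype] += 1
    n_calls = {s: len(v) for s, v in by_sample.items()}
    if len(set(n_calls.values())) != 1:
        raise ProfilerError("calls do not form a complete sample x gene grid")

    gene_phenotypes = {
        g: {p: (k, k / n) for p, k in per.items()} for g, per in counts.items()
    }

    burdens = [individual_burden(by_sample[s], gene_drug) for s in samples]
    n_ge1 = sum(1 for b in burdens if b.n_nontypical_genes >= 1)
    mean_drugs = sum(len(b.at_risk_drugs) for b in burdens) / n

    all_drugs = sorted({p.drug for p in gene_drug})
    drug_risk = {}
    for d in all_drugs:
        k = sum(1 for b in burdens if d in b.at_risk_drugs)
        drug_risk[d] = (k, k / n)
    over = [d for d in all_drugs if drug_risk[d][1] > risk_threshold]

    return CohortSummary(
        cohort_size=n,
        gene_phenotypes=gene_phenotypes,
        fraction_ge1=n_ge1 / n,
        mean_drugs=mean_drugs,
        drug_risk=drug_risk,
        drugs_over_threshold=over,
        risk_threshold=risk_threshold,
    )


def burden_distribution(
    all_calls: Sequence[PhenotypeCall],
    gene_drug: Sequence[GeneDrugPair],
) -> BurdenDistribution:
    """Histogram of at-risk drug counts (individuals with >= 1 drug only)."""
    samples = sorted({c.sample for c in all_calls})
    by_sample: dict[str, list[PhenotypeCall]] = {s: [] for s in samples}
    for c in all_calls:
        by_sample[c.sample].append(c)
    hist: Counter = Counter()
    for s in samples:
        b = individual_burden(by_sample[s], gene_drug)
        if b.at_risk_drugs:
            hist[len(b.at_risk_drugs)] += 1
    rows = [(k, d) for d, k in sorted(hist.items(), key=lambda t: -t[0])]
    return BurdenDistribution(rows=rows, cohort_size=len(samples))


def summarize_burden_distribution(
    dist: BurdenDistribution,
) -> tuple[int, float, float]:
    """Headline burden numbers from a (n_individuals, n_drugs) distribution.

    Returns (n individuals with >= 1 at-risk drug, that count as a
    percentage of the cohort rounded to 2 decimals, and the cohort mean
    number of at-risk drugs — individuals absent from the rows contribute
    zero drugs).
    """
    n_ge1 = sum(n for n, _ in dist.rows)
    if n_ge1 > dist.cohort_size:
        raise ProfilerError("distribution rows exceed cohort size")
    pct = round_half_up(100.0 * n_ge1 / dist.cohort_size, 2)
    mean_drugs = sum(n * d for n, d in dist.rows) / dist.cohort_size
    return n_ge1, pct, mean_drugs
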