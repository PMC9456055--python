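"""Pharmacogenetic knowledge tables.

Four plain-text tables parameterize the whole pipeline:

* **allele definitions** — for each pharmacogene, the variant sites that
  define its star alleles and the allele each star allele carries at each
  site (the PharmCAT-style exact-match definitions);
* **diplotype → phenotype map** — the CPIC phenotype label for each
  unordered star-allele pair, plus a per-(gene, phenotype) *nontypical*
  flag marking phenotypes for which CPIC guidance recommends an alternate
  dosage or drug;
* **gene–drug table** — CPIC gene/drug pairs with evidence level (A–D);
* **clinical annotations** — PharmGKB-style variant–drug annotations with
  evidence tiers 1A/1B/2A/2B (high evidence) and 3/4 (low evidence).

Nontypical status is *data*, not logic: the bundled fixture encodes which
phenotypes a published CPIC-based survey treated as nontypical, and real
exports can be swapped in through the same loaders.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import csv

__all__ = [
    "VariantSite",
    "StarAllele",
    "GeneDefinitionSet",
    "PhenotypeMap",
    "GeneDrugPair",
    "ClinicalAnnotation",
    "KnowledgeError",
    "load_allele_definitions",
    "write_allele_definitions",
    "load_phenotype_map",
    "write_phenotype_map",
    "load_gene_drug_table",
    "load_clinical_annotations",
    "is_high_evidence",
    "HIGH_EVIDENCE_LEVELS",
    "LOW_EVIDENCE_LEVELS",
    "RESERVED_PHENOTYPES",
]

#: Phenotype labels that are never nontypical: assigned when a diplotype
#: could not be called, or when the called pair has no phenotype entry.
RESERVED_PHENOTYPES = ("Not available", "Indeterminate")

HIGH_EVIDENCE_LEVELS = frozenset({"1A", "1B", "2A", "2B"})
LOW_EVIDENCE_LEVELS = frozenset({"3", "4"})
EVIDENCE_LEVELS = HIGH_EVIDENCE_LEVELS | LOW_EVIDENCE_LEVELS

CPIC_LEVELS = frozenset({"A", "B", "C", "D"})

PHENOTYPE_CATEGORIES = frozenset(
    {"Dosage", "Efficacy", "Toxicity", "Metabolism/PK", "Other"}
)


class KnowledgeError(ValueError):
    """Raised when a knowledge table violates its schema or invariants."""


@dataclass(frozen=True, order=True)
class VariantSite:
    """A biallelic genomic site, identified by (chrom, pos, ref, alt).

    Positions are 1-based as in VCF.  ``rsid`` may be empty for sites
    without a dbSNP identifier.
    """

    chrom: str
    pos: int
    rsid: str
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise KnowledgeError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise KnowledgeError(
                f"ref and alt alleles are identical at {self.chrom}:{self.pos}"
            )

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class StarAllele:
    """A named haplotype of a pharmacogene.

    ``defining`` maps each defining :class:`VariantSite` to the required
    allele string on the haplotype.  The reference star allele carries no
    requirements: it is the all-sites-reference haplotype.
    """

    gene: str
    name: str
    defining: Mapping[VariantSite, str] = field(default_factory=dict)
    is_reference: bool = False

    @property
    def n_defining(self) -> int:
        return len(self.defining)


@dataclass
class GeneDefinitionSet:
    """Star-allele definitions for a set of genes.

    ``genes`` maps gene symbol to its star alleles; ``sites`` maps gene
    symbol to the ordered list of declared variant sites for that gene.
    """

    genes: dict[str, list[StarAllele]]
    sites: dict[str, list[VariantSite]]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for gene, alleles in self.genes.items():
            names = [a.name for a in alleles]
            dup = {n for n in names if names.count(n) > 1}
            if dup:
                raise KnowledgeError(
                    f"duplicate allele name(s) {sorted(dup)} for gene {gene}"
                )
            refs = [a for a in alleles if a.is_reference]
            if len(refs) != 1:
                raise KnowledgeError(
                    f"gene {gene} must declare exactly one reference allele, "
                    f"found {len(refs)}"
                )
            declared = set(self.sites.get(gene, ()))
            seen: set[tuple[str, int, str, str]] = set()
            for site in self.sites.get(gene, ()):
                if site.key in seen:
                    raise KnowledgeError(
                        f"duplicate site {site.chrom}:{site.pos} for gene {gene}"
                    )
                seen.add(site.key)
            for allele in alleles:
                for site in allele.defining:
                    if site not in declared:
                        raise KnowledgeError(
                            f"allele {allele.name} of gene {gene} references "
                            f"undeclared site {site.chrom}:{site.pos}"
                        )

    def reference_allele(self, gene: str) -> StarAllele:
        return next(a for a in self.genes[gene] if a.is_reference)

    def gene_names(self) -> list[str]:
        return sorted(self.genes)

    def all_sites(self) -> list[VariantSite]:
        """All declared sites across genes, ordered by genomic coordinate."""
        out: list[VariantSite] = []
        for gene in sorted(self.sites):
            out.extend(self.sites[gene])
        return sorted(set(out))


def canonical_pair(
    defs: GeneDefinitionSet, gene: str, a: str, b: str
) -> tuple[str, str]:
    """Order a diplotype canonically: reference allele first, then lexicographic."""
    ref = defs.reference_allele(gene).name
    if b == ref and a != ref:
        return (b, a)
    if a == ref:
        return (a, b)
    return (a, b) if a <= b else (b, a)


# ---------------------------------------------------------------------------
# allele definitions
# ---------------------------------------------------------------------------

_DEF_HEADER = [
    "gene",
    "allele",
    "is_reference",
    "chrom",
    "pos",
    "rsid",
    "ref",
    "alt",
    "required_allele",
]


def _read_tsv(path: str | Path, expected_header: Sequence[str]) -> list[dict[str, str]]:
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or list(reader.fieldnames) != list(expected_header):
            raise KnowledgeError(
                f"{path.name}: expected header {list(expected_header)}, "
                f"got {reader.fieldnames}"
            )
        # short rows (e.g. reference-allele rows with no site columns) come
        # back with None values; coalesce them to empty strings
        return [
            {k: (v if v is not None else "") for k, v in row.items() if k is not None}
            for row in reader
        ]


def load_allele_definitions(path: str | Path) -> GeneDefinitionSet:
    """Load star-allele definitions from a TSV file.

    One row per (allele, defining site); the reference allele of each gene
    appears as a single row with empty site columns.  Declared sites of a
    gene are the union of sites across its alleles, ordered by coordinate.
    """
    rows = _read_tsv(path, _DEF_HEADER)
    alleles: dict[str, dict[str, dict]] = {}  # gene -> name -> {is_ref, defining}
    gene_sites: dict[str, dict[tuple, VariantSite]] = {}
    for i, row in enumerate(rows, start=2):
        gene = row["gene"].strip()
        name = row["allele"].strip()
        if not gene or not name:
            raise KnowledgeError(f"line {i}: empty gene or allele name")
        is_ref = row["is_reference"].strip() in {"1", "true", "True"}
        rec = alleles.setdefault(gene, {}).get(name)
        if rec is None:
            rec = {"is_reference": is_ref, "defining": {}}
            alleles[gene][name] = rec
        elif rec["is_reference"] != is_ref:
            raise KnowledgeError(
                f"line {i}: allele {name} of gene {gene} re-declared with a "
                f"different is_reference value"
            )
        if row["chrom"].strip():
            site = VariantSite(
                chrom=row["chrom"].strip(),
                pos=int(row["pos"]),
                rsid=row["rsid"].strip(),
                ref=row["ref"].strip(),
                alt=row["alt"].strip(),
            )
            if site in rec["defining"]:
                raise KnowledgeError(
                    f"line {i}: duplicate allele definition row for {name} of "
                    f"gene {gene} at {site.chrom}:{site.pos}"
                )
            required = row["required_allele"].strip()
            if required not in (site.ref, site.alt):
                raise KnowledgeError(
                    f"line {i}: required allele {required!r} is neither ref nor "
                    f"alt of {site.chrom}:{site.pos}"
                )
            rec["defining"][site] = required
            gene_sites.setdefault(gene, {})[site.key] = site
        elif rec["defining"]:
            raise KnowledgeError(
                f"line {i}: duplicate site-free row for allele {name} of gene {gene}"
            )
    genes = {
        gene: [
            StarAllele(
                gene=gene,
                name=name,
                defining=dict(rec["defining"]),
                is_reference=rec["is_reference"],
            )
            for name, rec in sorted(per_gene.items())
        ]
        for gene, per_gene in alleles.items()
    }
    sites = {
        gene: sorted(gene_sites.get(gene, {}).values())
        for gene in genes
    }
    return GeneDefinitionSet(genes=genes, sites=sites)


def write_allele_definitions(defs: GeneDefinitionSet, path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_DEF_HEADER)
        for gene in sorted(defs.genes):
            for allele in defs.genes[gene]:
                flag = "1" if allele.is_reference else "0"
                if not allele.defining:
                    w.writerow([gene, allele.name, flag, "", "", "", "", "", ""])
                    continue
                for site, req in sorted(allele.defining.items()):
                    w.writerow(
                        [gene, allele.name, flag, site.chrom, site.pos,
                         site.rsid, site.ref, site.alt, req]
                    )


# ---------------------------------------------------------------------------
# diplotype -> phenotype map
# ---------------------------------------------------------------------------


@dataclass
class PhenotypeMap:
    """Unordered diplotype → phenotype map with nontypical flags.

    Lookups are symmetric in the allele pair.  The reserved labels
    ``"Not available"`` and ``"Indeterminate"`` are always typical
    (nontypical = False), whether or not the flag table lists them.
    """

    entries: dict[tuple[str, tuple[str, str]], str]
    nontypical: dict[tuple[str, str], bool]

    def __post_init__(self) -> None:
        for (gene, label), flag in self.nontypical.items():
            if label in RESERVED_PHENOTYPES and flag:
                raise KnowledgeError(
                    f"reserved phenotype {label!r} may not be nontypical "
                    f"(gene {gene})"
                )
        for (gene, _pair), label in self.entries.items():
            if label in RESERVED_PHENOTYPES:
                continue
            if (gene, label) not in self.nontypical:
                raise KnowledgeError(
                    f"phenotype {label!r} of gene {gene} has no nontypical flag"
                )

    @staticmethod
    def _key(gene: str, a: str, b: str) -> tuple[str, tuple[str, str]]:
        return (gene, tuple(sorted((a, b))))  # type: ignore[return-value]

    def lookup(self, gene: str, a: str, b: str) -> str | None:
        return self.entries.get(self._key(gene, a, b))

    def is_nontypical(self, gene: str, phenotype: str) -> bool:
        if phenotype in RESERVED_PHENOTYPES:
            return False
        return self.nontypical[(gene, phenotype)]

    def genes(self) -> set[str]:
        return {gene for gene, _ in self.entries}


_MAP_HEADER = ["gene", "allele1", "allele2", "phenotype"]
_FLAG_HEADER = ["gene", "phenotype", "nontypical"]


def load_phenotype_map(path: str | Path, flags_path: str | Path) -> PhenotypeMap:
    """Load the diplotype→phenotype table and its nontypical flag table."""
    entries: dict[tuple[str, tuple[str, str]], str] = {}
    for i, row in enumerate(_read_tsv(path, _MAP_HEADER), start=2):
        gene = row["gene"].strip()
        a, b = row["allele1"].strip(), row["allele2"].strip()
        label = row["phenotype"].strip()
        if not (gene and a and b and label):
            raise KnowledgeError(f"{Path(path).name} line {i}: malformed pair row")
        key = PhenotypeMap._key(gene, a, b)
        if key in entries and entries[key] != label:
            raise KnowledgeError(
                f"{Path(path).name} line {i}: conflicting phenotype for "
                f"{gene} {a}/{b}"
            )
        entries[key] = label
    flags: dict[tuple[str, str], bool] = {}
    for i, row in enumerate(_read_tsv(flags_path, _FLAG_HEADER), start=2):
        gene = row["gene"].strip()
        label = row["phenotype"].strip()
        raw = row["nontypical"].strip()
        if raw not in {"0", "1"}:
            raise KnowledgeError(
                f"{Path(flags_path).name} line {i}: nontypical must be 0/1"
            )
        flags[(gene, label)] = raw == "1"
    return PhenotypeMap(entries=entries, nontypical=flags)


def write_phenotype_map(
    pmap: PhenotypeMap, path: str | Path, flags_path: str | Path
) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_MAP_HEADER)
        for (gene, (a, b)), label in sorted(pmap.entries.items()):
            w.writerow([gene, a, b, label])
    with Path(flags_path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_FLAG_HEADER)
        for (gene, label), flag in sorted(pmap.nontypical.items()):
            w.writerow([gene, label, "1" if flag else "0"])


# ---------------------------------------------------------------------------
# gene-drug table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneDrugPair:
    gene: str
    drug: str
    cpic_level: str


_GD_HEADER = ["gene", "drug", "cpic_level"]


def load_gene_drug_table(
    path: str | Path, level_filter: Iterable[str] = frozenset({"A"})
) -> list[GeneDrugPair]:
    """Load CPIC gene–drug pairs, keeping only the requested evidence levels.

    Drug names are normalized (trimmed, lower-cased) so that the same drug
    listed under two genes is counted once in drug-set unions; pairs are
    deduplicated on (gene, drug).
    """
    level_filter = set(level_filter)
    out: list[GeneDrugPair] = []
    seen: set[tuple[str, str]] = set()
    for i, row in enumerate(_read_tsv(path, _GD_HEADER), start=2):
        level = row["cpic_level"].strip()
        if level not in CPIC_LEVELS:
            raise KnowledgeError(
                f"{Path(path).name} line {i}: unknown CPIC level {level!r}"
            )
        if level not in level_filter:
            continue
        gene = row["gene"].strip()
        drug = row["drug"].strip().lower()
        if (gene, drug) in seen:
            continue
        seen.add((gene, drug))
        out.append(GeneDrugPair(gene=gene, drug=drug, cpic_level=level))
    return out


# ---------------------------------------------------------------------------
# clinical annotations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClinicalAnnotation:
    """A variant–drug clinical annotation with a PharmGKB-style evidence tier."""

    annotation_id: str
    rsid: str
    gene: str
    evidence_level: str
    phenotype_category: str
    drugs: tuple[str, ...]
    pediatric: bool

    @property
    def high_evidence(self) -> bool:
        return self.evidence_level in HIGH_EVIDENCE_LEVELS


def is_high_evidence(level: str) -> bool:
    """True iff the evidence tier is one of 1A/1B/2A/2B."""
    if level not in EVIDENCE_LEVELS:
        raise KnowledgeError(f"unknown evidence level {level!r}")
    return level in HIGH_EVIDENCE_LEVELS


_ANN_HEADER = [
    "annotation_id",
    "rsid",
    "gene",
    "evidence_level",
    "phenotype_category",
    "drugs",
    "pediatric",
]


def load_clinical_annotations(path: str | Path) -> list[ClinicalAnnotation]:
    out: list[ClinicalAnnotation] = []
    for i, row in enumerate(_read_tsv(path, _ANN_HEADER), start=2):
        level = row["evidence_level"].strip()
        if level not in EVIDENCE_LEVELS:
            raise KnowledgeError(
                f"{Path(path).name} line {i}: evidence level {level!r} not in "
                f"{sorted(EVIDENCE_LEVELS)}"
            )
        category = row["phenotype_category"].strip()
        if category not in PHENOTYPE_CATEGORIES:
            raise KnowledgeError(
                f"{Path(path).name} line {i}: unknown phenotype category "
                f"{category!r}"
            )
        pediatric = row["pediatric"].strip()
        if pediatric not in {"0", "1"}:
            raise KnowledgeError(
                f"{Path(path).name} line {i}: pediatric must be 0/1"
            )
        drugs = tuple(
            d.strip().lower() for d in row["drugs"].split(";") if d.strip()
        )
        out.append(
            ClinicalAnnotation(
                annotation_id=row["annotation_id"].strip(),
                rsid=row["rsid"].strip(),
                gene=row["gene"].strip(),
                evidence_level=level,
                phenotype_category=category,
                drugs=drugs,
                pediatric=pediatric == "1",
            )
        )
    return out
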