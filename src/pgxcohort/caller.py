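"""Star-allele diplotype calling by exact haplotype matching.

A star allele matches a phased haplotype iff every one of its defining
sites is observed and carries the required allele, *and* every other
declared site of the gene that is observed carries the reference allele.
The reference star allele therefore matches exactly the all-observed-
reference haplotype.  Any missing declared site makes the haplotype
incomplete and the diplotype ``not_available`` — no fuzzy or partial
matching is attempted, mirroring exact-match engines.

Structural variants and copy number are not modeled; genes whose alleles
require them (notably CYP2D6) inherit that limitation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort import MISSING, CohortGenotypes
from .knowledge import GeneDefinitionSet, canonical_pair

__all__ = [
    "HaplotypeMatch",
    "DiplotypeCall",
    "match_haplotype",
    "call_diplotype",
    "call_cohort",
    "diplotype_frequency_table",
    "CallerError",
]

logger = logging.getLogger(__name__)


class CallerError(ValueError):
    pass


@dataclass(frozen=True)
class HaplotypeMatch:
    gene: str
    haplotype_index: int
    #: star alleles matching the haplotype, best first (most defining sites
    #: satisfied, then lexicographic name)
    matched_alleles: tuple[str, ...]
    #: per matched allele, how many of its defining sites were satisfied
    n_defining_matched: tuple[int, ...]
    #: True iff every declared site of the gene was observed
    complete: bool


@dataclass(frozen=True)
class DiplotypeCall:
    sample: str
    gene: str
    #: canonical ordered pair (reference first, then lexicographic); empty
    #: unless status == "called"
    allele_pair: tuple[str, str] | tuple[()]
    status: str  # called | not_available | ambiguous

    def __post_init__(self) -> None:
        if (self.status == "called") != bool(self.allele_pair):
            raise CallerError("allele_pair must be set iff status == 'called'")


def match_haplotype(
    haplotype: Sequence[int],
    gene: str,
    defs: GeneDefinitionSet,
    haplotype_index: int = 0,
) -> HaplotypeMatch:
    """Match one haplotype against a gene's star-allele definitions.

    ``haplotype`` holds allele codes (0 ref / 1 alt / -1 missing) over the
    gene's declared site list, in declared order.
    """
    sites = defs.sites[gene]
    if len(haplotype) != len(sites):
        raise CallerError(
            f"haplotype length {len(haplotype)} != {len(sites)} declared sites "
            f"of gene {gene}"
        )
    codes = {site: int(c) for site, c in zip(sites, haplotype)}
    complete = all(c != MISSING for c in codes.values())

    matched: list[tuple[str, int]] = []
    for allele in defs.genes[gene]:
        ok = True
        n_sat = 0
        for site, required in allele.defining.items():
            code = codes[site]
            want = 1 if required == site.alt else 0
            if code == MISSING or code != want:
                ok = False
                break
            n_sat += 1
        if not ok:
            continue
        # all other observed sites must be reference
        defining_sites = set(allele.defining)
        for site, code in codes.items():
            if site in defining_sites or code == MISSING:
                continue
            if code != 0:
                ok = False
                break
        if ok:
            matched.append((allele.name, n_sat))

    matched.sort(key=lambda t: (-t[1], t[0]))
    return HaplotypeMatch(
        gene=gene,
        haplotype_index=haplotype_index,
        matched_alleles=tuple(n for n, _ in matched),
        n_defining_matched=tuple(k for _, k in matched),
        complete=complete,
    )


def _best_allele(match: HaplotypeMatch, defs: GeneDefinitionSet) -> str | None:
    """Resolve a haplotype's match to one allele, or None if ambiguous.

    Alleles tying at the maximal number of satisfied defining sites cannot
    be distinguished by the exact-match rule and yield an ambiguous call.
    """
    if not match.matched_alleles:
        return None
    if len(match.matched_alleles) == 1:
        return match.matched_alleles[0]
    best = match.n_defining_matched[0]
    ties = [
        a for a, k in zip(match.matched_alleles, match.n_defining_matched) if k == best
    ]
    return ties[0] if len(ties) == 1 else None


def call_diplotype(
    sample: str,
    gene: str,
    hap_pair: tuple[Sequence[int], Sequence[int]],
    defs: GeneDefinitionSet,
) -> DiplotypeCall:
    """Combine the two phased haplotypes of a sample into a diplotype call.

    The call is invariant under swapping the two haplotypes; the emitted
    pair is in canonical order (reference allele first, then lexicographic).
    """
    matches = [
        match_haplotype(h, gene, defs, haplotype_index=i)
        for i, h in enumerate(hap_pair)
    ]
    if not all(m.complete for m in matches):
        return DiplotypeCall(sample=sample, gene=gene, allele_pair=(), status="not_available")
    if any(not m.matched_alleles for m in matches):
        return DiplotypeCall(sample=sample, gene=gene, allele_pair=(), status="not_available")
    resolved = [_best_allele(m, defs) for m in matches]
    if any(r is None for r in resolved):
        return DiplotypeCall(sample=sample, gene=gene, allele_pair=(), status="ambiguous")
    pair = canonical_pair(defs, gene, resolved[0], resolved[1])
    return DiplotypeCall(sample=sample, gene=gene, allele_pair=pair, status="called")


def call_cohort(
    cohort: CohortGenotypes, defs: GeneDefinitionSet
) -> list[DiplotypeCall]:
    """Call every sample at every gene of the definition set.

    Defining sites absent from the cohort are treated as missing for all
    samples; a gene with zero sites present yields ``not_available`` calls
    for the whole cohort (logged as a warning, not an error).
    """
    index = cohort.marker_index()
    calls: list[DiplotypeCall] = []
    for gene in defs.gene_names():
        sites = defs.sites[gene]
        cols = [index.get(s.key) for s in sites]
        if sites and all(c is None for c in cols):
            logger.warning("gene %s: no defining sites present in cohort", gene)
        n = cohort.n_samples
        # (n, n_sites, 2) gene-local haplotype codes, missing where absent
        local = np.full((n, len(sites), 2), MISSING, dtype=np.int8)
        for k, c in enumerate(cols):
            if c is not None:
                local[:, k, :] = cohort.haplotypes[:, c, :]
        for i, sample in enumerate(cohort.samples):
            calls.append(
                call_diplotype(
                    sample, gene, (local[i, :, 0], local[i, :, 1]), defs
                )
            )
    return calls


def diplotype_frequency_table(calls: Iterable[DiplotypeCall]) -> pd.DataFrame:
    """Per-gene diplotype counts and frequencies (``status`` rows included).

    Frequencies are relative to the number of samples called for the gene,
    so per gene the counts sum to the cohort size.
    """
    rows = []
    for c in calls:
        label = "/".join(c.allele_pair) if c.allele_pair else c.status
        rows.append({"gene": c.gene, "diplotype": label})
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["gene", "diplotype"]).size().rename("count").reset_index()
    )
    totals = out.groupby("gene")["count"].transform("sum")
    out["frequency"] = out["count"] / totals
    return out.sort_values(["gene", "count"], ascending=[True, False]).reset_index(drop=True)
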