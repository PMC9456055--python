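"""Synthetic phased cohorts with known star-allele truth.

The generator emulates the statistical structure of a phased, imputed
population cohort: per gene, the two haplotypes of each sample are drawn
i.i.d. from a star-allele frequency table (Hardy–Weinberg), rendered to
site-level alleles through the allele definitions, and then degraded with
per-genotype missingness and (heterozygote-only) unphasing.  Designated
variant pairs can be locked to perfect correlation (r^2 = 1), mirroring
tightly linked regulatory variants.  Trio samples transmit one whole-gene
haplotype per parent, so parent–offspring pairs have expected IBD
proportion 0.5 by construction.

No background LD, demography or imputation-error model is simulated
beyond these knobs; the truth table records every sample's drawn
diplotype before degradation, which is what recovery tests compare
against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .cohort import MISSING, CohortGenotypes, _build_markers, write_phased_cohort
from .knowledge import GeneDefinitionSet, PhenotypeMap, VariantSite, canonical_pair
from .profiler import PhenotypeCall
from .relatedness import PedigreeInfo

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "SimulationError",
    "simulate_cohort",
    "simulate_trios",
    "simulate_marker_panel",
    "build_table2_cohort",
]


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    n_samples: int
    seed: int
    #: gene -> star allele -> haplotype frequency (sums to 1 per gene)
    haplotype_freqs: Mapping[str, Mapping[str, float]]
    missingness_rate: float = 0.0
    unphase_rate: float = 0.0
    trio_count: int = 0
    #: rsid pairs forced to identical ALT carriage on every haplotype
    ld_locked_pairs: Sequence[tuple[str, str]] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for gene, freqs in self.haplotype_freqs.items():
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-9:
                raise SimulationError(
                    f"haplotype frequencies for {gene} sum to {total}, not 1"
                )
        for rate, name in ((self.missingness_rate, "missingness_rate"),
                           (self.unphase_rate, "unphase_rate")):
            if not 0.0 <= rate <= 1.0:
                raise SimulationError(f"{name} must lie in [0, 1]")


@dataclass
class TruthTable:
    #: (sample, gene) -> canonical star-allele pair drawn for that sample
    diplotypes: dict[tuple[str, str], tuple[str, str]]
    #: site key -> theoretical ALT frequency implied by the haplotype table
    site_alt_freq: dict[tuple[str, int, str, str], float]

    def concordance(self, calls) -> float:
        """Fraction of `called` diplotypes equal to the truth (1.0 = perfect)."""
        called = [c for c in calls if c.status == "called"]
        if not called:
            return float("nan")
        ok = sum(
            1 for c in called if self.diplotypes[(c.sample, c.gene)] == c.allele_pair
        )
        return ok / len(called)


def _allele_rendering(defs: GeneDefinitionSet, gene: str) -> dict[str, np.ndarray]:
    """Per star allele, the 0/1 site-code vector over the gene's site list."""
    sites = defs.sites[gene]
    out = {}
    for allele in defs.genes[gene]:
        codes = np.zeros(len(sites), dtype=np.int8)
        for k, site in enumerate(sites):
            req = allele.defining.get(site)
            if req is not None and req == site.alt:
                codes[k] = 1
        out[allele.name] = codes
    return out


def _theoretical_site_freqs(
    defs: GeneDefinitionSet, freqs: Mapping[str, Mapping[str, float]]
) -> dict[tuple[str, int, str, str], float]:
    out: dict[tuple[str, int, str, str], float] = {}
    for gene, table in freqs.items():
        rendering = _allele_rendering(defs, gene)
        for k, site in enumerate(defs.sites[gene]):
            out[site.key] = sum(
                f for name, f in table.items() if rendering[name][k] == 1
            )
    return out


def _draw_gene_haplotypes(
    rng: np.random.Generator,
    defs: GeneDefinitionSet,
    config: SimulationConfig,
    sample_names: Sequence[str],
) -> tuple[
    np.ndarray,
    list[VariantSite],
    dict[tuple[str, str], tuple[str, str]],
    dict[tuple[str, str], tuple[str, str]],
]:
    """Draw diplotypes for all genes and render them to site codes.

    Returns the haplotype codes, the site list, the canonical truth pairs,
    and the draw-ordered pairs (haplotype 0 / haplotype 1), which trio
    transmission needs to stay consistent with the rendered codes.
    """
    genes = sorted(config.haplotype_freqs)
    for gene in genes:
        if gene not in defs.genes:
            raise SimulationError(f"frequency table references unknown gene {gene}")
        for name in config.haplotype_freqs[gene]:
            if all(a.name != name for a in defs.genes[gene]):
                raise SimulationError(
                    f"frequency for unknown allele {name} of gene {gene}"
                )
    n = len(sample_names)
    all_sites: list[VariantSite] = []
    blocks: list[np.ndarray] = []
    truth: dict[tuple[str, str], tuple[str, str]] = {}
    drawn: dict[tuple[str, str], tuple[str, str]] = {}
    for gene in genes:
        table = config.haplotype_freqs[gene]
        names = sorted(table)
        probs = np.array([table[a] for a in names])
        draws = rng.choice(len(names), size=(n, 2), p=probs / probs.sum())
        rendering = _allele_rendering(defs, gene)
        sites = defs.sites[gene]
        block = np.zeros((n, len(sites), 2), dtype=np.int8)
        for i, sample in enumerate(sample_names):
            a, b = names[draws[i, 0]], names[draws[i, 1]]
            truth[(sample, gene)] = canonical_pair(defs, gene, a, b)
            drawn[(sample, gene)] = (a, b)
            block[i, :, 0] = rendering[a]
            block[i, :, 1] = rendering[b]
        all_sites.extend(sites)
        blocks.append(block)
    hap = np.concatenate(blocks, axis=1) if blocks else np.zeros((n, 0, 2), dtype=np.int8)
    return hap, all_sites, truth, drawn


def _apply_ld_locks(
    hap: np.ndarray, sites: Sequence[VariantSite], pairs: Sequence[tuple[str, str]]
) -> None:
    by_rsid = {s.rsid: k for k, s in enumerate(sites) if s.rsid}
    for a, b in pairs:
        if a not in by_rsid or b not in by_rsid:
            raise SimulationError(f"ld-locked pair ({a}, {b}) not among simulated sites")
        hap[:, by_rsid[b], :] = hap[:, by_rsid[a], :]


def _degrade(
    rng: np.random.Generator,
    hap: np.ndarray,
    missingness: float,
    unphase: float,
) -> tuple[np.ndarray, np.ndarray]:
    n, m, _ = hap.shape
    phased = np.ones((n, m), dtype=bool)
    if missingness > 0:
        drop = rng.random((n, m)) < missingness
        hap[drop] = MISSING
    if unphase > 0:
        het = hap[:, :, 0] != hap[:, :, 1]
        het &= (hap != MISSING).all(axis=2)
        flip = (rng.random((n, m)) < unphase) & het
        phased[flip] = False
    return hap, phased


def _finalize(
    sample_names: list[str],
    hap: np.ndarray,
    phased: np.ndarray,
    sites: Sequence[VariantSite],
    out_vcf: str | Path | None,
    seed: int,
) -> CohortGenotypes:
    markers = _build_markers(sites, [None] * len(sites), hap)
    cohort = CohortGenotypes(
        samples=sample_names, markers=markers, haplotypes=hap, phased=phased
    )
    if out_vcf is not None:
        write_phased_cohort(
            cohort, out_vcf, header_comments=[f"pgxcohort_simulation_seed={seed}"]
        )
    return cohort


def simulate_cohort(
    config: SimulationConfig,
    defs: GeneDefinitionSet,
    out_vcf: str | Path | None = None,
) -> tuple[CohortGenotypes, TruthTable]:
    """Simulate an unrelated phased cohort under Hardy–Weinberg.

    Deterministic under a fixed seed; the seed is recorded in the VCF
    header when a path is given.
    """
    rng = np.random.default_rng(config.seed)
    names = [f"S{i + 1:05d}" for i in range(config.n_samples)]
    hap, sites, truth, _ = _draw_gene_haplotypes(rng, defs, config, names)
    _apply_ld_locks(hap, sites, config.ld_locked_pairs)
    hap, phased = _degrade(rng, hap, config.missingness_rate, config.unphase_rate)
    cohort = _finalize(names, hap, phased, sites, out_vcf, config.seed)
    return cohort, TruthTable(
        diplotypes=truth,
        site_alt_freq=_theoretical_site_freqs(defs, config.haplotype_freqs),
    )


def simulate_trios(
    config: SimulationConfig,
    defs: GeneDefinitionSet,
    out_vcf: str | Path | None = None,
) -> tuple[CohortGenotypes, TruthTable, PedigreeInfo]:
    """Simulate ``n_samples`` unrelated individuals plus ``trio_count`` trios.

    Parents are drawn like unrelated samples; each child receives one
    whole-gene haplotype from each parent (uniformly chosen), so a child's
    haplotypes are each identical to one parental haplotype.
    """
    if config.trio_count < 1:
        raise SimulationError("trio_count must be >= 1 for simulate_trios")
    rng = np.random.default_rng(config.seed)
    unrelated = [f"S{i + 1:05d}" for i in range(config.n_samples)]
    fathers = [f"F{k + 1:04d}" for k in range(config.trio_count)]
    mothers = [f"M{k + 1:04d}" for k in range(config.trio_count)]
    children = [f"C{k + 1:04d}" for k in range(config.trio_count)]
    founders = unrelated + fathers + mothers
    hap, sites, truth, drawn = _draw_gene_haplotypes(rng, defs, config, founders)

    genes = sorted(config.haplotype_freqs)
    site_slices: dict[str, slice] = {}
    offset = 0
    for gene in genes:
        k = len(defs.sites[gene])
        site_slices[gene] = slice(offset, offset + k)
        offset += k

    child_blocks = np.zeros((config.trio_count, hap.shape[1], 2), dtype=np.int8)
    names = founders + children
    for t, child in enumerate(children):
        fi = founders.index(fathers[t])
        mi = founders.index(mothers[t])
        for gene in genes:
            sl = site_slices[gene]
            fh = int(rng.integers(2))
            mh = int(rng.integers(2))
            child_blocks[t, sl, 0] = hap[fi, sl, fh]
            child_blocks[t, sl, 1] = hap[mi, sl, mh]
            # transmitted allele names come from the draw-ordered pairs so
            # they stay aligned with the copied haplotype codes
            truth[(child, gene)] = canonical_pair(
                defs, gene, drawn[(fathers[t], gene)][fh], drawn[(mothers[t], gene)][mh]
            )
    hap = np.concatenate([hap, child_blocks], axis=0)
    _apply_ld_locks(hap, sites, config.ld_locked_pairs)
    hap, phased = _degrade(rng, hap, config.missingness_rate, config.unphase_rate)
    cohort = _finalize(names, hap, phased, sites, out_vcf, config.seed)
    ped = PedigreeInfo(trios=list(zip(fathers, mothers, children)))
    return (
        cohort,
        TruthTable(
            diplotypes=truth,
            site_alt_freq=_theoretical_site_freqs(defs, config.haplotype_freqs),
        ),
        ped,
    )


def simulate_marker_panel(
    n_unrelated: int,
    n_trios: int,
    n_markers: int,
    seed: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
) -> tuple[CohortGenotypes, PedigreeInfo]:
    """Unlinked genome-wide SNP panel for relatedness estimation.

    Founder haplotypes are independent Bernoulli draws at per-marker ALT
    frequencies uniform over ``maf_range``; trio children inherit one
    allele per marker from each parent (a recombining mosaic, which leaves
    pairwise IBD sharing exact: one allele IBD with each parent
    everywhere).
    """
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(*maf_range, size=n_markers)
    unrelated = [f"S{i + 1:05d}" for i in range(n_unrelated)]
    fathers = [f"F{k + 1:04d}" for k in range(n_trios)]
    mothers = [f"M{k + 1:04d}" for k in range(n_trios)]
    children = [f"C{k + 1:04d}" for k in range(n_trios)]
    founders = unrelated + fathers + mothers
    hap = (rng.random((len(founders), n_markers, 2)) < freqs[None, :, None]).astype(np.int8)
    child_hap = np.zeros((n_trios, n_markers, 2), dtype=np.int8)
    for t in range(n_trios):
        fi = founders.index(fathers[t])
        mi = founders.index(mothers[t])
        pick_f = rng.integers(2, size=n_markers)
        pick_m = rng.integers(2, size=n_markers)
        child_hap[t, :, 0] = hap[fi, np.arange(n_markers), pick_f]
        child_hap[t, :, 1] = hap[mi, np.arange(n_markers), pick_m]
    hap = np.concatenate([hap, child_hap], axis=0)
    names = founders + children
    sites = [
        VariantSite(chrom="1", pos=10_000 + 100 * j, rsid=f"sim{j}", ref="A", alt="G")
        for j in range(n_markers)
    ]
    phased = np.ones((len(names), n_markers), dtype=bool)
    markers = _build_markers(sites, [None] * n_markers, hap)
    cohort = CohortGenotypes(samples=names, markers=markers, haplotypes=hap, phased=phased)
    return cohort, PedigreeInfo(trios=list(zip(fathers, mothers, children)))


def build_table2_cohort(
    target_counts: Mapping[str, Mapping[str, int]],
    defs: GeneDefinitionSet,
    pmap: PhenotypeMap,
) -> list[PhenotypeCall]:
    """Deterministic phenotype-call cohort reproducing per-gene marginal counts.

    ``target_counts`` maps gene -> phenotype label -> count; counts must sum
    to the same cohort size for every gene.  Labels are dealt to sample
    identifiers S00001.. in sorted label order, which reproduces the target
    marginals exactly (the joint distribution across genes is arbitrary and
    irrelevant to marginal summaries).
    """
    sizes = {g: sum(per.values()) for g, per in target_counts.items()}
    if len(set(sizes.values())) != 1:
        raise SimulationError(f"per-gene counts sum to different cohort sizes: {sizes}")
    n = next(iter(sizes.values()))
    samples = [f"S{i + 1:05d}" for i in range(n)]
    calls: list[PhenotypeCall] = []
    for gene in sorted(target_counts):
        cursor = 0
        for label in sorted(target_counts[gene]):
            count = target_counts[gene][label]
            if count < 0:
                raise SimulationError(f"negative count for {gene}/{label}")
            flag = pmap.is_nontypical(gene, label) if (
                label in ("Not available", "Indeterminate")
                or (gene, label) in pmap.nontypical
            ) else False
            for s in samples[cursor : cursor + count]:
                calls.append(PhenotypeCall(sample=s, gene=gene, phenotype=label, nontypical=flag))
            cursor += count
    return calls
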