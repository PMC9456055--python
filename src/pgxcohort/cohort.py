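"""Phased cohort genotypes: VCF I/O, marker quality filtering, allele frequencies.

The in-memory container is :class:`CohortGenotypes`, a (sample x site x 2)
haplotype matrix with per-site metadata.  Only biallelic records and the GT
subfield are interpreted; imputation quality is read from a configurable
INFO key (``RSQR`` by default, the Minimac dosage-r2 metric) and missing
quality marks a directly genotyped marker.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .knowledge import VariantSite

__all__ = [
    "MarkerRecord",
    "CohortGenotypes",
    "CohortError",
    "read_phased_cohort",
    "write_phased_cohort",
    "filter_markers_by_quality",
    "estimate_allele_frequencies",
]

MISSING = -1  # haplotype allele code for a missing call


class CohortError(ValueError):
    """Raised on malformed or unusable genotype input."""


@dataclass(frozen=True)
class MarkerRecord:
    """Per-site metadata: the site itself, imputation quality and frequencies.

    ``imputation_quality`` is None for directly genotyped markers.  ``maf``
    is always ``min(alt_freq, 1 - alt_freq)``; both are NaN when every
    genotype at the site is missing.
    """

    site: VariantSite
    imputation_quality: float | None
    alt_freq: float
    maf: float


@dataclass
class CohortGenotypes:
    """Phased diploid genotypes for a cohort.

    ``haplotypes`` has shape (n_samples, n_markers, 2) with codes
    0 = ref, 1 = alt, -1 = missing; a genotype with any missing allele is
    missing as a unit.  ``phased`` flags each genotype; homozygotes are
    always treated as phased (phase carries no information there).
    """

    samples: list[str]
    markers: list[MarkerRecord]
    haplotypes: np.ndarray
    phased: np.ndarray

    def __post_init__(self) -> None:
        n, m = len(self.samples), len(self.markers)
        if self.haplotypes.shape != (n, m, 2):
            raise CohortError(
                f"haplotype matrix shape {self.haplotypes.shape} does not match "
                f"{n} samples x {m} markers"
            )
        if self.phased.shape != (n, m):
            raise CohortError("phased matrix shape mismatch")
        if not np.isin(self.haplotypes, (-1, 0, 1)).all():
            raise CohortError("allele codes must be in {0, 1, -1}")
        # a half-missing genotype is missing as a unit
        half = (self.haplotypes == MISSING).sum(axis=2) == 1
        if half.any():
            raise CohortError("genotypes with exactly one missing allele found")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def sample_index(self, sample: str) -> int:
        return self.samples.index(sample)

    def marker_index(self) -> dict[tuple[str, int, str, str], int]:
        return {m.site.key: i for i, m in enumerate(self.markers)}

    def dosage(self) -> np.ndarray:
        """(n_samples, n_markers) ALT dosage in {0,1,2}; NaN where missing."""
        h = self.haplotypes.astype(float)
        h[h == MISSING] = np.nan
        return h.sum(axis=2)


def _alt_freq(hap_column: np.ndarray) -> tuple[float, float]:
    valid = hap_column != MISSING
    n = int(valid.sum())
    if n == 0:
        return float("nan"), float("nan")
    af = float(hap_column[valid].sum()) / n
    return af, min(af, 1.0 - af)


def _build_markers(
    sites: Sequence[VariantSite],
    quality: Sequence[float | None],
    haplotypes: np.ndarray,
) -> list[MarkerRecord]:
    markers = []
    for j, (site, q) in enumerate(zip(sites, quality)):
        af, maf = _alt_freq(haplotypes[:, j, :].ravel())
        markers.append(MarkerRecord(site=site, imputation_quality=q, alt_freq=af, maf=maf))
    return markers


def read_phased_cohort(
    vcf_path: str | Path,
    region_set: Sequence[tuple[str, int, int]] | None = None,
    *,
    quality_key: str = "RSQR",
    require_phase: bool = True,
    on_multiallelic: str = "reject",
    on_unphased_het: str = "error",
) -> CohortGenotypes:
    """Read a phased multi-sample VCF into a :class:`CohortGenotypes`.

    Parameters
    ----------
    region_set
        Optional list of (chrom, start, end) 1-based inclusive intervals;
        records outside every interval are skipped.
    quality_key
        INFO key holding the imputation quality; an absent key marks the
        marker as directly genotyped.
    on_multiallelic
        ``"reject"`` (default) raises on multiallelic records; ``"skip"``
        drops them with a warning.
    on_unphased_het
        When ``require_phase`` is true, what to do with an unphased
        heterozygote: ``"error"`` (default) or ``"missing"`` (set the
        genotype missing).  Homozygotes are accepted regardless of the
        phase separator.
    """
    if on_multiallelic not in {"reject", "skip"}:
        raise CohortError(f"unknown multiallelic policy {on_multiallelic!r}")
    if on_unphased_het not in {"error", "missing"}:
        raise CohortError(f"unknown unphased-het policy {on_unphased_het!r}")

    sites: list[VariantSite] = []
    quality: list[float | None] = []
    hap_rows: list[np.ndarray] = []
    phased_rows: list[np.ndarray] = []

    with pysam.VariantFile(str(vcf_path)) as vcf:
        if "GT" not in vcf.header.formats:
            raise CohortError(f"{vcf_path}: VCF has no GT FORMAT field")
        samples = list(vcf.header.samples)
        for rec in vcf:
            if region_set is not None and not any(
                rec.contig == c and s <= rec.pos <= e for c, s, e in region_set
            ):
                continue
            alts = rec.alts or ()
            if len(alts) != 1:
                if on_multiallelic == "reject":
                    raise CohortError(
                        f"multiallelic record at {rec.contig}:{rec.pos} "
                        f"(alts={alts}); split it upstream or pass "
                        f"on_multiallelic='skip'"
                    )
                warnings.warn(
                    f"skipping multiallelic record at {rec.contig}:{rec.pos}"
                )
                continue
            site = VariantSite(
                chrom=rec.contig,
                pos=rec.pos,
                rsid=rec.id or "",
                ref=rec.ref,
                alt=alts[0],
            )
            q = rec.info.get(quality_key)
            if isinstance(q, tuple):
                q = q[0]
            hap = np.full((len(samples), 2), MISSING, dtype=np.int8)
            ph = np.zeros(len(samples), dtype=bool)
            for i, s in enumerate(samples):
                call = rec.samples[s]
                gt = call.get("GT")
                if gt is None or len(gt) != 2 or any(a is None for a in gt):
                    continue  # missing genotype
                a, b = int(gt[0]), int(gt[1])
                is_het = a != b
                is_phased = bool(call.phased) or not is_het
                if is_het and not call.phased and require_phase:
                    if on_unphased_het == "error":
                        raise CohortError(
                            f"unphased heterozygote for sample {s} at "
                            f"{rec.contig}:{rec.pos}"
                        )
                    continue  # leave missing
                hap[i] = (a, b)
                ph[i] = is_phased
            sites.append(site)
            quality.append(float(q) if q is not None else None)
            hap_rows.append(hap)
            phased_rows.append(ph)

    if not sites:
        haplotypes = np.empty((len(samples), 0, 2), dtype=np.int8)
        phased = np.empty((len(samples), 0), dtype=bool)
        return CohortGenotypes(samples=samples, markers=[], haplotypes=haplotypes, phased=phased)

    haplotypes = np.stack(hap_rows, axis=1).astype(np.int8)  # (n, m, 2)
    phased = np.stack(phased_rows, axis=1)
    markers = _build_markers(sites, quality, haplotypes)
    return CohortGenotypes(
        samples=samples, markers=markers, haplotypes=haplotypes, phased=phased
    )


def write_phased_cohort(
    cohort: CohortGenotypes,
    vcf_path: str | Path,
    *,
    quality_key: str = "RSQR",
    header_comments: Sequence[str] = (),
) -> None:
    """Write a cohort back to VCF 4.2 with ``|``-separated phased genotypes."""
    header = pysam.VariantHeader()
    for line in header_comments:
        header.add_line(f"##{line}")
    header.add_meta(
        "INFO",
        items=[("ID", quality_key), ("Number", "1"), ("Type", "Float"),
               ("Description", "Imputation quality (dosage r2)")],
    )
    header.add_meta(
        "FORMAT",
        items=[("ID", "GT"), ("Number", "1"), ("Type", "String"),
               ("Description", "Genotype")],
    )
    for contig in dict.fromkeys(m.site.chrom for m in cohort.markers):
        header.contigs.add(contig)
    for s in cohort.samples:
        header.add_sample(s)

    with pysam.VariantFile(str(vcf_path), "w", header=header) as out:
        for j, marker in enumerate(cohort.markers):
            site = marker.site
            rec = out.new_record(
                contig=site.chrom,
                start=site.pos - 1,
                stop=site.pos - 1 + len(site.ref),
                alleles=(site.ref, site.alt),
                id=site.rsid or None,
            )
            if marker.imputation_quality is not None:
                rec.info[quality_key] = marker.imputation_quality
            for i, s in enumerate(cohort.samples):
                a, b = cohort.haplotypes[i, j]
                if a == MISSING:
                    rec.samples[s]["GT"] = (None, None)
                else:
                    rec.samples[s]["GT"] = (int(a), int(b))
                    rec.samples[s].phased = bool(cohort.phased[i, j])
            out.write(rec)


def filter_markers_by_quality(
    cohort: CohortGenotypes,
    rsq_common: float = 0.3,
    rsq_rare: float = 0.6,
    maf_cut: float = 0.01,
) -> CohortGenotypes:
    """Apply the post-imputation marker filter.

    A marker is retained when its imputation quality exceeds ``rsq_common``
    at MAF >= ``maf_cut``, exceeds ``rsq_rare`` at MAF < ``maf_cut``, or has
    no quality value (directly genotyped).  The sample set is unchanged and
    the filter is idempotent.
    """
    keep = []
    for j, m in enumerate(cohort.markers):
        q = m.imputation_quality
        if q is None:
            keep.append(j)
        elif m.maf >= maf_cut:
            if q > rsq_common:
                keep.append(j)
        elif q > rsq_rare:
            keep.append(j)
    idx = np.asarray(keep, dtype=int)
    return CohortGenotypes(
        samples=list(cohort.samples),
        markers=[cohort.markers[j] for j in keep],
        haplotypes=cohort.haplotypes[:, idx, :],
        phased=cohort.phased[:, idx],
    )


def estimate_allele_frequencies(
    cohort: CohortGenotypes, subset: Sequence[str] | None = None
) -> pd.DataFrame:
    """ALT allele frequencies on a sample subset.

    Denominators count non-missing haplotypes only; a site where every
    genotype in the subset is missing reports NaN frequencies with
    ``n_hap`` 0.  Returns a DataFrame with columns
    ``chrom pos rsid ref alt alt_freq maf n_hap``.
    """
    if subset is None:
        subset = cohort.samples
    if len(subset) == 0:
        raise CohortError("empty sample subset")
    missing = set(subset) - set(cohort.samples)
    if missing:
        raise CohortError(f"subset samples not in cohort: {sorted(missing)[:5]}")
    rows = []
    pos = [cohort.sample_index(s) for s in subset]
    sub = cohort.haplotypes[pos]  # (k, m, 2)
    for j, m in enumerate(cohort.markers):
        col = sub[:, j, :].ravel()
        valid = col != MISSING
        n = int(valid.sum())
        af, maf = _alt_freq(col)
        rows.append(
            {
                "chrom": m.site.chrom,
                "pos": m.site.pos,
                "rsid": m.site.rsid,
                "ref": m.site.ref,
                "alt": m.site.alt,
                "alt_freq": af,
                "maf": maf,
                "n_hap": n,
            }
        )
    return pd.DataFrame(rows)


def subset_samples(cohort: CohortGenotypes, keep: Sequence[str]) -> CohortGenotypes:
    """Restrict the cohort to ``keep`` (order preserved), recomputing MAFs."""
    pos = [cohort.sample_index(s) for s in keep]
    hap = cohort.haplotypes[pos]
    markers = _build_markers(
        [m.site for m in cohort.markers],
        [m.imputation_quality for m in cohort.markers],
        hap,
    )
    return CohortGenotypes(
        samples=list(keep), markers=markers, haplotypes=hap, phased=cohort.phased[pos]
    )
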