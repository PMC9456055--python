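"""Study-vs-reference comparison of allele and phenotype frequencies.

Two analyses live here:

* a **differentiation screen** over clinically annotated variants: per
  variant the signed ALT-frequency difference ``delta = af_study − af_ref``
  and ratio are computed, and variants are tiered — high-evidence
  annotations (1A/1B/2A/2B) by ``|delta| >= 0.05`` and ``delta >= 0.10``,
  low-evidence annotations (3/4) by ``delta >= 0.10`` (study-elevated) and
  ``delta <= −0.10`` (study-depleted);
* **phenotype-frequency tests**: per (gene, phenotype) a two-sided Fisher
  exact test on the 2x2 count table, with Benjamini–Hochberg FDR control
  across phenotypes.

The two-sided Fisher p-value follows the point-probability rule: the sum
of hypergeometric outcome probabilities no larger than that of the
observed table.  Small tables (total N <= 500) are evaluated in exact
integer arithmetic, so ties are decided exactly; larger tables use
floating-point log-probabilities with the customary 1 + 1e-7 relative tie
tolerance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .knowledge import ClinicalAnnotation, is_high_evidence
from .profiler import CohortSummary

__all__ = [
    "FrequencyComparison",
    "PhenotypeComparison",
    "ScreenReport",
    "CompareError",
    "compare_allele_frequencies",
    "screen_differentiated_variants",
    "fisher_exact_2x2",
    "bh_adjust",
    "compare_phenotype_frequencies",
]

#: evidence tiers ordered strongest first, for picking a variant's best tier
_LEVEL_ORDER = {"1A": 0, "1B": 1, "2A": 2, "2B": 3, "3": 4, "4": 5}

_AMBIGUOUS = {frozenset({"A", "T"}), frozenset({"C", "G"})}


class CompareError(ValueError):
    pass


@dataclass(frozen=True)
class FrequencyComparison:
    chrom: str
    pos: int
    rsid: str
    gene: str
    ref: str
    alt: str
    af_study: float
    af_ref: float
    delta: float
    ratio: float | None  # None when af_ref == 0
    evidence_level: str

    @property
    def high_evidence(self) -> bool:
        return is_high_evidence(self.evidence_level)


@dataclass(frozen=True)
class PhenotypeComparison:
    gene: str
    phenotype: str
    count_study: int
    n_study: int
    count_ref: int
    n_ref: int
    freq_delta: float
    p_value: float
    q_value: float
    significant: bool


@dataclass
class ScreenReport:
    """Tiered differentiation screen output (lists of FrequencyComparison)."""

    high_abs: list[FrequencyComparison]   # high evidence, |delta| >= high_cut
    high_up: list[FrequencyComparison]    # high evidence, delta >= high_up_cut
    low_up: list[FrequencyComparison]     # low evidence, delta >= low_up_cut
    low_down: list[FrequencyComparison]   # low evidence, delta <= low_down_cut


def _require_columns(df: pd.DataFrame, cols: Sequence[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise CompareError(f"{name} table lacks columns {missing}")


def compare_allele_frequencies(
    study: pd.DataFrame,
    reference: pd.DataFrame,
    annotations: Sequence[ClinicalAnnotation],
) -> tuple[list[FrequencyComparison], list[str]]:
    """Join study and reference AF tables over the annotated variants.

    Tables are keyed on ``rsid`` and must carry ``alt_freq`` (or
    ``af_study`` / ``af_ref``) plus ``ref``/``alt`` when harmonization is
    wanted: if the reference table declares the swapped ref/alt, its
    frequency is flipped; strand-ambiguous A/T and C/G sites are dropped
    with a warning.  Each variant gets its strongest annotation tier.
    Output is sorted by |delta| descending; annotated variants absent from
    either table are returned in the skipped list.
    """
    study = study.rename(columns={"af_study": "alt_freq"}).copy()
    reference = reference.rename(columns={"af_ref": "alt_freq"}).copy()
    _require_columns(study, ["rsid", "alt_freq"], "study")
    _require_columns(reference, ["rsid", "alt_freq"], "reference")
    s_idx = study.set_index("rsid")
    r_idx = reference.set_index("rsid")

    best: dict[str, ClinicalAnnotation] = {}
    for ann in annotations:
        cur = best.get(ann.rsid)
        if cur is None or _LEVEL_ORDER[ann.evidence_level] < _LEVEL_ORDER[cur.evidence_level]:
            best[ann.rsid] = ann

    rows: list[FrequencyComparison] = []
    skipped: list[str] = []
    for rsid, ann in sorted(best.items()):
        if rsid not in s_idx.index or rsid not in r_idx.index:
            skipped.append(rsid)
            continue
        s = s_idx.loc[rsid]
        r = r_idx.loc[rsid]
        af_s = float(s["alt_freq"])
        af_r = float(r["alt_freq"])
        ref = str(s.get("ref", ""))
        alt = str(s.get("alt", ""))
        if ref and alt and "ref" in r_idx.columns:
            r_ref, r_alt = str(r["ref"]), str(r["alt"])
            if frozenset({ref, alt}) in _AMBIGUOUS and (r_ref, r_alt) != (ref, alt):
                warnings.warn(f"dropping strand-ambiguous site {rsid} ({ref}/{alt})")
                skipped.append(rsid)
                continue
            if (r_ref, r_alt) == (alt, ref):
                af_r = 1.0 - af_r
            elif (r_ref, r_alt) != (ref, alt):
                skipped.append(rsid)
                continue
        delta = af_s - af_r
        rows.append(
            FrequencyComparison(
                chrom=str(s.get("chrom", "")),
                pos=int(s.get("pos", 0)),
                rsid=rsid,
                gene=str(s.get("gene", ann.gene)),
                ref=ref,
                alt=alt,
                af_study=af_s,
                af_ref=af_r,
                delta=delta,
                ratio=(af_s / af_r) if af_r > 0 else None,
                evidence_level=ann.evidence_level,
            )
        )
    rows.sort(key=lambda r: (-abs(r.delta), r.rsid))
    return rows, skipped


def screen_differentiated_variants(
    rows: Iterable[FrequencyComparison],
    high_cut: float = 0.05,
    high_up_cut: float = 0.10,
    low_up_cut: float = 0.10,
    low_down_cut: float = -0.10,
) -> ScreenReport:
    """Partition annotated variants into the differentiation tiers."""
    rows = list(rows)
    high = [r for r in rows if r.high_evidence]
    low = [r for r in rows if not r.high_evidence]
    return ScreenReport(
        high_abs=[r for r in high if abs(r.delta) >= high_cut],
        high_up=[r for r in high if r.delta >= high_up_cut],
        low_up=[r for r in low if r.delta >= low_up_cut],
        low_down=[r for r in low if r.delta <= low_down_cut],
    )


# ---------------------------------------------------------------------------
# Fisher exact test and BH-FDR
# ---------------------------------------------------------------------------

_EXACT_LIMIT = 500  # total table size up to which the integer path is used


def _fisher_exact_int(a: int, n_a: int, b: int, n_b: int) -> float:
    """Exact two-sided Fisher via integer hypergeometric numerators."""
    k = a + b  # successes total; margins fixed
    n = n_a + n_b
    lo = max(0, k - n_b)
    hi = min(k, n_a)
    nums = [math.comb(n_a, x) * math.comb(n_b, k - x) for x in range(lo, hi + 1)]
    obs = nums[a - lo]
    total = sum(nums)
    tail = sum(v for v in nums if v <= obs)
    return tail / total


def _fisher_exact_float(a: int, n_a: int, b: int, n_b: int) -> float:
    k = a + b
    n = n_a + n_b
    lo = max(0, k - n_b)
    hi = min(k, n_a)
    support = np.arange(lo, hi + 1)
    logp = hypergeom.logpmf(support, n, k, n_a)
    log_obs = logp[a - lo]
    # point-probability rule with the customary relative tie tolerance
    mask = logp <= log_obs + math.log1p(1e-7)
    return float(min(1.0, np.exp(logp[mask]).sum()))


def fisher_exact_2x2(count_a: int, n_a: int, count_b: int, n_b: int) -> float:
    """Two-sided Fisher exact p for successes/totals in two groups.

    Sums hypergeometric point probabilities no larger than the observed
    table's over the margin-fixed support.
    """
    if n_a <= 0 or n_b <= 0:
        raise CompareError("group totals must be positive")
    if not (0 <= count_a <= n_a and 0 <= count_b <= n_b):
        raise CompareError("counts must lie in [0, total]")
    if n_a + n_b <= _EXACT_LIMIT:
        return _fisher_exact_int(count_a, n_a, count_b, n_b)
    return _fisher_exact_float(count_a, n_a, count_b, n_b)


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up q-values, in the input order.

    q_(i) = min_{j : p_(j) >= p_(i)} p_(j) * m / rank(j), clipped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise CompareError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q.tolist()


def compare_phenotype_frequencies(
    summary_study: CohortSummary,
    reference_freqs: pd.DataFrame,
    alpha: float = 0.05,
    use_q: bool = True,
) -> list[PhenotypeComparison]:
    """Fisher + BH comparison of per-gene phenotype frequencies.

    ``reference_freqs`` needs columns ``gene, phenotype, frequency, n_ref``;
    reference counts are reconstructed as ``round(frequency * n_ref)`` since
    exact testing needs counts.  Phenotypes present in only one cohort are
    tested with a zero count on the absent side.  Significance is flagged
    on the BH q-value by default (``use_q=False`` flags on the raw p).
    """
    _require_columns(reference_freqs, ["gene", "phenotype", "frequency", "n_ref"], "reference")
    if reference_freqs["n_ref"].isna().any():
        raise CompareError("reference table has missing n_ref")
    n_study = summary_study.cohort_size

    ref_rows = {
        (str(r.gene), str(r.phenotype)): (int(round(float(r.frequency) * int(r.n_ref))), int(r.n_ref))
        for r in reference_freqs.itertuples()
    }
    study_rows = {
        (g, p): c
        for g, per in summary_study.gene_phenotypes.items()
        for p, (c, _f) in per.items()
    }
    ref_n_by_gene: dict[str, int] = {}
    for (g, _p), (_c, nr) in ref_rows.items():
        ref_n_by_gene[g] = nr

    keys = sorted(set(study_rows) | set(ref_rows))
    prelim = []
    for g, p in keys:
        c_s = study_rows.get((g, p), 0)
        c_r, n_r = ref_rows.get((g, p), (0, ref_n_by_gene.get(g, 0)))
        if n_r <= 0:
            raise CompareError(f"no reference cohort size for gene {g}")
        pval = fisher_exact_2x2(c_s, n_study, c_r, n_r)
        prelim.append((g, p, c_s, c_r, n_r, pval))
    qvals = bh_adjust([t[5] for t in prelim])
    out = []
    for (g, p, c_s, c_r, n_r, pval), q in zip(prelim, qvals):
        crit = q if use_q else pval
        out.append(
            PhenotypeComparison(
                gene=g,
                phenotype=p,
                count_study=c_s,
                n_study=n_study,
                count_ref=c_r,
                n_ref=n_r,
                freq_delta=c_s / n_study - c_r / n_r,
                p_value=pval,
                q_value=q,
                significant=crit < alpha,
            )
        )
    return out
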