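"""End-to-end orchestration: read → filter → (prune) → call → profile → compare.

:func:`run_profile` executes the full profiling pipeline from a config and
writes every table plus a reproducibility log (seeds, thresholds, input
digests); :func:`run_simulate` writes a synthetic bundle (VCF, truth
table, pedigree) and can immediately re-profile it to report caller
recovery.  Both validate their outputs before writing — a failed schema
check is a hard error, never a silently partial file.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import datasets, knowledge
from .caller import call_cohort, diplotype_frequency_table
from .cohort import (
    estimate_allele_frequencies,
    filter_markers_by_quality,
    read_phased_cohort,
    subset_samples,
)
from .popcompare import compare_allele_frequencies, screen_differentiated_variants
from .profiler import (
    assign_phenotype,
    burden_distribution,
    cohort_summary,
    summarize_burden_distribution,
)
from .relatedness import estimate_pairwise_pi, prune_related, read_pedigree
from .simulate import SimulationConfig, simulate_cohort, simulate_trios

__all__ = ["PipelineConfig", "PipelineError", "run_profile", "run_simulate"]

logger = logging.getLogger(__name__)


class PipelineError(ValueError):
    pass


@dataclass
class PipelineConfig:
    vcf: Path | None = None
    knowledge_dir: Path | None = None  # None -> bundled fixture
    ref_af: Path | None = None
    pedigree: Path | None = None
    out_dir: Path = Path("pgx_out")
    risk_threshold: float = 0.40
    pi_threshold: float = 0.05
    high_delta_cut: float = 0.05
    up_delta_cut: float = 0.10
    alpha: float = 0.05
    prune: bool = False
    seed: int = 0
    n_samples: int = 200
    missingness_rate: float = 0.0
    unphase_rate: float = 0.0
    trio_count: int = 0

    def validate_for_profile(self) -> None:
        if self.vcf is None or not Path(self.vcf).exists():
            raise PipelineError(f"VCF path missing or not found: {self.vcf}")
        if self.prune and self.pedigree is not None and not Path(self.pedigree).exists():
            raise PipelineError(f"pedigree path not found: {self.pedigree}")
        if self.ref_af is not None and not Path(self.ref_af).exists():
            raise PipelineError(f"reference AF path not found: {self.ref_af}")
        for name, lo, hi in (
            ("risk_threshold", 0.0, 1.0),
            ("pi_threshold", 0.0, 1.0),
            ("alpha", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if not lo < v < hi:
                raise PipelineError(f"{name} must lie in ({lo}, {hi}), got {v}")


def _knowledge_bundle(config: PipelineConfig):
    if config.knowledge_dir is None:
        return (
            datasets.load_default_definitions(),
            datasets.load_default_phenotype_map(),
            datasets.load_default_gene_drug(),
            datasets.load_default_annotations(),
        )
    d = Path(config.knowledge_dir)
    return (
        knowledge.load_allele_definitions(d / "allele_definitions.tsv"),
        knowledge.load_phenotype_map(d / "phenotype_map.tsv", d / "phenotype_flags.tsv"),
        knowledge.load_gene_drug_table(d / "gene_drug_cpic.tsv"),
        knowledge.load_clinical_annotations(d / "clinical_annotations.tsv"),
    )


def _digest(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path, required: list[str]) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise PipelineError(f"output table {path.name} lacks columns {missing}")
    df.to_csv(path, sep="\t", index=False)


def run_profile(config: PipelineConfig) -> dict:
    """Run the profiling pipeline; returns the summary dict it also writes."""
    config.validate_for_profile()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"stage": None, "inputs": {"vcf": str(config.vcf), "vcf_sha256": _digest(config.vcf)},
                 "thresholds": {"risk": config.risk_threshold, "pi": config.pi_threshold,
                                "alpha": config.alpha, "high_delta": config.high_delta_cut,
                                "up_delta": config.up_delta_cut}}
    try:
        log["stage"] = "knowledge"
        defs, pmap, gene_drug, annotations = _knowledge_bundle(config)
        log["n_genes"] = len(defs.genes)

        log["stage"] = "read"
        cohort = read_phased_cohort(config.vcf)
        log["n_samples"], log["n_markers"] = cohort.n_samples, cohort.n_markers

        log["stage"] = "filter"
        cohort = filter_markers_by_quality(cohort)
        log["n_markers_after_filter"] = cohort.n_markers

        if config.prune:
            log["stage"] = "prune"
            pi = estimate_pairwise_pi(cohort)
            ped = read_pedigree(config.pedigree) if config.pedigree else None
            retained = prune_related(pi, ped, threshold=config.pi_threshold)
            (out / "retained_samples.txt").write_text("\n".join(retained) + "\n")
            cohort = subset_samples(cohort, retained)
            log["n_samples_after_prune"] = cohort.n_samples

        log["stage"] = "call"
        calls = call_cohort(cohort, defs)
        calls_df = pd.DataFrame(
            {
                "sample": c.sample,
                "gene": c.gene,
                "allele1": c.allele_pair[0] if c.allele_pair else "",
                "allele2": c.allele_pair[1] if c.allele_pair else "",
                "status": c.status,
            }
            for c in calls
        )
        _write_tsv(calls_df, out / "calls.tsv", ["sample", "gene", "allele1", "allele2", "status"])
        _write_tsv(
            diplotype_frequency_table(calls),
            out / "diplotype_freq.tsv",
            ["gene", "diplotype", "count", "frequency"],
        )

        log["stage"] = "profile"
        pheno = [assign_phenotype(c, pmap) for c in calls]
        summary = cohort_summary(pheno, gene_drug, risk_threshold=config.risk_threshold)
        dist = burden_distribution(pheno, gene_drug)
        n_ge1, pct_ge1, mean_drugs = summarize_burden_distribution(dist)
        _write_tsv(
            summary.gene_phenotype_frame(),
            out / "gene_phenotype_freq.tsv",
            ["gene", "phenotype", "count", "frequency"],
        )
        _write_tsv(
            summary.drug_risk_frame(), out / "drug_risk.tsv", ["drug", "n_at_risk", "fraction"]
        )
        burden_df = pd.DataFrame(dist.rows, columns=["n_individuals", "n_drugs"])
        _write_tsv(burden_df, out / "burden.tsv", ["n_individuals", "n_drugs"])
        summary_json = {
            "cohort_size": summary.cohort_size,
            "n_ge1": n_ge1,
            "pct_ge1": pct_ge1,
            "fraction_ge1": summary.fraction_ge1,
            "mean_at_risk_drugs": mean_drugs,
            "drugs_over_threshold": summary.drugs_over_threshold,
            "risk_threshold": config.risk_threshold,
        }

        if config.ref_af is not None:
            log["stage"] = "compare"
            study_af = estimate_allele_frequencies(cohort)
            ref_af = pd.read_csv(config.ref_af, sep="\t")
            ref_af = ref_af.rename(columns={"af_ref": "alt_freq"})
            rows, skipped = compare_allele_frequencies(study_af, ref_af, annotations)
            report = screen_differentiated_variants(
                rows, high_cut=config.high_delta_cut, high_up_cut=config.up_delta_cut
            )
            comp_df = pd.DataFrame(
                {
                    "chrom": r.chrom, "pos": r.pos, "rsid": r.rsid, "gene": r.gene,
                    "alt": r.alt, "af_study": r.af_study, "af_ref": r.af_ref,
                    "delta": r.delta, "evidence_level": r.evidence_level,
                }
                for r in rows
            )
            _write_tsv(comp_df, out / "freq_compare.tsv", ["rsid", "delta"])
            summary_json["n_high_evidence_differentiated"] = len(report.high_abs)
            summary_json["skipped_variants"] = skipped

        (out / "summary.json").write_text(json.dumps(summary_json, indent=2) + "\n")
        log["stage"] = "done"
        (out / "run_log.json").write_text(json.dumps(log, indent=2) + "\n")
        return summary_json
    except Exception:
        logger.error("pipeline failed at stage %s", log["stage"])
        (out / "run_log.json").write_text(json.dumps(log, indent=2) + "\n")
        raise


def run_simulate(config: PipelineConfig, check: bool = False) -> dict:
    """Write a synthetic phased bundle; optionally report caller recovery."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    defs = datasets.load_default_definitions()
    sim = SimulationConfig(
        n_samples=config.n_samples,
        seed=config.seed,
        haplotype_freqs=datasets.load_default_haplotype_frequencies(),
        missingness_rate=config.missingness_rate,
        unphase_rate=config.unphase_rate,
        trio_count=config.trio_count,
        ld_locked_pairs=datasets.DEFAULT_LD_LOCKED_PAIRS,
    )
    vcf_path = out / "simulated.vcf"
    if config.trio_count > 0:
        cohort, truth, ped = simulate_trios(sim, defs, out_vcf=vcf_path)
        from .relatedness import write_pedigree

        write_pedigree(ped, out / "pedigree.tsv")
    else:
        cohort, truth = simulate_cohort(sim, defs, out_vcf=vcf_path)
    truth_df = pd.DataFrame(
        {"sample": s, "gene": g, "allele1": pair[0], "allele2": pair[1]}
        for (s, g), pair in sorted(truth.diplotypes.items())
    )
    _write_tsv(truth_df, out / "truth.tsv", ["sample", "gene", "allele1", "allele2"])
    result = {
        "seed": config.seed,
        "n_samples": cohort.n_samples,
        "n_markers": cohort.n_markers,
        "vcf": str(vcf_path),
    }
    if check:
        calls = call_cohort(cohort, defs)
        result["diplotype_concordance"] = truth.concordance(calls)
        result["n_called"] = sum(1 for c in calls if c.status == "called")
    (out / "simulate_log.json").write_text(json.dumps(result, indent=2) + "\n")
    return result
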