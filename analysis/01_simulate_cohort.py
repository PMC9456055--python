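#!/usr/bin/env python
"""Simulate a phased 1577-sample cohort and verify caller recovery.

Draws star-allele diplotypes for the 14-gene toy fixture under
Hardy-Weinberg at the bundled haplotype frequencies (VKORC1 promoter
variant at its published frequency 0.509, r^2 = 1 lock between the two
promoter-region sites), writes the VCF/truth bundle under scratch/, and
re-calls it to confirm 100% diplotype recovery at zero noise.
"""

import json
from pathlib import Path

from pgxcohort import datasets
from pgxcohort.caller import call_cohort
from pgxcohort.simulate import SimulationConfig, simulate_cohort

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"
SEED = 1


def main() -> None:
    SCRATCH.mkdir(exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    defs = datasets.load_default_definitions()
    config = SimulationConfig(
        n_samples=datasets.COHORT_SIZE,
        seed=SEED,
        haplotype_freqs=datasets.load_default_haplotype_frequencies(),
        ld_locked_pairs=datasets.DEFAULT_LD_LOCKED_PAIRS,
    )
    vcf = SCRATCH / "simulated_cohort.vcf"
    cohort, truth = simulate_cohort(config, defs, out_vcf=vcf)
    calls = call_cohort(cohort, defs)
    vk = next(m for m in cohort.markers if m.site.rsid == "rs9923231")
    summary = {
        "seed": SEED,
        "n_samples": cohort.n_samples,
        "n_markers": cohort.n_markers,
        "diplotype_concordance": truth.concordance(calls),
        "vkorc1_promoter_alt_freq": round(vk.alt_freq, 4),
        "vcf": str(vcf),
    }
    (RESULTS / "01_simulation_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    print(json.dumps(summary, indent=2))
    print(
        f"Simulated {cohort.n_samples} samples over {cohort.n_markers} sites; "
        f"caller recovered the planted diplotypes at "
        f"{100 * summary['diplotype_concordance']:.1f}% concordance."
    )


if __name__ == "__main__":
    main()
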