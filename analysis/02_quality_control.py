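"""Quality control of the simulated cohort: missingness, Hardy-Weinberg
exact-test filtering (Bonferroni), MAF, and sliding-window LD pruning.

Writes the QC report to results/02_qc_report.json.
"""

import json

from common import RESULTS, cohort
from founder_tracer.qc import QcThresholds, run_qc


def main() -> None:
    gm = cohort().haplotypes.to_genotypes()
    thresholds = QcThresholds()  # 0.05 / 0.05 missingness, MAF 0.01, 50-5-0.1
    gm_qc, kept_ids, report = run_qc(gm, thresholds)

    RESULTS.mkdir(exist_ok=True)
    payload = report.to_dict()
    payload["kept_after_ld_prune"] = len(kept_ids)
    (RESULTS / "02_qc_report.json").write_text(json.dumps(payload, indent=1))

    print(f"input: {report.initial_shape[0]} samples x {report.initial_shape[1]} SNPs")
    for step in report.steps:
        print(
            f"  {step['filter']}: -{step['removed_variants']} variants, "
            f"-{step['removed_samples']} samples  {step['params']}"
        )
    print(
        f"post-QC: {gm_qc.n_samples} samples x {gm_qc.n_variants} SNPs; "
        f"{len(kept_ids)} quasi-independent SNPs survive LD pruning"
    )


if __name__ == "__main__":
    main()
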