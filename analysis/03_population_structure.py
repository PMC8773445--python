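"""Population structure and relatedness of the cohort: PCA on the pruned
genotypes and the genome-wide IBD "top 1%" unrelatedness screen.

In a single founder-event cohort the carriers should look like ordinary
members of the background population genome-wide: no carrier pair should
exceed the top 1% of the carrier-control PI_HAT distribution.

Writes results/03_pca.tsv, results/03_ibd_pairs.tsv, results/03_structure.json.
"""

import json

import numpy as np
import pandas as pd

from common import RESULTS, cohort
from founder_tracer.qc import QcThresholds, run_qc
from founder_tracer.structure import relatedness_screen, run_pca


def main() -> None:
    sim = cohort()
    gm = sim.haplotypes.to_genotypes()
    gm_qc, kept_ids, _ = run_qc(gm, QcThresholds())
    keep = gm_qc.variants["id"].isin(set(kept_ids)).to_numpy()
    gm_pruned = gm_qc.subset_variants(np.flatnonzero(keep))

    pca = run_pca(gm_pruned, k=4)
    screen = relatedness_screen(gm_qc, sim.sheet)

    RESULTS.mkdir(exist_ok=True)
    pca.coords.round(4).to_csv(RESULTS / "03_pca.tsv", sep="\t")
    pairs = pd.concat(
        [screen.carrier_carrier.assign(kind="carrier-carrier"),
         screen.carrier_control.assign(kind="carrier-control")],
        ignore_index=True,
    )
    pairs.round(5).to_csv(RESULTS / "03_ibd_pairs.tsv", sep="\t", index=False)
    summary = {
        "pca_explained_variance": [round(float(x), 4) for x in pca.explained],
        "ibd_top1pct_cutoff": screen.cutoff,
        "carrier_carrier_max_pi_hat": float(screen.carrier_carrier["PI_HAT"].max()),
        "flagged_pairs": [list(p) for p in screen.flagged_pairs],
    }
    (RESULTS / "03_structure.json").write_text(json.dumps(summary, indent=1))

    print(
        "PCA explained-variance fractions (PC1..PC4): "
        + ", ".join(f"{x:.3f}" for x in pca.explained)
    )
    print(
        f"carrier-carrier PI_HAT max {summary['carrier_carrier_max_pi_hat']:.3f} "
        f"vs top-1% carrier-control cutoff {screen.cutoff:.3f}"
    )
    if screen.flagged_pairs:
        print(f"flagged as related: {screen.flagged_pairs}")
    else:
        print("no carrier pair exceeds the top-1% rule: carriers are "
              "genome-wide unrelated, as in a deep founder event")


if __name__ == "__main__":
    main()
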