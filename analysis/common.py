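"""Shared configuration for the numbered analysis scripts.

One desk-scale cohort emulating the study design: 7 carriers of a rare focal
mutation among 84 background controls, three chromosomes of 2,000 array-like
SNPs each (the focal one labeled "21"), founder event 50 generations back.
Every script regenerates the cohort deterministically from this config, so
the steps can be run independently.
"""

from pathlib import Path

from founder_tracer.synthetic_data import SimConfig, make_cohort

REPO = Path(__file__).resolve().parent.parent
RESULTS = REPO / "results"
SCRATCH = REPO / "scratch"

COHORT_CONFIG = SimConfig(
    n_carriers=7,
    n_controls=84,
    n_chromosomes=3,
    n_snps=2000,
    founder_tmrca=50.0,
    missing_rate=0.01,
    seed=2022,
)


def cohort():
    return make_cohort(COHORT_CONFIG)
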