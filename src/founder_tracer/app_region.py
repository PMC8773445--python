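"""Published inputs for the APP A713T founder-segment worked example.

The A713T mutation in the amyloid precursor protein gene (APP, chromosome
21) is a rare Alzheimer's-disease variant repeatedly observed in families
from Calabria (Southern Italy).  In the published carrier cohort, five of
seven array-genotyped carriers share a haplotype segment of 300 SNPs and
1.72 Mbp centered on the mutation; nested sub-segments of 110 SNPs / 0.59
Mbp and 47 SNPs / 0.25 Mbp extend the sharing to the sixth and seventh
carrier.  These printed segment sizes are the inputs to the dating worked
example; the carriers' genotypes themselves are not redistributable.

The genetic map configured here for the APP region is a constant-rate
approximation at 1.31 cM/Mb, consistent with the chromosome-21 average
recombination rate (~1.3 cM/Mb in HapMap-derived maps).
"""

from __future__ import annotations

from .datamodel import GeneticMap
from .haploshare import SharedSegment
from .tmrca import TmrcaModel, TmrcaPosterior, tmrca_from_segment

#: A713T (rs63750066) position on chromosome 21, GRCh37 coordinates.
APP_A713T_CHROM = "21"
APP_A713T_POS_BP = 27_269_932

#: constant-rate approximation for the APP region, cM/Mb
APP_REGION_CM_PER_MB = 1.31

#: (n_carriers_sharing, n_snps, length_bp) of the published nested segments
REPORTED_SEGMENTS = {
    5: (300, 1_720_000),
    6: (110, 590_000),
    7: (47, 250_000),
}


def app_region_map() -> GeneticMap:
    return GeneticMap.constant(APP_REGION_CM_PER_MB)


def reported_segment(n_carriers: int = 5) -> SharedSegment:
    """The published shared segment, centered on the focal mutation."""
    if n_carriers not in REPORTED_SEGMENTS:
        raise KeyError(f"no reported segment for {n_carriers} carriers")
    n_snps, length_bp = REPORTED_SEGMENTS[n_carriers]
    half = length_bp // 2
    return SharedSegment(
        chrom=APP_A713T_CHROM,
        start_bp=APP_A713T_POS_BP - half,
        end_bp=APP_A713T_POS_BP - half + length_bp,
        n_snps=n_snps,
        members=tuple(f"carrier{i+1}_h0" for i in range(n_carriers)),
    )


def date_reported_segment(
    n_carriers: int = 5, model: TmrcaModel | None = None
) -> TmrcaPosterior:
    """Coalescent dating of a published segment under the configured map."""
    seg = reported_segment(n_carriers)
    return tmrca_from_segment(seg, app_region_map(), n_carriers, model)
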