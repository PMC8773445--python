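"""Phased synthetic cohorts with a planted founder event and known truth.

The generator emulates the study design the pipeline is built for: a modest
diploid cohort (7 carriers of a rare focal mutation embedded among 84
background controls by default, scaled down from a ~500K-SNP array to a few
thousand SNPs per chromosome) of phased haplotypes with short-range LD, where
the carriers inherit a founder haplotype around one focal site on the
"chr21" analogue and recombination has eroded each carrier's retained tract
for ``founder_tmrca`` generations.

Background LD is produced by Li-Stephens-style blockwise copying from a small
founder-haplotype pool: along each simulated haplotype the copying template
persists between adjacent sites with probability ``copy_prob``, so
``copy_prob = 0`` gives independent sites (no LD) and ``copy_prob -> 1``
collapses haplotypes onto the pool (perfect long-range LD).

Everything is deterministic given ``(config, seed)``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .datamodel import (
    MISSING,
    GeneticMap,
    HaplotypeMatrix,
    SampleSheet,
)
from . import io_formats

log = logging.getLogger(__name__)


class SimulationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic cohort."""

    n_carriers: int = 7
    n_controls: int = 84
    n_chromosomes: int = 3
    n_snps: int = 3000            # per chromosome
    snp_spacing_bp: int = 5000
    beta_a: float = 1.0           # alt-frequency spectrum Beta(a, b)
    beta_b: float = 1.0
    freq_floor: float = 0.02      # clip spectrum away from fixation
    n_founder_haps: int = 20      # background copying pool size
    copy_prob: float = 0.97       # template persistence between adjacent sites
    copy_noise: float = 0.01      # per-site chance of a fresh frequency draw
    founder_tmrca: float = 50.0   # generations t*
    erosion_rate_per_side: float = 1.0  # c_sim: per-lineage per-side rate x t*
    focal_chrom: str = "21"
    focal_index: int | None = None  # SNP index on the focal chromosome (mid)
    carriers_homozygous: bool = False
    missing_rate: float = 0.0
    cm_per_mb: float = 1.3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_carriers, self.n_controls, self.n_chromosomes,
               self.n_snps, self.n_founder_haps) < 1:
            raise SimulationError("all counts must be positive")
        if self.founder_tmrca <= 0:
            raise SimulationError("founder_tmrca must be > 0")
        if self.beta_a <= 0 or self.beta_b <= 0:
            raise SimulationError("degenerate Beta spectrum parameters")
        if not 0 <= self.copy_prob <= 1:
            raise SimulationError("copy_prob must be in [0,1]")
        if not 0 <= self.missing_rate < 1:
            raise SimulationError("missing_rate must be in [0,1)")
        if not 0 < self.freq_floor < 0.5:
            raise SimulationError("freq_floor must be in (0, 0.5)")

    @property
    def chromosomes(self) -> list[str]:
        labels = [str(i + 1) for i in range(self.n_chromosomes - 1)]
        return labels + [self.focal_chrom]

    @property
    def n_samples(self) -> int:
        return self.n_carriers + self.n_controls

    @property
    def carrier_ids(self) -> list[str]:
        return [f"PAT{i+1:02d}" for i in range(self.n_carriers)]

    @property
    def control_ids(self) -> list[str]:
        return [f"CTL{i+1:02d}" for i in range(self.n_controls)]

    def genetic_map(self) -> GeneticMap:
        return GeneticMap.constant(self.cm_per_mb)

    def focal_site(self) -> tuple[str, int]:
        idx = self.n_snps // 2 if self.focal_index is None else self.focal_index
        if not 0 <= idx < self.n_snps:
            raise SimulationError("focal_index outside the focal chromosome")
        return self.focal_chrom, idx


@dataclass
class FounderTruth:
    """Ground truth emitted alongside a planted founder event."""

    tmrca: float
    focal_chrom: str
    focal_pos_bp: int
    founder_haplotype: np.ndarray = field(repr=False)
    carriers: list[str] = field(default_factory=list)
    carrier_phase: dict[str, int] = field(default_factory=dict)
    retained_bp: dict[str, tuple[int, int]] = field(default_factory=dict)
    retry_count: int = 0

    def intersection_bp(self) -> tuple[int, int]:
        starts = [iv[0] for iv in self.retained_bp.values()]
        ends = [iv[1] for iv in self.retained_bp.values()]
        return max(starts), min(ends)

    def to_dict(self) -> dict:
        return {
            "tmrca": self.tmrca,
            "focal_chrom": self.focal_chrom,
            "focal_pos_bp": self.focal_pos_bp,
            "carriers": self.carriers,
            "carrier_phase": self.carrier_phase,
            "retained_bp": {k: list(v) for k, v in self.retained_bp.items()},
            "retry_count": self.retry_count,
            "founder_haplotype": self.founder_haplotype.tolist(),
        }


# ---------------------------------------------------------------------------
# background cohort
# ---------------------------------------------------------------------------

def _simulate_chromosome(
    config: SimConfig, n_haps: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """One chromosome: (haplotypes (n_haps, m), alt frequencies)."""
    m = config.n_snps
    freqs = rng.beta(config.beta_a, config.beta_b, size=m)
    freqs = np.clip(freqs, config.freq_floor, 1.0 - config.freq_floor)
    pool = (rng.random((config.n_founder_haps, m)) < freqs).astype(np.int8)

    haps = np.empty((n_haps, m), dtype=np.int8)
    switch = 1.0 - config.copy_prob
    for i in range(n_haps):
        # blockwise template path through the pool
        new_template = rng.random(m) < switch
        new_template[0] = True
        seg_id = np.cumsum(new_template) - 1
        template = rng.integers(0, config.n_founder_haps, seg_id[-1] + 1)
        hap = pool[template[seg_id], np.arange(m)]
        noise = rng.random(m) < config.copy_noise
        if noise.any():
            hap = np.where(noise, (rng.random(m) < freqs), hap).astype(np.int8)
        haps[i] = hap
    return haps, freqs


def simulate_background(
    config: SimConfig, rng: np.random.Generator | None = None
) -> HaplotypeMatrix:
    """Null cohort of carriers + controls (no founder event planted yet)."""
    import pandas as pd

    rng = rng or np.random.default_rng(config.seed)
    n_haps = 2 * config.n_samples
    blocks = []
    var_rows = []
    for chrom in config.chromosomes:
        haps, _ = _simulate_chromosome(config, n_haps, rng)
        blocks.append(haps)
        pos = (np.arange(config.n_snps) + 1) * config.snp_spacing_bp
        for j, p in enumerate(pos):
            var_rows.append(
                {"chrom": chrom, "pos": int(p), "id": f"snp_{chrom}_{j+1}",
                 "ref": "A", "alt": "G"}
            )
    matrix = np.concatenate(blocks, axis=1)
    variants = pd.DataFrame(var_rows)

    # the focal site is reserved for the planted mutation: background carries
    # the reference allele only (worldwide-rare risk allele)
    chrom, idx = config.focal_site()
    focal_col = config.chromosomes.index(chrom) * config.n_snps + idx
    matrix[:, focal_col] = 0

    samples = config.carrier_ids + config.control_ids
    return HaplotypeMatrix(samples, variants, matrix)


# ---------------------------------------------------------------------------
# founder event
# ---------------------------------------------------------------------------

def plant_founder(
    hm: HaplotypeMatrix,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    gmap: GeneticMap | None = None,
) -> tuple[HaplotypeMatrix, FounderTruth]:
    """Plant a founder haplotype among the carriers.

    One haplotype per carrier receives the founder alleles over an interval
    extending left and right of the focal site by independent
    Exponential(erosion_rate_per_side * t*) genetic distances (converted to bp
    through the map).  Carriers are heterozygous at the focal site unless
    ``carriers_homozygous``; controls never carry the risk allele.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    gmap = gmap or config.genetic_map()
    chrom, idx = config.focal_site()
    chrom_mask = (hm.variants["chrom"] == chrom).to_numpy()
    chrom_idx = np.flatnonzero(chrom_mask)
    pos = hm.variants["pos"].to_numpy()[chrom_idx]
    focal_global = int(chrom_idx[idx])
    focal_bp = int(pos[idx])

    haplotypes = hm.haplotypes.copy()

    # founder haplotype = one extra background draw over the focal chromosome
    founder, _ = _simulate_chromosome(config, 1, rng)
    founder = founder[0]
    founder[idx] = 1  # risk allele

    rate = config.erosion_rate_per_side * config.founder_tmrca  # per Morgan
    focal_cm = gmap.cm_at(chrom, focal_bp)
    truth = FounderTruth(
        tmrca=config.founder_tmrca,
        focal_chrom=chrom,
        focal_pos_bp=focal_bp,
        founder_haplotype=founder,
        carriers=list(config.carrier_ids),
    )

    for carrier in config.carrier_ids:
        for attempt in range(1000):
            d_left_m = rng.exponential(1.0 / rate)
            d_right_m = rng.exponential(1.0 / rate)
            left_bp = gmap.bp_at_cm(chrom, focal_cm - 100.0 * d_left_m)
            right_bp = gmap.bp_at_cm(chrom, focal_cm + 100.0 * d_right_m)
            left_bp = max(int(np.ceil(left_bp)), int(pos[0]))
            right_bp = min(int(np.floor(right_bp)), int(pos[-1]))
            lo = int(np.searchsorted(pos, left_bp, side="left"))
            hi = int(np.searchsorted(pos, right_bp, side="right"))  # exclusive
            if hi - lo >= 1 and lo <= idx < hi:
                break
            truth.retry_count += 1
        else:
            raise SimulationError("could not draw a non-empty retained interval")
        phase = int(rng.integers(0, 2))
        row = hm.hap_row(carrier, phase)
        haplotypes[row, chrom_idx[lo]: chrom_idx[hi - 1] + 1] = founder[lo:hi]
        if config.carriers_homozygous:
            other = hm.hap_row(carrier, 1 - phase)
            haplotypes[other, focal_global] = 1
        truth.carrier_phase[carrier] = phase
        truth.retained_bp[carrier] = (int(pos[lo]), int(pos[hi - 1]))

    if truth.retry_count:
        log.info("plant_founder: %d interval resamples", truth.retry_count)
    out = HaplotypeMatrix(list(hm.sample_ids), hm.variants, haplotypes)
    return out, truth


def inject_missingness(
    hm: HaplotypeMatrix, rate: float, seed: int
) -> HaplotypeMatrix:
    """I.i.d. masking of haplotype alleles at the given rate."""
    if not 0 <= rate < 1:
        raise SimulationError("rate must be in [0,1)")
    if rate == 0:
        return hm
    rng = np.random.default_rng(seed)
    mask = rng.random(hm.haplotypes.shape) < rate
    haps = hm.haplotypes.copy()
    haps[mask] = MISSING
    return HaplotypeMatrix(list(hm.sample_ids), hm.variants, haps)


# ---------------------------------------------------------------------------
# one-call cohort + writer
# ---------------------------------------------------------------------------

@dataclass
class CohortSim:
    haplotypes: HaplotypeMatrix
    truth: FounderTruth
    sheet: SampleSheet
    gmap: GeneticMap
    config: SimConfig


def make_cohort(config: SimConfig) -> CohortSim:
    """Background + founder event + optional missingness, with sample sheet."""
    rng = np.random.default_rng(config.seed)
    hm = simulate_background(config, rng)
    hm, truth = plant_founder(hm, config, rng)
    if config.missing_rate > 0:
        hm = inject_missingness(hm, config.missing_rate, config.seed + 2)
    sheet = SampleSheet.from_roles(config.carrier_ids, config.control_ids)
    return CohortSim(hm, truth, sheet, config.genetic_map(), config)


def write_cohort(cohort: CohortSim, out_dir: str | Path) -> dict[str, str]:
    """Emit phased VCF, sample sheet, genetic map anchors and truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": str(out / "cohort.vcf"),
        "sheet": str(out / "samples.tsv"),
        "map": str(out / "genetic_map.tsv"),
        "truth": str(out / "founder_truth.json"),
        "config": str(out / "sim_config.json"),
    }
    io_formats.write_phased_vcf(cohort.haplotypes, paths["vcf"])
    io_formats.write_sample_sheet(cohort.sheet, paths["sheet"])
    # materialize the constant map as two anchors per chromosome so the file
    # round-trips through read_genetic_map
    anchors = {}
    for chrom in cohort.config.chromosomes:
        pos = cohort.haplotypes.variants.loc[
            cohort.haplotypes.variants["chrom"] == chrom, "pos"
        ]
        lo, hi = float(pos.min()), float(pos.max())
        anchors[chrom] = (
            np.array([lo, hi]),
            np.array([
                cohort.gmap.cm_at(chrom, lo),
                cohort.gmap.cm_at(chrom, hi),
            ]),
        )
    io_formats.write_genetic_map(
        GeneticMap(anchors, cohort.gmap.fallback_cm_per_mb), paths["map"]
    )
    with open(paths["truth"], "w") as fh:
        json.dump(cohort.truth.to_dict(), fh, indent=1)
    with open(paths["config"], "w") as fh:
        json.dump(dataclasses.asdict(cohort.config), fh, indent=1)
    return paths
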