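import json

import numpy as np
import pytest

from founder_tracer.datamodel import MISSING
from founder_tracer import io_formats
from founder_tracer import synthetic_data as sd
from founder_tracer.haploshare import FocalSpec, focal_shared_segment
from founder_tracer.qc import dosage_r2


def small_config(**kw):
    base = dict(n_carriers=4, n_controls=8, n_chromosomes=2, n_snps=300, seed=11)
    base.update(kw)
    return sd.SimConfig(**base)


class TestBackground:
    def test_same_seed_is_byte_identical(self):
        a = sd.simulate_background(small_config())
        b = sd.simulate_background(small_config())
        assert np.array_equal(a.haplotypes, b.haplotypes)
        c = sd.simulate_background(small_config(seed=12))
        assert not np.array_equal(a.haplotypes, c.haplotypes)

    def adjacent_r2(self, hm, n_pairs=150):
        gm = hm.to_genotypes()
        vals = [
            dosage_r2(gm.calls[:, j], gm.calls[:, j + 1])
            for j in range(n_pairs)
            if gm.calls[:, j].std() > 0 and gm.calls[:, j + 1].std() > 0
        ]
        return float(np.mean(vals))

    def test_copy_prob_zero_gives_no_ld(self):
        hm = sd.simulate_background(
            small_config(copy_prob=0.0, n_controls=40, n_snps=200)
        )
        assert self.adjacent_r2(hm) < 0.05

    def test_high_copy_prob_gives_strong_ld(self):
        # near-1 copying over a tiny founder pool collapses haplotypes onto
        # the founders, making adjacent polymorphic sites strongly correlated
        hm = sd.simulate_background(
            small_config(
                copy_prob=0.999, copy_noise=0.0, n_founder_haps=2,
                n_controls=40, n_snps=200,
            )
        )
        assert self.adjacent_r2(hm) > 0.5

    def test_background_lacks_risk_allele_at_focal(self):
        cfg = small_config()
        hm = sd.simulate_background(cfg)
        chrom, idx = cfg.focal_site()
        col = cfg.chromosomes.index(chrom) * cfg.n_snps + idx
        assert (hm.haplotypes[:, col] == 0).all()

    def test_degenerate_beta_rejected(self):
        with pytest.raises(sd.SimulationError):
            small_config(beta_a=0.0)


class TestFounderEvent:
    def test_tiny_tmrca_spans_nearly_whole_chromosome(self):
        cfg = small_config(founder_tmrca=0.1, n_snps=500)
        hm, truth = sd.plant_founder(sd.simulate_background(cfg), cfg)
        chrom_pos = hm.variants.loc[
            hm.variants["chrom"] == truth.focal_chrom, "pos"
        ]
        lo, hi = chrom_pos.min(), chrom_pos.max()
        for start, end in truth.retained_bp.values():
            assert (end - start) > 0.9 * (hi - lo)

    def test_erosion_matches_exponential_mean(self):
        # one-sided retained genetic length averages 1/t* Morgans at c_sim=1
        cfg = sd.SimConfig(
            n_carriers=60, n_controls=2, n_chromosomes=1, n_snps=6000,
            snp_spacing_bp=2000, founder_tmrca=50.0, cm_per_mb=2.0, seed=5,
        )
        hm, truth = sd.plant_founder(sd.simulate_background(cfg), cfg)
        gmap = cfg.genetic_map()
        focal_cm = gmap.cm_at(truth.focal_chrom, truth.focal_pos_bp)
        one_sided = []
        for start, end in truth.retained_bp.values():
            one_sided.append((focal_cm - gmap.cm_at(truth.focal_chrom, start)) / 100)
            one_sided.append((gmap.cm_at(truth.focal_chrom, end) - focal_cm) / 100)
        # SNP discretization truncates each side by up to one spacing
        assert np.mean(one_sided) == pytest.approx(1 / 50.0, rel=0.25)

    def test_controls_never_carry_risk_allele(self):
        cfg = small_config()
        cohort = sd.make_cohort(cfg)
        hm = cohort.haplotypes
        focal = hm.variant_index(cohort.truth.focal_chrom, cohort.truth.focal_pos_bp)
        for ctl in cfg.control_ids:
            for phase in (0, 1):
                assert hm.haplotypes[hm.hap_row(ctl, phase), focal] == 0

    def test_carriers_heterozygous_by_default_homozygous_by_flag(self):
        cohort = sd.make_cohort(small_config())
        hm = cohort.haplotypes
        focal = hm.variant_index(cohort.truth.focal_chrom, cohort.truth.focal_pos_bp)
        for pat, phase in cohort.truth.carrier_phase.items():
            assert hm.haplotypes[hm.hap_row(pat, phase), focal] == 1
            assert hm.haplotypes[hm.hap_row(pat, 1 - phase), focal] == 0
        hom = sd.make_cohort(small_config(carriers_homozygous=True))
        fh = hom.haplotypes.variant_index(
            hom.truth.focal_chrom, hom.truth.focal_pos_bp
        )
        for pat in hom.truth.carriers:
            assert hom.haplotypes.haplotypes[hom.haplotypes.hap_row(pat, 0), fh] == 1
            assert hom.haplotypes.haplotypes[hom.haplotypes.hap_row(pat, 1), fh] == 1

    def test_retained_intervals_contain_focal(self):
        cohort = sd.make_cohort(small_config(founder_tmrca=200.0))
        for start, end in cohort.truth.retained_bp.values():
            assert start <= cohort.truth.focal_pos_bp <= end


class TestMissingness:
    def test_rate_zero_identity(self):
        hm = sd.simulate_background(small_config())
        assert sd.inject_missingness(hm, 0.0, seed=1) is hm

    def test_realized_rate_within_binomial_error(self):
        hm = sd.simulate_background(small_config(n_controls=20, n_snps=500))
        out = sd.inject_missingness(hm, 0.5, seed=3)
        n = out.haplotypes.size
        realized = (out.haplotypes == MISSING).mean()
        assert abs(realized - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_deterministic_given_seed(self):
        hm = sd.simulate_background(small_config())
        a = sd.inject_missingness(hm, 0.2, seed=9)
        b = sd.inject_missingness(hm, 0.2, seed=9)
        assert np.array_equal(a.haplotypes, b.haplotypes)


class TestWriteCohort:
    def test_write_read_round_trip(self, tmp_path):
        cohort = sd.make_cohort(small_config(missing_rate=0.02))
        paths = sd.write_cohort(cohort, tmp_path)
        back, _ = io_formats.read_phased_vcf(paths["vcf"])
        assert np.array_equal(back.haplotypes, cohort.haplotypes.haplotypes)
        assert back.sample_ids == cohort.haplotypes.sample_ids
        sheet = io_formats.read_sample_sheet(paths["sheet"])
        assert set(sheet.carriers) == set(cohort.config.carrier_ids)
        gmap = io_formats.read_genetic_map(paths["map"])
        chrom = cohort.truth.focal_chrom
        pos = cohort.truth.focal_pos_bp
        assert gmap.cm_at(chrom, pos) == pytest.approx(
            cohort.gmap.cm_at(chrom, pos)
        )

    def test_truth_json_invariants(self, tmp_path):
        cohort = sd.make_cohort(small_config())
        paths = sd.write_cohort(cohort, tmp_path)
        truth = json.loads((tmp_path / "founder_truth.json").read_text())
        for start, end in truth["retained_bp"].values():
            assert start <= truth["focal_pos_bp"] <= end
        roles = io_formats.read_sample_sheet(paths["sheet"])
        assert sorted(roles.carriers + roles.controls) == sorted(
            cohort.haplotypes.sample_ids
        )


def test_detected_segment_covers_planted_intersection():
    """End-to-end: detection recovers (at least) the planted intersection.

    The detected segment can extend past the planted boundaries only by
    chance agreement of the flanking background haplotypes.
    """
    for seed in range(5):
        cfg = sd.SimConfig(
            n_carriers=5, n_controls=5, n_chromosomes=1, n_snps=2500,
            founder_tmrca=40.0, seed=100 + seed,
        )
        cohort = sd.make_cohort(cfg)
        truth = cohort.truth
        spec = FocalSpec(truth.focal_chrom, truth.focal_pos_bp, 1, truth.carriers)
        seg = focal_shared_segment(cohort.haplotypes, spec)
        lo, hi = truth.intersection_bp()
        assert seg.start_bp <= lo and seg.end_bp >= hi
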