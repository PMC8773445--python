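import numpy as np
import pytest

from founder_tracer import haploshare as hs
from founder_tracer.datamodel import MISSING

from conftest import hm_from_rows, random_hm
from oracles import focal_oracle, scan_oracle


def spec_for(hm, focal_idx, carriers, risk=1):
    return hs.FocalSpec(
        chrom=hm.variants["chrom"].iloc[focal_idx],
        pos_bp=int(hm.variants["pos"].iloc[focal_idx]),
        risk_allele=risk,
        carriers=carriers,
    )


class TestCarrierHaplotypes:
    def test_het_carriers_contribute_one_row_each(self):
        hm = hm_from_rows(["010", "000"] * 5)
        spec = spec_for(hm, 1, [f"S{i+1}" for i in range(5)])
        rows = hs.carrier_haplotypes(hm, spec)
        assert rows == [0, 2, 4, 6, 8]

    def test_homozygote_tie_rule_phase0(self):
        hm = hm_from_rows(["010", "010", "010", "000"])
        spec = spec_for(hm, 1, ["S1", "S2"])
        rows = hs.carrier_haplotypes(hm, spec)
        assert rows == [0, 2]  # S1 homozygous -> phase 0

    def test_phase1_carrier_selected(self):
        hm = hm_from_rows(["000", "010"])
        spec = spec_for(hm, 1, ["S1"])
        assert hs.carrier_haplotypes(hm, spec) == [1]

    def test_noncarrier_named_in_error(self):
        hm = hm_from_rows(["000", "000"])
        spec = spec_for(hm, 1, ["S1"])
        with pytest.raises(hs.HaploshareError, match="S1"):
            hs.carrier_haplotypes(hm, spec)


class TestFocalSegment:
    def test_planted_300_snp_segment(self, rng):
        n_snps = 600
        founder = (rng.random(n_snps) < 0.5).astype(np.int8)
        founder[250] = 1
        haps = (rng.random((10, n_snps)) < 0.5).astype(np.int8)
        for k in range(5):
            haps[2 * k, 100:400] = founder[100:400]
            # engineered mismatches flanking the planted block
            haps[2 * k, 99] = k % 2
            haps[2 * k, 400] = (k + 1) % 2
        rows = ["".join(str(x) for x in h) for h in haps]
        hm = hm_from_rows(rows)
        spec = spec_for(hm, 250, [f"S{i+1}" for i in range(5)])
        seg = hs.focal_shared_segment(hm, spec)
        assert seg.n_snps == 300
        assert seg.idx_start == 100 and seg.idx_end == 399

    def test_adjacent_mismatch_excluded(self):
        hm = hm_from_rows(["0110", "0000", "0010", "0000"])
        spec = spec_for(hm, 2, ["S1", "S2"])
        seg = hs.focal_shared_segment(hm, spec)
        assert (seg.idx_start, seg.idx_end) == (2, 3)

    def test_disagreement_at_focal_degenerates_with_warning(self):
        # carrier selection guarantees agreement at the focal site, so the
        # degenerate path is exercised on explicit member rows
        hm = hm_from_rows(["010", "000", "000", "010"])
        spec = spec_for(hm, 1, ["S1", "S2"])
        with pytest.warns(UserWarning, match="degenerate"):
            seg = hs._focal_segment_for_rows(hm, np.array([0, 2]), spec, 1, False)
        assert seg.n_snps == 1
        assert seg.start_bp == seg.end_bp == spec.pos_bp

    def test_missing_does_not_break_but_does_not_count(self):
        hm = hm_from_rows(["01110", "00000", "11.11", "00000"])
        spec = spec_for(hm, 3, ["S1", "S2"])
        seg = hs.focal_shared_segment(hm, spec)
        assert (seg.idx_start, seg.idx_end) == (1, 3)
        assert seg.n_snps == 2  # the masked site does not count

    def test_strict_missing_breaks(self):
        hm = hm_from_rows(["01110", "00000", "11.11", "00000"])
        spec = spec_for(hm, 3, ["S1", "S2"])
        seg = hs.focal_shared_segment(hm, spec, strict_missing=True)
        assert (seg.idx_start, seg.idx_end) == (3, 3)

    def test_try_both_phases_can_extend(self):
        # S1 homozygous at focal; phase 1 matches S2's haplotype further left
        hm = hm_from_rows(["0011", "1111", "1111", "0000"])
        spec = spec_for(hm, 2, ["S1", "S2"])
        default = hs.focal_shared_segment(hm, spec)
        widened = hs.focal_shared_segment(hm, spec, try_both_phases=True)
        assert widened.n_snps >= default.n_snps
        assert widened.n_snps == 4

    def test_monotone_in_member_set(self, rng):
        hm = random_hm(rng, 12, 400)
        haps = hm.haplotypes
        haps[0::2, 150:250] = haps[0, 150:250]  # common core for phase-0 rows
        haps[0::2, 200] = 1
        carriers = [f"S{i+1}" for i in range(6)]
        spec = spec_for(hm, 200, carriers)
        prev = None
        for k in range(2, 7):
            seg = hs.focal_shared_segment(hm, spec, carriers=carriers[:k])
            if prev is not None:
                assert seg.n_snps <= prev.n_snps
                assert seg.length_bp <= prev.length_bp
            prev = seg


class TestGenomewideScan:
    def test_identical_members_one_segment(self):
        row = "0110100101" * 100
        hm = hm_from_rows([row, "0" * 1000, row, "1" * 1000])
        segs = hs.genomewide_segment_scan(hm, [0, 2])
        assert len(segs) == 1
        assert segs[0].n_snps == 1000

    def test_single_mismatch_splits_into_two(self):
        row = "0" * 1000
        other = "0" * 500 + "1" + "0" * 499
        hm = hm_from_rows([row, "1" * 1000, other, "1" * 1000])
        segs = hs.genomewide_segment_scan(hm, [0, 2])
        assert len(segs) == 2
        assert [s.n_snps for s in segs] == [500, 499]

    def test_matches_oracle_on_random_fixtures(self, rng):
        for _ in range(15):
            hm = random_hm(
                rng,
                int(rng.integers(2, 8)) * 2,
                int(rng.integers(50, 300)),
                missing_rate=float(rng.choice([0.0, 0.05])),
                n_chroms=int(rng.integers(1, 3)),
            )
            k = int(rng.integers(2, min(6, hm.n_haplotypes) + 1))
            rows = rng.choice(hm.n_haplotypes, size=k, replace=False)
            strict = bool(rng.integers(2))
            got = [
                (s.chrom, s.start_bp, s.end_bp, s.n_snps)
                for s in hs.genomewide_segment_scan(hm, rows, strict_missing=strict)
            ]
            assert got == scan_oracle(hm, rows, strict_missing=strict)

    def test_sizes_table_agrees_with_object_scan(self, rng):
        hm = random_hm(rng, 10, 500, missing_rate=0.03)
        rows = [0, 3, 5]
        segs = hs.genomewide_segment_scan(hm, rows)
        sizes = hs.scan_segment_sizes(hm, rows)
        assert len(segs) == len(sizes)
        assert [s.n_snps for s in segs] == sizes["n_snps"].tolist()
        assert [s.start_bp for s in segs] == sizes["start_bp"].tolist()

    def test_emitted_segments_verify_against_members(self, rng):
        hm = random_hm(rng, 8, 300, missing_rate=0.05)
        for seg in hs.genomewide_segment_scan(hm, [0, 2, 4]):
            assert hs.verify_segment(hm, seg)

    def test_needs_two_members(self, rng):
        hm = random_hm(rng, 4, 50)
        with pytest.raises(hs.HaploshareError):
            hs.genomewide_segment_scan(hm, [1])


class TestRankStatistics:
    @staticmethod
    def seg(n_snps, start=0, length=10_000, chrom="1"):
        return hs.SharedSegment(
            chrom=chrom, start_bp=start, end_bp=start + length,
            n_snps=n_snps, members=("S1_h0", "S2_h0"),
        )

    def test_focal_strictly_largest(self):
        focal = self.seg(500, start=10**6)
        scan = [focal] + [self.seg(i % 100 + 1, start=2 * 10**6 + 20_000 * i)
                          for i in range(9_999)]
        res = hs.rank_statistics(focal, scan)
        assert res["snps"].p == pytest.approx(1 / 10_000)

    def test_two_other_segments_at_least_as_large(self):
        focal = self.seg(47, start=10**6, length=250_000)
        others = [self.seg(47, start=3 * 10**6), self.seg(51, start=5 * 10**6)]
        fillers = [self.seg(5, start=7 * 10**6 + 10_000 * i) for i in range(97)]
        res = hs.rank_statistics(focal, [focal] + others + fillers)
        assert res["snps"].n_at_least == 3
        assert res["snps"].p == pytest.approx(3 / 100)
        # bp metric ranks independently: focal has the longest span here
        assert res["bp"].p == pytest.approx(1 / 100)

    def test_empty_scan_errors(self):
        with pytest.raises(hs.HaploshareError):
            hs.rank_statistics(self.seg(10), [])


class TestPatientControlNull:
    def build(self, rng, plant=False):
        hm = random_hm(rng, 12, 600)
        if plant:  # long shared tract between carrier S1 phase0 and control S4
            hm.haplotypes[6, 100:500] = hm.haplotypes[0, 100:500]
        hm.haplotypes[0, 300] = 1  # risk allele on S1 phase 0
        if plant:
            hm.haplotypes[6, 300] = hm.haplotypes[0, 300]
        spec = spec_for(hm, 300, ["S1"])
        controls = ["S4", "S5", "S6"]
        return hm, spec, controls

    def test_unreachable_target_gives_bound(self, rng):
        hm, spec, controls = self.build(rng)
        results, _ = hs.patient_control_null(
            hm, spec, controls, target_snps=10**6, target_bp=10**9
        )
        r = results[0]
        assert r.count_snps == 0
        assert r.p_snps == pytest.approx(1.0 / (r.n_segments + 1))

    def test_planted_tract_is_counted(self, rng):
        hm, spec, controls = self.build(rng, plant=True)
        results, _ = hs.patient_control_null(
            hm, spec, controls, target_snps=300, target_bp=300_000
        )
        assert results[0].count_snps >= 1
        assert results[0].p_snps > 0

    def test_bonferroni_arithmetic(self, rng):
        hm, spec, controls = self.build(rng)
        _, threshold = hs.patient_control_null(
            hm, spec, controls, target_snps=5, target_bp=5_000, alpha=0.05
        )
        assert threshold == pytest.approx(0.05 / (1 * 3))


def test_focal_oracle_agreement_on_random_fixtures(rng):
    for _ in range(15):
        hm = random_hm(rng, 8, 200, missing_rate=0.04)
        rows = [0, 2, 4]
        hm.haplotypes[rows, 100] = 1  # make all members carry the risk allele
        carriers = ["S1", "S2", "S3"]
        spec = spec_for(hm, 100, carriers)
        seg = hs.focal_shared_segment(hm, spec)
        assert (seg.chrom, seg.start_bp, seg.end_bp, seg.n_snps) == focal_oracle(
            hm, rows, 100
        )
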