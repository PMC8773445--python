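"""Shared-haplotype segment detection and empirical significance.

Given phased haplotypes and a focal mutation, this module

1. selects, per carrier, the haplotype bearing the risk allele
   (:func:`carrier_haplotypes`),
2. finds the maximal segment over which those haplotypes are identical
   around the focal site (:func:`focal_shared_segment`),
3. enumerates every distinct maximal shared segment of the same haplotype
   set genome-wide (:func:`genomewide_segment_scan`) and ranks the focal
   segment against them (:func:`rank_statistics`), and
4. asks how often each carrier shares a comparably sized tract with any
   control haplotype (:func:`patient_control_null`).

Missing-data rule (default): a missing allele never breaks a segment but does
not count toward its SNP total; ``strict_missing=True`` makes missing calls
break segments instead.  Both rules are exercised by the test suite.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from .datamodel import MISSING, HaplotypeMatrix, normalize_chrom


class HaploshareError(ValueError):
    pass


@dataclass
class FocalSpec:
    """The focal mutation and its reported carriers."""

    chrom: str
    pos_bp: int
    risk_allele: int  # 0 = ref, 1 = alt
    carriers: list[str]

    def __post_init__(self) -> None:
        self.chrom = normalize_chrom(self.chrom)
        if self.risk_allele not in (0, 1):
            raise HaploshareError("risk_allele must be 0 (ref) or 1 (alt)")
        if not self.carriers:
            raise HaploshareError("at least one carrier required")


@dataclass
class SharedSegment:
    """A maximal interval over which a haplotype set is identical."""

    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int
    members: tuple[str, ...]
    consensus: np.ndarray = field(repr=False, default_factory=lambda: np.array([]))
    idx_start: int = -1   # variant indices of the outermost matching SNPs
    idx_end: int = -1

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp

    def same_locus(self, other: "SharedSegment") -> bool:
        return (
            self.chrom == other.chrom
            and self.start_bp == other.start_bp
            and self.end_bp == other.end_bp
        )


@dataclass
class RankResult:
    """Empirical genome-wide rank of the focal segment for one size metric."""

    metric: str               # "snps" or "bp"
    focal_value: int
    n_at_least: int           # segments >= focal, focal itself included
    n_total: int
    @property
    def p(self) -> float:
        return self.n_at_least / self.n_total


@dataclass
class ControlNullResult:
    """Carrier-vs-control sharing counts for one carrier."""

    carrier: str
    target_snps: int
    target_bp: int
    count_snps: int
    count_bp: int
    n_segments: int           # distinct segments scanned for this carrier
    p_snps: float
    p_bp: float


# ---------------------------------------------------------------------------
# site agreement and run extraction
# ---------------------------------------------------------------------------

def _site_agreement(
    h: np.ndarray, strict_missing: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site flags for a (k, m) haplotype slice.

    Returns ``agree`` (the site does not break a segment) and ``full`` (all
    members observed and identical; counts toward n_snps).
    """
    obs = h != MISSING
    hi = np.where(obs, h, np.int8(-2)).max(axis=0)
    lo = np.where(obs, h, np.int8(2)).min(axis=0)
    any_obs = obs.any(axis=0)
    equal = hi == lo
    full = obs.all(axis=0) & equal
    if strict_missing:
        agree = full
    else:
        agree = np.where(any_obs, equal, True)
    return agree, full


def _runs_of_true(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, stop) runs of True."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts, stops))


def _segment_from_run(
    hm: HaplotypeMatrix,
    rows: np.ndarray,
    members: tuple[str, ...],
    chrom: str,
    chrom_idx: np.ndarray,
    run: tuple[int, int],
    full: np.ndarray,
) -> SharedSegment | None:
    """Build a segment from a run of agreeing sites (chromosome-local)."""
    a, b = run
    full_local = np.flatnonzero(full[a:b]) + a
    if full_local.size == 0:
        return None  # no fully matching SNP inside -> not a reportable segment
    first, last = int(full_local[0]), int(full_local[-1])
    gidx_first = int(chrom_idx[first])
    gidx_last = int(chrom_idx[last])
    pos = hm.variants["pos"].to_numpy()
    sl = hm.haplotypes[np.ix_(rows, chrom_idx[first: last + 1])]
    obs = sl != MISSING
    cons = np.where(
        obs.any(axis=0),
        np.where(obs, sl, np.int8(-2)).max(axis=0),
        np.int8(MISSING),
    ).astype(np.int8)
    return SharedSegment(
        chrom=chrom,
        start_bp=int(pos[gidx_first]),
        end_bp=int(pos[gidx_last]),
        n_snps=int(full_local.size),
        members=members,
        consensus=cons,
        idx_start=gidx_first,
        idx_end=gidx_last,
    )


def _chrom_indices(hm: HaplotypeMatrix) -> dict[str, np.ndarray]:
    chroms = hm.variants["chrom"].to_numpy()
    return {c: np.flatnonzero(chroms == c) for c in dict.fromkeys(chroms)}


# ---------------------------------------------------------------------------
# carrier haplotype selection
# ---------------------------------------------------------------------------

def carrier_haplotypes(
    hm: HaplotypeMatrix, spec: FocalSpec, try_both_phases: bool = False
) -> list[int]:
    """Row index of the risk-allele-bearing haplotype for each carrier.

    A homozygous carrier contributes phase 0 by default (deterministic tie
    rule); with ``try_both_phases`` the caller receives phase 0 here and may
    swap via :func:`focal_shared_segment`'s tie search.
    """
    focal = hm.variant_index(spec.chrom, spec.pos_bp)
    rows = []
    for carrier in spec.carriers:
        r0 = hm.hap_row(carrier, 0)
        a0 = hm.haplotypes[r0, focal]
        a1 = hm.haplotypes[r0 + 1, focal]
        if a0 == MISSING and a1 == MISSING:
            raise HaploshareError(f"carrier {carrier} not genotyped at focal site")
        has0 = a0 == spec.risk_allele
        has1 = a1 == spec.risk_allele
        if not has0 and not has1:
            raise HaploshareError(
                f"carrier {carrier} lacks the risk allele at "
                f"{spec.chrom}:{spec.pos_bp} - the mutation must tag a haplotype"
            )
        rows.append(r0 if has0 else r0 + 1)
    return rows


# ---------------------------------------------------------------------------
# focal segment
# ---------------------------------------------------------------------------

def focal_shared_segment(
    hm: HaplotypeMatrix,
    spec: FocalSpec,
    carriers: list[str] | None = None,
    strict_missing: bool = False,
    try_both_phases: bool = False,
) -> SharedSegment:
    """Maximal segment around the focal site shared by the carrier haplotypes.

    ``carriers`` restricts to a subset (e.g. for the nested drop-one
    analysis).  With ``try_both_phases``, homozygous carriers are assigned
    the phase that maximizes the resulting segment's SNP count.
    """
    sub = spec if carriers is None else FocalSpec(
        spec.chrom, spec.pos_bp, spec.risk_allele, list(carriers)
    )
    rows = carrier_haplotypes(hm, sub)
    focal = hm.variant_index(sub.chrom, sub.pos_bp)

    homozygous = []
    if try_both_phases:
        for k, carrier in enumerate(sub.carriers):
            r0 = hm.hap_row(carrier, 0)
            if (
                hm.haplotypes[r0, focal] == sub.risk_allele
                and hm.haplotypes[r0 + 1, focal] == sub.risk_allele
            ):
                homozygous.append(k)

    best = _focal_segment_for_rows(hm, np.array(rows), sub, focal, strict_missing)
    for combo in _phase_combos(homozygous):
        alt_rows = list(rows)
        for k in combo:
            alt_rows[k] += 1
        seg = _focal_segment_for_rows(
            hm, np.array(alt_rows), sub, focal, strict_missing
        )
        if seg.n_snps > best.n_snps:
            best = seg
    return best


def _phase_combos(homozygous: list[int]):
    for r in range(1, len(homozygous) + 1):
        yield from itertools.combinations(homozygous, r)


def _focal_segment_for_rows(
    hm: HaplotypeMatrix,
    rows: np.ndarray,
    spec: FocalSpec,
    focal: int,
    strict_missing: bool,
) -> SharedSegment:
    members = tuple(hm.hap_id(int(r)) for r in rows)
    by_chrom = _chrom_indices(hm)
    chrom_idx = by_chrom[spec.chrom]
    local_focal = int(np.searchsorted(chrom_idx, focal))
    h = hm.haplotypes[np.ix_(rows, chrom_idx)]
    agree, full = _site_agreement(h, strict_missing)
    if not agree[local_focal]:
        warnings.warn(
            f"carrier haplotypes disagree at the focal site "
            f"{spec.chrom}:{spec.pos_bp}; returning a degenerate 1-SNP segment",
            stacklevel=2,
        )
        pos = int(hm.variants["pos"].iloc[focal])
        return SharedSegment(
            chrom=spec.chrom, start_bp=pos, end_bp=pos, n_snps=1,
            members=members, consensus=np.array([spec.risk_allele], np.int8),
            idx_start=focal, idx_end=focal,
        )
    for run in _runs_of_true(agree):
        if run[0] <= local_focal < run[1]:
            seg = _segment_from_run(
                hm, rows, members, spec.chrom, chrom_idx, run, full
            )
            if seg is None:  # focal observed in carriers, cannot happen here
                raise HaploshareError("focal run contains no matching SNP")
            return seg
    raise AssertionError("unreachable: focal site in no run")


# ---------------------------------------------------------------------------
# genome-wide scan
# ---------------------------------------------------------------------------

def genomewide_segment_scan(
    hm: HaplotypeMatrix,
    member_rows: list[int] | np.ndarray,
    strict_missing: bool = False,
    chroms: list[str] | None = None,
) -> list[SharedSegment]:
    """Every distinct maximal segment shared by ``member_rows`` genome-wide.

    Breakpoints are sites where the members disagree; each maximal
    breakpoint-delimited run containing at least one fully matching SNP
    yields one segment.
    """
    rows = np.asarray(member_rows)
    if rows.size < 2:
        raise HaploshareError("need at least 2 member haplotypes")
    members = tuple(hm.hap_id(int(r)) for r in rows)
    segments: list[SharedSegment] = []
    for chrom, chrom_idx in _chrom_indices(hm).items():
        if chroms is not None and chrom not in chroms:
            continue
        h = hm.haplotypes[np.ix_(rows, chrom_idx)]
        agree, full = _site_agreement(h, strict_missing)
        for run in _runs_of_true(agree):
            seg = _segment_from_run(hm, rows, members, chrom, chrom_idx, run, full)
            if seg is not None:
                segments.append(seg)
    return segments


def scan_segment_sizes(
    hm: HaplotypeMatrix,
    member_rows: list[int] | np.ndarray,
    strict_missing: bool = False,
    chroms: list[str] | None = None,
):
    """Vectorized genome-wide scan returning only segment coordinates/sizes.

    Produces one row per distinct shared segment (same definition as
    :func:`genomewide_segment_scan`) with columns
    ``chrom, start_bp, end_bp, n_snps, length_bp`` - no consensus vectors,
    so it is cheap enough for the all-pairs carrier-vs-control null.
    """
    import pandas as pd

    rows = np.asarray(member_rows)
    if rows.size < 2:
        raise HaploshareError("need at least 2 member haplotypes")
    pos_all = hm.variants["pos"].to_numpy()
    frames = []
    for chrom, chrom_idx in _chrom_indices(hm).items():
        if chroms is not None and chrom not in chroms:
            continue
        h = hm.haplotypes[np.ix_(rows, chrom_idx)]
        agree, full = _site_agreement(h, strict_missing)
        runs = _runs_of_true(agree)
        if not runs:
            continue
        a = np.array([r[0] for r in runs])
        b = np.array([r[1] for r in runs])  # exclusive
        cumfull = np.concatenate(([0], np.cumsum(full)))
        counts = cumfull[b] - cumfull[a]
        keep = counts >= 1
        if not keep.any():
            continue
        a, b, counts = a[keep], b[keep], counts[keep]
        full_idx = np.flatnonzero(full)
        first = full_idx[np.searchsorted(full_idx, a, side="left")]
        last = full_idx[np.searchsorted(full_idx, b, side="left") - 1]
        pos = pos_all[chrom_idx]
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start_bp": pos[first].astype(int),
                    "end_bp": pos[last].astype(int),
                    "n_snps": counts.astype(int),
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["chrom", "start_bp", "end_bp", "n_snps",
                                     "length_bp"])
    table = pd.concat(frames, ignore_index=True)
    table["length_bp"] = table["end_bp"] - table["start_bp"]
    return table


def verify_segment(hm: HaplotypeMatrix, seg: SharedSegment) -> bool:
    """Re-check that every member matches the consensus over the segment."""
    rows = [hm.hap_row(*_split_hap_id(m)) for m in seg.members]
    sl = hm.haplotypes[np.ix_(rows, np.arange(seg.idx_start, seg.idx_end + 1))]
    obs = sl != MISSING
    return bool(np.all((sl == seg.consensus[None, :]) | ~obs))


def _split_hap_id(hap_id: str) -> tuple[str, int]:
    sample, _, phase = hap_id.rpartition("_h")
    return sample, int(phase)


# ---------------------------------------------------------------------------
# rank statistics
# ---------------------------------------------------------------------------

def rank_statistics(
    focal: SharedSegment,
    scan: list[SharedSegment],
    exclude_focal_locus: bool = True,
) -> dict[str, RankResult]:
    """Empirical rank of the focal segment among the genome-wide scan.

    ``p = (1 + #non-focal segments >= focal) / total``; the focal segment
    itself contributes the ``1``, so p is never 0.  ``exclude_focal_locus``
    removes the focal segment itself from the comparison set (the rest of the
    focal chromosome stays in the null).
    """
    if not scan:
        raise HaploshareError("empty genome-wide scan")
    others = [s for s in scan if not s.same_locus(focal)] if exclude_focal_locus \
        else list(scan)
    n_total = len(others) + 1
    out = {}
    for metric, value in (("snps", focal.n_snps), ("bp", focal.length_bp)):
        attr = "n_snps" if metric == "snps" else "length_bp"
        n_ge = 1 + sum(1 for s in others if getattr(s, attr) >= value)
        out[metric] = RankResult(metric, value, n_ge, n_total)
    return out


# ---------------------------------------------------------------------------
# carrier-vs-control empirical null
# ---------------------------------------------------------------------------

def patient_control_null(
    hm: HaplotypeMatrix,
    spec: FocalSpec,
    control_samples: list[str],
    target_snps: int,
    target_bp: int,
    alpha: float = 0.05,
    strict_missing: bool = False,
) -> tuple[list[ControlNullResult], float]:
    """Per-carrier probability of sharing a target-sized tract with controls.

    Each carrier's risk haplotype is compared against both haplotypes of
    every control; each pairwise genome-wide scan contributes its distinct
    segments.  ``p = count / n_segments``; a zero count is reported as the
    one-sided bound ``1 / (n_segments + 1)``.  Returns the per-carrier results
    and the Bonferroni threshold ``alpha / (n_carriers * n_controls)``.
    """
    if not control_samples:
        raise HaploshareError("at least one control required")
    carrier_rows = carrier_haplotypes(hm, spec)
    results = []
    for carrier, row in zip(spec.carriers, carrier_rows):
        count_snps = count_bp = n_segments = 0
        for control in control_samples:
            for phase in (0, 1):
                crow = hm.hap_row(control, phase)
                sizes = scan_segment_sizes(
                    hm, [row, crow], strict_missing=strict_missing
                )
                n_segments += len(sizes)
                count_snps += int((sizes["n_snps"] >= target_snps).sum())
                count_bp += int((sizes["length_bp"] >= target_bp).sum())
        p_snps = count_snps / n_segments if count_snps else 1.0 / (n_segments + 1)
        p_bp = count_bp / n_segments if count_bp else 1.0 / (n_segments + 1)
        results.append(
            ControlNullResult(
                carrier=carrier,
                target_snps=target_snps,
                target_bp=target_bp,
                count_snps=count_snps,
                count_bp=count_bp,
                n_segments=n_segments,
                p_snps=p_snps,
                p_bp=p_bp,
            )
        )
    threshold = alpha / (len(spec.carriers) * len(control_samples))
    return results, threshold


# ---------------------------------------------------------------------------
# convenience: pairwise sharing matrix (per-pair focal segments)
# ---------------------------------------------------------------------------

def pairwise_focal_segments(
    hm: HaplotypeMatrix, spec: FocalSpec, strict_missing: bool = False
) -> dict[tuple[str, str], SharedSegment]:
    """Focal shared segment for every carrier pair (sharing-matrix analogue)."""
    out = {}
    for a, b in itertools.combinations(spec.carriers, 2):
        out[(a, b)] = focal_shared_segment(
            hm, spec, carriers=[a, b], strict_missing=strict_missing
        )
    return out
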