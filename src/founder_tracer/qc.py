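"""Variant/sample quality control for SNP-array genotype matrices.

The stack mirrors the standard pre-analysis pipeline for array cohorts:

1. missingness filters (variants first, then samples),
2. Hardy-Weinberg exact test with a Bonferroni family-wise threshold,
3. minor-allele-frequency filter (strict ``MAF < min_maf`` removal),
4. sliding-window LD pruning on genotype-dosage r^2.

Every filter is a pure function of its input and thresholds, and returns the
filtered matrix together with a :class:`QcReport` entry recording exactly what
was removed and which realized threshold was applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.special import gammaln, logsumexp

from .datamodel import MISSING, GenotypeMatrix


class QcError(ValueError):
    pass


@dataclass
class QcThresholds:
    """Filter thresholds; defaults follow common array-QC practice."""

    max_variant_missing: float = 0.05
    max_sample_missing: float = 0.05
    hwe_alpha: float = 0.05  # family-wise, Bonferroni over tested variants
    min_maf: float = 0.01
    ld_window: int = 50
    ld_step: int = 5
    ld_r2: float = 0.1

    def __post_init__(self) -> None:
        for name in ("max_variant_missing", "max_sample_missing", "hwe_alpha",
                     "min_maf", "ld_r2"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise QcError(f"{name} must be in [0,1], got {v}")
        if not self.ld_window >= self.ld_step >= 1:
            raise QcError("require ld_window >= ld_step >= 1")


@dataclass
class QcReport:
    """Ordered record of applied filters and their removal counts."""

    initial_shape: tuple[int, int] = (0, 0)
    final_shape: tuple[int, int] = (0, 0)
    steps: list[dict[str, Any]] = field(default_factory=list)

    def add(self, name: str, removed_variants: int = 0, removed_samples: int = 0,
            **params: Any) -> None:
        self.steps.append(
            {
                "filter": name,
                "removed_variants": int(removed_variants),
                "removed_samples": int(removed_samples),
                "params": params,
            }
        )

    def to_dict(self) -> dict[str, Any]:
        return {
            "initial_shape": list(self.initial_shape),
            "final_shape": list(self.final_shape),
            "steps": self.steps,
        }

    def check_consistency(self) -> None:
        dv = sum(s["removed_variants"] for s in self.steps)
        ds = sum(s["removed_samples"] for s in self.steps)
        ok = (
            self.initial_shape[0] - ds == self.final_shape[0]
            and self.initial_shape[1] - dv == self.final_shape[1]
        )
        if not ok:
            raise QcError("QcReport removal counts inconsistent with shapes")


def _require_nonempty(gm: GenotypeMatrix, stage: str) -> None:
    if gm.n_variants == 0 or gm.n_samples == 0:
        raise QcError(f"matrix empty after {stage} filtering")


# ---------------------------------------------------------------------------
# missingness
# ---------------------------------------------------------------------------

def variant_missingness(gm: GenotypeMatrix) -> np.ndarray:
    return (gm.calls == MISSING).mean(axis=0)


def sample_missingness(gm: GenotypeMatrix) -> np.ndarray:
    return (gm.calls == MISSING).mean(axis=1)


def filter_missingness(
    gm: GenotypeMatrix, thresholds: QcThresholds | None = None
) -> tuple[GenotypeMatrix, QcReport]:
    """Drop variants then samples whose missingness is >= the threshold.

    Retention is strict (< threshold), and variants are filtered before
    samples so that a badly genotyped variant cannot drag samples down.
    """
    th = thresholds or QcThresholds()
    report = QcReport(initial_shape=(gm.n_samples, gm.n_variants))

    keep_v = variant_missingness(gm) < th.max_variant_missing
    out = gm.subset_variants(np.flatnonzero(keep_v))
    report.add("variant_missingness", removed_variants=int((~keep_v).sum()),
               threshold=th.max_variant_missing)
    _require_nonempty(out, "variant-missingness")

    keep_s = sample_missingness(out) < th.max_sample_missing
    out = out.subset_samples(np.flatnonzero(keep_s))
    report.add("sample_missingness", removed_samples=int((~keep_s).sum()),
               threshold=th.max_sample_missing)
    _require_nonempty(out, "sample-missingness")

    report.final_shape = (out.n_samples, out.n_variants)
    report.check_consistency()
    return out, report


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact Hardy-Weinberg test on genotype counts.

    Conditional on the observed allele counts, sums the probabilities of all
    heterozygote configurations whose probability does not exceed that of the
    observed configuration.  Monomorphic sites return 1.0 by convention.
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(int(c) != c or c < 0 for c in counts):
        raise QcError(f"genotype counts must be non-negative integers: {counts}")
    n_hom_ref, n_het, n_hom_alt = (int(c) for c in counts)
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise QcError("at least one observation required")
    n_rare = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)
    if n_rare == 0:
        return 1.0

    # heterozygote counts with the parity of the rare-allele total
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    # log P(het = h | n, n_rare) up to a shared constant:
    #   2^h * n! / (((n_rare-h)/2)! h! ((2n-n_rare-h)/2)!)
    logw = (
        hets * np.log(2.0)
        - gammaln((n_rare - hets) / 2 + 1)
        - gammaln(hets + 1)
        - gammaln((2 * n - n_rare - hets) / 2 + 1)
    )
    logp = logw - logsumexp(logw)
    p_obs = logp[np.searchsorted(hets, n_het)]
    # tolerance absorbs float noise in tie detection
    keep = logp <= p_obs + 1e-10
    return float(min(1.0, np.exp(logsumexp(logp[keep]))))


def genotype_counts(gm: GenotypeMatrix) -> np.ndarray:
    """Per-variant (n_hom_ref, n_het, n_hom_alt) over non-missing calls."""
    c = gm.calls
    return np.stack(
        [(c == 0).sum(axis=0), (c == 1).sum(axis=0), (c == 2).sum(axis=0)], axis=1
    )


def hwe_filter(
    gm: GenotypeMatrix, thresholds: QcThresholds | None = None
) -> tuple[GenotypeMatrix, QcReport]:
    """Remove variants whose exact HWE p is below alpha / n_variants_tested."""
    th = thresholds or QcThresholds()
    report = QcReport(initial_shape=(gm.n_samples, gm.n_variants))
    counts = genotype_counts(gm)
    pvals = np.array([hwe_exact_test(*row) for row in counts])
    realized = th.hwe_alpha / gm.n_variants
    keep = pvals >= realized
    out = gm.subset_variants(np.flatnonzero(keep))
    report.add("hwe", removed_variants=int((~keep).sum()),
               alpha=th.hwe_alpha, n_tested=gm.n_variants,
               realized_threshold=realized)
    _require_nonempty(out, "HWE")
    report.final_shape = (out.n_samples, out.n_variants)
    report.check_consistency()
    return out, report


# ---------------------------------------------------------------------------
# minor allele frequency
# ---------------------------------------------------------------------------

def alt_allele_frequency(gm: GenotypeMatrix) -> np.ndarray:
    """Alt-allele frequency per variant over non-missing calls (nan if none)."""
    c = gm.calls.astype(float)
    obs = gm.calls != MISSING
    with np.errstate(invalid="ignore"):
        return np.where(obs, c, 0.0).sum(axis=0) / (2.0 * obs.sum(axis=0))


def minor_allele_frequency(gm: GenotypeMatrix) -> np.ndarray:
    p = alt_allele_frequency(gm)
    return np.minimum(p, 1.0 - p)


def maf_filter(
    gm: GenotypeMatrix, thresholds: QcThresholds | None = None
) -> tuple[GenotypeMatrix, QcReport]:
    """Remove variants with MAF strictly lower than ``min_maf``."""
    th = thresholds or QcThresholds()
    report = QcReport(initial_shape=(gm.n_samples, gm.n_variants))
    maf = minor_allele_frequency(gm)
    keep = ~(maf < th.min_maf)  # NaN (all-missing) kept for missingness filter
    out = gm.subset_variants(np.flatnonzero(keep))
    report.add("maf", removed_variants=int((~keep).sum()), min_maf=th.min_maf)
    _require_nonempty(out, "MAF")
    report.final_shape = (out.n_samples, out.n_variants)
    report.check_consistency()
    return out, report


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def dosage_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors, pairwise-complete."""
    m = (x != MISSING) & (y != MISSING)
    if m.sum() < 2:
        return 0.0
    xv = x[m].astype(float)
    yv = y[m].astype(float)
    sx = xv.std()
    sy = yv.std()
    if sx == 0 or sy == 0:
        return 0.0
    r = ((xv - xv.mean()) * (yv - yv.mean())).mean() / (sx * sy)
    return float(r * r)


def ld_prune(
    gm: GenotypeMatrix, thresholds: QcThresholds | None = None
) -> tuple[list[str], QcReport]:
    """Greedy sliding-window LD pruning; returns the kept variant IDs.

    Within each window of ``ld_window`` variants (advancing by ``ld_step``),
    pairs of kept variants with dosage r^2 above ``ld_r2`` are broken by
    removing the variant with the lower MAF (ties: the later one in position
    order).  Post-condition: no surviving within-window pair exceeds the
    threshold.
    """
    th = thresholds or QcThresholds()
    report = QcReport(initial_shape=(gm.n_samples, gm.n_variants))
    maf = minor_allele_frequency(gm)
    keep = np.ones(gm.n_variants, dtype=bool)

    for chrom in gm.variants["chrom"].unique():
        idx = np.flatnonzero((gm.variants["chrom"] == chrom).to_numpy())
        if idx.size < 2:
            continue
        start = 0
        while start < idx.size:
            window = idx[start: start + th.ld_window]
            if window.size >= 2:
                _prune_window(gm.calls, window, keep, maf, th.ld_r2)
            if start + th.ld_window >= idx.size:
                break
            start += th.ld_step

    kept_ids = gm.variants["id"].to_numpy()[keep].tolist()
    report.add("ld_prune", removed_variants=int((~keep).sum()),
               window=th.ld_window, step=th.ld_step, r2=th.ld_r2)
    report.final_shape = (gm.n_samples, int(keep.sum()))
    report.check_consistency()
    return kept_ids, report


def _prune_window(calls: np.ndarray, window: np.ndarray, keep: np.ndarray,
                  maf: np.ndarray, r2_thr: float) -> None:
    active = [int(v) for v in window if keep[v]]
    changed = True
    while changed and len(active) >= 2:
        changed = False
        for a_pos in range(len(active)):
            for b_pos in range(a_pos + 1, len(active)):
                a, b = active[a_pos], active[b_pos]
                if dosage_r2(calls[:, a], calls[:, b]) > r2_thr:
                    # remove lower-MAF variant; ties -> later in position order
                    victim = b if (maf[b] < maf[a] or maf[a] == maf[b]) else a
                    keep[victim] = False
                    active.remove(victim)
                    changed = True
                    break
            if changed:
                break


# ---------------------------------------------------------------------------
# full stack
# ---------------------------------------------------------------------------

def run_qc(
    gm: GenotypeMatrix, thresholds: QcThresholds | None = None
) -> tuple[GenotypeMatrix, list[str], QcReport]:
    """missingness -> HWE -> MAF -> LD prune; returns (post-QC matrix minus
    the LD step, kept-after-prune variant IDs, combined report)."""
    th = thresholds or QcThresholds()
    combined = QcReport(initial_shape=(gm.n_samples, gm.n_variants))
    out, rep = filter_missingness(gm, th)
    combined.steps += rep.steps
    out, rep = hwe_filter(out, th)
    combined.steps += rep.steps
    out, rep = maf_filter(out, th)
    combined.steps += rep.steps
    kept_ids, rep = ld_prune(out, th)
    combined.steps += rep.steps
    combined.final_shape = (out.n_samples, len(kept_ids))
    combined.check_consistency()
    return out, kept_ids, combined
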