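"""Genotype-based population structure and relatedness.

* :func:`run_pca` - PCA on frequency-standardized dosages (the smartpca-style
  scaling by sqrt(p(1-p))), used to place carriers inside the background
  population's variability.
* :func:`ibd_moments` - method-of-moments genome-wide IBD for a sample pair
  (the classic --genome estimator): observed identity-by-state counts are
  inverted against their allele-frequency expectations to give Z0/Z1/Z2 and
  PI_HAT = Z1/2 + Z2.
* :func:`relatedness_screen` - the "top 1%" unrelatedness rule: a
  carrier-carrier pair is flagged when its PI_HAT exceeds the empirical 99th
  percentile (nearest-rank) of the carrier-control PI_HAT distribution.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import MISSING, GenotypeMatrix, SampleSheet


class StructureError(ValueError):
    pass


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PcaResult:
    coords: pd.DataFrame          # samples x PC1..PCk
    explained: np.ndarray         # explained-variance fraction per component
    loadings: np.ndarray | None = None


def run_pca(gm: GenotypeMatrix, k: int = 10) -> PcaResult:
    """Eigendecomposition of the sample covariance of standardized dosages.

    Missing calls are mean-imputed per variant; variants are centered and
    scaled by sqrt(p(1-p)) with p the alt-allele frequency; monomorphic
    variants are dropped.
    """
    if k >= gm.n_samples:
        raise StructureError(f"k={k} must be < n_samples={gm.n_samples}")
    X = gm.calls.astype(float)
    obs = gm.calls != MISSING
    n_obs = obs.sum(axis=0)
    if (n_obs == 0).any():
        raise StructureError("variant with no observed calls")
    mean = np.where(obs, X, 0.0).sum(axis=0) / n_obs
    X = np.where(obs, X, mean)  # mean imputation
    p = mean / 2.0
    poly = (p > 0) & (p < 1) & (X.std(axis=0) > 0)
    X = X[:, poly]
    p = p[poly]
    Z = (X - X.mean(axis=0)) / np.sqrt(p * (1 - p))
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    coords = U[:, :k] * s[:k]
    explained = (s**2) / (s**2).sum()
    return PcaResult(
        coords=pd.DataFrame(
            coords, index=gm.samples, columns=[f"PC{i+1}" for i in range(k)]
        ),
        explained=explained[:k],
        loadings=Vt[:k].T,
    )


# ---------------------------------------------------------------------------
# method-of-moments IBD
# ---------------------------------------------------------------------------

@dataclass
class IbdEstimate:
    sample_1: str
    sample_2: str
    z0: float
    z1: float
    z2: float
    n_sites: int

    @property
    def pi_hat(self) -> float:
        return self.z1 / 2.0 + self.z2


def _ibs_state_expectations(p: np.ndarray) -> np.ndarray:
    """P(IBS=s | Z=z) summed over sites; rows s=0,1,2, cols z=0,1,2."""
    q = 1.0 - p
    e = np.zeros((3, 3))
    e[0, 0] = (2 * p**2 * q**2).sum()
    e[1, 0] = (4 * p**3 * q + 4 * p * q**3).sum()
    e[2, 0] = (p**4 + q**4 + 4 * p**2 * q**2).sum()
    e[0, 1] = 0.0
    e[1, 1] = (2 * p**2 * q + 2 * p * q**2).sum()
    e[2, 1] = p.size - e[1, 1]
    e[0, 2] = 0.0
    e[1, 2] = 0.0
    e[2, 2] = float(p.size)
    return e


def ibd_moments(
    gm: GenotypeMatrix,
    pair: tuple[str, str],
    freqs: np.ndarray | None = None,
    min_informative: int = 100,
) -> IbdEstimate:
    """Method-of-moments Z0/Z1/Z2 for one sample pair.

    Allele frequencies default to the full-sample estimates.  Sites missing in
    either member or monomorphic are dropped (pairwise-complete).  Estimates
    are clamped to [0,1] and renormalized.
    """
    s1, s2 = pair
    if s1 == s2:
        raise StructureError("IBD of a sample with itself is undefined")
    i = gm.sample_index(s1)
    j = gm.sample_index(s2)
    from .qc import alt_allele_frequency

    p_all = alt_allele_frequency(gm) if freqs is None else np.asarray(freqs, float)
    x = gm.calls[i]
    y = gm.calls[j]
    use = (x != MISSING) & (y != MISSING) & (p_all > 0) & (p_all < 1)
    x = x[use].astype(int)
    y = y[use].astype(int)
    p = p_all[use]
    n = int(use.sum())
    if n < min_informative:
        import warnings

        warnings.warn(
            f"only {n} informative sites for pair {pair}; estimates are noisy",
            stacklevel=2,
        )
    if n == 0:
        raise StructureError(f"no informative sites for pair {pair}")

    diff = np.abs(x - y)
    obs = np.array([(diff == 2).sum(), (diff == 1).sum(), (diff == 0).sum()], float)
    e = _ibs_state_expectations(p)

    z0 = obs[0] / e[0, 0] if e[0, 0] > 0 else 0.0
    z1 = (obs[1] - z0 * e[1, 0]) / e[1, 1] if e[1, 1] > 0 else 0.0
    z2 = (obs[2] - z0 * e[2, 0] - z1 * e[2, 1]) / e[2, 2]
    z = np.clip([z0, z1, z2], 0.0, 1.0)
    total = z.sum()
    z = z / total if total > 0 else np.array([1.0, 0.0, 0.0])
    return IbdEstimate(s1, s2, float(z[0]), float(z[1]), float(z[2]), n)


# ---------------------------------------------------------------------------
# top-1% relatedness screen
# ---------------------------------------------------------------------------

@dataclass
class RelatednessVerdict:
    sample_1: str
    sample_2: str
    pi_hat: float
    quantile: float          # position within the carrier-control distribution
    flagged: bool            # above the top-1% cutoff


@dataclass
class RelatednessScreen:
    verdicts: list[RelatednessVerdict]
    cutoff: float            # nearest-rank 99th percentile of carrier-control
    carrier_control: pd.DataFrame
    carrier_carrier: pd.DataFrame

    @property
    def flagged_pairs(self) -> list[tuple[str, str]]:
        return [(v.sample_1, v.sample_2) for v in self.verdicts if v.flagged]


def nearest_rank_quantile(values: np.ndarray, q: float) -> float:
    """Nearest-rank (ceiling) empirical quantile of ``values``."""
    v = np.sort(np.asarray(values, float))
    if v.size == 0:
        raise StructureError("empty sample for quantile")
    rank = max(1, math.ceil(q * v.size))
    return float(v[rank - 1])


def relatedness_screen(
    gm: GenotypeMatrix,
    sheet: SampleSheet,
    top_quantile: float = 0.99,
    min_controls: int = 10,
) -> RelatednessScreen:
    """Screen carrier pairs against the carrier-control PI_HAT distribution."""
    carriers = [s for s in sheet.carriers if s in gm.samples]
    controls = [s for s in sheet.controls if s in gm.samples]
    if len(carriers) < 2:
        raise StructureError("need at least 2 carriers")
    if len(controls) < min_controls:
        raise StructureError(f"need at least {min_controls} controls, got {len(controls)}")

    from .qc import alt_allele_frequency

    freqs = alt_allele_frequency(gm)
    cc_rows = []
    for a in carriers:
        for b in controls:
            est = ibd_moments(gm, (a, b), freqs=freqs)
            cc_rows.append((a, b, est.z0, est.z1, est.z2, est.pi_hat))
    carrier_control = pd.DataFrame(
        cc_rows, columns=["id1", "id2", "Z0", "Z1", "Z2", "PI_HAT"]
    )
    null = carrier_control["PI_HAT"].to_numpy()
    cutoff = nearest_rank_quantile(null, top_quantile)

    pp_rows = []
    verdicts = []
    for a, b in itertools.combinations(carriers, 2):
        est = ibd_moments(gm, (a, b), freqs=freqs)
        pi = est.pi_hat
        quant = float((null <= pi).mean())
        verdicts.append(RelatednessVerdict(a, b, pi, quant, bool(pi > cutoff)))
        pp_rows.append((a, b, est.z0, est.z1, est.z2, pi))
    carrier_carrier = pd.DataFrame(
        pp_rows, columns=["id1", "id2", "Z0", "Z1", "Z2", "PI_HAT"]
    )
    return RelatednessScreen(verdicts, cutoff, carrier_control, carrier_carrier)
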