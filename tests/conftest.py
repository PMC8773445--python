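from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from founder_tracer.datamodel import HaplotypeMatrix


def hm_from_rows(
    rows: list[str], chrom: str = "1", spacing: int = 1000, start: int = 1000
) -> HaplotypeMatrix:
    """Build a haplotype matrix from allele strings ('0','1','.'=missing).

    Rows must come in pairs (two haplotypes per sample); samples are named
    S1, S2, ...
    """
    if len(rows) % 2:
        raise ValueError("need an even number of haplotype rows")
    m = len(rows[0])
    code = {"0": 0, "1": 1, ".": -1}
    haps = np.array([[code[ch] for ch in r] for r in rows], dtype=np.int8)
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": start + spacing * np.arange(m),
            "id": [f"snp{j+1}" for j in range(m)],
            "ref": "A",
            "alt": "G",
        }
    )
    samples = [f"S{i+1}" for i in range(len(rows) // 2)]
    return HaplotypeMatrix(samples, variants, haps)


def random_hm(
    rng: np.random.Generator,
    n_haps: int,
    n_snps: int,
    missing_rate: float = 0.0,
    n_chroms: int = 1,
) -> HaplotypeMatrix:
    """Random phased matrix (iid alleles) for oracle-equivalence checks."""
    if n_haps % 2:
        n_haps += 1
    per = n_snps // n_chroms
    frames, blocks = [], []
    for c in range(n_chroms):
        freqs = rng.uniform(0.1, 0.9, per)
        h = (rng.random((n_haps, per)) < freqs).astype(np.int8)
        if missing_rate > 0:
            h[rng.random(h.shape) < missing_rate] = -1
        blocks.append(h)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": str(c + 1),
                    "pos": 1000 + 1000 * np.arange(per),
                    "id": [f"c{c+1}_snp{j}" for j in range(per)],
                    "ref": "A",
                    "alt": "G",
                }
            )
        )
    variants = pd.concat(frames, ignore_index=True)
    haps = np.concatenate(blocks, axis=1)
    samples = [f"S{i+1}" for i in range(n_haps // 2)]
    return HaplotypeMatrix(samples, variants, haps)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240117)
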