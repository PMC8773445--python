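"""In-memory containers shared by every stage of the pipeline.

Conventions
-----------
* Positions are 1-based inclusive bp (VCF convention); the physical length of
  a segment is ``end_bp - start_bp``.
* Genotype calls are alt-allele dosages in {0, 1, 2}; haplotype alleles are in
  {0, 1}.  Missing data is encoded as :data:`MISSING` (-1) in both.
* Genetic distances are carried in centimorgans at map level and converted to
  Morgans where a recombination model needs them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING: int = -1

#: column order for variant tables
VARIANT_COLUMNS = ["chrom", "pos", "id", "ref", "alt"]

AUTOSOMES = {str(i) for i in range(1, 23)}


class DataModelError(ValueError):
    """Raised when a container invariant is violated."""


def normalize_chrom(label: str) -> str:
    """Strip a leading ``chr`` prefix so '21' and 'chr21' compare equal."""
    label = str(label)
    return label[3:] if label.lower().startswith("chr") else label


def is_autosome(label: str) -> bool:
    return normalize_chrom(label) in AUTOSOMES


def _check_variants(variants: pd.DataFrame) -> pd.DataFrame:
    missing_cols = [c for c in VARIANT_COLUMNS if c not in variants.columns]
    if missing_cols:
        raise DataModelError(f"variant table lacks columns {missing_cols}")
    variants = variants.reset_index(drop=True)
    for chrom, sub in variants.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise DataModelError(
                f"positions not strictly increasing on chromosome {chrom}"
            )
    return variants


@dataclass
class GenotypeMatrix:
    """Diploid alt-allele dosages for ``samples x variants``."""

    samples: list[str]
    variants: pd.DataFrame
    calls: np.ndarray  # int8, shape (n_samples, n_variants), MISSING allowed

    def __post_init__(self) -> None:
        self.variants = _check_variants(self.variants)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.variants)):
            raise DataModelError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        bad = (self.calls < MISSING) | (self.calls > 2)
        if bad.any():
            raise DataModelError("genotype calls must be in {0,1,2} or missing")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def subset_variants(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=self.variants.iloc[index],
            calls=self.calls[:, index],
        )

    def subset_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in index],
            variants=self.variants,
            calls=self.calls[index, :],
        )

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise DataModelError(f"unknown sample {sample!r}") from None


@dataclass
class HaplotypeMatrix:
    """Phased haplotypes: two rows per sample (phase 0 then phase 1)."""

    sample_ids: list[str]
    variants: pd.DataFrame
    haplotypes: np.ndarray  # int8, shape (2*n_samples, n_variants)

    def __post_init__(self) -> None:
        self.variants = _check_variants(self.variants)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        expected = (2 * len(self.sample_ids), len(self.variants))
        if self.haplotypes.shape != expected:
            raise DataModelError(
                f"haplotype shape {self.haplotypes.shape}, expected {expected}"
            )
        bad = (self.haplotypes < MISSING) | (self.haplotypes > 1)
        if bad.any():
            raise DataModelError("haplotype alleles must be 0/1 or missing")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def hap_row(self, sample: str, phase: int) -> int:
        if phase not in (0, 1):
            raise DataModelError("phase must be 0 or 1")
        try:
            i = self.sample_ids.index(sample)
        except ValueError:
            raise DataModelError(f"unknown sample {sample!r}") from None
        return 2 * i + phase

    def sample_of_row(self, row: int) -> tuple[str, int]:
        return self.sample_ids[row // 2], row % 2

    def hap_id(self, row: int) -> str:
        sample, phase = self.sample_of_row(row)
        return f"{sample}_h{phase}"

    def to_genotypes(self) -> GenotypeMatrix:
        """Collapse phased pairs into dosages; any missing allele -> missing."""
        h0 = self.haplotypes[0::2, :].astype(np.int16)
        h1 = self.haplotypes[1::2, :].astype(np.int16)
        calls = h0 + h1
        calls[(h0 == MISSING) | (h1 == MISSING)] = MISSING
        return GenotypeMatrix(
            samples=list(self.sample_ids),
            variants=self.variants,
            calls=calls.astype(np.int8),
        )

    def variant_index(self, chrom: str, pos: int) -> int:
        chrom = normalize_chrom(chrom)
        chroms = self.variants["chrom"].map(normalize_chrom)
        hit = np.flatnonzero((chroms == chrom) & (self.variants["pos"] == pos))
        if hit.size != 1:
            raise DataModelError(f"site {chrom}:{pos} not found (or duplicated)")
        return int(hit[0])


@dataclass
class GeneticMap:
    """Piecewise-linear bp -> cM map with a constant-rate fallback.

    ``anchors`` maps a chromosome label to sorted ``(pos_bp, cM)`` arrays.
    Queries between anchors interpolate linearly; queries beyond the terminal
    anchors extrapolate at ``fallback_cm_per_mb``.  When ``anchors`` is None
    the map is a pure constant-rate map valid for every chromosome; otherwise
    an unknown chromosome is an error.
    """

    anchors: dict[str, tuple[np.ndarray, np.ndarray]] | None = None
    fallback_cm_per_mb: float = 1.0

    def __post_init__(self) -> None:
        if self.anchors is not None:
            clean: dict[str, tuple[np.ndarray, np.ndarray]] = {}
            for chrom, (pos, cm) in self.anchors.items():
                pos = np.asarray(pos, dtype=float)
                cm = np.asarray(cm, dtype=float)
                if pos.shape != cm.shape or pos.ndim != 1 or pos.size == 0:
                    raise DataModelError("map anchors must be matching 1-d arrays")
                if np.any(np.diff(pos) <= 0):
                    raise DataModelError(f"map positions not increasing on {chrom}")
                if np.any(np.diff(cm) < 0):
                    raise DataModelError(f"cM not non-decreasing on {chrom}")
                clean[normalize_chrom(chrom)] = (pos, cm)
            self.anchors = clean
        if self.fallback_cm_per_mb < 0:
            raise DataModelError("fallback rate must be >= 0")

    @classmethod
    def constant(cls, cm_per_mb: float) -> "GeneticMap":
        return cls(anchors=None, fallback_cm_per_mb=cm_per_mb)

    def _chrom_anchors(self, chrom: str) -> tuple[np.ndarray, np.ndarray] | None:
        if self.anchors is None:
            return None
        chrom = normalize_chrom(chrom)
        if chrom not in self.anchors:
            raise DataModelError(f"chromosome {chrom!r} absent from genetic map")
        return self.anchors[chrom]

    def cm_at(self, chrom: str, pos_bp) -> np.ndarray | float:
        """Map position(s) in bp to cM (chromosome-local coordinates)."""
        pos = np.asarray(pos_bp, dtype=float)
        pair = self._chrom_anchors(chrom)
        rate = self.fallback_cm_per_mb / 1e6  # cM per bp
        if pair is None:
            out = pos * rate
        else:
            apos, acm = pair
            out = np.interp(pos, apos, acm)
            below = pos < apos[0]
            above = pos > apos[-1]
            out = np.where(below, acm[0] - (apos[0] - pos) * rate, out)
            out = np.where(above, acm[-1] + (pos - apos[-1]) * rate, out)
        return float(out) if np.isscalar(pos_bp) else out

    def bp_at_cm(self, chrom: str, cm) -> np.ndarray | float:
        """Inverse query (used by the simulator to convert erosion distances)."""
        val = np.asarray(cm, dtype=float)
        pair = self._chrom_anchors(chrom)
        rate = self.fallback_cm_per_mb / 1e6
        if rate == 0 and pair is None:
            raise DataModelError("cannot invert a zero-rate constant map")
        if pair is None:
            out = val / rate
        else:
            apos, acm = pair
            out = np.interp(val, acm, apos)
            below = val < acm[0]
            above = val > acm[-1]
            if rate > 0:
                out = np.where(below, apos[0] - (acm[0] - val) / rate, out)
                out = np.where(above, apos[-1] + (val - acm[-1]) / rate, out)
        return float(out) if np.isscalar(cm) else out

    def genetic_length(self, chrom: str, start_bp: int, end_bp: int) -> float:
        """Genetic length of ``[start_bp, end_bp]`` in Morgans (>= 0)."""
        if start_bp > end_bp:
            raise DataModelError("start_bp must be <= end_bp")
        length_cm = self.cm_at(chrom, end_bp) - self.cm_at(chrom, start_bp)
        return max(float(length_cm), 0.0) / 100.0


CARRIER = "carrier"
CONTROL = "control"


@dataclass
class SampleSheet:
    """Role (carrier/control) and free-text population label per sample."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        required = {"sample", "role", "population"}
        if not required.issubset(self.table.columns):
            raise DataModelError(f"sample sheet needs columns {sorted(required)}")
        if self.table["sample"].duplicated().any():
            raise DataModelError("duplicate sample in sheet")
        bad = ~self.table["role"].isin([CARRIER, CONTROL])
        if bad.any():
            raise DataModelError(
                f"roles must be '{CARRIER}' or '{CONTROL}', got "
                f"{sorted(self.table.loc[bad, 'role'].unique())}"
            )
        self.table = self.table.reset_index(drop=True)

    @classmethod
    def from_roles(
        cls, carriers: list[str], controls: list[str], population: str = "synthetic"
    ) -> "SampleSheet":
        rows = [{"sample": s, "role": CARRIER, "population": population} for s in carriers]
        rows += [{"sample": s, "role": CONTROL, "population": population} for s in controls]
        return cls(pd.DataFrame(rows, columns=["sample", "role", "population"]))

    @property
    def carriers(self) -> list[str]:
        return self.table.loc[self.table["role"] == CARRIER, "sample"].tolist()

    @property
    def controls(self) -> list[str]:
        return self.table.loc[self.table["role"] == CONTROL, "sample"].tolist()

    def validate_against(self, samples: list[str]) -> None:
        """Every matrix sample appears exactly once in the sheet."""
        sheet = set(self.table["sample"])
        missing = [s for s in samples if s not in sheet]
        if missing:
            raise DataModelError(f"samples absent from sheet: {missing[:5]}")
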