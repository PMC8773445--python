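"""Readers and writers for the plain-text formats the pipeline touches.

Supported formats: phased VCF 4.x (via :mod:`cyvcf2` for reading), the PLINK
text PED/MAP dialect, HapMap-style genetic map TSV (``chrom  pos_bp
rate_cM_per_Mb  map_cM``) and the sample-sheet TSV (``sample  role
population``).  All writers emit uncompressed text and every format
round-trips losslessly through its reader (calls, positions, sample order).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    MISSING,
    DataModelError,
    GeneticMap,
    GenotypeMatrix,
    HaplotypeMatrix,
    SampleSheet,
    is_autosome,
    normalize_chrom,
)

log = logging.getLogger(__name__)


class FormatError(ValueError):
    """Raised on malformed input files."""


def _position_order(variants: pd.DataFrame) -> np.ndarray:
    """Sort by position within chromosome, keeping chromosome file order."""
    rank = {c: i for i, c in enumerate(dict.fromkeys(variants["chrom"]))}
    return np.lexsort(
        (variants["pos"].to_numpy(), variants["chrom"].map(rank).to_numpy())
    )


# ---------------------------------------------------------------------------
# phased VCF
# ---------------------------------------------------------------------------

def read_phased_vcf(
    path: str | Path, permissive_unphased: bool = False
) -> tuple[HaplotypeMatrix, dict[str, int]]:
    """Load biallelic autosomal SNVs from a phased VCF.

    Returns the haplotype matrix and a dict of skipped-record counts
    (``multiallelic``, ``non_snv``, ``non_autosomal``).  A heterozygous
    unphased call is an error unless ``permissive_unphased`` is set, in which
    case it becomes a missing call.
    """
    from cyvcf2 import VCF

    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as exc:  # cyvcf2 raises bare OSError on parse failure
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    if not samples:
        raise FormatError(f"VCF {path} has no samples")

    skipped = {"multiallelic": 0, "non_snv": 0, "non_autosomal": 0}
    rows = []
    haps: list[np.ndarray] = []
    for v in vcf:
        if len(v.ALT) != 1:
            skipped["multiallelic"] += 1
            continue
        if len(v.REF) != 1 or len(v.ALT[0]) != 1:
            skipped["non_snv"] += 1
            continue
        if not is_autosome(v.CHROM):
            skipped["non_autosomal"] += 1
            continue
        col = np.empty(2 * len(samples), dtype=np.int8)
        for i, g in enumerate(v.genotypes):
            a, b, phased = g[0], g[1], g[-1]
            if a >= 0 and b >= 0 and a != b and not phased:
                if not permissive_unphased:
                    raise FormatError(
                        f"unphased heterozygote at {v.CHROM}:{v.POS} sample "
                        f"{samples[i]}; rerun with permissive_unphased to mask"
                    )
                a = b = MISSING
            col[2 * i] = a if a >= 0 else MISSING
            col[2 * i + 1] = b if b >= 0 else MISSING
        rows.append(
            {
                "chrom": normalize_chrom(v.CHROM),
                "pos": int(v.POS),
                "id": v.ID or f"{normalize_chrom(v.CHROM)}:{v.POS}",
                "ref": v.REF,
                "alt": v.ALT[0],
            }
        )
        haps.append(col)
    vcf.close()
    if not rows:
        raise FormatError(f"no biallelic autosomal SNVs in {path}")
    variants = pd.DataFrame(rows)
    matrix = np.stack(haps, axis=1)
    order = _position_order(variants)
    if not np.array_equal(order, np.arange(len(variants))):
        variants = variants.iloc[order]
        matrix = matrix[:, order]
    total_skipped = sum(skipped.values())
    if total_skipped:
        log.info("read_phased_vcf: skipped %d records %s", total_skipped, skipped)
    return HaplotypeMatrix(samples, variants, matrix), skipped


def write_phased_vcf(hm: HaplotypeMatrix, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=founder-tracer\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(hm.sample_ids)
            + "\n"
        )
        h = hm.haplotypes

        def allele(x: int) -> str:
            return "." if x == MISSING else str(int(x))

        for j, var in enumerate(hm.variants.itertuples(index=False)):
            gts = "\t".join(
                f"{allele(h[2 * i, j])}|{allele(h[2 * i + 1, j])}"
                for i in range(hm.n_samples)
            )
            fh.write(
                f"{var.chrom}\t{var.pos}\t{var.id}\t{var.ref}\t{var.alt}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# PLINK text PED/MAP
# ---------------------------------------------------------------------------

def read_plink_text(ped_path: str | Path, map_path: str | Path) -> GenotypeMatrix:
    """Read a whitespace-delimited PED/MAP pair.

    Allele coding is normalized to alt-dosage against a per-site reference
    allele: the first non-missing allele seen at each site becomes ``ref``.
    ``0`` is the missing-allele code.
    """
    map_df = pd.read_csv(
        map_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "pos"],
        dtype={"chrom": str},
    )
    n_sites = len(map_df)
    samples: list[str] = []
    allele_rows: list[list[str]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_sites:
                raise FormatError(
                    f"PED row length mismatch vs MAP for sample "
                    f"{fields[1] if len(fields) > 1 else f'line {lineno}'}: "
                    f"expected {6 + 2 * n_sites} fields, got {len(fields)}"
                )
            samples.append(fields[1])
            allele_rows.append(fields[6:])

    ref = [""] * n_sites
    alt = [""] * n_sites
    calls = np.full((len(samples), n_sites), MISSING, dtype=np.int8)
    for i, row in enumerate(allele_rows):
        for j in range(n_sites):
            a1, a2 = row[2 * j], row[2 * j + 1]
            if a1 == "0" or a2 == "0":
                continue  # missing genotype
            dose = 0
            for a in (a1, a2):
                if not ref[j]:
                    ref[j] = a
                if a != ref[j]:
                    if not alt[j]:
                        alt[j] = a
                    elif a != alt[j]:
                        raise FormatError(f"site {map_df['id'][j]} is multi-allelic")
                    dose += 1
            calls[i, j] = dose

    variants = pd.DataFrame(
        {
            "chrom": map_df["chrom"].map(normalize_chrom),
            "pos": map_df["pos"].astype(int),
            "id": map_df["id"],
            "ref": [r or "A" for r in ref],
            "alt": [a or "B" for a in alt],
        }
    )
    order = _position_order(variants)
    return GenotypeMatrix(samples, variants.iloc[order], calls[:, order])


def write_plink_text(
    gm: GenotypeMatrix, ped_path: str | Path, map_path: str | Path
) -> None:
    with open(map_path, "w") as fh:
        for var in gm.variants.itertuples(index=False):
            fh.write(f"{var.chrom}\t{var.id}\t0\t{var.pos}\n")
    with open(ped_path, "w") as fh:
        for i, sample in enumerate(gm.samples):
            fields = [sample, sample, "0", "0", "0", "-9"]
            for j, var in enumerate(gm.variants.itertuples(index=False)):
                d = gm.calls[i, j]
                if d == MISSING:
                    fields += ["0", "0"]
                else:
                    fields += [var.ref if d < 2 else var.alt,
                               var.ref if d < 1 else var.alt]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# genetic map / sample sheet TSVs
# ---------------------------------------------------------------------------

def read_genetic_map(path: str | Path, fallback_cm_per_mb: float = 1.0) -> GeneticMap:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos_bp", "map_cM"}
    if not required.issubset(df.columns):
        raise FormatError(f"genetic map needs columns {sorted(required)}")
    anchors = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values("pos_bp")
        anchors[chrom] = (
            sub["pos_bp"].to_numpy(float),
            sub["map_cM"].to_numpy(float),
        )
    try:
        return GeneticMap(anchors=anchors, fallback_cm_per_mb=fallback_cm_per_mb)
    except DataModelError as exc:
        raise FormatError(str(exc)) from exc


def write_genetic_map(gmap: GeneticMap, path: str | Path) -> None:
    if gmap.anchors is None:
        raise FormatError("constant-rate maps have no anchors to write")
    rows = []
    for chrom, (pos, cm) in gmap.anchors.items():
        rate = np.empty_like(cm)
        if len(pos) > 1:
            rate[:-1] = np.diff(cm) / np.maximum(np.diff(pos), 1) * 1e6
            rate[-1] = rate[-2] if len(pos) > 2 else rate[0]
        else:
            rate[:] = gmap.fallback_cm_per_mb
        for p, r, c in zip(pos, rate, cm):
            rows.append((chrom, int(p), r, c))
    pd.DataFrame(rows, columns=["chrom", "pos_bp", "rate_cM_per_Mb", "map_cM"]).to_csv(
        path, sep="\t", index=False
    )


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype=str)
    try:
        return SampleSheet(df)
    except DataModelError as exc:
        raise FormatError(str(exc)) from exc


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.table.to_csv(path, sep="\t", index=False)
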