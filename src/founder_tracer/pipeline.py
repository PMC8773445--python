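"""End-to-end orchestration: simulate -> qc -> structure -> share -> tmrca.

A run is configured by a single strict-keyed mapping (usually a YAML file),
executed stage by stage into an append-only run directory, and summarized in
a machine-readable :class:`RunReport` (JSON).  Rerunning with the same config
and seed reproduces the report bit for bit (timestamps excluded).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .datamodel import SampleSheet
from .haploshare import (
    FocalSpec,
    carrier_haplotypes,
    focal_shared_segment,
    genomewide_segment_scan,
    pairwise_focal_segments,
    patient_control_null,
    rank_statistics,
)
from .qc import QcThresholds, run_qc
from .structure import relatedness_screen, run_pca
from .synthetic_data import SimConfig, make_cohort, write_cohort
from .tmrca import TmrcaModel, tmrca_from_segment

log = logging.getLogger(__name__)

STAGES = ("simulate", "qc", "structure", "share", "tmrca")


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _strict_kwargs(block: dict, cls, name: str) -> dict:
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in '{name}': {sorted(unknown)}")
    return dict(block)


@dataclasses.dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "run"
    stages: tuple[str, ...] = STAGES
    sim: SimConfig = dataclasses.field(default_factory=SimConfig)
    qc: QcThresholds = dataclasses.field(default_factory=QcThresholds)
    pca_components: int = 4
    tmrca: TmrcaModel = dataclasses.field(default_factory=TmrcaModel)
    control_null_alpha: float = 0.05

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        raw = dict(raw)
        top_allowed = {"seed", "out_dir", "stages", "simulate", "qc",
                       "structure", "tmrca", "share"}
        unknown = set(raw) - top_allowed
        if unknown:
            raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
        stages = tuple(raw.get("stages", STAGES))
        bad = [s for s in stages if s not in STAGES]
        if bad:
            raise ConfigError(f"unknown stages {bad}; valid: {list(STAGES)}")
        seed = int(raw.get("seed", 0))
        sim_block = dict(raw.get("simulate", {}))
        sim_block.setdefault("seed", seed)
        structure_block = dict(raw.get("structure", {}))
        unknown = set(structure_block) - {"pca_components"}
        if unknown:
            raise ConfigError(f"unknown keys in 'structure': {sorted(unknown)}")
        share_block = dict(raw.get("share", {}))
        unknown = set(share_block) - {"control_null_alpha"}
        if unknown:
            raise ConfigError(f"unknown keys in 'share': {sorted(unknown)}")
        try:
            return cls(
                seed=seed,
                out_dir=str(raw.get("out_dir", "run")),
                stages=stages,
                sim=SimConfig(**_strict_kwargs(sim_block, SimConfig, "simulate")),
                qc=QcThresholds(**_strict_kwargs(raw.get("qc", {}), QcThresholds, "qc")),
                pca_components=int(structure_block.get("pca_components", 4)),
                tmrca=TmrcaModel(**_strict_kwargs(raw.get("tmrca", {}), TmrcaModel, "tmrca")),
                control_null_alpha=float(share_block.get("control_null_alpha", 0.05)),
            )
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError("run config must be a mapping")
        return cls.from_dict(raw)


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the enabled stages in order; returns the RunReport dict.

    A stage failure raises :class:`StageError` after writing the partial
    report (with the failing stage named) to the run directory.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "stages": list(config.stages),
        "config": {
            "simulate": dataclasses.asdict(config.sim),
            "qc": dataclasses.asdict(config.qc),
            "tmrca": dataclasses.asdict(config.tmrca),
            "pca_components": config.pca_components,
        },
    }
    state: dict[str, Any] = {}
    try:
        for stage in config.stages:
            log.info("running stage %s", stage)
            _STAGE_FUNCS[stage](config, state, report, out)
    except Exception as exc:
        report["failed_stage"] = getattr(exc, "stage", stage)
        _write_report(report, out)
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, exc) from exc
    _write_report(report, out)
    return report


def _write_report(report: dict[str, Any], out: Path) -> None:
    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(config: RunConfig, state, report, out: Path) -> None:
    cohort = make_cohort(config.sim)
    state["cohort"] = cohort
    state["hm"] = cohort.haplotypes
    state["gm"] = cohort.haplotypes.to_genotypes()
    state["sheet"] = cohort.sheet
    state["gmap"] = cohort.gmap
    paths = write_cohort(cohort, out / "cohort")
    report["simulate"] = {
        "n_samples": cohort.haplotypes.n_samples,
        "n_variants": cohort.haplotypes.n_variants,
        "true_tmrca": cohort.truth.tmrca,
        "focal": f"{cohort.truth.focal_chrom}:{cohort.truth.focal_pos_bp}",
        "files": paths,
    }


def _stage_qc(config: RunConfig, state, report, out: Path) -> None:
    gm = state["gm"]
    gm_qc, kept_ids, qc_report = run_qc(gm, config.qc)
    state["gm_qc"] = gm_qc
    keep = gm_qc.variants["id"].isin(kept_ids).to_numpy()
    state["gm_pruned"] = gm_qc.subset_variants(np.flatnonzero(keep))
    report["qc"] = qc_report.to_dict()


def _stage_structure(config: RunConfig, state, report, out: Path) -> None:
    gm = state.get("gm_pruned") or state.get("gm_qc") or state["gm"]
    sheet: SampleSheet = state["sheet"]
    pca = run_pca(gm, k=min(config.pca_components, gm.n_samples - 1))
    pca.coords.to_csv(out / "pca.tsv", sep="\t")
    # IBD on the full post-QC set (spec default), not only the pruned one
    screen = relatedness_screen(state.get("gm_qc", gm), sheet)
    pd_concat = screen.carrier_control
    pd_concat.to_csv(out / "ibd_carrier_control.tsv", sep="\t", index=False)
    screen.carrier_carrier.to_csv(out / "ibd_carrier_carrier.tsv", sep="\t",
                                  index=False)
    report["structure"] = {
        "pca_explained": pca.explained.tolist(),
        "ibd_top1pct_cutoff": screen.cutoff,
        "flagged_pairs": [list(p) for p in screen.flagged_pairs],
    }


def _focal_spec(state) -> FocalSpec:
    cohort = state["cohort"]
    truth = cohort.truth
    return FocalSpec(
        chrom=truth.focal_chrom,
        pos_bp=truth.focal_pos_bp,
        risk_allele=1,
        carriers=list(truth.carriers),
    )


def _stage_share(config: RunConfig, state, report, out: Path) -> None:
    hm = state["hm"]
    spec = _focal_spec(state)
    focal = focal_shared_segment(hm, spec)
    rows = carrier_haplotypes(hm, spec)
    scan = genomewide_segment_scan(hm, rows)
    ranks = rank_statistics(focal, scan)
    pairwise = pairwise_focal_segments(hm, spec)
    controls = state["sheet"].controls
    null_results, bonferroni = patient_control_null(
        hm, spec, controls, target_snps=focal.n_snps,
        target_bp=focal.length_bp, alpha=config.control_null_alpha,
    )
    state["focal_segment"] = focal
    report["share"] = {
        "focal_segment": {
            "chrom": focal.chrom,
            "start_bp": focal.start_bp,
            "end_bp": focal.end_bp,
            "n_snps": focal.n_snps,
            "length_bp": focal.length_bp,
        },
        "rank_snps_p": ranks["snps"].p,
        "rank_bp_p": ranks["bp"].p,
        "n_genomewide_segments": ranks["snps"].n_total,
        "pairwise_n_snps": {
            f"{a}|{b}": seg.n_snps for (a, b), seg in pairwise.items()
        },
        "control_null": [dataclasses.asdict(r) for r in null_results],
        "control_null_bonferroni": bonferroni,
    }


def _stage_tmrca(config: RunConfig, state, report, out: Path) -> None:
    focal = state["focal_segment"]
    gmap = state["gmap"]
    n = len(state["cohort"].truth.carriers)
    post = tmrca_from_segment(focal, gmap, n, config.tmrca)
    np.savetxt(
        out / "tmrca_posterior.tsv",
        np.column_stack([post.grid, post.density]),
        header="generations\tdensity", delimiter="\t", comments="",
    )
    report["tmrca"] = post.summary()


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "structure": _stage_structure,
    "share": _stage_share,
    "tmrca": _stage_tmrca,
}


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_report(report: dict[str, Any], out_dir: str | Path) -> list[str]:
    """Human-readable summary + figures (sharing matrix, posterior curve)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    lines = [f"founder-tracer run report (v{report.get('version', '?')})"]
    if "qc" in report:
        qc = report["qc"]
        lines.append(
            f"QC: {qc['initial_shape']} -> {qc['final_shape']} "
            f"({len(qc['steps'])} filters)"
        )
    if "structure" in report:
        s = report["structure"]
        lines.append(
            f"relatedness: top-1% cutoff PI_HAT={s['ibd_top1pct_cutoff']:.4f}, "
            f"{len(s['flagged_pairs'])} flagged pair(s)"
        )
    if "share" in report:
        sh = report["share"]
        seg = sh["focal_segment"]
        lines.append(
            f"focal segment {seg['chrom']}:{seg['start_bp']}-{seg['end_bp']} "
            f"({seg['n_snps']} SNPs, {seg['length_bp']} bp); "
            f"RankSNPs={sh['rank_snps_p']:.2e}, RankDIM(bp)={sh['rank_bp_p']:.2e}"
        )
        pairs = sh.get("pairwise_n_snps", {})
        if pairs:
            carriers = sorted({c for k in pairs for c in k.split("|")})
            n = len(carriers)
            mat = np.zeros((n, n))
            for k, v in pairs.items():
                a, b = k.split("|")
                i, j = carriers.index(a), carriers.index(b)
                mat[i, j] = mat[j, i] = v
            fig, ax = plt.subplots(figsize=(4, 3.5))
            im = ax.imshow(mat, cmap="viridis")
            ax.set_xticks(range(n), carriers, rotation=90, fontsize=6)
            ax.set_yticks(range(n), carriers, fontsize=6)
            fig.colorbar(im, ax=ax, label="shared SNPs at focal locus")
            fig.tight_layout()
            path = out / "sharing_matrix.png"
            fig.savefig(path, dpi=120)
            plt.close(fig)
            written.append(str(path))
    if "tmrca" in report and report["tmrca"]:
        t = report["tmrca"]
        lines.append(
            f"tMRCA: mean {t['mean_generations']:.1f} g "
            f"(mode {t['mode_generations']:.1f}); "
            f"~{t['mean_years']:.0f} years at {t['generation_years']} y/g"
        )
        curve = Path(out) / "tmrca_posterior.tsv"
        if curve.exists():
            data = np.loadtxt(curve, skiprows=1)
            fig, ax = plt.subplots(figsize=(4.5, 3))
            ax.plot(data[:, 0], data[:, 1])
            ax.set_xlim(0, min(data[-1, 0], t["mean_generations"] * 4))
            ax.set_xlabel("generations to common ancestor")
            ax.set_ylabel("posterior density")
            fig.tight_layout()
            path = out / "tmrca_posterior.png"
            fig.savefig(path, dpi=120)
            plt.close(fig)
            written.append(str(path))
    else:
        lines.append("tMRCA: not computed in this run")

    summary = out / "summary.txt"
    summary.write_text("\n".join(lines) + "\n")
    written.append(str(summary))
    return written
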