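"""Config-driven end-to-end orchestration.

Stages: read (or generate) -> dynamic-range filter -> aorta weight
normalization -> below-LOD imputation -> UV scaling -> two-block joint/unique
decomposition -> group orientation -> rank-based importance per block ->
class sums / ratio biomarkers with ROC scoring -> serialized report.  A run
is fully determined by (config, seed): rerunning writes byte-identical
outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import biomarkers as bm
from . import io as block_io
from .blocks import ConcentrationBlock, Tissue, filter_dynamic_range, \
    impute_below_lod, normalize_by_weight
from .importance import importance_table, volcano_coordinates
from .moca import fit_moca, orient_model, save_model, scale_blocks, variance_table
from .simulate import CohortSpec, generate_cohort

log = logging.getLogger("mocamet")


@dataclass
class PipelineConfig:
    """All thresholds and knobs of one analysis run."""

    plasma_path: Optional[str] = None
    aorta_path: Optional[str] = None
    generate: bool = False            # synthesize a cohort instead of reading
    min_fraction: float = 0.70        # dynamic-range retention rule (> 70%)
    imputation: str = "half_min"
    n_joint: int = 2
    n_unique: str | int = "auto"      # permutation-null rule by default
    q: float = 0.05                   # BH FDR level
    auc_cutoff: float = 0.80          # good-classifier convention
    seed: int = 0
    out_dir: str = "mocamet_results"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class PipelineResult:
    config: PipelineConfig
    model: object
    variance: pd.DataFrame
    importance: dict[str, pd.DataFrame]
    volcano: dict[str, pd.DataFrame]
    biomarkers: pd.DataFrame
    dropped: dict[str, pd.DataFrame]
    groups: np.ndarray
    summary: dict


def _stage(name: str):
    log.info("stage: %s", name)
    return time.perf_counter()


def run_pipeline(
    config: PipelineConfig,
    blocks: Optional[tuple[ConcentrationBlock, ConcentrationBlock]] = None,
) -> PipelineResult:
    """Run the full analysis; writes all outputs under ``config.out_dir``.

    ``blocks`` may carry pre-built (plasma, aorta) blocks; otherwise they are
    read from the configured paths or generated synthetically.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()

    _stage("input")
    if blocks is not None:
        plasma, aorta = blocks
    elif config.generate:
        plasma, aorta, _ = generate_cohort(CohortSpec(seed=config.seed))
    else:
        if not (config.plasma_path and config.aorta_path):
            raise ValueError("configure plasma_path/aorta_path or generate=True")
        plasma = block_io.read_block(config.plasma_path, Tissue.PLASMA)
        aorta = block_io.read_block(config.aorta_path, Tissue.AORTA)
    if [s.sample_id for s in plasma.samples] != [s.sample_id for s in aorta.samples]:
        raise ValueError("input: plasma and aorta sample IDs do not match")

    _stage("filter")
    plasma, dropped_pl = filter_dynamic_range(plasma, config.min_fraction)
    aorta, dropped_ao = filter_dynamic_range(aorta, config.min_fraction)

    _stage("normalize")
    aorta = normalize_by_weight(aorta)

    _stage("impute")
    plasma, n_imp_pl = impute_below_lod(plasma, config.imputation)
    aorta, n_imp_ao = impute_below_lod(aorta, config.imputation)

    _stage("scale")
    scaled, realizations = scale_blocks({"plasma": plasma, "aorta": aorta})

    _stage("decompose")
    rng = np.random.default_rng(config.seed)
    model = fit_moca(
        scaled["plasma"],
        scaled["aorta"],
        n_joint=config.n_joint,
        n_unique_pl=config.n_unique,
        n_unique_ao=config.n_unique,
        metabolite_names={
            "plasma": plasma.metabolite_names,
            "aorta": aorta.metabolite_names,
        },
        scaling=realizations,
        rng=rng,
    )
    model = orient_model(model, plasma.groups)
    variance = variance_table(model)

    _stage("importance")
    importance = {
        "plasma": importance_table(plasma, model, "plasma", q=config.q),
        "aorta": importance_table(aorta, model, "aorta", q=config.q),
    }
    volcano = {b: volcano_coordinates(importance[b]) for b in importance}

    _stage("biomarkers")
    biomarker_table = bm.evaluate_biomarkers(plasma, cutoff=config.auc_cutoff)

    _stage("report")
    config.to_yaml(out / "config.yaml")
    save_model(model, out / "model")
    for b in ("plasma", "aorta"):
        importance[b].to_csv(out / f"importance_{b}.tsv", sep="\t", index=False)
        volcano[b].to_csv(out / f"volcano_{b}.tsv", sep="\t", index=False)
    dropped = {"plasma": dropped_pl.to_frame(), "aorta": dropped_ao.to_frame()}
    for b in dropped:
        dropped[b].to_csv(out / f"dropped_{b}.tsv", sep="\t", index=False)
    biomarker_table.to_csv(out / "biomarkers.tsv", sep="\t", index=False)
    variance.to_csv(out / "variance.tsv", sep="\t", index=False)

    groups = plasma.groups
    t1 = model.joint_scores[:, 0]
    summary = {
        "seed": config.seed,
        "n_samples": int(plasma.n_samples),
        "n_metabolites": {
            "plasma": len(plasma.metabolites),
            "aorta": len(aorta.metabolites),
        },
        "n_dropped": {b: int(len(dropped[b])) for b in dropped},
        "n_imputed": {"plasma": n_imp_pl, "aorta": n_imp_ao},
        "r2_joint_percent": {
            b: round(100 * model.r2_joint(b), 4) for b in ("plasma", "aorta")
        },
        "t_j1_group_medians": {
            g: round(float(np.median(t1[groups == g])), 6)
            for g in ("SHAM", "HCD", "ANG")
        },
        "n_significant": {
            b: int(importance[b]["significant"].sum()) for b in importance
        },
        "runtime_s": round(time.perf_counter() - t0, 3),
    }
    # runtime varies between reruns; keep the serialized summary deterministic
    stable = {k: v for k, v in summary.items() if k != "runtime_s"}
    (out / "summary.json").write_text(json.dumps(stable, indent=2, sort_keys=True))

    return PipelineResult(
        config=config,
        model=model,
        variance=variance,
        importance=importance,
        volcano=volcano,
        biomarkers=biomarker_table,
        dropped=dropped,
        groups=groups,
        summary=summary,
    )


def summarize(result: PipelineResult, top_k: int = 10) -> str:
    """Human-readable report of one completed run."""
    lines = ["== mocamet run summary =="]
    lines.append(
        f"samples: {result.summary['n_samples']}  "
        f"(plasma {result.summary['n_metabolites']['plasma']} / "
        f"aorta {result.summary['n_metabolites']['aorta']} metabolites kept)"
    )
    for b in ("plasma", "aorta"):
        lines.append(
            f"{b}: joint R2 {result.summary['r2_joint_percent'][b]:.1f}%  "
            f"significant metabolites: {result.summary['n_significant'][b]}"
        )
    med = result.summary["t_j1_group_medians"]
    lines.append(
        "t_j,1 group medians: "
        + "  ".join(f"{g}={med[g]:+.3f}" for g in ("SHAM", "HCD", "ANG"))
    )
    for b in ("plasma", "aorta"):
        table = result.importance[b]
        if not table["significant"].any():
            lines.append(f"{b}: no metabolites pass FDR")
            continue
        sig = table[table["significant"]]
        top = sig.reindex(
            sig["tau"].abs().sort_values(ascending=False).index
        ).head(top_k)
        lines.append(f"{b}: top hits by |tau|:")
        for _, r in top.iterrows():
            lines.append(
                f"  {r['metabolite']:<16s} tau={r['tau']:+.3f} "
                f"p={r['p_value']:.2e} loading={r['loading']:+.3f}"
            )
    lines.append("biomarker AUCs (plasma):")
    for _, r in result.biomarkers.iterrows():
        flag = "good" if r["good_classifier"] else "weak"
        lines.append(
            f"  {r['spec']:<12s} {r['contrast']:<12s} "
            f"AUC={r['auc']:.3f} [{r['ci_low']:.3f}, {r['ci_high']:.3f}] {flag}"
        )
    return "\n".join(lines)
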