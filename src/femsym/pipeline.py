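"""End-to-end study pipeline: simulate/load -> combined model -> adjust -> report.

Stages (each persisted so any analysis can be re-run in isolation):

1. load a landmark dataset from a manifest, or simulate one;
2. build the combined 130-point shape model and score every retained mode
   for mirror-oppositional variation;
3. exclude the oppositional modes (manual list or automatic thresholds) and
   re-evaluate all 130 points of every subject;
4. build single 65-point models before and after adjustment and produce the
   symmetry reports;
5. compute hip geometric measurements and the cohort asymmetry tables
   before and after adjustment.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import geometry, positioning, symmetry
from .landmark_io import (CombinedContour, FemurContour, IndexMap,
                          load_dataset, write_manifest, write_pts)
from .shape_model import build_model, fit_shape, generalized_procrustes, save_model
from .synthetic import SyntheticConfig, generate_dataset, make_template

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunResult", "run_full_analysis", "adjust_dataset"]


@dataclass
class RunConfig:
    """Configuration of a full analysis run.

    Exactly one input source: a dataset manifest, an in-memory dataset, or a
    synthetic-data configuration.  Mode exclusion is either a manual 1-based
    index list or automatic classification by oppositional score.
    """

    out_dir: Path
    manifest: Path | None = None
    dataset: Sequence[CombinedContour] | None = None
    simulate: SyntheticConfig | None = None
    variance_threshold: float = 0.95
    exclude_modes: Sequence[int] | None = None   # manual; None => automatic
    sym_threshold: float = positioning.DEFAULT_SYM_THRESHOLD
    opp_threshold: float = positioning.DEFAULT_OPP_THRESHOLD
    family_alpha: float = 0.05
    index_map: IndexMap | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        sources = sum(x is not None for x in (self.manifest, self.dataset, self.simulate))
        if sources != 1:
            raise ValueError("exactly one of manifest/dataset/simulate must be given")
        if not -1 <= self.opp_threshold < self.sym_threshold <= 1:
            raise ValueError("invalid classification thresholds")


@dataclass
class RunResult:
    out_dir: Path
    dataset: list[CombinedContour]
    adjusted: list[CombinedContour]
    excluded_modes: list[int]
    mode_scores: pd.DataFrame
    combined_retained: int
    report_before: symmetry.SymmetryReport
    report_after: symmetry.SymmetryReport
    geometry_before: pd.DataFrame
    geometry_after: pd.DataFrame
    geometry_change: pd.DataFrame
    adjustment_effects: pd.DataFrame
    log: dict


def adjust_dataset(dataset: Sequence[CombinedContour],
                   variance_threshold: float = 0.95,
                   exclude_modes: Sequence[int] | None = None,
                   sym_threshold: float = positioning.DEFAULT_SYM_THRESHOLD,
                   opp_threshold: float = positioning.DEFAULT_OPP_THRESHOLD):
    """Combined-model positioning adjustment of a whole dataset.

    Returns ``(adjusted contours, excluded mode list, mode-score table,
    combined model, per-subject fits)``.  With ``exclude_modes=None`` the
    oppositional modes are selected automatically by their mirror score.
    """
    shapes = np.stack([c.points for c in dataset])
    gpa = generalized_procrustes(shapes)
    model = build_model(gpa.aligned, variance_threshold=variance_threshold)
    scores = positioning.classify_modes(model, sym_threshold, opp_threshold)
    score_df = pd.DataFrame([{"mode_index": s.mode_index,
                              "score": s.score,
                              "classification": s.classification,
                              "variance": model.variances[s.mode_index - 1],
                              "variance_fraction": model.variances[s.mode_index - 1]
                              / model.total_variance if model.total_variance > 0 else 0.0}
                             for s in scores])
    if exclude_modes is None:
        excluded = [s.mode_index for s in scores if s.classification == "oppositional"]
    else:
        excluded = sorted(set(int(j) for j in exclude_modes))
        if any(j < 1 or j > model.k for j in excluded):
            raise IndexError(f"exclude indices must be within the {model.k} retained modes")
    fits = [fit_shape(model, c.points) for c in dataset]
    adjusted = [
        CombinedContour(c.subject_id,
                        positioning.exclude_modes_and_reevaluate(model, f, excluded))
        for c, f in zip(dataset, fits)
    ]
    return adjusted, excluded, score_df, model, fits


def _geometry_tables(dataset: Sequence[CombinedContour], index_map: IndexMap):
    left = []
    right = []
    for c in dataset:
        left.append(geometry.measure_hip(c.left, index_map))
        # lengths and the inter-axis angle are reflection-invariant, so the
        # right femur is measured directly with the same index map
        right.append(geometry.measure_hip(c.right, index_map))
    return left, right


def run_full_analysis(config: RunConfig) -> RunResult:
    """Execute the whole pipeline and persist every stage under ``out_dir``."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"seed": config.seed, "stages": []}

    def stage(name: str, **info) -> None:
        logger.info("stage %s: %s", name, info)
        log["stages"].append({"stage": name, **info})

    try:
        # ---- input -------------------------------------------------------
        if config.simulate is not None:
            dataset, truth = generate_dataset(config.simulate)
            truth.write_csv(out / "ground_truth.csv")
            stage("simulate", n_subjects=len(dataset), seed=config.simulate.seed)
        elif config.manifest is not None:
            dataset = load_dataset(config.manifest)
            stage("load", n_subjects=len(dataset), manifest=str(config.manifest))
        else:
            dataset = list(config.dataset)  # type: ignore[arg-type]
            stage("load", n_subjects=len(dataset), manifest=None)
        if len(dataset) < 3:
            raise ValueError("pipeline needs at least 3 subjects")

        # ---- combined model + adjustment ---------------------------------
        adjusted, excluded, score_df, model, fits = adjust_dataset(
            dataset, config.variance_threshold, config.exclude_modes,
            config.sym_threshold, config.opp_threshold)
        save_model(model, out / "combined_model.ssm")
        score_df.to_csv(out / "mode_scores.csv", index=False)
        cum = np.cumsum(model.variances) / model.total_variance \
            if model.total_variance > 0 else np.zeros(model.k)
        pd.DataFrame({"mode_index": np.arange(1, model.k + 1),
                      "variance": model.variances,
                      "cumulative_fraction": cum}).to_csv(
            out / "variance_table.csv", index=False)
        stage("combined_model", retained_modes=model.k,
              excluded_modes=excluded,
              mode_selection="manual" if config.exclude_modes is not None else "auto")

        adj_dir = out / "adjusted"
        adj_dir.mkdir(exist_ok=True)
        entries = []
        for c in adjusted:
            lp, rp = f"{c.subject_id}_left.pts", f"{c.subject_id}_right.pts"
            write_pts(adj_dir / lp, c.left.points)
            write_pts(adj_dir / rp, c.right.points)
            entries.append((c.subject_id, lp, rp))
        write_manifest(adj_dir / "manifest.csv", entries)

        effects = pd.DataFrame({
            "subject_id": [c.subject_id for c in dataset],
            "adjustment_effect_mm": [
                positioning.adjustment_effect(o.points, a.points)
                for o, a in zip(dataset, adjusted)],
        })
        effects.to_csv(out / "adjustment_effects.csv", index=False)
        stage("adjust", mean_effect_mm=float(effects["adjustment_effect_mm"].mean()))

        # ---- symmetry before/after ----------------------------------------
        report_before = symmetry.analyze_symmetry(
            dataset, config.variance_threshold, config.family_alpha)
        report_after = symmetry.analyze_symmetry(
            adjusted, config.variance_threshold, config.family_alpha)
        report_before.round_for_reporting().to_csv(out / "symmetry_before.csv", index=False)
        report_after.round_for_reporting().to_csv(out / "symmetry_after.csv", index=False)
        stage("symmetry",
              mean_lr_distance_before_mm=report_before.mean_lr_distance,
              mean_lr_distance_after_mm=report_after.mean_lr_distance,
              retained_modes_before=report_before.retained_modes,
              retained_modes_after=report_after.retained_modes)

        # ---- geometry before/after ----------------------------------------
        if config.index_map is not None:
            imap = config.index_map
        else:
            _, imap = make_template()
        bl, br = _geometry_tables(dataset, imap)
        al, ar = _geometry_tables(adjusted, imap)
        geom_before = geometry.summarize_cohort(bl, br)
        geom_after = geometry.summarize_cohort(al, ar)
        geom_change = geometry.compare_adjustment(bl, br, al, ar)
        geom_before.to_csv(out / "geometry_before.csv", index=False)
        geom_after.to_csv(out / "geometry_after.csv", index=False)
        geom_change.to_csv(out / "geometry_change.csv", index=False)
        stage("geometry", n_measured=len(bl))

        summary = _write_summary(out, report_before, report_after, excluded, model.k)
        log["summary"] = summary
        (out / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
    except Exception:
        (out / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
        raise

    return RunResult(out_dir=out, dataset=list(dataset), adjusted=adjusted,
                     excluded_modes=excluded, mode_scores=score_df,
                     combined_retained=model.k,
                     report_before=report_before, report_after=report_after,
                     geometry_before=geom_before, geometry_after=geom_after,
                     geometry_change=geom_change, adjustment_effects=effects,
                     log=log)


def _write_summary(out: Path, before: symmetry.SymmetryReport,
                   after: symmetry.SymmetryReport, excluded: list[int],
                   combined_k: int) -> dict:
    summary = {
        "combined_retained_modes": combined_k,
        "excluded_modes": excluded,
        "mean_lr_distance_before_mm": round(before.mean_lr_distance, 1),
        "mean_lr_distance_after_mm": round(after.mean_lr_distance, 1),
        "single_model_modes_before": before.retained_modes,
        "single_model_modes_after": after.retained_modes,
        "bonferroni_alpha_before": before.bonferroni_alpha,
        "bonferroni_alpha_after": after.bonferroni_alpha,
    }
    lines = [
        "Proximal femur symmetry analysis",
        "================================",
        f"combined model: {combined_k} modes retained, "
        f"excluded oppositional modes: {excluded or 'none'}",
        f"mean left-right point-to-curve distance: "
        f"{summary['mean_lr_distance_before_mm']} mm before, "
        f"{summary['mean_lr_distance_after_mm']} mm after adjustment",
        f"single models: {before.retained_modes} modes before, "
        f"{after.retained_modes} after",
        f"Bonferroni per-mode alpha: {before.bonferroni_alpha:.4g} (before), "
        f"{after.bonferroni_alpha:.4g} (after)",
    ]
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
    return summary
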