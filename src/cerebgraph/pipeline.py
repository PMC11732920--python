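"""End-to-end orchestration: cohort -> QC -> denoise -> graphs -> statistics.

The pipeline mirrors a resting-state connectivity study design: subjects
enter an inclusion ledger (enrolled -> refused -> quality-excluded ->
motion-excluded -> analyzed), usable subjects are denoised and turned into
cost-thresholded graphs, nodal measures are compared between groups with a
covariate-adjusted GLM under FDR control, and estimated efficiency at the
altered nodes is correlated with cognitive scores within patients.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .connectivity import correlation_matrix, proportional_threshold
from .metrics import nodal_metrics_table, NODAL_METRICS
from .preprocess import DenoiseSettings, denoise_subject, qc_subject
from .stats import glm_group_comparison, demographics_tests, pearson_with_ci
from .synthetic import CohortConfig, simulate_cohort, write_cohort, read_cohort

log = logging.getLogger("cerebgraph")


@dataclass
class SubjectLedger:
    """Subject bookkeeping; analyzed = enrolled - sum of exclusions."""

    enrolled: int
    refused: int = 0
    quality_excluded: int = 0
    motion_excluded: int = 0

    def __post_init__(self):
        if min(self.enrolled, self.refused, self.quality_excluded,
               self.motion_excluded) < 0:
            raise ValueError("ledger counts must be non-negative")
        if self.analyzed < 0:
            raise ValueError("exclusions exceed enrolled subjects")

    @property
    def analyzed(self) -> int:
        return self.enrolled - self.refused - self.quality_excluded - self.motion_excluded

    def as_dict(self) -> dict:
        d = asdict(self)
        d["analyzed"] = self.analyzed
        return d


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    out_dir: str = "cerebgraph_out"
    in_dir: str | None = None           # ingest an existing cohort directory
    simulate: CohortConfig | None = None  # or simulate one
    settings: DenoiseSettings = field(default_factory=DenoiseSettings)
    cost: float = 0.20
    tr_seconds: float = 2.5
    fdr_family: str = "per_metric"
    metrics: tuple = NODAL_METRICS
    score_name: str = "verbal_memory"
    prior_exclusions: dict = field(default_factory=dict)  # e.g. {"refused": 2}
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.cost <= 1.0:
            raise ValueError("cost must lie in (0, 1]")
        if self.in_dir is None and self.simulate is None:
            raise ValueError("provide in_dir or a simulation config")


@dataclass
class RunManifest:
    config_hash: str
    version: str
    seed: int
    ledger: dict
    checksums: dict = field(default_factory=dict)

    def validate(self) -> None:
        led = self.ledger
        expected = (led["enrolled"] - led["refused"] - led["quality_excluded"]
                    - led["motion_excluded"])
        if led["analyzed"] != expected:
            raise ValueError("ledger counts do not conserve: "
                             f"analyzed {led['analyzed']} != {expected}")


@dataclass
class PipelineResult:
    qc: pd.DataFrame
    subjects: pd.DataFrame            # analyzed subjects incl. mean_rms + scores
    metrics_long: pd.DataFrame        # subject_id, label, metric, value
    group_comparison: pd.DataFrame
    correlations: pd.DataFrame
    demographics: dict
    ledger: SubjectLedger
    manifest: RunManifest | None = None


def analyze_cohort(records, settings: DenoiseSettings = DenoiseSettings(),
                   tr_seconds: float = 2.5, cost: float = 0.20,
                   metrics: tuple = NODAL_METRICS,
                   fdr_family: str = "per_metric",
                   score_name: str = "verbal_memory",
                   prior_exclusions: dict | None = None,
                   roi_labels=None) -> PipelineResult:
    """Run QC, denoising, graph construction and group statistics in memory.

    ``records`` are :class:`~cerebgraph.synthetic.SubjectRecord` objects
    (simulated or read from disk). Subjects failing motion QC are dropped
    before statistics; ``prior_exclusions`` (counts of subjects excluded
    before the data reached this pipeline, e.g. refusals or image-quality
    failures) only enter the ledger.
    """
    prior = prior_exclusions or {}
    qc_rows, subj_rows, metric_rows = [], [], []
    n_motion_excluded = 0
    for rec in records:
        clean, trimmed_motion, n_spikes = denoise_subject(
            rec.timeseries, rec.motion, rec.nuisance, tr_seconds, settings)
        report = qc_subject(trimmed_motion, settings, rec.subject_id, n_spikes)
        qc_rows.append({
            "subject_id": rec.subject_id, "group": rec.group,
            "mean_relative_rms": report.mean_relative_rms,
            "max_abs_translation": report.max_abs_translation,
            "max_abs_rotation": report.max_abs_rotation,
            "n_despiked_frames": report.n_despiked_frames,
            "excluded": report.excluded,
            "exclusion_reasons": "; ".join(report.exclusion_reasons),
        })
        if report.excluded:
            n_motion_excluded += 1
            log.info("excluding %s: %s", rec.subject_id,
                     "; ".join(report.exclusion_reasons))
            continue
        labels = roi_labels if roi_labels is not None else getattr(rec, "roi_labels", None)
        cm = correlation_matrix(clean, labels=labels)
        graph = proportional_threshold(cm, cost)
        table = nodal_metrics_table(graph)
        for label, row in table.iterrows():
            for m in metrics:
                metric_rows.append({"subject_id": rec.subject_id, "label": label,
                                    "metric": m, "value": float(row[m])})
        srow = {"subject_id": rec.subject_id, "group": rec.group,
                "age": rec.age, "sex": rec.sex,
                "mean_rms": report.mean_relative_rms}
        srow.update(rec.cognitive_scores)
        subj_rows.append(srow)

    qc = pd.DataFrame(qc_rows)
    subjects = pd.DataFrame(subj_rows)
    metrics_long = pd.DataFrame(metric_rows)
    ledger = SubjectLedger(
        enrolled=len(records) + sum(prior.values()),
        refused=prior.get("refused", 0),
        quality_excluded=prior.get("quality", 0),
        motion_excluded=n_motion_excluded,
    )
    comparison = glm_group_comparison(metrics_long, subjects, family=fdr_family)
    demo = demographics_tests(subjects)
    correlations = _behavior_correlations(metrics_long, subjects, comparison,
                                          score_name)
    return PipelineResult(qc=qc, subjects=subjects, metrics_long=metrics_long,
                          group_comparison=comparison, correlations=correlations,
                          demographics=demo, ledger=ledger)


def _behavior_correlations(metrics_long, subjects, comparison,
                           score_name) -> pd.DataFrame:
    """Exploratory Pearson correlations, within patients, between each
    significantly reduced node's global efficiency and the cognitive score."""
    if score_name not in subjects.columns:
        return pd.DataFrame(columns=["metric", "score", "label", "r", "n",
                                     "p_value", "ci_low", "ci_high"])
    sig = comparison[(comparison["q_value"] <= 0.05)
                     & (comparison["direction"] == "patients_lower")
                     & (comparison["metric"] == "global_efficiency")
                     & (comparison["label"] != "__network__")]
    patients = subjects[subjects["group"] == "patient"].set_index("subject_id")
    rows = []
    for label in sig["label"]:
        cell = metrics_long[(metrics_long["label"] == label)
                            & (metrics_long["metric"] == "global_efficiency")]
        cell = cell.set_index("subject_id").reindex(patients.index).dropna()
        scores = patients.loc[cell.index, score_name]
        if len(cell) < 4 or cell["value"].std() == 0 or scores.std() == 0:
            continue
        res = pearson_with_ci(cell["value"], scores,
                              metric="global_efficiency", score=score_name)
        rows.append({"metric": res.metric, "score": res.score, "label": label,
                     "r": res.r, "n": res.n, "p_value": res.p_value,
                     "ci_low": res.ci_low, "ci_high": res.ci_high})
    return pd.DataFrame(rows, columns=["metric", "score", "label", "r", "n",
                                       "p_value", "ci_low", "ci_high"])


def _config_hash(config: RunConfig) -> str:
    def default(o):
        if hasattr(o, "roi_labels"):
            return {"name": o.name, "roi_labels": list(o.roi_labels)}
        if hasattr(o, "__dict__"):
            return o.__dict__
        return str(o)
    blob = json.dumps(asdict(config) if not isinstance(config, dict) else config,
                      default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Full run with on-disk outputs and a reproducibility manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.simulate is not None:
        sim = config.simulate
        log.info("simulating cohort: %d patients, %d controls, %s",
                 sim.n_patients, sim.n_controls, sim.parcellation.name)
        records, truth = simulate_cohort(sim)
        write_cohort(records, truth, out / "cohort", sim)
        for rec in records:
            rec.roi_labels = list(sim.parcellation.roi_labels)
        tr = sim.tr_seconds
    else:
        records, roi_labels = read_cohort(config.in_dir)
        for rec in records:
            rec.roi_labels = roi_labels
        tr = config.tr_seconds

    result = analyze_cohort(records, config.settings, tr, config.cost,
                            config.metrics, config.fdr_family,
                            config.score_name, config.prior_exclusions)

    outputs = {
        "qc.tsv": result.qc,
        "subjects_analyzed.tsv": result.subjects,
        "nodal_metrics.tsv": result.metrics_long,
        "group_comparison.tsv": result.group_comparison,
        "correlations.tsv": result.correlations,
    }
    checksums = {}
    for name, frame in outputs.items():
        path = out / name
        frame.to_csv(path, sep="\t", index=False)
        checksums[name] = _checksum(path)
    manifest = RunManifest(config_hash=_config_hash(config), version=__version__,
                           seed=config.seed, ledger=result.ledger.as_dict(),
                           checksums=checksums)
    manifest.validate()
    (out / "manifest.json").write_text(
        json.dumps(asdict(manifest), indent=1, sort_keys=True))
    result.manifest = manifest
    return result


def report(result: PipelineResult) -> str:
    """Human-readable markdown summary of a completed run."""
    if result.manifest is not None:
        result.manifest.validate()
    led = result.ledger
    lines = ["# cerebgraph run summary", ""]
    lines += ["## Subject ledger",
              f"- enrolled: {led.enrolled}",
              f"- refused: {led.refused}",
              f"- quality-excluded: {led.quality_excluded}",
              f"- motion-excluded: {led.motion_excluded}",
              f"- analyzed: {led.analyzed}", ""]
    demo = result.demographics
    lines += ["## Demographics",
              f"- age: t = {demo['age_t']:.2f}, p = {demo['age_p']:.2f} "
              f"(Bartlett p = {demo['age_bartlett_p']:.2f})",
              f"- sex: chi-square = {demo['sex_chi2']:.2f}, p = {demo['sex_p']:.2f}", ""]
    sig = result.group_comparison[
        (result.group_comparison["q_value"] <= 0.05)
        & (result.group_comparison["label"] != "__network__")]
    lines.append("## Significant nodal differences (q <= 0.05)")
    if sig.empty:
        lines.append("- none")
    else:
        for _, row in sig.sort_values(["metric", "q_value"]).iterrows():
            lines.append(
                f"- {row['label']} / {row['metric']}: effect "
                f"{row['adjusted_group_difference']:+.3f} "
                f"(p = {row['p_value']:.3g}, q = {row['q_value']:.3g}, "
                f"{row['direction']})")
    lines.append("")
    lines.append("## Brain-behavior correlations (patients)")
    if result.correlations.empty:
        lines.append("- none computed")
    else:
        for _, row in result.correlations.iterrows():
            lines.append(
                f"- {row['label']} global efficiency vs {row['score']}: "
                f"r = {row['r']:.2f}, n = {row['n']}, p = {row['p_value']:.3g}, "
                f"CI = {row['ci_low']:.2f}-{row['ci_high']:.2f}")
    return "\n".join(lines) + "\n"
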