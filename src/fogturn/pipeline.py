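"""End-to-end study pipeline: simulate -> compute metrics -> annotate -> validate.

One call reproduces the structure of the validation study on a synthetic
cohort: the subgroup partition table, the per-metric classification table
(cutoff, sensitivity, specificity, AUC, AR, p) against four reference
classifications, and the Spearman correlation table of each metric against
%TF outcomes and the questionnaire total.  Every output embeds the seed and
a hash of the configuration; a rerun with the same configuration and seed is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotations import cohort_partition
from .estimators import METRIC_COLUMNS, FogIndexExtractor
from .simulate import CohortConfig, cohort_table, simulate_cohort
from .validation import roc_analysis, spearman

logger = logging.getLogger("fogturn.pipeline")

REFERENCE_GROUPS = ("clinical", "self_report", "aware", "unaware")


@dataclass(frozen=True)
class StudyConfig:
    """Single configuration object controlling every pipeline stage."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    window_s: float = 3.0
    overlap_fraction: float = 0.5
    squared_ratio: bool = False
    pool_shins: bool = True
    lowpass_hz: float | None = 1.5
    reversal_dwell_s: float = 0.5

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"].pop("base_phenotype", None)
        return d

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


@dataclass
class StudyRun:
    """All tables and provenance from one pipeline execution."""

    config: StudyConfig
    seed: int
    config_hash: str
    cohort: pd.DataFrame
    metrics: pd.DataFrame
    partition: pd.DataFrame
    classification: pd.DataFrame
    correlations: pd.DataFrame
    n_simulated: int
    n_excluded_zero_turns: int


class PipelineStageError(RuntimeError):
    """An error in a pipeline stage, tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _reference_frame(df: pd.DataFrame, reference: str) -> tuple[pd.DataFrame, pd.Series]:
    """Subset and binary labels for one reference classification.

    clinical: all subjects, positive = expert-rated freezer.
    self_report: all subjects, positive = questionnaire self-report.
    aware / unaware: that freezer subgroup vs the non-freezers.
    """
    if reference == "clinical":
        return df, df["expert_freezer"].astype(bool)
    if reference == "self_report":
        return df, df["self_report"].astype(bool)
    if reference in ("aware", "unaware"):
        sub = df[df["subgroup"].isin([reference, "non_freezer"])]
        return sub, (sub["subgroup"] == reference)
    raise ValueError(f"unknown reference {reference!r}; expected one of {REFERENCE_GROUPS}")


def _classification_table(df: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for reference in REFERENCE_GROUPS:
        sub, labels = _reference_frame(df, reference)
        n_pos = int(labels.sum())
        n_neg = int((~labels).sum())
        if n_pos == 0 or n_neg == 0:
            raise PipelineStageError(
                "validate",
                f"reference {reference!r} has a single class "
                f"({n_pos} positives, {n_neg} negatives); ROC undefined",
            )
        for metric in METRIC_COLUMNS:
            roc = roc_analysis(sub[metric].to_numpy(), labels.to_numpy())
            rows.append(
                {
                    "reference": reference,
                    "metric": metric,
                    "n_pos": n_pos,
                    "n_neg": n_neg,
                    "cutoff": roc.cutoff,
                    "sensitivity_pct": 100.0 * roc.sens_at_cutoff,
                    "specificity_pct": 100.0 * roc.spec_at_cutoff,
                    "auc": roc.auc,
                    "accuracy_rate": roc.accuracy_rate,
                    "p_value": roc.auc_p,
                }
            )
    return pd.DataFrame(rows)


def _correlation_table(df: pd.DataFrame) -> pd.DataFrame:
    groups = {
        "all": df,
        "expert_freezers": df[df["expert_freezer"] == 1],
        "self_reported": df[df["self_report"] == 1],
    }
    outcomes = {
        "tf_total_pct": "%TF all",
        "tf_trembling_pct": "%TF trembling",
        "tf_akinetic_pct": "%TF akinetic",
        "nfogq_total": "NFOGQ",
    }
    rows = []
    for gname, gdf in groups.items():
        for metric in METRIC_COLUMNS:
            for col, outcome in outcomes.items():
                if len(gdf) < 3:
                    continue
                res = spearman(gdf[metric].to_numpy(), gdf[col].to_numpy())
                rows.append(
                    {
                        "group": gname,
                        "metric": metric,
                        "outcome": outcome,
                        "rho": res.rho,
                        "p_value": res.p,
                        "n": res.n,
                        "constant_input": res.constant_input,
                    }
                )
    return pd.DataFrame(rows)


def run_study(config: StudyConfig | None = None) -> StudyRun:
    """Execute the full synthetic study and return all result tables."""
    config = config or StudyConfig()
    try:
        cohort = simulate_cohort(config.cohort)
    except ValueError as exc:
        raise PipelineStageError("simulate", str(exc)) from exc
    logger.info("simulate: %d subjects generated", len(cohort))

    records = [rec for rec, _t, _g in cohort]
    trials = [t for _rec, t, _g in cohort]
    cohort_df = cohort_table(cohort)

    try:
        extractor = FogIndexExtractor(
            window_s=config.window_s,
            overlap_fraction=config.overlap_fraction,
            squared_ratio=config.squared_ratio,
            pool_shins=config.pool_shins,
            lowpass_hz=config.lowpass_hz,
            reversal_dwell_s=config.reversal_dwell_s,
            on_zero_turns="drop",
        ).fit(trials)
        metrics = extractor.transform(trials)
    except ValueError as exc:
        raise PipelineStageError("compute", str(exc)) from exc

    excluded = metrics[metrics["n_turns"] == 0].index.tolist()
    if excluded:
        logger.info(
            "compute: excluding %d subject(s) with zero completed turns: %s",
            len(excluded), excluded,
        )
    metrics = metrics[metrics["n_turns"] > 0]
    logger.info("compute: %d -> %d subjects after exclusions", len(trials), len(metrics))

    df = cohort_df.set_index("subject_id").join(metrics, how="inner").reset_index()

    try:
        partition = cohort_partition([r for r in records if r.subject_id in set(metrics.index)])
        classification = _classification_table(df)
        correlations = _correlation_table(df)
    except PipelineStageError:
        raise
    except ValueError as exc:
        raise PipelineStageError("validate", str(exc)) from exc

    return StudyRun(
        config=config,
        seed=config.cohort.seed,
        config_hash=config.config_hash(),
        cohort=cohort_df,
        metrics=metrics.reset_index(),
        partition=partition,
        classification=classification,
        correlations=correlations,
        n_simulated=len(cohort),
        n_excluded_zero_turns=len(excluded),
    )


def make_report(run: StudyRun) -> str:
    """Render the three study tables and provenance as plain text."""
    lines = [
        f"fogturn {__version__} study report",
        f"seed: {run.seed}   config hash: {run.config_hash}",
        f"subjects simulated: {run.n_simulated}   "
        f"excluded (zero completed turns): {run.n_excluded_zero_turns}   "
        f"analyzed: {run.n_simulated - run.n_excluded_zero_turns}",
        "",
        "== Subgroup partition ==",
        run.partition.to_string(index=False, float_format=lambda v: f"{v:.1f}"),
        "",
        "== Classification (cutoff, sensitivity, specificity, AUC, AR, p) ==",
        run.classification.to_string(index=False, float_format=lambda v: f"{v:.3f}"),
        "",
        "== Spearman correlations vs %TF and NFOGQ ==",
        run.correlations.to_string(index=False, float_format=lambda v: f"{v:.3f}"),
        "",
    ]
    return "\n".join(lines)


def write_outputs(run: StudyRun, out_dir) -> dict[str, Path]:
    """Write all study tables plus the text report; returns written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, frame in (
        ("cohort", run.cohort),
        ("metrics", run.metrics),
        ("partition", run.partition),
        ("classification", run.classification),
        ("correlations", run.correlations),
    ):
        p = out / f"{name}.csv"
        with open(p, "w", newline="") as fh:
            fh.write(f"# fogturn {__version__} seed={run.seed} config={run.config_hash}\n")
            frame.to_csv(fh, index=False, float_format="%.9g")
        paths[name] = p
    report_path = out / "report.txt"
    report_path.write_text(make_report(run))
    paths["report"] = report_path
    return paths
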